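"""Synthetic time-lapse microscopy sequences with exact ground truth.

The generator emulates the data challenges the pipeline is designed for:
elliptical cells of random orientation and size undergoing Brownian-like
displacement, scheduled mitosis events (one mother replaced by two half-area
daughters displaced along the elongation axis), frame rendering with a 1-px
blur, additive Gaussian noise, and signal-dependent noise — so the
contrast-to-noise ratio varies with intensity, as in real fluorescence
imaging. Every frame comes with an exact label mask, a lineage table, and
per-pixel ground-truth motion, making each pipeline stage testable without
external data.

It does not model the optics (PSF tails, vignetting, photobleaching) or
cell-shape dynamics beyond rigid motion of ellipses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .io_ctc import (
    TrackFileRecord,
    write_label_masks,
    write_sequence,
    write_track_file,
)
from .motion import MotionField


@dataclass
class SimulationConfig:
    """Study conditions for one simulated sequence.

    Defaults describe a moderately noisy fluorescence-like recording of
    radius-6 px nuclei with ~1 px/frame Brownian motion and two divisions.
    """

    shape: tuple[int, int] = (128, 128)
    n_frames: int = 20
    n_cells: int = 8
    radius_mean: float = 6.0
    radius_sd: float = 1.0
    contrast: float = 0.5          # cell minus background intensity, [0,1] units
    background: float = 0.2
    noise_sd: float = 0.03         # additive Gaussian noise
    noise_gain: float = 0.02       # signal-dependent term: gain*sqrt(I)*N(0,1)
    motion_sd: float = 1.0         # Brownian step per frame (px)
    divisions: list[tuple[int, int]] = field(
        default_factory=lambda: [(1, 7), (4, 13)])  # (cell label, frame)
    elongation: float = 1.4
    blur_sigma: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        H, W = self.shape
        rmax = (self.radius_mean + 3 * self.radius_sd) * np.sqrt(self.elongation)
        if 2 * rmax + 4 > min(H, W):
            raise ValueError("cells too large for the frame")
        for lab, t in self.divisions:
            if t < 1 or t >= self.n_frames:
                raise ValueError(f"division of cell {lab} at invalid frame {t}")
        for name in ("radius_mean", "contrast", "elongation", "blur_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if min(self.noise_sd, self.noise_gain, self.motion_sd,
               self.radius_sd) < 0:
            raise ValueError("noise/motion parameters must be non-negative")


@dataclass
class _Cell:
    label: int
    center: np.ndarray            # (row, col), float
    radius: float
    theta: float
    elong: float
    birth: int
    parent: int = 0

    @property
    def axes(self) -> tuple[float, float]:
        return (self.radius * np.sqrt(self.elong),
                self.radius / np.sqrt(self.elong))


@dataclass
class SimulationResult:
    frames: np.ndarray                     # (T, H, W) float
    masks: list[np.ndarray]                # int label maps
    lineage: list[TrackFileRecord]
    motion_fields: list[MotionField]       # T-1 fields, frame t -> t+1
    config: SimulationConfig


def _rho2(cell: _Cell, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Squared normalized elliptical radius (<=1 inside the cell)."""
    a, b = cell.axes
    dr = rows - cell.center[0]
    dc = cols - cell.center[1]
    ca, sa = np.cos(cell.theta), np.sin(cell.theta)
    x = dc * ca + dr * sa
    y = -dc * sa + dr * ca
    return (x / a) ** 2 + (y / b) ** 2


def _render_mask(cells: list[_Cell], shape: tuple[int, int]) -> np.ndarray:
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    best = np.full(shape, np.inf)
    mask = np.zeros(shape, dtype=np.int64)
    for cell in cells:
        r2 = _rho2(cell, rows, cols)
        take = (r2 <= 1.0) & (r2 < best)   # overlap -> nearest normalized center
        mask[take] = cell.label
        best = np.where(take, r2, best)
    return mask


def _clamp_center(center: np.ndarray, cell_rmax: float,
                  shape: tuple[int, int]) -> np.ndarray:
    lo = cell_rmax + 1.0
    return np.clip(center, [lo, lo],
                   [shape[0] - 1 - lo, shape[1] - 1 - lo])


def _separate(cells: list[_Cell], shape, iters: int = 8) -> None:
    """Hard-core repulsion: cells may touch (1 px gap) but never
    interpenetrate, as physical nuclei would."""
    for _ in range(iters):
        moved = False
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                ci, cj = cells[i], cells[j]
                d = cj.center - ci.center
                dist = float(np.hypot(*d))
                min_d = max(ci.axes) + max(cj.axes) + 1.0
                if dist < min_d:
                    push = (d / dist if dist > 1e-9
                            else np.array([1.0, 0.0])) * (min_d - dist) / 2
                    ci.center = _clamp_center(ci.center - push, max(ci.axes), shape)
                    cj.center = _clamp_center(cj.center + push, max(cj.axes), shape)
                    moved = True
        if not moved:
            return


def simulate_sequence(cfg: SimulationConfig) -> SimulationResult:
    """Generate one sequence with masks, lineage, and ground-truth motion.

    Fully deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.shape

    # ---- initial population: non-overlapping at birth -------------------- #
    cells: list[_Cell] = []
    next_label = 1
    attempts = 0
    while len(cells) < cfg.n_cells:
        attempts += 1
        if attempts > 2000:
            raise ValueError("could not place cells without overlap")
        radius = max(2.0, rng.normal(cfg.radius_mean, cfg.radius_sd))
        theta = rng.uniform(0, np.pi)
        cand = _Cell(label=next_label,
                     center=np.array([rng.uniform(0, H), rng.uniform(0, W)]),
                     radius=radius, theta=theta, elong=cfg.elongation, birth=0)
        cand.center = _clamp_center(cand.center, max(cand.axes), (H, W))
        if all(np.hypot(*(cand.center - c.center))
               > max(cand.axes) + max(c.axes) + 2.0 for c in cells):
            cells.append(cand)
            next_label += 1

    birth = {c.label: 0 for c in cells}
    death: dict[int, int] = {}
    parent = {c.label: 0 for c in cells}
    division_at = {lab: t for lab, t in cfg.divisions}

    masks: list[np.ndarray] = []
    clean_frames: list[np.ndarray] = []
    fields: list[MotionField] = []
    prev_mask: np.ndarray | None = None
    prev_centers: dict[int, np.ndarray] = {}

    for t in range(cfg.n_frames):
        if t > 0:
            # divisions scheduled for this frame
            for lab, tf in division_at.items():
                if tf != t:
                    continue
                mother = next((c for c in cells if c.label == lab), None)
                if mother is None:
                    continue
                cells.remove(mother)
                death[lab] = t - 1
                a, _ = mother.axes
                axis = np.array([np.sin(mother.theta), np.cos(mother.theta)])
                r_d = mother.radius / np.sqrt(2.0)  # half-area daughters
                for sign in (+1.0, -1.0):
                    d = _Cell(
                        label=next_label,
                        center=_clamp_center(
                            mother.center + sign * 0.8 * a * axis, r_d, (H, W)),
                        radius=r_d,
                        theta=rng.uniform(0, np.pi),
                        elong=cfg.elongation, birth=t, parent=lab)
                    cells.append(d)
                    birth[next_label] = t
                    parent[next_label] = lab
                    next_label += 1
            # Brownian step
            for c in cells:
                c.center = _clamp_center(
                    c.center + rng.normal(0.0, cfg.motion_sd, 2),
                    max(c.axes), (H, W))
            _separate(cells, (H, W))

        mask = _render_mask(cells, (H, W))
        masks.append(mask)
        indicator = (mask > 0).astype(np.float64)
        clean = cfg.background + cfg.contrast * ndi.gaussian_filter(
            indicator, cfg.blur_sigma, mode="nearest")
        clean_frames.append(clean)

        centers = {c.label: c.center.copy() for c in cells}
        if prev_mask is not None:
            u = np.zeros((H, W))
            v = np.zeros((H, W))
            for lab, prev_c in prev_centers.items():
                region = prev_mask == lab
                if lab in centers:
                    dvec = centers[lab] - prev_c
                elif lab in division_at and division_at[lab] == t:
                    kids = [c for c in cells if c.parent == lab]
                    dvec = (np.mean([c.center for c in kids], axis=0) - prev_c
                            if kids else np.zeros(2))
                else:
                    dvec = np.zeros(2)
                v[region] = dvec[0]
                u[region] = dvec[1]
            fields.append(MotionField(u=u, v=v))
        prev_mask, prev_centers = mask, centers

    # noise: additive Gaussian + signal-dependent
    frames = np.stack(clean_frames)
    if cfg.noise_sd > 0:
        frames = frames + rng.normal(0.0, cfg.noise_sd, frames.shape)
    if cfg.noise_gain > 0:
        frames = frames + cfg.noise_gain * np.sqrt(
            np.maximum(np.stack(clean_frames), 0.0)
        ) * rng.normal(0.0, 1.0, frames.shape)
    frames = np.clip(frames, 0.0, 1.0)

    lineage = [
        TrackFileRecord(lab, birth[lab], death.get(lab, cfg.n_frames - 1),
                        parent[lab])
        for lab in sorted(birth)
    ]
    return SimulationResult(frames=frames, masks=masks, lineage=lineage,
                            motion_fields=fields, config=cfg)


def measure_cnr(result: SimulationResult) -> float:
    """Mean contrast-to-noise ratio: (mean cell - mean bg) / std(bg)."""
    vals = []
    for frame, mask in zip(result.frames, result.masks):
        cell = frame[mask > 0]
        bg = frame[mask == 0]
        if cell.size and bg.size and bg.std() > 0:
            vals.append((cell.mean() - bg.mean()) / bg.std())
    return float(np.mean(vals))


def default_fixture(
    noisy: bool = True, seed: int = 0
) -> dict[str, SimulationResult]:
    """The benchmark pair: sequences "01" and "02" with distinct seeds.

    Two 128x128, 20-frame sequences of 8 initial cells with 2 divisions
    each; ``noisy=False`` switches off both noise terms for the noise-free
    variant. ``seed`` offsets both sequence seeds so independent replicates
    can be drawn.
    """
    out = {}
    for name, offset in (("01", 101), ("02", 202)):
        cfg = SimulationConfig(seed=seed + offset)
        if not noisy:
            cfg.noise_sd = 0.0
            cfg.noise_gain = 0.0
        out[name] = simulate_sequence(cfg)
    return out


def write_ctc_layout(result: SimulationResult, root: str | Path,
                     name: str = "01") -> None:
    """Write a simulation in the challenge directory layout:
    ``{name}/tNNN.tif`` frames and ``{name}_GT/{SEG,TRA}`` references."""
    root = Path(root)
    write_sequence(result.frames, root / name, prefix="t")
    write_label_masks(result.masks, root / f"{name}_GT" / "SEG",
                      prefix="man_seg")
    write_label_masks(result.masks, root / f"{name}_GT" / "TRA",
                      prefix="man_track")
    write_track_file(result.lineage, root / f"{name}_GT" / "TRA" / "man_track.txt")
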