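"""Reading/writing time-lapse sequences, label masks and track files.

The on-disk layout follows the Cell Tracking Challenge conventions: a
directory of per-frame TIFFs (or a single multi-page TIFF) for intensities,
16-bit label TIFFs for masks, and a plain-text track file with one
``label begin end parent`` line per track.

Coordinate convention throughout the package: row-major ``(row, col)``,
0-based; frame indices are 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #

@dataclass
class SequenceHandle:
    """An ordered stack of 2D grayscale frames scaled to [0, 1].

    Normalization is sequence-level min-max (a single affine map for the whole
    stack), so frame-to-frame contrast variation — which the downstream
    scale-selection stage is designed to absorb — is preserved.
    """

    frames: np.ndarray                  # (T, H, W) float64 in [0, 1]
    frame_ids: list[int] = field(default_factory=list)
    pixel_spacing: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")
        if self.frames.shape[0] < 2:
            raise ValueError("a sequence needs at least 2 frames")
        if not self.frame_ids:
            self.frame_ids = list(range(self.frames.shape[0]))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def __len__(self) -> int:
        return self.n_frames


@dataclass(frozen=True)
class TrackFileRecord:
    """One track line ``L B E P``: label, begin frame, end frame, parent."""

    label: int
    begin_frame: int
    end_frame: int
    parent_label: int = 0

    def __post_init__(self) -> None:
        if self.label <= 0:
            raise ValueError(f"track label must be positive, got {self.label}")
        if self.parent_label < 0:
            raise ValueError("parent label must be non-negative")
        if self.begin_frame > self.end_frame:
            raise ValueError(
                f"track {self.label}: begin {self.begin_frame} > end {self.end_frame}"
            )
        if self.parent_label == self.label:
            raise ValueError(f"track {self.label} cannot be its own parent")


def validate_track_records(records: Sequence[TrackFileRecord]) -> None:
    """Check cross-record invariants (parent ends before child begins)."""
    by_label = {}
    for rec in records:
        if rec.label in by_label:
            raise ValueError(f"duplicate track label {rec.label}")
        by_label[rec.label] = rec
    for rec in records:
        if rec.parent_label:
            parent = by_label.get(rec.parent_label)
            if parent is None:
                raise ValueError(
                    f"track {rec.label}: unknown parent {rec.parent_label}"
                )
            if parent.end_frame >= rec.begin_frame:
                raise ValueError(
                    f"track {rec.label}: parent {parent.label} ends at frame "
                    f"{parent.end_frame}, not before child begins at {rec.begin_frame}"
                )


# --------------------------------------------------------------------------- #
# sequences
# --------------------------------------------------------------------------- #

_IMAGE_SUFFIXES = {".tif", ".tiff", ".png"}


def _read_frames(path: Path) -> list[np.ndarray]:
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise FileNotFoundError(f"no image frames found in {path}")
        return [np.asarray(tifffile.imread(str(p))) for p in files]
    if not path.exists():
        raise FileNotFoundError(str(path))
    stack = np.asarray(tifffile.imread(str(path)))
    if stack.ndim == 2:
        return [stack]
    return [stack[i] for i in range(stack.shape[0])]


def read_sequence(path: str | Path) -> SequenceHandle:
    """Read an ordered stack of grayscale frames from a directory or
    multi-page TIFF and min-max scale intensities to [0, 1] per sequence.
    """
    frames = _read_frames(Path(path))
    if len(frames) < 2:
        raise ValueError(f"sequence at {path} has fewer than 2 frames")
    shape = frames[0].shape
    for i, fr in enumerate(frames):
        if fr.ndim != 2:
            raise ValueError(f"frame {i} is not 2D grayscale (shape {fr.shape})")
        if fr.shape != shape:
            raise ValueError(
                f"frame {i} shape {fr.shape} differs from frame 0 shape {shape}"
            )
    stack = np.stack(frames).astype(np.float64)
    lo, hi = stack.min(), stack.max()
    if hi > lo:
        stack = (stack - lo) / (hi - lo)
    else:
        stack = np.zeros_like(stack)
    return SequenceHandle(frames=stack)


def write_sequence(frames: np.ndarray | Sequence[np.ndarray], path: str | Path,
                   prefix: str = "t") -> None:
    """Write intensity frames as per-frame 16-bit TIFFs ``{prefix}NNN.tif``.

    Float input is scaled from its [min, max] onto the full 16-bit range.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    stack = np.stack([np.asarray(f) for f in frames])
    if np.issubdtype(stack.dtype, np.floating):
        lo, hi = stack.min(), stack.max()
        scale = 65535.0 / (hi - lo) if hi > lo else 0.0
        stack = np.round((stack - lo) * scale).astype(np.uint16)
    for t in range(stack.shape[0]):
        tifffile.imwrite(str(out / f"{prefix}{t:03d}.tif"), stack[t])


# --------------------------------------------------------------------------- #
# label masks
# --------------------------------------------------------------------------- #

def write_label_masks(labelmaps: Sequence[np.ndarray], path: str | Path,
                      prefix: str = "mask") -> None:
    """Write per-frame 16-bit label masks, zero-padded frame index in name."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    for t, lab in enumerate(labelmaps):
        lab = np.asarray(lab)
        if lab.min() < 0:
            raise ValueError(f"frame {t}: negative labels are invalid")
        if lab.max() > 65535:
            raise ValueError(
                f"frame {t}: label {int(lab.max())} exceeds 16-bit range"
            )
        tifffile.imwrite(str(out / f"{prefix}{t:03d}.tif"), lab.astype(np.uint16))


def read_label_masks(path: str | Path, prefix: str | None = None) -> list[np.ndarray]:
    """Read all 16-bit label masks in a directory, in frame order."""
    root = Path(path)
    files = sorted(
        p for p in root.iterdir()
        if p.suffix.lower() in {".tif", ".tiff"}
        and (prefix is None or p.name.startswith(prefix))
    )
    if not files:
        raise FileNotFoundError(f"no label masks found in {root}")
    return [np.asarray(tifffile.imread(str(p))).astype(np.int64) for p in files]


# --------------------------------------------------------------------------- #
# track files
# --------------------------------------------------------------------------- #

def write_track_file(records: Sequence[TrackFileRecord], path: str | Path) -> None:
    """Serialize track records as sorted ``L B E P`` lines."""
    validate_track_records(records)
    lines = [
        f"{r.label} {r.begin_frame} {r.end_frame} {r.parent_label}"
        for r in sorted(records, key=lambda r: r.label)
    ]
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_track_file(path: str | Path) -> list[TrackFileRecord]:
    """Parse an ``L B E P`` track file back into records."""
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 integers, got {line!r}")
        lab, b, e, p = (int(x) for x in parts)
        records.append(TrackFileRecord(lab, b, e, p))
    validate_track_records(records)
    return records
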