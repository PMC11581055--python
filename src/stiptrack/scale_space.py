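"""Nonlinear spatio-temporal scale space by anisotropic diffusion.

Each frame is diffused jointly with its two temporal neighbors: a 3-slab
volume ``L(tau, i, j)`` with ``tau in {t-1, t, t+1}`` evolves under
Perona-Malik diffusion over the three coupled slices,

    dL/ds = div( g(|grad L|) grad L ),

discretized with an explicit scheme on the 6-neighborhood (2 spatial + 1
temporal axis), reflecting (Neumann) boundaries. Edges — spatial cell
boundaries as well as temporal discontinuities caused by cell motion — stop
the diffusion, so cell structure survives to coarser scales while noise is
removed, which is what the downstream automatic scale selection exploits.

Slab axis order is ``(tau, row, col)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: spatial+temporal dimensionality of the diffusion grid
_NDIM = 3
#: explicit-scheme stability bound: step <= 1/(2 d)
MAX_STABLE_STEP = 1.0 / (2 * _NDIM)


def conductance(gradmag: np.ndarray, k: float, form: str = "exponential") -> np.ndarray:
    """Edge-stopping function g(|grad L|) in (0, 1].

    ``exponential`` is the Perona-Malik g(x) = exp(-(x/k)^2) (favors
    high-contrast edges); ``rational`` is 1/(1+(x/k)^2); ``constant`` gives
    linear (Gaussian) diffusion and is used for the linear-limit checks.
    """
    if k <= 0:
        raise ValueError(f"conductance k must be positive, got {k}")
    gradmag = np.asarray(gradmag, dtype=np.float64)
    if form == "exponential":
        return np.exp(-((gradmag / k) ** 2))
    if form == "rational":
        return 1.0 / (1.0 + (gradmag / k) ** 2)
    if form == "constant":
        return np.ones_like(gradmag)
    raise ValueError(f"unknown conductance form {form!r}")


@dataclass
class ScaleSpace:
    """Stack of progressively diffused 3-slab volumes.

    ``maps[0]`` is the input (zero diffusion time); ``maps[s]`` is the
    diffusion of ``maps[s-1]`` by one time increment.
    """

    maps: np.ndarray                        # (S, 3, H, W)
    scale_params: list[float] = field(default_factory=list)  # cumulative time
    conductance_k: float = 0.0

    @property
    def n_scales(self) -> int:
        return self.maps.shape[0]

    def central(self, s: int) -> np.ndarray:
        """The central (tau = t) slab at scale index ``s``."""
        return self.maps[s, 1]


def _neighbor_diffs(vol: np.ndarray) -> list[np.ndarray]:
    """Forward/backward differences toward each of the 6 neighbors, with
    reflecting boundaries (difference 0 across the border)."""
    diffs = []
    for axis in range(vol.ndim):
        fwd = np.zeros_like(vol)
        bwd = np.zeros_like(vol)
        sl_all = [slice(None)] * vol.ndim
        sl_lo, sl_hi = list(sl_all), list(sl_all)
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        fwd[tuple(sl_lo)] = vol[tuple(sl_hi)] - vol[tuple(sl_lo)]
        bwd[tuple(sl_hi)] = vol[tuple(sl_lo)] - vol[tuple(sl_hi)]
        diffs.append(fwd)
        diffs.append(bwd)
    return diffs


def _diffusion_step(vol: np.ndarray, step: float, k: float, form: str) -> np.ndarray:
    flux = np.zeros_like(vol)
    for d in _neighbor_diffs(vol):
        flux += conductance(np.abs(d), k, form) * d
    return vol + step * flux


def estimate_conductance_k(vol: np.ndarray, percentile: float = 90.0) -> float:
    """Per-triplet conductance scale: the 90th percentile of |grad L|."""
    grads = np.gradient(vol)
    gradmag = np.sqrt(sum(g * g for g in grads))
    k = float(np.percentile(gradmag, percentile))
    return k if k > 0 else 1.0


def frame_triplet(seq, t: int) -> np.ndarray:
    """Stack frames ``t-1, t, t+1`` as a (3, H, W) slab.

    At sequence boundaries the missing neighbor is replicated.
    """
    frames = seq.frames if hasattr(seq, "frames") else np.asarray(seq)
    T = frames.shape[0]
    if not 0 <= t < T:
        raise IndexError(f"frame index {t} out of range [0, {T})")
    idx = [max(t - 1, 0), t, min(t + 1, T - 1)]
    return np.stack([frames[i] for i in idx]).astype(np.float64)


def diffuse_triplet(
    triplet: np.ndarray,
    n_scales: int = 8,
    step: float = 0.15,
    conductance_k: float | None = None,
    conductance_form: str = "exponential",
    steps_per_scale: int = 1,
) -> ScaleSpace:
    """Build the nonlinear scale space of one 3-frame slab.

    Parameters
    ----------
    triplet:
        (3, H, W) stack of a frame and its temporal neighbors.
    n_scales:
        Number of scale levels S >= 3 (level 0 is the undiffused input).
    step:
        Explicit diffusion time step; must satisfy ``step <= 1/6`` for
        stability (maximum principle).
    conductance_k:
        Edge-stopping scale; ``None`` estimates it as the 90th percentile of
        the triplet's gradient magnitude.
    steps_per_scale:
        Explicit iterations forming one scale increment.
    """
    vol = np.asarray(triplet, dtype=np.float64)
    if vol.ndim != 3 or vol.shape[0] != 3:
        raise ValueError(f"triplet must be a (3, H, W) stack, got {vol.shape}")
    if not np.all(np.isfinite(vol)):
        raise ValueError("non-finite values in input triplet")
    if n_scales < 3:
        raise ValueError(f"need at least 3 scales, got {n_scales}")
    if step <= 0 or step > MAX_STABLE_STEP + 1e-12:
        raise ValueError(
            f"step {step} unstable for the explicit scheme (max {MAX_STABLE_STEP:.4f})"
        )
    if steps_per_scale < 1:
        raise ValueError("steps_per_scale must be >= 1")
    k = conductance_k if conductance_k is not None else estimate_conductance_k(vol)

    maps = np.empty((n_scales,) + vol.shape, dtype=np.float64)
    maps[0] = vol
    times = [0.0]
    for s in range(1, n_scales):
        cur = maps[s - 1]
        for _ in range(steps_per_scale):
            cur = _diffusion_step(cur, step, k, conductance_form)
        maps[s] = cur
        times.append(times[-1] + step * steps_per_scale)
    return ScaleSpace(maps=maps, scale_params=times, conductance_k=k)
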