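"""Dense motion estimation by combined local/global optical flow (CLG).

The data term is the structure tensor of the brightness-constancy gradient
integrated over a rho-neighborhood (local, Lucas-Kanade style); the
regularizer is Horn-Schunck global smoothness with weight alpha. The
Euler-Lagrange system is solved by Jacobi-style fixed-point iteration; an
outer warping loop re-linearizes brightness constancy around the current
estimate so integer displacements of a few pixels are recovered on a single
pyramid level (cell displacements are small relative to frame size).

Flow convention: ``u`` is the column (x) displacement, ``v`` the row (y)
displacement, mapping a pixel of the prior frame t to frame t+1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi


@dataclass
class MotionField:
    """Per-pixel displacement (pixels) from the prior to the current frame."""

    u: np.ndarray   # column / x component
    v: np.ndarray   # row / y component

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        self.v = np.asarray(self.v, dtype=np.float64)
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must share a shape")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


def _avg(f: np.ndarray) -> np.ndarray:
    """4-neighbor mean with reflecting boundaries (Jacobi neighborhood)."""
    kernel = np.array([[0.0, 0.25, 0.0], [0.25, 0.0, 0.25], [0.0, 0.25, 0.0]])
    return ndi.correlate(f, kernel, mode="nearest")


def _warp_image(img: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    rows, cols = np.mgrid[0 : img.shape[0], 0 : img.shape[1]].astype(np.float64)
    return ndi.map_coordinates(img, [rows + v, cols + u], order=1,
                               mode="nearest")


def clgof(
    prior: np.ndarray,
    current: np.ndarray,
    alpha: float | None = None,
    rho: float = 2.0,
    n_iters: int = 200,
    n_warps: int = 3,
    tol: float = 1e-4,
) -> MotionField:
    """Estimate dense flow from ``prior`` (frame t) to ``current`` (t+1).

    Parameters
    ----------
    alpha:
        Global smoothness weight; ``None`` uses ``(0.05 * intensity range)^2``.
    rho:
        Gaussian integration scale (px) of the local structure-tensor term.
    n_iters:
        Jacobi iterations per warp; iteration stops early once the mean
        update falls below ``tol`` pixels.
    n_warps:
        Outer re-linearization (warping) steps.
    """
    prior = np.asarray(prior, dtype=np.float64)
    current = np.asarray(current, dtype=np.float64)
    if prior.shape != current.shape:
        raise ValueError(f"frame shapes differ: {prior.shape} vs {current.shape}")
    if alpha is None:
        rng_i = max(prior.max(), current.max()) - min(prior.min(), current.min())
        alpha = (0.05 * rng_i) ** 2 if rng_i > 0 else 0.05**2
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if rho < 0:
        raise ValueError("rho must be non-negative")

    u = np.zeros_like(prior)
    v = np.zeros_like(prior)
    for _ in range(max(1, n_warps)):
        warped = _warp_image(current, u, v)
        Ix = 0.5 * (np.gradient(prior, axis=1) + np.gradient(warped, axis=1))
        Iy = 0.5 * (np.gradient(prior, axis=0) + np.gradient(warped, axis=0))
        It = warped - prior

        def integ(p):
            return ndi.gaussian_filter(p, rho, mode="nearest") if rho > 0 else p

        J11 = integ(Ix * Ix)
        J22 = integ(Iy * Iy)
        J12 = integ(Ix * Iy)
        J13 = integ(Ix * It)
        J23 = integ(Iy * It)

        du = np.zeros_like(u)
        dv = np.zeros_like(v)
        c = 4.0 * alpha
        for _ in range(n_iters):
            du_bar = _avg(du)
            dv_bar = _avg(dv)
            du_new = (c * du_bar - J12 * dv_bar - J13) / (c + J11)
            dv_new = (c * dv_bar - J12 * du_bar - J23) / (c + J22)
            delta = np.mean(np.abs(du_new - du) + np.abs(dv_new - dv))
            du, dv = du_new, dv_new
            if delta < tol:
                break
        u = u + du
        v = v + dv
    return MotionField(u=u, v=v)


def warp_labels(prior_labels: np.ndarray, field: MotionField) -> np.ndarray:
    """Transport a label map along the flow with nearest-neighbor scatter.

    Labels are categorical, so each labeled pixel is moved to its rounded
    target location; pixels pushed outside the frame are dropped. The output
    label set is always a subset of the input's.
    """
    labels = np.asarray(prior_labels)
    if labels.shape != field.u.shape:
        raise ValueError("label map and motion field shapes differ")
    out = np.zeros_like(labels)
    rows, cols = np.nonzero(labels)
    if rows.size == 0:
        return out
    tr = np.rint(rows + field.v[rows, cols]).astype(np.int64)
    tc = np.rint(cols + field.u[rows, cols]).astype(np.int64)
    ok = (tr >= 0) & (tr < labels.shape[0]) & (tc >= 0) & (tc < labels.shape[1])
    out[tr[ok], tc[ok]] = labels[rows[ok], cols[ok]]
    return out
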