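"""Spatio-temporal interest-point detectors and regional-maxima extraction.

Three detector responses are computed on a diffused 3-slab volume
``L(tau, row, col)`` and evaluated on the central slab:

* ``moments`` — 3D extension of the Harris corner criterion: the structure
  tensor M of smoothed first-derivative products, scored as
  ``S = det(M) - kappa * trace(M)^3``.
* ``hessian_st`` — the 3x3 space-time Hessian of second derivatives, scored
  as ``S = |det(H)|`` (a blob detector).
* ``hessian_temporal`` — the 2x2 spatial Hessian of the first-order temporal
  derivative L_t, scored as ``S = |det(H_t)|``; responds only to moving
  structure.

Derivatives are central finite differences on the diffused maps — diffusion
already regularizes each scale, so no extra derivative kernels are applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import local_maxima


@dataclass
class ResponseMap:
    """Detector strength S over the central slab of a scale level."""

    S: np.ndarray
    detector: str
    scale_index: int = 0
    sigma_i: float = 0.0
    tau_i: float = 0.0


@dataclass
class InterestPointSet:
    """Regional-maxima loci of a response map, with their strengths."""

    points: np.ndarray      # (n, 2) int array of (row, col)
    strengths: np.ndarray   # (n,)
    scale_index: int = 0

    def __len__(self) -> int:
        return len(self.points)


# --------------------------------------------------------------------------- #
# derivatives (axis order: 0 = tau/z, 1 = row/y, 2 = col/x)
# --------------------------------------------------------------------------- #

def _first(vol: np.ndarray, axis: int) -> np.ndarray:
    return np.gradient(vol, axis=axis)


def _second(vol: np.ndarray, axis: int) -> np.ndarray:
    # pure second derivative, exact [1, -2, 1] stencil in the interior
    return ndi.correlate1d(vol, np.array([1.0, -2.0, 1.0]), axis=axis,
                           mode="nearest")


def _mixed(vol: np.ndarray, axis_a: int, axis_b: int) -> np.ndarray:
    return np.gradient(np.gradient(vol, axis=axis_a), axis=axis_b)


def _check_slab(slab: np.ndarray) -> np.ndarray:
    vol = np.asarray(slab, dtype=np.float64)
    if vol.ndim != 3 or vol.shape[0] != 3:
        raise ValueError(f"expected a (3, H, W) slab, got shape {vol.shape}")
    if not np.all(np.isfinite(vol)):
        raise ValueError("non-finite values in slab")
    return vol


def _det3(a11, a12, a13, a22, a23, a33, a21=None, a31=None, a32=None):
    """Determinant of a per-pixel symmetric (or full) 3x3 matrix field."""
    a21 = a12 if a21 is None else a21
    a31 = a13 if a31 is None else a31
    a32 = a23 if a32 is None else a32
    return (a11 * (a22 * a33 - a23 * a32)
            - a12 * (a21 * a33 - a23 * a31)
            + a13 * (a21 * a32 - a22 * a31))


# --------------------------------------------------------------------------- #
# detector responses
# --------------------------------------------------------------------------- #

def structure_tensor_response(
    L_slab: np.ndarray,
    sigma_i: float = 2.0,
    tau_i: float = 1.0,
    kappa: float = 0.005,
) -> ResponseMap:
    """3D Harris response from the spatio-temporal second-moment matrix.

    The tensor entries are Gaussian-smoothed products of first derivatives
    (integration scales ``sigma_i`` spatially, ``tau_i`` temporally); the
    criterion cubes the trace, hence the much smaller default ``kappa`` than
    the classic 2D value.
    """
    vol = _check_slab(L_slab)
    if sigma_i <= 0 or tau_i <= 0:
        raise ValueError("integration scales must be positive")
    Lz, Ly, Lx = (_first(vol, a) for a in (0, 1, 2))

    def smooth(p):
        return ndi.gaussian_filter(p, sigma=(tau_i, sigma_i, sigma_i),
                                   mode="nearest")

    Mxx = smooth(Lx * Lx)
    Mxy = smooth(Lx * Ly)
    Mxz = smooth(Lx * Lz)
    Myy = smooth(Ly * Ly)
    Myz = smooth(Ly * Lz)
    Mzz = smooth(Lz * Lz)

    det = _det3(Mxx, Mxy, Mxz, Myy, Myz, Mzz)
    trace = Mxx + Myy + Mzz
    S = det - kappa * trace**3
    return ResponseMap(S=S[1], detector="moments", sigma_i=sigma_i, tau_i=tau_i)


def hessian_st_response(L_slab: np.ndarray, sigma: float = 0.0,
                        tau: float = 0.0) -> ResponseMap:
    """|det| of the 3x3 space-time Hessian at scale (sigma, tau).

    The Hessian carries explicit differentiation scales: second differences
    are taken after Gaussian smoothing with spatial scale ``sigma`` and
    temporal scale ``tau``. For blob-like cells of radius r the matched
    choice ``sigma = r / sqrt(2)`` peaks the response at the blob center;
    ``sigma = tau = 0`` uses bare central differences on the diffused maps.
    """
    vol = _check_slab(L_slab)
    if sigma > 0 or tau > 0:
        vol = ndi.gaussian_filter(vol, sigma=(tau, sigma, sigma),
                                  mode="nearest")
    Hzz = _second(vol, 0)
    Hyy = _second(vol, 1)
    Hxx = _second(vol, 2)
    Hxy = _mixed(vol, 1, 2)
    Hxz = _mixed(vol, 0, 2)
    Hyz = _mixed(vol, 0, 1)
    det = _det3(Hxx, Hxy, Hxz, Hyy, Hyz, Hzz)
    return ResponseMap(S=np.abs(det[1]), detector="hessian_st")


def hessian_temporal_response(L_slab: np.ndarray, sigma: float = 0.0) -> ResponseMap:
    """|det| of the 2x2 spatial Hessian of the temporal derivative L_t.

    ``sigma > 0`` evaluates the spatial Hessian at that Gaussian scale.
    """
    vol = _check_slab(L_slab)
    Lt = 0.5 * (vol[2] - vol[0])            # central temporal difference
    if sigma > 0:
        Lt = ndi.gaussian_filter(Lt, sigma, mode="nearest")
    k2 = np.array([1.0, -2.0, 1.0])
    Hyy = ndi.correlate1d(Lt, k2, axis=0, mode="nearest")
    Hxx = ndi.correlate1d(Lt, k2, axis=1, mode="nearest")
    Hxy = np.gradient(np.gradient(Lt, axis=0), axis=1)
    det = Hxx * Hyy - Hxy * Hxy
    return ResponseMap(S=np.abs(det), detector="hessian_temporal")


_DETECTORS = {
    "moments": lambda slab, cfg: structure_tensor_response(
        slab, sigma_i=cfg["sigma_i"], tau_i=cfg["tau_i"], kappa=cfg["kappa"]),
    "hessian_st": lambda slab, cfg: hessian_st_response(
        slab, sigma=cfg.get("sigma", 0.0) or 0.0,
        tau=cfg.get("tau", 0.0) or 0.0),
    "hessian_temporal": lambda slab, cfg: hessian_temporal_response(
        slab, sigma=cfg.get("sigma", 0.0) or 0.0),
}


def detector_response(L_slab: np.ndarray, detector_cfg: dict) -> ResponseMap:
    """Dispatch to the configured detector (config section ``detector``)."""
    dtype = detector_cfg.get("type", "hessian_st")
    try:
        fn = _DETECTORS[dtype]
    except KeyError:
        raise ValueError(f"unknown detector type {dtype!r}") from None
    return fn(L_slab, detector_cfg)


# --------------------------------------------------------------------------- #
# regional maxima
# --------------------------------------------------------------------------- #

def regional_maxima(
    resp: ResponseMap | np.ndarray,
    min_strength: float = 0.0,
    connectivity: int = 8,
) -> InterestPointSet:
    """Extract regional maxima of a response map as interest points.

    A locus is a pixel whose strength is >= that of all connected neighbors
    and strictly above ``min_strength``. A plateau maximum contributes a
    single locus: its centroid rounded and snapped to the nearest plateau
    pixel. A plateau covering the whole map (constant input) yields nothing.
    """
    S = resp.S if isinstance(resp, ResponseMap) else np.asarray(resp)
    scale_index = resp.scale_index if isinstance(resp, ResponseMap) else 0
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    conn = 1 if connectivity == 4 else 2
    thr = max(float(min_strength), 0.0)

    if S.max() == S.min():
        return InterestPointSet(points=np.empty((0, 2), dtype=np.int64),
                                strengths=np.empty(0), scale_index=scale_index)

    mask = local_maxima(S, connectivity=conn, allow_borders=True)
    labels, n = ndi.label(mask, structure=ndi.generate_binary_structure(2, conn))
    pts, vals = [], []
    for comp in range(1, n + 1):
        rows, cols = np.nonzero(labels == comp)
        val = S[rows[0], cols[0]]
        if val <= thr:
            continue
        cr, cc = rows.mean(), cols.mean()
        # snap the rounded centroid to the nearest plateau pixel
        d2 = (rows - cr) ** 2 + (cols - cc) ** 2
        i = int(np.argmin(d2))
        pts.append((int(rows[i]), int(cols[i])))
        vals.append(float(val))
    if pts:
        order = np.lexsort(([p[1] for p in pts], [p[0] for p in pts]))
        points = np.array(pts, dtype=np.int64)[order]
        strengths = np.array(vals)[order]
    else:
        points = np.empty((0, 2), dtype=np.int64)
        strengths = np.empty(0)
    return InterestPointSet(points=points, strengths=strengths,
                            scale_index=scale_index)
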