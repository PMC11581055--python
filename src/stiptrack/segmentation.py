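"""Watershed superpixels from interest points and a Parzen-density relief.

Interest-point loci are turned into a stochastic density map by Parzen
(kernel) estimation; its inversion, fused with the gradient magnitude of the
selected-scale diffused map, forms a relief whose basins are cell interiors
and background pockets. Markers fuse the interest-point maxima with the
regional minima of that relief; marker-controlled watershed then partitions
every frame into superpixels — the classification units for cell detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import local_minima
from skimage.segmentation import watershed

from .interest_points import InterestPointSet


@dataclass
class DensityMap:
    """Parzen estimate of interest-point density (unnormalized kernel sum)."""

    d: np.ndarray
    bandwidth: float


@dataclass
class SuperpixelMap:
    """Positive-integer complete partition of a frame."""

    labels: np.ndarray

    @property
    def n_superpixels(self) -> int:
        return int(self.labels.max())


def parzen_density(
    points: InterestPointSet | np.ndarray,
    shape: tuple[int, int],
    bandwidth: float,
) -> DensityMap:
    """Sum of isotropic Gaussian kernels centered at each interest point.

    The kernel is ``exp(-r^2 / (2 h^2))`` (unit peak), evaluated exactly over
    the full grid — no truncation — so the map is a faithful kernel sum.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    pts = points.points if isinstance(points, InterestPointSet) else np.asarray(points)
    d = np.zeros(shape, dtype=np.float64)
    if len(pts) == 0:
        warnings.warn("empty interest point set; density is all-zero",
                      stacklevel=2)
        return DensityMap(d=d, bandwidth=bandwidth)
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    inv2h2 = 1.0 / (2.0 * bandwidth**2)
    for chunk in np.array_split(np.asarray(pts, dtype=np.float64),
                                max(1, len(pts) // 64)):
        dr = rows[None] - chunk[:, 0, None, None]
        dc = cols[None] - chunk[:, 1, None, None]
        d += np.exp(-(dr * dr + dc * dc) * inv2h2).sum(axis=0)
    return DensityMap(d=d, bandwidth=bandwidth)


def _norm01(a: np.ndarray) -> np.ndarray:
    lo, hi = a.min(), a.max()
    if hi > lo:
        return (a - lo) / (hi - lo)
    return np.zeros_like(a)


def relief_map(diffused: np.ndarray, density: DensityMap | np.ndarray) -> np.ndarray:
    """Fuse gradient magnitude with the inverted density into one relief.

    Both terms are min-max scaled to [0, 1] and summed with equal weights;
    the relief is low inside cells (high density, flat intensity) and high on
    boundaries (strong gradients, low density).
    """
    d = density.d if isinstance(density, DensityMap) else np.asarray(density)
    diffused = np.asarray(diffused, dtype=np.float64)
    if diffused.shape != d.shape:
        raise ValueError("diffused map and density shapes differ")
    gy, gx = np.gradient(diffused)
    gradmag = np.hypot(gy, gx)
    inverted = d.max() - d
    return _norm01(gradmag) + _norm01(inverted)


def fuse_markers(
    feature_maxima: InterestPointSet | np.ndarray,
    edge_minima: np.ndarray,
) -> np.ndarray:
    """Merge interest-point seeds with relief regional-minima components.

    Interest-point loci are dilated by 1 px; the union with the minima mask
    is connected-component labeled, so overlapping seeds collapse into a
    single marker id.
    """
    minima = np.asarray(edge_minima) > 0
    seeds = np.zeros_like(minima, dtype=bool)
    pts = (feature_maxima.points if isinstance(feature_maxima, InterestPointSet)
           else np.asarray(feature_maxima))
    if len(pts):
        pts = np.asarray(pts, dtype=np.int64)
        seeds[pts[:, 0], pts[:, 1]] = True
        seeds = ndi.binary_dilation(seeds, structure=np.ones((3, 3), bool))
    markers, _ = ndi.label(seeds | minima,
                           structure=ndi.generate_binary_structure(2, 1))
    return markers


def edge_map(diffused: np.ndarray) -> np.ndarray:
    """Spatial gradient magnitude of the selected-scale diffused map.

    Its regional minima — flat plateaus inside cells and in the background —
    are the non-feature marker components for the watershed.
    """
    gy, gx = np.gradient(np.asarray(diffused, dtype=np.float64))
    return np.hypot(gy, gx)


def relief_minima(relief: np.ndarray, connectivity: int = 4) -> np.ndarray:
    """Boolean mask of a map's regional minima (plateaus included)."""
    conn = 1 if connectivity == 4 else 2
    return local_minima(relief, connectivity=conn, allow_borders=True)


def watershed_superpixels(
    relief: np.ndarray,
    markers: np.ndarray,
    min_size: int = 5,
    connectivity: int = 4,
) -> SuperpixelMap:
    """Marker-controlled watershed of the relief.

    Every pixel is assigned a label; fragments smaller than ``min_size`` are
    merged into the adjacent region across the lowest ridge (lowest mean
    relief on the shared border).
    """
    markers = np.asarray(markers)
    if markers.max() == 0:
        raise ValueError("no markers supplied")
    conn = 1 if connectivity == 4 else 2
    labels = watershed(relief, markers=markers, connectivity=conn)
    labels = _merge_small(labels, relief, min_size)
    # compact to 1..K
    _, labels = np.unique(labels, return_inverse=True)
    return SuperpixelMap(labels=(labels + 1).reshape(relief.shape))


def _merge_small(labels: np.ndarray, relief: np.ndarray, min_size: int) -> np.ndarray:
    labels = labels.copy()
    struct = ndi.generate_binary_structure(2, 1)
    while True:
        ids, counts = np.unique(labels, return_counts=True)
        small = ids[counts < min_size]
        if small.size == 0 or ids.size == 1:
            return labels
        merged_any = False
        for sid in small:
            mask = labels == sid
            border = ndi.binary_dilation(mask, structure=struct) & ~mask
            neigh = labels[border]
            if neigh.size == 0:
                continue
            # lowest ridge: neighbor with minimum mean relief on the contact zone
            best, best_val = None, np.inf
            for nid in np.unique(neigh):
                val = relief[border & (labels == nid)].mean()
                if val < best_val:
                    best, best_val = nid, val
            labels[mask] = best
            merged_any = True
        if not merged_any:
            return labels
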