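"""Detector responses vs brute-force oracles; regional maxima extraction."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from stiptrack.interest_points import (
    hessian_st_response,
    hessian_temporal_response,
    regional_maxima,
    structure_tensor_response,
)

# ---------------------------------------------------------------------------
# independent oracles: explicit per-pixel loops, numpy determinants
# ---------------------------------------------------------------------------


def _oracle_first(vol, axis):
    return np.gradient(vol, axis=axis)


def oracle_structure_tensor(vol, sigma_i, tau_i, kappa):
    Lz = _oracle_first(vol, 0)
    Ly = _oracle_first(vol, 1)
    Lx = _oracle_first(vol, 2)
    prods = {}
    for (na, A) in (("x", Lx), ("y", Ly), ("z", Lz)):
        for (nb, B) in (("x", Lx), ("y", Ly), ("z", Lz)):
            prods[na + nb] = ndi.gaussian_filter(
                A * B, sigma=(tau_i, sigma_i, sigma_i), mode="nearest")
    H, W = vol.shape[1:]
    S = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            M = np.array([
                [prods["xx"][1, i, j], prods["xy"][1, i, j], prods["xz"][1, i, j]],
                [prods["xy"][1, i, j], prods["yy"][1, i, j], prods["yz"][1, i, j]],
                [prods["xz"][1, i, j], prods["yz"][1, i, j], prods["zz"][1, i, j]],
            ])
            S[i, j] = np.linalg.det(M) - kappa * np.trace(M) ** 3
    return S


def oracle_hessian_st(vol):
    k2 = np.array([1.0, -2.0, 1.0])
    second = {a: ndi.correlate1d(vol, k2, axis=a, mode="nearest")
              for a in (0, 1, 2)}
    mixed = {(a, b): np.gradient(np.gradient(vol, axis=a), axis=b)
             for a, b in ((1, 2), (0, 2), (0, 1))}
    H_, W_ = vol.shape[1:]
    S = np.zeros((H_, W_))
    for i in range(H_):
        for j in range(W_):
            H = np.array([
                [second[2][1, i, j], mixed[(1, 2)][1, i, j], mixed[(0, 2)][1, i, j]],
                [mixed[(1, 2)][1, i, j], second[1][1, i, j], mixed[(0, 1)][1, i, j]],
                [mixed[(0, 2)][1, i, j], mixed[(0, 1)][1, i, j], second[0][1, i, j]],
            ])
            S[i, j] = abs(np.linalg.det(H))
    return S


def oracle_hessian_temporal(vol):
    Lt = 0.5 * (vol[2] - vol[0])
    k2 = np.array([1.0, -2.0, 1.0])
    Hyy = ndi.correlate1d(Lt, k2, axis=0, mode="nearest")
    Hxx = ndi.correlate1d(Lt, k2, axis=1, mode="nearest")
    Hxy = np.gradient(np.gradient(Lt, axis=0), axis=1)
    H_, W_ = Lt.shape
    S = np.zeros((H_, W_))
    for i in range(H_):
        for j in range(W_):
            S[i, j] = abs(Hxx[i, j] * Hyy[i, j] - Hxy[i, j] ** 2)
    return S


class TestStructureTensor:
    def test_constant_slab_gives_zero(self):
        resp = structure_tensor_response(np.full((3, 10, 10), 0.5))
        assert np.allclose(resp.S, 0.0)

    def test_single_axis_variation_is_nonpositive(self):
        # rank-1 tensor: det = 0, so S = -kappa * trace^3 <= 0
        x = np.linspace(0, 1, 12)
        slab = np.broadcast_to(x, (3, 12, 12)).copy()
        resp = structure_tensor_response(slab, kappa=0.005)
        assert resp.S.max() <= 1e-15

    def test_matches_bruteforce_oracle(self, rng):
        slab = rng.random((3, 8, 8))
        resp = structure_tensor_response(slab, sigma_i=2.0, tau_i=1.0,
                                         kappa=0.005)
        ref = oracle_structure_tensor(slab, 2.0, 1.0, 0.005)
        assert np.max(np.abs(resp.S - ref)) < 1e-10

    def test_nonpositive_integration_scale_rejected(self):
        with pytest.raises(ValueError):
            structure_tensor_response(np.zeros((3, 8, 8)), sigma_i=0.0)


class TestHessianST:
    def test_constant_slab_gives_zero(self):
        resp = hessian_st_response(np.full((3, 10, 10), 2.0))
        assert np.allclose(resp.S, 0.0)

    def test_separable_quadratic_closed_form(self):
        # a x^2 + b y^2 + c z^2: Hessian diag(2a, 2b, 2c) -> |det| = |8abc|
        a, b, c = 0.7, -0.4, 0.9
        z, y, x = np.mgrid[0:3, 0:16, 0:16].astype(float)
        slab = a * x**2 + b * y**2 + c * z**2
        resp = hessian_st_response(slab)
        interior = resp.S[4:-4, 4:-4]
        assert np.allclose(interior, abs(8 * a * b * c), atol=1e-10)

    def test_matches_cofactor_oracle(self, rng):
        slab = rng.random((3, 8, 8))
        resp = hessian_st_response(slab)
        assert np.max(np.abs(resp.S - oracle_hessian_st(slab))) < 1e-10


class TestHessianTemporal:
    def test_temporally_constant_gives_zero(self, rng):
        frame = rng.random((10, 10))
        resp = hessian_temporal_response(np.stack([frame] * 3))
        assert np.allclose(resp.S, 0.0)

    def test_antisymmetric_neighbors_give_zero(self, rng):
        a = rng.random((10, 10))
        b = rng.random((10, 10))
        resp = hessian_temporal_response(np.stack([a, b, a]))
        assert np.allclose(resp.S, 0.0)

    def test_gaussian_bump_peaks_at_center(self):
        y, x = np.mgrid[0:21, 0:21].astype(float)
        bump = np.exp(-((x - 10) ** 2 + (y - 10) ** 2) / (2 * 3.0**2))
        slab = np.stack([np.zeros_like(bump), bump / 2, bump])  # Lt = bump/2
        resp = hessian_temporal_response(slab)
        assert np.unravel_index(np.argmax(resp.S), resp.S.shape) == (10, 10)

    def test_matches_oracle(self, rng):
        slab = rng.random((3, 8, 8))
        resp = hessian_temporal_response(slab)
        assert np.max(np.abs(resp.S - oracle_hessian_temporal(slab))) < 1e-10

    def test_needs_three_slices(self):
        with pytest.raises(ValueError):
            hessian_temporal_response(np.zeros((2, 8, 8)))


class TestResponseInvariances:
    @pytest.fixture()
    def slab(self, rng):
        return rng.random((3, 10, 10))

    def test_offset_invariance(self, slab):
        for fn in (lambda v: structure_tensor_response(v).S,
                   lambda v: hessian_st_response(v).S,
                   lambda v: hessian_temporal_response(v).S):
            assert np.allclose(fn(slab), fn(slab + 5.0), atol=1e-9)

    @pytest.mark.parametrize("fn,power", [
        (lambda v: structure_tensor_response(v, kappa=0.005).S, 6),
        (lambda v: hessian_st_response(v).S, 3),
        (lambda v: hessian_temporal_response(v).S, 2),
    ])
    def test_intensity_power_law(self, slab, fn, power):
        c = 1.7
        base = fn(slab)
        scaled = fn(c * slab)
        mask = np.abs(base) > 1e-12
        ratio = scaled[mask] / base[mask]
        assert np.allclose(ratio, c**power, rtol=1e-8)


class TestRegionalMaxima:
    def test_single_bump_yields_one_point_at_peak(self):
        y, x = np.mgrid[0:31, 0:31].astype(float)
        bump = np.exp(-((x - 14) ** 2 + (y - 17) ** 2) / (2 * 4.0**2))
        pts = regional_maxima(bump, min_strength=0.01)
        assert len(pts) == 1
        assert tuple(pts.points[0]) == (17, 14)

    def test_constant_map_yields_nothing(self):
        assert len(regional_maxima(np.full((16, 16), 3.0),
                                   min_strength=0.1)) == 0

    def test_two_equal_bumps_yield_two_points(self):
        y, x = np.mgrid[0:24, 0:40].astype(float)
        m = (np.exp(-((x - 10) ** 2 + (y - 12) ** 2) / 8.0)
             + np.exp(-((x - 20) ** 2 + (y - 12) ** 2) / 8.0))
        pts = regional_maxima(m, min_strength=1e-3)
        # oracle: exhaustive 8-neighbor comparison
        oracle = []
        for i in range(1, 23):
            for j in range(1, 39):
                nb = m[i - 1:i + 2, j - 1:j + 2]
                if m[i, j] >= nb.max() and (nb < m[i, j]).sum() == 8:
                    oracle.append((i, j))
        assert len(pts) == 2
        assert {tuple(p) for p in pts.points} == set(oracle)

    def test_plateau_contributes_single_centroid_locus(self):
        m = np.zeros((15, 15))
        m[5:8, 5:10] = 1.0  # 3x5 plateau, centroid (6, 7)
        pts = regional_maxima(m, min_strength=0.5)
        assert len(pts) == 1
        assert tuple(pts.points[0]) == (6, 7)

    def test_threshold_is_strict(self):
        m = np.zeros((9, 9))
        m[4, 4] = 1.0
        assert len(regional_maxima(m, min_strength=1.0)) == 0
        assert len(regional_maxima(m, min_strength=0.99)) == 1

    def test_invalid_connectivity_rejected(self):
        with pytest.raises(ValueError):
            regional_maxima(np.zeros((4, 4)), connectivity=6)
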