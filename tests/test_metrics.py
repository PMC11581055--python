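"""SEG / DET / TRA evaluation vs independent enumeration oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stiptrack.io_ctc import TrackFileRecord
from stiptrack.metrics import (
    DEFAULT_WEIGHTS,
    build_eval_graph,
    det_measure,
    dsc,
    evaluate_sequences,
    jaccard,
    seg_measure,
    tra_measure,
)

# ---------------------------------------------------------------------------
# independent oracle: naive loop-based operation enumeration
# ---------------------------------------------------------------------------


def oracle_costs(res_masks, res_edges, ref_masks, ref_edges, w=DEFAULT_WEIGHTS):
    """Count AOGM edit operations by direct set enumeration."""
    # detection test per frame: ref cell -> res cell covering > half of it
    match = {}
    for t, (res, ref) in enumerate(zip(res_masks, ref_masks)):
        for g in np.unique(ref[ref > 0]):
            gm = ref == g
            found = None
            for r in np.unique(res[res > 0]):
                if ((res == r) & gm).sum() > 0.5 * gm.sum():
                    found = (t, int(r))
                    break
            match[(t, int(g))] = found
    res_nodes = {(t, int(r)) for t, res in enumerate(res_masks)
                 for r in np.unique(res[res > 0])}
    fn = sum(1 for v in match.values() if v is None)
    by_res = {}
    for g, r in match.items():
        if r is not None:
            by_res.setdefault(r, []).append(g)
    ns = sum(len(v) - 1 for v in by_res.values())
    fp = len([r for r in res_nodes if r not in by_res])

    ed = ec = 0
    covered = set()
    for (a, b), kind in res_edges.items():
        pairs = [(x, y) for x in by_res.get(a, []) for y in by_res.get(b, [])
                 if (x, y) in ref_edges]
        if not pairs:
            ed += 1
        elif any(ref_edges[p] == kind for p in pairs):
            covered.update(p for p in pairs if ref_edges[p] == kind)
        else:
            ec += 1
            covered.update(pairs)
    ea = len([e for e in ref_edges if e not in covered])

    n_ref = sum(len(np.unique(ref[ref > 0])) for ref in ref_masks)
    aogmd = w["ns"] * ns + w["fn"] * fn + w["fp"] * fp
    aogm = aogmd + w["ed"] * ed + w["ea"] * ea + w["ec"] * ec
    aogmd0 = w["fn"] * n_ref
    aogm0 = aogmd0 + w["ea"] * len(ref_edges)
    det = 1.0 if aogmd0 == 0 else max(0.0, 1 - min(aogmd, aogmd0) / aogmd0)
    tra = 1.0 if aogm0 == 0 else max(0.0, 1 - min(aogm, aogm0) / aogm0)
    return det, tra


def _square(frame, r0, c0, size, label):
    frame[r0:r0 + size, c0:c0 + size] = label


class TestOverlapMeasures:
    def test_jaccard_examples(self):
        a = [(0, j) for j in range(10)]
        b = [(1, j) for j in range(10)]
        c = [(0, j) for j in range(5, 15)]
        assert jaccard(a, a) == 1.0
        assert jaccard(a, b) == 0.0
        assert jaccard(a, c) == pytest.approx(1 / 3)
        assert jaccard([], []) == 1.0

    def test_dsc_examples(self):
        a = [(0, j) for j in range(10)]
        c = [(0, j) for j in range(5, 15)]
        assert dsc(a, a) == 1.0
        assert dsc(a, [(9, 9)]) == 0.0
        assert dsc(a, c) == pytest.approx(0.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_dsc_jaccard_identity_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((12, 12)) > 0.5
        b = rng.random((12, 12)) > 0.5
        j = jaccard(a, b)
        assert dsc(a, b) == pytest.approx(2 * j / (1 + j))
        assert dsc(a, b) >= j


class TestSegMeasure:
    def test_identity_scores_one(self):
        m = np.zeros((16, 16), int)
        _square(m, 2, 2, 5, 1)
        _square(m, 9, 9, 4, 2)
        assert seg_measure([m], [m]) == 1.0

    def test_half_overlap_scores_zero(self):
        ref = np.zeros((8, 12), int)
        ref[0, :10] = 1                 # 10-px reference cell
        res = np.zeros((8, 12), int)
        res[0, 5:12] = 1                # overlap exactly 5 px = 0.5*|ref|
        assert seg_measure([res], [ref]) == 0.0

    def test_mean_over_reference_cells(self):
        ref = np.zeros((20, 20), int)
        _square(ref, 2, 2, 4, 1)
        _square(ref, 10, 10, 4, 2)
        res = ref.copy()
        # degrade cell 2 to Jaccard 0.5: 16-px ref, result covers 12 of it
        # plus 8 extra -> inter 12, union 24 -> 0.5
        res[ref == 2] = 0
        res[10:13, 10:14] = 2
        res[14:16, 10:14] = 2
        inter = ((res == 2) & (ref == 2)).sum()
        union = ((res == 2) | (ref == 2)).sum()
        assert inter / union == 0.5
        assert seg_measure([res], [ref]) == pytest.approx(0.75)

    def test_frame_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            seg_measure([np.zeros((4, 4), int)], [])


class TestDetTra:
    def _graphs(self, res_masks, res_records, ref_masks, ref_records):
        return (build_eval_graph(res_masks, res_records),
                build_eval_graph(ref_masks, ref_records))

    def test_perfect_result_scores_one(self):
        m = np.zeros((12, 12), int)
        _square(m, 2, 2, 4, 1)
        recs = [TrackFileRecord(1, 0, 1, 0)]
        res_g, ref_g = self._graphs([m, m], recs, [m, m], recs)
        assert det_measure(res_g, ref_g) == 1.0
        assert tra_measure(res_g, ref_g) == 1.0

    def test_empty_result_scores_zero(self):
        m = np.zeros((12, 12), int)
        _square(m, 2, 2, 4, 1)
        empty = np.zeros_like(m)
        res_g, ref_g = self._graphs([empty, empty], [],
                                    [m, m], [TrackFileRecord(1, 0, 1, 0)])
        assert det_measure(res_g, ref_g) == 0.0
        assert tra_measure(res_g, ref_g) == 0.0

    def test_one_missed_cell_of_ten(self):
        ref = np.zeros((8, 100), int)
        for k in range(10):
            _square(ref, 2, 10 * k + 1, 4, k + 1)
        res = ref.copy()
        res[res == 10] = 0
        refs = [TrackFileRecord(k + 1, 0, 0, 0) for k in range(10)]
        ress = [TrackFileRecord(k + 1, 0, 0, 0) for k in range(9)]
        res_g, ref_g = self._graphs([res], ress, [ref], refs)
        assert det_measure(res_g, ref_g) == pytest.approx(0.9)

    def test_missing_migration_edge_micro_case(self):
        # 2 cells, 3 frames; the result loses cell 2 in frame 1, breaking
        # its chain into two tracks -> 1 FN node and 2 missing edges
        ref = np.zeros((10, 20), int)
        _square(ref, 1, 1, 4, 1)
        _square(ref, 1, 12, 4, 2)
        ref_masks = [ref, ref, ref]
        ref_recs = [TrackFileRecord(1, 0, 2, 0), TrackFileRecord(2, 0, 2, 0)]
        res1 = ref.copy()
        res1[res1 == 2] = 0
        res_masks = [ref, res1, ref]
        res_recs = [TrackFileRecord(1, 0, 2, 0), TrackFileRecord(2, 0, 0, 0),
                    TrackFileRecord(3, 2, 2, 0)]
        rm = [m.copy() for m in res_masks]
        rm[2] = np.where(rm[2] == 2, 3, rm[2])
        res_g, ref_g = self._graphs(rm, res_recs, ref_masks, ref_recs)
        got_det = det_measure(res_g, ref_g)
        got_tra = tra_measure(res_g, ref_g)
        # enumeration oracle on the same case
        odet, otra = oracle_costs(
            rm, res_g.edges, ref_masks, ref_g.edges)
        assert got_det == pytest.approx(odet)
        assert got_tra == pytest.approx(otra)
        # hand count: 1 FN of 6 nodes; 2 edges to add of 4 reference edges
        assert got_det == pytest.approx(1 - 10 / (10 * 6))
        assert got_tra == pytest.approx(1 - (10 + 2 * 1.5) / (10 * 6 + 1.5 * 4))

    def test_micro_case_family_matches_enumeration_oracle(self):
        # all combinations of dropping cells/frames in a 3-cell 3-frame scene
        ref = np.zeros((8, 30), int)
        _square(ref, 1, 1, 4, 1)
        _square(ref, 1, 11, 4, 2)
        _square(ref, 1, 21, 4, 3)
        ref_masks = [ref] * 3
        ref_recs = [TrackFileRecord(k, 0, 2, 0) for k in (1, 2, 3)]
        ref_g = build_eval_graph(ref_masks, ref_recs)
        for drop in itertools.product([None, 1, 2, 3], repeat=3):
            res_masks = []
            for t in range(3):
                m = ref.copy()
                if drop[t] is not None:
                    m[m == drop[t]] = 0
                res_masks.append(m)
            res_g = build_eval_graph(res_masks, None)
            odet, otra = oracle_costs(res_masks, res_g.edges,
                                      ref_masks, ref_g.edges)
            assert det_measure(res_g, ref_g) == pytest.approx(odet)
            assert tra_measure(res_g, ref_g) == pytest.approx(otra)

    def test_monotone_under_added_false_positives(self):
        ref = np.zeros((10, 30), int)
        _square(ref, 1, 1, 4, 1)
        recs = [TrackFileRecord(1, 0, 1, 0)]
        res0 = [ref.copy(), ref.copy()]
        res1 = [ref.copy(), ref.copy()]
        for m in res1:
            _square(m, 5, 20, 3, 9)
        g_ref = build_eval_graph([ref, ref], recs)
        d0 = det_measure(build_eval_graph(res0, recs), g_ref)
        d1 = det_measure(build_eval_graph(res1, recs), g_ref)
        assert d1 < d0 == 1.0
        t0 = tra_measure(build_eval_graph(res0, recs), g_ref)
        t1 = tra_measure(build_eval_graph(res1, recs), g_ref)
        assert t1 < t0 == 1.0


class TestEvaluateSequences:
    def test_self_comparison_is_perfect(self, fixture_noisefree):
        res = fixture_noisefree["01"]
        rep = evaluate_sequences(res.masks, res.lineage,
                                 res.masks, res.lineage)
        assert rep.seg == rep.det == rep.tra == 1.0
        assert rep.mean_jaccard == rep.mean_dsc == 1.0

    def test_report_bounds(self, fixture_noisefree):
        res = fixture_noisefree["01"]
        shifted = [np.roll(m, 3, axis=1) for m in res.masks]
        rep = evaluate_sequences(shifted, res.lineage,
                                 res.masks, res.lineage)
        for v in (rep.seg, rep.det, rep.tra, rep.mean_jaccard, rep.mean_dsc):
            assert 0.0 <= v <= 1.0
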