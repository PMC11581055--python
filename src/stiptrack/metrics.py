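"""Segmentation and tracking evaluation: Jaccard, DSC, SEG, DET, TRA.

SEG is the mean Jaccard over reference cells, where a reference cell scores
0 unless some result region covers strictly more than half of it (at most
one such region can exist). DET and TRA normalize acyclic-oriented-graph
matching (AOGM) costs: the weighted number of node (DET) or node+edge (TRA)
edit operations needed to turn the computed tracking graph into the
reference graph, divided by the cost of building the reference from scratch:

    DET = 1 - min(AOGM_D, AOGM_D0) / AOGM_D0
    TRA = 1 - min(AOGM,   AOGM_0)  / AOGM_0

Default operation weights follow the published AOGM convention (node split
5, false negative 10, false positive 1; edge delete 1, edge add 1.5, edge
semantics 1) and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_ctc import TrackFileRecord

DEFAULT_WEIGHTS = {"ns": 5.0, "fn": 10.0, "fp": 1.0,
                   "ed": 1.0, "ea": 1.5, "ec": 1.0}


# --------------------------------------------------------------------------- #
# region overlap measures
# --------------------------------------------------------------------------- #

def _as_set(a) -> set:
    if isinstance(a, np.ndarray) and a.dtype == bool:
        return set(map(tuple, np.argwhere(a)))
    return set(map(tuple, a))


def jaccard(a, b) -> float:
    """|a n b| / |a u b|; defined as 1 for two empty sets."""
    sa, sb = _as_set(a), _as_set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


def dsc(a, b) -> float:
    """Dice similarity 2|a n b| / (|a| + |b|); 1 for two empty sets."""
    sa, sb = _as_set(a), _as_set(b)
    if not sa and not sb:
        return 1.0
    denom = len(sa) + len(sb)
    return 2.0 * len(sa & sb) / denom if denom else 1.0


# --------------------------------------------------------------------------- #
# node matching (shared by SEG / DET / TRA)
# --------------------------------------------------------------------------- #

def _frame_overlaps(res: np.ndarray, ref: np.ndarray):
    """Intersection counts {(ref_label, res_label): n} plus per-label areas."""
    res = np.asarray(res)
    ref = np.asarray(ref)
    ref_ids, ref_areas = np.unique(ref[ref > 0], return_counts=True)
    res_ids, res_areas = np.unique(res[res > 0], return_counts=True)
    inter: dict[tuple[int, int], int] = {}
    both = (ref > 0) & (res > 0)
    if both.any():
        k = ref[both].astype(np.int64) * (int(res.max()) + 1) + res[both]
        uniq, counts = np.unique(k, return_counts=True)
        m = int(res.max()) + 1
        for key, c in zip(uniq, counts):
            inter[(int(key // m), int(key % m))] = int(c)
    return (inter, dict(zip(ref_ids.tolist(), ref_areas.tolist())),
            dict(zip(res_ids.tolist(), res_areas.tolist())))


def _match_nodes(res_masks, ref_masks):
    """CTC detection test per frame: ref cell -> res cell whose intersection
    exceeds half the reference area (unique if it exists)."""
    match: dict[tuple[int, int], Optional[tuple[int, int]]] = {}
    overlaps: dict[tuple[int, int], tuple[int, int, int]] = {}
    res_nodes: list[tuple[int, int]] = []
    for t, (res, ref) in enumerate(zip(res_masks, ref_masks)):
        inter, ref_areas, res_areas = _frame_overlaps(res, ref)
        for rid in res_areas:
            res_nodes.append((t, rid))
        for gid, ga in ref_areas.items():
            found = None
            for (g, r), n in inter.items():
                if g == gid and n > 0.5 * ga:
                    found = (t, r)
                    overlaps[(t, gid)] = (n, ga, res_areas[r])
                    break
            match[(t, gid)] = found
    return match, overlaps, res_nodes


def seg_measure(result: Sequence[np.ndarray], reference: Sequence[np.ndarray]) -> float:
    """Mean Jaccard over all reference cells, zeroing unmatched cells."""
    if len(result) != len(reference):
        raise ValueError("result and reference frame counts differ")
    match, overlaps, _ = _match_nodes(result, reference)
    if not match:
        return 1.0
    scores = []
    for key, m in match.items():
        if m is None:
            scores.append(0.0)
        else:
            n, ga, ra = overlaps[key]
            scores.append(n / (ga + ra - n))
    return float(np.mean(scores))


# --------------------------------------------------------------------------- #
# evaluation graphs
# --------------------------------------------------------------------------- #

@dataclass
class EvalGraph:
    """Tracking result in evaluable form: per-frame track-labeled masks plus
    the edge set implied by the track records."""

    masks: list[np.ndarray]
    nodes: set[tuple[int, int]] = field(default_factory=set)
    edges: dict[tuple[tuple[int, int], tuple[int, int]], str] = field(
        default_factory=dict)


def build_eval_graph(
    masks: Sequence[np.ndarray],
    records: Sequence[TrackFileRecord] | None = None,
) -> EvalGraph:
    """Assemble the acyclic oriented graph of a tracking result.

    Nodes are the labeled regions present in the masks. Migration edges
    connect consecutive occurrences of a track label; division edges connect
    a parent's last occurrence to a child's first.
    """
    masks = [np.asarray(m) for m in masks]
    g = EvalGraph(masks=list(masks))
    present: dict[int, list[int]] = {}
    for t, m in enumerate(masks):
        for lab in np.unique(m[m > 0]):
            g.nodes.add((t, int(lab)))
            present.setdefault(int(lab), []).append(t)
    for lab, ts in present.items():
        for t0, t1 in zip(ts, ts[1:]):
            if t1 == t0 + 1:
                g.edges[((t0, lab), (t1, lab))] = "migration"
    if records:
        last = {lab: ts[-1] for lab, ts in present.items()}
        first = {lab: ts[0] for lab, ts in present.items()}
        for rec in records:
            if rec.parent_label and rec.parent_label in last \
                    and rec.label in first:
                g.edges[((last[rec.parent_label], rec.parent_label),
                         (first[rec.label], rec.label))] = "division"
    return g


# --------------------------------------------------------------------------- #
# AOGM costs
# --------------------------------------------------------------------------- #

def _aogm_costs(res: EvalGraph, ref: EvalGraph, weights: dict):
    """Node and edge edit-operation counts transforming ``res`` into ``ref``."""
    if len(res.masks) != len(ref.masks):
        raise ValueError("result and reference frame counts differ")
    match, _, _ = _match_nodes(res.masks, ref.masks)

    fn = sum(1 for m in match.values() if m is None)
    matched_res: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for gnode, rnode in match.items():
        if rnode is not None:
            matched_res.setdefault(rnode, []).append(gnode)
    ns = sum(len(v) - 1 for v in matched_res.values())
    fp = sum(1 for rnode in res.nodes if rnode not in matched_res)

    # map result edges into the reference domain through the node matching
    res_to_ref: dict[tuple[int, int], list[tuple[int, int]]] = matched_res
    ed = ec = 0
    covered: set[tuple] = set()
    for (a, b), kind in res.edges.items():
        ra = res_to_ref.get(a, [])
        rb = res_to_ref.get(b, [])
        induced = [(x, y) for x in ra for y in rb if (x, y) in ref.edges]
        if not induced:
            ed += 1
            continue
        ok = [p for p in induced if ref.edges[p] == kind]
        if ok:
            covered.update(ok)
        else:
            ec += 1
            covered.update(induced)
    ea = sum(1 for e in ref.edges if e not in covered)

    w = {**DEFAULT_WEIGHTS, **(weights or {})}
    node_cost = w["ns"] * ns + w["fn"] * fn + w["fp"] * fp
    edge_cost = w["ed"] * ed + w["ea"] * ea + w["ec"] * ec
    counts = {"ns": ns, "fn": fn, "fp": fp, "ed": ed, "ea": ea, "ec": ec}
    node_cost0 = w["fn"] * len(ref.nodes)
    full_cost0 = node_cost0 + w["ea"] * len(ref.edges)
    return node_cost, edge_cost, node_cost0, full_cost0, counts


def det_measure(
    result_graph: EvalGraph,
    reference_graph: EvalGraph,
    weights: dict | None = None,
) -> float:
    """Normalized node-level AOGM detection accuracy, clamped to [0, 1]."""
    node, _, node0, _, _ = _aogm_costs(result_graph, reference_graph,
                                       weights or {})
    if node0 == 0:
        return 1.0
    return float(np.clip(1.0 - min(node, node0) / node0, 0.0, 1.0))


def tra_measure(
    result_graph: EvalGraph,
    reference_graph: EvalGraph,
    weights: dict | None = None,
) -> float:
    """Normalized full AOGM tracking accuracy, clamped to [0, 1]."""
    node, edge, _, full0, _ = _aogm_costs(result_graph, reference_graph,
                                          weights or {})
    if full0 == 0:
        return 1.0
    return float(np.clip(1.0 - min(node + edge, full0) / full0, 0.0, 1.0))


# --------------------------------------------------------------------------- #
# report
# --------------------------------------------------------------------------- #

@dataclass
class EvaluationReport:
    """Sequence-level evaluation summary with per-frame SEG breakdown."""

    seg: float
    det: float
    tra: float
    mean_jaccard: float
    mean_dsc: float
    per_frame_seg: list[float]
    aogm_counts: dict

    def as_dict(self) -> dict:
        return {
            "SEG": self.seg, "DET": self.det, "TRA": self.tra,
            "mean_jaccard": self.mean_jaccard, "mean_dsc": self.mean_dsc,
            "per_frame_seg": self.per_frame_seg,
            "aogm_counts": self.aogm_counts,
        }


def evaluate_sequences(
    res_masks: Sequence[np.ndarray],
    res_records: Sequence[TrackFileRecord] | None,
    ref_masks: Sequence[np.ndarray],
    ref_records: Sequence[TrackFileRecord] | None,
    weights: dict | None = None,
) -> EvaluationReport:
    """Full SEG/DET/TRA evaluation of a tracked result against a reference."""
    res_g = build_eval_graph(res_masks, res_records)
    ref_g = build_eval_graph(ref_masks, ref_records)
    node, edge, node0, full0, counts = _aogm_costs(res_g, ref_g, weights or {})
    det = 1.0 if node0 == 0 else float(
        np.clip(1.0 - min(node, node0) / node0, 0.0, 1.0))
    tra = 1.0 if full0 == 0 else float(
        np.clip(1.0 - min(node + edge, full0) / full0, 0.0, 1.0))

    match, overlaps, _ = _match_nodes(res_masks, ref_masks)
    per_frame: dict[int, list[float]] = {}
    jac, dice = [], []
    for (t, gid), m in match.items():
        if m is None:
            score = 0.0
        else:
            n, ga, ra = overlaps[(t, gid)]
            score = n / (ga + ra - n)
        per_frame.setdefault(t, []).append(score)
        jac.append(score)
        dice.append(2 * score / (1 + score))
    seg = float(np.mean(jac)) if jac else 1.0
    per_frame_seg = [float(np.mean(per_frame[t]))
                     for t in sorted(per_frame)] if per_frame else []
    return EvaluationReport(
        seg=seg, det=det, tra=tra,
        mean_jaccard=float(np.mean(jac)) if jac else 1.0,
        mean_dsc=float(np.mean(dice)) if dice else 1.0,
        per_frame_seg=per_frame_seg, aogm_counts=counts,
    )
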