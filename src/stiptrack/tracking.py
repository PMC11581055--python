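"""Graph-based cell tracking with mitosis detection.

Cells are linked frame to frame by maximum-likelihood matching: every cell
of the current frame is compared against all cells of the prior frame after
motion compensation (the prior label map warped by the optical-flow field),
and the likelihood of a correspondence is the intersection-over-union of the
indicator regions. A reject option (low maximum likelihood) signals cell
appearance. Two current cells claiming the same prior cell encode a
division. Backward traversal of the per-frame links yields chains; chains
sharing a common ancestor prefix are split into a mother track and daughter
tracks, and the result is emitted as an acyclic oriented lineage graph
(migration edges within tracks, division edges mother -> daughters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy import ndimage as ndi

from .io_ctc import TrackFileRecord
from .motion import MotionField, warp_labels


@dataclass
class CellState:
    """One segmented cell instance in one frame."""

    t: int
    label: int
    centroid: tuple[float, float]
    area: int


@dataclass(frozen=True)
class TrackRecordQ:
    """Per-state linkage record (frame, label, previous frame, previous
    label); ``xi_n is None`` marks an appearance."""

    t: int
    xi_m: int
    t_p: Optional[int]
    xi_n: Optional[int]

    def __post_init__(self) -> None:
        if self.xi_n is not None and (self.t_p is None or self.t_p >= self.t):
            raise ValueError("previous frame must precede the current frame")


@dataclass
class Track:
    """A non-branching chain of cell states in consecutive frames."""

    id: int
    states: list[tuple[int, int]]       # (frame, frame-local label)
    parent: int = 0

    @property
    def begin(self) -> int:
        return self.states[0][0]

    @property
    def end(self) -> int:
        return self.states[-1][0]


# --------------------------------------------------------------------------- #
# bi-frame matching
# --------------------------------------------------------------------------- #

def match_likelihood(current_pixels, warped_prior_pixels) -> float:
    """Intersection-over-union of a current region and a motion-compensated
    prior region (0 when disjoint, 1 when identical)."""
    a = set(map(tuple, current_pixels))
    b = set(map(tuple, warped_prior_pixels))
    if not a and not b:
        return 1.0
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def _region_table(labels: np.ndarray) -> dict[int, int]:
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    return dict(zip(ids.tolist(), counts.tolist()))


def match_cells(
    current: np.ndarray,
    prior: np.ndarray,
    field_: MotionField | None,
    reject_threshold: float = 0.1,
    expected_radius: float = 6.0,
    fallback_sigma_rel: float = 1.0,
    max_daughters: int = 2,
) -> dict[int, Optional[int]]:
    """Assign each current-frame cell its max-likelihood prior-frame cell.

    Returns ``{current_label: prior_label or None}`` (``None`` = appearance).
    A prior cell may be claimed by several current cells — that encodes
    division — but claims are capped at ``max_daughters`` (binary fission);
    excess claimants, in likelihood order, become appearances. When every
    IoU is zero but a warped prior centroid lies within
    ``2 * expected_radius``, a Gaussian centroid-distance likelihood
    (sigma = ``fallback_sigma_rel * expected_radius``) stands in, which
    tolerates low temporal resolution.
    """
    current = np.asarray(current)
    prior = np.asarray(prior)
    if current.shape != prior.shape:
        raise ValueError("frame shapes differ")
    warped = (warp_labels(prior, field_) if field_ is not None else prior)

    cur_areas = _region_table(current)
    warp_areas = _region_table(warped)
    # joint histogram of (current, warped) overlaps
    both = (current > 0) & (warped > 0)
    pairs: dict[tuple[int, int], int] = {}
    if both.any():
        cu, wa = current[both], warped[both]
        keys = cu.astype(np.int64) * (warped.max() + 1) + wa
        uniq, counts = np.unique(keys, return_counts=True)
        for k, c in zip(uniq, counts):
            pairs[(int(k // (warped.max() + 1)), int(k % (warped.max() + 1)))] = int(c)

    warp_cents = {}
    if warp_areas:
        ids = sorted(warp_areas)
        cents = ndi.center_of_mass(warped > 0, labels=warped, index=ids)
        warp_cents = dict(zip(ids, cents))
    cur_cents = {}
    if cur_areas:
        ids = sorted(cur_areas)
        cents = ndi.center_of_mass(current > 0, labels=current, index=ids)
        cur_cents = dict(zip(ids, cents))

    sigma = fallback_sigma_rel * expected_radius
    assignment: dict[int, Optional[int]] = {}
    likelihood: dict[int, float] = {}
    for ci in sorted(cur_areas):
        ious = {}
        for pj in warp_areas:
            inter = pairs.get((ci, pj), 0)
            if inter:
                ious[pj] = inter / (cur_areas[ci] + warp_areas[pj] - inter)
        if ious:
            best = max(sorted(ious), key=lambda j: ious[j])
            if ious[best] >= reject_threshold:
                assignment[ci] = best
                likelihood[ci] = ious[best]
            else:
                assignment[ci] = None
        else:
            # centroid-proximity fallback for non-overlapping candidates
            assignment[ci] = None
            if warp_cents:
                cr, cc = cur_cents[ci]
                dists = {j: np.hypot(cr - r, cc - c)
                         for j, (r, c) in warp_cents.items()}
                jbest = min(sorted(dists), key=lambda j: dists[j])
                if dists[jbest] <= 2.0 * expected_radius:
                    assignment[ci] = jbest
                    likelihood[ci] = float(np.exp(-dists[jbest] ** 2 /
                                                  (2 * sigma**2)))
    # cap division arity
    claims: dict[int, list[int]] = {}
    for ci, pj in assignment.items():
        if pj is not None:
            claims.setdefault(pj, []).append(ci)
    for pj, cis in claims.items():
        if len(cis) > max_daughters:
            cis_sorted = sorted(cis, key=lambda c: (-likelihood.get(c, 0.0), c))
            for ci in cis_sorted[max_daughters:]:
                assignment[ci] = None
    return assignment


# --------------------------------------------------------------------------- #
# track construction
# --------------------------------------------------------------------------- #

def build_tracks(
    matchings: Sequence[dict[int, Optional[int]]],
    labels_per_frame: Sequence[Sequence[int]],
) -> tuple[list[Track], list[TrackRecordQ]]:
    """Build mother/daughter tracks from per-frame matchings.

    ``matchings[t-1]`` maps labels of frame ``t`` to labels of frame ``t-1``
    (or ``None``). Backward traversal from every chain end produces maximal
    chains; chains sharing a common ancestor prefix are split recursively
    into a mother track plus daughter tracks.
    """
    T = len(labels_per_frame)
    if len(matchings) != T - 1:
        raise ValueError("need one matching per consecutive frame pair")

    # forward links: (t, label) -> labels in t+1 matched to it
    children: dict[tuple[int, int], list[int]] = {}
    for t in range(1, T):
        seen = set()
        for ci, pj in matchings[t - 1].items():
            if ci in seen:
                raise ValueError(f"label {ci} matched twice in frame {t}")
            seen.add(ci)
            if pj is not None:
                children.setdefault((t - 1, pj), []).append(ci)

    # chain ends: states with no successor in the next frame
    ends = []
    for t in range(T):
        for lab in labels_per_frame[t]:
            if t == T - 1 or not children.get((t, lab)):
                ends.append((t, lab))

    chains = []
    for t_end, lab in sorted(ends):
        chain = [(t_end, lab)]
        t, cur = t_end, lab
        while t > 0:
            prev = matchings[t - 1].get(cur)
            if prev is None:
                break
            chain.append((t - 1, prev))
            t, cur = t - 1, prev
        chains.append(chain[::-1])

    tracks: list[Track] = []

    def lcp(group: list[list[tuple[int, int]]]) -> int:
        n = min(len(c) for c in group)
        for i in range(n):
            first = group[0][i]
            if any(c[i] != first for c in group[1:]):
                return i
        return n

    def emit(group: list[list[tuple[int, int]]], parent: int) -> None:
        by_head: dict[tuple[int, int], list[list[tuple[int, int]]]] = {}
        for c in group:
            by_head.setdefault(c[0], []).append(c)
        for _, sub in sorted(by_head.items()):
            if len(sub) == 1:
                tracks.append(Track(id=len(tracks) + 1, states=sub[0],
                                    parent=parent))
                continue
            k = lcp(sub)
            if k == 0:
                raise ValueError("overlapping chains share no prefix "
                                 "(inconsistent matching upstream)")
            mother = Track(id=len(tracks) + 1, states=sub[0][:k], parent=parent)
            tracks.append(mother)
            suffixes = [c[k:] for c in sub]
            if any(not s for s in suffixes):
                raise ValueError("duplicate chains detected "
                                 "(inconsistent matching upstream)")
            emit(suffixes, mother.id)

    emit(chains, 0)

    # conservation check: every state in exactly one track
    used: set[tuple[int, int]] = set()
    for tr in tracks:
        for st in tr.states:
            if st in used:
                raise ValueError(f"state {st} assigned to multiple tracks")
            used.add(st)

    track_of = {tr.id: tr for tr in tracks}
    q_records: list[TrackRecordQ] = []
    for tr in tracks:
        for i, (t, lab) in enumerate(tr.states):
            if i > 0:
                tp, xp = tr.states[i - 1]
                q_records.append(TrackRecordQ(t, lab, tp, xp))
            elif tr.parent:
                tp, xp = track_of[tr.parent].states[-1]
                q_records.append(TrackRecordQ(t, lab, tp, xp))
            else:
                q_records.append(TrackRecordQ(t, lab, None, None))
    return tracks, q_records


def split_overlapping_tracks(
    chains: Sequence[Sequence[tuple[int, int]]],
) -> list[Track]:
    """Resolve prefix-sharing chains into mother/daughter tracks.

    Convenience wrapper over the splitting step of :func:`build_tracks` for
    pre-built chains.
    """
    labels_per_frame: dict[int, list[int]] = {}
    for c in chains:
        for t, lab in c:
            labels_per_frame.setdefault(t, [])
            if lab not in labels_per_frame[t]:
                labels_per_frame[t].append(lab)
    if not labels_per_frame:
        return []
    T = max(labels_per_frame) + 1
    matchings: list[dict[int, Optional[int]]] = [dict() for _ in range(T - 1)]
    heads = set()
    for c in chains:
        heads.add(c[0])
        for (t0, l0), (t1, l1) in zip(c, c[1:]):
            if t1 != t0 + 1:
                raise ValueError("chain frames must be consecutive")
            matchings[t0][l1] = l0
    for t in range(T):
        for lab in labels_per_frame.get(t, []):
            if t > 0 and lab not in matchings[t - 1] and (t, lab) not in heads:
                matchings[t - 1][lab] = None
    frames = [labels_per_frame.get(t, []) for t in range(T)]
    tracks, _ = build_tracks(matchings, frames)
    return tracks


# --------------------------------------------------------------------------- #
# lineage graph
# --------------------------------------------------------------------------- #

def build_lineage_graph(tracks: Sequence[Track]) -> nx.DiGraph:
    """Acyclic oriented graph over cell states.

    Nodes are ``(frame, track_id)`` — the global graph labeling of cell
    states; migration edges connect consecutive states of a track, division
    edges run from a mother's last state to each daughter's first state.
    """
    g = nx.DiGraph()
    track_of = {tr.id: tr for tr in tracks}
    for tr in tracks:
        for t, _ in tr.states:
            g.add_node((t, tr.id))
        for (t0, _), (t1, _) in zip(tr.states, tr.states[1:]):
            if t1 != t0 + 1:
                raise ValueError(f"track {tr.id}: non-consecutive frames")
            g.add_edge((t0, tr.id), (t1, tr.id), kind="migration")
    for tr in tracks:
        if tr.parent:
            mother = track_of[tr.parent]
            g.add_edge((mother.end, mother.id), (tr.begin, tr.id),
                       kind="division")
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("lineage graph contains a cycle")
    for node in g.nodes:
        if g.in_degree(node) > 1:
            raise ValueError(f"state {node} has multiple predecessors")
    for node in g.nodes:
        div = [e for e in g.out_edges(node, data=True)
               if e[2]["kind"] == "division"]
        if len(div) > 2:
            raise ValueError(f"state {node} has more than 2 division edges")
    return g


def count_divisions(tracks: Sequence[Track]) -> int:
    """Number of mother tracks (tracks with at least one daughter)."""
    return len({tr.parent for tr in tracks if tr.parent})


def tracks_to_records(tracks: Sequence[Track]) -> list[TrackFileRecord]:
    """Serialize tracks as ``L B E P`` records (label = track id)."""
    return [TrackFileRecord(tr.id, tr.begin, tr.end, tr.parent)
            for tr in tracks]


def relabel_masks_by_track(
    labelmaps: Sequence[np.ndarray], tracks: Sequence[Track]
) -> list[np.ndarray]:
    """Rewrite per-frame segmentation labels as global track ids."""
    out = [np.zeros_like(np.asarray(lm), dtype=np.int64) for lm in labelmaps]
    for tr in tracks:
        for t, lab in tr.states:
            out[t][np.asarray(labelmaps[t]) == lab] = tr.id
    return out


def track_sequence(
    labelmaps: Sequence[np.ndarray],
    fields: Sequence[MotionField | None] | None = None,
    reject_threshold: float = 0.1,
    expected_radius: float = 6.0,
    fallback_sigma_rel: float = 1.0,
    max_daughters: int = 2,
):
    """Full tracking of a segmented sequence.

    ``fields[t]`` carries frame ``t`` onto frame ``t+1``; ``None`` (or a
    missing list) disables motion compensation. Returns
    ``(tracked_masks, records, tracks, graph)``.
    """
    T = len(labelmaps)
    matchings = []
    for t in range(1, T):
        fld = fields[t - 1] if fields is not None else None
        matchings.append(match_cells(
            np.asarray(labelmaps[t]), np.asarray(labelmaps[t - 1]), fld,
            reject_threshold=reject_threshold,
            expected_radius=expected_radius,
            fallback_sigma_rel=fallback_sigma_rel,
            max_daughters=max_daughters))
    frames = [np.unique(np.asarray(lm)[np.asarray(lm) > 0]).tolist()
              for lm in labelmaps]
    tracks, _ = build_tracks(matchings, frames)
    graph = build_lineage_graph(tracks)
    masks = relabel_masks_by_track(labelmaps, tracks)
    records = tracks_to_records(tracks)
    return masks, records, tracks, graph
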