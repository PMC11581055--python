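"""End-to-end orchestration: scale selection -> segmentation -> detection ->
refinement -> tracking, mirroring the train-on-01 / test-on-02 protocol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import detection, refinement, segmentation, tracking
from .config import default_config
from .interest_points import (InterestPointSet, detector_response,
                              regional_maxima)
from .io_ctc import SequenceHandle
from .motion import MotionField, clgof
from .scale_selection import feature_counts, select_scale
from .scale_space import diffuse_triplet, frame_triplet


@dataclass
class FrameAnalysis:
    """All per-frame intermediates needed by detection and refinement."""

    t: int
    scale_index: int
    diffused: np.ndarray            # central slab at the selected scale
    response: np.ndarray            # detector strength at the selected scale
    points: InterestPointSet
    superpixels: segmentation.SuperpixelMap
    gradmag: np.ndarray             # spatio-temporal |grad L| at the scale
    density: segmentation.DensityMap
    relief: np.ndarray


def _analyze_frame(seq: SequenceHandle, t: int, cfg: dict) -> FrameAnalysis:
    sc = cfg["scale_space"]
    triplet = frame_triplet(seq, t)
    ss = diffuse_triplet(
        triplet, n_scales=sc["n_scales"], step=sc["step"],
        conductance_k=sc["conductance_k"],
        conductance_form=sc["conductance_form"],
        steps_per_scale=sc["steps_per_scale"])
    det_cfg = dict(cfg["detector"])
    if det_cfg.get("sigma") is None:
        # matched blob scale: for moderately elongated cells the semi-major
        # axis is a ~ 1.15 r, so a/sqrt(2) ~ 0.8 r centers the |det H|
        # response on the blob
        det_cfg["sigma"] = 0.8 * cfg["detection"]["expected_radius"]
    # scale selection counts *noise* features, which the bare (unsmoothed)
    # response tracks; the blob-matched scale then localizes the points
    raw_cfg = dict(det_cfg)
    raw_cfg["sigma"] = 0.0
    raw_cfg["tau"] = 0.0
    msf = feature_counts(ss, raw_cfg)
    s_star = select_scale(msf.profile)
    diffused = ss.central(s_star)
    resp = detector_response(ss.maps[s_star], det_cfg)
    resp.scale_index = s_star
    points = regional_maxima(
        resp, min_strength=det_cfg["min_strength_rel"] * float(resp.S.max()),
        connectivity=det_cfg["connectivity"])
    slab = ss.maps[s_star]
    gz, gy, gx = np.gradient(slab)
    gradmag = np.sqrt(gz**2 + gy**2 + gx**2)[1]

    seg_cfg = cfg["segmentation"]
    bandwidth = seg_cfg["bandwidth_rel"] * cfg["detection"]["expected_radius"]
    density = segmentation.parzen_density(points, seq.shape, bandwidth)
    relief = segmentation.relief_map(diffused, density)
    edges = segmentation.edge_map(diffused)
    minima = segmentation.relief_minima(edges, seg_cfg["connectivity"])
    markers = segmentation.fuse_markers(points, minima)
    sp = segmentation.watershed_superpixels(
        relief, markers, min_size=seg_cfg["min_superpixel_px"],
        connectivity=seg_cfg["connectivity"])
    return FrameAnalysis(t=t, scale_index=s_star, diffused=diffused,
                         response=resp.S, points=points,
                         superpixels=sp, gradmag=gradmag, density=density,
                         relief=relief)


def motion_fields(seq: SequenceHandle, cfg: dict) -> list[MotionField]:
    """Optical-flow fields between all consecutive frame pairs (t -> t+1)."""
    mo = cfg["motion"]
    return [
        clgof(seq.frames[t], seq.frames[t + 1], alpha=mo["alpha"],
              rho=mo["rho"], n_iters=mo["n_iters"], n_warps=mo["n_warps"])
        for t in range(seq.n_frames - 1)
    ]


def analyze_sequence(
    seq: SequenceHandle, cfg: dict | None = None
) -> tuple[list[FrameAnalysis], list[MotionField]]:
    """Per-frame multi-scale analysis plus inter-frame motion."""
    cfg = cfg or default_config()
    fields = motion_fields(seq, cfg)
    analyses = [_analyze_frame(seq, t, cfg) for t in range(seq.n_frames)]
    return analyses, fields


def _frame_motion_mag(fields: list[MotionField], t: int) -> np.ndarray:
    """Motion magnitude attributed to frame t (field arriving at t)."""
    idx = t - 1 if t > 0 else 0
    return fields[idx].magnitude


def sequence_descriptors(
    analyses: Sequence[FrameAnalysis], fields: Sequence[MotionField]
):
    """Superpixel descriptors for every frame: list of (X, ids)."""
    out = []
    for fa in analyses:
        X, ids = detection.compute_descriptors(
            fa.superpixels, fa.diffused, fa.response,
            _frame_motion_mag(list(fields), fa.t), fa.gradmag)
        out.append((X, ids))
    return out


def train_on_sequence(
    seq: SequenceHandle,
    ref_masks: Sequence[np.ndarray],
    cfg: dict | None = None,
    analyses: Sequence[FrameAnalysis] | None = None,
    fields: Sequence[MotionField] | None = None,
) -> detection.DetectorModel:
    """Fit the cell/non-cell classifier on a reference-annotated sequence.

    Superpixels overlapping reference cells by >= 50% are the cell class.
    The descriptor cloud is DBSCAN-clustered (Mahalanobis metric) and the
    dominant cluster undersampled before training.
    """
    cfg = cfg or default_config()
    if analyses is None or fields is None:
        analyses, fields = analyze_sequence(seq, cfg)
    det_cfg = cfg["detection"]
    Xs, ys = [], []
    for (X, ids), fa, ref in zip(
            sequence_descriptors(analyses, fields), analyses, ref_masks):
        Xs.append(X)
        ys.append(detection.descriptor_labels(fa.superpixels, ref, ids))
    X = np.concatenate(Xs)
    y = np.concatenate(ys)
    assignment = detection.dbscan_cluster(
        X, min_pts=det_cfg["min_pts"],
        eps_percentile=det_cfg["eps_percentile"], seed=det_cfg["seed"])
    Xb, yb, _ = detection.balance_training_set(
        X, assignment, seed=det_cfg["seed"], extra=y)
    return detection.train_detector(
        Xb, yb, epochs=det_cfg["epochs"], lr=det_cfg["lr"],
        seed=det_cfg["seed"], batch=det_cfg["batch"],
        momentum=det_cfg["momentum"])


def segment_sequence(
    seq: SequenceHandle,
    model: detection.DetectorModel,
    cfg: dict | None = None,
    analyses: Sequence[FrameAnalysis] | None = None,
    fields: Sequence[MotionField] | None = None,
    refine: bool = True,
) -> list[np.ndarray]:
    """Classify superpixels, refine boundaries, split clusters.

    Returns one label map per frame (labels are frame-local, pre-tracking).
    """
    cfg = cfg or default_config()
    if analyses is None or fields is None:
        analyses, fields = analyze_sequence(seq, cfg)
    ref_cfg = cfg["refinement"]
    from scipy import ndimage as ndi

    labelmaps = []
    for (X, ids), fa in zip(sequence_descriptors(analyses, fields), analyses):
        _, mask = detection.classify_superpixels(model, X, fa.superpixels, ids)
        if refine and mask.any():
            mask = refinement.levelset_refine(
                fa.diffused, mask, n_iters=ref_cfg["n_iters"],
                nu=ref_cfg["nu"], window=ref_cfg["window"],
                reinit_every=ref_cfg["reinit_every"])
        labels, _ = ndi.label(mask, structure=ndi.generate_binary_structure(2, 1))
        # drop specks the level set could not remove
        ids_, counts = np.unique(labels[labels > 0], return_counts=True)
        tiny = ids_[counts < max(ref_cfg.get("min_region_px", 9), 1)]
        if tiny.size:
            labels[np.isin(labels, tiny)] = 0
        r = cfg["detection"]["expected_radius"]
        min_piece = ref_cfg["min_piece_px"]
        if min_piece is None:
            min_piece = int(round(0.15 * np.pi * r * r))
        labels = refinement.separate_clusters(
            labels, solidity_threshold=ref_cfg["solidity_threshold"],
            hmax=ref_cfg["hmax"],
            max_area=ref_cfg["area_factor"] * np.pi * r * r,
            min_piece=min_piece, intensity=fa.diffused,
            valley_rel=ref_cfg.get("valley_rel", 0.2))
        labelmaps.append(labels)
    return labelmaps


def track_segmented(
    labelmaps: Sequence[np.ndarray],
    fields: Sequence[MotionField] | None,
    cfg: dict | None = None,
):
    """Link a segmented sequence into tracks (see tracking.track_sequence)."""
    cfg = cfg or default_config()
    tr = cfg["tracking"]
    return tracking.track_sequence(
        labelmaps, fields,
        reject_threshold=tr["reject_threshold"],
        expected_radius=cfg["detection"]["expected_radius"],
        fallback_sigma_rel=tr["fallback_sigma_rel"],
        max_daughters=tr["max_daughters"])


def foreground_f1(
    pred_masks: Sequence[np.ndarray], ref_masks: Sequence[np.ndarray]
) -> float:
    """Per-pixel foreground F1 over a whole sequence."""
    tp = fp = fn = 0
    for p, r in zip(pred_masks, ref_masks):
        pb = np.asarray(p) > 0
        rb = np.asarray(r) > 0
        tp += int((pb & rb).sum())
        fp += int((pb & ~rb).sum())
        fn += int((~pb & rb).sum())
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 1.0
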