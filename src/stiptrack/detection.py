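"""Superpixel cell/non-cell classification.

Each watershed superpixel is summarized by a 9-dimensional descriptor —
regional mean and variance of (i) selected-scale diffused intensity,
(ii) detector response strength, (iii) motion displacement magnitude,
(iv) spatio-temporal intensity-gradient magnitude, plus the region area.

Background superpixels vastly outnumber cell superpixels, so before training
the descriptor cloud is clustered with DBSCAN under the Mahalanobis metric
and the most populous cluster is undersampled to the size of the second most
populous one (class-prototype balancing). A small fully connected network
(9 -> 12 -> 6 -> 2, ReLU, softmax cross-entropy; 212 parameters) then
separates cell from non-cell regions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from sklearn.cluster import DBSCAN

from .segmentation import SuperpixelMap

LAYER_SIZES = (9, 12, 6, 2)
N_PARAMS = sum(a * b for a, b in zip(LAYER_SIZES[:-1], LAYER_SIZES[1:])) + sum(
    LAYER_SIZES[1:]
)  # 192 weights + 20 biases = 212


# --------------------------------------------------------------------------- #
# descriptors
# --------------------------------------------------------------------------- #

def compute_descriptors(
    superpixels: SuperpixelMap | np.ndarray,
    diffused: np.ndarray,
    response: np.ndarray,
    motion_mag: np.ndarray,
    gradmag: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-superpixel 9-feature descriptors.

    Returns ``(X, ids)`` with ``X[k]`` the descriptor of superpixel
    ``ids[k]``: [mean_int, var_int, mean_resp, var_resp, mean_mot, var_mot,
    mean_grad, var_grad, area]. Variances are population variances.
    """
    labels = (superpixels.labels if isinstance(superpixels, SuperpixelMap)
              else np.asarray(superpixels))
    maps = [np.asarray(m, dtype=np.float64)
            for m in (diffused, response, motion_mag, gradmag)]
    for m in maps:
        if m.shape != labels.shape:
            raise ValueError("all maps must share the superpixel map shape")
    ids = np.unique(labels)
    ids = ids[ids > 0]
    feats = []
    # scipy's labeled stats bin over 0..max(label) internally and emit a
    # harmless 0/0 warning for absent bins; the requested ids are all present
    with np.errstate(invalid="ignore", divide="ignore"):
        for m in maps:
            feats.append(ndi.mean(m, labels=labels, index=ids))
            feats.append(ndi.variance(m, labels=labels, index=ids))
        area = ndi.sum_labels(np.ones_like(labels, dtype=np.float64),
                              labels=labels, index=ids)
    feats.append(area)
    return np.stack(feats, axis=1), ids


def descriptor_labels(
    superpixels: SuperpixelMap | np.ndarray,
    reference_mask: np.ndarray,
    ids: np.ndarray,
    min_overlap: float = 0.5,
) -> np.ndarray:
    """Supervised labels: 1 if >= ``min_overlap`` of a superpixel's pixels
    lie inside reference cell regions, else 0."""
    labels = (superpixels.labels if isinstance(superpixels, SuperpixelMap)
              else np.asarray(superpixels))
    frac = ndi.mean((np.asarray(reference_mask) > 0).astype(np.float64),
                    labels=labels, index=ids)
    return (np.asarray(frac) >= min_overlap).astype(np.int64)


# --------------------------------------------------------------------------- #
# DBSCAN class-prototype balancing
# --------------------------------------------------------------------------- #

@dataclass
class ClusterAssignment:
    """Per-sample DBSCAN result: cluster id (-1 = noise) and core flag."""

    cluster_ids: np.ndarray
    is_core: np.ndarray


def mahalanobis_inverse_cov(X: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
    """Inverse covariance for the Mahalanobis metric, ridge-regularized so a
    singular (e.g. constant-feature) covariance still inverts."""
    X = np.asarray(X, dtype=np.float64)
    C = np.cov(X, rowvar=False)
    C = np.atleast_2d(C)
    lam = ridge * max(np.trace(C) / C.shape[0], 1.0)
    return np.linalg.inv(C + lam * np.eye(C.shape[0]))


def estimate_eps(
    X: np.ndarray,
    VI: np.ndarray,
    percentile: float = 15.0,
    max_samples: int = 500,
    seed: int = 0,
) -> float:
    """Epsilon as a percentile of pairwise Mahalanobis distances on a seeded
    subsample (adapts to feature scaling without manual tuning)."""
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=np.float64)
    if len(X) > max_samples:
        X = X[rng.choice(len(X), max_samples, replace=False)]
    diffs = X[:, None, :] - X[None, :, :]
    d2 = np.einsum("ijk,kl,ijl->ij", diffs, VI, diffs)
    iu = np.triu_indices(len(X), k=1)
    dists = np.sqrt(np.maximum(d2[iu], 0.0))
    eps = float(np.percentile(dists, percentile))
    return eps if eps > 0 else 1.0


def dbscan_cluster(
    samples: np.ndarray,
    eps: float | None = None,
    min_pts: int = 10,
    eps_percentile: float = 15.0,
    seed: int = 0,
) -> ClusterAssignment:
    """Density-based clustering of descriptors under Mahalanobis distance."""
    X = np.asarray(samples, dtype=np.float64)
    if len(X) < min_pts:
        raise ValueError(f"need at least min_pts={min_pts} samples, got {len(X)}")
    VI = mahalanobis_inverse_cov(X)
    if eps is None:
        eps = estimate_eps(X, VI, percentile=eps_percentile, seed=seed)
    db = DBSCAN(eps=eps, min_samples=min_pts, metric="mahalanobis",
                metric_params={"VI": VI}, algorithm="brute").fit(X)
    is_core = np.zeros(len(X), dtype=bool)
    is_core[db.core_sample_indices_] = True
    return ClusterAssignment(cluster_ids=db.labels_.astype(np.int64),
                             is_core=is_core)


def balance_training_set(
    samples: np.ndarray,
    assignment: ClusterAssignment,
    seed: int = 0,
    extra: np.ndarray | None = None,
):
    """Undersample the most populous cluster to the size of the second most
    populous one.

    Only multiplicities change — feature vectors are never altered; noise
    points and all other clusters are kept as-is. Returns
    ``(balanced_samples, kept_indices)`` or, with ``extra`` (e.g. class
    labels), ``(balanced_samples, balanced_extra, kept_indices)``.
    """
    X = np.asarray(samples)
    cids = np.asarray(assignment.cluster_ids)
    real = cids[cids >= 0]
    uniq, counts = (np.unique(real, return_counts=True) if real.size
                    else (np.array([], dtype=int), np.array([], dtype=int)))
    if uniq.size < 2:
        warnings.warn("fewer than 2 DBSCAN clusters; training set unchanged",
                      stacklevel=2)
        keep = np.arange(len(X))
    else:
        order = np.argsort(counts)[::-1]
        largest = uniq[order[0]]
        target = int(counts[order[1]])
        members = np.flatnonzero(cids == largest)
        rng = np.random.default_rng(seed)
        kept_members = rng.choice(members, size=target, replace=False)
        keep = np.sort(np.concatenate(
            [np.flatnonzero(cids != largest), kept_members]))
    if extra is not None:
        return X[keep], np.asarray(extra)[keep], keep
    return X[keep], keep


# --------------------------------------------------------------------------- #
# the 9x12x6x2 dense network
# --------------------------------------------------------------------------- #

@dataclass
class DetectorModel:
    """Fully connected 9->12->6->2 classifier with z-score standardization.

    Weights/biases are plain NumPy arrays; the stored standardization
    constants are applied identically at train and predict time.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    mu: np.ndarray
    sd: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return int(sum(w.size for w in self.weights)
                   + sum(b.size for b in self.biases))

    def _forward(self, X: np.ndarray):
        acts = [X]
        h = X
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ W + b
            if i < len(self.weights) - 1:
                h = np.maximum(h, 0.0)
            acts.append(h)
        return acts

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = (np.asarray(X, dtype=np.float64) - self.mu) / self.sd
        logits = self._forward(X)[-1]
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != LAYER_SIZES[0]:
            raise ValueError(f"descriptors must be (n, {LAYER_SIZES[0]})")
        if len(X) == 0:
            return np.empty(0, dtype=np.int64)
        return np.argmax(self.predict_proba(X), axis=1)

    def save(self, path: str | Path) -> None:
        payload = {
            "layer_sizes": list(LAYER_SIZES),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "mu": self.mu.tolist(),
            "sd": self.sd.tolist(),
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "DetectorModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            weights=[np.array(w) for w in payload["weights"]],
            biases=[np.array(b) for b in payload["biases"]],
            mu=np.array(payload["mu"]),
            sd=np.array(payload["sd"]),
            meta=payload.get("meta", {}),
        )


def _softmax_xent(logits: np.ndarray, y: np.ndarray):
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    p = e / e.sum(axis=1, keepdims=True)
    n = len(y)
    loss = -np.log(np.maximum(p[np.arange(n), y], 1e-300)).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


def train_detector(
    X: np.ndarray,
    y: np.ndarray,
    epochs: int = 200,
    lr: float = 1e-2,
    seed: int = 0,
    batch: int = 64,
    momentum: float = 0.9,
) -> DetectorModel:
    """Train the 9x12x6x2 network with seeded SGD + momentum.

    Features are z-scored with training-set statistics (stored in the
    model). Training is fully deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if X.ndim != 2 or X.shape[1] != LAYER_SIZES[0]:
        raise ValueError(f"training descriptors must be (n, {LAYER_SIZES[0]})")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires samples from both classes")

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd

    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(LAYER_SIZES[:-1], LAYER_SIZES[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    vel_w = [np.zeros_like(w) for w in weights]
    vel_b = [np.zeros_like(b) for b in biases]

    model = DetectorModel(weights=weights, biases=biases, mu=mu, sd=sd)
    n = len(Xs)
    loss_curve = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            xb, yb = Xs[idx], y[idx]
            acts = model._forward(xb)
            loss, dlogits = _softmax_xent(acts[-1], yb)
            epoch_loss += loss * len(idx)
            # backprop through the dense stack
            grad = dlogits
            for i in range(len(weights) - 1, -1, -1):
                a_in = acts[i]
                gw = a_in.T @ grad
                gb = grad.sum(axis=0)
                if i > 0:
                    grad = (grad @ weights[i].T) * (acts[i] > 0)
                vel_w[i] = momentum * vel_w[i] - lr * gw
                vel_b[i] = momentum * vel_b[i] - lr * gb
                weights[i] += vel_w[i]
                biases[i] += vel_b[i]
        loss_curve.append(epoch_loss / n)
    model.meta = {"seed": int(seed), "epochs": int(epochs),
                  "loss_curve": loss_curve}
    assert model.n_params == N_PARAMS
    return model


def classify_superpixels(
    model: DetectorModel,
    descriptors: np.ndarray,
    superpixels: SuperpixelMap | np.ndarray | None = None,
    ids: np.ndarray | None = None,
):
    """Assign cell (1) / non-cell (0) to each superpixel descriptor.

    With ``superpixels``/``ids`` given, also return the binary cell mask
    obtained by merging all foreground superpixels.
    """
    pred = model.predict(descriptors)
    if superpixels is None:
        return pred
    labels = (superpixels.labels if isinstance(superpixels, SuperpixelMap)
              else np.asarray(superpixels))
    if ids is None:
        ids = np.unique(labels)
        ids = ids[ids > 0]
    lut = np.zeros(int(labels.max()) + 1, dtype=bool)
    lut[np.asarray(ids)[pred == 1]] = True
    return pred, lut[labels]
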