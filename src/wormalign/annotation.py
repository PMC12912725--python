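"""Pixel-weighted multi-spectral cell annotation utilities.

A labeler network emits a per-pixel probability map over ``K = 185``
classes (background plus every cell label in the corpus).  This module
implements the machinery around that map: the pixel-weighting scheme used
during training (rare labels and high-confidence human labels weigh
more), the pixel-wise weighted cross-entropy loss and weighted MeanIoU
metric, the mask-weighted extraction of per-ROI label probabilities, and
the label postprocessing heuristics (over/under-segmentation handling,
L/R ambiguity, rare-class and non-neuronal deletions, confidence floor).

Probability maps and one-hot targets are stored ``(K, X, Y, Z)``
channel-first; ROI volumes are the usual integer grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_softmax, softmax

from wormalign.volume import roi_centroids, roi_indices

#: Human-confidence weighting: confidence score -> weight factor.
CONFIDENCE_WEIGHTS = {2: 50.0, 3: 600.0, 4: 900.0, 5: 1000.0}

#: Corpus count of the most frequent neuronal label; normalizes rarity weights.
COUNT_NORMALIZATION = 130.0

#: Classes with too few human labels to train or evaluate on; deleted in
#: postprocessing, together with the non-neuronal 'glia' and 'granule'.
RARE_CLASSES = (
    "ADF", "AFD", "AVF", "AVG", "DB02", "DD01", "RIF", "RIG",
    "RMF", "RMH", "SAB", "SABV", "SIAD", "SIBD", "VA01", "VD01",
)

NON_NEURONAL = ("glia", "granule")

#: Weight given to pixels of ROIs the human left unlabeled.
UNLABELED_WEIGHT = 1e-3


@dataclass
class LabelCatalog:
    """Ordered label list (background first) with per-label corpus counts."""

    labels: list[str]
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.labels or self.labels[0] != "background":
            raise ValueError("catalog must start with the background label")

    @property
    def k(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    @classmethod
    def generic(cls, k: int = 185, counts: dict[str, int] | None = None) -> "LabelCatalog":
        """A synthetic catalog of ``k`` classes for tests and desk-scale runs."""
        labels = ["background"] + [f"N{i:03d}" for i in range(1, k)]
        return cls(labels, counts or {})


def build_weight_volume(
    labels: dict[int, tuple[str, int]],
    rois: np.ndarray,
    catalog: LabelCatalog,
    confidence_weights: dict[int, float] | None = None,
    unlabeled_weight: float = UNLABELED_WEIGHT,
) -> np.ndarray:
    """Per-pixel training weights from human labels.

    Background pixels get weight 1; pixels of an ROI labeled ``l`` with
    confidence ``c`` get ``(130 / N(l)) * f(c)`` where ``N(l)`` is the
    corpus count of the label; pixels of unlabeled ROIs get a near-zero
    weight so they neither train as background nor as their (unknown)
    class.
    """
    f = confidence_weights or CONFIDENCE_WEIGHTS
    rois = np.asarray(rois)
    weights = np.ones(rois.shape, dtype=float)
    for k in roi_indices(rois):
        mask = rois == k
        entry = labels.get(int(k))
        if entry is None:
            weights[mask] = unlabeled_weight
            continue
        label, confidence = entry
        if confidence not in f:
            raise ValueError(f"confidence {confidence} outside {sorted(f)}")
        count = catalog.counts.get(label, 0)
        if count <= 0:
            raise ValueError(f"label {label!r} has no corpus count")
        weights[mask] = (COUNT_NORMALIZATION / count) * f[confidence]
    return weights


def one_hot_labels(
    labels: dict[int, str], rois: np.ndarray, catalog: LabelCatalog
) -> np.ndarray:
    """One-hot ``(K, X, Y, Z)`` target; background channel where no label."""
    rois = np.asarray(rois)
    out = np.zeros((catalog.k,) + rois.shape, dtype=float)
    claimed = np.zeros(rois.shape, dtype=bool)
    for k, label in labels.items():
        mask = rois == k
        out[catalog.index(label)][mask] = 1.0
        claimed |= mask
    out[0][~claimed] = 1.0
    return out


def weighted_cross_entropy(
    logits: np.ndarray, target: np.ndarray, weights: np.ndarray
) -> float:
    """Pixel-wise weighted cross-entropy, ``-1/(XYZK) sum W L log softmax``.

    Note the normalization includes the number of classes ``K``, so the
    per-pixel contribution is ``W * log K / K`` under uniform logits.
    """
    logits = np.asarray(logits, dtype=float)
    target = np.asarray(target, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if logits.shape != target.shape or logits.shape[1:] != weights.shape:
        raise ValueError("shape mismatch between logits, target, and weights")
    logp = log_softmax(logits, axis=0)
    return float(-(weights[None] * target * logp).sum() / logits.size)


def argmax_map(probabilities: np.ndarray) -> np.ndarray:
    """One-hot argmax of a probability map; ties go to the lowest label index."""
    p = np.asarray(probabilities)
    out = np.zeros_like(p, dtype=float)
    idx = p.argmax(axis=0)
    np.put_along_axis(out, idx[None], 1.0, axis=0)
    return out


def weighted_mean_iou(
    probabilities: np.ndarray,
    target: np.ndarray,
    weights: np.ndarray,
    empty_channel_value: float | None = 1.0,
) -> float:
    """Weighted intersection-over-union of the argmax map, averaged over classes.

    Per class the score is ``sum(W L A) / sum(W max(L, A))`` over pixels.
    Channels whose weighted union is empty contribute
    ``empty_channel_value`` (vacuous truth, the default) or are skipped
    when it is None.
    """
    a = argmax_map(probabilities)
    target = np.asarray(target, dtype=float)
    w = np.asarray(weights, dtype=float)[None]
    inter = (w * target * a).sum(axis=(1, 2, 3))
    union = (w * np.maximum(target, a)).sum(axis=(1, 2, 3))
    scores = []
    for i, u in zip(inter, union):
        if u == 0:
            if empty_channel_value is not None:
                scores.append(empty_channel_value)
        else:
            scores.append(i / u)
    return float(np.mean(scores))


@dataclass
class PredictionMatrix:
    """Per-ROI label probabilities ``D`` (rows sum to 1) with the ROI indices."""

    d: np.ndarray  # (V, K)
    roi_indices: np.ndarray  # (V,) ROI index per row

    def label_index(self, row: int) -> int:
        return int(self.d[row].argmax())

    def confidence(self, row: int) -> float:
        return float(self.d[row].max())


def _boundary_mask(rois: np.ndarray, index: int) -> np.ndarray:
    """Voxels of an ROI with an existing face-adjacent voxel outside it.

    Neighbors beyond the volume faces do not exist and are ignored, so a
    voxel on the volume face can still be interior.
    """
    mask = rois == index
    padded = np.pad(mask, 1, mode="edge")
    boundary = np.zeros_like(mask)
    for axis in range(3):
        for step in (0, 2):
            sl = [slice(1, -1)] * 3
            sl[axis] = slice(step, padded.shape[axis] - 2 + step)
            boundary |= mask & ~padded[tuple(sl)]
    return boundary


def extract_roi_labels(
    probabilities: np.ndarray, rois: np.ndarray
) -> PredictionMatrix:
    """Mask-weighted average of the probability map over every ROI.

    The mask is 0 outside the ROI, 0.01 on its face-adjacent boundary
    voxels and 1 in the interior, weighting central pixels most when
    deciding identity.  Each row of the result sums to 1.
    """
    p = np.asarray(probabilities, dtype=float)
    rois = np.asarray(rois)
    idxs = roi_indices(rois)
    d = np.zeros((len(idxs), p.shape[0]))
    for row, k in enumerate(idxs):
        mask = rois == k
        if not mask.any():
            raise ValueError(f"empty ROI {k}")
        m = np.where(mask, 1.0, 0.0)
        m[_boundary_mask(rois, int(k))] = 0.01
        total = m.sum()
        d[row] = (p * m[None]).sum(axis=(1, 2, 3)) / total
    return PredictionMatrix(d, idxs.astype(int))


def softmax_probabilities(logits: np.ndarray) -> np.ndarray:
    """Convert raw network output to per-pixel class probabilities."""
    return softmax(np.asarray(logits, dtype=float), axis=0)


def postprocess_labels(
    pred: PredictionMatrix,
    rois: np.ndarray,
    catalog: LabelCatalog,
    probabilities: np.ndarray | None = None,
    confidence_floor: float = 0.75,
    merge_threshold: float = 3.0,
    lr_threshold: float = 0.10,
    underseg_prob: float = 0.75,
    underseg_min_voxels: int = 10,
    underseg_min_fraction: float = 0.20,
    deleted_classes: tuple[str, ...] = RARE_CLASSES + NON_NEURONAL,
) -> dict[int, tuple[str, float]]:
    """Resolve per-ROI labels into a final consistent assignment.

    ROIs are visited by descending confidence.  A duplicate label within
    ``merge_threshold`` voxels is kept on both ROIs (over-segmentation);
    farther duplicates lose the lower-confidence label.  An ROI where
    another class exceeds ``underseg_prob`` on at least
    ``underseg_min_voxels`` voxels or ``underseg_min_fraction`` of its
    voxels is dropped (under-segmentation).  When both L and R subclasses
    of a class exceed ``lr_threshold``, the class-level label is emitted
    with the summed confidence.  Labels in ``deleted_classes``, background
    argmaxes, and labels below ``confidence_floor`` are removed.
    """
    rois = np.asarray(rois)
    centroids = {
        int(k): c
        for k, c in zip(pred.roi_indices, roi_centroids(rois, pred.roi_indices))
    }
    order = np.argsort(-pred.d.max(axis=1), kind="stable")
    assigned: dict[str, tuple[int, np.ndarray]] = {}  # label -> (roi, centroid)
    out: dict[int, tuple[str, float]] = {}
    for row in order:
        k = int(pred.roi_indices[row])
        n_i = pred.label_index(row)
        if n_i == 0:
            continue  # background is not a cell label
        label = catalog.labels[n_i]
        confidence = pred.confidence(row)

        # L/R ambiguity: report the class with summed confidence
        if label[-1] in "LR" and len(label) > 2:
            stem = label[:-1]
            sibling = stem + ("R" if label[-1] == "L" else "L")
            if sibling in catalog.labels:
                p_self = pred.d[row, n_i]
                p_sib = pred.d[row, catalog.index(sibling)]
                if p_self > lr_threshold and p_sib > lr_threshold:
                    label = stem
                    confidence = float(p_self + p_sib)

        # under-segmentation: strong foreign predictions inside the ROI
        if probabilities is not None:
            mask = rois == k
            strong = np.asarray(probabilities) > underseg_prob
            strong[n_i] = False
            foreign = int((strong[:, mask]).any(axis=0).sum())
            if foreign >= underseg_min_voxels or foreign >= underseg_min_fraction * mask.sum():
                continue

        if label in assigned:
            other_roi, other_centroid = assigned[label]
            dist = float(np.linalg.norm(centroids[k] - other_centroid))
            if dist > merge_threshold:
                continue  # distant duplicate: drop the lower-confidence label
        else:
            assigned[label] = (k, centroids[k])
        out[k] = (label, confidence)

    return {
        k: (label, conf)
        for k, (label, conf) in out.items()
        if label not in deleted_classes and conf >= confidence_floor
    }
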