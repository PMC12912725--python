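"""ROI linkage across time points or animals by similarity-matrix clustering.

Every pair of registered images contributes candidate links between the
warped moving ROIs and the fixed ROIs.  Each link is scored by the
heuristic

``M_ij = R * 1/(1 + w1*d) * q^w2 * r^w3 * exp(-(w4*a + w5*c + w6*n))``

where ``R`` indicates that the pair was registered, ``d`` the displacement
of the moving ROI under the DDF, ``q`` the registration quality (global
NCC of warped vs fixed image), ``r`` the fractional ROI overlap, ``a`` a
brightness (within-animal tracking) or color (cross-animal) dissimilarity,
``c`` the residual centroid distance, and ``n`` the unweighted nonrigid
penalty of the DDF.  The sparse symmetric matrix over all ROIs is then
agglomeratively clustered; each cluster is one cell identity.

The cross-animal variant replaces the brightness heuristic with a
4-channel color distance (weight ``w4 = 7``), forbids collisions
(``w8 = 0``), and lowers the merge floor to ``w7 = 1e-9``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from wormalign import losses
from wormalign.ddf import sample_ddf, warp_image
from wormalign.euler import ncc
from wormalign.volume import roi_centroids, roi_indices


@dataclass(frozen=True)
class LinkageWeights:
    """Similarity-heuristic weights ``w1..w6`` plus the clustering
    parameters ``w7`` (merge floor) and ``w8`` (acceptable collision
    fraction)."""

    w1: float = 2.0
    w2: float = 25.0
    w3: float = 1.0
    w4: float = 3.0
    w5: float = 1.0
    w6: float = 1.0
    w7: float = 1e-4
    w8: float = 0.05
    use_color: bool = False

    def __post_init__(self):
        for name in ("w1", "w2", "w3", "w4", "w5", "w6", "w7", "w8"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def within_animal(cls) -> "LinkageWeights":
        """Within-animal tracking defaults."""
        return cls()

    @classmethod
    def cross_animal(cls) -> "LinkageWeights":
        """Cross-animal variant: color heuristic, w4=7, w7=1e-9, w8=0."""
        return cls(w4=7.0, w7=1e-9, w8=0.0, use_color=True)


@dataclass
class RoiPairFeatures:
    """Per-link features entering the similarity heuristic."""

    registered: bool = True
    displacement: float = 0.0  # d: moving-ROI centroid displacement (voxels)
    quality: float = 1.0  # q: NCC of warped moving vs fixed image
    overlap: float = 1.0  # r: intersection / max size
    brightness: float = 0.0  # a: brightness or color dissimilarity
    centroid_distance: float = 0.0  # c: warped vs fixed centroid distance
    nonrigid: float = 0.0  # n: unweighted nonrigid penalty of the DDF


def similarity_entry(f: RoiPairFeatures, w: LinkageWeights | None = None) -> float:
    """Evaluate the linkage heuristic for one ROI pair.

    ``q`` is clamped to [0, 1] before exponentiation: a negative NCC means
    the registration carries no confidence.
    """
    w = w or LinkageWeights()
    if not f.registered:
        return 0.0
    q = min(max(f.quality, 0.0), 1.0)
    return float(
        1.0
        / (1.0 + w.w1 * f.displacement)
        * q**w.w2
        * f.overlap**w.w3
        * np.exp(-(w.w4 * f.brightness + w.w5 * f.centroid_distance + w.w6 * f.nonrigid))
    )


def color_vector(roi_mask: np.ndarray, four_channel_volume: np.ndarray) -> np.ndarray:
    """Per-channel mean brightness of an ROI, normalized to mean 1."""
    vol = np.asarray(four_channel_volume, dtype=float)
    if vol.ndim != 4:
        raise ValueError("expected a channel-last 4-D volume")
    mask = np.asarray(roi_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI")
    means = vol[mask].mean(axis=0)
    total = means.mean()
    if total == 0:
        raise ValueError("all-zero ROI")
    return means / total


def color_distance(a: np.ndarray, b: np.ndarray) -> float:
    """L1 distance between two normalized color vectors."""
    return float(np.abs(np.asarray(a, float) - np.asarray(b, float)).sum())


@dataclass
class Registration:
    """A solved registration problem: DDF maps ``fixed`` frame coordinates
    to ``moving`` frame coordinates."""

    moving: int
    fixed: int
    ddf: np.ndarray


@dataclass
class SimilarityMatrix:
    """Sparse symmetric linkage matrix plus the ROI bookkeeping."""

    matrix: sparse.csr_matrix
    roi_ids: list[tuple[int, int]]  # global index -> (timepoint/animal, roi index)
    index: dict[tuple[int, int], int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {key: i for i, key in enumerate(self.roi_ids)}


def build_similarity_matrix(
    registrations: list[Registration],
    rois: dict[int, np.ndarray],
    intensities: dict[int, np.ndarray],
    weights: LinkageWeights | None = None,
) -> SimilarityMatrix:
    """Score all candidate ROI links from a set of solved registrations.

    ``rois[t]`` is the ROI volume and ``intensities[t]`` the marker image
    at timepoint (or animal) ``t``; for the color variant ``intensities``
    must be channel-last 4-channel volumes.  Unregistered pairs contribute
    nothing.  The matrix is symmetrized by ``M_ji <- M_ij`` wherever
    ``M_ji = 0`` and ``M_ij != 0``.
    """
    w = weights or LinkageWeights()
    roi_ids = [
        (t, int(k)) for t in sorted(rois) for k in roi_indices(rois[t])
    ]
    index = {key: i for i, key in enumerate(roi_ids)}
    n = len(roi_ids)

    # per-timepoint brightness / color summaries for the a_ij heuristic
    bright: dict[tuple[int, int], float] = {}
    colors: dict[tuple[int, int], np.ndarray] = {}
    for t in sorted(rois):
        vol = np.asarray(intensities[t], dtype=float)
        idxs = roi_indices(rois[t])
        if w.use_color:
            for k in idxs:
                colors[(t, int(k))] = color_vector(rois[t] == k, vol)
        else:
            means = {
                int(k): float(vol[rois[t] == k].mean()) for k in idxs
            }
            mu = np.mean(list(means.values())) if means else 1.0
            for k, v in means.items():
                bright[(t, k)] = v / mu if mu > 0 else v

    mat = sparse.lil_matrix((n, n))
    for reg in registrations:
        if reg.fixed not in rois or reg.moving not in rois:
            raise KeyError(f"missing ROI volume for pair {reg.moving}->{reg.fixed}")
        fixed_rois = rois[reg.fixed]
        moving_rois = rois[reg.moving]
        warped = warp_image(moving_rois, reg.ddf, interpolation="nearest")
        fixed_img = np.asarray(intensities[reg.fixed], dtype=float)
        moving_img = np.asarray(intensities[reg.moving], dtype=float)
        warped_img = warp_image(moving_img, reg.ddf)
        quality = ncc(fixed_img, warped_img)
        nonrigid = losses.nonrigid_penalty(reg.ddf)

        warped_idx = roi_indices(warped)
        if len(warped_idx) == 0:
            continue
        warped_centroids = {
            int(k): c for k, c in zip(warped_idx, roi_centroids(warped, warped_idx))
        }
        warped_sizes = {int(k): int((warped == k).sum()) for k in warped_idx}
        fixed_idx = roi_indices(fixed_rois)
        fixed_centroids = {
            int(k): c for k, c in zip(fixed_idx, roi_centroids(fixed_rois, fixed_idx))
        }
        fixed_sizes = {int(k): int((fixed_rois == k).sum()) for k in fixed_idx}

        # overlap counts between warped moving and fixed ROIs
        both = (warped > 0) & (fixed_rois > 0)
        pairs = Counter(zip(warped[both].ravel().tolist(), fixed_rois[both].ravel().tolist()))
        for (ki, kj), inter in pairs.items():
            ki, kj = int(ki), int(kj)
            gi = index[(reg.moving, ki)]
            gj = index[(reg.fixed, kj)]
            cen_w = warped_centroids[ki]
            disp = float(np.linalg.norm(sample_ddf(reg.ddf, cen_w)[0]))
            if w.use_color:
                a = color_distance(
                    colors[(reg.moving, ki)], colors[(reg.fixed, kj)]
                )
            else:
                a = abs(bright[(reg.moving, ki)] - bright[(reg.fixed, kj)])
            feats = RoiPairFeatures(
                registered=True,
                displacement=disp,
                quality=quality,
                overlap=inter / max(warped_sizes[ki], fixed_sizes[kj]),
                brightness=a,
                centroid_distance=float(
                    np.linalg.norm(cen_w - fixed_centroids[kj])
                ),
                nonrigid=nonrigid,
            )
            val = similarity_entry(feats, w)
            if val > 0:
                mat[gi, gj] = max(mat[gi, gj], val)

    mat = mat.tocsr()
    lower = mat.T.multiply(mat.T.astype(bool) > mat.astype(bool))
    mat = mat + lower.tocsr()
    return SimilarityMatrix(mat, roi_ids)


@dataclass
class ClusterAssignment:
    """Mapping from ROI to cluster id; members listed per cluster."""

    clusters: list[list[tuple[int, int]]]

    @property
    def roi_to_cluster(self) -> dict[tuple[int, int], int]:
        return {
            roi: ci for ci, members in enumerate(self.clusters) for roi in members
        }


def cluster_rois(
    sim: SimilarityMatrix, w7: float = 1e-4, w8: float = 0.05
) -> ClusterAssignment:
    """Greedy average-linkage agglomeration of the similarity matrix.

    Merges happen in decreasing cluster-similarity order; a merge below
    ``w7`` is never performed; a merge is rejected (and that pair barred)
    when the merged cluster's collision fraction — the fraction of its
    timepoints contributing more than one ROI — would exceed ``w8``.
    """
    n = sim.matrix.shape[0]
    dense = np.asarray(sim.matrix.todense(), dtype=float)
    dense = np.maximum(dense, dense.T)
    np.fill_diagonal(dense, 0.0)

    members: list[list[int] | None] = [[i] for i in range(n)]
    sizes = np.ones(n)
    active = np.ones(n, dtype=bool)
    sims = dense.copy()
    times = [sim.roi_ids[i][0] for i in range(n)]

    def collision_ok(a: int, b: int) -> bool:
        counts = Counter(times[i] for i in members[a] + members[b])
        collisions = sum(1 for v in counts.values() if v > 1)
        return collisions / len(counts) <= w8

    while True:
        sims_masked = np.where(np.outer(active, active), sims, -np.inf)
        np.fill_diagonal(sims_masked, -np.inf)
        flat = np.argmax(sims_masked)
        a, b = np.unravel_index(flat, sims_masked.shape)
        best = sims_masked[a, b]
        if not np.isfinite(best) or best < w7:
            break
        if a > b:
            a, b = b, a
        if not collision_ok(a, b):
            sims[a, b] = sims[b, a] = 0.0
            continue
        # average-linkage update (Lance-Williams)
        na, nb = sizes[a], sizes[b]
        sims[a, :] = (na * sims[a, :] + nb * sims[b, :]) / (na + nb)
        sims[:, a] = sims[a, :]
        sims[a, b] = sims[b, a] = 0.0
        members[a] = members[a] + members[b]
        members[b] = None
        sizes[a] = na + nb
        active[b] = False

    clusters = [
        [sim.roi_ids[i] for i in m] for m in members if m is not None
    ]
    return ClusterAssignment(clusters)


def extract_traces(
    assignment: ClusterAssignment,
    green: dict[int, np.ndarray],
    red: dict[int, np.ndarray],
    rois: dict[int, np.ndarray],
) -> "pd.DataFrame":
    """Per-cluster activity traces: mean in-ROI green / mean in-ROI red.

    Returns a timepoint-by-cluster table; timepoints where a cluster has no
    ROI are missing (NaN), not zero.  A cluster with several ROIs at one
    timepoint (a collision) averages over their union.
    """
    import pandas as pd

    timepoints = sorted(rois)
    data = np.full((len(timepoints), len(assignment.clusters)), np.nan)
    t_index = {t: i for i, t in enumerate(timepoints)}
    for ci, roi_list in enumerate(assignment.clusters):
        per_t: dict[int, list[int]] = {}
        for t, k in roi_list:
            per_t.setdefault(t, []).append(k)
        for t, ks in per_t.items():
            mask = np.isin(rois[t], ks)
            if not mask.any():
                raise ValueError(f"empty ROI {ks} at timepoint {t}")
            denom = float(np.asarray(red[t], float)[mask].mean())
            data[t_index[t], ci] = (
                float(np.asarray(green[t], float)[mask].mean()) / denom
            )
    return pd.DataFrame(data, index=timepoints)


def cluster_label_accuracy(
    assignment: ClusterAssignment,
    labels: dict[tuple[int, int], str | None],
    ignore_lr: bool = False,
    min_labels: int = 3,
) -> float:
    """Fraction of known labels matching their cluster's majority label.

    Only clusters with more than two known labels enter either sum.  With
    ``ignore_lr`` the trailing L/R subclass letter is stripped before
    comparison.  Raises if no cluster qualifies.
    """

    def canon(label: str) -> str:
        if ignore_lr and len(label) > 2 and label[-1] in "LR":
            return label[:-1]
        return label

    num = 0
    den = 0
    for members in assignment.clusters:
        lab = [
            canon(labels[roi])
            for roi in members
            if labels.get(roi) not in (None, "UNKNOWN")
        ]
        if len(lab) < min_labels:
            continue
        counts = Counter(lab)
        num += counts.most_common(1)[0][1]
        den += len(lab)
    if den == 0:
        raise ValueError("no cluster with more than two known labels")
    return num / den


def filter_clusters_by_presence(
    assignment: ClusterAssignment, n_groups: int, min_fraction: float = 0.5
) -> ClusterAssignment:
    """Keep clusters present in more than ``min_fraction`` of groups (animals)."""
    kept = []
    for members in assignment.clusters:
        groups = {t for t, _ in members}
        if len(groups) > min_fraction * n_groups:
            kept.append(members)
    return ClusterAssignment(kept)
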