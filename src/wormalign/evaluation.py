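"""Registration / tracking / annotation quality statistics.

Three estimators: the mean matched-centroid distance between ROI volumes,
the sparse-GFP trace-mismatch error rate (an estimate of the
mis-registration rate of a tracking run), and a simulation-based
estimator of labeling accuracy from behavior-encoding consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from wormalign.volume import roi_centroids, roi_indices


def centroid_distance_metric(
    fixed_rois: np.ndarray, warped_rois: np.ndarray
) -> float:
    """Mean Euclidean distance between per-index centroids of two ROI volumes.

    Only indices present in both volumes contribute; raises when none are
    shared.
    """
    shared = np.intersect1d(roi_indices(fixed_rois), roi_indices(warped_rois))
    if len(shared) == 0:
        raise ValueError("no shared ROI indices")
    a = roi_centroids(fixed_rois, shared)
    b = roi_centroids(warped_rois, shared)
    return float(np.linalg.norm(a - b, axis=1).mean())


def gfp_error_rate(
    traces: np.ndarray, threshold: float = 1.5
) -> tuple[float, float]:
    """Mis-registration rate from a sparse-GFP recording.

    ``traces`` is a (timepoints, neurons) array of green/red ratios (NaN
    where a neuron is absent).  A neuron is GFP-positive iff its median
    trace exceeds ``threshold``.  A sample is a mismatch iff it differs
    from the neuron's median by more than ``threshold`` and exactly one of
    {sample, median} exceeds ``threshold`` — i.e. a GFP-negative neuron
    picked up a GFP-positive timepoint or vice versa.  The rate is

    ``mismatches / (total samples * 2 * Frac * (1 - Frac))``

    where ``Frac`` is the GFP-positive fraction; the denominator corrects
    for same-polarity errors this analysis cannot see.  Returns
    ``(rate, Frac)``.
    """
    t = np.asarray(traces, dtype=float)
    if t.ndim != 2 or t.size == 0:
        raise ValueError("traces must be a nonempty (timepoints, neurons) array")
    present = np.isfinite(t)
    if not present.any():
        raise ValueError("no finite samples")
    medians = np.nanmedian(np.where(present, t, np.nan), axis=0)
    frac = float((medians > threshold).mean())
    if frac in (0.0, 1.0):
        raise ValueError(
            "GFP-positive fraction is 0 or 1; the detectability correction "
            "is undefined"
        )
    deviates = np.abs(t - medians[None]) > threshold
    crosses = (t > threshold) ^ (medians[None] > threshold)
    mismatches = int((deviates & crosses & present).sum())
    total = int(present.sum())
    rate = mismatches / (total * 2.0 * frac * (1.0 - frac))
    return rate, frac


@dataclass
class EncodingAtlas:
    """Behavior-encoding expectations and pools for the accuracy simulation.

    ``expected`` maps each consistently encoding cell class to its expected
    encoding.  ``class_pools[c]`` lists the encodings of every
    human-labeled neuron of class ``c`` across reference animals;
    ``animal_pools[a]`` lists the encodings of every fitted neuron in
    animal ``a`` of the evaluated cohort.
    """

    expected: dict[str, str]
    class_pools: dict[str, list[str]] = field(default_factory=dict)
    animal_pools: dict[int, list[str]] = field(default_factory=dict)


def estimate_label_accuracy(
    labels: list[tuple[int, str]],
    atlas: EncodingAtlas,
    observed_match_fraction: float,
    trials: int = 1000,
    seed: int = 0,
) -> int:
    """Simulation-based estimate of the percentage of correct labels.

    For every candidate accuracy ``p_sim`` in 0..100 percent: in each
    trial, every label (an ``(animal, class)`` pair over the consistent
    classes) is reassigned with probability ``p_sim`` to a random
    human-labeled neuron of the same class, else to a random neuron of the
    same animal; the simulated fraction with the expected encoding is
    averaged over ``trials``.  The estimate is the ``p_sim`` whose mean
    simulated fraction is closest to the observed one (ties toward the
    lower value).
    """
    labels = [(a, c) for a, c in labels if c in atlas.expected]
    if not labels:
        raise ValueError("no labels from consistently encoding classes")
    p_correct = []
    p_random = []
    for animal, cls in labels:
        pool = atlas.class_pools.get(cls)
        if not pool:
            raise ValueError(f"empty atlas pool for class {cls!r}")
        rand_pool = atlas.animal_pools.get(animal)
        if not rand_pool:
            raise ValueError(f"empty neuron pool for animal {animal!r}")
        exp = atlas.expected[cls]
        p_correct.append(np.mean([e == exp for e in pool]))
        p_random.append(np.mean([e == exp for e in rand_pool]))
    p_correct = np.asarray(p_correct)
    p_random = np.asarray(p_random)

    rng = np.random.default_rng(seed)
    n = len(labels)
    f_sim = np.zeros(101)
    for p in range(101):
        correct = rng.random((trials, n)) < p / 100.0
        match_prob = np.where(correct, p_correct[None], p_random[None])
        matches = rng.random((trials, n)) < match_prob
        f_sim[p] = matches.mean()
    return int(np.argmin(np.abs(f_sim - observed_match_fraction)))
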