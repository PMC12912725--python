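"""Canonical volume / ROI / centroid types and preprocessing.

Conventions
-----------
* Intensity volumes are float arrays indexed ``(x, y, z)`` (optionally a
  trailing channel axis ``c``), 0-based, coordinates at voxel centers.
* ROI volumes are non-negative integer arrays of the same spatial shape;
  0 is background and each positive index is one cell.  Indices need not be
  contiguous.
* Centroid sets are ``(200, 3)`` float arrays in voxel units.  Valid rows
  have all coordinates >= 0; padding rows are exactly ``(-1, -1, -1)`` and
  sit contiguously at the tail.  Row order is the matching key between the
  fixed and moving sets.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

#: Canonical spatial dimensions used for full-scale registration problems.
CANONICAL_DIMS = (284, 120, 64)

#: Number of rows in a padded centroid set.
CENTROID_CAPACITY = 200

#: Sentinel value of padding rows in a centroid set.
CENTROID_PAD = -1.0


def preprocess_volume(raw: np.ndarray, target_dims: tuple[int, int, int]) -> np.ndarray:
    """Median-subtract, clamp, and crop/pad a raw volume about its center of mass.

    The median pixel value is subtracted, negative values are clamped to
    zero, and the result is cropped or zero-padded to ``target_dims`` about
    the intensity center of mass (computed on the clamped image).  Ties in
    crop-window placement are resolved toward lower indices.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("preprocess_volume: input contains non-finite values")
    if raw.ndim != 3:
        raise ValueError("preprocess_volume expects a scalar 3-D volume")
    work = raw - np.median(raw)
    np.clip(work, 0.0, None, out=work)

    total = work.sum()
    if total > 0:
        com = np.array(ndimage.center_of_mass(work))
    else:
        com = (np.array(work.shape, dtype=float) - 1.0) / 2.0

    out = np.zeros(target_dims, dtype=work.dtype)
    src_lo, src_hi, dst_lo, dst_hi = [], [], [], []
    for axis, tgt in enumerate(target_dims):
        # window start so that the center of mass lands mid-window;
        # exact half-voxel ties go to the lower index
        ideal = com[axis] - (tgt - 1) / 2.0
        start = math.ceil(ideal - 0.5)
        lo, hi = start, start + tgt
        src_lo.append(max(lo, 0))
        src_hi.append(min(hi, work.shape[axis]))
        dst_lo.append(max(-lo, 0))
        dst_hi.append(max(-lo, 0) + max(0, min(hi, work.shape[axis]) - max(lo, 0)))
    if all(hi > lo for lo, hi in zip(src_lo, src_hi)):
        out[tuple(slice(a, b) for a, b in zip(dst_lo, dst_hi))] = work[
            tuple(slice(a, b) for a, b in zip(src_lo, src_hi))
        ]
    return out


def roi_indices(rois: np.ndarray) -> np.ndarray:
    """Sorted positive cell indices present in an ROI volume."""
    vals = np.unique(np.asarray(rois))
    return vals[vals > 0]


def roi_centroids(rois: np.ndarray, indices: np.ndarray | None = None) -> np.ndarray:
    """Mean voxel coordinate of every requested ROI index, shape ``(n, 3)``."""
    rois = np.asarray(rois)
    if indices is None:
        indices = roi_indices(rois)
    if len(indices) == 0:
        return np.zeros((0, 3))
    coms = ndimage.center_of_mass(np.ones_like(rois, dtype=float), rois, indices)
    return np.asarray(coms, dtype=float).reshape(len(indices), 3)


def pad_centroids(entries: np.ndarray, capacity: int = CENTROID_CAPACITY) -> np.ndarray:
    """Pad an ``(n, 3)`` centroid table to ``(capacity, 3)`` with the sentinel."""
    entries = np.asarray(entries, dtype=float).reshape(-1, 3)
    if entries.shape[0] > capacity:
        raise ValueError(
            f"{entries.shape[0]} centroids exceed capacity {capacity}"
        )
    out = np.full((capacity, 3), CENTROID_PAD)
    out[: entries.shape[0]] = entries
    return out


def valid_rows(centroids: np.ndarray) -> np.ndarray:
    """Boolean mask of non-padding rows of a centroid set."""
    centroids = np.asarray(centroids)
    return ~np.all(centroids == CENTROID_PAD, axis=1)


def extract_matched_centroids(
    fixed_rois: np.ndarray,
    moving_rois: np.ndarray,
    capacity: int = CENTROID_CAPACITY,
) -> tuple[np.ndarray, np.ndarray]:
    """Matched, padded centroid sets for the indices shared by two ROI volumes.

    Indices absent from either volume are dropped; both outputs share row
    ordering (ascending shared index) and are padded to ``capacity`` rows
    with ``(-1, -1, -1)``.
    """
    fixed_rois = np.asarray(fixed_rois)
    moving_rois = np.asarray(moving_rois)
    if fixed_rois.shape != moving_rois.shape:
        raise ValueError("ROI volumes must share dimensions")
    shared = np.intersect1d(roi_indices(fixed_rois), roi_indices(moving_rois))
    if len(shared) > capacity:
        raise ValueError(
            f"{len(shared)} shared ROIs exceed centroid capacity {capacity}"
        )
    return (
        pad_centroids(roi_centroids(fixed_rois, shared), capacity),
        pad_centroids(roi_centroids(moving_rois, shared), capacity),
    )


def convert_axis_order(vol: np.ndarray, order_tag: str) -> np.ndarray:
    """Permute a volume stored with axis order ``order_tag`` into canonical order.

    ``order_tag`` names the storage order of the input axes using the letters
    ``x``, ``y``, ``z`` and optionally ``c`` (e.g. ``"zyx"`` or ``"czyx"``).
    The canonical order is ``xyz`` with any channel axis last.  The
    permutation is lossless; converting back with :func:`revert_axis_order`
    is bit-identical.
    """
    perm = _permutation(order_tag, np.asarray(vol).ndim)
    return np.transpose(vol, perm)


def revert_axis_order(vol: np.ndarray, order_tag: str) -> np.ndarray:
    """Inverse of :func:`convert_axis_order` for the same tag."""
    perm = _permutation(order_tag, np.asarray(vol).ndim)
    return np.transpose(vol, np.argsort(perm))


def _permutation(order_tag: str, ndim: int) -> tuple[int, ...]:
    tag = order_tag.lower()
    if sorted(tag) not in (["x", "y", "z"], ["c", "x", "y", "z"]):
        raise ValueError(f"unknown axis-order tag: {order_tag!r}")
    if len(tag) != ndim:
        raise ValueError(
            f"axis-order tag {order_tag!r} does not match a {ndim}-D array"
        )
    canonical = "xyz" + ("c" if "c" in tag else "")
    return tuple(tag.index(axis) for axis in canonical)
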