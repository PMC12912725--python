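"""Dense displacement fields (DDFs) and warping.

A DDF is an ``(X, Y, Z, 3)`` array of displacements ``(dx, dy, dz)`` in
voxels.  Semantics are *pull-based*: fixed-image coordinate ``(x, y, z)``
corresponds to moving-image coordinate ``(x, y, z) + DDF[x, y, z]``, so the
warped (predicted fixed) image reads the moving image at displaced fixed
coordinates.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from wormalign.volume import CENTROID_PAD, valid_rows


def _base_grid(dims: tuple[int, int, int]) -> np.ndarray:
    return np.stack(
        np.meshgrid(*(np.arange(d, dtype=float) for d in dims), indexing="ij"),
        axis=-1,
    )


def warp_image(
    moving: np.ndarray,
    ddf: np.ndarray,
    interpolation: str = "trilinear",
    fill: float = 0.0,
) -> np.ndarray:
    """Warp a moving image (or ROI volume) by a DDF.

    ``out[x, y, z] = moving[(x, y, z) + ddf[x, y, z]]`` with trilinear
    interpolation for intensities or nearest-neighbor for integer label
    volumes.  Out-of-bounds samples take ``fill`` (default 0).  Multi-channel
    inputs (trailing channel axis) are warped per channel with the same DDF.
    """
    moving = np.asarray(moving)
    ddf = np.asarray(ddf, dtype=float)
    spatial = moving.shape[:3]
    if ddf.shape != spatial + (3,):
        raise ValueError(f"DDF shape {ddf.shape} does not match volume {spatial}")
    order = {"trilinear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    coords = _base_grid(spatial) + ddf
    coord_list = [coords[..., 0], coords[..., 1], coords[..., 2]]
    if moving.ndim == 3:
        return ndimage.map_coordinates(
            moving, coord_list, order=order, mode="constant", cval=fill
        )
    if moving.ndim == 4:
        return np.stack(
            [
                ndimage.map_coordinates(
                    moving[..., c], coord_list, order=order, mode="constant", cval=fill
                )
                for c in range(moving.shape[3])
            ],
            axis=-1,
        )
    raise ValueError("moving must be a 3-D or 4-D (channel-last) array")


def sample_ddf(ddf: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Trilinearly sample a DDF at fractional points, shape ``(n, 3)``.

    Sampling is edge-clamped so points on the volume boundary are valid.
    """
    ddf = np.asarray(ddf, dtype=float)
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    coord_list = [points[:, 0], points[:, 1], points[:, 2]]
    return np.stack(
        [
            ndimage.map_coordinates(ddf[..., m], coord_list, order=1, mode="nearest")
            for m in range(3)
        ],
        axis=-1,
    )


def warp_centroids(fixed_centroids: np.ndarray, ddf: np.ndarray) -> np.ndarray:
    """Predicted moving centroids: fixed centroid + DDF at the centroid.

    The DDF is evaluated at the fractional centroid position by trilinear
    interpolation.  Padding rows ``(-1, -1, -1)`` pass through unchanged.
    """
    fixed_centroids = np.asarray(fixed_centroids, dtype=float)
    out = np.full_like(fixed_centroids, CENTROID_PAD)
    mask = valid_rows(fixed_centroids)
    if mask.any():
        pts = fixed_centroids[mask]
        out[mask] = pts + sample_ddf(ddf, pts)
    return out


def rigid_ddf(
    theta_deg: float,
    translation: tuple[float, float, float],
    dims: tuple[int, int, int],
) -> np.ndarray:
    """DDF of a rigid-body transform: z-rotation about the image center plus a shift.

    ``d[p] = R (p - c) + c + t - p`` with ``c = (dims - 1) / 2``.
    """
    theta = np.deg2rad(theta_deg)
    rot = np.array(
        [
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    center = (np.array(dims, dtype=float) - 1.0) / 2.0
    grid = _base_grid(tuple(dims))
    rel = grid - center
    return rel @ rot.T + center + np.asarray(translation, dtype=float) - grid


def mask_z(ddf: np.ndarray) -> np.ndarray:
    """Zero the z-displacement component, keeping voxels within their z-slice."""
    out = np.array(ddf, dtype=float, copy=True)
    out[..., 2] = 0.0
    return out
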