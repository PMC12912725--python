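"""Differentiable versions of the registration losses.

These mirror the plain-numpy definitions in :mod:`wormalign.losses`
(which are the reference implementations for metrics and tests) but
operate on :class:`~wormalign.nn.tensor.Tensor` displacement fields in
channel-first layout ``(N, 3, X, Y, Z)``.  Agreement between the two
implementations is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np

from wormalign.losses import M_FLOOR, LossWeights, SlidingWindowSpec
from wormalign.nn import functional as F
from wormalign.nn.tensor import Tensor


def lncc_image_loss(
    fixed: np.ndarray, warped: Tensor, spec: SlidingWindowSpec
) -> Tensor:
    """Negative local squared zero-normalized cross-correlation.

    ``fixed`` and ``warped`` are ``(N, X, Y, Z)`` (single channel).
    """
    n = spec.n
    f = Tensor(fixed)
    ef = F.window_mean3d(f, n)
    ep = F.window_mean3d(warped, n)
    efp = F.window_mean3d(f * warped, n)
    vf = (F.window_mean3d(f * f, n) - ef * ef).clip_min(0.0)
    vp = (F.window_mean3d(warped * warped, n) - ep * ep).clip_min(0.0)
    num = efp - ef * ep
    return -((num * num) / (vf * vp + spec.epsilon)).mean()


def ncc2_image_loss(fixed: np.ndarray, warped: Tensor) -> Tensor:
    """Negative squared channel-averaged global NCC for (N, C, X, Y, Z) pairs."""
    n, c = fixed.shape[:2]
    m = fixed[0, 0].size
    total = None
    for b in range(n):
        for ch in range(c):
            f = fixed[b, ch]
            p = warped[b, ch]
            mu_p = p.mean()
            centered = p - mu_p
            var_p = (centered * centered).mean() + 1e-12
            f0 = f - f.mean()
            var_f = float(f0.var()) + 1e-12
            num = (Tensor(f0) * centered).sum()
            term = (num * num) / (m**2 * var_f) / var_p
            total = term if total is None else total + term
    return -total * (1.0 / (n * c))


def centroid_alignment_loss(
    ddf: Tensor, fixed_points: np.ndarray, moving_points: np.ndarray
) -> Tensor:
    """Mean distance between predicted and true moving centroids (one sample).

    ``ddf`` is ``(3, X, Y, Z)``; the points are the valid (unpadded) rows.
    """
    offsets = F.sample_points3d(ddf, fixed_points)
    diff = offsets + Tensor(fixed_points - moving_points)
    sq = (diff * diff).sum(axis=1) + 1e-12
    return (sq**0.5).mean()


def _central_diffs(d: Tensor) -> tuple[Tensor, Tensor, Tensor]:
    i = slice(1, -1)
    dx = (d[:, :, 2:, i, i] - d[:, :, :-2, i, i]) * 0.5
    dy = (d[:, :, i, 2:, i] - d[:, :, i, :-2, i]) * 0.5
    dz = (d[:, :, i, i, 2:] - d[:, :, i, i, :-2]) * 0.5
    return dx, dy, dz


def gradient_norm(d: Tensor) -> Tensor:
    dx, dy, dz = _central_diffs(d)
    return (dx * dx + dy * dy + dz * dz).mean()


def gradient_norm_2d(d: Tensor) -> Tensor:
    i = slice(1, -1)
    dx = (d[:, :, 2:, i, :] - d[:, :, :-2, i, :]) * 0.5
    dy = (d[:, :, i, 2:, :] - d[:, :, i, :-2, :]) * 0.5
    return (dx * dx + dy * dy).mean()


def difference_norm(d: Tensor) -> Tensor:
    return (d * d).mean()


def axis_difference_norm(d: Tensor) -> Tensor:
    dz = d[:, 2]
    return (dz * dz).mean()


def nonrigid_penalty(d: Tensor) -> Tensor:
    dims = d.shape[2:]
    grid = np.stack(
        np.meshgrid(*(np.arange(s, dtype=d.data.dtype) for s in dims), indexing="ij"),
        axis=0,
    )[None]
    diff = d + Tensor(grid)
    dx, dy, dz = _central_diffs(diff)
    m = (dx * dx + dy * dy + dz * dz).clip_min(M_FLOOR)
    return (m + m**-1.0 - 2.0).abs().mean()


def composite_loss(
    ddf: Tensor,
    fixed: np.ndarray,
    warped: Tensor,
    weights: LossWeights,
    window: SlidingWindowSpec,
    fixed_points: list[np.ndarray] | None = None,
    moving_points: list[np.ndarray] | None = None,
) -> tuple[Tensor, dict[str, float]]:
    """Assemble the full training loss for one minibatch.

    ``ddf`` is ``(N, 3, X, Y, Z)``; ``fixed``/``warped`` are
    ``(N, C, X, Y, Z)``; the centroid point lists hold the valid rows per
    sample.  Returns the scalar loss tensor and a float breakdown.
    """
    if weights.image_loss == "lncc":
        image = lncc_image_loss(fixed[:, 0], warped[:, 0], window)
    elif weights.image_loss == "ncc2":
        image = ncc2_image_loss(fixed, warped)
    else:
        raise ValueError(f"unknown image loss {weights.image_loss!r}")

    grad = gradient_norm_2d(ddf) if weights.grad_2d else gradient_norm(ddf)
    diff = difference_norm(ddf)
    axis = axis_difference_norm(ddf)
    nonrigid = nonrigid_penalty(ddf)

    total = weights.w_image * image + weights.w_reg * (
        weights.reg_grad * grad
        + weights.reg_diff * diff
        + weights.reg_axis * axis
        + weights.reg_nonrigid * nonrigid
    )
    parts = {
        "image": image.item(),
        "grad": grad.item(),
        "diff": diff.item(),
        "axis": axis.item(),
        "nonrigid": nonrigid.item(),
    }
    if weights.use_centroid and fixed_points is not None:
        terms = []
        for b, (fp, mp) in enumerate(zip(fixed_points, moving_points)):
            if len(fp):
                terms.append(centroid_alignment_loss(ddf[b], fp, mp))
        if terms:
            cent = terms[0]
            for t in terms[1:]:
                cent = cent + t
            cent = cent * (1.0 / len(terms))
            total = total + weights.w_centroid * cent
            parts["centroid"] = cent.item()
    parts["total"] = total.item()
    return total, parts
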