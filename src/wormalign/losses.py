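"""Registration loss and regularization terms.

The composite training objective is

``Loss = w_I * L_I + w_C * L_C + w_R * (g * L_Grad + d * L_Diff + a * L_AxisDiff + n * L_Nonrigid)``

with an image term (negative local squared zero-normalized cross
correlation), a supervised centroid-alignment term, and four DDF
regularizers.  Presets cover the single-channel worm configuration, the
jellyfish variant (no centroid supervision, 2-D gradient norm, z-masked
DDF), and the unsupervised multi-channel discovery variant (squared
channel-averaged global NCC image loss).

These are the plain numpy evaluations used for metrics and tests; the
differentiable counterparts used in training live in
:mod:`wormalign.nn.losses` and are tested for agreement with these.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from wormalign.volume import valid_rows

#: Floor applied to the gradient-magnitude statistic M before forming 1/M.
M_FLOOR = 1e-8


@dataclass(frozen=True)
class SlidingWindowSpec:
    """LNCC sliding-cube parameters: side length ``n`` and stabilizer ``epsilon``."""

    n: int = 16
    epsilon: float = 1e-5

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("window side must be >= 2")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass(frozen=True)
class LossWeights:
    """Weights of the composite loss and its regularization sub-terms."""

    w_image: float = 1.0
    w_centroid: float = 0.1
    w_reg: float = 1.0
    reg_grad: float = 0.02
    reg_diff: float = 0.005
    reg_axis: float = 0.001
    reg_nonrigid: float = 0.02
    use_centroid: bool = True
    grad_2d: bool = False
    image_loss: str = "lncc"  # "lncc" or "ncc2" (squared channel-averaged NCC)
    mask_z: bool = False

    def __post_init__(self):
        for name in (
            "w_image",
            "w_centroid",
            "w_reg",
            "reg_grad",
            "reg_diff",
            "reg_axis",
            "reg_nonrigid",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def worm(cls) -> "LossWeights":
        """Single-channel worm preset (the defaults)."""
        return cls()

    @classmethod
    def jellyfish(cls) -> "LossWeights":
        """No centroid supervision, in-plane gradient norm, z-masked DDF."""
        return cls(w_centroid=0.0, use_centroid=False, grad_2d=True, mask_z=True)

    @classmethod
    def discovery(cls) -> "LossWeights":
        """Unsupervised multi-channel preset: squared channel-averaged NCC image
        loss; regularizer sub-weights (0.05, 0.0025, 0, 0.05)."""
        return cls(
            w_centroid=0.0,
            use_centroid=False,
            image_loss="ncc2",
            reg_grad=0.05,
            reg_diff=0.0025,
            reg_axis=0.0,
            reg_nonrigid=0.05,
        )

    def scaled(self, **kwargs) -> "LossWeights":
        return replace(self, **kwargs)


def _window_sum(x: np.ndarray, n: int) -> np.ndarray:
    """Sums over all valid n-cube window positions via integral volumes."""
    s = x
    for axis in range(3):
        c = np.cumsum(s, axis=axis)
        pad_shape = list(c.shape)
        pad_shape[axis] = 1
        c = np.concatenate([np.zeros(pad_shape, dtype=c.dtype), c], axis=axis)
        hi = [slice(None)] * 3
        lo = [slice(None)] * 3
        hi[axis] = slice(n, c.shape[axis])
        lo[axis] = slice(0, c.shape[axis] - n)
        s = c[tuple(hi)] - c[tuple(lo)]
    return s


def image_loss_lncc(
    fixed: np.ndarray, warped: np.ndarray, spec: SlidingWindowSpec | None = None
) -> float:
    """Negative local squared zero-normalized cross-correlation.

    ``L_I = -mean over valid n-cube positions of
    [E(F P) - E(F) E(P)]^2 / (V(F) V(P) + eps)`` with sliding-cube mean
    ``E`` and variance ``V = E(X^2) - E(X)^2``.  Windows are dense (stride
    1), valid positions only.
    """
    spec = spec or SlidingWindowSpec()
    fixed = np.asarray(fixed, dtype=float)
    warped = np.asarray(warped, dtype=float)
    if fixed.shape != warped.shape:
        raise ValueError("images must share dimensions")
    if any(d < spec.n for d in fixed.shape):
        raise ValueError(f"image dims {fixed.shape} smaller than window {spec.n}")
    n3 = spec.n**3
    ef = _window_sum(fixed, spec.n) / n3
    ep = _window_sum(warped, spec.n) / n3
    efp = _window_sum(fixed * warped, spec.n) / n3
    vf = np.maximum(_window_sum(fixed * fixed, spec.n) / n3 - ef * ef, 0.0)
    vp = np.maximum(_window_sum(warped * warped, spec.n) / n3 - ep * ep, 0.0)
    lncc = (efp - ef * ep) ** 2 / (vf * vp + spec.epsilon)
    return float(-lncc.mean())


def centroid_loss(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean Euclidean distance between matched centroid rows.

    Padding rows ``(-1, -1, -1)`` are excluded from both the sum and the
    denominator.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    mask = valid_rows(y_true) & valid_rows(y_pred)
    if not mask.any():
        raise ValueError("centroid_loss requires at least one valid row")
    d = np.linalg.norm(y_true[mask] - y_pred[mask], axis=1)
    return float(d.mean())


def _central_differences(d: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interior central differences of an (X, Y, Z, 3) field along x, y, z."""
    i = slice(1, -1)
    dx = 0.5 * (d[2:, i, i] - d[:-2, i, i])
    dy = 0.5 * (d[i, 2:, i] - d[i, :-2, i])
    dz = 0.5 * (d[i, i, 2:] - d[i, i, :-2])
    return dx, dy, dz


def gradient_norm(d: np.ndarray) -> float:
    """Mean squared central-difference gradient of the DDF over interior voxels."""
    d = np.asarray(d, dtype=float)
    if any(s < 3 for s in d.shape[:3]):
        raise ValueError("gradient_norm requires dims >= 3 per axis")
    dx, dy, dz = _central_differences(d)
    total = (dx * dx + dy * dy + dz * dz).sum()
    interior = (d.shape[0] - 2) * (d.shape[1] - 2) * (d.shape[2] - 2)
    return float(total / (3 * interior))


def gradient_norm_2d(d: np.ndarray) -> float:
    """In-plane variant: only x- and y-derivatives enter the penalty.

    Used for recordings where deformation is constrained to z-slices; fields
    varying only along z contribute nothing.
    """
    d = np.asarray(d, dtype=float)
    if any(s < 3 for s in d.shape[:2]):
        raise ValueError("gradient_norm_2d requires x/y dims >= 3")
    i = slice(1, -1)
    dx = 0.5 * (d[2:, i, :] - d[:-2, i, :])
    dy = 0.5 * (d[i, 2:, :] - d[i, :-2, :])
    total = (dx * dx + dy * dy).sum()
    interior = (d.shape[0] - 2) * (d.shape[1] - 2) * d.shape[2]
    return float(total / (3 * interior))


def difference_norm(d: np.ndarray) -> float:
    """Mean squared voxel displacement: ``sum(D^2) / (3 X Y Z)``."""
    d = np.asarray(d, dtype=float)
    return float((d * d).sum() / (3 * d[..., 0].size))


def axis_difference_norm(d: np.ndarray) -> float:
    """Mean squared z-displacement: ``sum(D_z^2) / (X Y Z)``."""
    d = np.asarray(d, dtype=float)
    dz = d[..., 2]
    return float((dz * dz).sum() / dz.size)


def nonrigid_penalty(d: np.ndarray) -> float:
    """Rigidity-aware bending penalty; exactly zero on rigid-body DDFs.

    The difference field ``D_diff = D - D_ref`` with
    ``D_ref[x, y, z] = (-x, -y, -z)`` has a rotation-invariant gradient
    magnitude ``M = (dD_diff/dx)^2 + (dD_diff/dy)^2 + (dD_diff/dz)^2`` per
    component; under any rigid-body transform ``M = 1``.  The penalty is the
    interior mean of ``|M + 1/M - 2|`` (``M`` floored at ``M_FLOOR`` before
    inversion).
    """
    d = np.asarray(d, dtype=float)
    if any(s < 3 for s in d.shape[:3]):
        raise ValueError("nonrigid_penalty requires dims >= 3 per axis")
    grid = np.stack(
        np.meshgrid(*(np.arange(s, dtype=float) for s in d.shape[:3]), indexing="ij"),
        axis=-1,
    )
    diff = d + grid  # D - D_ref with D_ref = -p
    dx, dy, dz = _central_differences(diff)
    m = np.maximum(dx * dx + dy * dy + dz * dz, M_FLOOR)
    interior = (d.shape[0] - 2) * (d.shape[1] - 2) * (d.shape[2] - 2)
    return float(np.abs(m + 1.0 / m - 2.0).sum() / (3 * interior))


def multichannel_ncc_loss(fixed: np.ndarray, warped: np.ndarray) -> float:
    """Negative squared channel-averaged global NCC for channel-last 4-D volumes."""
    fixed = np.asarray(fixed, dtype=float)
    warped = np.asarray(warped, dtype=float)
    if fixed.shape != warped.shape or fixed.ndim != 4:
        raise ValueError("expected matching 4-D channel-last volumes")
    total = 0.0
    for c in range(fixed.shape[3]):
        f = fixed[..., c]
        p = warped[..., c]
        vf, vp = f.var(), p.var()
        if vf == 0.0 or vp == 0.0:
            raise ValueError(f"zero-variance channel {c}")
        num = ((f - f.mean()) * (p - p.mean())).sum()
        total += num**2 / (f.size**2 * vf * vp)
    return float(-total / fixed.shape[3])


def total_loss(
    image_term: float,
    centroid_term: float,
    reg_terms: tuple[float, float, float, float],
    weights: LossWeights | None = None,
) -> float:
    """Assemble the composite loss from precomputed components.

    ``reg_terms`` is ``(L_Grad, L_Diff, L_AxisDiff, L_Nonrigid)``.  Presets
    without centroid supervision drop that term regardless of its value.
    """
    w = weights or LossWeights()
    grad, diff, axis, nonrigid = reg_terms
    reg = (
        w.reg_grad * grad
        + w.reg_diff * diff
        + w.reg_axis * axis
        + w.reg_nonrigid * nonrigid
    )
    out = w.w_image * image_term + w.w_reg * reg
    if w.use_centroid:
        out += w.w_centroid * centroid_term
    return float(out)
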