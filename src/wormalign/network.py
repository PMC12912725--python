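"""Registration-network training, inference, and augmentation.

The registration model maps a concatenated (fixed, moving) volume pair to
a dense displacement field and is trained to minimize the composite loss
of :mod:`wormalign.losses`: local NCC between the warped moving and fixed
images, supervised centroid alignment, and the four DDF regularizers.
Variants: the jellyfish configuration masks z-displacements and drops
centroid supervision; the multi-channel discovery configuration
concatenates 4-channel pairs along the existing channel axis and trains
unsupervised with a squared channel-averaged NCC image loss.

Full-scale training (16 base channels, canonical ``(284, 120, 64)``
volumes, thousands of problems) requires accelerator hardware; the
defaults here are desk-scale: 4 base channels on ``(64, 32, 16)``
phantoms, which train in minutes on one CPU.
"""

from __future__ import annotations

import gc
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from wormalign.losses import LossWeights, SlidingWindowSpec
from wormalign.nn import losses as nnl
from wormalign.nn.functional import warp3d
from wormalign.nn.modules import LabelerUNet, LocalNet, Module
from wormalign.nn.optim import Adam
from wormalign.nn.tensor import Tensor
from wormalign.volume import CENTROID_PAD, valid_rows


@dataclass
class LocalNetSpec:
    """Architecture hyperparameters of the registration backbone."""

    in_channels: int = 2
    base_channels: int = 16
    mask_z: bool = False
    seed: int = 0

    @classmethod
    def desk(cls, in_channels: int = 2, **kwargs) -> "LocalNetSpec":
        """Reduced model for CPU-scale experiments."""
        return cls(in_channels=in_channels, base_channels=4, **kwargs)


def build_localnet(spec: LocalNetSpec | None = None) -> LocalNet:
    spec = spec or LocalNetSpec()
    return LocalNet(
        in_channels=spec.in_channels,
        base_channels=spec.base_channels,
        seed=spec.seed,
        mask_z=spec.mask_z,
    )


@dataclass
class LabelerUNetSpec:
    """Architecture contract of the annotation U-Net (full scale: base 64,
    185 classes, 4-channel input)."""

    in_channels: int = 4
    base_channels: int = 64
    n_classes: int = 185
    group_size: int = 16
    seed: int = 0


def build_labeler_unet(spec: LabelerUNetSpec | None = None) -> LabelerUNet:
    spec = spec or LabelerUNetSpec()
    return LabelerUNet(
        in_channels=spec.in_channels,
        base_channels=spec.base_channels,
        n_classes=spec.n_classes,
        group_size=spec.group_size,
        seed=spec.seed,
    )


def _to_batch(vol: np.ndarray) -> np.ndarray:
    """Channel-last (or scalar) volume -> (C, X, Y, Z) float32."""
    v = np.asarray(vol, dtype=np.float32)
    if v.ndim == 3:
        return v[None]
    return np.moveaxis(v, -1, 0)


@dataclass
class RegistrationProblem:
    """One training tuple; centroids are padded (200, 3) tables or None."""

    fixed: np.ndarray
    moving: np.ndarray
    fixed_centroids: np.ndarray | None = None
    moving_centroids: np.ndarray | None = None


def forward_register(model: LocalNet, fixed: np.ndarray, moving: np.ndarray) -> np.ndarray:
    """Run the network on one preprocessed, Euler-aligned pair.

    Returns the DDF in channel-last ``(X, Y, Z, 3)`` layout.  Multi-channel
    pairs are concatenated along the existing channel axis.
    """
    f = _to_batch(fixed)
    m = _to_batch(moving)
    if f.shape != m.shape:
        raise ValueError("fixed and moving volumes must share dimensions")
    model.set_training(False)
    x = Tensor(np.concatenate([m, f], axis=0)[None])
    ddf = model(x)
    model.set_training(True)
    out = np.moveaxis(ddf.data[0].astype(float), 0, -1)
    del ddf, x
    gc.collect()  # inference graphs hold closure cycles; free them promptly
    return out


@dataclass
class AffineAugmentSpec:
    """Random affine augmentation built from perturbed cube corners."""

    magnitude: float = 1.5
    rot90_z: bool = False
    rot180_random_axis: bool = False


def _fit_affine(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares affine A, b with dst ~ A src + b."""
    design = np.hstack([src, np.ones((len(src), 1))])
    theta, *_ = np.linalg.lstsq(design, dst, rcond=None)
    return theta[:3].T, theta[3]


def random_affine_pair(
    fixed: np.ndarray,
    moving: np.ndarray,
    fixed_centroids: np.ndarray | None,
    moving_centroids: np.ndarray | None,
    spec: AffineAugmentSpec,
    rng: np.random.Generator,
):
    """Apply one random affine transform identically to both images and
    both centroid sets.

    The transform comes from perturbing the corner points of the volume
    cube by uniform amounts up to ``magnitude`` voxels; degenerate corner
    draws are resampled.  Images are pull-warped by the map ``T`` and
    centroids move by ``T^{-1}``, so blob centers keep tracking blobs.
    With ``rot90_z``, both images are additionally rotated in-plane by a
    random multiple of 90 degrees.
    """
    dims = np.asarray(fixed.shape[:3], dtype=float)
    corners = np.array(
        [[x, y, z] for x in (0, dims[0] - 1) for y in (0, dims[1] - 1) for z in (0, dims[2] - 1)]
    )
    for _ in range(100):
        perturbed = corners + rng.uniform(-spec.magnitude, spec.magnitude, corners.shape)
        mat, offset = _fit_affine(corners, perturbed)
        if abs(np.linalg.det(mat)) > 0.1:
            break
    else:
        raise RuntimeError("could not draw a non-degenerate affine transform")

    # a numerically-identity fit must act as the exact identity: scipy's
    # affine_transform treats a 1e-15 offset at the volume faces as
    # out-of-bounds and zero-fills them
    if np.allclose(mat, np.eye(3), atol=1e-9) and np.allclose(offset, 0, atol=1e-9):
        mat, offset = np.eye(3), np.zeros(3)
        identity = True
    else:
        identity = False

    def warp(vol):
        vol = np.asarray(vol, dtype=float)
        if identity:
            return vol.copy()
        if vol.ndim == 4:
            return np.stack(
                [
                    ndimage.affine_transform(vol[..., c], mat, offset, order=1, cval=0.0)
                    for c in range(vol.shape[3])
                ],
                axis=-1,
            )
        return ndimage.affine_transform(vol, mat, offset, order=1, cval=0.0)

    inv = np.linalg.inv(mat)

    def move_points(pts):
        if pts is None:
            return None
        out = np.full_like(np.asarray(pts, dtype=float), CENTROID_PAD)
        mask = valid_rows(pts)
        out[mask] = (np.asarray(pts, dtype=float)[mask] - offset) @ inv.T
        return out

    fixed_a, moving_a = warp(fixed), warp(moving)
    fc, mc = move_points(fixed_centroids), move_points(moving_centroids)

    if spec.rot90_z:
        k = int(rng.integers(0, 4))
        if k:
            if k % 2 and fixed.shape[0] != fixed.shape[1]:
                raise ValueError("90-degree rotations require square x/y dims")
            fixed_a = np.rot90(fixed_a, k, axes=(0, 1)).copy()
            moving_a = np.rot90(moving_a, k, axes=(0, 1)).copy()
            for pts in (fc, mc):
                if pts is None:
                    continue
                mask = valid_rows(pts)
                xy = pts[mask][:, :2]
                ny = fixed.shape[1]
                # np.rot90 over (x, y): a point (x, y) moves to (ny-1-y, x)
                for _ in range(k):
                    xy = np.stack([ny - 1 - xy[:, 1], xy[:, 0]], axis=1)
                pts[mask, 0], pts[mask, 1] = xy[:, 0], xy[:, 1]
    if spec.rot180_random_axis:
        axis = int(rng.integers(0, 3))
        axes = tuple(a for a in range(3) if a != axis)
        fixed_a = np.rot90(fixed_a, 2, axes=axes).copy()
        moving_a = np.rot90(moving_a, 2, axes=axes).copy()
        for pts in (fc, mc):
            if pts is None:
                continue
            mask = valid_rows(pts)
            for a in axes:
                pts[mask, a] = fixed.shape[a] - 1 - pts[mask, a]
    return fixed_a, moving_a, fc, mc


@dataclass
class LabelerAugmentSpec:
    """Augmentation battery for annotation-network training.

    One draw applies, in order: a smooth B-spline-style worm bend in the
    xy plane, a random affine (rotation/translation/scale/shear via
    perturbed cube corners), an optional 180-degree rotation about a
    random axis, and — image only — per-channel contrast adjustment, a
    z-gradient Gaussian blur mimicking depth-dependent optics, and
    Gaussian plus Poisson noise.  Images interpolate linearly with
    missing pixels set to the image median; label and weight volumes use
    nearest-neighbor interpolation with zero fill.  Magnitudes are this
    package's defaults; every term can be disabled.
    """

    bend_amplitude: float = 3.0
    bend_points: int = 5
    affine_magnitude: float = 1.5
    rot180: bool = True
    contrast_range: tuple[float, float] = (0.8, 1.25)
    blur_sigma_max: float = 1.0
    gaussian_noise: float = 0.01
    poisson_scale: float = 200.0


def random_labeler_augmentation(
    image: np.ndarray,
    label: np.ndarray,
    weight: np.ndarray,
    spec: LabelerAugmentSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply one random draw of the labeler augmentation battery.

    ``image`` is channel-last (or scalar) and is warped linearly with
    median fill; ``label``/``weight`` share the same geometry with
    nearest-neighbor interpolation and zero fill.
    """
    image = np.asarray(image, dtype=float)
    spatial = image.shape[:3]
    grid = np.stack(
        np.meshgrid(*(np.arange(s, dtype=float) for s in spatial), indexing="ij"),
        axis=0,
    )

    # smooth worm bend: y-displacement from noisy control points along x
    coords = grid.copy()
    if spec.bend_amplitude > 0:
        xs = np.linspace(0, spatial[0] - 1, spec.bend_points)
        dy = rng.normal(0.0, spec.bend_amplitude, size=spec.bend_points)
        coords[1] += np.interp(grid[0], xs, dy)

    corners = np.array(
        [
            [x, y, z]
            for x in (0, spatial[0] - 1)
            for y in (0, spatial[1] - 1)
            for z in (0, spatial[2] - 1)
        ],
        dtype=float,
    )
    perturbed = corners + rng.uniform(
        -spec.affine_magnitude, spec.affine_magnitude, corners.shape
    )
    mat, offset = _fit_affine(corners, perturbed)
    if not (
        np.allclose(mat, np.eye(3), atol=1e-9) and np.allclose(offset, 0, atol=1e-9)
    ):
        coords = np.einsum("ij,jxyz->ixyz", mat, coords) + offset.reshape(3, 1, 1, 1)
    geometry_identity = np.array_equal(coords, grid)

    def resample(vol, order, fill):
        if geometry_identity:
            return np.asarray(vol, dtype=float).copy()
        vol = np.asarray(vol)
        coord_list = [coords[0], coords[1], coords[2]]
        if vol.ndim == 4:
            return np.stack(
                [
                    ndimage.map_coordinates(
                        vol[..., c], coord_list, order=order, cval=fill, mode="constant"
                    )
                    for c in range(vol.shape[3])
                ],
                axis=-1,
            )
        return ndimage.map_coordinates(
            vol, coord_list, order=order, cval=fill, mode="constant"
        )

    out_image = resample(image, order=1, fill=float(np.median(image)))
    out_label = resample(label, order=0, fill=0)
    out_weight = resample(weight, order=0, fill=0)

    if spec.rot180:
        axis = int(rng.integers(0, 3))
        axes = tuple(a for a in range(3) if a != axis)
        out_image = np.rot90(out_image, 2, axes=axes).copy()
        out_label = np.rot90(out_label, 2, axes=axes).copy()
        out_weight = np.rot90(out_weight, 2, axes=axes).copy()

    # intensity-only transforms (never applied to label/weight)
    if out_image.ndim == 4:
        gains = rng.uniform(*spec.contrast_range, size=out_image.shape[3])
        out_image = out_image * gains
    else:
        out_image = out_image * rng.uniform(*spec.contrast_range)
    if spec.blur_sigma_max > 0:
        sigmas = np.linspace(0.0, spec.blur_sigma_max, spatial[2])
        for z in range(spatial[2]):
            if sigmas[z] > 0:
                out_image[:, :, z] = ndimage.gaussian_filter(
                    out_image[:, :, z], sigmas[z]
                )
    if spec.gaussian_noise > 0:
        out_image = out_image + rng.normal(0, spec.gaussian_noise, out_image.shape)
    if spec.poisson_scale > 0:
        out_image = rng.poisson(
            np.clip(out_image, 0, None) * spec.poisson_scale
        ) / spec.poisson_scale
    return out_image, out_label, out_weight


@dataclass
class TrainConfig:
    """Optimization settings: Adam with learning rate 1e-4 by default."""

    lr: float = 1e-4
    epochs: int = 100
    batch_size: int = 4
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights.worm)
    window: SlidingWindowSpec = field(default_factory=SlidingWindowSpec)
    augment: AffineAugmentSpec | None = None
    validation: list[RegistrationProblem] = field(default_factory=list)
    keep_best_validation: bool = True


def _problem_arrays(p: RegistrationProblem):
    f = _to_batch(p.fixed)
    m = _to_batch(p.moving)
    fp = mp = np.zeros((0, 3))
    if p.fixed_centroids is not None and p.moving_centroids is not None:
        mask = valid_rows(p.fixed_centroids) & valid_rows(p.moving_centroids)
        fp = np.asarray(p.fixed_centroids, dtype=float)[mask]
        mp = np.asarray(p.moving_centroids, dtype=float)[mask]
    return f, m, fp, mp


def _batch_loss(model, batch, cfg, train: bool) -> Tensor:
    fixed = np.stack([b[0] for b in batch])
    moving = np.stack([b[1] for b in batch])
    x = Tensor(np.concatenate([moving, fixed], axis=1))
    ddf = model(x)
    warped = warp3d(moving, ddf)
    total, _ = nnl.composite_loss(
        ddf,
        fixed,
        warped,
        cfg.weights,
        cfg.window,
        fixed_points=[b[2] for b in batch],
        moving_points=[b[3] for b in batch],
    )
    return total


def evaluate_loss(model: Module, problems: list[RegistrationProblem], cfg: TrainConfig) -> float:
    """Mean composite loss over problems without gradient tracking."""
    model.set_training(False)
    vals = []
    for p in problems:
        arrays = _problem_arrays(p)
        for param in model.parameters():
            param.requires_grad = False
        try:
            vals.append(_batch_loss(model, [arrays], cfg, train=False).item())
        finally:
            for param in model.parameters():
                param.requires_grad = True
            gc.collect()
    model.set_training(True)
    return float(np.mean(vals))


def train_alignment(
    model: Module,
    problems: list[RegistrationProblem],
    cfg: TrainConfig | None = None,
    on_epoch=None,
) -> dict[str, list[float]]:
    """Minimize the composite loss with Adam; returns the loss history.

    ``history["train"]`` holds the mean minibatch loss per epoch;
    ``history["validation"]`` is filled when validation problems are
    configured, and with ``keep_best_validation`` the parameters of the
    best-validation epoch are restored at the end.  A non-finite loss
    aborts with diagnostics.
    """
    cfg = cfg or TrainConfig()
    if not problems:
        raise ValueError("training requires at least one problem")
    rng = np.random.default_rng(cfg.seed)
    arrays = [_problem_arrays(p) for p in problems]
    optimizer = Adam(model.parameters(), lr=cfg.lr)
    history: dict[str, list[float]] = {"train": []}
    if cfg.validation:
        history["validation"] = []
    best = (np.inf, None)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(arrays))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = [arrays[i] for i in order[start : start + cfg.batch_size]]
            if cfg.augment is not None:
                batch = [_augmented(a, cfg.augment, rng) for a in batch]
            model.zero_grad()
            loss = _batch_loss(model, batch, cfg, train=True)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite loss {loss.item()} at epoch {epoch}"
                )
            loss.backward()
            optimizer.step()
            epoch_losses.append(loss.item())
        history["train"].append(float(np.mean(epoch_losses)))
        if cfg.validation:
            val = evaluate_loss(model, cfg.validation, cfg)
            history["validation"].append(val)
            if cfg.keep_best_validation and val < best[0]:
                best = (val, {k: v.copy() for k, v in model.state_dict().items()})
        if on_epoch is not None:
            on_epoch(epoch, history)
    if cfg.validation and cfg.keep_best_validation and best[1] is not None:
        model.load_state_dict(best[1])
    return history


def _augmented(arrays, spec: AffineAugmentSpec, rng: np.random.Generator):
    f, m, fp, mp = arrays
    fixed = np.moveaxis(f, 0, -1) if f.shape[0] > 1 else f[0]
    moving = np.moveaxis(m, 0, -1) if m.shape[0] > 1 else m[0]
    pad = 200 - len(fp)
    fc = np.vstack([fp, np.full((pad, 3), CENTROID_PAD)]) if len(fp) else None
    mc = np.vstack([mp, np.full((pad, 3), CENTROID_PAD)]) if len(mp) else None
    fixed_a, moving_a, fc_a, mc_a = random_affine_pair(fixed, moving, fc, mc, spec, rng)
    fp_a = fc_a[valid_rows(fc_a)] if fc_a is not None else np.zeros((0, 3))
    mp_a = mc_a[valid_rows(mc_a)] if mc_a is not None else np.zeros((0, 3))
    return _to_batch(fixed_a), _to_batch(moving_a), fp_a, mp_a


def save_checkpoint(model: Module, path) -> None:
    np.savez(path, **model.state_dict())


def load_checkpoint(model: Module, path) -> None:
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
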