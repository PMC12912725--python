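"""Brute-force rigid (Euler) pre-alignment maximizing NCC.

Non-rigid registration struggles to absorb large rotations and
translations, so image pairs are first rigidly aligned: an exhaustive
search over in-plane rotation and translation on downsampled
maximum-intensity projections, followed by a z-shift scan maximizing the
full 3-D NCC.

Transform convention: parameters map moving-image coordinates into the
fixed frame, ``apply_euler(moving, p) ~ fixed``, via the pull transform
``out[p] = moving[R (p - c) + c + t]`` (rotation about the image center,
zero fill outside).  This matches :func:`wormalign.ddf.rigid_ddf`, so a
rigid DDF with the same parameters produces the same warp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class EulerGrid:
    """Search ranges and step sizes for the brute-force grid.

    Translations are in full-resolution voxels.  The xy-translation search
    first runs at integer pixel shifts on the factor-downsampled MIP and is
    then refined on the full-resolution MIP at ``txy_step`` resolution
    around the coarse optimum.
    """

    theta_range: tuple[float, float] = (-180.0, 180.0)
    theta_step: float = 2.0
    txy_range: float = 40.0
    txy_step: float = 2.0
    tz_range: float = 10.0
    tz_step: float = 1.0
    downsample_factor: int = 4

    def thetas(self) -> np.ndarray:
        lo, hi = self.theta_range
        vals = np.arange(lo, hi, self.theta_step)
        if len(vals) == 0:
            raise ValueError("empty rotation grid")
        return vals


@dataclass
class EulerParams:
    """Rigid transform parameters: z-rotation (degrees) and voxel shifts."""

    theta_deg: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    ncc: float | None = field(default=None, compare=False)

    @property
    def txy(self) -> np.ndarray:
        return np.array([self.tx, self.ty])


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Global zero-normalized cross-correlation of two equally sized images.

    ``sum((F - mu_F)(P - mu_P)) / (XYZ * sqrt(var_F * var_P))``; 1.0 means
    the images are identical up to affine intensity scaling.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("ncc requires identical dimensions")
    va = a.var()
    vb = b.var()
    if va == 0.0 or vb == 0.0:
        raise ValueError("ncc undefined for zero-variance input")
    return float(((a - a.mean()) * (b - b.mean())).sum() / (a.size * np.sqrt(va * vb)))


def project_and_downsample(vol: np.ndarray, factor: int = 4) -> np.ndarray:
    """z-axis maximum-intensity projection followed by block-max downsampling.

    Edge rows/columns that do not fill a complete ``factor x factor`` block
    are truncated.
    """
    if factor < 1:
        raise ValueError("downsampling factor must be >= 1")
    mip = np.asarray(vol, dtype=float).max(axis=2)
    if factor == 1:
        return mip
    nx, ny = (mip.shape[0] // factor) * factor, (mip.shape[1] // factor) * factor
    blocks = mip[:nx, :ny].reshape(nx // factor, factor, ny // factor, factor)
    return blocks.max(axis=(1, 3))


def _rotation2(theta_deg: float) -> np.ndarray:
    t = np.deg2rad(theta_deg)
    return np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])


def _rotate_image(img: np.ndarray, theta_deg: float) -> np.ndarray:
    """Pull-rotate a 2-D image about its center: out[p] = img[R (p - c) + c]."""
    rot = _rotation2(theta_deg)
    center = (np.array(img.shape, dtype=float) - 1.0) / 2.0
    return ndimage.affine_transform(
        img, rot, offset=center - rot @ center, order=1, mode="constant", cval=0.0
    )


def _best_integer_shift(
    fixed: np.ndarray, rotated: np.ndarray, max_shift: int, step: int = 1
) -> tuple[tuple[int, int], float]:
    """Exact NCC argmax over zero-filled integer shifts of ``rotated``.

    The shifted prediction is ``P[p] = rotated[p + s]`` with zeros outside;
    sums over the overlap give the exact global NCC for every shift.
    """
    f = fixed - fixed.mean()
    sigma_f = fixed.std()
    npix = fixed.size
    best = (-np.inf, (0, 0))
    shifts = range(-max_shift, max_shift + 1, step)
    for sx in shifts:
        fx_lo, fx_hi = max(0, -sx), min(fixed.shape[0], rotated.shape[0] - sx)
        if fx_hi <= fx_lo:
            continue
        for sy in shifts:
            fy_lo, fy_hi = max(0, -sy), min(fixed.shape[1], rotated.shape[1] - sy)
            if fy_hi <= fy_lo:
                continue
            patch = rotated[fx_lo + sx : fx_hi + sx, fy_lo + sy : fy_hi + sy]
            s1 = patch.sum()
            s2 = (patch * patch).sum()
            var_p = s2 / npix - (s1 / npix) ** 2
            if var_p <= 0 or sigma_f == 0:
                continue
            num = (f[fx_lo:fx_hi, fy_lo:fy_hi] * patch).sum()
            val = num / (npix * np.sqrt(sigma_f**2 * var_p))
            if val > best[0]:
                best = (val, (sx, sy))
    return best[1], best[0]


def apply_euler(vol: np.ndarray, params: EulerParams) -> np.ndarray:
    """Apply rigid parameters to a volume (pull semantics, zero fill).

    Every z-slice is rotated/translated by ``(theta, tx, ty)`` about the
    image center with bilinear interpolation, then the stack is shifted by
    ``tz``.
    """
    vol = np.asarray(vol, dtype=float)
    rot3 = np.eye(3)
    rot3[:2, :2] = _rotation2(params.theta_deg)
    center = (np.array(vol.shape, dtype=float) - 1.0) / 2.0
    center[2] = 0.0  # rotation is in-plane; z handled by tz only
    offset = center - rot3 @ center + np.array([params.tx, params.ty, params.tz])
    if (
        params.theta_deg == 0.0
        and params.tx == 0.0
        and params.ty == 0.0
        and params.tz == 0.0
    ):
        return vol.copy()
    return ndimage.affine_transform(
        vol, rot3, offset=offset, order=1, mode="constant", cval=0.0
    )


def euler_grid_search(
    fixed: np.ndarray, moving: np.ndarray, grid: EulerGrid | None = None
) -> EulerParams:
    """Exhaustive rigid alignment of ``moving`` onto ``fixed``.

    Stage 1 scans (theta, tx, ty) by NCC of downsampled z-MIPs, stage 2
    refines (tx, ty) on the full-resolution MIP, stage 3 scans tz by full
    3-D NCC.  Ties are broken by the first candidate in scan order, making
    the argmax deterministic.
    """
    grid = grid or EulerGrid()
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving volumes must share dimensions")
    factor = grid.downsample_factor
    fixed_mip = project_and_downsample(fixed, factor)
    moving_mip = project_and_downsample(moving, factor)
    fixed_full = project_and_downsample(fixed, 1)
    moving_full = project_and_downsample(moving, 1)

    coarse_max = max(1, int(round(grid.txy_range / factor)))
    best = (-np.inf, 0.0, (0, 0))
    for theta in grid.thetas():
        rotated = _rotate_image(moving_mip, theta)
        if rotated.std() == 0:
            continue
        (sx, sy), val = _best_integer_shift(fixed_mip, rotated, coarse_max)
        if val > best[0]:
            best = (val, theta, (sx, sy))
    _, theta, (sx, sy) = best

    # refine translation at full resolution around the coarse optimum
    rotated_full = _rotate_image(moving_full, theta)
    step = max(1, int(round(grid.txy_step)))
    window = factor + step
    fr = fixed_full - fixed_full.mean()
    sigma_f = fixed_full.std()
    npix = fixed_full.size
    best_t = (-np.inf, (sx * factor, sy * factor))
    for dx in range(sx * factor - window, sx * factor + window + 1, step):
        if abs(dx) > grid.txy_range:
            continue
        for dy in range(sy * factor - window, sy * factor + window + 1, step):
            if abs(dy) > grid.txy_range:
                continue
            fx_lo, fx_hi = max(0, -dx), min(fr.shape[0], rotated_full.shape[0] - dx)
            fy_lo, fy_hi = max(0, -dy), min(fr.shape[1], rotated_full.shape[1] - dy)
            if fx_hi <= fx_lo or fy_hi <= fy_lo:
                continue
            patch = rotated_full[fx_lo + dx : fx_hi + dx, fy_lo + dy : fy_hi + dy]
            var_p = (patch * patch).sum() / npix - (patch.sum() / npix) ** 2
            if var_p <= 0:
                continue
            val = (fr[fx_lo:fx_hi, fy_lo:fy_hi] * patch).sum() / (
                npix * np.sqrt(sigma_f**2 * var_p)
            )
            if val > best_t[0]:
                best_t = (val, (dx, dy))
    shift = np.array(best_t[1], dtype=float)
    # an integer shift s of the rotated image corresponds to translation R s
    txy = _rotation2(theta) @ shift

    # z scan by full 3-D NCC
    base = EulerParams(theta_deg=float(theta), tx=float(txy[0]), ty=float(txy[1]))
    planar = apply_euler(moving, base)
    best_z = (-np.inf, 0.0)
    for tz in np.arange(-grid.tz_range, grid.tz_range + grid.tz_step / 2, grid.tz_step):
        shifted = ndimage.shift(
            planar, (0, 0, -tz), order=1, mode="constant", cval=0.0
        )
        if shifted.std() == 0 or fixed.std() == 0:
            continue
        val = ncc(fixed, shifted)
        if val > best_z[0]:
            best_z = (val, float(tz))
    # note apply_euler uses +tz in the pull map: out[.., z] = vol[.., z + tz];
    # ndimage.shift by -tz realizes the same map, so tz carries over directly.
    return EulerParams(
        theta_deg=float(theta),
        tx=float(txy[0]),
        ty=float(txy[1]),
        tz=best_z[1],
        ncc=best_z[0] if np.isfinite(best_z[0]) else None,
    )
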