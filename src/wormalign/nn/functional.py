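"""Layer-level differentiable operations with hand-written backward passes.

Array layout is channel-first: feature maps are ``(N, C, X, Y, Z)`` and
displacement fields ``(N, 3, X, Y, Z)``.  Convolutions use kernel size 3
with "same" padding; im2col plus one matmul keeps the heavy lifting in
BLAS.
"""

from __future__ import annotations

import numpy as np

from wormalign.nn.tensor import Tensor

_KERNEL = 3
_OFFSETS = [(i, j, k) for i in range(3) for j in range(3) for k in range(3)]


def _im2col(xp: np.ndarray, stride: int) -> np.ndarray:
    """(N, C, Xp, Yp, Zp) padded input -> (N, C*27, Xo*Yo*Zo) columns."""
    n, c, xp_, yp_, zp_ = xp.shape
    xo = (xp_ - _KERNEL) // stride + 1
    yo = (yp_ - _KERNEL) // stride + 1
    zo = (zp_ - _KERNEL) // stride + 1
    cols = np.empty((n, c, 27, xo, yo, zo), dtype=xp.dtype)
    for idx, (i, j, k) in enumerate(_OFFSETS):
        cols[:, :, idx] = xp[
            :,
            :,
            i : i + stride * xo : stride,
            j : j + stride * yo : stride,
            k : k + stride * zo : stride,
        ]
    return cols.reshape(n, c * 27, xo * yo * zo), (xo, yo, zo)


def _col2im(
    dcols: np.ndarray, shape_padded: tuple[int, ...], out_dims: tuple[int, int, int], stride: int
) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter columns back into the padded grid."""
    n, c27, _ = dcols.shape
    c = c27 // 27
    xo, yo, zo = out_dims
    dcols = dcols.reshape(n, c, 27, xo, yo, zo)
    dx = np.zeros(shape_padded, dtype=dcols.dtype)
    for idx, (i, j, k) in enumerate(_OFFSETS):
        dx[
            :,
            :,
            i : i + stride * xo : stride,
            j : j + stride * yo : stride,
            k : k + stride * zo : stride,
        ] += dcols[:, :, idx]
    return dx


def conv3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """3-D convolution, kernel 3, padding 1.  ``w`` is (C_out, C_in, 3, 3, 3).

    The im2col buffer is transient and rebuilt in the backward pass, so the
    autodiff graph retains only the activations.
    """
    xp = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
    cols, out_dims = _im2col(xp, stride)
    c_out = w.shape[0]
    w2 = w.data.reshape(c_out, -1)
    y = np.matmul(w2, cols) + b.data.reshape(1, c_out, 1)
    del cols
    n = x.shape[0]
    out = Tensor(
        y.reshape(n, c_out, *out_dims),
        x.requires_grad or w.requires_grad or b.requires_grad,
        (x, w, b),
    )

    def backward():
        g2 = out.grad.reshape(n, c_out, -1)
        xp_b = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        if w.requires_grad:
            cols_b, _ = _im2col(xp_b, stride)
            # cols_b[i] is contiguous; transposing the small g2 factor keeps
            # the big operand copy-free in BLAS
            dwt = np.zeros((cols_b.shape[1], c_out), dtype=w.data.dtype)
            for i in range(n):
                dwt += cols_b[i] @ np.ascontiguousarray(g2[i].T)
            w.accumulate(dwt.T.reshape(w.shape))
            del cols_b
        if b.requires_grad:
            b.accumulate(g2.sum(axis=(0, 2)))
        if x.requires_grad:
            dcols = np.matmul(w2.T, g2)
            dxp = _col2im(dcols, xp_b.shape, out_dims, stride)
            x.accumulate(dxp[:, :, 1:-1, 1:-1, 1:-1])

    out._backward = backward
    return out


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Transposed 3-D convolution, kernel 3, stride 2: doubles each spatial dim.

    Implemented as the adjoint of the stride-2 convolution with the same
    weight, which is stored ``(C_in, C_out, 3, 3, 3)``.
    """
    n, c_in = x.shape[:2]
    dims = x.shape[2:]
    big_dims = tuple(2 * d for d in dims)
    c_out = w.shape[1]
    w2 = w.data.reshape(c_in, -1)  # (C_in, C_out*27)
    x2 = x.data.reshape(n, c_in, -1)
    dcols = np.matmul(w2.T, x2)  # (N, C_out*27, M)
    yp_shape = (n, c_out) + tuple(d + 2 for d in big_dims)
    yp = _col2im(dcols, yp_shape, dims, stride=2)
    y = yp[:, :, 1:-1, 1:-1, 1:-1] + b.data.reshape(1, c_out, 1, 1, 1)
    out = Tensor(y, x.requires_grad or w.requires_grad or b.requires_grad, (x, w, b))

    def backward():
        gp = np.pad(out.grad, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        cols_g, _ = _im2col(gp, stride=2)  # (N, C_out*27, M)
        if x.requires_grad:
            x.accumulate(np.matmul(w2, cols_g).reshape(x.shape))
        if w.requires_grad:
            dw = np.zeros((c_in, cols_g.shape[1]), dtype=w.data.dtype)
            for i in range(n):
                dw += x2[i] @ cols_g[i].T
            w.accumulate(dw.reshape(w.shape))
        if b.requires_grad:
            b.accumulate(out.grad.sum(axis=(0, 2, 3, 4)))

    out._backward = backward
    return out


def maxpool3d(x: Tensor) -> Tensor:
    """2x2x2 max pooling; odd spatial dims are padded with -inf first."""
    n, c = x.shape[:2]
    dims = x.shape[2:]
    pads = [(0, d % 2) for d in dims]
    xp = x.data
    if any(p[1] for p in pads):
        xp = np.pad(
            xp, [(0, 0), (0, 0)] + pads, mode="constant", constant_values=-np.inf
        )
    pd = xp.shape[2:]
    xo, yo, zo = pd[0] // 2, pd[1] // 2, pd[2] // 2
    windows = (
        xp.reshape(n, c, xo, 2, yo, 2, zo, 2)
        .transpose(0, 1, 2, 4, 6, 3, 5, 7)
        .reshape(n, c, xo, yo, zo, 8)
    )
    idx = windows.argmax(axis=-1)
    y = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
    out = Tensor(y, x.requires_grad, (x,))

    def backward():
        gwin = np.zeros_like(windows)
        np.put_along_axis(gwin, idx[..., None], out.grad[..., None], axis=-1)
        gxp = (
            gwin.reshape(n, c, xo, yo, zo, 2, 2, 2)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(n, c, *pd)
        )
        x.accumulate(gxp[:, :, : dims[0], : dims[1], : dims[2]])

    out._backward = backward
    return out


def batchnorm3d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    mean: np.ndarray | None = None,
    var: np.ndarray | None = None,
    eps: float = 1e-5,
) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fused batch normalization over (N, spatial) per channel.

    With ``mean``/``var`` given (evaluation mode) those statistics are
    used; otherwise batch statistics are computed and returned alongside
    the output.
    """
    axes = (0, 2, 3, 4)
    shape = (1, -1, 1, 1, 1)
    training = mean is None
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(shape)) * inv.reshape(shape)
    y = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)
    out = Tensor(
        y,
        x.requires_grad or gamma.requires_grad or beta.requires_grad,
        (x, gamma, beta),
    )

    def backward():
        g = out.grad
        dbeta = g.sum(axis=axes)
        dgamma = (g * xhat).sum(axis=axes)
        if gamma.requires_grad:
            gamma.accumulate(dgamma)
        if beta.requires_grad:
            beta.accumulate(dbeta)
        if x.requires_grad:
            scale = (gamma.data * inv).reshape(shape)
            if training:
                count = g.size / g.shape[1]
                x.accumulate(
                    scale
                    * (
                        g
                        - dbeta.reshape(shape) / count
                        - xhat * dgamma.reshape(shape) / count
                    )
                )
            else:
                x.accumulate(scale * g)

    out._backward = backward
    return out, mean, var


_RESIZE_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) linear-interpolation matrix with half-pixel centers."""
    key = (n_in, n_out)
    if key not in _RESIZE_CACHE:
        m = np.zeros((n_out, n_in))
        src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        src = np.clip(src, 0, n_in - 1)
        i0 = np.floor(src).astype(int)
        i1 = np.minimum(i0 + 1, n_in - 1)
        w1 = src - i0
        m[np.arange(n_out), i0] += 1 - w1
        m[np.arange(n_out), i1] += w1
        _RESIZE_CACHE[key] = m
    return _RESIZE_CACHE[key]


def resize3d(x: Tensor, target: tuple[int, int, int]) -> Tensor:
    """Trilinear (separable linear) resize of the spatial dims of (N, C, X, Y, Z)."""
    if tuple(x.shape[2:]) == tuple(target):
        return x
    mats = [
        _resize_matrix(x.shape[2 + a], target[a]).astype(x.data.dtype)
        for a in range(3)
    ]

    def apply(data, transpose=False):
        for axis, m in enumerate(mats):
            mm = m.T if transpose else m
            data = np.moveaxis(
                np.tensordot(mm, data, axes=([1], [2 + axis])), 0, 2 + axis
            )
        return data

    out = Tensor(apply(x.data), x.requires_grad, (x,))
    out._backward = lambda: x.accumulate(apply(out.grad, transpose=True))
    return out


def window_mean3d(x: Tensor, n: int) -> Tensor:
    """Mean over all valid n-cube windows of a (N, X, Y, Z) tensor."""

    def sliding_sum(data):
        s = data
        for axis in range(1, 4):
            c = np.cumsum(s, axis=axis)
            pad = [(0, 0)] * 4
            pad[axis] = (1, 0)
            c = np.pad(c, pad)
            hi = [slice(None)] * 4
            lo = [slice(None)] * 4
            hi[axis] = slice(n, c.shape[axis])
            lo[axis] = slice(0, c.shape[axis] - n)
            s = c[tuple(hi)] - c[tuple(lo)]
        return s

    scale = 1.0 / n**3
    out = Tensor(sliding_sum(x.data) * scale, x.requires_grad, (x,))

    def backward():
        pad = [(0, 0)] + [(n - 1, n - 1)] * 3
        x.accumulate(sliding_sum(np.pad(out.grad, pad)) * scale)

    out._backward = backward
    return out


def warp3d(moving: np.ndarray, d: Tensor) -> Tensor:
    """Pull-warp a constant moving image by a displacement-field tensor.

    ``moving`` is ``(N, C, X, Y, Z)`` (no gradient); ``d`` is
    ``(N, 3, X, Y, Z)``.  Output voxel ``p`` samples the moving image at
    ``p + d[p]`` trilinearly with zero fill; the gradient with respect to
    the field is the spatial derivative of the interpolant.
    """
    n, c = moving.shape[:2]
    dims = moving.shape[2:]
    grid = np.meshgrid(*(np.arange(s, dtype=d.data.dtype) for s in dims), indexing="ij")
    coords = [grid[a][None] + d.data[:, a] for a in range(3)]  # each (N, X, Y, Z)

    i0 = [np.floor(cc).astype(np.int64) for cc in coords]
    frac = [cc - f for cc, f in zip(coords, i0)]

    def gather(ix, iy, iz):
        valid = (
            (ix >= 0) & (ix < dims[0])
            & (iy >= 0) & (iy < dims[1])
            & (iz >= 0) & (iz < dims[2])
        )
        ixc = np.clip(ix, 0, dims[0] - 1)
        iyc = np.clip(iy, 0, dims[1] - 1)
        izc = np.clip(iz, 0, dims[2] - 1)
        batch = np.arange(n)[:, None, None, None]
        vals = moving[batch, :, ixc, iyc, izc]  # (N, X, Y, Z, C)
        return np.moveaxis(vals, -1, 1) * valid[:, None]

    corners = {}
    for dx_ in (0, 1):
        for dy_ in (0, 1):
            for dz_ in (0, 1):
                corners[(dx_, dy_, dz_)] = gather(
                    i0[0] + dx_, i0[1] + dy_, i0[2] + dz_
                )

    fx, fy, fz = (f[:, None] for f in frac)
    wx = {0: 1 - fx, 1: fx}
    wy = {0: 1 - fy, 1: fy}
    wz = {0: 1 - fz, 1: fz}
    # a sample whose coordinate leaves [0, dim-1] on any axis is fully
    # out of bounds and reads 0 (no partial blending at the volume faces)
    inside = (
        (coords[0] >= 0) & (coords[0] <= dims[0] - 1)
        & (coords[1] >= 0) & (coords[1] <= dims[1] - 1)
        & (coords[2] >= 0) & (coords[2] <= dims[2] - 1)
    )[:, None]
    y = inside * sum(
        wx[a] * wy[b] * wz[cc] * corners[(a, b, cc)]
        for a in (0, 1) for b in (0, 1) for cc in (0, 1)
    )
    out = Tensor(y, d.requires_grad, (d,))

    def backward():
        sign = {0: -1.0, 1: 1.0}
        gx = sum(
            sign[a] * wy[b] * wz[cc] * corners[(a, b, cc)]
            for a in (0, 1) for b in (0, 1) for cc in (0, 1)
        )
        gy = sum(
            wx[a] * sign[b] * wz[cc] * corners[(a, b, cc)]
            for a in (0, 1) for b in (0, 1) for cc in (0, 1)
        )
        gz = sum(
            wx[a] * wy[b] * sign[cc] * corners[(a, b, cc)]
            for a in (0, 1) for b in (0, 1) for cc in (0, 1)
        )
        g = out.grad * inside  # (N, C, X, Y, Z)
        d.accumulate(
            np.stack(
                [(g * gg).sum(axis=1) for gg in (gx, gy, gz)],
                axis=1,
            )
        )

    out._backward = backward
    return out


def sample_points3d(d: Tensor, points: np.ndarray) -> Tensor:
    """Trilinearly sample a (3, X, Y, Z) field tensor at (P, 3) points.

    Coordinates are edge-clamped; the operation is linear in the field, so
    the backward pass scatter-adds into the eight surrounding corners.
    """
    dims = d.shape[1:]
    pts = np.asarray(points, dtype=float)
    pts = np.clip(pts, 0.0, np.asarray(dims, dtype=float) - 1.0)
    i0 = np.floor(pts).astype(np.int64)
    i0 = np.minimum(i0, np.asarray(dims) - 2) if min(dims) >= 2 else i0
    frac = pts - i0

    weights = []
    indices = []
    for dx_ in (0, 1):
        for dy_ in (0, 1):
            for dz_ in (0, 1):
                w = (
                    (frac[:, 0] if dx_ else 1 - frac[:, 0])
                    * (frac[:, 1] if dy_ else 1 - frac[:, 1])
                    * (frac[:, 2] if dz_ else 1 - frac[:, 2])
                )
                weights.append(w)
                indices.append((i0[:, 0] + dx_, i0[:, 1] + dy_, i0[:, 2] + dz_))

    vals = sum(
        w[None] * d.data[:, ix, iy, iz] for w, (ix, iy, iz) in zip(weights, indices)
    )
    out = Tensor(vals.T, d.requires_grad, (d,))  # (P, 3)

    def backward():
        g = np.zeros_like(d.data)
        gt = out.grad.T  # (3, P)
        for w, (ix, iy, iz) in zip(weights, indices):
            np.add.at(g, (slice(None), ix, iy, iz), w[None] * gt)
        d.accumulate(g)

    out._backward = backward
    return out
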