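"""Network building blocks and the two architectures.

``LocalNet`` is the registration backbone: a 3-level 3-D U-Net whose
output layer averages displacement-field heads from the bottom block and
every decoder level.  ``LabelerUNet`` is the annotation architecture
contract: a 4-level group-normalized 3-D U-Net with a K-channel 1x1
output head.
"""

from __future__ import annotations

import numpy as np

from wormalign.nn import functional as F
from wormalign.nn.tensor import Tensor, add_n, concat


class Module:
    """Minimal parameter container with recursive traversal."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in vars(self).values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def set_training(self, flag: bool) -> None:
        for mod in self.modules():
            if hasattr(mod, "training"):
                mod.training = flag

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("parameter count mismatch")
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch at parameter {i}")
            p.data = arr.astype(p.data.dtype)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(
        rng.normal(0.0, std, size=shape).astype(np.float32), requires_grad=True
    )


class Conv3d(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, stride: int = 1):
        self.stride = stride
        self.weight = _he_init(rng, (c_out, c_in, 3, 3, 3), c_in * 27)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv3d(x, self.weight, self.bias, self.stride)


class ConvTranspose3d(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.weight = _he_init(rng, (c_in, c_out, 3, 3, 3), c_in * 27)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv_transpose3d(x, self.weight, self.bias)


class BatchNorm3d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            out, mean, var = F.batchnorm3d(x, self.gamma, self.beta, eps=self.eps)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
            return out
        out, _, _ = F.batchnorm3d(
            x, self.gamma, self.beta, self.running_mean, self.running_var, self.eps
        )
        return out


class GroupNorm3d(Module):
    def __init__(self, channels: int, groups: int, eps: float = 1e-5):
        if channels % groups:
            raise ValueError("channels must be divisible by group count")
        self.groups = groups
        self.eps = eps
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        n, c = x.shape[:2]
        dims = x.shape[2:]
        g = x.reshape(n, self.groups, c // self.groups, *dims)
        mu = g.mean(axis=(2, 3, 4, 5), keepdims=True)
        centered = g - mu
        var = (centered * centered).mean(axis=(2, 3, 4, 5), keepdims=True)
        norm = (centered * ((var + self.eps) ** -0.5)).reshape(n, c, *dims)
        shape = (1, -1, 1, 1, 1)
        return norm * self.gamma.reshape(shape) + self.beta.reshape(shape)


class ConvBlock(Module):
    """conv(k3) -> batch norm -> ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv = Conv3d(c_in, c_out, rng)
        self.norm = BatchNorm3d(c_out)

    def __call__(self, x: Tensor) -> Tensor:
        return self.norm(self.conv(x)).relu()


class ResidualConvBlock(Module):
    """Two conv blocks; the input joins before the second ReLU."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.block = ConvBlock(channels, channels, rng)
        self.conv = Conv3d(channels, channels, rng)
        self.norm = BatchNorm3d(channels)

    def __call__(self, x: Tensor) -> Tensor:
        return (self.norm(self.conv(self.block(x))) + x).relu()


class EncoderBlock(Module):
    """conv block -> residual conv block; the caller pools afterwards."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.block = ConvBlock(c_in, c_out, rng)
        self.res = ResidualConvBlock(c_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.res(self.block(x))


class UpsampleBlock(Module):
    """Transposed conv doubling dims + resized split-channel-sum branch."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        if c_in != 2 * c_out:
            raise ValueError("upsampling halves the channel count")
        self.up = ConvTranspose3d(c_in, c_out, rng)
        self.c_out = c_out

    def __call__(self, x: Tensor, target: tuple[int, int, int]) -> Tensor:
        y = F.resize3d(self.up(x), target)
        resized = F.resize3d(x, target)
        branch = resized[:, : self.c_out] + resized[:, self.c_out :]
        return y + branch


class DecoderBlock(Module):
    def __init__(self, c_in: int, c_skip: int, c_out: int, rng: np.random.Generator):
        self.upsample = UpsampleBlock(c_in, c_in // 2, rng)
        self.block = ConvBlock(c_in // 2 + c_skip, c_out, rng)
        self.res = ResidualConvBlock(c_out, rng)

    def __call__(self, x: Tensor, skip: Tensor) -> Tensor:
        up = self.upsample(x, tuple(skip.shape[2:]))
        return self.res(self.block(concat([up, skip], axis=1)))


class LocalNet(Module):
    """Registration backbone producing a dense displacement field.

    Three encoder levels with ``base_channels * 2**i`` features, a bottom
    block, three decoder levels, and a displacement head (3-channel conv +
    trilinear resize to input dims) at the bottom and at every decoder
    output; the four head images are averaged into the final field.  The
    default base of 16 matches the full-scale architecture; desk-scale
    runs use a smaller base.
    """

    def __init__(
        self,
        in_channels: int = 2,
        base_channels: int = 16,
        seed: int = 0,
        mask_z: bool = False,
    ):
        rng = np.random.default_rng(seed)
        b = base_channels
        self.mask_z = mask_z
        self.enc0 = EncoderBlock(in_channels, b, rng)
        self.enc1 = EncoderBlock(b, 2 * b, rng)
        self.enc2 = EncoderBlock(2 * b, 4 * b, rng)
        self.bottom = ConvBlock(4 * b, 4 * b, rng)
        self.dec2 = DecoderBlock(4 * b, 4 * b, 2 * b, rng)
        self.dec1 = DecoderBlock(2 * b, 2 * b, b, rng)
        # final decoder: upsample to full resolution, skip = pre-pool features
        self.dec0 = DecoderBlock(b, b, max(3 * b // 4, 3), rng)
        self.head_bottom = Conv3d(4 * b, 3, rng)
        self.head2 = Conv3d(2 * b, 3, rng)
        self.head1 = Conv3d(b, 3, rng)
        self.head0 = Conv3d(max(3 * b // 4, 3), 3, rng)
        # zero-initialized displacement heads: the untrained network warps
        # with the identity, and training refines from there
        for head in (self.head_bottom, self.head2, self.head1, self.head0):
            head.weight.data = np.zeros_like(head.weight.data)

    def __call__(self, x: Tensor) -> Tensor:
        dims = tuple(x.shape[2:])
        s0 = self.enc0(x)  # full res, b channels (skip of the final decoder)
        p0 = F.maxpool3d(s0)
        s1 = self.enc1(p0)  # /2, 2b
        p1 = F.maxpool3d(s1)
        s2 = self.enc2(p1)  # /4, 4b
        p2 = F.maxpool3d(s2)
        bottom = self.bottom(p2)  # /8, 4b
        d2 = self.dec2(bottom, s2)  # /4
        d1 = self.dec1(d2, s1)  # /2
        d0 = self.dec0(d1, s0)  # full res
        heads = [
            F.resize3d(self.head_bottom(bottom), dims),
            F.resize3d(self.head2(d2), dims),
            F.resize3d(self.head1(d1), dims),
            self.head0(d0),
        ]
        ddf = add_n(heads) * 0.25
        if self.mask_z:
            mask = np.ones((1, 3, 1, 1, 1), dtype=ddf.data.dtype)
            mask[:, 2] = 0.0
            ddf = ddf * Tensor(mask)
        return ddf


class LabelerConvBlock(Module):
    """group norm -> conv(k3) -> ReLU."""

    def __init__(self, c_in: int, c_out: int, groups: int, rng: np.random.Generator):
        self.norm = GroupNorm3d(c_in, groups)
        self.conv = Conv3d(c_in, c_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(self.norm(x)).relu()


class LabelerUNet(Module):
    """Annotation architecture: 4-level group-normalized 3-D U-Net.

    ``base_channels * 2**i`` features at level i, interpolation upsampling
    with skip concatenation, and a 1x1x1 head with ``n_classes`` output
    channels.  Full scale is base 64 and 185 classes; softmax is applied
    at evaluation, not here.
    """

    def __init__(
        self,
        in_channels: int = 4,
        base_channels: int = 64,
        n_classes: int = 185,
        group_size: int = 16,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        b = base_channels

        def groups(c: int) -> int:
            g = max(c // group_size, 1)
            while c % g:
                g -= 1
            return g

        self.encoders = []
        c_prev = in_channels
        for level in range(4):
            c = b * 2**level
            first_groups = 1 if level == 0 else groups(c_prev)
            self.encoders.append(
                (
                    LabelerConvBlock(c_prev, c, first_groups, rng),
                    LabelerConvBlock(c, c, groups(c), rng),
                )
            )
            c_prev = c
        self.decoders = []
        for level in (2, 1, 0):
            c_hi = b * 2 ** (level + 1)
            c = b * 2**level
            self.decoders.append(
                (
                    LabelerConvBlock(c_hi + c, c, groups(c_hi + c), rng),
                    LabelerConvBlock(c, c, groups(c), rng),
                )
            )
        self.head = _he_init(rng, (n_classes, b, 1, 1, 1), b)
        self.head_bias = Tensor(np.zeros(n_classes, dtype=np.float32), requires_grad=True)
        self._flat = [blk for pair in self.encoders + self.decoders for blk in pair]

    def parameters(self) -> list:
        params = []
        for blk in self._flat:
            params.extend(blk.parameters())
        params.extend([self.head, self.head_bias])
        return params

    def modules(self) -> list:
        mods = [self]
        for blk in self._flat:
            mods.extend(blk.modules())
        return mods

    def __call__(self, x: Tensor) -> Tensor:
        skips = []
        for level, (blk1, blk2) in enumerate(self.encoders):
            if level > 0:
                x = F.maxpool3d(x)
            x = blk2(blk1(x))
            skips.append(x)
        y = skips[-1]
        for (blk1, blk2), skip in zip(self.decoders, reversed(skips[:-1])):
            y = F.resize3d(y, tuple(skip.shape[2:]))
            y = blk2(blk1(concat([y, skip], axis=1)))
        # 1x1x1 convolution as a tensordot-style conv with kernel 1
        n = y.shape[0]
        flat = y.reshape(n, y.shape[1], -1)
        w = self.head.reshape(self.head.shape[0], self.head.shape[1])
        out = _matmul_channels(flat, w, self.head_bias)
        return out.reshape(n, self.head.shape[0], *y.shape[2:])


def _matmul_channels(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """(N, C, M) x (K, C) -> (N, K, M) with bias (K,)."""
    out = Tensor(
        np.matmul(w.data, x.data) + b.data.reshape(1, -1, 1),
        x.requires_grad or w.requires_grad or b.requires_grad,
        (x, w, b),
    )

    def backward():
        if w.requires_grad:
            w.accumulate(np.einsum("nkm,ncm->kc", out.grad, x.data))
        if b.requires_grad:
            b.accumulate(out.grad.sum(axis=(0, 2)))
        if x.requires_grad:
            x.accumulate(np.matmul(w.data.T, out.grad))

    out._backward = backward
    return out
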