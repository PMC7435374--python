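"""Network building blocks on top of the autograd engine.

Conventions follow the CycleGAN/pix2pix family: instance normalization
without learned affine parameters, ReLU in the generator, LeakyReLU(0.2)
in the discriminators, and transposed convolution realized as
zero-insertion upsampling followed by an ordinary convolution with the
spatially flipped, channel-transposed kernel (the two are algebraically
identical for stride 2, padding 1, output padding 1).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module", "Conv2d", "ConvTranspose2d", "InstanceNorm2d",
    "ReLU", "LeakyReLU", "Sigmoid", "Sequential", "ResidualBlock",
]


class Module:
    """Base class: parameter discovery and flat state dict."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                state[key] = value.data
            elif isinstance(value, Module):
                state.update(value.state_dict(prefix=f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        state.update(item.state_dict(prefix=f"{key}.{i}."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                if key not in state:
                    raise KeyError(f"missing parameter in checkpoint: {key}")
                if state[key].shape != value.data.shape:
                    raise ValueError(f"shape mismatch for {key}")
                value.data = np.array(state[key], dtype=value.data.dtype)
            elif isinstance(value, Module):
                value.load_state_dict(state, prefix=f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item.load_state_dict(state, prefix=f"{key}.{i}.")

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


def _init_weight(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
                 init: str) -> np.ndarray:
    if init == "dcgan":      # N(0, 0.02), the CycleGAN/pix2pix convention
        return rng.normal(0.0, 0.02, size=shape)
    if init == "kaiming":    # scale-preserving, for fixed random feature trunks
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
    raise ValueError(f"unknown init {init!r}")


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None,
                 bias: bool = True, init: str = "dcgan"):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(_init_weight(rng, (out_ch, in_ch, kernel, kernel), fan_in, init),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvTranspose2d(Module):
    """Stride-2 upsampling conv; doubles H and W for kernel 3, padding 1."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 2,
                 padding: int = 1, output_padding: int = 1,
                 rng: np.random.Generator | None = None, init: str = "dcgan"):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        # stored in the (in, out, kh, kw) layout conventional for deconvolutions
        self.weight = Tensor(_init_weight(rng, (in_ch, out_ch, kernel, kernel), fan_in, init),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)
        self.stride = stride
        self.padding = padding
        self.output_padding = output_padding
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        k, s, p, op = self.kernel, self.stride, self.padding, self.output_padding
        # zero-stuff, pad asymmetrically, then correlate with the rotated kernel
        x = x.dilate2d(s)
        lo = k - 1 - p
        x = x.pad2d(lo, lo + op, lo, lo + op)
        w = self.weight.swapaxes(0, 1).flip_spatial()
        return x.conv2d(w, None, stride=1, padding=0) + self.bias.reshape(1, -1, 1, 1)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization over the spatial axes (no affine)."""

    def __init__(self, eps: float = 1e-5):
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=(2, 3), keepdims=True)
        return centered * (var + self.eps) ** -0.5


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class ResidualBlock(Module):
    """Two 3x3 conv + instance-norm layers with an identity skip."""

    def __init__(self, channels: int, kernel: int = 3, rng: np.random.Generator | None = None):
        pad = kernel // 2
        self.conv1 = Conv2d(channels, channels, kernel, padding=pad, rng=rng)
        self.norm1 = InstanceNorm2d()
        self.conv2 = Conv2d(channels, channels, kernel, padding=pad, rng=rng)
        self.norm2 = InstanceNorm2d()

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm1(self.conv1(x)).relu()
        h = self.norm2(self.conv2(h))
        return x + h
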