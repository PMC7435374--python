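"""Generator, local-global discriminator pair, and the perceptual backbone.

The architectures are written as compact layer strings in the grammar

    CIR<m>F<n>   conv (m filters, n x n) - instance norm - ReLU
    CILR<m>F<n>  conv - instance norm - LeakyReLU(0.2)
    CLR<m>F<n>   conv - LeakyReLU(0.2)           (no normalization)
    Res<m>       residual block, m 3x3 filters
    DCIR<m>F<n>  transposed conv - instance norm - ReLU
    C<m>F<n>     plain conv

The generator is a CycleGAN-style encoder / 9-residual-block bottleneck /
decoder ending in a sigmoid; the global discriminator is a pix2pix-style
patch critic over the (image, label) concatenation; the local
discriminator is the same but one convolution shallower, judging 64x64
crops.  ``base_width_scale`` shrinks every channel width proportionally
so the full stack runs quickly on a CPU in tests.
"""

from __future__ import annotations

import dataclasses
import re

import numpy as np

from .nn import (
    Conv2d, ConvTranspose2d, InstanceNorm2d, Module, ResidualBlock, Tensor,
    as_tensor, concat,
)

GENERATOR_SPEC = ("CIR64F7-CIR128F3-CIR256F3-" + "-".join(["Res256"] * 9)
                  + "-DCIR128F3-DCIR64F3-C1F7")
GLOBAL_DISCRIMINATOR_SPEC = "CLR64F4-CILR128F4-CILR256F4-CILR512F4-CILR512F4-CILR512F4-C1F4"
LOCAL_DISCRIMINATOR_SPEC = "CLR64F4-CILR128F4-CILR256F4-CILR512F4-CILR512F4-C1F4"

_TOKEN_RE = re.compile(
    r"^(?:(?P<kind>CIR|CILR|CLR|DCIR|C)(?P<ch>\d+)F(?P<k>\d+)|Res(?P<res_ch>\d+))$")


@dataclasses.dataclass(frozen=True)
class LayerToken:
    kind: str          # CIR | CILR | CLR | DCIR | C | Res
    channels: int
    kernel: int        # 3 for Res blocks

    def render(self) -> str:
        if self.kind == "Res":
            return f"Res{self.channels}"
        return f"{self.kind}{self.channels}F{self.kernel}"


@dataclasses.dataclass
class NetworkSpec:
    """A parsed layer string plus a global channel-width multiplier."""

    layer_tokens: list[LayerToken]
    base_width_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.base_width_scale <= 0:
            raise ValueError("base_width_scale must be positive")

    @classmethod
    def parse(cls, text: str, base_width_scale: float = 1.0) -> "NetworkSpec":
        tokens: list[LayerToken] = []
        for raw in text.replace("−", "-").split("-"):
            raw = raw.strip()
            m = _TOKEN_RE.match(raw)
            if not m:
                raise ValueError(f"unparseable layer token: {raw!r}")
            if m.group("res_ch") is not None:
                tokens.append(LayerToken("Res", int(m.group("res_ch")), 3))
            else:
                tokens.append(LayerToken(m.group("kind"), int(m.group("ch")), int(m.group("k"))))
        return cls(layer_tokens=tokens, base_width_scale=base_width_scale)

    def render(self) -> str:
        return "-".join(t.render() for t in self.layer_tokens)

    def scaled(self, channels: int) -> int:
        return max(1, round(channels * self.base_width_scale))

    @property
    def n_res_blocks(self) -> int:
        return sum(1 for t in self.layer_tokens if t.kind == "Res")

    @property
    def n_conv_layers(self) -> int:
        return sum(1 for t in self.layer_tokens if t.kind != "Res")


def _pad(k: int) -> int:
    return (k - 1) // 2


class Generator(Module):
    """Encoder / residual bottleneck / decoder; sigmoid output in [0, 1]."""

    def __init__(self, in_channels: int, spec: NetworkSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.in_channels = in_channels
        self.spec_string = spec.render()
        mods: list[Module] = []
        prev = in_channels
        n_down = 0
        seen_cir = 0
        for tok in spec.layer_tokens:
            ch = spec.scaled(tok.channels)
            if tok.kind == "CIR":
                stride = 1 if seen_cir == 0 else 2
                if stride == 2:
                    n_down += 1
                mods.append(_ConvNormAct(prev, ch, tok.kernel, stride, _pad(tok.kernel),
                                         norm=True, act="relu", rng=rng))
                seen_cir += 1
                prev = ch
            elif tok.kind == "Res":
                mods.append(ResidualBlock(ch, tok.kernel, rng=rng))
                prev = ch
            elif tok.kind == "DCIR":
                mods.append(_DeconvNormAct(prev, ch, tok.kernel, rng=rng))
                prev = ch
            elif tok.kind == "C":
                mods.append(Conv2d(prev, ch, tok.kernel, stride=1, padding=_pad(tok.kernel), rng=rng))
                prev = ch
            else:
                raise ValueError(f"token {tok.render()} not valid in a generator spec")
        self.body = mods
        self.downsample_factor = 2 ** n_down

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(f"expected (N, {self.in_channels}, H, W) input, got {x.shape}")
        h, w = x.shape[2], x.shape[3]
        f = self.downsample_factor
        if h % f or w % f:
            raise ValueError(f"spatial dims ({h}, {w}) must be divisible by {f}")
        for m in self.body:
            x = m(x)
        return x.sigmoid()


class _ConvNormAct(Module):
    def __init__(self, in_ch, out_ch, kernel, stride, padding, norm, act, rng):
        self.conv = Conv2d(in_ch, out_ch, kernel, stride=stride, padding=padding,
                           rng=rng, bias=not norm)
        self.norm = InstanceNorm2d() if norm else None
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        x = self.conv(x)
        if self.norm is not None:
            x = self.norm(x)
        return x.relu() if self.act == "relu" else x.leaky_relu(0.2)


class _DeconvNormAct(Module):
    def __init__(self, in_ch, out_ch, kernel, rng):
        self.deconv = ConvTranspose2d(in_ch, out_ch, kernel, stride=2,
                                      padding=_pad(kernel), output_padding=1, rng=rng)
        self.norm = InstanceNorm2d()

    def forward(self, x: Tensor) -> Tensor:
        return self.norm(self.deconv(x)).relu()


class PatchDiscriminator(Module):
    """Least-squares patch critic; emits a 2-D map of realism scores."""

    def __init__(self, in_channels: int, spec: NetworkSpec, seed: int = 0,
                 expected_size: int | None = None, strict: bool = False):
        rng = np.random.default_rng(seed)
        self.in_channels = in_channels
        self.spec_string = spec.render()
        self.expected_size = expected_size
        self.strict = strict
        n = len(spec.layer_tokens)
        mods: list[Module] = []
        prev = in_channels
        n_down = min(4, n - 2)  # at most four halvings so 64-px crops stay valid
        for i, tok in enumerate(spec.layer_tokens):
            ch = spec.scaled(tok.channels)
            stride = 2 if i < n_down else 1
            if tok.kind == "CLR":
                mods.append(_ConvNormAct(prev, ch, tok.kernel, stride, _pad(tok.kernel),
                                         norm=False, act="leaky", rng=rng))
            elif tok.kind == "CILR":
                mods.append(_ConvNormAct(prev, ch, tok.kernel, stride, _pad(tok.kernel),
                                         norm=True, act="leaky", rng=rng))
            elif tok.kind == "C":
                mods.append(Conv2d(prev, ch, tok.kernel, stride=stride,
                                   padding=_pad(tok.kernel), rng=rng))
            else:
                raise ValueError(f"token {tok.render()} not valid in a discriminator spec")
            prev = ch
        self.body = mods

    @property
    def n_conv_layers(self) -> int:
        return len(self.body)

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(f"expected (N, {self.in_channels}, H, W) input, got {x.shape}")
        if self.strict and self.expected_size is not None:
            if x.shape[2] != self.expected_size or x.shape[3] != self.expected_size:
                raise ValueError(
                    f"discriminator expects {self.expected_size}x{self.expected_size} "
                    f"crops, got {x.shape[2]}x{x.shape[3]}")
        for m in self.body:
            x = m(x)
        return x


def build_generator(in_channels: int, spec: NetworkSpec | str | None = None,
                    base_width_scale: float = 1.0, seed: int = 0) -> Generator:
    spec = _coerce_spec(spec, GENERATOR_SPEC, base_width_scale)
    if spec.n_res_blocks != 9:
        raise ValueError(f"generator spec must contain exactly 9 Res tokens, got {spec.n_res_blocks}")
    return Generator(in_channels, spec, seed=seed)


def build_global_discriminator(in_channels: int, spec: NetworkSpec | str | None = None,
                               base_width_scale: float = 1.0, seed: int = 0) -> PatchDiscriminator:
    spec = _coerce_spec(spec, GLOBAL_DISCRIMINATOR_SPEC, base_width_scale)
    return PatchDiscriminator(in_channels, spec, seed=seed)


def build_local_discriminator(spec: NetworkSpec | str | None = None,
                              base_width_scale: float = 1.0, seed: int = 0,
                              crop_size: int = 64, strict: bool = True) -> PatchDiscriminator:
    """Critic for 1-channel 64x64 crops (images only, no label channels)."""
    spec = _coerce_spec(spec, LOCAL_DISCRIMINATOR_SPEC, base_width_scale)
    return PatchDiscriminator(1, spec, seed=seed, expected_size=crop_size, strict=strict)


def _coerce_spec(spec, default: str, base_width_scale: float) -> NetworkSpec:
    if spec is None:
        return NetworkSpec.parse(default, base_width_scale)
    if isinstance(spec, str):
        return NetworkSpec.parse(spec, base_width_scale)
    if base_width_scale != 1.0 and spec.base_width_scale == 1.0:
        spec = dataclasses.replace(spec, base_width_scale=base_width_scale)
    return spec


# ---------------------------------------------------------------------------
# Perceptual feature extractor
# ---------------------------------------------------------------------------

_VGG_BLOCKS = ((2, 64), (2, 128), (4, 256), (4, 512))  # (convs per block, width)
_IMAGENET_MEAN = np.array([0.485, 0.456, 0.406]).reshape(1, 3, 1, 1)
_IMAGENET_STD = np.array([0.229, 0.224, 0.225]).reshape(1, 3, 1, 1)


class FeatureExtractor(Module):
    """VGG-19 convolutional trunk used for the perceptual loss and FID.

    Exposes post-ReLU feature maps under tags ``conv<block>_<index>``; the
    default four blocks include ``conv3_4`` (the fourth convolution before
    the third max-pooling) and ``conv4_4``.  Weights are fixed at
    construction from ``seed``; when pretrained VGG-19 weights are at hand
    they can be injected with :meth:`load_state_dict`, but a fixed random
    trunk already defines a valid deep feature metric.
    """

    def __init__(self, width_scale: float = 1.0, seed: int = 0, n_blocks: int = 4):
        if not 1 <= n_blocks <= len(_VGG_BLOCKS):
            raise ValueError(f"n_blocks must be in [1, {len(_VGG_BLOCKS)}]")
        rng = np.random.default_rng(seed)
        self.convs: list[Conv2d] = []
        self._plan: list[tuple[str, int]] = []  # (tag, conv index); "pool" entries have index -1
        prev = 3
        for b, (n_convs, width) in enumerate(_VGG_BLOCKS[:n_blocks], start=1):
            ch = max(1, round(width * width_scale))
            for i in range(1, n_convs + 1):
                self.convs.append(Conv2d(prev, ch, 3, stride=1, padding=1, rng=rng,
                                         init="kaiming"))
                self._plan.append((f"conv{b}_{i}", len(self.convs) - 1))
                prev = ch
            if b < n_blocks:
                self._plan.append(("pool", -1))
        self.n_blocks = n_blocks

    @property
    def tags(self) -> list[str]:
        return [t for t, _ in self._plan if t != "pool"]

    @property
    def deepest_tag(self) -> str:
        return self.tags[-1]

    def preprocess(self, image) -> Tensor:
        """[0,1] grayscale of shape (H,W), (N,H,W) or (N,1,H,W) -> normalized (N,3,H,W)."""
        x = image if isinstance(image, Tensor) else Tensor(np.asarray(image, dtype=np.float64))
        if x.ndim == 2:
            x = x.reshape(1, 1, *x.shape)
        elif x.ndim == 3:
            x = x.reshape(x.shape[0], 1, x.shape[1], x.shape[2])
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected single-channel images, got shape {x.shape}")
        rgb = concat([x, x, x], axis=1)
        return (rgb - Tensor(_IMAGENET_MEAN)) * Tensor(1.0 / _IMAGENET_STD)

    def features(self, image, tags: list[str] | tuple[str, ...]) -> dict[str, Tensor]:
        unknown = [t for t in tags if t not in self.tags]
        if unknown:
            raise KeyError(f"unknown feature tag(s) {unknown}; available: {self.tags}")
        x = self.preprocess(image)
        out: dict[str, Tensor] = {}
        remaining = set(tags)
        for tag, idx in self._plan:
            if tag == "pool":
                x = x.max_pool2x2()
                continue
            x = self.convs[idx](x).relu()
            if tag in remaining:
                out[tag] = x
                remaining.discard(tag)
                if not remaining:
                    break
        return out

    def pooled(self, images) -> np.ndarray:
        """Spatially averaged deepest features, one vector per image (for FID)."""
        feats = self.features(images, [self.deepest_tag])[self.deepest_tag]
        return feats.data.mean(axis=(2, 3))

    def forward(self, x: Tensor) -> Tensor:  # deepest feature map
        return self.features(x, [self.deepest_tag])[self.deepest_tag]


def extract_features(extractor: FeatureExtractor, image,
                     tags: list[str] | tuple[str, ...] = ("conv3_4", "conv4_4")) -> dict[str, Tensor]:
    """Feature maps of `image` at the requested tags (single forward pass)."""
    return extractor.features(image, tags)
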