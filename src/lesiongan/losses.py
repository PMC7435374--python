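"""Training objectives: regional perceptual, regional L1, local-global LSGAN.

The regional perceptual loss compares deep features of *masked* images —
masking happens in pixel space, before feature extraction — so the
generator is scored against the background donor's tissue on the tissue
region and against the tumor donor's lesion on the tumor region:

    L_rp = l1 * MSE(phi_a(y * R_tis), phi_a(x_b * R_tis))
         + l2 * MSE(phi_b(y * R_tis), phi_b(x_b * R_tis))
         + l3 * MSE(phi_b(y * R_tum), phi_b(x_a * R_tum))

with (l1 : l2 : l3) = 1 : 100 : 100 and (phi_a, phi_b) the conv3_4 /
conv4_4 maps of the perceptual backbone.  The regional L1 loss is the
mean absolute tissue-region difference.  Both discriminators use the
least-squares objective; the total generator objective weights the three
families 1 : 1000 : 1000.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .networks import FeatureExtractor, extract_features
from .nn import Tensor, as_tensor
from .preprocessing import RegionMasks

DEFAULT_PERCEPTUAL_TAGS = ("conv3_4", "conv4_4")


@dataclasses.dataclass
class LossWeights:
    """(lambda1, lambda2, lambda3) inside the perceptual loss and
    (lam, mu, gamma) weighting perceptual : L1 : adversarial in the total."""

    lambda1: float = 1.0
    lambda2: float = 100.0
    lambda3: float = 100.0
    lam: float = 1.0
    mu: float = 1000.0
    gamma: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "lambda3", "lam", "mu", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"loss weight {name} must be non-negative")


@dataclasses.dataclass
class LossRecord:
    """Per-step scalar losses; total = lam*l_rp + mu*l_1 + gamma*l_adv."""

    step: int
    l_rp: float
    l_1: float
    l_g: float
    l_l: float
    l_adv: float
    total: float

    def __post_init__(self) -> None:
        vals = [self.l_rp, self.l_1, self.l_g, self.l_l, self.l_adv, self.total]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite loss in record: {self}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _to_nchw(image) -> Tensor:
    x = as_tensor(image)
    if x.ndim == 2:
        x = x.reshape(1, 1, *x.shape)
    elif x.ndim == 3:
        x = x.reshape(x.shape[0], 1, x.shape[1], x.shape[2])
    if x.ndim != 4:
        raise ValueError(f"expected image of 2-4 dims, got shape {x.shape}")
    return x


def _mask_nchw(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask, dtype=np.float64)
    if m.ndim == 2:
        m = m[None, None]
    elif m.ndim == 3:
        m = m[:, None]
    return m


def masked_image(image, mask) -> Tensor:
    """Elementwise product of an image with a binary region mask."""
    x = _to_nchw(image)
    m = _mask_nchw(mask)
    if m.shape[-2:] != x.shape[-2:]:
        raise ValueError(f"mask shape {m.shape[-2:]} does not match image {x.shape[-2:]}")
    return x * Tensor(m)


def _mse(a: Tensor, b: Tensor) -> Tensor:
    d = a - b
    return (d * d).mean()


def regional_perceptual_loss(y, x_b, x_a, masks: RegionMasks,
                             extractor: FeatureExtractor,
                             w: LossWeights | None = None,
                             tags: tuple[str, str] = DEFAULT_PERCEPTUAL_TAGS) -> Tensor:
    """Feature-space MSE over the masked tissue and tumor regions.

    Returns a scalar autograd tensor; ``float()`` gives the value.
    """
    w = w or LossWeights()
    tag_a, tag_b = tags
    y_tis = masked_image(y, masks.tissue_mask)
    xb_tis = masked_image(as_tensor(x_b).detach(), masks.tissue_mask)
    y_tum = masked_image(y, masks.tumor_mask)
    xa_tum = masked_image(as_tensor(x_a).detach(), masks.tumor_mask)

    f_y_tis = extract_features(extractor, y_tis, (tag_a, tag_b))
    f_xb_tis = extract_features(extractor, xb_tis, (tag_a, tag_b))
    f_y_tum = extract_features(extractor, y_tum, (tag_b,))
    f_xa_tum = extract_features(extractor, xa_tum, (tag_b,))

    return (w.lambda1 * _mse(f_y_tis[tag_a], f_xb_tis[tag_a].detach())
            + w.lambda2 * _mse(f_y_tis[tag_b], f_xb_tis[tag_b].detach())
            + w.lambda3 * _mse(f_y_tum[tag_b], f_xa_tum[tag_b].detach()))


def regional_l1_loss(y, x_b, tissue_mask: np.ndarray) -> Tensor:
    """Mean absolute difference of y and x_b restricted to the tissue region
    (averaged over all pixels, masked pixels contributing zero)."""
    y_tis = masked_image(y, tissue_mask)
    xb_tis = masked_image(as_tensor(x_b).detach(), tissue_mask)
    return (y_tis - xb_tis).abs().mean()


def lsgan_d_loss(d_real_out, d_fake_out) -> Tensor:
    """Least-squares discriminator objective: real -> 1, fake -> 0."""
    r = as_tensor(d_real_out)
    f = as_tensor(d_fake_out)
    if r.shape != f.shape:
        raise ValueError(f"patch map shapes differ: {r.shape} vs {f.shape}")
    one = Tensor(np.ones_like(r.data))
    return _mse(r, one) + (f * f).mean()


def lsgan_g_loss(d_fake_out) -> Tensor:
    """Generator-side least-squares term: push fake patches toward 1."""
    f = as_tensor(d_fake_out)
    one = Tensor(np.ones_like(f.data))
    return _mse(f, one)


def total_loss(l_rp, l_1, l_adv, w: LossWeights | None = None) -> Tensor:
    """Weighted sum lam*L_rp + mu*L_1 + gamma*L_adv."""
    w = w or LossWeights()
    parts = [as_tensor(v) for v in (l_rp, l_1, l_adv)]
    for name, p in zip(("l_rp", "l_1", "l_adv"), parts):
        if not np.all(np.isfinite(p.data)):
            raise ValueError(f"non-finite loss component {name}")
    return w.lam * parts[0] + w.mu * parts[1] + w.gamma * parts[2]
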