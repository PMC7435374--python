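"""Loss identities and agreement with an independent term-by-term oracle."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from lesiongan.losses import (
    LossRecord, LossWeights, lsgan_d_loss, lsgan_g_loss, masked_image,
    regional_l1_loss, regional_perceptual_loss, total_loss,
)
from lesiongan.networks import FeatureExtractor
from lesiongan.preprocessing import RegionMasks

RNG = np.random.default_rng(11)


# ---------------------------------------------------------------------------
# Independent oracle: plain-numpy VGG-block forward + per-term Eq arithmetic
# ---------------------------------------------------------------------------

def oracle_features(ext: FeatureExtractor, image2d: np.ndarray) -> dict[str, np.ndarray]:
    mean = np.array([0.485, 0.456, 0.406])
    std = np.array([0.229, 0.224, 0.225])
    x = np.stack([(image2d - m) / s for m, s in zip(mean, std)])
    out = {}
    conv_idx = 0
    for tag, idx in ext._plan:
        if tag == "pool":
            c, h, w = x.shape
            x = x[:, :h // 2 * 2, :w // 2 * 2].reshape(c, h // 2, 2, w // 2, 2).max(axis=(2, 4))
            continue
        conv = ext.convs[idx]
        w_ = conv.weight.data
        b_ = conv.bias.data
        y = np.stack([
            sum(correlate2d(x[ci], w_[oi, ci], mode="same", boundary="fill")
                for ci in range(x.shape[0])) + b_[oi]
            for oi in range(w_.shape[0])
        ])
        x = np.maximum(y, 0.0)
        out[tag] = x
        conv_idx += 1
    return out


def oracle_perceptual(y, x_b, x_a, tis, tum, ext, w, tags):
    def mse(a, b):
        return float(np.mean((a - b) ** 2))
    fy_tis = oracle_features(ext, y * tis)
    fxb_tis = oracle_features(ext, x_b * tis)
    fy_tum = oracle_features(ext, y * tum)
    fxa_tum = oracle_features(ext, x_a * tum)
    return (w.lambda1 * mse(fy_tis[tags[0]], fxb_tis[tags[0]])
            + w.lambda2 * mse(fy_tis[tags[1]], fxb_tis[tags[1]])
            + w.lambda3 * mse(fy_tum[tags[1]], fxa_tum[tags[1]]))


def random_phantom_like_slice(rng, n=16):
    """Tiny slice with brain, nested tumor, and disjoint region masks."""
    yy, xx = np.mgrid[:n, :n]
    cy, cx = rng.uniform(n * 0.4, n * 0.6, 2)
    brain = (yy - cy) ** 2 + (xx - cx) ** 2 <= (n * 0.45) ** 2
    tum_cy, tum_cx = rng.uniform(n * 0.35, n * 0.65, 2)
    tumor = ((yy - tum_cy) ** 2 + (xx - tum_cx) ** 2 <= (n * 0.2) ** 2) & brain
    tissue = brain & ~tumor
    img = np.clip(rng.normal(0.5, 0.15, (n, n)), 0, 1) * brain
    return img, tumor.astype(float), tissue.astype(float)


class TestMaskedImage:
    def test_full_and_zero_masks(self):
        img = RNG.random((4, 4))
        np.testing.assert_array_equal(masked_image(img, np.ones((4, 4))).data[0, 0], img)
        assert masked_image(img, np.zeros((4, 4))).data.sum() == 0.0

    def test_elementwise_toy(self):
        img = np.arange(16.0).reshape(4, 4) / 16
        mask = (np.arange(16).reshape(4, 4) % 2).astype(float)
        np.testing.assert_array_equal(masked_image(img, mask).data[0, 0], img * mask)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mask shape"):
            masked_image(np.zeros((4, 4)), np.zeros((3, 3)))


class TestIdentities:
    def test_perceptual_zero_when_regions_match(self):
        ext = FeatureExtractor(width_scale=0.125, seed=0, n_blocks=2)
        img, tum, tis = random_phantom_like_slice(np.random.default_rng(0))
        x_b = RNG.random((16, 16))
        x_a = RNG.random((16, 16))
        y = x_b * tis + x_a * tum  # agrees with x_b on tissue, x_a on tumor
        masks = RegionMasks(tumor_mask=tum.astype(bool), tissue_mask=tis.astype(bool))
        val = regional_perceptual_loss(y, x_b, x_a, masks, ext,
                                       tags=("conv1_2", "conv2_2"))
        assert abs(float(val)) < 1e-6

    def test_perceptual_zero_weights(self):
        ext = FeatureExtractor(width_scale=0.125, seed=0, n_blocks=2)
        w0 = LossWeights(lambda1=0, lambda2=0, lambda3=0)
        masks = RegionMasks(np.zeros((16, 16), bool), np.ones((16, 16), bool))
        val = regional_perceptual_loss(RNG.random((16, 16)), RNG.random((16, 16)),
                                       RNG.random((16, 16)), masks, ext, w0,
                                       tags=("conv1_2", "conv2_2"))
        assert float(val) == 0.0

    def test_perceptual_ignores_pixels_outside_both_masks(self):
        ext = FeatureExtractor(width_scale=0.125, seed=0, n_blocks=2)
        img, tum, tis = random_phantom_like_slice(np.random.default_rng(3))
        x_b, x_a = RNG.random((16, 16)), RNG.random((16, 16))
        masks = RegionMasks(tum.astype(bool), tis.astype(bool))
        outside = ~(masks.tumor_mask | masks.tissue_mask)
        y1 = img.copy()
        y2 = img.copy()
        y2[outside] = RNG.random(int(outside.sum()))
        v1 = float(regional_perceptual_loss(y1, x_b, x_a, masks, ext,
                                            tags=("conv1_2", "conv2_2")))
        v2 = float(regional_perceptual_loss(y2, x_b, x_a, masks, ext,
                                            tags=("conv1_2", "conv2_2")))
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_l1_identities_and_toy(self):
        y = RNG.random((8, 8))
        assert float(regional_l1_loss(y, y, np.ones((8, 8)))) == 0.0
        assert float(regional_l1_loss(y, RNG.random((8, 8)), np.zeros((8, 8)))) == 0.0
        # 2x2 toy: masked difference |0.5-0.25| on one pixel, averaged over 4
        y2 = np.array([[0.5, 0.9], [0.3, 0.1]])
        x2 = np.array([[0.25, 0.4], [0.8, 0.9]])
        m = np.array([[1.0, 0.0], [0.0, 0.0]])
        assert float(regional_l1_loss(y2, x2, m)) == pytest.approx(0.0625)

    @pytest.mark.parametrize("real,fake,expected", [
        (1.0, 0.0, 0.0), (0.0, 1.0, 2.0), (0.5, 0.5, 0.5),
    ])
    def test_lsgan_d_values(self, real, fake, expected):
        r = np.full((2, 1, 3, 3), real)
        f = np.full((2, 1, 3, 3), fake)
        assert float(lsgan_d_loss(r, f)) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("fake,expected", [(1.0, 0.0), (0.0, 1.0), (0.5, 0.25)])
    def test_lsgan_g_values(self, fake, expected):
        assert float(lsgan_g_loss(np.full((1, 1, 2, 2), fake))) == pytest.approx(expected)

    def test_total_loss_arithmetic_and_linearity(self):
        w = LossWeights()
        assert float(total_loss(1.0, 1.0, 1.0, w)) == pytest.approx(2001.0)
        assert float(total_loss(0.0, 0.0, 0.0, w)) == 0.0
        assert float(total_loss(2.0, 0.001, 0.0005, w)) == pytest.approx(3.5)
        a = float(total_loss(1.0, 2.0, 3.0, w))
        b = float(total_loss(2.0, 2.0, 3.0, w))
        assert b - a == pytest.approx(w.lam)

    def test_total_loss_rejects_non_finite(self):
        with pytest.raises(ValueError, match="non-finite"):
            total_loss(np.nan, 0.0, 0.0)


class TestOracleEquivalence:
    def test_perceptual_and_l1_match_independent_reimplementation(self):
        ext = FeatureExtractor(width_scale=0.125, seed=9, n_blocks=2)
        w = LossWeights()
        tags = ("conv1_2", "conv2_2")
        rng = np.random.default_rng(123)
        for trial in range(5):
            img, tum, tis = random_phantom_like_slice(rng)
            y = np.clip(img + rng.normal(0, 0.1, img.shape), 0, 1)
            x_b = np.clip(img + rng.normal(0, 0.05, img.shape), 0, 1)
            x_a = rng.random(img.shape)
            masks = RegionMasks(tum.astype(bool), tis.astype(bool))
            ours = float(regional_perceptual_loss(y, x_b, x_a, masks, ext, w, tags))
            ref = oracle_perceptual(y, x_b, x_a, tis, tum, ext, w, tags)
            assert ours == pytest.approx(ref, rel=1e-6)
            ours_l1 = float(regional_l1_loss(y, x_b, tis))
            ref_l1 = float(np.abs(y * tis - x_b * tis).mean())
            assert ours_l1 == pytest.approx(ref_l1, rel=1e-6)


def test_loss_record_invariant():
    rec = LossRecord(step=0, l_rp=1.0, l_1=0.5, l_g=0.2, l_l=0.1, l_adv=0.3,
                     total=1.0 + 500.0 + 300.0)
    assert rec.l_adv == pytest.approx(rec.l_g + rec.l_l)
    with pytest.raises(ValueError, match="non-finite"):
        LossRecord(step=0, l_rp=np.inf, l_1=0, l_g=0, l_l=0, l_adv=0, total=0)


def test_weights_must_be_non_negative():
    with pytest.raises(ValueError, match="non-negative"):
        LossWeights(mu=-1.0)
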