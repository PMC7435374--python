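"""Normalization, slicing, label encoding and the regional masks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from lesiongan.preprocessing import (
    SemanticLabel, brain_mask_from_image, decode_label, encode_label,
    extract_slices, normalize_intensity, one_hot, region_masks, resize_slice,
)


def make_label(classes, patient="p", idx=0):
    return SemanticLabel(classes=np.asarray(classes), patient_id=patient, slice_index=idx)


class TestNormalizeIntensity:
    def test_direct_substitution(self):
        out = normalize_intensity(np.array([[0.0, 51.0], [255.0, 0.0]]))
        np.testing.assert_allclose(out, [[0.0, 0.2], [1.0, 0.0]])

    @given(hnp.arrays(np.float64, (6, 6),
                      elements=st.floats(-50, 50, allow_nan=False)))
    @settings(max_examples=50, deadline=None)
    def test_output_spans_unit_interval(self, image):
        if image.max() == image.min():
            with pytest.raises(ValueError, match="constant"):
                normalize_intensity(image)
            return
        out = normalize_intensity(image)
        assert out.min() == 0.0 and out.max() == 1.0
        # idempotent on already-normalized images
        np.testing.assert_allclose(normalize_intensity(out), out)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="finite"):
            normalize_intensity(np.array([[0.0, np.inf]]))


class TestExtractSlices:
    def test_default_window_gives_80_slices(self):
        vol = np.zeros((155, 4, 4))
        assert len(extract_slices(vol)) == 80

    def test_full_window(self):
        vol = np.arange(5 * 2 * 2).reshape(5, 2, 2)
        out = extract_slices(vol, 0, 5)
        assert len(out) == 5
        np.testing.assert_array_equal(out[3], vol[3])

    def test_shallow_volume_rejected(self):
        with pytest.raises(ValueError, match="depth 50"):
            extract_slices(np.zeros((50, 4, 4)))


class TestResizeSlice:
    def test_label_codes_preserved(self):
        lab = np.zeros((32, 32), dtype=int)
        lab[10:20, 10:20] = 2
        lab[14:16, 14:16] = 1
        out = resize_slice(lab, 64, is_label=True)
        assert out.shape == (64, 64)
        assert set(np.unique(out)) <= {0, 1, 2}

    def test_intensity_resize(self):
        const = resize_slice(np.full((32, 32), 0.7), 64)
        np.testing.assert_allclose(const, 0.7)
        assert resize_slice(np.random.default_rng(0).random((128, 128)), 256).shape == (256, 256)

    def test_minimum_size(self):
        with pytest.raises(ValueError, match=">= 16"):
            resize_slice(np.zeros((32, 32)), 8)


class TestBrainMask:
    def test_empty_image_rejected(self):
        with pytest.raises(ValueError, match="empty brain mask"):
            brain_mask_from_image(np.zeros((8, 8)))

    def test_holes_filled(self):
        img = np.zeros((16, 16))
        img[4:12, 4:12] = 1.0
        img[7:9, 7:9] = 0.0  # interior hole
        mask = brain_mask_from_image(img)
        assert mask[7, 7] and mask[8, 8]
        assert mask.sum() == 64

    def test_largest_component_kept(self):
        # brute-force expectation on a toy 8x8 grid: two positive islands
        img = np.zeros((8, 8))
        img[1:4, 1:4] = 1.0   # 9 pixels
        img[6:8, 6:8] = 1.0   # 4 pixels
        mask = brain_mask_from_image(img)
        expected = np.zeros((8, 8), dtype=bool)
        expected[1:4, 1:4] = True
        np.testing.assert_array_equal(mask, expected)


class TestEncodeLabel:
    def test_mapping_table(self):
        raw = np.array([[0, 0, 2], [1, 4, 0]])
        brain = np.array([[0, 1, 1], [1, 1, 1]], dtype=bool)
        lab = encode_label(raw, brain)
        np.testing.assert_array_equal(lab.classes, [[0, 1, 2], [3, 4, 1]])

    def test_decode_inverts_encode(self):
        raw = np.array([[0, 2, 2], [1, 4, 0], [0, 0, 0]])
        brain = raw >= 0
        lab = encode_label(raw, brain)
        np.testing.assert_array_equal(decode_label(lab), raw)

    def test_tumor_outside_mask_rejected(self):
        raw = np.array([[4, 0], [0, 0]])
        brain = np.array([[0, 1], [1, 1]], dtype=bool)
        with pytest.raises(ValueError, match="outside the brain"):
            encode_label(raw, brain)

    def test_unexpected_code_rejected(self):
        with pytest.raises(ValueError, match="unexpected raw label"):
            encode_label(np.array([[3]]), np.ones((1, 1), bool))


class TestRegionMasks:
    def test_tumor_free_donor(self):
        s_a = make_label(np.ones((4, 4), dtype=int))
        s_b_cls = np.ones((4, 4), dtype=int)
        s_b_cls[1, 1] = 2
        s_b = make_label(s_b_cls)
        masks = region_masks(s_a, s_b)
        assert masks.tumor_mask.sum() == 0
        expected_tissue = (s_b_cls == 1)
        np.testing.assert_array_equal(masks.tissue_mask, expected_tissue)

    def test_self_pair(self, toy_labels):
        s_a, _ = toy_labels
        masks = region_masks(s_a, s_a)
        np.testing.assert_array_equal(masks.tumor_mask, np.isin(s_a.classes, (2, 3, 4)))
        np.testing.assert_array_equal(
            masks.tissue_mask, (s_a.classes >= 1) & ~np.isin(s_a.classes, (2, 3, 4)))
        assert not (masks.tumor_mask & masks.tissue_mask).any()

    def test_overlapping_tumors_match_set_formula(self, toy_labels):
        s_a, s_b = toy_labels
        masks = region_masks(s_a, s_b)
        # brute-force pixel enumeration of the defining sets
        for i in range(6):
            for j in range(6):
                in_tum_a = s_a.classes[i, j] in (2, 3, 4)
                in_tis = (s_b.classes[i, j] >= 1 and not in_tum_a
                          and s_b.classes[i, j] not in (2, 3, 4))
                assert masks.tumor_mask[i, j] == in_tum_a
                assert masks.tissue_mask[i, j] == in_tis

    @given(st.integers(0, 2 ** 18))
    @settings(max_examples=40, deadline=None)
    def test_masks_always_disjoint_and_within_brains(self, bits):
        rng = np.random.default_rng(bits)
        grids = rng.integers(0, 5, size=(2, 5, 5))
        s_a, s_b = (make_label(g) for g in grids)
        masks = region_masks(s_a, s_b)
        assert not (masks.tumor_mask & masks.tissue_mask).any()
        union = masks.tumor_mask | masks.tissue_mask
        assert not (union & ~(s_a.brain_mask() | s_b.brain_mask())).any()


def test_one_hot_partitions_image():
    lab = SemanticLabel(np.array([[0, 1], [3, 4]]), "p", 0)
    oh = one_hot(lab)
    assert oh.shape == (5, 2, 2)
    np.testing.assert_array_equal(oh.sum(axis=0), 1.0)
    assert oh[3, 1, 0] == 1.0
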