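"""From raw volumes to the normalized slices, labels and masks the GAN consumes.

Raw BraTS-style volumes carry skull-stripped intensities (zero outside the
brain) and tumor codes {0, 1, 2, 4}.  Internally each slice is re-encoded
to five classes so the brain background is an explicit region:

    0 outside brain | 1 brain tissue | 2 edema | 3 necrotic/non-enhancing
    core | 4 enhancing tumor

Intensities are min-max normalized per slice to [0, 1]; label slices are
resized with nearest-neighbor so no new codes appear.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

TUMOR_CLASSES = (2, 3, 4)  # edema, core, enhancing (internal encoding)
N_CLASSES = 5


@dataclasses.dataclass
class ModalitySlice:
    """One normalized 2-D brain image of a named modality."""

    pixels: np.ndarray
    modality: str
    patient_id: str
    slice_index: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("ModalitySlice expects a 2-D array")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("ModalitySlice pixels must lie in [0, 1]")


@dataclasses.dataclass
class SemanticLabel:
    """Per-pixel class map over the 5-class internal encoding."""

    classes: np.ndarray
    patient_id: str
    slice_index: int

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        if self.classes.ndim != 2:
            raise ValueError("SemanticLabel expects a 2-D array")
        codes = set(np.unique(self.classes).tolist())
        if not codes <= {0, 1, 2, 3, 4}:
            raise ValueError(f"unexpected class code(s): {sorted(codes - {0, 1, 2, 3, 4})}")

    def brain_mask(self) -> np.ndarray:
        return self.classes >= 1

    def tumor_mask(self) -> np.ndarray:
        return np.isin(self.classes, TUMOR_CLASSES)

    def has_tumor(self) -> bool:
        return bool(self.tumor_mask().any())


@dataclasses.dataclass
class RegionMasks:
    """The disjoint masks driving the regional losses.

    ``tumor_mask`` covers the tumor of the donor label (R^tum of patient A);
    ``tissue_mask`` covers the background donor's healthy tissue excluding
    both donors' tumor sites (R^tis of patient B).
    """

    tumor_mask: np.ndarray
    tissue_mask: np.ndarray

    def __post_init__(self) -> None:
        self.tumor_mask = np.asarray(self.tumor_mask, dtype=bool)
        self.tissue_mask = np.asarray(self.tissue_mask, dtype=bool)
        if self.tumor_mask.shape != self.tissue_mask.shape:
            raise ValueError("mask shape mismatch")
        if (self.tumor_mask & self.tissue_mask).any():
            raise ValueError("tumor and tissue masks must be disjoint")


def normalize_intensity(image: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]: (I - Imin) / (Imax - Imin)."""
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    lo, hi = image.min(), image.max()
    if hi == lo:
        raise ValueError("constant image: min-max normalization undefined")
    return (image - lo) / (hi - lo)


def extract_slices(volume: np.ndarray, low: int = 30, high: int = 110) -> list[np.ndarray]:
    """Axial slices with index in the half-open window [low, high).

    The defaults keep the 80 central slices where tumors live, discarding
    the mostly-empty top and bottom of the head.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("expected a 3-D volume")
    depth = volume.shape[0]
    if not (0 <= low < high):
        raise ValueError(f"invalid window [{low}, {high})")
    if depth < high:
        raise ValueError(f"volume depth {depth} is smaller than the slice window upper bound {high}")
    return [volume[i] for i in range(low, high)]


def resize_slice(image: np.ndarray, size: int = 256, is_label: bool = False) -> np.ndarray:
    """Resize to size x size: bilinear for intensities, nearest-neighbor for labels."""
    if size < 16:
        raise ValueError("size must be >= 16")
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2-D slice")
    if image.shape == (size, size):
        return image.copy()
    if is_label:
        out = _sk_resize(image.astype(np.float64), (size, size), order=0,
                         preserve_range=True, anti_aliasing=False)
        return np.rint(out).astype(image.dtype if np.issubdtype(image.dtype, np.integer) else np.int64)
    out = _sk_resize(image.astype(np.float64), (size, size), order=1,
                     preserve_range=True, anti_aliasing=False)
    return out


def brain_mask_from_image(image: np.ndarray) -> np.ndarray:
    """Brain mask of a skull-stripped raw slice: positive support, largest
    connected component, holes filled."""
    image = np.asarray(image)
    mask = image > 0
    if not mask.any():
        raise ValueError("empty brain mask: image has no positive intensities")
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def encode_label(raw_label: np.ndarray, brain_mask: np.ndarray,
                 patient_id: str = "", slice_index: int = -1) -> SemanticLabel:
    """Map raw BraTS codes {0,1,2,4} + brain mask to the 5-class encoding.

    0 stays 0 outside the brain; healthy brain becomes 1; edema (2) stays 2;
    necrotic/non-enhancing core (1) becomes 3; enhancing (4) stays 4.
    """
    raw_label = np.asarray(raw_label)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if raw_label.shape != brain_mask.shape:
        raise ValueError("raw label / brain mask shape mismatch")
    codes = set(np.unique(raw_label).tolist())
    if not codes <= {0, 1, 2, 4}:
        raise ValueError(f"unexpected raw label code(s): {sorted(codes - {0, 1, 2, 4})}")
    if ((raw_label > 0) & ~brain_mask).any():
        raise ValueError("tumor voxel(s) outside the brain mask")
    out = np.zeros(raw_label.shape, dtype=np.int64)
    out[brain_mask & (raw_label == 0)] = 1
    out[raw_label == 2] = 2
    out[raw_label == 1] = 3
    out[raw_label == 4] = 4
    return SemanticLabel(classes=out, patient_id=patient_id, slice_index=slice_index)


def decode_label(label: SemanticLabel) -> np.ndarray:
    """Inverse of :func:`encode_label`: back to raw BraTS codes {0,1,2,4}."""
    cls = label.classes
    out = np.zeros(cls.shape, dtype=np.int64)
    out[cls == 2] = 2
    out[cls == 3] = 1
    out[cls == 4] = 4
    return out


def region_masks(s_a: SemanticLabel, s_b: SemanticLabel) -> RegionMasks:
    """Masks for the regional losses given tumor donor A and background donor B.

    tumor_mask  = tumor support of s_a;
    tissue_mask = brain of s_b minus both donors' tumor supports.
    The two are disjoint by construction.
    """
    if s_a.classes.shape != s_b.classes.shape:
        raise ValueError("semantic labels differ in shape")
    tumor_a = s_a.tumor_mask()
    tissue = s_b.brain_mask() & ~tumor_a & ~s_b.tumor_mask()
    return RegionMasks(tumor_mask=tumor_a, tissue_mask=tissue)


def one_hot(label: SemanticLabel, n_classes: int = N_CLASSES) -> np.ndarray:
    """(n_classes, H, W) float one-hot stack for conditioning the networks."""
    cls = label.classes
    out = np.zeros((n_classes,) + cls.shape, dtype=np.float64)
    for c in range(n_classes):
        out[c] = cls == c
    return out
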