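"""Synthetic multi-modal brain-slice phantoms with nested tumor sub-regions.

Produces skull-stripped-looking volumes in the BraTS 2017 layout: one
intensity volume per modality (flair / t1 / t1ce / t2) plus a label
volume with raw codes 0 (background), 1 (necrotic / non-enhancing core),
2 (edema) and 4 (enhancing tumor).  Geometry is deliberately simple —
the brain is a thresholded sum of smooth 3-D Gaussian bumps, the tumor
an ellipsoidal blob peeled into nested shells by its interior distance
transform — but the phantoms preserve the structural facts downstream
code relies on: a closed brain region, tumor strictly inside the brain,
nested sub-regions, and modality-dependent contrast (the tumor core is
brightest in the t1ce channel).
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

MODALITIES = ("flair", "t1", "t1ce", "t2")
RAW_LABEL_CODES = frozenset({0, 1, 2, 4})

# Region intensities per modality, on a [0, 1] scale before rescaling to
# arbitrary scanner-like units.  Chosen to mimic the qualitative contrast
# of each sequence: edema brightest in flair/t2, enhancing rim brightest
# in t1ce, tumor dark in t1.
_REGION_LEVELS: dict[str, dict[str, float]] = {
    "flair": {"tissue": 0.50, "edema": 0.85, "core": 0.65, "enhancing": 0.70},
    "t1":    {"tissue": 0.60, "edema": 0.45, "core": 0.35, "enhancing": 0.50},
    "t1ce":  {"tissue": 0.55, "edema": 0.45, "core": 0.70, "enhancing": 0.95},
    "t2":    {"tissue": 0.45, "edema": 0.85, "core": 0.60, "enhancing": 0.55},
}

_INTENSITY_SCALE = 200.0  # arbitrary non-negative units
_NOISE_SIGMA_FRACTION = 0.03  # of the intensity range


@dataclasses.dataclass
class PhantomCase:
    """One synthetic patient: per-modality volumes plus a raw label volume."""

    case_id: str
    volumes: dict[str, np.ndarray]
    label_volume: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        shapes = {m: v.shape for m, v in self.volumes.items()}
        if not self.volumes:
            raise ValueError("PhantomCase requires at least one modality volume")
        if len(set(shapes.values())) != 1 or self.label_volume.shape not in set(shapes.values()):
            raise ValueError(f"volume/label shape mismatch: {shapes}, label {self.label_volume.shape}")
        codes = set(np.unique(self.label_volume).tolist())
        if not codes <= RAW_LABEL_CODES:
            raise ValueError(f"unexpected label code(s): {sorted(codes - RAW_LABEL_CODES)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.label_volume.shape

    @property
    def modalities(self) -> list[str]:
        return list(self.volumes)

    def brain_mask(self) -> np.ndarray:
        """Voxels with nonzero intensity in every modality (skull-stripped convention)."""
        mask = np.ones(self.shape, dtype=bool)
        for vol in self.volumes.values():
            mask &= vol > 0
        return mask


def _smooth_bump_field(rng: np.random.Generator, shape: tuple[int, int, int],
                       n_bumps: int = 6) -> np.ndarray:
    d, h, w = shape
    zz, yy, xx = np.meshgrid(np.arange(d), np.arange(h), np.arange(w), indexing="ij")
    field = np.zeros(shape, dtype=np.float64)
    for _ in range(n_bumps):
        cz = d * rng.uniform(0.40, 0.60)
        cy = h * rng.uniform(0.42, 0.58)
        cx = w * rng.uniform(0.42, 0.58)
        sz = d * rng.uniform(0.30, 0.45)
        sy = h * rng.uniform(0.22, 0.32)
        sx = w * rng.uniform(0.22, 0.32)
        amp = rng.uniform(0.6, 1.0)
        field += amp * np.exp(-((zz - cz) ** 2 / (2 * sz ** 2)
                                + (yy - cy) ** 2 / (2 * sy ** 2)
                                + (xx - cx) ** 2 / (2 * sx ** 2)))
    return field


def _brain_mask_3d(rng: np.random.Generator, shape: tuple[int, int, int]) -> np.ndarray:
    """Closed smooth blob covering 30-70% of the central slices."""
    field = _smooth_bump_field(rng, shape)
    mid = field[shape[0] // 2]
    target = rng.uniform(0.40, 0.55)  # central-slice area fraction
    tau = np.quantile(mid, 1.0 - target)
    mask = field > tau
    for z in range(shape[0]):
        sl = mask[z]
        if not sl.any():
            continue
        labels, n = ndimage.label(sl)
        if n > 1:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
            sl = labels == (1 + int(np.argmax(sizes)))
        mask[z] = ndimage.binary_fill_holes(sl)
    return mask


def _tumor_regions(rng: np.random.Generator, brain: np.ndarray,
                   shape: tuple[int, int, int]) -> np.ndarray | None:
    """Raw label volume: nested edema (2) ⊃ core (1) ⊇ enhancing (4), inside the brain."""
    d, h, w = shape
    interior = ndimage.binary_erosion(brain, iterations=2)
    candidates = np.argwhere(interior)
    if candidates.size == 0:
        candidates = np.argwhere(brain)
    if candidates.size == 0:
        return None
    cz, cy, cx = candidates[rng.integers(len(candidates))]
    rz = d * rng.uniform(0.18, 0.30)
    ry = h * rng.uniform(0.12, 0.22)
    rx = w * rng.uniform(0.12, 0.22)
    zz, yy, xx = np.meshgrid(np.arange(d), np.arange(h), np.arange(w), indexing="ij")
    ellipsoid = ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    tumor = ellipsoid & brain
    if tumor.sum() < 8:
        return None
    dist = ndimage.distance_transform_edt(tumor)
    dmax = dist.max()
    core = dist > 0.35 * dmax
    enhancing = dist > 0.65 * dmax
    if not enhancing.any() or not (tumor & ~core).any() or not (core & ~enhancing).any():
        return None  # too thin to carve three nested shells
    raw = np.zeros(shape, dtype=np.int16)
    raw[tumor] = 2
    raw[core] = 1
    raw[enhancing] = 4
    return raw


def generate_phantom_case(seed: int, shape: tuple[int, int, int] = (16, 64, 64),
                          modalities: list[str] | tuple[str, ...] = MODALITIES,
                          case_id: str | None = None,
                          tumor_probability: float = 1.0) -> PhantomCase:
    """Generate one deterministic phantom patient.

    Parameters
    ----------
    seed:
        Seeds all geometry and noise; identical seeds give bit-identical cases.
    shape:
        (depth, height, width); every dimension must be >= 32 except depth,
        which must be >= 8 (slices are the unit of analysis).
    modalities:
        Subset of ``("flair", "t1", "t1ce", "t2")``.
    tumor_probability:
        Chance that the case carries a tumor. The label compositor requires
        tumor donors, so the default is 1.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or shape[0] < 8 or shape[1] < 32 or shape[2] < 32:
        raise ValueError(f"invalid shape {shape}: need depth >= 8 and in-plane dims >= 32")
    modalities = list(modalities)
    if not modalities:
        raise ValueError("modalities must be non-empty")
    unknown = [m for m in modalities if m not in MODALITIES]
    if unknown:
        raise ValueError(f"unknown modality name(s) {unknown}; expected subset of {MODALITIES}")

    rng = np.random.default_rng(seed)
    brain = _brain_mask_3d(rng, shape)

    raw = np.zeros(shape, dtype=np.int16)
    if rng.uniform() < tumor_probability:
        regions = None
        for _attempt in range(50):  # redraw geometry until all shells are nonempty
            regions = _tumor_regions(rng, brain, shape)
            if regions is not None:
                break
        if regions is None:
            raise RuntimeError(f"could not place a nested tumor for seed {seed}")
        raw = regions

    edema = raw == 2
    core = raw == 1
    enh = raw == 4
    tissue = brain & (raw == 0)

    noise_sigma = _NOISE_SIGMA_FRACTION * _INTENSITY_SCALE
    volumes: dict[str, np.ndarray] = {}
    for mod in modalities:
        lv = _REGION_LEVELS[mod]
        img = np.zeros(shape, dtype=np.float64)
        img[tissue] = lv["tissue"]
        img[edema] = lv["edema"]
        img[core] = lv["core"]
        img[enh] = lv["enhancing"]
        # gentle intra-tissue shading so slices are not piecewise-constant
        shading = ndimage.gaussian_filter(rng.normal(0, 1, size=shape), sigma=6.0)
        shading /= max(np.abs(shading).max(), 1e-12)
        img[brain] *= 1.0 + 0.10 * shading[brain]
        img *= _INTENSITY_SCALE
        img[brain] += rng.normal(0.0, noise_sigma, size=int(brain.sum()))
        img = np.clip(img, 0.0, None)
        img[brain] = np.maximum(img[brain], 1.0)  # tumor/tissue voxels stay strictly positive
        img[~brain] = 0.0
        volumes[mod] = img.astype(np.float32)

    cid = case_id or f"phantom_{seed:05d}"
    return PhantomCase(case_id=cid, volumes=volumes, label_volume=raw, seed=seed)


def write_case_nifti(case: PhantomCase, directory: str | os.PathLike) -> list[Path]:
    """Write ``<case_id>_<modality>.nii.gz`` per modality plus ``<case_id>_seg.nii.gz``."""
    if not case.volumes:
        raise ValueError("case has no modality volumes to write")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    written: list[Path] = []
    try:
        for mod, vol in case.volumes.items():
            path = directory / f"{case.case_id}_{mod}.nii.gz"
            nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), str(path))
            written.append(path)
        seg_path = directory / f"{case.case_id}_seg.nii.gz"
        nib.save(nib.Nifti1Image(case.label_volume.astype(np.int16), affine), str(seg_path))
        written.append(seg_path)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise OSError(f"failed writing case {case.case_id} under {directory}: {exc}") from exc
    return written


def read_case_nifti(directory: str | os.PathLike, case_id: str,
                    modalities: list[str] | tuple[str, ...] | None = None) -> PhantomCase:
    """Load a case written by :func:`write_case_nifti` (or a real BraTS case folder)."""
    directory = Path(directory)
    if modalities is None:
        found = [m for m in MODALITIES if (directory / f"{case_id}_{m}.nii.gz").exists()]
        if not found:
            raise FileNotFoundError(
                f"no modality files matching {case_id}_<modality>.nii.gz in {directory}; "
                f"expected one or more of {MODALITIES}")
        modalities = found
    missing = [m for m in modalities if not (directory / f"{case_id}_{m}.nii.gz").exists()]
    if missing:
        raise FileNotFoundError(
            f"missing modality file(s) {[f'{case_id}_{m}.nii.gz' for m in missing]} in "
            f"{directory}; found {[f.name for f in sorted(directory.glob(f'{case_id}_*.nii.gz'))]}")
    seg_path = directory / f"{case_id}_seg.nii.gz"
    if not seg_path.exists():
        raise FileNotFoundError(f"missing label file {seg_path.name} in {directory}")

    volumes = {
        m: np.asarray(nib.load(str(directory / f"{case_id}_{m}.nii.gz")).dataobj,
                      dtype=np.float32)
        for m in modalities
    }
    label = np.asarray(nib.load(str(seg_path)).dataobj)
    if not np.issubdtype(label.dtype, np.integer):
        rounded = np.rint(label)
        if not np.allclose(label, rounded):
            raise ValueError(f"label file {seg_path.name} holds non-integer values")
        label = rounded
    label = label.astype(np.int16)
    codes = set(np.unique(label).tolist())
    if not codes <= RAW_LABEL_CODES:
        raise ValueError(f"unexpected label code(s) {sorted(codes - RAW_LABEL_CODES)} in {seg_path.name}")
    return PhantomCase(case_id=case_id, volumes=volumes, label_volume=label)


def export_slice_png(case: PhantomCase, modality: str, slice_index: int,
                     path: str | os.PathLike) -> Path:
    """8-bit PNG of one slice, for visual inspection."""
    import imageio.v3 as iio

    vol = case.volumes[modality]
    sl = vol[slice_index].astype(np.float64)
    rng_span = sl.max() - sl.min()
    img = np.zeros_like(sl) if rng_span == 0 else (sl - sl.min()) / rng_span
    path = Path(path)
    iio.imwrite(path, (img * 255).astype(np.uint8))
    return path
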