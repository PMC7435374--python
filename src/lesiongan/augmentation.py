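"""Emit virtual (image, label) training pairs with a trained generator.

Each output row composites the label of a sampled donor pair, runs the
generator on the composite label conditioned on the tumor donor's image,
and writes the synthetic image and its label as paired PNGs plus a CSV
manifest recording full provenance (who donated the tumor, who the
background).
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .compositor import InadmissiblePairError, composite_label
from .nn import Tensor, concat
from .preprocessing import one_hot
from .training import SliceDataset

MANIFEST_COLUMNS = ("out_image", "out_label", "tumor_donor", "background_donor",
                    "slice_index", "modality")


@dataclasses.dataclass
class ManifestRow:
    out_image: str
    out_label: str
    tumor_donor: str
    background_donor: str
    slice_index: int
    modality: str


def generate_augmented_dataset(generator, dataset: SliceDataset, k: int, seed: int,
                               out_dir: str | Path, max_dropped: float = 0.05,
                               max_retries_per_sample: int = 50) -> list[ManifestRow]:
    """Write ``k`` virtual (image, label) pairs and a manifest.csv to ``out_dir``."""
    donor_ids = dataset.patient_ids
    pairs = [(a, b) for a in donor_ids for b in sorted(dataset.brain_slices) if a != b]
    if k > len(pairs):
        raise ValueError(f"k={k} exceeds the {len(pairs)} available donor pairs")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))

    rows: list[ManifestRow] = []
    cursor = 0
    for i in range(k):
        composite = sample_a = None
        for _ in range(max_retries_per_sample):
            if cursor >= len(order):  # recycle remaining pairs with fresh slices
                order = rng.permutation(len(pairs))
                cursor = 0
            a, b = pairs[order[cursor]]
            cursor += 1
            pool_a = dataset.tumor_slices[a]
            pool_b = dataset.brain_slices[b]
            sample_a = pool_a[int(rng.integers(len(pool_a)))]
            sample_b = pool_b[int(rng.integers(len(pool_b)))]
            try:
                composite = composite_label(sample_a.label, sample_b.label, max_dropped)
                break
            except InadmissiblePairError:
                continue
        if composite is None:
            raise RuntimeError("admissible-pair budget exhausted during augmentation")

        s_ab = Tensor(one_hot(composite.label)[None])
        x_a = Tensor(sample_a.image[None, None])
        y = generator(concat([s_ab, x_a], axis=1)).data[0, 0]

        stem = f"virtual_{i:04d}"
        img_path = out_dir / f"{stem}_{dataset.modality}.png"
        lab_path = out_dir / f"{stem}_label.png"
        iio.imwrite(img_path, np.clip(np.rint(y * 255), 0, 255).astype(np.uint8))
        iio.imwrite(lab_path, composite.label.classes.astype(np.uint8))
        rows.append(ManifestRow(
            out_image=img_path.name, out_label=lab_path.name,
            tumor_donor=f"{composite.tumor_donor[0]}:{composite.tumor_donor[1]}",
            background_donor=f"{composite.background_donor[0]}:{composite.background_donor[1]}",
            slice_index=composite.background_donor[1], modality=dataset.modality,
        ))

    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=MANIFEST_COLUMNS)
        writer.writeheader()
        for row in rows:
            writer.writerow(dataclasses.asdict(row))
    return rows


def load_augmented_pair(out_dir: str | Path, row: ManifestRow) -> tuple[np.ndarray, np.ndarray]:
    """Read back one (image in [0,1], label classes) pair from disk."""
    out_dir = Path(out_dir)
    img = iio.imread(out_dir / row.out_image).astype(np.float64) / 255.0
    lab = iio.imread(out_dir / row.out_label).astype(np.int64)
    return img, lab
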