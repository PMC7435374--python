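"""Emit virtual (image, label) pairs with a (briefly) trained generator.

Writes paired PNGs plus a provenance manifest naming each sample's tumor
donor and background donor.
"""

import tempfile
from pathlib import Path

from lesiongan import TrainConfig, train
from lesiongan.augmentation import generate_augmented_dataset
from lesiongan.training import build_networks, build_optimizers, load_checkpoint, load_dataset

cfg = TrainConfig(iterations=10, image_size=64, base_width_scale=0.125, seed=0,
                  phantom_shape=(8, 64, 64), n_phantom_cases=3,
                  checkpoint_every=0, out_dir="scratch/aug_run")
result = train(cfg)
nets = build_networks(cfg)
load_checkpoint(result.checkpoint_path, nets, build_optimizers(nets, cfg))
dataset = load_dataset(cfg)

with tempfile.TemporaryDirectory() as tmp:
    rows = generate_augmented_dataset(nets.generator, dataset, k=4, seed=1, out_dir=tmp)
    print(f"wrote {len(rows)} virtual pairs to {tmp}")
    for row in rows:
        print(f"  {row.out_image}: tumor from {row.tumor_donor}, "
              f"background from {row.background_donor}")
    print(f"files: {sorted(p.name for p in Path(tmp).glob('*'))[:4]} ...")
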