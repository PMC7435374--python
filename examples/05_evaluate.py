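"""Quality metrics: per-region Dice overlap and Frechet inception distance.

Dice groups the label codes BraTS-style (whole / core / enhancing); FID
compares Gaussian fits to pooled deep features of two image sets (lower =
more similar). With no pretrained backbone available the extractor is a
fixed-seed random VGG-19 trunk, so FID values are internally consistent
rather than comparable to published numbers.
"""

import numpy as np

from lesiongan import FeatureExtractor, fid_images, region_dice
from lesiongan.phantom import generate_phantom_case

case = generate_phantom_case(3, (8, 64, 64), ["flair"])
z = int((case.label_volume == 4).sum(axis=(1, 2)).argmax())  # richest slice
true_lab = case.label_volume[z]
# a deliberately imperfect "prediction": erode the tumor by one pixel ring
from scipy import ndimage
pred = true_lab.copy()
shrunk = ndimage.binary_erosion(true_lab > 0)
pred[(true_lab > 0) & ~shrunk] = 0
# map raw codes to the internal 5-class encoding for scoring
remap = {0: 0, 1: 3, 2: 2, 4: 4}
t5 = np.vectorize(remap.get)(true_lab)
p5 = np.vectorize(remap.get)(pred)
rep = region_dice(t5, p5)
print("Dice of an eroded-tumor prediction vs truth:")
print(f"  whole {rep.whole:.3f}  core {rep.core:.3f}  en {rep.en:.3f}  "
      f"mean {rep.mean:.3f}")

ext = FeatureExtractor(width_scale=0.125, seed=0, n_blocks=2)
real = np.stack([generate_phantom_case(10 + i, (8, 64, 64), ["flair"])
                 .volumes["flair"][4] / 255.0 for i in range(6)])
noisy = np.clip(real + np.random.default_rng(0).normal(0, 0.1, real.shape), 0, 1)
print(f"FID(real, real)  = {fid_images(real, real, ext):.6f}  (zero to itself)")
print(f"FID(real, noisy) = {fid_images(real, noisy, ext):.4f}  "
      "(grows with corruption)")
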