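"""Composite a virtual semantic label: patient A's tumor on patient B's brain.

From n patients the ordered donor pairs give n^2 - n virtual samples
(226 patients -> 50,850). Prints the pair arithmetic and one composite
with its dropped-tumor fraction (pairs losing > 5% are inadmissible).
"""

import numpy as np

from lesiongan import (
    composite_label, enumerate_pairs, generate_phantom_case, sample_pairs,
)
from lesiongan.training import SliceDataset

print(f"226 patients -> {len(enumerate_pairs([str(i) for i in range(226)])):,} "
      "ordered (tumor donor, background donor) pairs")

cases = [generate_phantom_case(100 + i, (8, 64, 64), ["flair"]) for i in range(3)]
ds = SliceDataset(cases, "flair", 64)
pairs = enumerate_pairs(ds.patient_ids)
print(f"{len(ds.patient_ids)} phantom patients -> {len(pairs)} pairs; "
      f"a seeded sample of 2: {sample_pairs(pairs, 2, seed=0)}")

a, b = pairs[0]
# middle slices: largest brain cross-sections, so the paste is admissible
s_a = ds.tumor_slices[a][len(ds.tumor_slices[a]) // 2].label
s_b = ds.brain_slices[b][len(ds.brain_slices[b]) // 2].label
out = composite_label(s_a, s_b)
n_a = int(np.isin(s_a.classes, (2, 3, 4)).sum())
n_ab = int(np.isin(out.label.classes, (2, 3, 4)).sum())
print(f"composite {a} -> {b}: tumor pixels {n_a} in donor, {n_ab} in composite, "
      f"dropped fraction {out.dropped_fraction:.3f}")
print("B's own tumor was relabeled to healthy tissue; A's tumor keeps its "
      "pixel coordinates wherever they fall inside B's brain.")
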