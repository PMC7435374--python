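"""A tiny CPU training run of the conditional GAN on phantom slices.

Uses 1/8-width networks on 64x64 slices so 40 alternating D-then-G steps
finish in seconds. Prints the per-component losses: l_rp (regional
perceptual), l_1 (regional tissue L1), l_g / l_l (global / local
least-squares critic losses) and the weighted total.
"""

from lesiongan import TrainConfig, train

cfg = TrainConfig(iterations=40, image_size=64, base_width_scale=0.125, seed=0,
                  phantom_shape=(8, 64, 64), n_phantom_cases=4,
                  checkpoint_every=0, out_dir="scratch/example_run")
result = train(cfg)
for rec in result.records[::8]:
    print(f"step {rec.step:3d}  l_rp {rec.l_rp:7.2f}  l_1 {rec.l_1:.4f}  "
          f"l_g {rec.l_g:.3f}  l_l {rec.l_l:.3f}  total {rec.total:8.1f}")
print(f"checkpoint: {result.checkpoint_path}")
print(f"loss log:   {result.log_path}")
print("The critics (l_g, l_l) fall as they learn real-vs-fake; the generator "
      "total is dominated by the 1000-weighted L1 and adversarial terms.")
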