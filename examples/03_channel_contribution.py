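"""Rank input channels by perturbing them one at a time with Rician noise.

For each channel, a Rician-noised copy (sigma = 10% of the channel's
within-mask mean) replaces the original, the volume is re-translated,
and the RMSE against the unperturbed output measures how much the
network relies on that channel.  Normalized shares drive channel
ranking and acquisition-subset selection.
"""

import numpy as np

import mrh
from mrh.pipeline import acquisition_budget

spec = mrh.default_phantom_spec(
    shape=(24, 24, 24), n_channels=8, n_classes=3,
    mapping_form="subset-dependent", active_channels=(0, 1),
    noise_sigma_fraction=0.05, uninformative_decoys=True, seed=1,
)
# fixed effect sizes: the stain depends on channels 0 and 1 only
w = np.zeros(8)
q = np.zeros(8)
w[:2] = [1.0, -0.8]
q[:2] = [0.4, 0.3]
spec.mapping = mrh.GroundTruthMapping(
    "subset-dependent", weights=w, intercept=0.5, quad_weights=q,
    cross_terms=[(0, 1, 0.5)], active_channels=np.arange(2),
)
volume, target, mask, _ = mrh.make_phantom(spec, seed=2)
patches = mrh.extract_patches(volume, target, mask, n=4500, seed=3)
patches, _ = mrh.normalize_channels(patches, "fit", normalize_target=True)
train_ps, val_ps = mrh.split_validation(patches, 600, seed=4)
model = mrh.train(
    mrh.build_mrh(mrh.NetworkSpec(in_channels=8, n_residual_blocks=4,
                                  channels_per_layer=16), seed=5),
    train_ps, val_ps,
    mrh.TrainingConfig(learning_rate=0.05, max_epochs=25, patience=8, seed=6),
)

report = mrh.channel_contribution(model, volume, mask,
                                  noise_fraction=0.10, repeats=3, seed=7)
print("channel contributions (target truly depends on channels 0 and 1):")
for _, row in report.to_dataframe().sort_values("rank").iterrows():
    print(f"  rank {row['rank']:2d}  channel {row['channel']:2d}  "
          f"contribution {row['contribution']:.3f}  "
          f"cumulative {row['cumulative']:.3f}")

subset, time_fraction = acquisition_budget(
    report, np.ones(8), coverage=0.9
)
print(f"\nchannels covering 90% of total contribution: {sorted(subset.tolist())}")
print(f"with uniform per-channel acquisition times they need "
      f"{100 * time_fraction:.0f}% of the full protocol's scan time.")
print("note: unused channels keep a few-percent contribution floor — the "
      "perturbation (10% of the raw channel mean) is large in normalized "
      "units for variance-poor channels — so high coverage targets still "
      "include some of them.")
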