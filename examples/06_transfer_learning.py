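"""Adapt a trained network to a new stain by refining its last 3 layers.

A network trained on one target mapping is transferred to a second
mapping over the same input channels: all weights are frozen except
the final three convolutions, trained at learning rate 1e-4.  This is
the protocol for stains with scarce training data.
"""

import numpy as np

import mrh
from mrh.mrhnet import count_parameters

spec_a = mrh.default_phantom_spec(
    shape=(24, 24, 24), n_channels=6, n_classes=3,
    mapping_form="subset-dependent", active_channels=(0, 1),
    noise_sigma_fraction=0.05, seed=1,
)
vol, tgt, mask, _ = mrh.make_phantom(spec_a, seed=2)
ps = mrh.extract_patches(vol, tgt, mask, n=4500, seed=3)
ps, _ = mrh.normalize_channels(ps, "fit", normalize_target=True)
tr, va = mrh.split_validation(ps, 600, seed=4)
source = mrh.train(
    mrh.build_mrh(mrh.NetworkSpec(in_channels=6, n_residual_blocks=4,
                                  channels_per_layer=16), seed=5),
    tr, va, mrh.TrainingConfig(learning_rate=0.05, max_epochs=12, patience=5,
                               seed=6),
)
print(f"source model: val MAE {min(source.history['val_loss']):.4f}")

# second stain: a different mapping over the same input channels
import dataclasses
spec_b = dataclasses.replace(
    spec_a,
    mapping=mrh.GroundTruthMapping(
        "linear", weights=np.r_[0.0, 0.8, -0.6, 0.0, 0.0, 0.0], intercept=1.0
    ),
)
vol_b, tgt_b, mask_b, _ = mrh.make_phantom(spec_b, seed=7)
ps_b = mrh.extract_patches(vol_b, tgt_b, mask_b, n=3000, seed=8)
ps_b, _ = mrh.normalize_channels(ps_b, source.norm_stats)
ps_b, _ = mrh.normalize_channels(ps_b, ps_b.norm_stats, normalize_target=True)
tr_b, va_b = mrh.split_validation(ps_b, 400, seed=9)

adapted = mrh.transfer_train(source, tr_b, va_b)
print(f"transfer: val MAE {min(adapted.history['val_loss']):.4f} "
      f"(initial learning rate {adapted.config.learning_rate})")

n_total = count_parameters(adapted.network)
n_train = count_parameters(adapted.network, trainable_only=True)
print(f"trainable parameters during transfer: {n_train} of {n_total} "
      f"({100 * n_train / n_total:.1f}%) -- only the last 3 conv layers")

frozen_identical = all(
    np.array_equal(a[0], b[0])
    for a, b in zip(source.network.get_weights()[:-3],
                    adapted.network.get_weights()[:-3])
)
print(f"all weights outside the last 3 layers bit-identical: {frozen_identical}")
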