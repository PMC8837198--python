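import numpy as np
import pytest

import mrh


@pytest.fixture(scope="session")
def small_spec():
    """8-channel, 3-class phantom spec with mild noise."""
    return mrh.default_phantom_spec(
        shape=(24, 24, 24),
        n_channels=8,
        n_classes=3,
        mapping_form="subset-dependent",
        active_channels=(0, 1),
        noise_sigma_fraction=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return mrh.make_phantom(small_spec, seed=21)


@pytest.fixture(scope="session")
def linear_spec():
    """Zero-noise linear phantom: exact ground truth, identifiable fit."""
    return mrh.default_phantom_spec(
        shape=(24, 24, 24),
        n_channels=6,
        n_classes=3,
        mapping_form="linear",
        active_channels=(0, 2, 4),
        noise_sigma_fraction=0.0,
        seed=12,
    )


@pytest.fixture(scope="session")
def linear_phantom(linear_spec):
    return mrh.make_phantom(linear_spec, seed=22)


@pytest.fixture(scope="session")
def tiny_trained_model(small_phantom):
    """A quickly trained small network on the small noisy phantom."""
    vol, tgt, mask, _ = small_phantom
    ps = mrh.extract_patches(vol, tgt, mask, k=3, n=4000, seed=31)
    ps, _ = mrh.normalize_channels(ps, "fit", normalize_target=True)
    train_ps, val_ps = mrh.split_validation(ps, 500, seed=32)
    spec = mrh.NetworkSpec(
        in_channels=vol.n_channels, n_residual_blocks=2, channels_per_layer=16
    )
    net = mrh.build_mrh(spec, seed=33)
    config = mrh.TrainingConfig(max_epochs=6, patience=5, seed=34)
    return mrh.train(net, train_ps, val_ps, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
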