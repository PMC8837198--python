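"""Derived maps: MTR, tensor/kurtosis log-linear fits, polynomial baselines."""

import numpy as np
import pytest

import mrh
from mrh.contrasts import DiffusionScheme, fa_from_eigenvalues


def _directions30(seed=0):
    """30 well-spread unit vectors (deterministic)."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(30, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _two_shell_scheme():
    g = _directions30()
    b = np.r_[0.0, np.full(30, 2000.0), np.full(30, 5000.0)]
    dirs = np.vstack([np.zeros(3), g, g])
    return DiffusionScheme(b, dirs)


def _simulate_tensor(evals, evecs=None, S0=1000.0, scheme=None):
    """Noise-free DWI stack for one SPD tensor, replicated over a 3x3x3 grid."""
    scheme = scheme or _two_shell_scheme()
    if evecs is None:
        evecs = np.eye(3)
    D = evecs @ np.diag(evals) @ evecs.T
    att = np.array(
        [np.exp(-b * g @ D @ g) for b, g in zip(scheme.b_values, scheme.directions)]
    )
    sig = S0 * att
    vol = np.broadcast_to(sig, (3, 3, 3, scheme.n_images)).copy()
    return vol, scheme, np.ones((3, 3, 3), bool)


class TestMTR:
    def test_direct_formula(self):
        m0 = np.full((4, 4, 4), 1.0)
        mt = np.full((4, 4, 4), 0.6)
        mask = np.ones((4, 4, 4), bool)
        out = mrh.compute_mtr(m0, mt, mask)
        np.testing.assert_allclose(out.MTR[mask], 0.4)

    def test_equal_images_give_zero(self, rng):
        m0 = rng.uniform(0.5, 1.5, (4, 4, 4))
        mask = np.ones((4, 4, 4), bool)
        out = mrh.compute_mtr(m0, m0, mask)
        np.testing.assert_allclose(out.MTR[mask], 0.0)

    def test_zero_m0_marked_invalid(self):
        m0 = np.ones((4, 4, 4))
        m0[0, 0, 0] = 0.0
        mask = np.ones((4, 4, 4), bool)
        out = mrh.compute_mtr(m0, 0.5 * m0, mask)
        assert not out.valid_mask[0, 0, 0]
        assert np.isfinite(out.MTR).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mrh.compute_mtr(np.ones((4, 4, 4)), np.ones((5, 4, 4)),
                            np.ones((4, 4, 4), bool))


class TestTensorFit:
    def test_isotropic_recovery(self):
        """S = S0 exp(-b 1e-3) must fit to MD = 1e-3, FA = 0 exactly."""
        vol, scheme, mask = _simulate_tensor([1e-3, 1e-3, 1e-3])
        maps = mrh.fit_tensor_loglinear(vol, scheme, mask)
        np.testing.assert_allclose(maps.MD[mask], 1e-3, rtol=1e-9)
        np.testing.assert_allclose(maps.FA[mask], 0.0, atol=1e-6)

    def test_prolate_tensor_fa_oracle(self):
        """Prolate (1.7, 0.3, 0.3)e-3: FA from the closed-form eigenvalue
        formula ~0.80; the fit must agree to machine precision."""
        evals = np.array([1.7e-3, 0.3e-3, 0.3e-3])
        fa_closed = fa_from_eigenvalues(evals)
        assert abs(fa_closed - 0.80) < 2e-3
        vol, scheme, mask = _simulate_tensor(evals)
        maps = mrh.fit_tensor_loglinear(vol, scheme, mask)
        np.testing.assert_allclose(maps.FA[mask], fa_closed, rtol=1e-9)
        np.testing.assert_allclose(maps.D_R[mask], 0.3e-3, rtol=1e-9)

    def test_rotated_tensor_invariance(self, rng):
        """Eigenvalue recovery is exact for arbitrarily rotated tensors."""
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        evals = np.array([1.5e-3, 0.6e-3, 0.2e-3])
        vol, scheme, mask = _simulate_tensor(evals, evecs=q)
        maps = mrh.fit_tensor_loglinear(vol, scheme, mask)
        np.testing.assert_allclose(
            np.sort(maps.eigenvalues[mask][0]), np.sort(evals), rtol=1e-8
        )

    def test_zero_voxel_excluded(self):
        vol, scheme, mask = _simulate_tensor([1e-3] * 3)
        vol[1, 1, 1] = 0.0
        maps = mrh.fit_tensor_loglinear(vol, scheme, mask)
        assert not maps.valid_mask[1, 1, 1]
        assert maps.valid_mask.sum() == mask.sum() - 1

    def test_too_few_directions_rejected(self):
        g = _directions30()[:4]
        b = np.r_[0.0, np.full(4, 2000.0)]
        scheme = DiffusionScheme(b, np.vstack([np.zeros(3), g]))
        with pytest.raises(ValueError, match="deficiency"):
            mrh.fit_tensor_loglinear(
                np.ones((2, 2, 2, 5)), scheme, np.ones((2, 2, 2), bool)
            )

    def test_shell_restriction(self):
        """Restricting to one shell uses only that shell's images."""
        evals = [1.2e-3, 0.4e-3, 0.4e-3]
        vol, scheme, mask = _simulate_tensor(evals)
        m_all = mrh.fit_tensor_loglinear(vol, scheme, mask)
        m_lo = mrh.fit_tensor_loglinear(vol, scheme, mask, shell=2000.0)
        np.testing.assert_allclose(m_lo.MD[mask], m_all.MD[mask], rtol=1e-6)


class TestDKIFit:
    def test_exact_two_shell_recovery(self):
        """Signals generated with D = 0.8e-3 and K = 1 at b = 2000/5000 are
        recovered exactly (2x2 linear system, noise-free)."""
        D, K = 0.8e-3, 1.0
        scheme = _two_shell_scheme()
        sig = np.empty(scheme.n_images)
        for i, b in enumerate(scheme.b_values):
            sig[i] = 1000.0 * np.exp(-b * D + b ** 2 * D ** 2 * K / 6.0)
        vol = np.broadcast_to(sig, (2, 2, 2, scheme.n_images)).copy()
        mask = np.ones((2, 2, 2), bool)
        maps = mrh.fit_dki_loglinear(vol, scheme, mask)
        np.testing.assert_allclose(maps.MD[mask], D, rtol=1e-10)
        np.testing.assert_allclose(maps.MK[mask], K, rtol=1e-8)

    def test_monoexponential_gives_zero_kurtosis(self):
        scheme = _two_shell_scheme()
        sig = 500.0 * np.exp(-scheme.b_values * 1e-3)
        vol = np.broadcast_to(sig, (2, 2, 2, scheme.n_images)).copy()
        maps = mrh.fit_dki_loglinear(vol, scheme, np.ones((2, 2, 2), bool))
        np.testing.assert_allclose(maps.MK[np.ones((2, 2, 2), bool)], 0.0,
                                   atol=1e-10)

    def test_single_shell_rejected(self):
        g = _directions30()
        scheme = DiffusionScheme(
            np.r_[0.0, np.full(30, 2000.0)], np.vstack([np.zeros(3), g])
        )
        with pytest.raises(ValueError, match="shells"):
            mrh.fit_dki_loglinear(
                np.ones((2, 2, 2, 31)), scheme, np.ones((2, 2, 2), bool)
            )

    def test_degenerate_negative_d_flagged(self):
        """Identical signals on both shells imply D <= 0: flagged invalid."""
        scheme = _two_shell_scheme()
        sig = np.ones(scheme.n_images)
        vol = np.broadcast_to(sig, (2, 2, 2, scheme.n_images)).copy()
        maps = mrh.fit_dki_loglinear(vol, scheme, np.ones((2, 2, 2), bool))
        assert not maps.valid_mask.any()

    def test_kurtosis_clamping_reported(self):
        """K = 20 signals exceed the ceiling: clamped to 10 and counted."""
        D, K = 0.8e-3, 20.0
        scheme = _two_shell_scheme()
        sig = 1000.0 * np.exp(
            -scheme.b_values * D + scheme.b_values ** 2 * D ** 2 * K / 6.0
        )
        vol = np.broadcast_to(sig, (2, 2, 2, scheme.n_images)).copy()
        mask = np.ones((2, 2, 2), bool)
        maps = mrh.fit_dki_loglinear(vol, scheme, mask)
        assert maps.extras["k_clamped_high"] > 0
        np.testing.assert_allclose(maps.MK[maps.valid_mask], 10.0)


class TestPolynomialBaseline:
    def test_order1_exact_recovery(self, rng):
        X = rng.uniform(0, 2, (200, 5))
        y = 2.0 * X[:, 1] + 3.0
        model = mrh.polynomial_baseline_fit(X, y, order=1)
        expected = np.zeros(5)
        expected[1] = 2.0
        np.testing.assert_allclose(model.linear_weights, expected, atol=1e-10)
        assert abs(model.intercept - 3.0) < 1e-10
        assert model.training_residual < 1e-10

    def test_order2_exact_recovery(self, rng):
        X = rng.uniform(0, 2, (300, 3))
        y = X[:, 0] ** 2
        model = mrh.polynomial_baseline_fit(X, y, order=2)
        pred = model.predict(X)
        np.testing.assert_allclose(pred, y, atol=1e-9)
        assert model.training_residual < 1e-9

    def test_underdetermined_rejected(self, rng):
        X = rng.uniform(0, 1, (5, 67))
        with pytest.raises(ValueError, match="underdetermined"):
            mrh.polynomial_baseline_fit(X, np.ones(5), order=1)

    def test_collinear_design_reported(self, rng):
        X = rng.uniform(0, 1, (100, 3))
        X[:, 2] = X[:, 0] + X[:, 1]
        with pytest.raises(ValueError, match="rank-deficient"):
            mrh.polynomial_baseline_fit(X, X[:, 0], order=1)

    def test_constant_prediction(self):
        model = mrh.contrasts.PolynomialBaseline(
            order=1, n_channels=3, coefficients=np.zeros(3), intercept=4.2,
            feature_names=["x0", "x1", "x2"],
        )
        out = model.predict(np.random.default_rng(0).uniform(size=(10, 3)))
        np.testing.assert_allclose(out, 4.2)

    def test_channel_mismatch_rejected(self, rng):
        X = rng.uniform(0, 1, (50, 4))
        model = mrh.polynomial_baseline_fit(X, X[:, 0], order=1)
        with pytest.raises(ValueError):
            model.predict(rng.uniform(size=(10, 5)))

    def test_label_aware_permutation_invariance(self, rng):
        """Predicting on permuted channels with labels gives identical maps."""
        labels = ["t2w", "mt", "b0", "dwi1"]
        X = rng.uniform(0, 2, (150, 4))
        y = X @ [1.0, -2.0, 0.5, 0.0] + 1.0
        model = mrh.polynomial_baseline_fit(X, y, order=1, channel_labels=labels)
        perm = [2, 0, 3, 1]
        out = model.predict(X[:, perm], channel_labels=[labels[i] for i in perm])
        np.testing.assert_allclose(out, model.predict(X), atol=1e-9)

    def test_linear_phantom_coefficient_recovery(self, linear_spec, linear_phantom):
        """Order-1 fit on a zero-noise linear phantom recovers the generating
        coefficients to machine precision."""
        vol, tgt, mask, _ = linear_phantom
        model = mrh.polynomial_baseline_fit(
            vol.data[mask].astype(float), tgt.data[mask].astype(float), order=1
        )
        true_w = linear_spec.mapping.weights
        err = np.abs(model.linear_weights - true_w).max() / np.abs(true_w).max()
        assert err < 1e-8
        assert abs(model.intercept - linear_spec.mapping.intercept) < 1e-8


def test_scheme_validation():
    with pytest.raises(ValueError):
        DiffusionScheme([0, 1000], np.array([[0, 0, 0], [2, 0, 0]]))
    s = _two_shell_scheme()
    assert s.shells.tolist() == [2000.0, 5000.0]
    assert s.select(2000.0).sum() == 31
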