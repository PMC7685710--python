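"""Information theory: QE bias correction, balanced resampling, synergy /
redundancy, SVM decoding."""

import numpy as np
import pytest

from endosim.infotheory import (
    balanced_mi,
    confusion_matrix_information,
    discretize,
    fit_info_distribution,
    mi_direct,
    pair_co_information,
    plugin_mi,
    radius_pooling_curve,
    svm_decoding_info,
)


def _exact_mi(joint):
    joint = np.asarray(joint, float)
    joint = joint / joint.sum()
    px = joint.sum(1, keepdims=True)
    py = joint.sum(0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = joint * np.log2(joint / (px * py))
    return float(np.nansum(t))


class TestMiDirect:
    def test_independent_data_corrected_to_zero(self, rng):
        x = rng.normal(0, 1, 10_000)
        s = (rng.random(10_000) < 0.5).astype(int)
        assert abs(mi_direct(x, s, rng=rng)) < 0.01

    def test_identity_channel_is_one_bit(self, rng):
        s = np.tile([0, 1], 500)
        assert mi_direct(s.astype(float), s, rng=rng) == pytest.approx(1.0, abs=0.01)

    def test_sampled_joint_matches_closed_form(self, rng):
        # P(r=1|s=0)=0.2, P(r=1|s=1)=0.7, P(s=1)=0.5
        n = 10_000
        s = (rng.random(n) < 0.5).astype(int)
        p1 = np.where(s == 1, 0.7, 0.2)
        r = (rng.random(n) < p1).astype(int)
        joint = np.array([[0.5 * 0.8, 0.5 * 0.2], [0.5 * 0.3, 0.5 * 0.7]])
        mi = mi_direct(r, s, rng=rng, discretized=True)
        assert mi == pytest.approx(_exact_mi(joint), abs=0.02)

    def test_single_state_rejected(self, rng):
        with pytest.raises(ValueError):
            mi_direct(rng.normal(0, 1, 100), np.zeros(100, int), rng=rng)

    def test_correction_reduces_independence_bias(self, rng):
        """On independent data the QE-corrected MI is closer to zero than the
        plug-in estimate, on average over many small fixtures."""
        plug, corr = [], []
        for _ in range(150):
            x = discretize(rng.normal(0, 1, 120))
            s = (rng.random(120) < 0.5).astype(int)
            if len(np.unique(s)) < 2:
                continue
            plug.append(plugin_mi(x, s))
            corr.append(mi_direct(x, s, rng=rng, discretized=True))
        assert np.mean(corr) < np.mean(plug)


class TestBalancedMI:
    def test_state_modulated_response_is_significant(self, rng):
        n = 1200
        s = (rng.random(n) < 0.4).astype(int)
        resp = rng.poisson(np.where(s == 1, 1.0, 0.1)).astype(float)
        est = balanced_mi(resp, s, n_iter=30, n_shuffle=200, rng=rng)
        assert est.significant
        assert est.mi > 0.1

    def test_constant_response_carries_nothing(self, rng):
        s = (rng.random(400) < 0.5).astype(int)
        est = balanced_mi(np.ones(400), s, n_iter=10, n_shuffle=50, rng=rng)
        assert est.mi == 0.0
        assert not est.significant

    def test_type_one_error_rate_near_nominal(self, rng):
        """State-independent responses are called significant ~5% of the time."""
        hits = 0
        n_fix = 120
        for _ in range(n_fix):
            s = (rng.random(220) < 0.5).astype(int)
            if len(np.unique(s)) < 2:
                continue
            resp = rng.poisson(0.5, 220).astype(float)
            est = balanced_mi(resp, s, n_iter=10, n_shuffle=60, rng=rng)
            hits += est.significant
        rate = hits / n_fix
        assert rate < 0.13

    def test_tiny_state_occupancy_flagged_unstable(self, rng):
        s = np.zeros(100, int)
        s[:5] = 1
        with pytest.warns(UserWarning, match="unstable"):
            est = balanced_mi(rng.normal(0, 1, 100), s, n_iter=5,
                              n_shuffle=20, rng=rng)
        assert est.unstable


class TestInfoDistribution:
    def test_noise_free_double_exponential_recovered(self):
        i = np.arange(1, 101, dtype=float)
        y = 0.1 * np.exp(-0.05 * i) + 0.02 * np.exp(-0.005 * i)
        fit = fit_info_distribution(y)
        assert fit.r_squared > 0.999
        pred = fit.a * np.exp(-fit.b * i) + fit.c * np.exp(-fit.d * i)
        assert np.allclose(pred, y, rtol=0.01)
        assert fit.a + fit.c == pytest.approx(y[0] * np.exp(0.0), rel=0.06)

    def test_degenerate_equal_values_flagged(self):
        fit = fit_info_distribution(np.full(20, 0.3))
        assert not fit.converged
        assert abs(fit.b) < 1e-6 and abs(fit.d) < 1e-6

    def test_too_few_rois_rejected(self):
        with pytest.raises(ValueError):
            fit_info_distribution(np.ones(5))


class TestCoInformation:
    def test_copy_channel_is_fully_redundant(self, rng):
        n = 4000
        s = (rng.random(n) < 0.5).astype(int)
        r1 = s + rng.normal(0, 0.2, n)
        delta, cls, _ = pair_co_information(r1, r1.copy(), s, n_perm=100, rng=rng)
        i1 = mi_direct(r1, s, rng=rng)
        assert cls == "redundancy"
        assert delta == pytest.approx(-i1, abs=0.05)

    def test_xor_construction_is_synergistic(self, rng):
        n = 4000
        r1 = (rng.random(n) < 0.5).astype(float)
        r2 = (rng.random(n) < 0.5).astype(float)
        s = (r1.astype(int) ^ r2.astype(int))
        delta, cls, sig = pair_co_information(r1, r2, s, n_perm=100, rng=rng)
        assert cls == "synergy"
        assert delta > 0.8
        assert sig

    def test_matches_bruteforce_enumeration_without_bias_terms(self, rng):
        """Plug-in co-information equals an exhaustive enumeration over the
        empirical joint distribution."""
        n = 600
        s = (rng.random(n) < 0.5).astype(int)
        b1 = (rng.random(n) < np.where(s == 1, 0.7, 0.3)).astype(int)
        b2 = (rng.random(n) < np.where(b1 == 1, 0.6, 0.4)).astype(int)
        # implementation path, no bias correction / no permutation subtraction
        i12 = plugin_mi(b1 * 2 + b2, s)
        i1 = plugin_mi(b1, s)
        i2 = plugin_mi(b2, s)
        delta_impl = i12 - i1 - i2
        # oracle: exhaustive sum over the 2x2x2 empirical joint
        joint = np.zeros((2, 2, 2))
        for si, x1, x2 in zip(s, b1, b2):
            joint[si, x1, x2] += 1
        joint /= joint.sum()
        j12 = joint.reshape(2, 4)
        j1 = joint.sum(axis=2)
        j2 = joint.sum(axis=1)
        delta_ref = _exact_mi(j12) - _exact_mi(j1) - _exact_mi(j2)
        assert delta_impl == pytest.approx(delta_ref, abs=1e-12)


class TestDecoding:
    GRID = {"C": [1.0], "gamma": ["scale"]}

    def test_shuffled_labels_decode_nothing(self, rng):
        X = rng.normal(0, 1, (400, 5))
        s = (rng.random(400) < 0.5).astype(int)
        mi = svm_decoding_info(X, s, n_iter=5, rng=rng, param_grid=self.GRID,
                               cv_folds=5)
        assert mi < 0.1

    def test_separable_clusters_decode_one_bit(self, rng):
        s = (rng.random(300) < 0.5).astype(int)
        X = rng.normal(0, 0.2, (300, 3)) + 3.0 * s[:, None]
        mi = svm_decoding_info(X, s, n_iter=5, rng=rng, param_grid=self.GRID,
                               cv_folds=5)
        assert mi > 0.9

    def test_bounded_by_bayes_optimal_confusion(self, rng):
        # 1D two-Gaussian problem with known Bayes accuracy
        n = 800
        s = (rng.random(n) < 0.5).astype(int)
        mu = 1.0
        X = rng.normal(0, 1, (n, 1)) + mu * (2 * s[:, None] - 1)
        from scipy.stats import norm
        acc = norm.cdf(mu)  # Bayes accuracy for threshold 0
        cm = np.array([[acc, 1 - acc], [1 - acc, acc]]) / 2
        bayes_mi = confusion_matrix_information(cm)
        mi = svm_decoding_info(X, s, n_iter=5, rng=rng, param_grid=self.GRID,
                               cv_folds=5)
        assert mi <= bayes_mi + 0.05

    def test_pooling_curve_flat_when_info_is_central(self, rng):
        n = 600
        s = (rng.random(n) < 0.5).astype(int)
        X = rng.normal(0, 1, (n, 8))
        X[:, :2] += 2.5 * s[:, None]  # informative ROIs at the center
        dist = np.array([10, 20, 200, 210, 220, 230, 240, 245], float)
        curve = radius_pooling_curve(dist, X, s, fov_radius_um=250.0,
                                     n_iter=4, rng=rng, param_grid=self.GRID,
                                     cv_folds=5)
        assert curve[0]["n_rois"] == 2
        assert abs(curve[-1]["mi_bits"] - curve[0]["mi_bits"]) < 0.2

    def test_single_roi_curve_is_constant(self, rng):
        s = (rng.random(300) < 0.5).astype(int)
        X = rng.normal(0, 1, (300, 1)) + 1.5 * s[:, None]
        curve = radius_pooling_curve(np.array([5.0]), X, s, n_iter=3, rng=rng,
                                     param_grid=self.GRID, cv_folds=5)
        assert all(c["n_rois"] == 1 for c in curve)
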