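"""Ground-truth scene generation: geometry, spiking, calcium, fluorescence."""

import numpy as np
import pytest

from endosim.scene import (
    Neuron,
    build_synchronicity,
    calcium_to_fluorescence,
    place_neurons,
    simulate_activity,
    simulate_spikes,
    simulate_state_session,
    spikes_to_calcium,
)


class TestPlacement:
    def test_density_target_reached_in_full_volume(self, rng):
        vol = place_neurons((500, 500, 80), rng=rng)
        # 83,100 cells/mm^3 * 0.02 mm^3 = 1662 cells
        assert vol.n_neurons == 1662
        assert vol.density == pytest.approx(83_100, rel=0.01)

    def test_empty_extent_places_nothing(self, rng):
        assert place_neurons((0, 0, 0), rng=rng).n_neurons == 0

    def test_no_overlap_exhaustive_pair_check(self, rng):
        vol = place_neurons((100, 100, 100), target_density=1e4, rng=rng)
        assert vol.n_neurons == 10
        neurons = vol.neurons
        for i in range(len(neurons)):
            for j in range(i + 1, len(neurons)):
                d = np.linalg.norm(neurons[i].center - neurons[j].center)
                assert d >= neurons[i].radius + neurons[j].radius

    def test_spheres_inside_volume_and_radii_truncated(self, rng):
        vol = place_neurons((200, 200, 80), rng=rng)
        for n in vol.neurons:
            assert n.radius > 1.0
            assert 0 < n.shell_width <= n.radius
            assert np.all(n.center - n.radius >= 0)
            assert np.all(n.center + n.radius <= np.array(vol.extent))

    def test_invalid_extent_rejected(self, rng):
        with pytest.raises(ValueError):
            place_neurons((-1, 10, 10), rng=rng)

    def test_partial_volume_warns_when_budget_exhausted(self, rng):
        with pytest.warns(UserWarning, match="placement budget"):
            vol = place_neurons((60, 60, 30), target_density=3e6,
                                rng=rng, max_attempts_factor=2)
        assert vol.n_neurons < 3e6 * 60 * 60 * 30 * 1e-9

    def test_deterministic_given_seed(self):
        v1 = place_neurons((100, 100, 80), rng=np.random.default_rng(3))
        v2 = place_neurons((100, 100, 80), rng=np.random.default_rng(3))
        assert np.allclose(v1.centers(), v2.centers())

    def test_neuron_invariants(self):
        with pytest.raises(ValueError):
            Neuron(0, np.zeros(3), radius=-1.0, shell_width=0.5)
        with pytest.raises(ValueError):
            Neuron(0, np.zeros(3), radius=5.0, shell_width=6.0)


class TestSynchronicity:
    def test_zero_probability_gives_zero_matrix(self, rng):
        m = build_synchronicity(10, 0.0, rng).matrix
        assert not m.any()

    def test_unit_probability_links_everything(self, rng):
        m = build_synchronicity(5, 1.0, rng).matrix
        assert np.array_equal(m, 1 - np.eye(5, dtype=m.dtype))

    def test_link_fraction_within_binomial_ci(self, rng):
        n = 200
        m = build_synchronicity(n, 0.8, rng).matrix
        n_pairs = n * (n - 1) // 2
        frac = m[np.triu_indices(n, 1)].mean()
        ci = 2.58 * np.sqrt(0.8 * 0.2 / n_pairs)
        assert abs(frac - 0.8) < ci

    def test_invalid_probability_rejected(self, rng):
        with pytest.raises(ValueError):
            build_synchronicity(5, 1.5, rng)


class TestSpiking:
    def test_zero_rate_is_silent(self, rng):
        sync = build_synchronicity(4, 0.8, rng)
        assert not simulate_spikes(sync, 0.0, 100, rng).any()

    def test_mean_rate_matches_within_poisson_ci(self, rng):
        n_frames = 100_000
        sync = build_synchronicity(5, 0.8, rng)
        sp = simulate_spikes(sync, 0.4, n_frames, rng)
        ci = 2.58 * np.sqrt(0.4 / n_frames)
        assert np.all(np.abs(sp.mean(axis=1) - 0.4) < 4 * ci)

    def test_fully_shared_process_gives_correlation_q(self, rng):
        # with link probability 1 the common source is fully shared and the
        # analytic pair correlation equals the common fraction q
        q = 0.3
        sync = build_synchronicity(2, 1.0, rng)
        sp = simulate_spikes(sync, 0.5, 200_000, rng, common_fraction=q)
        r = np.corrcoef(sp)[0, 1]
        assert r == pytest.approx(q, abs=0.02)

    def test_negative_rate_rejected(self, rng):
        sync = build_synchronicity(2, 0.5, rng)
        with pytest.raises(ValueError):
            simulate_spikes(sync, -0.1, 10, rng)


class TestCalcium:
    def test_impulse_response_is_gamma_powers(self):
        s = np.zeros(30)
        s[4] = 1.0
        c = spikes_to_calcium(s, gamma=0.7)
        k = np.arange(26)
        assert np.allclose(c[4:], 0.7**k)
        assert np.allclose(c[:4], 0.0)

    def test_matches_bruteforce_recursion(self, rng):
        s = rng.poisson(0.3, size=(3, 200))
        c = spikes_to_calcium(s, 0.7)
        for i in range(3):
            ref = np.zeros(200)
            ref[0] = s[i, 0]
            for t in range(1, 200):
                ref[t] = 0.7 * ref[t - 1] + s[i, t]
            assert np.allclose(c[i], ref)

    def test_divergent_gamma_rejected(self):
        with pytest.raises(ValueError):
            spikes_to_calcium(np.zeros(5), gamma=1.0)


class TestFluorescence:
    def test_zero_calcium_gives_baseline(self):
        f = calcium_to_fluorescence(np.zeros(10), noise_var=0.0)
        assert np.allclose(f, 0.0)

    def test_printed_parameters_at_unit_calcium(self):
        # amplitude 1500, n = 1, kd = 1: F(1) = 1500 * 1/(1+1) = 750
        f = calcium_to_fluorescence(np.array([1.0]), noise_var=0.0)
        assert f[0] == pytest.approx(750.0)

    def test_saturates_at_amplitude(self):
        f = calcium_to_fluorescence(np.array([1e9]), noise_var=0.0)
        assert f[0] == pytest.approx(1500.0, rel=1e-6)

    def test_noise_free_bounded_by_baseline_and_amplitude(self, rng):
        c = rng.exponential(1.0, 1000)
        f = calcium_to_fluorescence(c, noise_var=0.0)
        assert np.all(f >= 0.0) and np.all(f < 1500.0)


class TestGroundTruthCorrelation:
    def test_mean_pairwise_calcium_correlation_is_calibrated(self, rng):
        """At the default generative parameters the population-average
        pairwise correlation of ground-truth calcium reproduces 0.084."""
        # the single shared common source makes pair correlations co-fluctuate,
        # so the population mean has sampling sd ~0.005 even at 20k frames;
        # the tolerance is 3 sigma of that
        act = simulate_activity(120, n_frames=20_000, rng=rng)
        cm = np.corrcoef(act.calcium)
        iu = np.triu_indices(120, 1)
        assert cm[iu].mean() == pytest.approx(0.084, abs=0.015)

    def test_bit_reproducible_under_fixed_seed(self):
        a1 = simulate_activity(10, 50, rng=np.random.default_rng(5))
        a2 = simulate_activity(10, 50, rng=np.random.default_rng(5))
        assert np.array_equal(a1.spikes, a2.spikes)
        assert np.array_equal(a1.fluorescence, a2.fluorescence)


class TestStateSession:
    def test_empty_states_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_state_session(3, np.array([]), rng=rng)

    def test_state_dependent_rates_match_exact_joint_mi(self, rng):
        """Binarized response MI matches the analytic MI of the exact joint."""
        from endosim.infotheory import plugin_mi

        states = (rng.random(40_000) < 0.5).astype(int)
        act, labels = simulate_state_session(
            1, states, rate_Q=0.1, rate_A=0.8, module_spec=[[0]],
            rng=rng, module_common_fraction=0.0)
        resp = (act.spikes[0] > 0).astype(int)
        # exact joint: P(resp=1 | state) = 1 - exp(-rate)
        p1 = {0: 1 - np.exp(-0.1), 1: 1 - np.exp(-0.8)}
        joint = np.array([[0.5 * (1 - p1[0]), 0.5 * p1[0]],
                          [0.5 * (1 - p1[1]), 0.5 * p1[1]]])
        px = joint.sum(1, keepdims=True)
        py = joint.sum(0, keepdims=True)
        exact = np.nansum(joint * np.log2(joint / (px * py)))
        assert plugin_mi(resp, labels) == pytest.approx(exact, abs=0.02)

    def test_equal_rates_carry_no_information(self, rng):
        from endosim.infotheory import mi_direct

        states = (rng.random(10_000) < 0.5).astype(int)
        act, labels = simulate_state_session(
            1, states, rate_Q=0.5, rate_A=0.5, module_spec=[[0]], rng=rng)
        mi = mi_direct(act.calcium[0], labels, rng=rng)
        assert abs(mi) < 0.01
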