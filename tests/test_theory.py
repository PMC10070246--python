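"""Closed-form timescale theory: rate mapping, spectra, nonlinear gains."""

import numpy as np
import pytest

from multitau import theory


class TestRateMapping:
    def test_rate_sum_identity(self):
        """alpha1 + alpha2 = -ln(p_s)/dt to machine precision."""
        for p_s in (0.5, 0.88, 0.99):
            r = theory.map_discrete_to_rates(p_s, 0.01, 1e-4)
            assert r.alpha1 + r.alpha2 == pytest.approx(-np.log(p_s), rel=1e-12)

    def test_printed_values(self):
        r = theory.map_discrete_to_rates(0.88, 0.01375, 1e-4)
        assert r.alpha1 + r.alpha2 == pytest.approx(0.127833, abs=1e-6)
        g = -np.log(0.88) / (1 - 0.88)
        assert r.beta1 == pytest.approx(0.01375 * g) and r.beta1 == r.beta2

    def test_no_external_drive(self):
        assert theory.map_discrete_to_rates(0.9, 0.01, 0.0).alpha1 == 0.0

    @pytest.mark.parametrize("p_s", [0.0, 1.0])
    def test_bounds_rejected(self, p_s):
        with pytest.raises(ValueError):
            theory.map_discrete_to_rates(p_s, 0.01, 1e-4)


class TestSteadyState:
    def test_arithmetic(self):
        assert theory.steady_state(0.88, (0.99 - 0.88) / 8, 1e-4) == pytest.approx(0.01)

    def test_isolated_limit(self):
        assert theory.steady_state(0.9, 0.0, 1e-4) == pytest.approx(1e-4 / 0.1)

    def test_supercritical_rejected(self):
        with pytest.raises(ValueError, match="branching"):
            theory.steady_state(0.9, 0.02, 1e-4)


class TestTauSelf:
    def test_known_values(self):
        assert theory.tau_self(np.exp(-1.0)) == pytest.approx(1.0)
        assert theory.tau_self(0.88) == pytest.approx(7.8231, abs=1e-3)

    def test_monotone_in_p_s(self):
        ps = np.linspace(0.5, 0.99, 20)
        taus = [theory.tau_self(p) for p in ps]
        assert np.all(np.diff(taus) > 0)


class TestMarkovAC:
    def test_values(self):
        assert theory.markov_ac(0.5, 0) == 1.0
        assert theory.markov_ac(0.5, 2) == 0.25

    def test_matches_isolated_unit_simulation(self):
        """Eq-29 oracle: an isolated two-state unit's AC decays as p_s^t."""
        from multitau import lattice

        cfg = lattice.LatticeConfig(L=24, variant="spatial", p_s=0.8, p_r=0.0,
                                    p_ext=0.02, steps=30_000, seed=11)
        run = lattice.simulate(cfg)
        ac = lattice.unit_autocorrelation(run, max_lag=15)
        np.testing.assert_allclose(ac.values, theory.markov_ac(0.8, np.arange(16)),
                                   atol=0.03)


class TestInteractionTimescales:
    def test_zero_mode_equals_global(self):
        for p_s, p_r in [(0.88, 0.01375), (0.81, 0.02), (0.95, 0.005)]:
            assert theory.tau_int_k(p_s, p_r, 0.0, 0.0) == pytest.approx(
                theory.tau_global(p_s, p_r), rel=1e-12)

    def test_monotone_nonincreasing_in_k(self):
        k = np.linspace(0, np.pi / 2, 30)
        taus = theory.tau_int_k(0.88, 0.012, k, k)
        assert np.all(np.diff(taus) <= 1e-12)

    def test_no_interaction_reduces_to_self(self):
        k1, k2 = theory.mode_grid(20)
        np.testing.assert_allclose(theory.tau_int_k(0.88, 0.0, k1, k2),
                                   theory.tau_self(0.88))

    def test_global_printed_value(self):
        assert theory.tau_global(0.88, 0.11 / 8) == pytest.approx(93.87, abs=0.01)

    def test_global_diverges_towards_criticality(self):
        bps = np.array([0.95, 0.97, 0.99, 0.999])
        taus = [theory.tau_global(0.88, (bp - 0.88) / 8) for bp in bps]
        assert np.all(np.diff(taus) > 0)

    def test_mode_grid_size(self):
        k1, k2 = theory.mode_grid(40)
        assert k1.size == 40 * 40 // 4


class TestSpectrumAndWeights:
    def test_effective_single_mode(self):
        spec = theory.TimescaleSpectrum(
            k1=np.zeros(1), k2=np.zeros(1), tau_int_ms=np.array([42.0]),
            weights=np.array([0.3]), tau_self_ms=5.0, tau_global_ms=42.0)
        assert theory.tau_int_effective(spec) == pytest.approx(42.0)

    def test_effective_equal_weights(self):
        spec = theory.TimescaleSpectrum(
            k1=np.zeros(2), k2=np.zeros(2), tau_int_ms=np.array([10.0, 30.0]),
            weights=np.array([0.5, 0.5]), tau_self_ms=5.0, tau_global_ms=30.0)
        assert theory.tau_int_effective(spec) == pytest.approx(20.0)

    def test_white_field_uniform_weights(self, rng):
        hist = (rng.random((400, 24 * 24)) < 0.3).astype(np.uint8)
        w = theory.mode_weights(hist, 24, subsample=1)
        assert np.all(w >= 0)
        assert w.max() / w.min() < 2.0  # flat spectrum up to sampling noise

    def test_smooth_field_shifts_weight_to_low_k(self, rng):
        from scipy.ndimage import uniform_filter

        base = rng.standard_normal((300, 16, 16))
        smooth = uniform_filter(base, size=(1, 5, 5), mode="wrap")
        w_white = theory.mode_weights(base.reshape(300, -1), 16, subsample=1)
        w_smooth = theory.mode_weights(smooth.reshape(300, -1), 16, subsample=1)
        low = (slice(0, 3), slice(0, 3))
        assert w_smooth[low].sum() > w_white[low].sum()

    def test_ac_analytic_pure_exponential(self):
        t = np.arange(0, 50.0)
        k1, _ = theory.mode_grid(10)
        ac = theory.ac_analytic(0.88, 0.01, 10, np.zeros_like(k1), t)
        np.testing.assert_allclose(ac.values, np.exp(-t / theory.tau_self(0.88)))
        assert ac.values[0] == pytest.approx(1.0)

    def test_ac_analytic_normalised(self):
        t = np.arange(0, 50.0)
        k1, _ = theory.mode_grid(10)
        w = np.full_like(k1, 0.4 / k1.size)
        ac = theory.ac_analytic(0.88, 0.01, 10, w, t)
        assert ac.values[0] == pytest.approx(1.0)


class TestNonlinear:
    def test_small_gain_limit_recovers_linear(self):
        """theta -> 0 with beta' = n*beta/theta reduces to the linear model."""
        p_s, p_r, p_ext, n = 0.88, 0.012, 1e-4, 8
        lin = theory.map_discrete_to_rates(p_s, p_r, p_ext)
        theta = 1e-6
        bare = n * lin.beta1 / theta
        nl = theory.nonlinear_effective_params(p_s, p_ext, bare, bare, theta, 0.0)
        assert nl.tau_self_ms == pytest.approx(theory.tau_self(p_s), rel=1e-3)
        assert nl.tau_global_ms == pytest.approx(theory.tau_global(p_s, p_r), rel=1e-3)

    def test_input_raises_self_timescale_when_condition_holds(self):
        p_s, p_ext = 0.88, 1e-4
        g = -np.log(p_s) / (1 - p_s)
        b1, b2 = 0.05 * g, 0.15 * g  # beta1' < beta2'
        taus = [theory.nonlinear_effective_params(p_s, p_ext, b1, b2, 2.0, I).tau_self_ms
                for I in (0.0, 0.05, 0.1, 0.2)]
        assert np.all(np.diff(taus) > 0)
        nl = theory.nonlinear_effective_params(p_s, p_ext, b1, b2, 2.0, 0.1)
        assert nl.tau_self_increases_with_input

    def test_mean_activity_matches_nonlinear_lattice(self):
        """Self-consistent mean activity vs the multiplicative-rule lattice."""
        from multitau import lattice

        p_s, p_r, p_ext = 0.8, 0.01, 5e-3
        cfg = lattice.LatticeConfig(L=30, variant="spatial", rule="nonlinear",
                                    p_s=p_s, p_r=p_r, p_ext=p_ext, steps=20_000, seed=4)
        run = lattice.simulate(cfg)
        sim_mean = run.history.mean()
        # map the multiplicative rule to the rate form: for k active partners
        # the drive is 1-(1-p_r)^k ~ F with theta/n = -ln(1-p_r)
        g = -np.log(p_s) / (1 - p_s)
        theta = -8 * np.log(1 - p_r)
        nl = theory.nonlinear_effective_params(
            p_s, p_ext, (1 - p_ext) * g, (1 - p_ext) * (1 - p_s) * g, theta, 0.0)
        assert sim_mean == pytest.approx(nl.s_bar, rel=0.25)
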