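"""Binary-unit lattice models: connectivity, update rules, correlations."""

import numpy as np
import pytest

from multitau import lattice, theory


class TestConnectivity:
    def test_moore_neighbourhood_exact(self):
        cfg = lattice.LatticeConfig(L=5, variant="spatial", steps=10)
        adj = lattice.build_connectivity(cfg)
        # unit at (2,2) -> index 12; neighbours are the surrounding 8 cells
        expected = {6, 7, 8, 11, 13, 16, 17, 18}
        assert set(adj[12].tolist()) == expected

    @pytest.mark.parametrize("variant,kw", [
        ("spatial", {}),
        ("dispersed", {"radius": 3}),
        ("random", {}),
        ("two_type", {"p_s": (0.88, 0.976), "p_r": (0.01375, 0.00175)}),
    ])
    def test_in_degree_and_no_self_loops(self, variant, kw):
        cfg = lattice.LatticeConfig(L=12, variant=variant, steps=10, seed=0, **kw)
        adj = lattice.build_connectivity(cfg, np.random.default_rng(0))
        n = cfg.n_units
        assert adj.shape == (n, 8)
        assert not np.any(adj == np.arange(n)[:, None])
        for row in adj:
            assert np.unique(row).size == 8

    def test_dispersed_partners_within_radius(self):
        r, L = 3, 20
        cfg = lattice.LatticeConfig(L=L, variant="dispersed", radius=r, steps=10, seed=1)
        adj = lattice.build_connectivity(cfg, np.random.default_rng(1))
        xs, ys = np.divmod(np.arange(L * L), L)
        for i in range(L * L):
            dx = np.abs(xs[adj[i]] - xs[i])
            dy = np.abs(ys[adj[i]] - ys[i])
            cheb = np.maximum(np.minimum(dx, L - dx), np.minimum(dy, L - dy))
            assert np.all(cheb <= r)

    def test_infeasible_radius_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            lattice.LatticeConfig(L=5, variant="dispersed", radius=3, steps=10)


class TestDynamics:
    def test_all_quiescent_absorbing_without_external_drive(self):
        cfg = lattice.LatticeConfig(L=10, p_s=0.9, p_r=0.01, p_ext=0.0,
                                    steps=200, burn_in=0, seed=0)
        run = lattice.simulate(cfg)
        assert run.history.sum() == 0

    def test_seed_reproducibility(self):
        cfg = lattice.LatticeConfig(L=12, p_s=0.85, p_r=0.01, p_ext=1e-3,
                                    steps=500, seed=42)
        a = lattice.simulate(cfg)
        b = lattice.simulate(cfg)
        np.testing.assert_array_equal(a.history, b.history)

    def test_isolated_unit_transition_frequencies(self, rng):
        """With p_r = 0 the persistence frequency matches p_s + p_ext and
        activation matches p_ext (transition-frequency check on Eq-style
        probabilities)."""
        p_s, p_ext = 0.7, 0.05
        cfg = lattice.LatticeConfig(L=16, p_s=p_s, p_r=0.0, p_ext=p_ext,
                                    steps=4000, burn_in=200, seed=9)
        run = lattice.simulate(cfg)
        h = run.history.astype(bool)
        prev, nxt = h[:-1], h[1:]
        stay = nxt[prev].mean()
        act = nxt[~prev].mean()
        n_act = prev.sum()
        assert stay == pytest.approx(p_s + p_ext, abs=3 * np.sqrt(0.25 / n_act))
        assert act == pytest.approx(p_ext, abs=3 * np.sqrt(p_ext / (~prev).sum()) + 1e-3)

    def test_steady_state_matches_mean_field(self, small_spatial_run):
        run = small_spatial_run
        cfg = run.config
        pred = theory.steady_state(cfg.p_s, cfg.p_r, cfg.p_ext)
        mean = run.history.mean()
        # effective sample count discounted by the global correlation time
        tau_g = theory.tau_global(cfg.p_s, cfg.p_r)
        n_eff = run.history.shape[0] * run.history.shape[1] / (2 * tau_g)
        se = np.sqrt(pred * (1 - pred) / n_eff)
        assert mean == pytest.approx(pred, abs=3 * se + 0.1 * pred)

    def test_nonlinear_activation_probability_at_zero_input(self):
        """With no active partners the multiplicative rule activates with
        p_ext exactly."""
        p_ext = 0.03
        cfg = lattice.LatticeConfig(L=14, rule="nonlinear", p_s=0.6, p_r=0.03,
                                    p_ext=p_ext, steps=3000, burn_in=100, seed=3)
        run = lattice.simulate(cfg)
        h = run.history.astype(bool)
        adj = run.adjacency
        prev, nxt = h[:-1], h[1:]
        k = prev[:, adj].sum(axis=2)
        mask = (~prev) & (k == 0)
        assert nxt[mask].mean() == pytest.approx(p_ext, abs=3 * np.sqrt(p_ext / mask.sum()))

    def test_nonlinear_small_p_r_matches_linear_rates(self):
        """As p_r -> 0 the multiplicative rule reduces to the isolated
        linear unit."""
        cfg = lattice.LatticeConfig(L=14, rule="nonlinear", p_s=0.8, p_r=0.0,
                                    p_ext=0.02, steps=3000, burn_in=100, seed=5)
        run = lattice.simulate(cfg)
        h = run.history.astype(bool)
        stay = h[1:][h[:-1]].mean()
        assert stay == pytest.approx((1 - 0.02) * 0.8 + 0.02, abs=0.02)

    def test_synaptic_filter_relaxation(self):
        """The recurrent-input filter relaxes geometrically to p_r * k with
        rate dt/tau_synapse (solving the linear recursion)."""
        tau, p_r, k = 20.0, 0.05, 4.0
        f = 0.0
        vals = []
        for _ in range(100):
            f = f + (p_r * k - f) / tau
            vals.append(f)
        vals = np.array(vals)
        expected = p_r * k * (1 - (1 - 1 / tau) ** np.arange(1, 101))
        np.testing.assert_allclose(vals, expected, rtol=1e-10)
        # tau = dt: tracks the input in a single step
        assert 0.0 + (p_r * k - 0.0) / 1.0 == pytest.approx(p_r * k)

    def test_probability_clipping_counted(self):
        cfg = lattice.LatticeConfig(L=10, p_s=0.9, p_r=0.1, p_ext=0.5,
                                    steps=100, burn_in=0, seed=0)
        run = lattice.simulate(cfg)
        assert run.clip_count > 0


class TestCorrelationMeasures:
    def test_isolated_units_ac_is_markov_power_law(self):
        cfg = lattice.LatticeConfig(L=24, p_s=0.85, p_r=0.0, p_ext=0.01,
                                    steps=30_000, seed=2)
        run = lattice.simulate(cfg)
        ac = lattice.unit_autocorrelation(run, max_lag=20)
        np.testing.assert_allclose(ac.values, theory.markov_ac(0.85, np.arange(21)),
                                   atol=0.04)

    def test_global_ac_decays_at_global_timescale(self, small_spatial_run):
        run = small_spatial_run
        cfg = run.config
        ac = lattice.global_autocorrelation(run, max_lag=120)
        tau_g = theory.tau_global(cfg.p_s, cfg.p_r)
        # log-linear slope over the decaying section
        t = ac.lags_ms[5:60]
        y = ac.values[5:60]
        good = y > 0.02
        slope = np.polyfit(t[good], np.log(y[good]), 1)[0]
        assert -1.0 / slope == pytest.approx(tau_g, rel=0.35)

    def test_unit_sample_subsampling_consistent(self, small_spatial_run):
        full = lattice.unit_autocorrelation(small_spatial_run, max_lag=30)
        sub = lattice.unit_autocorrelation(small_spatial_run, max_lag=30,
                                           unit_sample=200,
                                           rng=np.random.default_rng(0))
        np.testing.assert_allclose(full.values, sub.values, atol=0.05)
        assert sub.n_windows == 200

    def test_shadow_requires_recurrence(self):
        cfg = lattice.LatticeConfig(L=10, p_r=0.0, steps=100)
        with pytest.raises(ValueError, match="p_r"):
            lattice.shadow_input_autocorrelation(cfg)

    def test_shadow_tracks_slow_interaction_component(self):
        """The shadow-unit (recurrent-input) AC retains most of its lag-1
        value at lags where the self-excitation component has decayed away:
        the slow tail of the unit AC is inherited from the inputs."""
        cfg = lattice.LatticeConfig(L=50, p_s=0.88, p_r=(0.99 - 0.88) / 8,
                                    p_ext=1e-4, steps=100_000, shadow_unit=0)
        ac = lattice.shadow_input_autocorrelation(cfg, np.random.default_rng(3),
                                                  max_lag=60)
        tau_self = theory.tau_self(cfg.p_s)  # ~7.8 ms
        slow_band = ac.values[8:20].mean()
        self_pred = np.exp(-14.0 / tau_self)  # ~0.17: self-component remnant
        assert slow_band > self_pred * ac.values[1]
        assert slow_band > 0.005

    def test_chebyshev_shell_sizes(self):
        for d in (1, 2, 5):
            assert lattice._chebyshev_shell(d, 50).shape[0] == 8 * d

    def test_spatial_cc_decreases_with_distance(self, small_spatial_run):
        ccs = lattice.cc_by_distance(small_spatial_run, distances=(1, 2, 4),
                                     n_pairs=3000, rng=np.random.default_rng(1))
        v = [ccs[d].values[0] for d in (1, 2, 4)]
        assert v[0] > v[1] > v[2] > 0

    def test_random_cc_flat_in_distance(self):
        cfg = lattice.LatticeConfig(L=32, variant="random", p_s=0.88,
                                    p_r=(0.95 - 0.88) / 8, p_ext=1e-3,
                                    steps=15_000, seed=8)
        run = lattice.simulate(cfg)
        ccs = lattice.cc_by_distance(run, distances=(1, 4, 8), n_pairs=3000,
                                     rng=np.random.default_rng(2))
        v = np.array([ccs[d].values[0] for d in (1, 4, 8)])
        assert np.ptp(v) < 0.25 * max(v.mean(), 1e-3) + 0.005

    def test_two_type_node_activity_sums_pairs(self):
        cfg = lattice.LatticeConfig(L=10, variant="two_type",
                                    p_s=(0.8, 0.9), p_r=(0.02, 0.0075),
                                    p_ext=1e-2, steps=500, seed=1)
        run = lattice.simulate(cfg)
        node = run.node_activity()
        assert node.shape == (500, 100)
        assert node.max() <= 2 and node.min() >= 0


class TestCriticalitySlowdown:
    def test_fitted_slow_timescale_increases_with_branching_parameter(self):
        """Closer to criticality (BP -> 1) the slow component of the unit AC
        lengthens (critical slowing down)."""
        from multitau.matching import fit_double_exponential

        taus = []
        for bp in (0.95, 0.97, 0.99):
            cfg = lattice.LatticeConfig(L=40, p_s=0.88, p_r=(bp - 0.88) / 8,
                                        p_ext=1e-3, steps=25_000, seed=21)
            run = lattice.simulate(cfg)
            ac = lattice.unit_autocorrelation(run, max_lag=150)
            taus.append(fit_double_exponential(ac).tau2)
        assert taus[0] < taus[1] < taus[2]
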