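"""Correlation estimators: windowing, lag-dependent means, QC, RF grouping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from multitau import spikecorr
from multitau.types import BinnedCounts, CorrFunction


def eq1_bruteforce(a):
    """Literal loop evaluation of the windowed autocorrelation estimator."""
    a = np.asarray(a, dtype=float)
    n = a.size
    sig2 = a.var(ddof=1)
    out = np.empty(n)
    for j in range(n):
        lead, lag = a[: n - j], a[j:]
        mu1, mu2 = lead.mean(), lag.mean()
        out[j] = np.sum((lead - mu1) * (lag - mu2)) / (sig2 * (n - j))
    return out


def eq8_bruteforce(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    n = a.size
    norm = np.sqrt(a.var(ddof=1) * b.var(ddof=1))
    out = np.empty(n)
    for j in range(n):
        mu_a, mu_b = a[: n - j].mean(), b[j:].mean()
        out[j] = np.sum((a[: n - j] - mu_a) * (b[j:] - mu_b)) / (norm * (n - j))
    return out


class TestAutocorrelation:
    def test_matches_bruteforce_oracle(self, rng):
        w = rng.standard_normal(64)
        ac = spikecorr.autocorrelation(w, bin_ms=2.0)
        np.testing.assert_allclose(ac.values, eq1_bruteforce(w), atol=1e-10)

    @settings(max_examples=25, deadline=None)
    @given(arrays(np.float64, 40, elements=st.floats(-5, 5, allow_nan=False)))
    def test_lag_zero_identity(self, w):
        """AC(0) = (N-1)/N for every non-constant window (algebraic identity)."""
        if np.var(w, ddof=1) <= 1e-12:
            return
        ac = spikecorr.autocorrelation(w)
        assert ac.values[0] == pytest.approx((w.size - 1) / w.size, abs=1e-9)

    def test_white_noise_decorrelated(self, rng):
        n_windows, n = 400, 100
        mat = rng.standard_normal((n_windows, n))
        bc = BinnedCounts(counts=mat, bin_ms=2.0, window_ms=200.0)
        ac = spikecorr.windowed_average_autocorrelation(bc)
        se = 3.0 / np.sqrt(n * n_windows)
        assert np.mean(np.abs(ac.values[1:20])) < 3 * se + 0.02

    def test_constant_window_rejected(self):
        with pytest.raises(ValueError, match="zero variance|constant"):
            spikecorr.autocorrelation(np.ones(20))

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            spikecorr.autocorrelation(np.array([1.0, 2.0]))

    def test_max_lag_truncation(self, rng):
        w = rng.standard_normal(50)
        ac = spikecorr.autocorrelation(w, max_lag_bins=10)
        assert ac.values.size == 11


class TestCrossCorrelation:
    def test_self_at_lag_zero(self, rng):
        w = rng.standard_normal(80)
        cc = spikecorr.cross_correlation(w, w)
        assert cc.values[0] == pytest.approx(79 / 80, abs=1e-10)

    def test_matches_bruteforce_oracle(self, rng):
        a, b = rng.standard_normal(50), rng.standard_normal(50)
        cc = spikecorr.cross_correlation(a, b)
        np.testing.assert_allclose(cc.values, eq8_bruteforce(a, b), atol=1e-10)

    def test_asymmetric_in_lead(self, rng):
        a, b = rng.standard_normal(50), rng.standard_normal(50)
        ab = spikecorr.cross_correlation(a, b).values
        ba = spikecorr.cross_correlation(b, a).values
        assert not np.allclose(ab[1:], ba[1:])

    def test_independent_series_near_zero(self, rng):
        a = rng.standard_normal((300, 100))
        b = rng.standard_normal((300, 100))
        vals = np.mean(
            [spikecorr.cross_correlation(x, y).values for x, y in zip(a, b)], axis=0
        )
        n_per_lag = 100 - np.arange(100)
        assert np.all(np.abs(vals) < 4 / np.sqrt(n_per_lag * 300) + 0.01)

    def test_channel_gap_rule(self, rng):
        """Pairs closer than two channels apart are not analysed."""
        mats = {c: BinnedCounts(rng.poisson(3.0, (10, 30)).astype(float)
                                + rng.standard_normal((10, 30)) * 0.01,
                                bin_ms=2.0, window_ms=60.0) for c in (1, 2, 3)}
        out = spikecorr.channel_cross_correlations(mats, min_channel_gap=2)
        assert (1, 3) in out and (1, 2) not in out and (2, 3) not in out


class TestBinAndPool:
    def _events(self, times, trial=0, cond="a", channel=0, trial_ms=None):
        df = pd.DataFrame({
            "session": "s0", "trial": trial, "channel": channel,
            "time_ms": times, "condition": cond,
        })
        if trial_ms is not None:
            df["trial_ms"] = trial_ms
        return df

    def test_direct_counts(self):
        ev = self._events([1.0, 3.0, 3.0], trial_ms=6.0)
        bc = spikecorr.bin_and_pool(ev, bin_ms=2.0, window_ms=6.0)
        np.testing.assert_array_equal(bc.counts, [[1, 2, 0]])

    def test_long_trial_split_remainder_discarded(self):
        """A 1900 ms trial yields two 700 ms windows; 500 ms is discarded."""
        ev = self._events(np.linspace(0, 1899, 200), trial_ms=1900.0)
        bc = spikecorr.bin_and_pool(ev, bin_ms=2.0, window_ms=700.0)
        assert bc.n_windows == 2
        assert bc.counts.sum() == np.sum(np.linspace(0, 1899, 200) < 1400)

    def test_short_trial_dropped_and_flagged(self):
        ev = pd.concat([
            self._events(np.arange(0, 400, 7.0), trial=0, trial_ms=400.0),
            self._events(np.arange(0, 600, 7.0), trial=1, trial_ms=600.0),
        ])
        bc = spikecorr.bin_and_pool(ev, bin_ms=2.0, window_ms=500.0)
        assert bc.n_windows == 1
        assert [t for t, _ in bc.dropped_trials] == [0]

    def test_epoch_start_offset(self):
        ev = self._events([10.0, 210.0, 399.0], trial_ms=400.0)
        bc = spikecorr.bin_and_pool(ev, bin_ms=2.0, window_ms=200.0, epoch_start_ms=200.0)
        assert bc.n_windows == 1
        assert bc.counts.sum() == 2  # spike at 10 ms falls before the epoch

    def test_channel_selection(self):
        ev = pd.concat([
            self._events([1.0], channel=0, trial_ms=6.0),
            self._events([3.0], channel=5, trial_ms=6.0),
        ])
        bc = spikecorr.bin_and_pool(ev, bin_ms=2.0, window_ms=6.0, channels=[0])
        assert bc.counts.sum() == 1
        with pytest.raises(ValueError, match="empty channel"):
            spikecorr.bin_and_pool(ev, bin_ms=2.0, window_ms=6.0, channels=[])


class TestSubtractConditionMean:
    def test_identical_trials_zero_residual(self):
        bc = BinnedCounts(np.array([[3, 1, 4], [3, 1, 4]]), 2.0, 6.0)
        out = spikecorr.subtract_condition_mean(bc)
        np.testing.assert_allclose(out.counts, 0.0)

    def test_two_trial_arithmetic(self):
        bc = BinnedCounts(np.array([[1, 2], [3, 4]]), 2.0, 4.0)
        out = spikecorr.subtract_condition_mean(bc)
        np.testing.assert_allclose(out.counts, [[-1, -1], [1, 1]])

    def test_conditions_handled_independently(self, rng):
        mat = rng.poisson(5.0, (20, 10)).astype(float)
        cond = np.array(["a"] * 10 + ["b"] * 10, dtype=object)
        bc = BinnedCounts(mat, 2.0, 20.0, condition=cond)
        out = spikecorr.subtract_condition_mean(bc)
        for c in ("a", "b"):
            np.testing.assert_allclose(out.counts[cond == c].mean(axis=0), 0.0, atol=1e-12)

    def test_single_trial_condition_errors(self):
        bc = BinnedCounts(np.ones((1, 4)), 2.0, 8.0)
        with pytest.raises(ValueError, match="fewer than 2"):
            spikecorr.subtract_condition_mean(bc)

    def test_preserves_stationary_lag_structure(self, rng):
        """Mean subtraction leaves the AC of a condition-stationary process
        unchanged in expectation."""
        from multitau import ou
        from multitau.types import OUMixtureParams

        params = OUMixtureParams(tau_ms=[20.0], coeffs=[1.0])
        latent = ou.simulate_ou_mixture(params, 600, 250, 2.0, rng)
        bc = BinnedCounts(latent, 2.0, 500.0)
        ac_raw = spikecorr.windowed_average_autocorrelation(bc, max_lag_bins=30)
        ac_sub = spikecorr.windowed_average_autocorrelation(
            spikecorr.subtract_condition_mean(bc), max_lag_bins=30)
        np.testing.assert_allclose(ac_raw.values, ac_sub.values, atol=0.03)


class TestAveraging:
    def _cf(self, values):
        return CorrFunction(np.arange(len(values)) * 2.0, values)

    def test_identity_on_copies(self):
        c = self._cf([1.0, 0.5, 0.2])
        out = spikecorr.average_correlations([c, c, c])
        np.testing.assert_allclose(out.values, c.values)
        assert out.n_windows == 3

    def test_two_window_mean(self):
        out = spikecorr.average_correlations([self._cf([1, 0]), self._cf([0, 1])])
        np.testing.assert_allclose(out.values, [0.5, 0.5])

    def test_mixed_grid_rejected(self):
        a = CorrFunction(np.array([0.0, 2.0]), np.array([1.0, 0.5]))
        b = CorrFunction(np.array([0.0, 4.0]), np.array([1.0, 0.5]))
        with pytest.raises(ValueError, match="lag grid"):
            spikecorr.average_correlations([a, b])


class TestSessionQC:
    def test_exponential_decay_included(self):
        t = np.arange(0, 100, 2.0)
        ac = CorrFunction(t, 0.5 * np.exp(-t / 50.0))
        assert spikecorr.session_qc(ac)  # AC(20) ~ 0.335 >= 0.01

    def test_small_value_in_early_lags_excluded(self):
        t = np.arange(0, 100, 2.0)
        v = 0.5 * np.exp(-t / 50.0)
        v[t == 16.0] = 0.005
        assert not spikecorr.session_qc(CorrFunction(t, v))

    def test_noise_crossing_threshold_excluded(self, rng):
        t = np.arange(0, 40, 2.0)
        v = np.full(t.size, 0.02)
        v[5] = -0.01  # dips below threshold at lag 10 ms
        assert not spikecorr.session_qc(CorrFunction(t, v))

    def test_late_dip_ignored(self):
        t = np.arange(0, 200, 2.0)
        v = np.full(t.size, 0.05)
        v[t > 20] = -0.5
        assert spikecorr.session_qc(CorrFunction(t, v))


class TestRFDistanceGrouping:
    def _pairs(self, dists, rng):
        rf = pd.DataFrame({
            "channel": np.arange(len(dists) + 1),
            "x_dva": np.concatenate([[0.0], np.asarray(dists, float)]),
            "y_dva": np.zeros(len(dists) + 1),
        })
        cc = {(0, i + 1): CorrFunction(np.array([0.0]), np.array([1.0 / (i + 1)]))
              for i in range(len(dists))}
        return cc, rf

    def test_median_split(self, rng):
        cc, rf = self._pairs([1.0, 2.0, 3.0, 4.0], rng)
        out = spikecorr.group_cc_by_rf_distance(cc, rf)
        assert out["median_distance_dva"] == pytest.approx(2.5)
        assert out["n_short"] == 2 and out["n_long"] == 2
        assert out["short"].values[0] == pytest.approx((1.0 + 0.5) / 2)

    def test_ties_go_to_short_group(self, rng):
        cc, rf = self._pairs([1.0, 2.0, 2.0, 4.0], rng)
        out = spikecorr.group_cc_by_rf_distance(cc, rf)
        assert out["n_short"] == 3 and out["n_long"] == 1

    def test_degenerate_distances_rejected(self, rng):
        cc, rf = self._pairs([2.0, 2.0], rng)
        with pytest.raises(ValueError, match="single RF distance"):
            spikecorr.group_cc_by_rf_distance(cc, rf)
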