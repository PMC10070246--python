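"""Doubly stochastic spike-count generator: OU-mixture rate, gamma counts.

The latent rate fluctuation is a linear mixture of independent
Ornstein-Uhlenbeck processes,

    A(t) = sum_k sqrt(c_k) A_{tau_k}(t),    sum_k c_k = 1,

each component simulated by its exact discretisation — a stationary AR(1)
with coefficient exp(-dt/tau_k) and unit stationary variance — so that the
mixture has unit variance and autocorrelation sum_k c_k exp(-t/tau_k).

Counts in each bin are drawn from a gamma distribution with mean lambda and
variance alpha*lambda, where alpha is the dispersion (variance/mean) of the
count distribution; alpha = 1 recovers Poisson-like dispersion. The latent
fluctuation is rescaled affinely so that the simulated counts match a target
mean and variance: by the law of total variance,

    Var[counts] = alpha * E[lambda] + Var[lambda],

so Var[lambda] = target_variance - alpha * target_mean must be non-negative
(otherwise the requested dispersion is infeasible for those moments).
Negative instantaneous rates produced by the rescaling are clipped to zero
before sampling; the identical rule applies when fitting, so the clipping
bias cancels between data-matched surrogates and model candidates.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.signal import lfilter

from .types import BinnedCounts, DataStats, OUMixtureParams


def simulate_ou_mixture(
    params: OUMixtureParams,
    n_trials: int,
    n_bins: int,
    bin_ms: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance OU-mixture latent traces, shape (n_trials, n_bins).

    Each component starts from its stationary distribution, so every trial is
    a stationary draw (no transient)."""
    mix = np.zeros((n_trials, n_bins))
    for tau, c in zip(params.tau_ms, params.coeffs):
        if c == 0.0:
            continue
        a = np.exp(-bin_ms / tau)
        innov_sd = np.sqrt(1.0 - a * a)
        x = rng.standard_normal((n_trials, n_bins)) * innov_sd
        x[:, 0] = rng.standard_normal(n_trials)  # stationary start, sd 1
        # AR(1): y[i] = a*y[i-1] + x[i]; initial condition folded into x[:,0]
        y = lfilter([1.0], [1.0, -a], x, axis=1)
        mix += np.sqrt(c) * y
    return mix


def sample_counts(
    rates: np.ndarray,
    stats: DataStats,
    alpha: float,
    rng: np.random.Generator,
) -> BinnedCounts:
    """Gamma spike counts whose moments match ``stats`` in expectation.

    ``rates`` is the unit-variance latent fluctuation; it is mapped to
    lambda = mean + sqrt(var - alpha*mean) * rates, clipped at zero, and each
    bin's count is drawn from Gamma(shape=lambda/alpha, scale=alpha).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    rate_var = stats.count_variance - alpha * stats.count_mean
    if rate_var < -1e-9 * max(stats.count_variance, 1.0):
        raise ValueError(
            f"infeasible dispersion: target variance {stats.count_variance:.4g} < "
            f"alpha*mean = {alpha * stats.count_mean:.4g}; the count distribution "
            "cannot be underdispersed below the gamma floor"
        )
    lam = stats.count_mean + np.sqrt(max(rate_var, 0.0)) * rates
    np.clip(lam, 0.0, None, out=lam)
    counts = np.zeros_like(lam)
    pos = lam > 0
    counts[pos] = rng.standard_gamma(lam[pos] / alpha) * alpha
    return BinnedCounts(counts=counts, bin_ms=stats.bin_ms, window_ms=stats.window_ms)


def matched_counts(
    params: OUMixtureParams,
    stats: DataStats,
    rng: np.random.Generator,
) -> np.ndarray:
    """Raw (n_trials, n_bins) matched count array; the allocation-light path
    used inside likelihood-free fitting loops."""
    n_trials, n_bins, bin_ms = stats.n_trials, stats.n_bins, stats.bin_ms
    rate_var = stats.count_variance - params.alpha * stats.count_mean
    if rate_var < -1e-9 * max(stats.count_variance, 1.0):
        raise ValueError("infeasible dispersion for target moments")
    mix = np.zeros((n_trials, n_bins))
    for tau, c in zip(params.tau_ms, params.coeffs):
        if c == 0.0:
            continue
        a = np.exp(-bin_ms / tau)
        x = rng.standard_normal((n_trials, n_bins)) * np.sqrt(1.0 - a * a)
        x[:, 0] = rng.standard_normal(n_trials)
        mix += np.sqrt(c) * lfilter([1.0], [1.0, -a], x, axis=1)
    lam = stats.count_mean + np.sqrt(max(rate_var, 0.0)) * mix
    np.clip(lam, 0.0, None, out=lam)
    counts = np.zeros_like(lam)
    pos = lam > 0
    counts[pos] = rng.standard_gamma(lam[pos] / params.alpha) * params.alpha
    return counts


def generate_matched_dataset(
    params: OUMixtureParams,
    stats: DataStats,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> BinnedCounts:
    """Convenience composition: simulate the latent mixture for
    ``stats.n_trials`` independent trials and sample matched counts."""
    if rng is None:
        rng = np.random.default_rng(seed)
    rates = simulate_ou_mixture(params, stats.n_trials, stats.n_bins, stats.bin_ms, rng)
    return sample_counts(rates, stats, params.alpha, rng)
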