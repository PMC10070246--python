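"""Analytical timescales of the lattice models (mean-field / master equation).

Mapping the discrete-time linear model to a continuous-time two-state rate
model gives non-interaction rates

    alpha_1 = p_ext * g,   alpha_2 = (1 - p_s - p_ext) * g,
    beta_1 = beta_2 = p_r * g,        g = -ln(p_s) / ((1 - p_s) dt),

with the built-in identity alpha_1 + alpha_2 = -ln(p_s)/dt. From these:

* steady-state occupancy  S = p_ext / (1 - (p_s + 8 p_r)),
* self-excitation timescale  tau_self = -dt / ln(p_s) (equivalently the AC
  decay of an isolated two-state Markov unit, AC(t) = p_s^t),
* interaction timescale of the spatial-frequency mode k = (k1, k2):

      tau_int(k) = tau_self / (1 - (n/4) (beta_1/(alpha_1+alpha_2))
                                  [cos k1 + cos k2 + 2 cos k1 cos k2])

  whose k = (0,0) member is the global timescale
  tau_global = -dt (1-p_s) / ((1 - p_s - 8 p_r) ln p_s).

The unit autocorrelation is then a mixture: one exponential at tau_self plus
L^2/4 exponentials at the tau_int(k), weighted by the spatial Fourier
amplitude of the equal-time cross-correlation at mode k. The weighted
average of the tau_int(k) is the effective interaction timescale that
dominates the slow decay. These mean-field expressions are accurate away
from the critical point; near BP = 1 the neglected higher moments matter.

For nonlinear (saturating) interactions with a uniform external input I,
the interaction terms are linearised around the operating point: effective
rates depend on the self-consistent mean activity, and the timescales
become input-dependent (the substrate for attentional modulation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .types import CorrFunction


@dataclass
class ContinuousRateParams:
    alpha1: float
    alpha2: float
    beta1: float
    beta2: float
    n: int = 8
    dt_ms: float = 1.0


@dataclass
class TimescaleSpectrum:
    """Interaction timescales and weights over the spatial-frequency grid
    k_i = 2*pi*m/L, m = 0..L/2-1 (L^2/4 modes)."""

    k1: np.ndarray
    k2: np.ndarray
    tau_int_ms: np.ndarray
    weights: np.ndarray
    tau_self_ms: float
    tau_global_ms: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"k1": self.k1.ravel(), "k2": self.k2.ravel(),
             "tau_ms": self.tau_int_ms.ravel(), "weight": self.weights.ravel()}
        )


@dataclass
class NonlinearParams:
    theta: float
    input_I: float
    beta1_bare: float
    beta2_bare: float
    alpha1_eff: float
    alpha2_eff: float
    beta_eff: float
    s_bar: float
    tau_self_ms: float
    tau_global_ms: float
    tau_self_increases_with_input: bool
    tau_global_increases_with_input: bool


def map_discrete_to_rates(p_s: float, p_r: float, p_ext: float, dt_ms: float = 1.0,
                          n: int = 8) -> ContinuousRateParams:
    """Exact printed mapping from discrete transition probabilities to
    continuous rates; alpha1 + alpha2 = -ln(p_s)/dt by construction."""
    if not 0.0 < p_s < 1.0:
        raise ValueError("p_s must lie strictly between 0 and 1")
    g = -np.log(p_s) / ((1.0 - p_s) * dt_ms)
    return ContinuousRateParams(
        alpha1=p_ext * g,
        alpha2=(1.0 - p_s - p_ext) * g,
        beta1=p_r * g,
        beta2=p_r * g,
        n=n,
        dt_ms=dt_ms,
    )


def steady_state(p_s: float, p_r: float, p_ext: float, n: int = 8) -> float:
    """Mean-field stationary occupancy; diverges as BP -> 1."""
    bp = p_s + n * p_r
    if bp >= 1.0:
        raise ValueError("branching parameter >= 1: activity diverges")
    return p_ext / (1.0 - bp)


def tau_self(p_s: float, dt_ms: float = 1.0) -> float:
    """Self-excitation timescale -dt/ln(p_s)."""
    if not 0.0 < p_s < 1.0:
        raise ValueError("p_s must lie strictly between 0 and 1")
    return -dt_ms / np.log(p_s)


def markov_ac(p_s: float, t) -> np.ndarray:
    """AC of the isolated two-state Markov unit at integer lag t: p_s^t."""
    t = np.asarray(t)
    if np.any(t < 0):
        raise ValueError("lags must be non-negative")
    return np.asarray(p_s, dtype=float) ** t


def tau_int_k(p_s: float, p_r: float, k1, k2, dt_ms: float = 1.0, n: int = 8) -> np.ndarray:
    """Interaction timescale of mode (k1, k2).

    Implements the form that reduces exactly to the global timescale at
    k = (0,0): the geometric factor is (n/4) beta1/(alpha1+alpha2)
    [cos k1 + cos k2 + 2 cos k1 cos k2] = 2 p_r/(1-p_s) [...] for n = 8.
    """
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    ts = tau_self(p_s, dt_ms)
    geom = np.cos(k1) + np.cos(k2) + 2.0 * np.cos(k1) * np.cos(k2)
    denom = 1.0 - (n / 4.0) * (p_r / (1.0 - p_s)) * geom
    if np.any(denom <= 0):
        raise ValueError("non-positive denominator: mode beyond validity (BP >= 1 at k=0?)")
    return ts / denom


def tau_global(p_s: float, p_r: float, dt_ms: float = 1.0, n: int = 8) -> float:
    """Largest (zero-mode) interaction timescale
    -dt (1-p_s) / ((1 - p_s - n p_r) ln p_s)."""
    bp = p_s + n * p_r
    if bp >= 1.0:
        raise ValueError("branching parameter >= 1")
    return -dt_ms * (1.0 - p_s) / ((1.0 - bp) * np.log(p_s))


def mode_grid(L: int) -> Tuple[np.ndarray, np.ndarray]:
    """Spatial-frequency grid k_i = 2 pi m / L, m = 0..L/2-1 (L^2/4 modes)."""
    k = 2.0 * np.pi * np.arange(L // 2) / L
    return np.meshgrid(k, k, indexing="ij")


def mode_weights(history: np.ndarray, L: int, subsample: int = 5) -> np.ndarray:
    """Relative cross-correlation amplitude per spatial-frequency mode,
    estimated from simulated activity.

    ``history`` is (T, L*L) binary activity; the equal-time spatial power
    spectrum |F(k)|^2 of the mean-removed field, averaged over (subsampled)
    time steps and restricted to the mode grid, is returned normalised to
    sum 1. Spatially white activity gives uniform weights; longer-range
    covariance shifts mass to low k."""
    x = history[::subsample].astype(np.float64)
    x -= x.mean(axis=0, keepdims=True)
    fields = x.reshape(-1, L, L)
    spec = np.abs(np.fft.fft2(fields, axes=(1, 2))) ** 2
    spec = spec.mean(axis=0)[: L // 2, : L // 2]
    total = spec.sum()
    if total <= 0:
        raise ValueError("zero spatial covariance: cannot form mode weights")
    return spec / total


def timescale_spectrum(
    p_s: float,
    p_r: float,
    L: int,
    weights: Optional[np.ndarray] = None,
    dt_ms: float = 1.0,
    n: int = 8,
) -> TimescaleSpectrum:
    """Full interaction-timescale spectrum; uniform weights if none given."""
    k1, k2 = mode_grid(L)
    taus = tau_int_k(p_s, p_r, k1, k2, dt_ms, n)
    if weights is None:
        weights = np.full_like(taus, 1.0 / taus.size)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != taus.shape:
        raise ValueError("weights must match the mode grid")
    return TimescaleSpectrum(
        k1=k1, k2=k2, tau_int_ms=taus, weights=weights,
        tau_self_ms=tau_self(p_s, dt_ms), tau_global_ms=tau_global(p_s, p_r, dt_ms, n),
    )


def tau_int_effective(spectrum: TimescaleSpectrum) -> float:
    """Weight-normalised average of the interaction timescales; the single
    effective slow timescale approximating the interaction component."""
    w = spectrum.weights
    total = w.sum()
    if spectrum.tau_int_ms.size == 0 or total <= 0:
        raise ValueError("empty spectrum or non-positive weights")
    return float((w * spectrum.tau_int_ms).sum() / total)


def ac_analytic(
    p_s: float,
    p_r: float,
    L: int,
    weights: np.ndarray,
    t_ms: np.ndarray,
    interaction_fraction: Optional[float] = None,
    dt_ms: float = 1.0,
) -> CorrFunction:
    """Analytical unit autocorrelation: exp(-t/tau_self) plus the weighted
    interaction exponentials, normalised to AC(0) = 1.

    ``weights`` are relative mode amplitudes (they are renormalised to the
    ``interaction_fraction`` of total variance; if not given, the weights
    are taken as absolute amplitudes and the self component carries the
    remainder 1 - sum(weights))."""
    spec = timescale_spectrum(p_s, p_r, L, weights=None, dt_ms=dt_ms)
    w = np.asarray(weights, dtype=float)
    if w.shape != spec.tau_int_ms.shape:
        raise ValueError("weights must match the mode grid")
    if interaction_fraction is not None:
        if not 0.0 <= interaction_fraction < 1.0:
            raise ValueError("interaction_fraction must be in [0, 1)")
        w = w / w.sum() * interaction_fraction
    if w.sum() > 1.0 + 1e-9:
        raise ValueError("interaction weights exceed total variance")
    a_self = 1.0 - w.sum()
    t = np.asarray(t_ms, dtype=float)
    vals = a_self * np.exp(-t / spec.tau_self_ms)
    vals = vals + np.exp(-t[:, None] / spec.tau_int_ms.ravel()[None, :]) @ w.ravel()
    return CorrFunction(lags_ms=t, values=vals, kind="auto", n_windows=0, bin_ms=dt_ms)


def _activation(theta: float, n: int, s_sum):
    return 1.0 - np.exp(-(theta / n) * np.asarray(s_sum, dtype=float))


def nonlinear_effective_params(
    p_s: float,
    p_ext: float,
    beta1_bare: float,
    beta2_bare: float,
    theta: float,
    input_I: float,
    dt_ms: float = 1.0,
    n: int = 8,
    damping: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> NonlinearParams:
    """Input-dependent effective rates and timescales for the saturating
    interaction F(x) = 1 - exp(-theta x / n) with uniform input current I.

    The mean activity solves the self-consistent fixed point of the full
    nonlinear mean-field rates (damped iteration); the interaction terms are
    then linearised around it, giving effective alpha/beta and

        tau_self = 1 / (alpha1_eff + alpha2_eff),
        tau_global = tau_self / (1 - n beta / (alpha1_eff + alpha2_eff)).

    Also reports the sign conditions under which each timescale grows with
    the input: tau_self when beta1' < beta2'; tau_global when additionally
    -|beta1' - beta2'| S + beta1' < 0.
    """
    base = map_discrete_to_rates(p_s, 0.0, p_ext, dt_ms, n)
    a1, a2 = base.alpha1, base.alpha2

    def F(s_bar):
        return 1.0 - np.exp(-theta * s_bar - input_I)

    s = min(max(a1 / (a1 + a2), 1e-9), 0.5)
    for _ in range(max_iter):
        f = F(s)
        on = a1 + beta1_bare * f
        off = a2 - beta2_bare * f
        if on + off <= 0:
            raise RuntimeError("degenerate rates during fixed-point iteration")
        s_new = on / (on + off)
        if abs(s_new - s) < tol:
            s = s_new
            break
        s = (1.0 - damping) * s + damping * s_new
    else:
        raise RuntimeError("fixed-point iteration for mean activity did not converge")

    Fval = F(s)
    Fprime = (theta / n) * np.exp(-theta * s - input_I)  # dF/d(sum S) at operating point
    F0 = Fval - n * s * Fprime
    beta_eff = beta1_bare * Fprime
    alpha1_eff = a1 + beta1_bare * F0
    alpha2_eff = a2 - beta2_bare * F0
    rate_sum = alpha1_eff + alpha2_eff
    if rate_sum <= 0:
        raise RuntimeError("non-positive effective rate sum")
    t_self = 1.0 / rate_sum
    denom = 1.0 - n * beta_eff / rate_sum
    if denom <= 0:
        raise ValueError("effective branching parameter >= 1")
    diff = beta1_bare - beta2_bare
    return NonlinearParams(
        theta=theta,
        input_I=input_I,
        beta1_bare=beta1_bare,
        beta2_bare=beta2_bare,
        alpha1_eff=alpha1_eff,
        alpha2_eff=alpha2_eff,
        beta_eff=beta_eff,
        s_bar=float(s),
        tau_self_ms=float(t_self),
        tau_global_ms=float(t_self / denom),
        tau_self_increases_with_input=bool(diff < 0),
        tau_global_increases_with_input=bool(diff < 0 and (-abs(diff) * s + beta1_bare) < 0),
    )
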