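"""Shared containers for correlation functions, binned counts and model parameters.

All times are in milliseconds unless stated otherwise. Correlation functions
carry their lag grid and provenance (number of windows averaged, bin size) so
that downstream fitting can reproduce the exact estimator applied to the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass
class CorrFunction:
    """A lagged auto- or cross-correlation estimate.

    Attributes
    ----------
    lags_ms : array of non-negative lags in ms (lag grid equals the bin grid).
    values : correlation value per lag.
    kind : ``"auto"`` or ``"cross"``.
    n_windows : number of windows averaged into this estimate.
    bin_ms : bin size of the underlying count series.
    zero_lag_included : whether lag 0 is present in ``lags_ms``.
    condition : optional behavioural-condition label.
    """

    lags_ms: np.ndarray
    values: np.ndarray
    kind: str = "auto"
    n_windows: int = 1
    bin_ms: float = 2.0
    zero_lag_included: bool = True
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        self.lags_ms = np.asarray(self.lags_ms, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags_ms.shape != self.values.shape:
            raise ValueError("lags_ms and values must have the same shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("correlation values must be finite")

    def restrict(self, t_max_ms: float, excluded_lags_ms: Sequence[float] = ()) -> "CorrFunction":
        """Return a copy restricted to lags <= t_max_ms, dropping excluded lags."""
        keep = self.lags_ms <= t_max_ms + 1e-9
        for t in excluded_lags_ms:
            keep &= ~np.isclose(self.lags_ms, t)
        return CorrFunction(
            lags_ms=self.lags_ms[keep],
            values=self.values[keep],
            kind=self.kind,
            n_windows=self.n_windows,
            bin_ms=self.bin_ms,
            zero_lag_included=bool(keep[0]) and self.zero_lag_included,
            condition=self.condition,
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "lag_ms": self.lags_ms,
                "value": self.values,
                "kind": self.kind,
                "condition": self.condition,
                "n_windows": self.n_windows,
            }
        )


@dataclass
class BinnedCounts:
    """Windowed spike counts: one row per trial-window, one column per lag bin.

    ``counts`` may be integer (raw counts) or real valued (after mean
    subtraction). All windows have the same length; partial windows are
    discarded at construction time.
    """

    counts: np.ndarray  # (n_windows, n_bins)
    bin_ms: float
    window_ms: float
    condition: np.ndarray = None  # label per window
    trial_id: np.ndarray = None  # originating trial per window
    dropped_trials: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (windows x bins)")
        n = self.counts.shape[0]
        if self.condition is None:
            self.condition = np.array(["all"] * n, dtype=object)
        else:
            self.condition = np.asarray(self.condition, dtype=object)
        if self.trial_id is None:
            self.trial_id = np.arange(n)
        else:
            self.trial_id = np.asarray(self.trial_id)

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


@dataclass
class DataStats:
    """Summary statistics a generative model must match: trial geometry and
    the first two moments of the binned spike counts."""

    n_trials: int
    window_ms: float
    bin_ms: float
    count_mean: float
    count_variance: float

    def __post_init__(self) -> None:
        if self.count_variance < 0:
            raise ValueError("count_variance must be non-negative")
        if self.window_ms <= 0 or self.bin_ms <= 0:
            raise ValueError("window_ms and bin_ms must be positive")

    @property
    def n_bins(self) -> int:
        return int(round(self.window_ms / self.bin_ms))

    @classmethod
    def from_counts(cls, counts: BinnedCounts) -> "DataStats":
        return cls(
            n_trials=counts.n_windows,
            window_ms=counts.window_ms,
            bin_ms=counts.bin_ms,
            count_mean=float(np.mean(counts.counts)),
            count_variance=float(np.var(counts.counts)),
        )


@dataclass
class OUMixtureParams:
    """Parameters of the doubly stochastic generative model: a linear mixture
    of Ornstein-Uhlenbeck processes driving gamma-distributed spike counts.

    ``tau_ms`` are the mixture timescales (sorted ascending for
    identifiability), ``coeffs`` the mixture weights (sum to 1), ``alpha`` the
    count dispersion (variance/mean ratio; 1 = Poisson).
    """

    tau_ms: np.ndarray
    coeffs: np.ndarray
    alpha: float = 1.0

    def __post_init__(self) -> None:
        tau = np.atleast_1d(np.asarray(self.tau_ms, dtype=float))
        c = np.atleast_1d(np.asarray(self.coeffs, dtype=float))
        if tau.shape != c.shape:
            raise ValueError("tau_ms and coeffs must have the same length")
        if not (1 <= tau.size <= 3):
            raise ValueError("between 1 and 3 timescales supported")
        if np.any(~np.isfinite(tau)) or np.any(tau <= 0):
            raise ValueError("timescales must be positive and finite")
        if np.any(c < -1e-12) or abs(c.sum() - 1.0) > 1e-8:
            raise ValueError("coefficients must be in [0,1] and sum to 1")
        if not np.isfinite(self.alpha) or self.alpha <= 0:
            raise ValueError("alpha must be positive")
        order = np.argsort(tau)
        self.tau_ms = tau[order]
        self.coeffs = np.clip(c[order], 0.0, 1.0)

    @property
    def n_timescales(self) -> int:
        return self.tau_ms.size

    def latent_autocorrelation(self, lags_ms: np.ndarray) -> np.ndarray:
        """Closed-form AC of the latent rate: sum_k c_k exp(-t/tau_k)."""
        lags = np.asarray(lags_ms, dtype=float)[:, None]
        return (self.coeffs[None, :] * np.exp(-lags / self.tau_ms[None, :])).sum(axis=1)


@dataclass
class DoubleExpFit:
    """Result of fitting AC(t) = c1 exp(-t/tau1) + (1-c1) exp(-t/tau2)."""

    tau1: float
    tau2: float
    c1: float
    residual: float
    t_max_ms: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.tau1 > self.tau2:
            self.tau1, self.tau2 = self.tau2, self.tau1
            self.c1 = 1.0 - self.c1

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.c1 * np.exp(-t / self.tau1) + (1 - self.c1) * np.exp(-t / self.tau2)
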