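"""Synthetic columnar-recording sessions with known ground truth.

Emulates the structure of 16-channel laminar-array recordings: per-trial
spike events on overlapping channels whose receptive-field (RF) centers
drift laterally channel-by-channel, with attention-condition labels and
condition-dependent two-timescale latent dynamics. Two backends:

* ``ou`` — every channel reads the *same* trial-specific OU-mixture latent
  (scaled by a per-channel gain), so cross-correlations are flat in RF
  distance by construction; counts are gamma-Poisson with dispersion alpha
  (alpha = 1 is exactly Poisson).
* ``lattice`` — channels read out the summed activity of small lattice
  patches displaced according to the RF drift, so cross-correlations decay
  with channel distance by construction.

Every generated session ships with a manifest holding the full ground
truth; downstream recovery tests read truth only from the manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from . import ou
from .lattice import LatticeConfig, simulate
from .types import OUMixtureParams

DEFAULT_CONDITIONS: Dict[str, Dict] = {
    # condition-dependent two-timescale ground truth; the attend-in slow
    # timescale sits ~20% above attend-away, the experimentally observed
    # effect size
    "attend_away": {"tau_ms": (5.0, 115.0), "coeffs": (0.4, 0.6), "alpha": 1.0,
                    "rate_mean": 0.12, "rate_var": 0.18},
    "attend_in_covert": {"tau_ms": (5.0, 138.0), "coeffs": (0.4, 0.6), "alpha": 1.0,
                         "rate_mean": 0.12, "rate_var": 0.18},
    "attend_in_overt": {"tau_ms": (5.0, 138.0), "coeffs": (0.4, 0.6), "alpha": 1.0,
                        "rate_mean": 0.12, "rate_var": 0.18},
}


@dataclass
class SessionSpec:
    """Recipe for one synthetic session.

    ``conditions`` maps condition label -> ground truth: for the ``ou``
    backend (tau_ms, coeffs, alpha, rate_mean, rate_var) with rate moments
    per 2 ms bin per channel; for the ``lattice`` backend (p_s, p_r, p_ext).
    ``rf_drift_dva`` is the lateral RF displacement per channel step in
    degrees of visual angle."""

    session_id: str = "synth-000"
    n_trials: int = 100
    trial_ms: float = 500.0
    n_channels: int = 16
    bin_ms: float = 2.0
    backend: str = "ou"
    conditions: Dict[str, Dict] = field(default_factory=lambda: dict(DEFAULT_CONDITIONS))
    rf_drift_dva: float = 0.3
    rf_jitter_dva: float = 0.05
    gain_spread: float = 0.2
    lattice_L: int = 40
    lattice_patch: int = 3
    lattice_channel_step: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in ("ou", "lattice"):
            raise ValueError("backend must be 'ou' or 'lattice'")
        if not self.conditions:
            raise ValueError("at least one condition required")


def _integer_counts(lam: np.ndarray, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Integer spike counts with variance/mean ratio alpha >= 1: Poisson for
    alpha = 1, gamma-Poisson (negative-binomial) mixture otherwise."""
    lam = np.clip(lam, 0.0, None)
    if alpha <= 1.0 + 1e-9:
        return rng.poisson(lam)
    mix = np.zeros_like(lam)
    pos = lam > 0
    mix[pos] = rng.gamma(shape=lam[pos] / (alpha - 1.0), scale=alpha - 1.0)
    return rng.poisson(mix)


def _counts_to_events(counts: np.ndarray, bin_ms: float, rng: np.random.Generator) -> np.ndarray:
    """Spike times (ms) for one trial-channel count vector: uniform within
    each bin (only counts matter downstream)."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    bins = np.repeat(np.arange(counts.size), counts)
    return (bins + rng.random(total)) * bin_ms


def _rf_map(spec: SessionSpec, rng: np.random.Generator) -> pd.DataFrame:
    jit = rng.normal(0.0, spec.rf_jitter_dva, size=(spec.n_channels, 2))
    x = 2.0 + spec.rf_drift_dva * np.arange(spec.n_channels) + jit[:, 0]
    y = -3.0 + jit[:, 1]
    return pd.DataFrame({"channel": np.arange(spec.n_channels), "x_dva": x, "y_dva": y})


def _ou_condition_counts(
    spec: SessionSpec, truth: Dict, gains: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """(n_trials, n_channels, n_bins) integer counts from one shared latent
    per trial."""
    n_bins = int(round(spec.trial_ms / spec.bin_ms))
    params = OUMixtureParams(tau_ms=np.asarray(truth["tau_ms"], dtype=float),
                             coeffs=np.asarray(truth["coeffs"], dtype=float),
                             alpha=truth.get("alpha", 1.0))
    latent = ou.simulate_ou_mixture(params, spec.n_trials, n_bins, spec.bin_ms, rng)
    rate_mean, rate_var = truth["rate_mean"], truth["rate_var"]
    alpha = truth.get("alpha", 1.0)
    if rate_var <= alpha * rate_mean:
        raise ValueError(
            "infeasible rates: rate_var must exceed alpha*rate_mean (the count "
            "floor of a doubly stochastic process)")
    lam_sd = np.sqrt(rate_var - alpha * rate_mean)
    lam = rate_mean * gains[None, :, None] + lam_sd * gains[None, :, None] * latent[:, None, :]
    return _integer_counts(lam, alpha, rng)


def _lattice_condition_counts(
    spec: SessionSpec, truth: Dict, rng: np.random.Generator
) -> np.ndarray:
    """(n_trials, n_channels, n_bins) counts read from lattice patches at
    channel-specific lateral offsets."""
    n_bins = int(round(spec.trial_ms / spec.bin_ms))
    steps_per_bin = max(int(round(spec.bin_ms / 1.0)), 1)
    total_steps = spec.n_trials * n_bins * steps_per_bin
    cfg = LatticeConfig(L=spec.lattice_L, variant="spatial", rule="linear",
                        p_s=truth["p_s"], p_r=truth["p_r"],
                        p_ext=truth.get("p_ext", 1e-4), steps=total_steps)
    run = simulate(cfg, rng)
    L, half = spec.lattice_L, spec.lattice_patch // 2
    hist = run.history.reshape(spec.n_trials, n_bins, steps_per_bin, L, L)
    counts = np.empty((spec.n_trials, spec.n_channels, n_bins), dtype=np.int64)
    y0 = L // 2
    for c in range(spec.n_channels):
        x0 = (2 + c * spec.lattice_channel_step) % L
        xs = [(x0 + dx) % L for dx in range(-half, half + 1)]
        ys = [(y0 + dy) % L for dy in range(-half, half + 1)]
        patch = hist[:, :, :, xs][:, :, :, :, ys]
        counts[:, c, :] = patch.sum(axis=(2, 3, 4))
    return counts


def make_session(spec: SessionSpec) -> Tuple[pd.DataFrame, pd.DataFrame, Dict]:
    """Build one session: (spike-event table, RF map, ground-truth manifest).

    The event table has columns (session, trial, channel, time_ms,
    condition, trial_ms); trials are numbered consecutively across
    conditions."""
    rng = np.random.default_rng(spec.seed)
    rf = _rf_map(spec, rng)
    gains = np.exp(rng.normal(0.0, spec.gain_spread, size=spec.n_channels))
    gains /= gains.mean()

    frames = []
    trial_offset = 0
    for cond in sorted(spec.conditions):
        truth = spec.conditions[cond]
        if spec.backend == "ou":
            counts = _ou_condition_counts(spec, truth, gains, rng)
        else:
            counts = _lattice_condition_counts(spec, truth, rng)
        for tr in range(spec.n_trials):
            for ch in range(spec.n_channels):
                times = _counts_to_events(counts[tr, ch], spec.bin_ms, rng)
                if times.size == 0:
                    continue
                frames.append(pd.DataFrame({
                    "session": spec.session_id,
                    "trial": trial_offset + tr,
                    "channel": ch,
                    "time_ms": times,
                    "condition": cond,
                    "trial_ms": spec.trial_ms,
                }))
        trial_offset += spec.n_trials
    events = (pd.concat(frames, ignore_index=True)
              if frames else pd.DataFrame(columns=["session", "trial", "channel",
                                                   "time_ms", "condition", "trial_ms"]))
    manifest = {
        "session_id": spec.session_id,
        "backend": spec.backend,
        "n_trials_per_condition": spec.n_trials,
        "trial_ms": spec.trial_ms,
        "n_channels": spec.n_channels,
        "bin_ms": spec.bin_ms,
        "seed": spec.seed,
        "channel_gains": gains.tolist(),
        "conditions": {c: dict(t) for c, t in spec.conditions.items()},
        "rf_drift_dva": spec.rf_drift_dva,
    }
    return events, rf, manifest


def make_fixture_suite(seed: int = 0) -> Dict[str, Tuple[pd.DataFrame, pd.DataFrame, Dict]]:
    """Tiny deterministic sessions (4 channels, 50 trials, 500 ms) for unit
    tests; regenerable from the seed, loadable by the correlation reader."""
    out = {}
    for i, backend in enumerate(("ou", "lattice")):
        conds = ({"attend_away": {"tau_ms": (5.0, 80.0), "coeffs": (0.5, 0.5), "alpha": 1.0,
                                  "rate_mean": 0.3, "rate_var": 0.5},
                  "attend_in_covert": {"tau_ms": (5.0, 100.0), "coeffs": (0.5, 0.5), "alpha": 1.0,
                                       "rate_mean": 0.3, "rate_var": 0.5}}
                 if backend == "ou" else
                 {"attend_away": {"p_s": 0.85, "p_r": 0.0125, "p_ext": 1e-3},
                  "attend_in_covert": {"p_s": 0.85, "p_r": 0.0155, "p_ext": 1e-3}})
        spec = SessionSpec(session_id=f"fixture-{backend}", n_trials=50, trial_ms=500.0,
                           n_channels=4, backend=backend, conditions=conds,
                           lattice_L=24, seed=seed + i)
        out[backend] = make_session(spec)
    return out
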