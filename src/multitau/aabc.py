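"""Adaptive Approximate Bayesian Computation for timescale inference.

Fits the OU-mixture generative model to an observed spike-count
autocorrelation without a likelihood: candidate parameters are accepted when
the autocorrelation of a surrogate dataset — generated with the same trial
count, window length, count mean and variance as the data, and summarised
with the *identical* windowed estimator — lies within a shrinking error
threshold of the data autocorrelation. Because data and surrogates share the
finite-window statistical bias, the fitted timescales are unbiased estimates
of the underlying process timescales even though the raw autocorrelation is
biased low.

The sampler is a population Monte Carlo ABC (ABC-PMC): iteration 1 draws
from the uniform prior; later iterations resample previously accepted
particles in proportion to their importance weights, perturb them with a
Gaussian kernel whose covariance is twice the weighted sample covariance,
truncate to the prior box, and re-weight with the standard importance
formula. The error threshold is updated each iteration to the first quartile
of the accepted distances; the run stops when the acceptance rate falls
below ``accR_stop``.

Distance between autocorrelations (lags t_0..t_m on the bin grid):

    d = (1/m) * sum_{j=0}^{m} (AC_data(t_j) - AC_synth(t_j))^2

i.e. the sum over the m+1 included lags divided by m. Individual lags (e.g.
the zero lag, or an early lag contaminated by refractoriness) can be
excluded; m then counts the included lags minus one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sstats

from . import ou
from .spikecorr import _windowed_correlation
from .types import CorrFunction, DataStats, OUMixtureParams

logger = logging.getLogger(__name__)

#: Uniform prior boxes per model. M1: single timescale; M2: two timescales
#: (tau1 the fast one by prior range); M3: three timescales (exposed, not
#: default). Weights of M3 are constrained to the simplex c1 + c2 <= 1.
MODEL_PRIORS: Dict[str, Dict[str, Tuple[float, float]]] = {
    "M1": {"tau": (0.0, 400.0), "alpha": (0.7, 1.3)},
    "M2": {"tau1": (0.0, 60.0), "tau2": (0.0, 400.0), "c1": (0.0, 1.0), "alpha": (0.7, 1.3)},
    "M3": {
        "tau1": (0.0, 60.0),
        "tau2": (0.0, 400.0),
        "tau3": (0.0, 400.0),
        "c1": (0.0, 1.0),
        "c2": (0.0, 1.0),
        "alpha": (0.7, 1.3),
    },
}


class ABCError(RuntimeError):
    pass


@dataclass
class ABCConfig:
    """Sampler configuration. Defaults follow the reference analysis
    (eps0 = 0.1, 100 particles, accR_stop = 7e-4, fit lags up to 100 ms);
    ``max_iterations`` provides a hard cap for scaled-down runs."""

    eps0: float = 0.1
    samples_per_iter: int = 100
    accR_stop: float = 0.0007
    t_max_ms: float = 100.0
    excluded_lags_ms: Tuple[float, ...] = ()
    include_zero_lag: bool = True
    max_iterations: Optional[int] = None
    draw_cap: int = 1_000_000
    priors: Optional[Dict[str, Tuple[float, float]]] = None
    seed: Optional[int] = None


@dataclass
class PosteriorEnsemble:
    """Accepted particles of the final iteration with full run history."""

    samples: np.ndarray  # (n_particles, n_params)
    param_names: Tuple[str, ...]
    weights: np.ndarray
    distances: np.ndarray
    eps_history: np.ndarray
    accR_history: np.ndarray
    model_tag: str
    priors: Dict[str, Tuple[float, float]]
    stop_reason: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.weights = self.weights / self.weights.sum()

    def as_dict(self) -> Dict[str, np.ndarray]:
        return {name: self.samples[:, i] for i, name in enumerate(self.param_names)}

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.samples, columns=list(self.param_names))
        df["weight"] = self.weights
        df["distance"] = self.distances
        return df


def lag_mask(
    lags_ms: np.ndarray,
    t_max_ms: float,
    excluded_lags_ms: Sequence[float] = (),
    include_zero_lag: bool = True,
) -> np.ndarray:
    mask = lags_ms <= t_max_ms + 1e-9
    if not include_zero_lag:
        mask &= lags_ms > 0
    for t in excluded_lags_ms:
        mask &= ~np.isclose(lags_ms, t)
    return mask


def ac_distance(
    ac_data: CorrFunction,
    ac_synth: CorrFunction,
    t_max_ms: float = 100.0,
    excluded_lags_ms: Sequence[float] = (),
    include_zero_lag: bool = True,
) -> float:
    """Mean squared autocorrelation difference with the 1/m normalisation
    (m = included lags - 1)."""
    if ac_data.lags_ms.shape != ac_synth.lags_ms.shape or not np.allclose(
        ac_data.lags_ms, ac_synth.lags_ms
    ):
        raise ValueError("lag grid mismatch between data and synthetic AC")
    mask = lag_mask(ac_data.lags_ms, t_max_ms, excluded_lags_ms, include_zero_lag)
    diff = ac_data.values[mask] - ac_synth.values[mask]
    m = diff.size - 1
    if m < 1:
        raise ValueError("need at least 2 included lags")
    return float(np.sum(diff**2) / m)


def params_to_mixture(theta: np.ndarray, names: Sequence[str]) -> OUMixtureParams:
    """Map a parameter vector to mixture parameters, sorting timescales
    (label-switching control)."""
    p = dict(zip(names, theta))
    if "tau" in p:
        taus, coeffs = [p["tau"]], [1.0]
    elif "tau3" in p:
        taus = [p["tau1"], p["tau2"], p["tau3"]]
        coeffs = [p["c1"], p["c2"], 1.0 - p["c1"] - p["c2"]]
    else:
        taus = [p["tau1"], p["tau2"]]
        coeffs = [p["c1"], 1.0 - p["c1"]]
    return OUMixtureParams(tau_ms=np.asarray(taus), coeffs=np.asarray(coeffs), alpha=p["alpha"])


def _synthetic_ac_values(
    mixture: OUMixtureParams, stats: DataStats, n_lag_bins: int, rng: np.random.Generator
) -> np.ndarray:
    """Windowed-average AC of one matched surrogate dataset (same estimator
    as applied to data, same trial geometry)."""
    mat = ou.matched_counts(mixture, stats, rng)
    var = mat.var(axis=-1, ddof=1)
    mat = mat[var > 0]
    if mat.shape[0] == 0:  # pathological candidate (all-zero counts)
        return np.full(n_lag_bins, np.nan)
    return _windowed_correlation(mat, None, max_lag_bins=n_lag_bins - 1).mean(axis=0)


def _theta_valid(theta: np.ndarray, names: Sequence[str], bounds: np.ndarray) -> bool:
    if np.any(theta < bounds[:, 0]) or np.any(theta > bounds[:, 1]):
        return False
    p = dict(zip(names, theta))
    for key in ("tau", "tau1", "tau2", "tau3"):
        if key in p and p[key] <= 0:
            return False
    if "c2" in p and p["c1"] + p["c2"] > 1.0:
        return False
    return True


def abc_fit(
    ac_data: CorrFunction,
    stats: DataStats,
    model: str = "M2",
    cfg: Optional[ABCConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> PosteriorEnsemble:
    """Fit the generative model ``model`` to an observed autocorrelation.

    ``ac_data`` must be on the bin-resolution lag grid starting at lag 0 and
    should have passed session QC. Deterministic given (inputs, seed/rng).
    """
    cfg = cfg or ABCConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    priors = cfg.priors or MODEL_PRIORS[model]
    names = tuple(priors)
    bounds = np.array([priors[n] for n in names], dtype=float)

    mask = lag_mask(ac_data.lags_ms, cfg.t_max_ms, cfg.excluded_lags_ms, cfg.include_zero_lag)
    n_lag_bins = int(np.max(np.nonzero(mask)[0])) + 1
    data_vals = ac_data.values[:n_lag_bins]
    sub_mask = mask[:n_lag_bins]
    m_norm = int(sub_mask.sum()) - 1
    if m_norm < 1:
        raise ValueError("fit range leaves fewer than 2 lags")

    def distance_of(theta: np.ndarray) -> float:
        mixture = params_to_mixture(theta, names)
        synth = _synthetic_ac_values(mixture, stats, n_lag_bins, rng)
        if np.any(~np.isfinite(synth)):
            return np.inf
        diff = (data_vals - synth)[sub_mask]
        return float(np.sum(diff**2) / m_norm)

    n_particles = cfg.samples_per_iter
    eps = cfg.eps0
    eps_history, accR_history = [], []
    particles = weights = dists = None
    total_draws = 0
    stop_reason = "accR_stop"

    iteration = 0
    while True:
        iteration += 1
        accepted, acc_d = [], []
        draws = 0
        if particles is not None:
            cov = 2.0 * np.cov(particles.T, aweights=weights)
            cov = np.atleast_2d(cov) + 1e-12 * np.eye(len(names))
            chol = np.linalg.cholesky(cov)
        while len(accepted) < n_particles:
            if total_draws + draws >= cfg.draw_cap:
                if particles is None:
                    raise ABCError(
                        f"no complete iteration within draw cap ({cfg.draw_cap}); "
                        f"eps0={cfg.eps0}, accepted so far {len(accepted)}"
                    )
                stop_reason = "draw_cap"
                break
            if particles is None:
                theta = bounds[:, 0] + rng.random(len(names)) * (bounds[:, 1] - bounds[:, 0])
            else:
                idx = rng.choice(n_particles, p=weights)
                theta = particles[idx] + chol @ rng.standard_normal(len(names))
            draws += 1
            if not _theta_valid(theta, names, bounds):
                continue
            d = distance_of(theta)
            if d < eps:
                accepted.append(theta)
                acc_d.append(d)
        if stop_reason == "draw_cap" and len(accepted) < n_particles:
            total_draws += draws
            break
        new_particles = np.asarray(accepted)
        new_d = np.asarray(acc_d)
        if particles is None:
            new_weights = np.full(n_particles, 1.0 / n_particles)
        else:
            # importance weights: uniform prior / mixture-of-kernels proposal
            from scipy.special import logsumexp

            diffs = new_particles[:, None, :] - particles[None, :, :]
            sol = np.linalg.solve(chol, diffs.transpose(2, 0, 1).reshape(len(names), -1))
            maha = (sol**2).sum(axis=0).reshape(n_particles, n_particles)
            log_q = logsumexp(np.log(weights)[None, :] - 0.5 * maha, axis=1)
            new_weights = np.exp(-(log_q - log_q.min()))
            new_weights /= new_weights.sum()
        particles, weights, dists = new_particles, new_weights, new_d
        total_draws += draws
        accR = len(accepted) / max(draws, 1)
        eps_history.append(eps)
        accR_history.append(accR)
        logger.info(
            "aABC %s iter %d: eps=%.3g accR=%.4g draws=%d", model, iteration, eps, accR, draws
        )
        if accR < cfg.accR_stop:
            stop_reason = "accR_stop"
            break
        if cfg.max_iterations is not None and iteration >= cfg.max_iterations:
            stop_reason = "max_iterations"
            break
        eps = float(np.quantile(dists, 0.25))

    # report with sorted timescales (identifiability convention)
    sorted_particles = np.array(
        [_sorted_theta(th, names) for th in particles], dtype=float
    )
    return PosteriorEnsemble(
        samples=sorted_particles,
        param_names=names,
        weights=weights,
        distances=dists,
        eps_history=np.asarray(eps_history),
        accR_history=np.asarray(accR_history),
        model_tag=model,
        priors=dict(priors),
        stop_reason=stop_reason,
    )


def _sorted_theta(theta: np.ndarray, names: Sequence[str]) -> np.ndarray:
    p = dict(zip(names, theta))
    if "tau1" in p and "tau3" not in p and p["tau1"] > p["tau2"]:
        p["tau1"], p["tau2"] = p["tau2"], p["tau1"]
        p["c1"] = 1.0 - p["c1"]
    return np.array([p[n] for n in names])


def map_estimate(
    post: PosteriorEnsemble, grid_points: int = 50, refine: int = 2,
    chunk: int = 200_000,
) -> Dict[str, float]:
    """MAP of the kernel-smoothed joint posterior.

    A Gaussian KDE (Scott bandwidth, importance-weighted) is evaluated on a
    regular grid over the prior box (``grid_points`` per dimension); the
    grid is then re-centred ``refine`` times on the running arg-max with a
    span of one previous grid cell, removing the coarse-grid quantisation.
    ``np.argmax`` resolves ties at the first (lowest-value) grid point.
    Constant dimensions are held fixed at their value. Deterministic given
    the ensemble and grid settings.
    """
    names = post.param_names
    X = post.samples
    spreads = X.std(axis=0)
    active = spreads > 1e-12
    if not np.any(active):
        logger.warning("degenerate ensemble: all particles identical; returning that point")
        return dict(zip(names, X[0]))
    kde = sstats.gaussian_kde(X[:, active].T, weights=post.weights)
    boxes = [list(post.priors[name]) for i, name in enumerate(names) if active[i]]

    def search(boxes_now):
        axes = [np.linspace(lo, hi, grid_points) for lo, hi in boxes_now]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh])
        best_val, best_idx = -np.inf, 0
        for start in range(0, pts.shape[1], chunk):
            vals = kde(pts[:, start : start + chunk])
            i = int(np.argmax(vals))
            if vals[i] > best_val:
                best_val, best_idx = float(vals[i]), start + i
        return pts[:, best_idx], [(hi - lo) / (grid_points - 1) for lo, hi in boxes_now]

    centre, cell = search(boxes)
    for _ in range(refine):
        boxes_now = [
            (max(lo, c - w), min(hi, c + w))
            for (lo, hi), c, w in zip(boxes, centre, cell)
        ]
        centre, cell = search(boxes_now)

    out = {}
    j = 0
    for i, name in enumerate(names):
        if active[i]:
            out[name] = float(centre[j])
            j += 1
        else:
            out[name] = float(X[0, i])
    return out


def weighted_quantile(x: np.ndarray, q, weights: Optional[np.ndarray] = None) -> np.ndarray:
    """Weighted quantiles with the Hazen convention (plotting positions at
    cumulative weight minus half the point's weight); reduces to the standard
    Hazen sample quantile for uniform weights."""
    x = np.asarray(x, dtype=float)
    q = np.atleast_1d(q)
    if weights is None:
        weights = np.full(x.size, 1.0 / x.size)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cdf = np.cumsum(ws) - 0.5 * ws
    return np.interp(q, cdf, xs)


def posterior_summary(post: PosteriorEnsemble) -> Dict[str, Dict[str, float]]:
    """Per-parameter marginal summaries: mean, median, quartiles and a 95%
    credible interval, computed on the weighted ensemble."""
    out = {}
    for i, name in enumerate(post.param_names):
        x = post.samples[:, i]
        qs = weighted_quantile(x, [0.025, 0.25, 0.5, 0.75, 0.975], post.weights)
        out[name] = {
            "mean": float(np.average(x, weights=post.weights)),
            "ci_lo": float(qs[0]),
            "q1": float(qs[1]),
            "median": float(qs[2]),
            "q3": float(qs[3]),
            "ci_hi": float(qs[4]),
        }
    return out
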