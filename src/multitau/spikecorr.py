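"""Spike-count correlation estimation for columnar multi-channel recordings.

The pipeline here is: pool spikes over visually responsive channels, count in
small bins (2 ms default), subtract the per-condition trial-average at each
bin (removing task-locked rate changes), segment into fixed-length windows,
and compute correlations per window with lag-dependent sample means:

    AC(t_j) = 1 / (sigma^2 (N - j)) * sum_{i=1}^{N-j}
              (A(t_i) - mu1(j)) (A(t_{i+j}) - mu2(j))

where mu1(j) averages the first N-j bins, mu2(j) the last N-j bins, and
sigma^2 is the (N-1)-normalised sample variance of the whole window. The
single shared variance (rather than lag-dependent standard deviations) is a
deliberate property of the estimator: the same estimator is applied to
surrogate data during generative-model fitting, so its finite-window bias
cancels in the fit.

A direct algebraic consequence used as a self-check throughout: at lag 0 the
estimator equals (N-1)/N exactly for any non-constant window.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.fft as _fft

from .types import BinnedCounts, CorrFunction

logger = logging.getLogger(__name__)

#: Analysis-epoch defaults per task. Windows are non-overlapping; trials
#: shorter than one window are discarded.
EPOCH_DEFAULTS = {
    "FT": {"window_ms": 3000.0, "epoch_start_ms": 0.0},
    "AT1_stimulus": {"window_ms": 700.0, "epoch_start_ms": 400.0},
    "AT2_stimulus": {"window_ms": 500.0, "epoch_start_ms": 200.0},
    "AT2_spontaneous": {"window_ms": 800.0, "epoch_start_ms": 0.0},
}

REQUIRED_EVENT_COLUMNS = ("session", "trial", "channel", "time_ms", "condition")


def read_events(path) -> pd.DataFrame:
    """Read a spike-event table (CSV/TSV with session, trial, channel,
    time_ms, condition columns)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(REQUIRED_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    return df


def read_rf_map(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = {"channel", "x_dva", "y_dva"} - set(df.columns)
    if missing:
        raise ValueError(f"RF map missing columns: {sorted(missing)}")
    return df


def bin_and_pool(
    events: pd.DataFrame,
    bin_ms: float = 2.0,
    window_ms: float = 500.0,
    channels: Optional[Sequence[int]] = None,
    epoch_start_ms: float = 0.0,
    trial_ms: Optional[float] = None,
) -> BinnedCounts:
    """Pool spikes over ``channels``, count in ``bin_ms`` bins and segment
    into non-overlapping ``window_ms`` windows.

    Trials shorter than one window are dropped (and logged); on long trials
    as many full windows as fit are kept and the remainder is discarded.
    Trial duration is taken from ``trial_ms`` (scalar), a ``trial_ms`` column
    in ``events``, or inferred from the latest spike time per trial.
    """
    if channels is not None:
        channels = list(channels)
        if len(channels) == 0:
            raise ValueError("empty channel selection")
        events = events[events["channel"].isin(channels)]

    n_bins_per_window = int(round(window_ms / bin_ms))
    if abs(n_bins_per_window * bin_ms - window_ms) > 1e-9:
        raise ValueError("bin_ms must divide window_ms")

    windows, conditions, trial_ids, dropped = [], [], [], []
    for (trial, cond), grp in events.groupby(["trial", "condition"], sort=True):
        if trial_ms is not None:
            duration = float(trial_ms)
        elif "trial_ms" in grp.columns:
            duration = float(grp["trial_ms"].iloc[0])
        else:
            duration = float(grp["time_ms"].max())
        t = grp["time_ms"].to_numpy(dtype=float) - epoch_start_ms
        epoch_len = duration - epoch_start_ms
        if epoch_len < 0:
            dropped.append((trial, "epoch longer than trial"))
            logger.warning("trial %s rejected: epoch start beyond trial end", trial)
            continue
        n_win = int(epoch_len // window_ms)
        if n_win == 0:
            dropped.append((trial, "shorter than window"))
            logger.info("trial %s dropped: shorter than one %g ms window", trial, window_ms)
            continue
        total_bins = n_win * n_bins_per_window
        t = t[(t >= 0) & (t < total_bins * bin_ms)]
        counts = np.bincount((t // bin_ms).astype(int), minlength=total_bins)[:total_bins]
        for w in range(n_win):
            windows.append(counts[w * n_bins_per_window : (w + 1) * n_bins_per_window])
            conditions.append(cond)
            trial_ids.append(trial)

    if not windows:
        counts_arr = np.zeros((0, n_bins_per_window), dtype=int)
    else:
        counts_arr = np.asarray(windows, dtype=int)
    return BinnedCounts(
        counts=counts_arr,
        bin_ms=bin_ms,
        window_ms=window_ms,
        condition=np.asarray(conditions, dtype=object) if conditions else None,
        trial_id=np.asarray(trial_ids) if trial_ids else None,
        dropped_trials=dropped,
    )


def subtract_condition_mean(counts: BinnedCounts) -> BinnedCounts:
    """Subtract the per-condition, per-bin mean across windows.

    Removes correlations locked to task events. Requires at least two windows
    per condition (the residual of a single window would be identically
    zero)."""
    out = counts.counts.astype(float).copy()
    for cond in np.unique(counts.condition):
        mask = counts.condition == cond
        if mask.sum() < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 windows; mean subtraction would zero the data")
        out[mask] -= out[mask].mean(axis=0, keepdims=True)
    return BinnedCounts(
        counts=out,
        bin_ms=counts.bin_ms,
        window_ms=counts.window_ms,
        condition=counts.condition,
        trial_id=counts.trial_id,
        dropped_trials=counts.dropped_trials,
    )


def _lagged_sums(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Leading/trailing partial sums S1(j) = sum_{i<=N-j} x_i and
    S2(j) = sum_{i>j} x_i for batched rows. Shapes (n, N)."""
    csum = np.cumsum(x, axis=-1)
    tot = csum[..., -1:]
    n = x.shape[-1]
    # S1(j) = csum[N-1-j]; S2(j) = tot - csum[j-1], S2(0) = tot
    s1 = csum[..., ::-1]
    s2 = np.concatenate([tot, tot - csum[..., :-1]], axis=-1)
    return s1, s2


def _raw_corr(a: np.ndarray, b: np.ndarray, n_lags: int) -> np.ndarray:
    """C(j) = sum_{i=1}^{N-j} a_i b_{i+j} for j = 0..n_lags-1, batched rows,
    computed with FFTs (zero-padded to avoid circular wrap)."""
    n = a.shape[-1]
    nf = _fft.next_fast_len(n + n_lags)
    fa = _fft.rfft(a, n=nf, axis=-1)
    fb = _fft.rfft(b, n=nf, axis=-1)
    c = _fft.irfft(np.conj(fa) * fb, n=nf, axis=-1)
    return c[..., :n_lags]


def _windowed_correlation(
    a: np.ndarray, b: Optional[np.ndarray] = None, max_lag_bins: Optional[int] = None
) -> np.ndarray:
    """Batched estimator over windows (rows). ``b=None`` gives the
    autocorrelation; otherwise the cross-correlation with ``a`` leading."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    auto = b is None
    b = a if auto else np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("windows must have equal shape")
    n = a.shape[-1]
    if n < 3:
        raise ValueError("window length must be >= 3")
    n_lags = n if max_lag_bins is None else min(max_lag_bins + 1, n)

    var_a = a.var(axis=-1, ddof=1)
    var_b = var_a if auto else b.var(axis=-1, ddof=1)
    if np.any(var_a <= 0) or np.any(var_b <= 0):
        raise ValueError("constant window: correlation undefined (zero variance)")

    c = _raw_corr(a, b, n_lags)
    s1a, _ = _lagged_sums(a)
    _, s2b = _lagged_sums(b)
    denom_n = n - np.arange(n_lags, dtype=float)
    num = c - s1a[..., :n_lags] * s2b[..., :n_lags] / denom_n
    norm = np.sqrt(var_a * var_b)[..., None] * denom_n
    # variance products of near-constant windows can underflow to 0 even
    # though each variance passed the positivity check; poison those rows
    norm[norm == 0] = np.nan
    return num / norm


def autocorrelation(window: np.ndarray, bin_ms: float = 2.0, max_lag_bins: Optional[int] = None) -> CorrFunction:
    """Autocorrelation of a single mean-subtracted window (lag-dependent
    means, shared (N-1)-normalised variance). AC(0) = (N-1)/N identically."""
    values = _windowed_correlation(np.asarray(window, dtype=float), None, max_lag_bins)[0]
    lags = np.arange(values.size) * bin_ms
    return CorrFunction(lags_ms=lags, values=values, kind="auto", n_windows=1, bin_ms=bin_ms)


def cross_correlation(
    window_a: np.ndarray, window_b: np.ndarray, bin_ms: float = 2.0, max_lag_bins: Optional[int] = None
) -> CorrFunction:
    """Cross-correlation with ``window_a`` leading (asymmetric at lag > 0)."""
    values = _windowed_correlation(
        np.asarray(window_a, dtype=float), np.asarray(window_b, dtype=float), max_lag_bins
    )[0]
    lags = np.arange(values.size) * bin_ms
    return CorrFunction(lags_ms=lags, values=values, kind="cross", n_windows=1, bin_ms=bin_ms)


def windowed_average_autocorrelation(
    counts: BinnedCounts, condition: Optional[str] = None, max_lag_bins: Optional[int] = None
) -> CorrFunction:
    """Per-window autocorrelations averaged over windows of one condition
    (or all windows if ``condition`` is None)."""
    mat = counts.counts.astype(float)
    conds = counts.condition
    if condition is not None:
        mat = mat[conds == condition]
    if mat.shape[0] == 0:
        raise ValueError("no windows for requested condition")
    var = mat.var(axis=-1, ddof=1)
    keep = var > 0
    if not np.all(keep):
        logger.info("excluding %d zero-variance windows", int((~keep).sum()))
        mat = mat[keep]
    acs = _windowed_correlation(mat, None, max_lag_bins)
    lags = np.arange(acs.shape[-1]) * counts.bin_ms
    return CorrFunction(
        lags_ms=lags,
        values=acs.mean(axis=0),
        kind="auto",
        n_windows=mat.shape[0],
        bin_ms=counts.bin_ms,
        condition=condition,
    )


def average_correlations(corrs: Iterable[CorrFunction]) -> CorrFunction:
    """Unweighted mean over per-window correlation functions (identical lag
    grids required); total window count recorded."""
    corrs = list(corrs)
    if not corrs:
        raise ValueError("no correlation functions to average")
    lags = corrs[0].lags_ms
    for c in corrs[1:]:
        if c.lags_ms.shape != lags.shape or not np.allclose(c.lags_ms, lags):
            raise ValueError("mixed lag grids")
    values = np.mean([c.values for c in corrs], axis=0)
    return CorrFunction(
        lags_ms=lags,
        values=values,
        kind=corrs[0].kind,
        n_windows=int(sum(c.n_windows for c in corrs)),
        bin_ms=corrs[0].bin_ms,
        zero_lag_included=corrs[0].zero_lag_included,
        condition=corrs[0].condition,
    )


def session_qc(ac: CorrFunction, threshold: float = 0.01, max_lag_ms: float = 20.0) -> bool:
    """Session inclusion rule: exclude (return False) if the autocorrelation
    falls below ``threshold`` at any positive lag <= ``max_lag_ms``.

    Screens out sessions dominated by noise or oscillations that a mixture of
    exponential decays cannot describe."""
    mask = (ac.lags_ms > 0) & (ac.lags_ms <= max_lag_ms + 1e-9)
    return bool(np.all(ac.values[mask] >= threshold))


def channel_cross_correlations(
    counts_by_channel: Dict[int, BinnedCounts],
    min_channel_gap: int = 2,
    max_lag_bins: Optional[int] = None,
) -> Dict[Tuple[int, int], CorrFunction]:
    """Window-averaged cross-correlations for every ordered channel pair
    (a < b) at least ``min_channel_gap`` apart. Adjacent channels are skipped
    to avoid shared-electrode spike contamination."""
    chans = sorted(counts_by_channel)
    out: Dict[Tuple[int, int], CorrFunction] = {}
    for i, a in enumerate(chans):
        for b in chans[i + 1 :]:
            if abs(a - b) < min_channel_gap:
                continue
            ca, cb = counts_by_channel[a], counts_by_channel[b]
            if ca.counts.shape != cb.counts.shape:
                raise ValueError("channel count matrices must align window-for-window")
            va = ca.counts.astype(float).var(axis=-1, ddof=1)
            vb = cb.counts.astype(float).var(axis=-1, ddof=1)
            keep = (va > 0) & (vb > 0)
            ccs = _windowed_correlation(
                ca.counts[keep].astype(float), cb.counts[keep].astype(float), max_lag_bins
            )
            lags = np.arange(ccs.shape[-1]) * ca.bin_ms
            out[(a, b)] = CorrFunction(
                lags_ms=lags,
                values=ccs.mean(axis=0),
                kind="cross",
                n_windows=int(keep.sum()),
                bin_ms=ca.bin_ms,
            )
    return out


def group_cc_by_rf_distance(
    cc_by_pair: Dict[Tuple[int, int], CorrFunction], rf_map: pd.DataFrame
) -> Dict[str, object]:
    """Split channel-pair cross-correlations at the median RF-center distance.

    Euclidean distances between RF centers (degrees of visual angle) proxy
    lateral cortical distance. Pairs exactly at the median go to the
    short-distance group (deterministic tie rule). Returns the per-group
    unweighted mean cross-correlation and the median distance.
    """
    centers = {int(r.channel): np.array([r.x_dva, r.y_dva]) for r in rf_map.itertuples()}
    pairs, dists = [], []
    for (a, b), cc in cc_by_pair.items():
        if a not in centers or b not in centers:
            raise KeyError(f"RF center missing for channel pair ({a},{b})")
        pairs.append((a, b))
        dists.append(float(np.linalg.norm(centers[a] - centers[b])))
    dists = np.asarray(dists)
    if np.unique(dists).size < 2:
        raise ValueError("all channel pairs at a single RF distance; median split undefined")
    med = float(np.median(dists))
    short = [cc_by_pair[p] for p, d in zip(pairs, dists) if d <= med]
    long_ = [cc_by_pair[p] for p, d in zip(pairs, dists) if d > med]
    return {
        "short": average_correlations(short),
        "long": average_correlations(long_),
        "median_distance_dva": med,
        "n_short": len(short),
        "n_long": len(long_),
    }
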