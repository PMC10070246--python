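"""Probabilistic binary-unit network models on a 2-D periodic lattice.

Each unit is a two-state (on/off) stochastic unit standing in for a small
neural population (e.g. a cortical minicolumn). Units sit on an L x L square
lattice with periodic boundaries and receive input from exactly 8
presynaptic partners: the Moore neighborhood (spatial variant), 8 partners
drawn within a Chebyshev radius r (dispersed), or anywhere on the lattice
(random). All units update synchronously in discrete steps of dt (1 ms).

Linear (additive) rule, with h = p_r * (number of active partners):

    P(0 -> 1) = p_ext + h
    P(1 -> 1) = p_ext + p_s + h

Nonlinear (multiplicative) rule:

    P(0 -> 1) = 1 - (1 - p_ext)(1 - p_r)^k
    P(1 -> 0) = (1 - p_ext)(1 - p_s)(1 - p_r)^k      (k active partners)

The branching parameter BP = p_s + 8 p_r sets the distance to the critical
point BP = 1; the self-excitation probability p_s alone sets the fast
("self") timescale tau_self = -dt/ln(p_s).

Two further variants: a two-cell-type model (types A and B at every node
with distinct p_s per type, random connectivity across both populations,
observables computed on the per-node summed activity), and a synaptic-
filtering model where the recurrent drive h is replaced by a leaky
integrator f with time constant tau_synapse:

    f(t+1) = f(t) + (p_r * k - f(t)) / (tau_synapse/dt).

Probabilities are clipped to [0, 1]; clips are counted and reported.
Simulations start from the analytical steady-state occupancy and discard a
burn-in before recording.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import scipy.fft as _fft
import scipy.sparse as sp

from .types import CorrFunction

logger = logging.getLogger(__name__)

VARIANTS = ("spatial", "dispersed", "random", "two_type", "synaptic")


@dataclass
class LatticeConfig:
    """Simulation settings.

    ``p_s``/``p_r`` are scalars except for the two-type variant where they
    are (type-A, type-B) pairs; ``radius`` only applies to the dispersed
    variant. ``burn_in`` of None selects 10x the predicted global timescale
    (capped at 20000 steps)."""

    L: int = 100
    variant: str = "spatial"
    rule: str = "linear"
    p_s: object = 0.88
    p_r: object = 0.01375
    p_ext: float = 1e-4
    radius: int = 1
    tau_synapse_ms: float = 41.0
    theta: float = 1.0
    input_I: float = 0.0
    steps: int = 100_000
    dt_ms: float = 1.0
    burn_in: Optional[int] = None
    shadow_unit: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.rule not in ("linear", "nonlinear"):
            raise ValueError(f"unknown rule {self.rule!r}")
        for p in np.atleast_1d(self.p_s).tolist() + np.atleast_1d(self.p_r).tolist() + [self.p_ext]:
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.variant == "dispersed" and (self.radius < 1 or self.L < 2 * self.radius + 1):
            raise ValueError("infeasible connectivity radius")

    @property
    def n_nodes(self) -> int:
        return self.L * self.L

    @property
    def n_units(self) -> int:
        return 2 * self.n_nodes if self.variant == "two_type" else self.n_nodes

    @property
    def bp(self) -> float:
        return float(np.max(np.atleast_1d(self.p_s) + 8.0 * np.atleast_1d(self.p_r)))


@dataclass
class LatticeRun:
    """Recorded binary activity (after burn-in) plus provenance."""

    config: LatticeConfig
    history: np.ndarray  # (steps, n_units) uint8
    adjacency: np.ndarray  # (n_units, 8) presynaptic indices
    shadow: Optional[np.ndarray] = None  # (steps,) uint8
    clip_count: int = 0
    burn_in_used: int = 0

    def node_activity(self) -> np.ndarray:
        """Per-node activity: the unit state, or the A+B sum for the
        two-type variant (values 0, 1, 2)."""
        if self.config.variant == "two_type":
            n = self.config.n_nodes
            return self.history[:, :n] + self.history[:, n:]
        return self.history


def steady_state_activity(p_s: float, p_r: float, p_ext: float, n: int = 8) -> float:
    """Mean-field stationary occupancy p_ext / (1 - (p_s + n p_r))."""
    bp = p_s + n * p_r
    if bp >= 1.0:
        raise ValueError("branching parameter >= 1: no finite stationary activity")
    return p_ext / (1.0 - bp)


def build_connectivity(cfg: LatticeConfig, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Quenched presynaptic partner table, shape (n_units, 8).

    spatial: the 8 Moore neighbors (periodic wrap). dispersed: 8 distinct
    partners uniformly within Chebyshev radius ``cfg.radius`` (self
    excluded). random: 8 distinct partners anywhere. two_type: 8 distinct
    partners of either type anywhere (random connectivity)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    L, n = cfg.L, cfg.n_nodes
    if cfg.variant == "spatial" or (cfg.variant == "dispersed" and cfg.radius == 1):
        offs = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)]
        xs, ys = np.divmod(np.arange(n), L)
        adj = np.empty((n, 8), dtype=np.int64)
        for k, (dx, dy) in enumerate(offs):
            adj[:, k] = ((xs + dx) % L) * L + (ys + dy) % L
        return adj
    if cfg.variant == "dispersed":
        r = cfg.radius
        offs = np.array(
            [(dx, dy) for dx in range(-r, r + 1) for dy in range(-r, r + 1) if (dx, dy) != (0, 0)]
        )
        xs, ys = np.divmod(np.arange(n), L)
        adj = np.empty((n, 8), dtype=np.int64)
        for i in range(n):
            pick = rng.choice(offs.shape[0], size=8, replace=False)
            dx, dy = offs[pick, 0], offs[pick, 1]
            adj[i] = ((xs[i] + dx) % L) * L + (ys[i] + dy) % L
        return adj
    # random / two_type: partners anywhere, self excluded
    n_units = cfg.n_units
    adj = np.empty((n_units, 8), dtype=np.int64)
    for i in range(n_units):
        pick = rng.integers(0, n_units - 1, size=8)
        pick[pick >= i] += 1  # skip self
        while np.unique(pick).size < 8:  # enforce distinct partners
            pick = rng.integers(0, n_units - 1, size=8)
            pick[pick >= i] += 1
        adj[i] = pick
    return adj


def _adjacency_matrix(adj: np.ndarray) -> sp.csr_matrix:
    n = adj.shape[0]
    rows = np.repeat(np.arange(n), adj.shape[1])
    return sp.csr_matrix(
        (np.ones(adj.size), (rows, adj.ravel())), shape=(n, n)
    )


def _unit_params(cfg: LatticeConfig) -> Tuple[np.ndarray, np.ndarray]:
    """Per-unit (p_s, p_r) vectors; two-type layout is [A block, B block]."""
    if cfg.variant == "two_type":
        n = cfg.n_nodes
        ps = np.concatenate([np.full(n, np.atleast_1d(cfg.p_s)[0]), np.full(n, np.atleast_1d(cfg.p_s)[-1])])
        pr = np.concatenate([np.full(n, np.atleast_1d(cfg.p_r)[0]), np.full(n, np.atleast_1d(cfg.p_r)[-1])])
        return ps, pr
    n = cfg.n_units
    return np.full(n, float(np.atleast_1d(cfg.p_s)[0])), np.full(n, float(np.atleast_1d(cfg.p_r)[0]))


def simulate(cfg: LatticeConfig, rng: Optional[np.random.Generator] = None) -> LatticeRun:
    """Run the configured model and record the post-burn-in binary history.

    Initial states are Bernoulli draws at the analytical steady-state
    occupancy; a burn-in of 10x the predicted global timescale (capped)
    removes the residual transient. Reproducible from (config, seed)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    adj = build_connectivity(cfg, rng)
    A = _adjacency_matrix(adj)
    ps_vec, pr_vec = _unit_params(cfg)
    n = cfg.n_units
    p_ext = cfg.p_ext

    sbar = np.empty(n)
    for val_s, val_r in set(zip(ps_vec.tolist(), pr_vec.tolist())):
        m = (ps_vec == val_s) & (pr_vec == val_r)
        bp = val_s + 8 * val_r
        sbar[m] = p_ext / (1 - bp) if bp < 1 else 0.5
    state = (rng.random(n) < sbar).astype(np.float64)

    if cfg.burn_in is None:
        bp = cfg.bp
        if bp < 1:
            tau_g = -cfg.dt_ms * (1 - np.min(ps_vec)) / ((1 - bp) * np.log(np.min(ps_vec)))
        else:
            tau_g = 2000.0
        burn = int(np.clip(10 * tau_g / cfg.dt_ms, 100, 20_000))
    else:
        burn = int(cfg.burn_in)

    shadow_src = cfg.shadow_unit
    track_shadow = shadow_src is not None
    if track_shadow:
        shadow_partners = adj[shadow_src]
        shadow_state = 0.0
        shadow_hist = np.empty(cfg.steps, dtype=np.uint8)

    filt = np.zeros(n) if cfg.variant == "synaptic" else None
    history = np.empty((cfg.steps, n), dtype=np.uint8)
    clip_count = 0
    tau_ratio = cfg.tau_synapse_ms / cfg.dt_ms

    for t in range(burn + cfg.steps):
        k_active = A @ state
        if cfg.variant == "synaptic":
            filt = filt + (pr_vec * k_active - filt) / tau_ratio
            drive = filt
            p_next = np.where(state > 0, p_ext + ps_vec + drive, p_ext + drive)
        elif cfg.rule == "linear":
            drive = pr_vec * k_active
            p_next = np.where(state > 0, p_ext + ps_vec + drive, p_ext + drive)
        else:  # nonlinear multiplicative rule
            damp = (1.0 - pr_vec) ** k_active
            p_on = 1.0 - (1.0 - p_ext) * damp
            p_stay = 1.0 - (1.0 - p_ext) * (1.0 - ps_vec) * damp
            p_next = np.where(state > 0, p_stay, p_on)
        n_over = int(np.count_nonzero(p_next > 1.0))
        if n_over:
            clip_count += n_over
            np.clip(p_next, 0.0, 1.0, out=p_next)
        new_state = (rng.random(n) < p_next).astype(np.float64)
        if track_shadow:
            k_sh = state[shadow_partners].sum()
            if cfg.rule == "linear" or cfg.variant == "synaptic":
                p_sh = pr_vec[shadow_src] * k_sh
            else:
                p_sh = 1.0 - (1.0 - pr_vec[shadow_src]) ** k_sh
            shadow_state = 1.0 if rng.random() < min(p_sh, 1.0) else 0.0
            if t >= burn:
                shadow_hist[t - burn] = shadow_state
        state = new_state
        if t >= burn:
            history[t - burn] = state

    if clip_count:
        logger.info("clipped %d transition probabilities to [0,1]", clip_count)
    return LatticeRun(
        config=cfg,
        history=history,
        adjacency=adj,
        shadow=shadow_hist if track_shadow else None,
        clip_count=clip_count,
        burn_in_used=burn,
    )


def _series_autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Unbiased long-series AC for batched columns x (T, m): per-column mean
    removed, lag-j covariance normalised by (T - j) and the lag-0 variance."""
    x = x - x.mean(axis=0, keepdims=True)
    T = x.shape[0]
    nf = _fft.next_fast_len(T + max_lag + 1)
    F = _fft.rfft(x, n=nf, axis=0)
    c = _fft.irfft((F * np.conj(F)).real, n=nf, axis=0)[: max_lag + 1]
    c /= (T - np.arange(max_lag + 1, dtype=float))[:, None]
    return c / c[0]


def unit_autocorrelation(
    run: LatticeRun,
    max_lag: int = 200,
    unit_sample: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    chunk: int = 256,
) -> CorrFunction:
    """Autocorrelations of individual units (per-node summed activity for
    the two-type variant), averaged over units.

    Zero-variance units are excluded (logged). ``unit_sample`` averages over
    a random subset of units instead of all of them — the precision is set
    by units x steps and stays ample for a few hundred units."""
    act = run.node_activity().astype(np.float32)
    T, n = act.shape
    if T <= max_lag + 1:
        raise ValueError("run too short for requested maximum lag")
    if unit_sample is not None and unit_sample < n:
        if rng is None:
            rng = np.random.default_rng(0)
        act = act[:, rng.choice(n, size=unit_sample, replace=False)]
        n = unit_sample
    acc = np.zeros(max_lag + 1)
    used = 0
    for start in range(0, n, chunk):
        block = act[:, start : start + chunk]
        var = block.var(axis=0)
        block = block[:, var > 0]
        if block.shape[1] == 0:
            continue
        acc += _series_autocorrelation(block, max_lag).sum(axis=1)
        used += block.shape[1]
    if used == 0:
        raise ValueError("all units have zero variance")
    if used < n:
        logger.info("excluded %d zero-variance units from AC average", n - used)
    lags = np.arange(max_lag + 1) * run.config.dt_ms
    return CorrFunction(lags_ms=lags, values=acc / used, kind="auto", n_windows=used,
                        bin_ms=run.config.dt_ms)


def global_autocorrelation(run: LatticeRun, max_lag: int = 400) -> CorrFunction:
    """AC of the pooled (summed over units) activity."""
    pooled = run.node_activity().sum(axis=1).astype(np.float64)[:, None]
    values = _series_autocorrelation(pooled, max_lag)[:, 0]
    lags = np.arange(max_lag + 1) * run.config.dt_ms
    return CorrFunction(lags_ms=lags, values=values, kind="auto", n_windows=1,
                        bin_ms=run.config.dt_ms)


def shadow_input_autocorrelation(
    cfg: LatticeConfig, rng: Optional[np.random.Generator] = None, max_lag: int = 200
) -> CorrFunction:
    """AC of a passive "shadow" unit driven only by one unit's recurrent
    inputs (no self-excitation, no external drive, no feedback); isolates
    the interaction component of the unit autocorrelation."""
    if float(np.atleast_1d(cfg.p_r)[0]) == 0.0:
        raise ValueError("shadow unit would be silent: p_r = 0")
    cfg_sh = LatticeConfig(**{**cfg.__dict__, "shadow_unit": cfg.shadow_unit or 0})
    run = simulate(cfg_sh, rng)
    x = run.shadow.astype(np.float64)
    if x.var() == 0:
        raise ValueError("shadow unit never activated; run longer or raise p_r")
    values = _series_autocorrelation(x[:, None], max_lag)[:, 0]
    lags = np.arange(max_lag + 1) * cfg.dt_ms
    return CorrFunction(lags_ms=lags, values=values, kind="auto", n_windows=1, bin_ms=cfg.dt_ms)


def _chebyshev_shell(d: int, L: int) -> np.ndarray:
    """Offsets (dx, dy) at Chebyshev distance exactly d (8d of them)."""
    offs = []
    for dx in range(-d, d + 1):
        for dy in range(-d, d + 1):
            if max(abs(dx), abs(dy)) == d:
                offs.append((dx, dy))
    return np.array(offs)


def cc_by_distance(
    run: LatticeRun,
    distances: Sequence[int] = (1, 2, 3, 4, 5),
    n_pairs: int = 40_000,
    rng: Optional[np.random.Generator] = None,
    max_lag: int = 0,
) -> Dict[int, CorrFunction]:
    """Mean pairwise cross-correlation per Chebyshev distance (periodic
    wrap). Pairs are sampled without replacement from the (unit, shell
    offset) combinations; if fewer are available than requested, all are
    used (logged). ``max_lag=0`` returns the zero-lag correlation only."""
    if rng is None:
        rng = np.random.default_rng(0)
    act = run.node_activity().astype(np.float32)
    T, n = act.shape
    L = run.config.L
    mean = act.mean(axis=0)
    sd = act.std(axis=0)
    centered = act - mean
    out: Dict[int, CorrFunction] = {}
    for d in distances:
        shell = _chebyshev_shell(d, L)
        n_slots = n * shell.shape[0]
        k = min(n_pairs, n_slots)
        if k < n_pairs:
            logger.info("distance %d: only %d pairs available (requested %d)", d, n_slots, n_pairs)
        slots = rng.choice(n_slots, size=k, replace=False)
        units = slots // shell.shape[0]
        offs = shell[slots % shell.shape[0]]
        xs, ys = np.divmod(units, L)
        partners = ((xs + offs[:, 0]) % L) * L + (ys + offs[:, 1]) % L
        ok = (sd[units] > 0) & (sd[partners] > 0)
        units, partners = units[ok], partners[ok]
        if units.size == 0:
            raise ValueError(f"no variance at distance {d}")
        if max_lag == 0:
            num = np.einsum("ti,ti->i", centered[:, units], centered[:, partners]) / T
            vals = np.array([np.mean(num / (sd[units] * sd[partners]))])
        else:
            nf = _fft.next_fast_len(T + max_lag + 1)
            Fa = _fft.rfft(centered[:, units], n=nf, axis=0)
            Fb = _fft.rfft(centered[:, partners], n=nf, axis=0)
            c = _fft.irfft(np.conj(Fa) * Fb, n=nf, axis=0)[: max_lag + 1]
            c /= (T - np.arange(max_lag + 1, dtype=float))[:, None]
            c /= (sd[units] * sd[partners])[None, :]
            vals = c.mean(axis=1)
        lags = np.arange(vals.size) * run.config.dt_ms
        out[d] = CorrFunction(lags_ms=lags, values=vals, kind="cross",
                              n_windows=int(units.size), bin_ms=run.config.dt_ms)
    return out
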