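# multitau

Multiple intrinsic timescales in columnar spiking activity: estimation,
likelihood-free inference, and mechanistic network models.

Ongoing cortical activity decorrelates over more than one characteristic
time: autocorrelations (AC) of spike counts in visual-cortex columns show a
fast decay of a few milliseconds and a slow decay of 100–150 ms, and the
slow timescale lengthens when spatial attention is directed into the
neurons' receptive fields. `multitau` is a Python library for the full
analysis and modelling chain behind such findings, aimed at systems and
computational neuroscientists working with multi-channel spiking data:

* **`multitau.spikecorr`** — spike-count auto-/cross-correlations with the
  windowing, trial-average subtraction, lag-dependent-mean estimator,
  session QC, and receptive-field-distance grouping used for columnar
  array recordings.
* **`multitau.ou` / `multitau.aabc`** — a doubly stochastic generative
  model (spike counts with gamma dispersion `α` driven by a mixture of
  Ornstein–Uhlenbeck processes, AC(t) = Σ c_k e^{−t/τ_k}) fitted by
  adaptive Approximate Bayesian Computation. Surrogates match the data's
  trial geometry and count moments and are summarised with the identical
  windowed estimator, so the finite-window bias of the AC cancels and the
  posterior timescales are unbiased.
* **`multitau.model_select`** — one vs two timescales by the
  acceptance-rate approximation of the Bayes factor,
  BF(ε) = CDF_M2(ε)/CDF_M1(ε), gated on a rank-sum test.
* **`multitau.lattice` / `multitau.theory`** — probabilistic binary-unit
  networks on a periodic lattice (local, dispersed, random, two-cell-type
  and synaptic-filter variants; linear and saturating rules) together with
  closed-form timescales from the master-equation analysis:
  τ_self = −Δt/ln(p_s), mode-wise interaction timescales τ_int(k), and the
  global timescale τ_global = −Δt(1−p_s)/((1−BP) ln p_s) at branching
  parameter BP = p_s + 8p_r.
* **`multitau.matching`** — double-exponential summaries of simulated ACs
  and a theory-shortlisted grid search locating network operating points
  that reproduce measured timescale bands, including the
  attention-as-excitability scenario (raise p_r at fixed p_s).
* **`multitau.synthdata` / `multitau.pipeline`** — a ground-truth synthetic
  session generator emulating 16-channel columnar recordings, and an
  end-to-end pipeline (correlations → fits → model selection → paired
  attention contrast).

## Worked example

`examples/lattice_timescales.py` simulates the locally connected network
near criticality (p_s = 0.88, BP = 0.99, p_ext = 10⁻⁴) and compares the
fitted AC components with theory:

```
simulated 2500 units for 60000 steps; mean activity 0.0098 (mean-field prediction 0.0100)
double-exponential fit: tau1 = 7.86 ms (weight 0.72), tau2 = 43.7 ms
analytical self-excitation timescale: 7.82 ms
analytical global (zero-mode) timescale: 93.9 ms
zero-lag CC by Chebyshev distance: d=1: 0.242, d=3: 0.050, d=5: 0.012
```

The fast AC component sits at the self-excitation timescale; the slow
component is the weighted average of the spatial-interaction modes and lies
between τ_self and τ_global; cross-correlations decay with lattice distance
— the signature of spatially structured (rather than random) connectivity.

`examples/fit_timescales_abc.py` recovers known timescales from synthetic
spike counts (truth τ = (5, 115) ms, c1 = 0.4, α = 1):

```
MAP: tau1=5.16, tau2=122.45, c1=0.35, alpha=1.13
tau1: median 6.0 ms, quartiles [4.4, 7.5] ms
tau2: median 124.7 ms, quartiles [110.1, 145.2] ms
```

The remaining examples cover correlation estimation from a synthetic
session, Bayes-factor model comparison, matching network parameters to
cortical timescale bands, and the full pipeline.

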