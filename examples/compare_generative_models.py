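"""One vs two timescales: Bayes-factor model comparison.

Fits both generative models to data that truly contains two timescales and
compares them through the CDFs of posterior-predictive distances (the ratio
of acceptance rates approximates the Bayes factor). Prints the gate p-value
(rank-sum test), the Bayes-factor range over admissible thresholds, and the
verdict.
"""

import numpy as np

from multitau import aabc, model_select, ou, spikecorr
from multitau.types import DataStats, OUMixtureParams

truth = OUMixtureParams(tau_ms=[20.0, 120.0], coeffs=[0.5, 0.5], alpha=1.0)
stats = DataStats(n_trials=100, window_ms=500.0, bin_ms=2.0,
                  count_mean=2.0, count_variance=6.0)
counts = ou.generate_matched_dataset(truth, stats, seed=7)
ac = spikecorr.windowed_average_autocorrelation(counts)

cfg = aabc.ABCConfig(samples_per_iter=40, max_iterations=3, accR_stop=0.002)
post1 = aabc.abc_fit(ac, stats, "M1", cfg, rng=np.random.default_rng(1))
post2 = aabc.abc_fit(ac, stats, "M2", cfg, rng=np.random.default_rng(2))

d1 = model_select.posterior_predictive_distances(post1, ac, stats, n=200, seed=3)
d2 = model_select.posterior_predictive_distances(post2, ac, stats, n=200, seed=4)
result = model_select.compare_models(d1, d2)
rec = result.as_record()
print(f"median distance M1 = {rec['median_a']:.2e}, M2 = {rec['median_b']:.2e}")
print(f"gate p-value (rank-sum) = {rec['gate_p']:.2e}")
print(f"Bayes factor over admissible thresholds: "
      f"{rec['bf_min']:.1f} .. {rec['bf_max']:.1f}")
print(f"verdict: {result.verdict}")

# With two genuinely distinct timescales the two-timescale model fits
# uniformly better: BF > 1 for every admissible threshold, verdict M2.
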