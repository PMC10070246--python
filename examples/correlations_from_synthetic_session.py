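"""Compute windowed spike-count autocorrelations from a synthetic session.

Builds a small 8-channel session with two attention conditions whose latent
rate carries two timescales (5 and 115 ms), pools spikes across channels,
bins at 2 ms, removes the per-condition trial-average, and prints the
averaged autocorrelation at a few lags together with the session QC verdict.
"""

import numpy as np

from multitau import spikecorr, synthdata

spec = synthdata.SessionSpec(
    session_id="demo",
    n_trials=80,
    trial_ms=500.0,
    n_channels=8,
    conditions={
        "attend_away": {"tau_ms": (5.0, 115.0), "coeffs": (0.4, 0.6), "alpha": 1.0,
                        "rate_mean": 0.25, "rate_var": 0.45},
        "attend_in_covert": {"tau_ms": (5.0, 138.0), "coeffs": (0.4, 0.6), "alpha": 1.0,
                             "rate_mean": 0.25, "rate_var": 0.45},
    },
    seed=1,
)
events, rf_map, manifest = synthdata.make_session(spec)
print(f"session with {len(events)} spikes on {spec.n_channels} channels")

counts = spikecorr.bin_and_pool(events, bin_ms=2.0, window_ms=500.0)
centered = spikecorr.subtract_condition_mean(counts)
for cond in sorted(manifest["conditions"]):
    ac = spikecorr.windowed_average_autocorrelation(centered, condition=cond)
    keep = spikecorr.session_qc(ac)
    lags = [0, 2, 10, 50, 100]
    vals = ", ".join(f"AC({t} ms)={ac.values[int(t // 2)]:.3f}" for t in lags)
    print(f"{cond}: {vals}  QC={'include' if keep else 'exclude'}")

# The drop from AC(0) ~ 1 to AC(2 ms) reflects the count noise (law of total
# variance); the remaining decay mixes the fast (5 ms) and slow (>100 ms)
# latent timescales. Both conditions pass QC: AC stays above 0.01 out to
# 20 ms.
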