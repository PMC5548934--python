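"""Simulate the four-construct photobleach panel and estimate mobility.

21 cells per construct, 2% relative noise.  The estimators recover each
trace's recovery rate (mono-exponential fit per bleach cycle) and residual
fluorescence (end-of-protocol signal relative to the pre-bleach baseline).
"""

import numpy as np

from satb2phenomics import (
    construct_panel,
    estimate_trace,
    simulate_flip,
    summarize_constructs,
)

rng = np.random.default_rng(7)
estimates = []
for construct, params in construct_panel(noise_sd=0.02).items():
    for i in range(21):
        trace = simulate_flip(params, seed=int(rng.integers(2**31)),
                              cell_id=f"{construct}_{i}", construct=construct)
        estimates.append(estimate_trace(trace))

summary = summarize_constructs(estimates, min_n=21)
print(summary[["construct", "n", "k_rec_mean", "residual_mean",
               "residual_rank"]].to_string(index=False))
# The CUT1 missense analog (mobile fraction 0.8) keeps the highest residual
# fluorescence with a near-wild-type recovery rate; the CUT2 and
# inter-domain analogs (mobile fraction 0.2) lose the most fluorescence and
# recover slowest — the mutation-dependent mobility signature.
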