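#!/usr/bin/env python
"""Streptavidin label-count histograms and zero-truncated Poisson fits.

Each A tile carries one biotin, so the label count per detected filament
follows a zero-truncated Poisson whose mean tracks [M]0/[I]0.  At ratio 1 the
fraction of singly-labeled filaments is the stoichiometric signature of the
I-A-B complex.  Writes results/label_poisson_fits.csv.
"""

import math
from pathlib import Path

import pandas as pd

from dhtpoly import SimParams, fit_poisson, label_counts, simulate_living

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

rows = []
for r in (1, 2, 5, 10):
    pop = simulate_living(SimParams(ratio_MI=r, n_initiators=10_000, seed=900 + r))
    hist = label_counts(pop, labeling_efficiency=1.0, truncated=True)
    fit = fit_poisson(hist)
    rows.append({
        "ratio_MI": r,
        "n_detected": hist.n,
        "lambda_hat_ZT": fit.lambda_hat,
        "loglik": fit.log_likelihood,
        "pct_single_label": 100.0 * hist.counts.get(1, 0) / hist.n,
    })
df = pd.DataFrame(rows)
df.to_csv(RESULTS / "label_poisson_fits.csv", index=False)
print(df.to_string(index=False, float_format=lambda x: f"{x:.3f}"))

closed = 100.0 * math.exp(-1) / -math.expm1(-1)
print(f"\nratio-1 single-label fraction: {df.iloc[0]['pct_single_label']:.1f}% "
      f"(zero-truncated Poisson(1) closed form {closed:.1f}%; "
      f"AFM measurement reports 62%)")
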