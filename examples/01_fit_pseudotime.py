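"""Fit pseudotimes to a small marker panel and inspect the gene parameters.

Simulates a 60-cell, 6-gene panel (4 switch-like, 2 transient genes) from
the generative model, normalizes it, runs the variational backend, and
prints the recovered trajectory quality and per-gene regulation times.
"""

import numpy as np

from markertime import (
    SimulationConfig,
    compute_size_factors,
    fit_vi,
    normalize_expression,
    simulate_dataset,
    summarize_fit,
)

ds = simulate_dataset(SimulationConfig(n_cells=60, n_genes=6,
                                       frac_switch=4 / 6, seed=42))
Yn = normalize_expression(ds.Y, compute_size_factors(ds.Y))

fit = fit_vi(Yn, ds.true_behaviours, seed=42)
summary = summarize_fit(fit)

r = np.corrcoef(fit.pseudotime_mean, ds.true_t)[0, 1]
print(f"|Pearson r| between inferred and true pseudotimes: {abs(r):.3f}")
print("\nPer-gene regulation times (posterior mean and 95% HPD):")
times = summary.parameters.query("parameter in ('t0', 'p')")
for _, row in times.iterrows():
    print(f"  {row.gene_id} ({row.parameter}): "
          f"{row['mean']:.2f}  [{row.lower:.2f}, {row.upper:.2f}]")
print("\nA high |r| means the ordering is recovered despite dropout and")
print("dispersed noise; t0/p locate each gene's switch or peak along [0,1).")
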