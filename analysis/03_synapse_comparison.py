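"""Simulate synaptic input populations from decoder weights and compare
their tuning with the decoder output.

For each population kind, repeatedly (200 runs): build a fresh N = 1000
input population with c_o = 0.20, derive analytic weights, resample the
positive weights of the 0-degree decoder neuron into 100 synapses,
simulate 10 noisy trials per orientation on the 22.5-degree grid, and
compute per-synapse Pearson correlations with the decoder output plus
variability and selectivity statistics.  Findings: homogeneous inputs
give tightly co-tuned synapses (pooled median r ~ 0.66), heterogeneous
inputs give diverse ones (~0.19) with a positive bias; null-orientation
trial variability sits below preferred-orientation variability; synapses
more correlated with the output are not more direction-selective.
"""

from pathlib import Path

import pandas as pd

from popdecode.compare import (
    pca_slope_bootstrap,
    run_model_comparison,
    summarize_variability,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(parents=True, exist_ok=True)

results = run_model_comparison(n_runs=200, master_seed=303)

rows = []
for kind, res in results.items():
    res.per_input_r.to_csv(OUT / f"per_synapse_{kind}.csv", index=False)
    res.per_cell.to_csv(OUT / f"per_cell_{kind}.csv", index=False)
    row = {"kind": kind, "pooled_median_r": res.pooled_median_r,
           "per_cell_median_r": res.per_cell_median_r}
    row.update(summarize_variability(res.variability))
    df = res.per_input_r.dropna(subset=["r", "direction_vector_strength"])
    slope, se = pca_slope_bootstrap(
        df["r"].to_numpy(), df["direction_vector_strength"].to_numpy(),
        n_boot=2000, seed=304)
    row.update(pca_slope=slope, pca_slope_se=se)
    rows.append(row)
    print(f"{kind}: pooled median r = {res.pooled_median_r:.3f}, "
          f"per-cell median = {res.per_cell_median_r:.3f}, "
          f"null/pref s.d. = {row['median_null']:.3f}/"
          f"{row['median_preferred']:.3f}, "
          f"PCA slope = {slope:.4f} +- {se:.4f}")

pd.DataFrame(rows).to_csv(OUT / "comparison_summary.csv", index=False)
print(f"wrote comparison tables under {OUT}")
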