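"""Input-output tuning comparison statistics.

Compares the orientation tuning of a neuron's inputs (simulated synapses or
imaged dendritic spines) with its output tuning (decoder readout or somatic
response): per-input Pearson tuning correlations and their distributions,
Kullback-Leibler divergence between correlation histograms as a
model-identification statistic, the major-axis (PCA) slope between
input-output correlation and input selectivity, and trial-to-trial
variability at preferred versus null orientations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._seeding import derive_seed, rng_from
from .decoder import derive_weights
from .population import PopulationSpec, make_population
from .spines import normalize_spine_responses, vector_strength
from .synapses import (
    EXPERIMENTAL_GRID,
    direction_mean_curves,
    sample_synapses,
    simulate_synaptic_trials,
    weights_to_frequency,
)

__all__ = [
    "ComparisonResult",
    "tuning_correlation",
    "correlation_distribution",
    "correlation_histogram",
    "kl_divergence",
    "pca_slope_bootstrap",
    "variability_by_orientation",
    "simulate_comparison_cell",
    "run_model_comparison",
]

#: Histogram bin width for correlation distributions (domain [-1, 1]).
DEFAULT_BIN_SIZE = 0.05


@dataclass
class ComparisonResult:
    """Summary of one model-vs-model (or data-vs-model) comparison run."""

    per_input_r: pd.DataFrame       # cell, input, r, vector_strength, ...
    per_cell: pd.DataFrame          # cell, mean_r, n_inputs
    pooled_median_r: float
    per_cell_median_r: float
    variability: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def tuning_correlation(input_curve, output_curve) -> float:
    """Pearson correlation between trial-averaged input and output tuning.

    Undefined (raises) when either curve has zero variance; callers
    typically catch this and exclude the input from distributions.
    """
    x = np.asarray(input_curve, float)
    y = np.asarray(output_curve, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length curves with >= 3 stimuli")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("tuning correlation undefined for a zero-variance "
                         "curve")
    return float(stats.pearsonr(x, y).statistic)


def correlation_distribution(input_curves, output_curve) -> tuple[np.ndarray, int]:
    """Per-input tuning correlations against one output curve.

    Returns the array of valid correlations and the number of inputs
    excluded for zero variance.
    """
    curves = np.asarray(input_curves, float)
    rs, excluded = [], 0
    for row in curves:
        try:
            rs.append(tuning_correlation(row, output_curve))
        except ValueError:
            excluded += 1
    return np.asarray(rs), excluded


def correlation_histogram(r_values, bin_size: float = DEFAULT_BIN_SIZE,
                          pseudocount: float = 1.0) -> np.ndarray:
    """Probability histogram of correlations over [-1, 1].

    A pseudocount is added to every bin before normalization so that the
    Kullback-Leibler divergence between any two histograms is finite.
    """
    edges = np.arange(-1.0, 1.0 + bin_size / 2, bin_size)
    counts, _ = np.histogram(np.asarray(r_values, float),
                             bins=edges, range=(-1.0, 1.0))
    counts = counts.astype(float) + pseudocount
    return counts / counts.sum()


def kl_divergence(hist_p, hist_q) -> float:
    """``D_KL(p || q) = sum p ln(p/q)`` in nats for probability histograms.

    Both histograms must share the same binning; the convention throughout
    the pipeline is data (or test cell) as p and model as q.
    """
    p = np.asarray(hist_p, float)
    q = np.asarray(hist_q, float)
    if p.shape != q.shape:
        raise ValueError("histograms must share binning")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("histograms must be nonnegative")
    if not (np.isclose(p.sum(), 1.0) and np.isclose(q.sum(), 1.0)):
        raise ValueError("histograms must each sum to 1")
    mask = p > 0
    if np.any(q[mask] == 0):
        raise ValueError("q has zero mass where p is positive; apply a "
                         "pseudocount")
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def pca_slope_bootstrap(x, y, n_boot: int = 1000, seed: int = 0
                        ) -> tuple[float, float]:
    """Major-axis slope between two variables, with bootstrap s.e.

    The slope is the direction of the first principal component of the
    centered (x, y) cloud, expressed as dy/dx with the component oriented
    to have a positive x-loading.  The standard error comes from
    resampling points with replacement.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired points")
    if n_boot < 100:
        raise ValueError("need n_boot >= 100")
    if np.allclose(x, x[0]) and np.allclose(y, y[0]):
        raise ValueError("degenerate point cloud")

    def major_axis_slope(xv, yv):
        pts = np.column_stack([xv - xv.mean(), yv - yv.mean()])
        cov = pts.T @ pts / max(len(xv) - 1, 1)
        evals, evecs = np.linalg.eigh(cov)
        v = evecs[:, np.argmax(evals)]
        if v[0] < 0:
            v = -v
        if v[0] == 0:
            return np.inf
        return v[1] / v[0]

    slope = major_axis_slope(x, y)
    rng = rng_from(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    boots = np.array([major_axis_slope(x[i], y[i]) for i in idx])
    finite = boots[np.isfinite(boots)]
    se = float(finite.std(ddof=1)) if finite.size > 1 else np.nan
    return float(slope), se


def variability_by_orientation(trial_responses, preferred_indices,
                               grid=None) -> pd.DataFrame:
    """Trial-to-trial s.d. at each input's preferred and null orientation.

    ``trial_responses`` is trials x K x n_inputs, already peak-normalized
    per input.  For each input, the null stimulus is 90 degrees from its
    preferred (half the grid away).  Returns per-input s.d. values; use
    :func:`summarize_variability` for medians/IQR and the rank-sum test.
    """
    r = np.asarray(trial_responses, float)
    if r.ndim != 3 or r.shape[0] < 2:
        raise ValueError("need trials x K x n_inputs with >= 2 trials")
    k = r.shape[1]
    pref = np.asarray(preferred_indices, int)
    null = (pref + k // 2) % k
    n_inputs = r.shape[2]
    sd_pref = np.array([r[:, pref[i], i].std(ddof=1)
                        for i in range(n_inputs)])
    sd_null = np.array([r[:, null[i], i].std(ddof=1)
                        for i in range(n_inputs)])
    return pd.DataFrame({
        "input": np.arange(n_inputs),
        "pref_index": pref,
        "null_index": null,
        "sd_preferred": sd_pref,
        "sd_null": sd_null,
    })


def summarize_variability(var_df: pd.DataFrame) -> dict:
    """Medians/IQR of preferred and null s.d. plus a rank-sum statistic."""
    sd_p = var_df["sd_preferred"].to_numpy()
    sd_n = var_df["sd_null"].to_numpy()
    test = stats.mannwhitneyu(sd_n, sd_p, alternative="less")
    iqr = lambda v: float(np.subtract(*np.percentile(v, [75, 25])))  # noqa: E731
    return {
        "median_null": float(np.median(sd_n)),
        "iqr_null": iqr(sd_n),
        "median_preferred": float(np.median(sd_p)),
        "iqr_preferred": iqr(sd_p),
        "rank_sum_p": float(test.pvalue),
    }


def simulate_comparison_cell(kind: str, seed: int, *,
                             n_neurons: int = 1000,
                             max_correlation: float = 0.20,
                             n_synapses: int = 100,
                             n_trials: int = 10,
                             decoder_pref: float = 0.0) -> pd.DataFrame:
    """One simulated 'cell': population -> weights -> synapses -> trials.

    Builds a fresh input population of the given kind, derives analytic
    weights on the 22.5-degree experimental grid, resamples the positive
    weights of the decoder neuron preferring ``decoder_pref`` into a
    synaptic population, simulates noisy trials, and returns a per-synapse
    table with tuning correlation against the decoder output, vector
    strength, and normalized preferred/null trial s.d.
    """
    pop_seed = derive_seed(seed, "cell-pop")
    syn_seed = derive_seed(seed, "cell-syn")
    trial_seed = derive_seed(seed, "cell-trials")
    spec = PopulationSpec(
        n_neurons=n_neurons, kind=kind, max_correlation=max_correlation,
        n_stimuli=EXPERIMENTAL_GRID.size, seed=pop_seed)
    pop = make_population(spec)
    w = derive_weights(pop)
    k0 = w.class_index(decoder_pref)
    probs = weights_to_frequency(w.weights[k0])
    syn = sample_synapses(pop, probs, n_syn=n_synapses, seed=syn_seed,
                          weights=w, class_index=k0)
    syn = simulate_synaptic_trials(syn, pop, n_trials=n_trials,
                                   seed=trial_seed)
    dir_seed = derive_seed(seed, "cell-dir")
    dir_grid, dir_curves = direction_mean_curves(syn, pop,
                                                 n_trials=n_trials,
                                                 seed=dir_seed)
    dir_rad = np.deg2rad(dir_grid)

    out_curve = syn.decoder_output_tuning
    kgrid = syn.stimulus_grid.size
    rows = []
    for i in range(syn.n_synapses):
        trials_i = syn.trial_responses[:, :, i]
        mean_curve = trials_i.mean(axis=0)
        try:
            r = tuning_correlation(mean_curve, out_curve)
        except ValueError:
            r = np.nan
        pref_idx = int(np.argmax(mean_curve))
        null_idx = (pref_idx + kgrid // 2) % kgrid
        peak = mean_curve[pref_idx]
        if peak > 0:
            norm_trials, _ = normalize_spine_responses(trials_i)
            sd_pref = float(norm_trials[:, pref_idx].std(ddof=1))
            sd_null = float(norm_trials[:, null_idx].std(ddof=1))
        else:
            sd_pref = sd_null = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                vs = vector_strength(mean_curve, syn.stimulus_grid)
            except ValueError:
                vs = np.nan
        # selectivity on the direction circle, as measured in the imaging
        # experiment (16 drifting-grating directions); orientation-symmetric
        # tuning cancels and only trial noise contributes
        md = np.maximum(dir_curves[i], 0.0)
        total = md.sum()
        dir_vs = (np.abs(np.sum(md * np.exp(1j * dir_rad))) / total
                  if total > 0 else np.nan)
        rows.append({
            "synapse": i,
            "source": int(syn.source_indices[i]),
            "r": r,
            "vector_strength": vs,
            "direction_vector_strength": dir_vs,
            "sd_preferred": sd_pref,
            "sd_null": sd_null,
        })
    df = pd.DataFrame(rows)
    df.insert(0, "kind", kind)
    df.insert(1, "cell_seed", seed)
    return df


def run_model_comparison(kinds=("homogeneous", "heterogeneous"),
                         n_runs: int = 200, master_seed: int = 0,
                         **cell_kwargs) -> dict[str, ComparisonResult]:
    """Repeated-cell comparison for each population kind.

    Each run simulates one decoder neuron ('cell') end to end.  Returns,
    per kind, the pooled per-synapse correlations, per-cell means, and the
    variability summary.
    """
    results: dict[str, ComparisonResult] = {}
    for kind in kinds:
        tables = []
        for j in range(n_runs):
            seed = derive_seed(master_seed, f"compare-{kind}", j)
            tables.append(simulate_comparison_cell(kind, seed, **cell_kwargs))
        per_input = pd.concat(tables, ignore_index=True)
        valid = per_input.dropna(subset=["r"])
        per_cell = (valid.groupby("cell_seed", as_index=False)
                    .agg(mean_r=("r", "mean"), n_inputs=("r", "size")))
        var_df = per_input.dropna(subset=["sd_preferred", "sd_null"])
        results[kind] = ComparisonResult(
            per_input_r=per_input,
            per_cell=per_cell,
            pooled_median_r=float(valid["r"].median()),
            per_cell_median_r=float(per_cell["mean_r"].median()),
            variability=var_df[["sd_preferred", "sd_null"]].reset_index(
                drop=True),
            extras={"n_runs": n_runs,
                    "n_excluded": int(per_input["r"].isna().sum())},
        )
    return results
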