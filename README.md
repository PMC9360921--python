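# popdecode

Probabilistic population decoding of stimulus orientation, and the mapping
from decoder weights to the excitatory synaptic inputs of single cortical
neurons.

Cortical neurons receive thousands of excitatory synapses whose sensory
tuning is surprisingly diverse — many inputs prefer orientations far from
the cell's own preference. `popdecode` asks whether that diversity is what
an *optimal readout* of a realistic upstream population would look like. It
is written for computational neuroscientists who want to simulate
orientation-tuned input populations, derive maximum-likelihood readout
weights, resample those weights into synthetic "synaptic" input
populations, and compare their tuning statistics with dendritic-spine
calcium-imaging data.

## The model

An input population of N neurons encodes orientation θ with tuning curves

    f_i(θ) = α_i + β_i · exp(κ_i (cos²(θ − φ_i) − 1))

(α baseline, β tuned amplitude, κ concentration, φ preference; 180°
periodic) plus additive Gaussian noise with limited-range correlations:
corr(i, j) = c_o·exp(−|δ(φ_i, φ_j)|) with δ the circular orientation
difference in radians, scaled by each neuron's mean rate so that variance
equals mean (Poisson-like noise), giving a stimulus-independent covariance
Q. Populations are either *homogeneous* — shifted copies of one curve,
(α, β, κ) = (0, 5, 4) — or *heterogeneous*, with half-widths γ (defined at
1/√2 of peak height, κ = ln2 / (2 sin²γ)) drawn lognormal(μ = −1, σ = 0.6)
and V1-like amplitude/baseline variation.

For K discrete orientations the maximum-likelihood decoder is a softmax of
linear readouts,

    p(θ_k | R) = exp(Rᵀw_k + β_k) / Σ_i exp(Rᵀw_i + β_i),
    w_k = Q⁻¹ f(θ_k),      β_k = −½ f(θ_k)ᵀ Q⁻¹ f(θ_k) + ln p(θ_k),

so every decoder neuron is defined by a weight vector over the input
population. Treating positive weights as a frequency distribution of
fixed-size synapses turns a decoder neuron into a synthetic synaptic input
population that can be analyzed exactly like imaged dendritic spines
(22.5° stimulus grid, ~10 noisy trials, peak normalization, Pearson
correlation of input vs output tuning, Kullback–Leibler model comparison).

The package also contains a synthetic two-photon spine-imaging generator
and the matching preprocessing pipeline (back-propagating-action-potential
subtraction by robust regression, SNR/median-absolute-deviation and
dendrite-correlation inclusion filters, wrapped-Gaussian tuning fits,
vector-strength selectivity), validated end to end by parameter recovery.

## Worked example

```python
from popdecode import (PopulationSpec, make_population, derive_weights,
                       weights_to_frequency, sample_synapses,
                       simulate_synaptic_trials, tuning_correlation)

pop = make_population(PopulationSpec(
    n_neurons=1000, kind="heterogeneous", max_correlation=0.20,
    n_stimuli=8, seed=1))
w = derive_weights(pop)                      # w_k = Q^-1 f(theta_k)
k0 = w.class_index(0.0)                      # decoder neuron preferring 0 deg
probs = weights_to_frequency(w.weights[k0])  # positive weights -> frequencies
syn = sample_synapses(pop, probs, n_syn=100, seed=2, weights=w,
                      class_index=k0)
syn = simulate_synaptic_trials(syn, pop, n_trials=10, seed=3)
r = [tuning_correlation(syn.trial_responses[:, :, i].mean(axis=0),
                        syn.decoder_output_tuning)
     for i in range(syn.n_synapses)]
```

The analysis drivers under `analysis/` run the three main experiments and
print their findings; `python analysis/03_synapse_comparison.py` (200
simulated cells per population kind, a few minutes on one CPU) prints

```
homogeneous: pooled median r = 0.667, per-cell median = 0.542, null/pref s.d. = 0.063/0.429, PCA slope = -0.0003 +- 0.0007
heterogeneous: pooled median r = 0.191, per-cell median = 0.213, null/pref s.d. = 0.170/0.340, PCA slope = 0.0136 +- 0.0005
```

i.e. reading out a homogeneous population requires tightly co-tuned
excitatory inputs (pooled median input–output tuning correlation ≈ 0.67),
while the optimal readout of a realistic heterogeneous population recruits
functionally diverse inputs (≈ 0.19, with a positive bias); trial-to-trial
variability of the simulated inputs is lower at the null orientation than
at the preferred; and inputs more correlated with the output are no more
direction-selective (major-axis slope ≈ 0). `analysis/02_accuracy_sweep.py`
shows decoder accuracy growing with population size without noise
correlations, saturating for homogeneous populations once limited-range
correlations are present (gain 1.2–1.4 from N = 128 to 512) while
heterogeneous populations keep improving (gain 4–8), and collapsing when
heterogeneous weights are forcibly smoothed.

## Real imaging data

Recorded spine datasets are not bundled. The pipeline accepts user-supplied
recordings in the documented tidy-CSV schema (one cell per file stem, read
by `popdecode.io.read_spine_dataset`):

- `<stem>.responses.csv` — `spine_id, stimulus_deg, trial, response`
- `<stem>.blanks.csv` — `spine_id, sample, response` (blank-period samples)
- `<stem>.dendrite.csv` — `trial, stimulus_deg, response`
- `<stem>.truth.json` — stimulus grid, somatic tuning and (for synthetic
  data) generator ground truth

A `popdecode` CLI exposes the stages (`make-population`, `derive-weights`,
`smooth`, `sweep`, `sample-synapses`, `make-spines`, `qc`, `fit-tuning`,
`compare`, `run`); `popdecode run --config cfg.yaml --out dir` executes a
named experiment end to end and writes a replayable JSON manifest.
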