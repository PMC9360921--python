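# Methods

This note documents the models, estimators and numerical choices behind
`popdecode`, and what the synthetic-data experiments do and do not
establish.

## Encoding model

Each input neuron's mean response to orientation θ (degrees) is

    f_i(θ) = α_i + β_i exp(κ_i (cos²(θ − φ_i) − 1))
           = α_i + β_i exp(−κ_i sin²(θ − φ_i)),

which is 180°-periodic, peaks at α + β at θ = φ, and falls to
α + β e^{−κ} at the orthogonal orientation. Angles are stored in degrees
and converted to radians only inside trig calls. Tuning half-widths γ are
defined at 1/√2 of the tuned peak; the conversion
κ = ln2 / (1 − cos 2γ) = ln2 / (2 sin²γ) makes that definition exact under
the tuning curve above (e^{−κ sin²γ} = 2^{−1/2}).

Trial variability is additive multivariate Gaussian. The correlation
kernel is limited-range: C_ij = c_o e^{−δ_ij} off the diagonal, C_ii = 1,
with δ_ij ∈ [0, π/2] the circular orientation difference in radians
(computed on doubled angles and halved; the same metric is used by the
smoothing kernel). The covariance scales correlations by stimulus-averaged
mean rates, Q_ij = C_ij √(μ_i μ_j), so each variance equals its mean rate
(Poisson-like) while remaining stimulus-independent — the assumption that
makes the decoder linear. Rates below 10⁻³ are floored before scaling;
if a Cholesky factorization still fails, diagonal jitter of
10⁻⁸·trace/N is added and logged.

Population kinds:

- **homogeneous** — all neurons share (α, β, κ) = (0, 5, 4) (half-width
  ≈ 25°), preferences tiled uniformly over [−90°, 90°).
- **heterogeneous** — γ ~ lognormal(μ = −1, σ = 0.6) *in radians* (median
  ≈ 21°), converted to κ; β ~ lognormal with median 5 and log-σ 0.5;
  α ~ exponential with mean 0.5; φ uniform. The amplitude and baseline
  distributions are not constrained by any published value we rely on;
  they were fixed once as a qualitative match to V1 diversity (peak rates
  spanning roughly an order of magnitude, small but nonzero baselines)
  and are configurable in `PopulationSpec`.

## Decoder

With uniform prior the maximum-likelihood readout is the softmax of
R ᵀw_k + β_k with w_k = Q⁻¹f(θ_k) and
β_k = −½ f(θ_k)ᵀQ⁻¹f(θ_k) + ln p(θ_k). Weights are obtained by a
Cholesky-backed linear solve (never an explicit inverse); every row must
satisfy ‖w_k Q − f(θ_k)‖∞ / ‖f‖∞ < 10⁻⁸ or the derivation raises. The
softmax subtracts the max logit per trial. MAP ties break to the lowest
class index. Decoding error wraps the estimate−truth difference on the
orientation circle by angle doubling, err = (½ angle(e^{2iΔ}))² ∈
[0, (π/2)²]; with θ restricted to ±90° this differs from the unwrapped
convention only at wrap-around, and the wrapped form respects orientation
periodicity.

The same weights can be recovered numerically by multinomial logistic
regression on simulated trials (scikit-learn, lbfgs, light ridge for
identifiability); on small populations the two decoders agree in MAP label
on >99% of held-out trials, which the tests use as an independent check of
the analytic route.

**Smoothing penalty.** The smoothness manipulation is parameterized by a
prior kernel over neuron pairs, S⁺_ij = e^{−(ρ₁ + δ_ij/ρ₂)}; its
pseudoinverse acts as a smoothness precision, and weight rows pass through
the row-normalized ridge smoother (I + pinv(S⁺))⁻¹. Rough weight
components have near-zero prior variance under the kernel and are shrunk
away; row normalization preserves constant profiles. ρ₁ scales the overall
strength and ρ₂ the range of smoothing; (0, 0) is the no-smoothing
sentinel. How the kernel combines with the weights is a genuine design
choice (a direct application of the row-normalized pseudoinverse sharpens
rather than smooths); the ridge form was chosen because it yields strictly
decreasing high-frequency content across the parameter sets (0.1, 1) →
(0.2, 2) → (1, 10) used in the smoothing experiments.

**Accuracy sweeps** build a fresh population per cell, derive (and
optionally smooth) weights, and evaluate inverse mean-squared MAP error on
freshly seeded held-out trials (cross-validation by construction: weights
come from population parameters, never from evaluation trials). Default
problem sizes: K = 64 stimulus classes and 50 evaluation trials per class
for sweeps (a finer grid than the K = 16 default elsewhere, chosen so the
discrete MAP error stays informative at N = 512 — with coarse classes
large populations decode perfectly and the inverse error diverges); N up
to 512; 8 seeds per cell with standard errors reported. Performance is
1/max(MSE, 10⁻¹²).

## From weights to synapses

Under linear integration, synapse size and count trade off, so a decoder
neuron's nonnegative weight profile is converted to a sampling
distribution: negative and zero weights map to probability 0, positive
weights are normalized to sum 1, and 100 synapses are drawn i.i.d. with
replacement (duplicates are legitimate — two equal synapses equal one of
double weight). Each synapse inherits its source neuron's tuning evaluated
on the experimental 22.5° grid (8 orientations). Trials add independent
Gaussian noise per synapse with variance equal to the mean rate at that
stimulus (the same Poisson-like mean–variance relation as the population,
evaluated at stimulus resolution; floored at 10⁻³). A fixed-σ noise mode
exists as an orientation-independent control, and correlated draws via the
population correlation matrix are available behind a flag; the comparison
statistics are per-synapse marginals, so independence is the default.

The decoder neuron's own output tuning is the softmax posterior of its
class as the noiseless population response sweeps the stimulus grid. For
N = 1000 the posterior saturates (≈ one-hot); because Pearson correlation
is affine-invariant, trial-noisy or rectified-linear output variants give
identical correlation statistics, so this choice is not load-bearing.

## Synthetic spine datasets and preprocessing

The generator emulates the *structure* of a single-cell two-photon
experiment: 8 orientations at 22.5°, 8–10 trials, ΔF/F-like responses for
~159 spines, blank-period samples of pure baseline noise, and a shared
dendritic signal (somatic tuning with trial-gain variability) that leaks
into each spine in proportion to a per-spine contamination factor. Spine
tuning is wrapped-Gaussian with a mixture of soma-clustered and uniform
preferences. All generating parameters are recorded as ground truth.

It does **not** emulate raw movies, motion artifacts, ROI cross-talk,
indicator nonlinearity, or slow baseline drift — so passing recovery tests
show the estimators are correct under the generative model, not that they
are robust to every imaging pathology.

Pipeline stages and their numerical choices:

- **bAP subtraction.** The contamination scale is a Theil–Sen slope of
  spine on dendrite computed on within-stimulus trial fluctuations
  (per-stimulus means removed from both signals): bAP coupling transmits
  trial-to-trial dendritic fluctuations, whereas tuning similarity lives
  in the stimulus means, so a co-tuned but clean spine is not
  over-subtracted. The slope is clipped at 0; a constant dendrite gives
  scale 0. Recovery at SNR 3: median |error| < 0.1 for a true scale 0.5.
- **Inclusion filter.** SNR: the maximum trial-mean response after
  subtraction must exceed blank median + 2·MAD (MAD unscaled — no 1.4826
  consistency factor, per the plain criterion). Dendrite coupling:
  Spearman correlation between the raw spine and dendrite signals,
  dropping samples where the corrected trace is negative
  (post-subtraction negative events are artifacts), must be < 0.4. A
  spine that is a copy of the dendrite fails this even after perfect
  subtraction. Fewer than 3 usable samples → indeterminate, excluded.
- **Tuning fits.** Wrapped-Gaussian (baseline + amp·exp(−d²/2w²), d the
  wrapped orientation difference) by bounded nonlinear least squares,
  multi-started from every grid orientation; the converged flag is
  honest, and non-convergence falls back to the circular-mean preference.
  Width is bounded to [4°, 90°].
- **Selectivity.** Vector strength |Σ r e^{2iθ}|/Σr on doubled angles
  (orientation domain, 0 flat → 1 single-orientation); negative mean
  responses are floored at 0 with a warning. For the
  selectivity-vs-correlation slope the direction-circle variant (16
  grating directions, no doubling) is used, matching how drifting-grating
  experiments measure it; an orientation-symmetric response has an
  exactly cancelling direction resultant, so model selectivity there is
  noise-driven — which is why that slope is ≈ 0.
- **Normalization.** Trial responses are divided by the peak of the
  trial-mean curve (peak = 1), giving each spine equal weight;
  normalization commutes with trial averaging.

## Comparison statistics

Input–output tuning correlation is the Pearson correlation of
trial-averaged input and output curves; zero-variance curves are excluded
with counts logged. Distributions are binned over [−1, 1] with width 0.05
and one pseudocount per bin before normalization, so the Kullback–Leibler
divergence D(p‖q) = Σ p ln(p/q) (data or test cell as p, model reference
as q, consistently) is always finite. Model identification (which
population kind a cell's correlation histogram is closer to) is robust to
bin widths from 0.01 to 0.20 in the tests. The "PCA slope" is the
major-axis (total-least-squares) slope of the centered point cloud, first
principal component oriented with positive x-loading, with a bootstrap
standard error over input resampling (1000–2000 replicates at desk
scale). Null-vs-preferred variability takes, per input, the trial s.d. of
peak-normalized responses at its preferred stimulus (argmax of the
trial-mean curve) and at the stimulus 90° away, and reports population
medians, IQRs, and a rank-sum comparison.

## Replication scale and seeds

The full synapse comparison uses 200 simulated decoder neurons ("cells")
per population kind — 20,000 synapses pooled — for stable medians at
desk scale (each run is one 1000×1000 Cholesky solve plus sampling; the
whole comparison takes about a minute on one CPU). Every stochastic stage
takes an explicit seed derived from a master seed by SHA-256 over
(master, stage, counter), kept below 2³¹; a run manifest records all of
them, and identical configurations reproduce artifacts byte-for-byte
(floats serialized at 17 significant digits, re-parsed with round-trip
precision).

## Known limitations

- The equal-covariance Gaussian assumption is what makes the readout
  linear; stimulus-dependent covariance (and the quadratic readout it
  implies) is out of scope.
- Responses are unrectified Gaussian by default; true Poisson or
  rectified noise would change the variability statistics at low rates.
- The heterogeneous amplitude/baseline distributions are package choices
  (see above). The null-orientation variability of simulated synapses is
  particularly sensitive to the baseline distribution: with small
  baselines, null-orientation rates — and hence Poisson-like null
  variance — stay low. The preferred-orientation variability and the
  null < preferred ordering are robust to this choice; the absolute null
  median is not.
- Sampling-with-replacement treats synapses as exchangeable; dendritic
  placement, clustering and size heterogeneity are not modeled.
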