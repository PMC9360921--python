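"""From decoder weights to an excitatory synaptic input population (P_SYN).

Under linear synaptic integration, two equal synapses are equivalent to one
of double the weight, so a nonnegative weight profile over the input
population can be re-expressed as a *frequency distribution* of fixed-size
synapses: inputs are resampled with probability proportional to their
positive decoder weight.  Each sampled synapse inherits the tuning curve of
its source neuron, evaluated on the coarse experimental stimulus grid
(22.5-degree increments), and trial responses are simulated with
Poisson-like noise so the synthetic synapses can be analyzed exactly like
imaged dendritic spines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeding import rng_from
from .decoder import DecoderWeights, posterior
from .population import InputPopulation, stimulus_grid

__all__ = [
    "SynapticPopulation",
    "weights_to_frequency",
    "sample_synapses",
    "simulate_synaptic_trials",
    "EXPERIMENTAL_GRID",
]

#: The imaging experiment's stimulus grid: 8 orientations, 22.5-deg steps.
EXPERIMENTAL_GRID = stimulus_grid(8)

#: Variance floor for Poisson-like trial noise (keeps draws well-defined
#: where the tuning curve is numerically zero).
NOISE_VARIANCE_FLOOR = 1e-3

DEFAULT_N_SYNAPSES = 100
DEFAULT_N_TRIALS = 10


@dataclass
class SynapticPopulation:
    """A resampled excitatory input population for one decoder neuron."""

    source_indices: np.ndarray        # n_syn, indices into the population
    tuning_curves: np.ndarray         # n_syn x K_stim mean responses
    stimulus_grid: np.ndarray         # K_stim orientations (deg)
    decoder_output_tuning: np.ndarray  # K_stim readout response
    seed: int
    trial_responses: np.ndarray | None = None  # trials x K_stim x n_syn

    @property
    def n_synapses(self) -> int:
        return self.source_indices.size


def weights_to_frequency(weight_row) -> np.ndarray:
    """Convert one weight row into synapse-sampling probabilities.

    Negative and zero weights (inhibitory / absent inputs) map to
    probability zero; positive weights are normalized to sum to one, so a
    larger excitatory weight means a proportionally greater frequency of
    occurrence among sampled synapses.
    """
    w = np.asarray(weight_row, dtype=float)
    pos = np.clip(w, 0.0, None)
    total = pos.sum()
    if total <= 0:
        raise ValueError(
            "weight row has no positive entries; no excitatory synapses "
            "to sample")
    return pos / total


def decoder_output_tuning(pop: InputPopulation, weights: DecoderWeights,
                          class_index: int, grid=None) -> np.ndarray:
    """Mean readout response of one decoder neuron across stimuli.

    Pushes the noiseless population tuning f(theta) at each grid orientation
    through the decoder softmax and reports the posterior mass of the given
    class — the decoder neuron's output tuning curve.
    """
    grid = np.asarray(EXPERIMENTAL_GRID if grid is None else grid,
                      dtype=float)
    fmat = pop.tuning_at(grid)  # K_stim x N
    post = posterior(weights, fmat)
    return post.probabilities[:, class_index]


def sample_synapses(pop: InputPopulation, probs, n_syn: int = DEFAULT_N_SYNAPSES,
                    grid=None, seed: int = 0,
                    weights: DecoderWeights | None = None,
                    class_index: int | None = None) -> SynapticPopulation:
    """Draw a synaptic population from sampling probabilities.

    Sources are drawn i.i.d. *with replacement* (duplicates are legitimate:
    synapse count and size trade off under linear integration).  Each
    synapse's tuning curve is its source neuron's tuning evaluated on the
    coarse grid.  If ``weights``/``class_index`` are given, the decoder
    neuron's output tuning is attached for input-output comparisons.
    """
    p = np.asarray(probs, dtype=float)
    if n_syn < 1:
        raise ValueError("n_syn must be >= 1")
    if p.ndim != 1 or p.size != pop.n_neurons:
        raise ValueError("probs must be one probability per input neuron")
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("probs must be nonnegative and sum to 1")
    grid = np.asarray(EXPERIMENTAL_GRID if grid is None else grid,
                      dtype=float)
    rng = rng_from(seed)
    sources = rng.choice(pop.n_neurons, size=n_syn, p=p, replace=True)
    tuning = pop.tuning_at(grid).T[sources]  # n_syn x K_stim
    if weights is not None and class_index is not None:
        out_tuning = decoder_output_tuning(pop, weights, class_index, grid)
    else:
        out_tuning = np.full(grid.size, np.nan)
    return SynapticPopulation(
        source_indices=sources,
        tuning_curves=tuning,
        stimulus_grid=grid,
        decoder_output_tuning=out_tuning,
        seed=seed,
    )


def direction_mean_curves(syn: SynapticPopulation, pop: InputPopulation,
                          n_trials: int = DEFAULT_N_TRIALS,
                          seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged responses on the 16-point *direction* grid.

    The imaging experiment presents drifting gratings at 22.5-degree
    increments around the full direction circle; the model's tuning is
    purely orientation-based, so each synapse's mean response is duplicated
    at opposite directions and only trial noise (Poisson-like, independent
    per direction, already averaged over ``n_trials``) breaks the symmetry.
    Returns ``(grid_deg, curves)`` with ``curves`` of shape n_syn x 16.
    Used for direction-circle selectivity indices.
    """
    rng = rng_from(seed)
    dir_grid = np.concatenate([syn.stimulus_grid, syn.stimulus_grid + 180.0])
    tuning = np.concatenate([syn.tuning_curves, syn.tuning_curves], axis=1)
    diag = np.diag(pop.correlation_matrix)[syn.source_indices]
    var = np.maximum(diag[:, None] * tuning, NOISE_VARIANCE_FLOOR)
    sem = np.sqrt(var / n_trials)
    curves = tuning + rng.standard_normal(tuning.shape) * sem
    return dir_grid, curves


def simulate_synaptic_trials(syn: SynapticPopulation, pop: InputPopulation,
                             n_trials: int = DEFAULT_N_TRIALS, seed: int = 0,
                             noise: str = "poisson_like",
                             fixed_sigma: float = 1.0,
                             correlated: bool = False) -> SynapticPopulation:
    """Simulate per-synapse trial responses by adding noise to each tuning
    curve.

    ``noise="poisson_like"`` (default) draws Gaussian noise whose variance
    at each stimulus equals the source neuron's mean rate there (scaled by
    its unit correlation diagonal), floored at a small constant — the same
    mean-variance relationship used for the input population, but evaluated
    at the stimulus-specific rate so variability tracks the tuning curve.
    ``noise="fixed"`` uses a constant standard deviation ``fixed_sigma``
    (an orientation-independent control).  ``correlated=True`` couples
    synapses sharing a source via the population correlation matrix rows;
    by default synapses are independent.
    """
    if n_trials < 2:
        raise ValueError("need n_trials >= 2")
    rng = rng_from(seed)
    tuning = syn.tuning_curves  # n_syn x K
    n_syn, k = tuning.shape
    if noise == "poisson_like":
        diag = np.diag(pop.correlation_matrix)[syn.source_indices]
        var = np.maximum(diag[:, None] * tuning, NOISE_VARIANCE_FLOOR)
        sigma = np.sqrt(var)  # n_syn x K
    elif noise == "fixed":
        sigma = np.full((n_syn, k), float(fixed_sigma))
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    if correlated:
        corr = pop.correlation_matrix[np.ix_(syn.source_indices,
                                             syn.source_indices)]
        chol = np.linalg.cholesky(corr + 1e-8 * np.eye(n_syn))
        z = rng.standard_normal(size=(n_trials, k, n_syn)) @ chol.T
    else:
        z = rng.standard_normal(size=(n_trials, k, n_syn))
    trials = tuning.T[None, :, :] + z * sigma.T[None, :, :]
    return SynapticPopulation(
        source_indices=syn.source_indices,
        tuning_curves=syn.tuning_curves,
        stimulus_grid=syn.stimulus_grid,
        decoder_output_tuning=syn.decoder_output_tuning,
        seed=seed,
        trial_responses=trials,
    )
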