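"""Maximum-likelihood population decoder for orientation.

Under the Gaussian, equal-covariance encoding model the posterior over K
discrete orientations given a population response R is a softmax of linear
readouts,

    p(theta_k | R) = exp(R.T w_k + b_k) / sum_i exp(R.T w_i + b_i)

with closed-form weights and offsets

    w_k = Q^{-1} f(theta_k)
    b_k = -(1/2) f(theta_k).T Q^{-1} f(theta_k) + ln p(theta_k).

Each weight row is the readout of one "decoder neuron" preferring theta_k;
the rows double as candidate synaptic weight profiles over the input
population.  The module also provides a smoothness penalty on weight rows,
a multinomial-logistic numerical route to the same weights, and decoding
accuracy sweeps over population size / correlation / smoothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from ._seeding import derive_seed
from .population import (
    InputPopulation,
    PopulationSpec,
    ResponseSet,
    circular_orientation_difference,
    make_population,
    simulate_responses,
    stimulus_grid,
)

__all__ = [
    "DecoderWeights",
    "PosteriorTable",
    "AccuracyResult",
    "derive_weights",
    "posterior",
    "map_estimate",
    "circular_error",
    "smooth_weights",
    "fit_weights_logistic",
    "accuracy_sweep",
]

#: Relative residual tolerance for the analytic weight solve.
SOLVE_RTOL = 1e-8


@dataclass
class DecoderWeights:
    """Per-stimulus readout weights and offsets over an input population."""

    weights: np.ndarray        # K x N
    offsets: np.ndarray        # K
    prior: np.ndarray          # K, sums to 1
    stimulus_grid: np.ndarray  # K orientations (deg)
    provenance: str = "analytic"  # "analytic" | "logistic" | "smoothed(r1,r2)"

    @property
    def n_classes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[1]

    def class_index(self, theta: float) -> int:
        """Index of the decoder class nearest orientation ``theta`` (deg)."""
        d = circular_orientation_difference(self.stimulus_grid, theta)
        return int(np.argmin(d))


@dataclass
class PosteriorTable:
    """Posterior probabilities per trial and the MAP class indices."""

    probabilities: np.ndarray  # trials x K
    map_indices: np.ndarray    # trials


@dataclass
class AccuracyResult:
    """Decoding accuracy for one sweep cell."""

    per_stimulus_mse: np.ndarray  # K, squared radians on the doubled circle
    mse: float
    performance: float  # 1 / mse
    kind: str = ""
    n_neurons: int = 0
    max_correlation: float = 0.0
    smoothing: tuple[float, float] = (0.0, 0.0)
    seed: int = 0
    extras: dict = field(default_factory=dict)


def _normalize_prior(prior, k: int) -> np.ndarray:
    if prior is None:
        return np.full(k, 1.0 / k)
    p = np.asarray(prior, dtype=float)
    if p.shape != (k,):
        raise ValueError(f"prior must have length {k}")
    if np.any(p < 0) or p.sum() <= 0:
        raise ValueError("prior must be nonnegative with positive mass")
    if not np.isclose(p.sum(), 1.0):
        warnings.warn("prior does not sum to 1; normalizing", stacklevel=3)
        p = p / p.sum()
    return p


def derive_weights(pop: InputPopulation, prior=None) -> DecoderWeights:
    """Analytic maximum-likelihood weights: solve ``Q w_k = f(theta_k)``.

    Uses a Cholesky-backed linear solve (never an explicit inverse) and
    checks the relative residual of every row.
    """
    fmat = pop.mean_response_matrix  # K x N
    k, _ = fmat.shape
    q = pop.covariance_matrix
    p = _normalize_prior(prior, k)
    try:
        cho = linalg.cho_factor(q, lower=True)
    except linalg.LinAlgError as exc:
        cond = np.linalg.cond(q)
        raise np.linalg.LinAlgError(
            f"covariance is not positive definite (cond={cond:.3g}); "
            "cannot derive analytic weights") from exc
    weights = linalg.cho_solve(cho, fmat.T).T  # K x N
    resid = np.abs(weights @ q - fmat).max()
    scale = max(np.abs(fmat).max(), 1.0)
    if resid / scale > SOLVE_RTOL:
        raise np.linalg.LinAlgError(
            f"weight solve residual {resid / scale:.3g} exceeds "
            f"{SOLVE_RTOL:.0e}; covariance too ill-conditioned")
    offsets = -0.5 * np.einsum("kn,kn->k", fmat, weights) + np.log(p)
    return DecoderWeights(
        weights=weights, offsets=offsets, prior=p,
        stimulus_grid=pop.stimulus_grid.copy(), provenance="analytic",
    )


def posterior(weights: DecoderWeights, responses) -> PosteriorTable:
    """Softmax posterior over stimulus classes for response vector(s).

    ``responses`` may be a single length-N vector or a (trials x N) batch.
    The softmax subtracts the max logit per trial for numerical stability.
    """
    r = np.asarray(responses, dtype=float)
    single = r.ndim == 1
    r = np.atleast_2d(r)
    if r.shape[1] != weights.n_neurons:
        raise ValueError(
            f"response length {r.shape[1]} != population size "
            f"{weights.n_neurons}")
    logits = r @ weights.weights.T + weights.offsets[None, :]
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    if single:
        p = p  # keep 2-D; callers index row 0 if needed
    return PosteriorTable(probabilities=p, map_indices=np.argmax(p, axis=1))


def map_estimate(post: PosteriorTable, grid=None) -> np.ndarray:
    """MAP orientation per trial; exact ties break to the lowest index."""
    if grid is None:
        raise ValueError("stimulus grid required to map indices to degrees")
    grid = np.asarray(grid, dtype=float)
    return grid[post.map_indices]


def circular_error(estimates, truths) -> np.ndarray:
    """Squared wrapped orientation error per trial, in squared radians.

    The difference is wrapped on the orientation (180-degree) circle by
    doubling the angle: ``d = 0.5 * angle(exp(2i (est - true)))``, so the
    error lies in [0, (pi/2)^2] with the maximum at orthogonal estimates.
    """
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape:
        raise ValueError("estimates and truths must have the same shape")
    d = 0.5 * np.angle(np.exp(2j * np.deg2rad(est - tru)))
    return d**2


def smooth_weights(weights: DecoderWeights, rho1: float, rho2: float,
                   preferences) -> DecoderWeights:
    """Apply a smoothness penalty over preferred-orientation space.

    The penalty is parameterized by a smooth prior kernel over neuron pairs,

        Splus_ij = exp(-(rho1 + delta(phi_i, phi_j) / rho2)),

    whose pseudoinverse acts as a smoothness precision.  Weight rows are
    passed through the row-normalized ridge smoother
    ``(I + pinv(Splus))^{-1}``: rough components of a weight profile have
    near-zero prior variance under the kernel and are shrunk away, while the
    smooth components (and constants, via the row normalization) survive.
    ``rho1`` scales the overall amplitude of smoothing and ``rho2`` its
    functional range; (0, 0) is the no-smoothing sentinel and returns the
    weights unchanged.
    """
    if rho1 == 0 and rho2 == 0:
        return weights
    if rho1 < 0 or rho2 <= 0:
        raise ValueError("need rho1 >= 0 and rho2 > 0 (or (0,0) for none)")
    phi = np.asarray(preferences, dtype=float)
    if phi.size != weights.n_neurons:
        raise ValueError("need one preferred orientation per neuron")
    delta = circular_orientation_difference(phi[:, None], phi[None, :])
    splus = np.exp(-(rho1 + delta / rho2))
    precision = np.linalg.pinv(splus, rcond=1e-10, hermitian=True)
    smoother = np.linalg.solve(
        np.eye(phi.size) + precision, np.eye(phi.size))
    row_sums = smoother.sum(axis=1, keepdims=True)
    # guard pathological rows; row normalization preserves constant profiles
    row_sums[np.abs(row_sums) < 1e-12] = 1.0
    smoother = smoother / row_sums
    new_w = weights.weights @ smoother.T
    return DecoderWeights(
        weights=new_w,
        offsets=weights.offsets.copy(),
        prior=weights.prior.copy(),
        stimulus_grid=weights.stimulus_grid.copy(),
        provenance=f"smoothed({rho1},{rho2})",
    )


def fit_weights_logistic(responses: ResponseSet, labels=None,
                         ridge: float = 1e-4, prior=None) -> DecoderWeights:
    """Numerical route to the decoder: multinomial logistic regression.

    Flattens the trials x K x N response tensor into (trial, stimulus-label)
    pairs and fits a softmax-linear model with a light ridge penalty for
    identifiability.  Deterministic given the data (lbfgs, fixed start).
    """
    from sklearn.linear_model import LogisticRegression

    r = responses.responses
    n_trials, k, n = r.shape
    x = r.reshape(n_trials * k, n)
    if labels is None:
        y = np.tile(np.arange(k), n_trials)
    else:
        y = np.asarray(labels).ravel()
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 stimulus classes to fit")
    if x.shape[0] < classes.size:
        raise ValueError("need at least as many trials as classes")
    model = LogisticRegression(
        C=1.0 / (ridge * x.shape[0]), solver="lbfgs", max_iter=2000,
        tol=1e-8)
    model.fit(x, y)
    grid = np.asarray(responses.stimulus_grid, dtype=float)
    p = _normalize_prior(prior, classes.size)
    return DecoderWeights(
        weights=model.coef_.copy(),
        offsets=model.intercept_.copy(),
        prior=p,
        stimulus_grid=grid[classes],
        provenance="logistic",
    )


def evaluate_accuracy(pop: InputPopulation, weights: DecoderWeights,
                      n_eval_trials: int, seed: int) -> AccuracyResult:
    """Cross-validated accuracy on freshly simulated held-out trials."""
    rs = simulate_responses(pop, n_eval_trials, seed)
    grid = pop.stimulus_grid
    k = grid.size
    per_stim = np.empty(k)
    for j in range(k):
        post = posterior(weights, rs.responses[:, j, :])
        est = map_estimate(post, weights.stimulus_grid)
        per_stim[j] = circular_error(est, np.full(est.size, grid[j])).mean()
    mse = float(per_stim.mean())
    return AccuracyResult(
        per_stimulus_mse=per_stim,
        mse=mse,
        performance=1.0 / max(mse, 1e-12),
        n_neurons=pop.n_neurons,
        max_correlation=pop.spec.max_correlation,
        kind=pop.spec.kind,
        seed=seed,
    )


def accuracy_sweep(kinds=("homogeneous", "heterogeneous"),
                   n_grid=(8, 32, 128, 512),
                   c_o_grid=(0.0, 0.25, 0.5),
                   smoothing_grid=((0.0, 0.0),),
                   n_stimuli: int = 16,
                   n_eval_trials: int = 100,
                   n_seeds: int = 5,
                   master_seed: int = 0) -> pd.DataFrame:
    """Decoding-performance sweep over population size x correlation x
    smoothing, repeated over seeds.

    Each cell builds a fresh population, derives (and optionally smooths)
    analytic weights, and evaluates inverse mean-squared error on held-out
    simulated trials.  Returns a tidy DataFrame with one row per cell and
    seed; failed cells are recorded with NaN performance and the sweep
    continues.
    """
    rows = []
    counter = 0
    for kind in kinds:
        for c_o in c_o_grid:
            for n in n_grid:
                for rho1, rho2 in smoothing_grid:
                    for s in range(n_seeds):
                        counter += 1
                        pop_seed = derive_seed(master_seed, "sweep-pop", counter)
                        eval_seed = derive_seed(master_seed, "sweep-eval", counter)
                        row = {
                            "kind": kind, "n_neurons": n, "c_o": c_o,
                            "rho1": rho1, "rho2": rho2, "seed_index": s,
                        }
                        try:
                            spec = PopulationSpec(
                                n_neurons=n, kind=kind, max_correlation=c_o,
                                n_stimuli=n_stimuli, seed=pop_seed)
                            pop = make_population(spec)
                            w = derive_weights(pop)
                            if (rho1, rho2) != (0.0, 0.0):
                                w = smooth_weights(w, rho1, rho2,
                                                   pop.preferences)
                            acc = evaluate_accuracy(pop, w, n_eval_trials,
                                                    eval_seed)
                            row.update(mse=acc.mse,
                                       performance=acc.performance)
                        except (np.linalg.LinAlgError, ValueError) as exc:
                            warnings.warn(
                                f"sweep cell {row} failed: {exc}",
                                stacklevel=2)
                            row.update(mse=np.nan, performance=np.nan)
                        rows.append(row)
    df = pd.DataFrame(rows)
    return df


def summarize_sweep(df: pd.DataFrame) -> pd.DataFrame:
    """Mean performance with standard error across seeds per sweep cell."""
    grouped = df.groupby(["kind", "c_o", "n_neurons", "rho1", "rho2"],
                         as_index=False)
    out = grouped.agg(
        mean_mse=("mse", "mean"),
        mean_performance=("performance", "mean"),
        sem_performance=("performance", lambda v: v.std(ddof=1)
                         / np.sqrt(max(v.notna().sum(), 1))),
        n_seeds=("performance", "count"),
    )
    out["performance_of_mean_mse"] = 1.0 / np.maximum(out["mean_mse"], 1e-12)
    return out
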