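"""Orientation-tuned input populations with limited-range correlated noise.

An input population ("P_IN") is a set of N model neurons, each with an
exponential-of-cosine-squared orientation tuning curve

    f_i(theta) = alpha_i + beta_i * exp(kappa_i * (cos(theta - phi_i)^2 - 1))
              = alpha_i + beta_i * exp(-kappa_i * sin(theta - phi_i)^2)

(angles in degrees, 180-degree periodic since sin^2 has period 180),
responding to K orientations on an equally spaced grid spanning [-90, +90).  Trial-to-trial variability is
additive multivariate Gaussian noise whose correlation decays with the
difference in preferred orientation (limited-range correlations) and whose
variance is scaled by each neuron's mean rate (Poisson-like noise).

Two population kinds are supported:

* ``homogeneous`` — shifted copies of one tuning curve, (alpha, beta,
  kappa) = (0, 5, 4), preferences tiled uniformly.
* ``heterogeneous`` — V1-like diversity: tuning half-widths drawn from a
  lognormal distribution and converted to concentrations, amplitudes and
  baselines drawn from configurable distributions, preferences uniform.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from ._seeding import rng_from

logger = logging.getLogger(__name__)

__all__ = [
    "NeuronTuning",
    "PopulationSpec",
    "InputPopulation",
    "ResponseSet",
    "tuning_curve",
    "bandwidth_to_kappa",
    "make_population",
    "build_correlation_matrix",
    "scale_to_covariance",
    "simulate_responses",
    "stimulus_grid",
    "circular_orientation_difference",
]

#: Default concentration cap applied when a sampled half-width underflows.
KAPPA_MAX = 500.0

#: Floor applied to mean rates before covariance scaling, keeps Q invertible.
RATE_FLOOR = 1e-3

HOMOGENEOUS_PARAMS = (0.0, 5.0, 4.0)  # (alpha, beta, kappa)


@dataclass(frozen=True)
class NeuronTuning:
    """Tuning parameters of one model neuron.

    Parameters
    ----------
    baseline : float
        Untuned baseline rate alpha (>= 0, arbitrary rate units).
    amplitude : float
        Tuned response scale beta (>= 0); peak mean rate is alpha + beta.
    concentration : float
        Bandwidth parameter kappa (> 0); larger kappa = narrower tuning.
        The minimum mean response, at 90 degrees from preferred, is
        alpha + beta * exp(-kappa).
    preferred_orientation : float
        Preferred orientation phi in degrees, wrapped to [-90, +90).
    """

    baseline: float
    amplitude: float
    concentration: float
    preferred_orientation: float

    def __post_init__(self) -> None:
        vals = (self.baseline, self.amplitude, self.concentration,
                self.preferred_orientation)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite tuning parameters: {vals}")
        if self.baseline < 0 or self.amplitude < 0:
            raise ValueError("baseline and amplitude must be >= 0")
        if self.concentration <= 0:
            raise ValueError("concentration kappa must be > 0")


@dataclass(frozen=True)
class PopulationSpec:
    """Recipe for building an :class:`InputPopulation`."""

    n_neurons: int
    kind: str = "homogeneous"  # or "heterogeneous"
    max_correlation: float = 0.0  # c_o
    n_stimuli: int = 16
    seed: int = 0
    homogeneous_params: tuple[float, float, float] = HOMOGENEOUS_PARAMS
    # lognormal of the tuning half-width gamma, drawn in *radians*
    bandwidth_lognormal: tuple[float, float] = (-1.0, 0.6)
    # amplitude beta ~ lognormal(log-median, log-sigma)
    amplitude_lognormal: tuple[float, float] = (np.log(5.0), 0.5)
    # baseline alpha ~ exponential(mean)
    baseline_exponential_mean: float = 0.5

    def __post_init__(self) -> None:
        if self.n_neurons < 2:
            raise ValueError("population needs N >= 2 neurons")
        if self.n_stimuli < 2:
            raise ValueError("stimulus grid needs K >= 2 orientations")
        if not 0.0 <= self.max_correlation < 1.0:
            raise ValueError("max_correlation c_o must lie in [0, 1)")
        if self.kind not in ("homogeneous", "heterogeneous"):
            raise ValueError(f"unknown population kind {self.kind!r}")

    @property
    def stimulus_grid(self) -> np.ndarray:
        return stimulus_grid(self.n_stimuli)


@dataclass
class InputPopulation:
    """A built input population: tuning, mean responses and noise covariance."""

    neurons: list[NeuronTuning]
    mean_response_matrix: np.ndarray  # K x N
    correlation_matrix: np.ndarray    # N x N, unit diagonal
    covariance_matrix: np.ndarray     # N x N, rate-scaled
    spec: PopulationSpec

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def stimulus_grid(self) -> np.ndarray:
        return self.spec.stimulus_grid

    @property
    def preferences(self) -> np.ndarray:
        return np.array([n.preferred_orientation for n in self.neurons])

    @property
    def mean_rates(self) -> np.ndarray:
        """Stimulus-averaged mean rate per neuron (the Poisson-like scale)."""
        return self.mean_response_matrix.mean(axis=0)

    def tuning_at(self, theta) -> np.ndarray:
        """Mean response of every neuron at orientation(s) ``theta`` (deg)."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        out = np.empty((theta.size, self.n_neurons))
        for j, neuron in enumerate(self.neurons):
            out[:, j] = tuning_curve(neuron, theta)
        return out


@dataclass
class ResponseSet:
    """Simulated trial responses: ``responses[trial, stimulus, neuron]``."""

    responses: np.ndarray  # trials x K x N
    noise_model: str
    seed: int
    stimulus_grid: np.ndarray = field(default_factory=lambda: stimulus_grid(16))

    @property
    def n_trials(self) -> int:
        return self.responses.shape[0]


def stimulus_grid(n_stimuli: int) -> np.ndarray:
    """K equally spaced orientations spanning [-90, +90) degrees."""
    if n_stimuli < 2:
        raise ValueError("need K >= 2 orientations")
    return -90.0 + 180.0 * np.arange(n_stimuli) / n_stimuli


def wrap_orientation(theta) -> np.ndarray:
    """Wrap orientations (degrees) to [-90, +90)."""
    return (np.asarray(theta, dtype=float) + 90.0) % 180.0 - 90.0


def circular_orientation_difference(phi_a, phi_b) -> np.ndarray:
    """Absolute circular difference between orientations, in radians.

    Computed on doubled angles and halved, so the result lies in
    [0, pi/2]: co-tuned pairs give 0, orthogonally tuned pairs pi/2.
    """
    a = np.deg2rad(np.asarray(phi_a, dtype=float)) * 2.0
    b = np.deg2rad(np.asarray(phi_b, dtype=float)) * 2.0
    d = np.angle(np.exp(1j * (a - b)))
    return 0.5 * np.abs(d)


def tuning_curve(params: NeuronTuning, theta) -> np.ndarray:
    """Mean response at orientation(s) ``theta`` in degrees.

    ``alpha + beta * exp(kappa * (cos(theta - phi)^2 - 1))`` with the
    angle in radians inside the trig call; equivalently
    ``alpha + beta * exp(-kappa * sin(theta - phi)^2)``.  180-degree
    periodic, peaking at alpha + beta when theta = phi.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite orientation")
    delta = np.deg2rad(theta - params.preferred_orientation)
    return params.baseline + params.amplitude * np.exp(
        -params.concentration * np.sin(delta) ** 2
    )


def bandwidth_to_kappa(gamma_deg, kappa_max: float = KAPPA_MAX) -> np.ndarray:
    """Convert a tuning half-width gamma (degrees) to a concentration kappa.

    ``kappa = ln(2) / (1 - cos(2 gamma)) = ln(2) / (2 sin(gamma)^2)``;
    strictly decreasing in gamma.  Under the exp(-kappa sin^2) tuning
    curve this places the half-width at 1/sqrt(2) of the tuned peak:
    ``exp(-kappa sin(gamma)^2) = 2^{-1/2}``.  Very narrow half-widths
    overflow the formula and are capped at ``kappa_max``.  Half-widths
    >= 90 degrees are rejected (the criterion height is never reached
    within the orientation domain).
    """
    gamma = np.asarray(gamma_deg, dtype=float)
    scalar = gamma.ndim == 0
    gamma = np.atleast_1d(gamma)
    if np.any(gamma <= 0) or np.any(gamma >= 90):
        raise ValueError("half-width gamma must lie in (0, 90) degrees")
    denom = 2.0 * np.sin(np.deg2rad(gamma)) ** 2
    with np.errstate(divide="ignore", over="ignore"):
        kappa = np.log(2.0) / denom
    kappa = np.minimum(kappa, kappa_max)
    return float(kappa[0]) if scalar else kappa


def build_correlation_matrix(preferences, max_correlation: float) -> np.ndarray:
    """Limited-range correlation matrix from preferred orientations.

    ``C = A + (1 - c_o) I`` with ``A_ij = c_o * exp(-delta_ij)`` where
    ``delta_ij`` is the circular orientation difference in radians.  The
    diagonal is exactly 1; off-diagonals decay from ``c_o`` (co-tuned) to
    ``c_o * exp(-pi/2)`` (orthogonal).
    """
    if not 0.0 <= max_correlation < 1.0:
        raise ValueError("max pairwise correlation c_o must lie in [0, 1)")
    phi = np.asarray(preferences, dtype=float)
    delta = circular_orientation_difference(phi[:, None], phi[None, :])
    amat = max_correlation * np.exp(-delta)
    cmat = amat + (1.0 - max_correlation) * np.eye(phi.size)
    return cmat


def scale_to_covariance(correlation: np.ndarray, mean_rates,
                        rate_floor: float = RATE_FLOOR) -> np.ndarray:
    """Scale a correlation matrix by mean rates to Poisson-like covariance.

    ``Q_ij = C_ij * sqrt(mu_i * mu_j)`` where ``mu_i`` is the neuron's
    stimulus-averaged mean rate, so each variance equals its mean rate and
    the covariance is stimulus-independent (the equal-covariance assumption
    of the analytic decoder).  Rates below ``rate_floor`` are floored with a
    warning to keep Q invertible.
    """
    mu = np.asarray(mean_rates, dtype=float).copy()
    if np.any(mu < 0):
        raise ValueError("mean rates must be >= 0")
    if np.any(mu < rate_floor):
        warnings.warn(
            f"flooring {int(np.sum(mu < rate_floor))} mean rate(s) at "
            f"{rate_floor} for covariance scaling", stacklevel=2)
        mu = np.maximum(mu, rate_floor)
    scale = np.sqrt(mu)
    return correlation * np.outer(scale, scale)


def _ensure_positive_definite(q: np.ndarray) -> np.ndarray:
    """Add minimal diagonal jitter if Cholesky fails; log when it happens."""
    try:
        linalg.cholesky(q, lower=True)
        return q
    except linalg.LinAlgError:
        jitter = 1e-8 * np.trace(q) / q.shape[0]
        logger.info("covariance not PD; adding diagonal jitter %g", jitter)
        return q + jitter * np.eye(q.shape[0])


def make_population(spec: PopulationSpec) -> InputPopulation:
    """Build an :class:`InputPopulation` from a spec.

    Homogeneous populations are shifted copies of one tuning curve with
    preferences tiled uniformly over [-90, +90).  Heterogeneous populations
    draw half-widths from the configured lognormal (radians, converted to
    kappa), amplitudes lognormal, baselines exponential, and preferences
    uniformly at random.
    """
    rng = rng_from(spec.seed)
    n = spec.n_neurons
    if spec.kind == "homogeneous":
        alpha, beta, kappa = spec.homogeneous_params
        phis = stimulus_grid(n)  # uniform tiling over [-90, 90)
        neurons = [NeuronTuning(alpha, beta, kappa, float(p)) for p in phis]
    else:
        mu_g, sig_g = spec.bandwidth_lognormal
        gamma_rad = rng.lognormal(mean=mu_g, sigma=sig_g, size=n)
        gamma_deg = np.clip(np.rad2deg(gamma_rad), 1e-3, 89.999)
        kappas = bandwidth_to_kappa(gamma_deg)
        mu_b, sig_b = spec.amplitude_lognormal
        betas = rng.lognormal(mean=mu_b, sigma=sig_b, size=n)
        alphas = rng.exponential(scale=spec.baseline_exponential_mean, size=n)
        phis = rng.uniform(-90.0, 90.0, size=n)
        neurons = [
            NeuronTuning(float(a), float(b), float(k), float(p))
            for a, b, k, p in zip(alphas, betas, kappas, phis)
        ]

    grid = spec.stimulus_grid
    mean_resp = np.column_stack([tuning_curve(nr, grid) for nr in neurons])
    prefs = np.array([nr.preferred_orientation for nr in neurons])
    cmat = build_correlation_matrix(prefs, spec.max_correlation)
    qmat = scale_to_covariance(cmat, mean_resp.mean(axis=0))
    qmat = _ensure_positive_definite(qmat)
    return InputPopulation(
        neurons=neurons,
        mean_response_matrix=mean_resp,
        correlation_matrix=cmat,
        covariance_matrix=qmat,
        spec=spec,
    )


def simulate_responses(pop: InputPopulation, n_trials: int, seed: int,
                       rectify: bool = False) -> ResponseSet:
    """Simulate trial responses: ``R = f(theta_k) + eps``, eps ~ N(0, Q).

    The noise covariance is shared across stimuli.  Responses are left
    unrectified by default, matching the Gaussian assumption of the analytic
    decoder; ``rectify=True`` clips at zero.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = rng_from(seed)
    k, n = pop.mean_response_matrix.shape
    chol = linalg.cholesky(pop.covariance_matrix, lower=True)
    z = rng.standard_normal(size=(n_trials, k, n))
    noise = z @ chol.T
    responses = pop.mean_response_matrix[None, :, :] + noise
    if rectify:
        responses = np.maximum(responses, 0.0)
    return ResponseSet(
        responses=responses,
        noise_model="rectified-gaussian" if rectify else "gaussian",
        seed=seed,
        stimulus_grid=pop.stimulus_grid,
    )


def homogeneous_spec(n_neurons: int, *, max_correlation: float = 0.0,
                     n_stimuli: int = 16, seed: int = 0) -> PopulationSpec:
    """Convenience constructor for the standard homogeneous population."""
    return PopulationSpec(n_neurons=n_neurons, kind="homogeneous",
                          max_correlation=max_correlation,
                          n_stimuli=n_stimuli, seed=seed)


def heterogeneous_spec(n_neurons: int, *, max_correlation: float = 0.0,
                       n_stimuli: int = 16, seed: int = 0) -> PopulationSpec:
    """Convenience constructor for the V1-like heterogeneous population."""
    return PopulationSpec(n_neurons=n_neurons, kind="heterogeneous",
                          max_correlation=max_correlation,
                          n_stimuli=n_stimuli, seed=seed)
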