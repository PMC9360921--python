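"""Synthetic dendritic-spine datasets and the spine preprocessing pipeline.

Emulates the structure of a two-photon calcium-imaging experiment on a
single neuron: drifting gratings at 22.5-degree increments, 8-10 trials per
stimulus, dF/F-like responses for the soma, a dendritic segment and each
spine, plus blank-period samples of pure baseline noise.  Spine signals are
contaminated by back-propagating action potentials (a scaled copy of the
dendritic signal), which the pipeline removes by robust regression before
quality control, tuning fits and normalization.

The generator records ground truth (true preference, amplitude,
contamination factor) so that every preprocessing step can be validated by
parameter recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._seeding import rng_from
from .population import stimulus_grid, wrap_orientation

__all__ = [
    "SpineDataset",
    "SpineQCReport",
    "TuningFit",
    "generate_spine_dataset",
    "subtract_bap",
    "spine_inclusion_filter",
    "fit_tuning_gaussian",
    "vector_strength",
    "normalize_spine_responses",
    "wrapped_gaussian",
]

EXPERIMENTAL_GRID = stimulus_grid(8)  # 22.5-degree increments over 180 deg

#: Spearman correlation threshold with the dendritic signal; spines at or
#: above it are considered bAP-dominated and excluded.
DENDRITE_CORR_THRESHOLD = 0.4

#: Inclusion requires the preferred response to exceed the blank median by
#: this many (unscaled) median absolute deviations.
SNR_N_MADS = 2.0

DEFAULT_N_SPINES = 159  # typical visually-responsive spine count per cell


def wrapped_orientation_distance(theta_a, theta_b) -> np.ndarray:
    """Orientation difference in degrees wrapped to [-90, +90)."""
    return wrap_orientation(np.asarray(theta_a, float)
                            - np.asarray(theta_b, float))


def wrapped_gaussian(theta, baseline, amplitude, width, pref) -> np.ndarray:
    """Gaussian tuning curve on the orientation circle (degrees)."""
    d = wrapped_orientation_distance(theta, pref)
    return baseline + amplitude * np.exp(-(d**2) / (2.0 * width**2))


@dataclass
class SpineDataset:
    """Synthetic soma + spine trial responses for one simulated cell.

    ``spine_responses[s, t, k]`` is spine s's response on trial t of
    stimulus k; ``blank_samples[s, :]`` are that spine's blank-period
    baseline samples; ``dendrite_signal[t, k]`` is the shared dendritic /
    bAP component added to every spine in proportion to its contamination
    factor.
    """

    stimulus_grid: np.ndarray       # K_stim
    soma_tuning: np.ndarray         # K_stim
    spine_responses: np.ndarray     # n_spines x trials x K_stim
    blank_samples: np.ndarray       # n_spines x n_blank
    dendrite_signal: np.ndarray     # trials x K_stim
    ground_truth: pd.DataFrame      # per-spine pref/amp/width/contamination
    seed: int = 0

    @property
    def n_spines(self) -> int:
        return self.spine_responses.shape[0]

    @property
    def n_trials(self) -> int:
        return self.spine_responses.shape[1]


@dataclass
class SpineQCReport:
    """Per-spine inclusion decisions with reason codes."""

    table: pd.DataFrame  # spine, snr_stat, snr_threshold, dendrite_corr, ...

    @property
    def passed(self) -> np.ndarray:
        return self.table["passed"].to_numpy()


@dataclass
class TuningFit:
    """Result of a Gaussian tuning-curve fit to one spine."""

    preferred_orientation: float
    amplitude: float
    width: float
    baseline: float
    residual: float
    converged: bool


def generate_spine_dataset(
    n_spines: int = DEFAULT_N_SPINES,
    n_trials: int = 10,
    soma_pref: float = 0.0,
    pref_spread: float = 40.0,
    pref_uniform_fraction: float = 0.35,
    amplitude_mean: float = 1.0,
    amplitude_cv: float = 0.4,
    width_range: tuple[float, float] = (12.0, 35.0),
    contamination_range: tuple[float, float] = (0.0, 0.3),
    noise_scale: float = 0.15,
    n_blank: int = 20,
    seed: int = 0,
    tuning_curves: np.ndarray | None = None,
) -> SpineDataset:
    """Generate a synthetic single-cell spine imaging dataset.

    Spine preferences are a mixture of a wrapped-normal cluster around the
    somatic preference and a uniform component (functional diversity);
    responses are wrapped-Gaussian tuning plus i.i.d. Gaussian noise plus a
    per-spine contamination fraction of the shared dendritic signal.  Blank
    periods contain pure noise.  Alternatively, explicit per-spine
    ``tuning_curves`` (n_spines x 8, e.g. a model synaptic population) can
    be supplied.  All ground truth is recorded.
    """
    if n_spines < 1:
        raise ValueError("need n_spines >= 1")
    if not 2 <= n_trials:
        raise ValueError("need at least 2 trials")
    grid = EXPERIMENTAL_GRID
    k = grid.size
    rng = rng_from(seed)

    soma_amp, soma_width = 1.0, 25.0
    soma_tuning = wrapped_gaussian(grid, 0.05, soma_amp, soma_width,
                                   soma_pref)

    if tuning_curves is not None:
        curves = np.asarray(tuning_curves, float)
        if curves.shape != (n_spines, k):
            raise ValueError("tuning_curves must be n_spines x 8")
        prefs = grid[np.argmax(curves, axis=1)]
        amps = curves.max(axis=1) - curves.min(axis=1)
        widths = np.full(n_spines, np.nan)
    else:
        uniform = rng.random(n_spines) < pref_uniform_fraction
        prefs = np.where(
            uniform,
            rng.uniform(-90.0, 90.0, n_spines),
            wrap_orientation(soma_pref
                             + rng.normal(0.0, pref_spread, n_spines)),
        )
        amps = np.abs(rng.normal(amplitude_mean,
                                 amplitude_cv * amplitude_mean, n_spines))
        widths = rng.uniform(*width_range, n_spines)
        curves = np.stack([
            wrapped_gaussian(grid, 0.0, a, w, p)
            for a, w, p in zip(amps, widths, prefs)
        ])

    contamination = rng.uniform(*contamination_range, n_spines)

    # shared dendritic / bAP signal: somatic tuning expressed per trial,
    # with trial-to-trial gain variability and its own noise
    gain = np.abs(rng.normal(1.0, 0.3, size=(n_trials, 1)))
    dendrite = gain * soma_tuning[None, :] + rng.normal(
        0.0, noise_scale, size=(n_trials, k))

    noise = rng.normal(0.0, noise_scale, size=(n_spines, n_trials, k))
    spine_resp = (curves[:, None, :] + noise
                  + contamination[:, None, None] * dendrite[None, :, :])
    blanks = rng.normal(0.0, noise_scale, size=(n_spines, n_blank))

    gt = pd.DataFrame({
        "spine": np.arange(n_spines),
        "pref_deg": prefs,
        "amplitude": amps,
        "width_deg": widths,
        "contamination": contamination,
    })
    return SpineDataset(
        stimulus_grid=grid,
        soma_tuning=soma_tuning,
        spine_responses=spine_resp,
        blank_samples=blanks,
        dendrite_signal=dendrite,
        ground_truth=gt,
        seed=seed,
    )


def subtract_bap(spine_signal, dendrite_signal) -> tuple[np.ndarray, float]:
    """Remove back-propagating action potentials from a spine signal.

    Estimates the contamination scale by a robust rank-based (Theil-Sen)
    regression of the spine signal on the dendritic signal, clips it at
    zero (a spine cannot be negatively contaminated), and subtracts the
    scaled dendritic signal.  For trials x stimuli tables the regression
    uses within-stimulus trial fluctuations (per-stimulus means removed
    from both signals): bAP coupling passes trial-to-trial dendritic
    fluctuations into the spine, whereas the spine's own tuning — which
    may resemble the dendrite's stimulus preference — cancels out, so a
    co-tuned but uncontaminated spine is not over-subtracted.  A constant
    dendritic signal yields scale 0 and an unchanged spine.
    """
    spine = np.asarray(spine_signal, float)
    dend = np.asarray(dendrite_signal, float)
    if spine.shape != dend.shape:
        raise ValueError("spine and dendrite signals must share a shape")
    if np.ptp(dend) == 0:
        return spine.copy(), 0.0
    if spine.ndim == 2:
        x = (dend - dend.mean(axis=0, keepdims=True)).ravel()
        y = (spine - spine.mean(axis=0, keepdims=True)).ravel()
    else:
        x = dend.ravel()
        y = spine.ravel()
    if np.ptp(x) == 0:
        return spine.copy(), 0.0
    slope = stats.theilslopes(y, x).slope
    scale = float(max(slope, 0.0))
    return spine - scale * dend, scale


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def spine_inclusion_filter(dataset: SpineDataset,
                           subtract: bool = True) -> SpineQCReport:
    """Quality control: keep visually responsive, weakly bAP-coupled spines.

    A spine passes iff (a) its preferred response (maximum trial-mean
    across stimuli, after bAP subtraction) exceeds the blank-period median
    by more than ``SNR_N_MADS`` median absolute deviations, and (b) the
    Spearman correlation between its signal and the dendritic signal —
    computed after dropping samples where the bAP-corrected trace is
    negative (post-subtraction negative events are artifacts) — is below
    ``DENDRITE_CORR_THRESHOLD``.  A spine that is effectively a copy of
    the dendrite therefore fails (b) even when the subtraction removed it
    perfectly.  Spines with fewer than 3 usable samples for the
    correlation are flagged indeterminate and excluded.
    """
    rows = []
    dend = dataset.dendrite_signal
    for s in range(dataset.n_spines):
        raw = dataset.spine_responses[s]
        corrected, scale = subtract_bap(raw, dend) if subtract \
            else (raw.copy(), 0.0)
        blank = dataset.blank_samples[s]
        threshold = np.median(blank) + SNR_N_MADS * _mad(blank)
        preferred_response = corrected.mean(axis=0).max()
        snr_pass = bool(preferred_response > threshold)

        y = raw.ravel()
        x = dend.ravel()
        usable = corrected.ravel() >= 0
        reasons = []
        if usable.sum() < 3:
            corr = np.nan
            corr_pass = False
            reasons.append("indeterminate_correlation")
        else:
            corr = stats.spearmanr(y[usable], x[usable]).statistic
            if np.isnan(corr):  # constant traces after masking
                corr = 0.0
            corr_pass = bool(corr < DENDRITE_CORR_THRESHOLD)
            if not corr_pass:
                reasons.append("dendrite_correlated")
        if not snr_pass:
            reasons.append("low_snr")
        rows.append({
            "spine": s,
            "snr_stat": preferred_response,
            "snr_threshold": threshold,
            "snr_pass": snr_pass,
            "dendrite_corr": corr,
            "corr_pass": corr_pass,
            "bap_scale": scale,
            "passed": snr_pass and corr_pass,
            "reasons": ";".join(reasons) if reasons else "",
        })
    return SpineQCReport(table=pd.DataFrame(rows))


def fit_tuning_gaussian(responses, grid=None) -> TuningFit:
    """Fit a wrapped-Gaussian tuning curve to trial responses.

    ``responses`` is trials x K (or a length-K mean curve).  Nonlinear
    least squares with multi-start over a preferred-orientation grid; the
    reported preference is wrapped to [-90, +90).  If no start converges,
    ``converged`` is False and the preference falls back to the circular
    mean of the response profile.
    """
    grid = np.asarray(EXPERIMENTAL_GRID if grid is None else grid, float)
    r = np.asarray(responses, float)
    mean_curve = r.mean(axis=0) if r.ndim == 2 else r
    if np.unique(grid).size < 4:
        raise ValueError("need >= 4 distinct stimulus orientations")

    rng_span = float(mean_curve.max() - mean_curve.min())
    if rng_span == 0:
        return TuningFit(float(grid[0]), 0.0, 45.0, float(mean_curve[0]),
                         0.0, False)

    def model(theta, baseline, amplitude, width, pref):
        return wrapped_gaussian(theta, baseline, amplitude, width, pref)

    best = None
    lower = [-np.inf, 0.0, 4.0, -180.0]
    upper = [np.inf, np.inf, 90.0, 180.0]
    for start_pref in grid:
        p0 = [float(mean_curve.min()), rng_span, 25.0, float(start_pref)]
        try:
            popt, _ = optimize.curve_fit(
                model, grid, mean_curve, p0=p0,
                bounds=(lower, upper), maxfev=2000)
        except (RuntimeError, ValueError):
            continue
        resid = float(np.sum((model(grid, *popt) - mean_curve) ** 2))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        z = np.sum(np.maximum(mean_curve, 0.0)
                   * np.exp(2j * np.deg2rad(grid)))
        pref = float(wrap_orientation(np.rad2deg(np.angle(z)) / 2.0))
        return TuningFit(pref, rng_span, 45.0, float(mean_curve.min()),
                         np.inf, False)
    popt, resid = best
    baseline, amplitude, width, pref = popt
    return TuningFit(
        preferred_orientation=float(wrap_orientation(pref)),
        amplitude=float(amplitude),
        width=float(width),
        baseline=float(baseline),
        residual=resid,
        converged=True,
    )


def vector_strength(responses, grid=None) -> float:
    """Circular-resultant orientation selectivity in [0, 1].

    ``v = |sum_k r_k exp(2i theta_k)| / sum_k r_k`` on doubled angles
    (orientation is 180-degree periodic).  Negative mean responses are
    floored at zero with a warning; an all-zero profile is undefined.
    """
    grid = np.asarray(EXPERIMENTAL_GRID if grid is None else grid, float)
    r = np.asarray(responses, float)
    if r.ndim == 2:
        r = r.mean(axis=0)
    if r.shape != grid.shape:
        raise ValueError("need one mean response per stimulus")
    if np.any(r < 0):
        warnings.warn("flooring negative mean responses at 0 for vector "
                      "strength", stacklevel=2)
        r = np.maximum(r, 0.0)
    total = r.sum()
    if total <= 0:
        raise ValueError("vector strength undefined for zero total response")
    z = np.sum(r * np.exp(2j * np.deg2rad(grid)))
    return float(np.abs(z) / total)


def normalize_spine_responses(responses) -> tuple[np.ndarray, float]:
    """Scale trial responses so the peak trial-mean response equals 1.

    Returns the scaled trials x K array and the peak used.  Spines whose
    peak mean response is not positive should be excluded upstream.
    """
    r = np.asarray(responses, float)
    mean_curve = r.mean(axis=0) if r.ndim == 2 else r
    peak = float(mean_curve.max())
    if peak <= 0:
        raise ValueError("cannot normalize: peak mean response <= 0")
    return r / peak, peak
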