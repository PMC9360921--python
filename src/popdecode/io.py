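"""Serialization: CSV tables, JSON manifests, full-precision roundtrips.

All tabular artifacts are plain CSV with floats written at 17 significant
digits (enough to roundtrip IEEE doubles exactly); specs, seeds and
provenance go in JSON sidecars.  A :class:`RunManifest` records every
stage's seed and artifact path so a run can be replayed bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .decoder import DecoderWeights
from .population import (
    InputPopulation,
    NeuronTuning,
    PopulationSpec,
    build_correlation_matrix,
    scale_to_covariance,
    tuning_curve,
)
from .spines import SpineDataset
from .synapses import SynapticPopulation

__all__ = [
    "RunManifest",
    "write_population",
    "read_population",
    "write_weights",
    "read_weights",
    "write_synapses",
    "read_synapses",
    "write_spine_dataset",
    "read_spine_dataset",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.17g"


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _read_csv(path: Path) -> pd.DataFrame:
    # round_trip parsing: the default pandas float parser is not correctly
    # rounded and would break bit-exact roundtrips
    return pd.read_csv(path, float_precision="round_trip")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


@dataclasses.dataclass
class RunManifest:
    """Record of one pipeline run: config, per-stage seeds, artifacts."""

    experiment: str
    master_seed: int
    config: dict
    stage_seeds: dict = dataclasses.field(default_factory=dict)
    artifacts: dict = dataclasses.field(default_factory=dict)
    created: str = dataclasses.field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())
    version: str = "0.1.0"

    def record(self, stage: str, seed: int, *paths: Path) -> None:
        self.stage_seeds[stage] = int(seed)
        if paths:
            self.artifacts[stage] = [str(p) for p in paths]

    def write(self, path: Path) -> None:
        _write_json(dataclasses.asdict(self), Path(path))

    @classmethod
    def read(cls, path: Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


# -- input populations -------------------------------------------------------

def write_population(pop: InputPopulation, stem: Path,
                     include_covariance: bool = False) -> list[Path]:
    """Write a population as <stem>.neurons.csv + <stem>.spec.json."""
    stem = Path(stem)
    neurons_path = stem.with_suffix(".neurons.csv")
    spec_path = stem.with_suffix(".spec.json")
    df = pd.DataFrame({
        "alpha": [n.baseline for n in pop.neurons],
        "beta": [n.amplitude for n in pop.neurons],
        "kappa": [n.concentration for n in pop.neurons],
        "phi_deg": [n.preferred_orientation for n in pop.neurons],
    })
    _write_csv(df, neurons_path)
    spec = dataclasses.asdict(pop.spec)
    _write_json(spec, spec_path)
    written = [neurons_path, spec_path]
    if include_covariance:
        cov_path = stem.with_suffix(".covariance.csv")
        _write_csv(pd.DataFrame(pop.covariance_matrix), cov_path)
        written.append(cov_path)
    return written


def read_population(stem: Path) -> InputPopulation:
    """Rebuild a population from its neuron table + spec sidecar.

    The correlation and covariance matrices are reconstructed from the
    stored tuning parameters; this reproduces the written object exactly
    because both are deterministic functions of the neuron table.
    """
    stem = Path(stem)
    df = _read_csv(stem.with_suffix(".neurons.csv"))
    raw = json.loads(stem.with_suffix(".spec.json").read_text())
    for key in ("homogeneous_params", "bandwidth_lognormal",
                "amplitude_lognormal"):
        raw[key] = tuple(raw[key])
    spec = PopulationSpec(**raw)
    neurons = [
        NeuronTuning(row.alpha, row.beta, row.kappa, row.phi_deg)
        for row in df.itertuples()
    ]
    grid = spec.stimulus_grid
    mean_resp = np.column_stack([tuning_curve(n, grid) for n in neurons])
    prefs = np.array([n.preferred_orientation for n in neurons])
    cmat = build_correlation_matrix(prefs, spec.max_correlation)
    qmat = scale_to_covariance(cmat, mean_resp.mean(axis=0))
    return InputPopulation(neurons=neurons, mean_response_matrix=mean_resp,
                           correlation_matrix=cmat, covariance_matrix=qmat,
                           spec=spec)


# -- decoder weights ----------------------------------------------------------

def write_weights(weights: DecoderWeights, stem: Path) -> list[Path]:
    """Write weights as <stem>.weights.csv + <stem>.weights.json."""
    stem = Path(stem)
    csv_path = stem.with_suffix(".weights.csv")
    json_path = stem.with_suffix(".weights.json")
    df = pd.DataFrame(
        weights.weights,
        columns=[f"n{j}" for j in range(weights.n_neurons)])
    df.insert(0, "theta_deg", weights.stimulus_grid)
    df.insert(1, "offset", weights.offsets)
    df.insert(2, "prior", weights.prior)
    _write_csv(df, csv_path)
    _write_json({"provenance": weights.provenance,
                 "n_classes": int(weights.n_classes),
                 "n_neurons": int(weights.n_neurons)}, json_path)
    return [csv_path, json_path]


def read_weights(stem: Path) -> DecoderWeights:
    stem = Path(stem)
    df = _read_csv(stem.with_suffix(".weights.csv"))
    meta = json.loads(stem.with_suffix(".weights.json").read_text())
    wcols = [c for c in df.columns if c.startswith("n")]
    return DecoderWeights(
        weights=df[wcols].to_numpy(),
        offsets=df["offset"].to_numpy(),
        prior=df["prior"].to_numpy(),
        stimulus_grid=df["theta_deg"].to_numpy(),
        provenance=meta["provenance"],
    )


# -- synaptic populations -----------------------------------------------------

def write_synapses(syn: SynapticPopulation, stem: Path) -> list[Path]:
    """Tidy CSV: synapse_id, source_index, stimulus_deg, trial, response."""
    stem = Path(stem)
    csv_path = stem.with_suffix(".synapses.csv")
    json_path = stem.with_suffix(".synapses.json")
    if syn.trial_responses is None:
        raise ValueError("simulate trials before writing a synaptic "
                         "population")
    t, k, n = syn.trial_responses.shape
    trial_ix, stim_ix, syn_ix = np.meshgrid(
        np.arange(t), np.arange(k), np.arange(n), indexing="ij")
    df = pd.DataFrame({
        "synapse_id": syn_ix.ravel(),
        "source_index": syn.source_indices[syn_ix.ravel()],
        "stimulus_deg": syn.stimulus_grid[stim_ix.ravel()],
        "trial": trial_ix.ravel(),
        "response": syn.trial_responses.ravel(),
    })
    _write_csv(df, csv_path)
    _write_json({
        "seed": int(syn.seed),
        "stimulus_grid": list(map(float, syn.stimulus_grid)),
        "decoder_output_tuning": list(map(float, syn.decoder_output_tuning)),
        "tuning_curves": [list(map(float, row))
                          for row in syn.tuning_curves],
    }, json_path)
    return [csv_path, json_path]


def read_synapses(stem: Path) -> SynapticPopulation:
    stem = Path(stem)
    df = _read_csv(stem.with_suffix(".synapses.csv"))
    meta = json.loads(stem.with_suffix(".synapses.json").read_text())
    grid = np.array(meta["stimulus_grid"])
    n = int(df["synapse_id"].max()) + 1
    t = int(df["trial"].max()) + 1
    k = grid.size
    trials = np.empty((t, k, n))
    stim_index = {th: j for j, th in enumerate(grid)}
    trials[df["trial"], df["stimulus_deg"].map(stim_index),
           df["synapse_id"]] = df["response"]
    sources = (df.drop_duplicates("synapse_id")
               .sort_values("synapse_id")["source_index"].to_numpy())
    return SynapticPopulation(
        source_indices=sources,
        tuning_curves=np.array(meta["tuning_curves"]),
        stimulus_grid=grid,
        decoder_output_tuning=np.array(meta["decoder_output_tuning"]),
        seed=meta["seed"],
        trial_responses=trials,
    )


# -- spine datasets -----------------------------------------------------------

def write_spine_dataset(ds: SpineDataset, stem: Path) -> list[Path]:
    """Tidy CSVs (responses, blanks, dendrite) + JSON ground truth.

    The response schema (spine_id, stimulus_deg, trial, response) is also
    the documented format for user-supplied real recordings.
    """
    stem = Path(stem)
    resp_path = stem.with_suffix(".responses.csv")
    blank_path = stem.with_suffix(".blanks.csv")
    dend_path = stem.with_suffix(".dendrite.csv")
    truth_path = stem.with_suffix(".truth.json")
    s, t, k = ds.spine_responses.shape
    spine_ix, trial_ix, stim_ix = np.meshgrid(
        np.arange(s), np.arange(t), np.arange(k), indexing="ij")
    _write_csv(pd.DataFrame({
        "spine_id": spine_ix.ravel(),
        "stimulus_deg": ds.stimulus_grid[stim_ix.ravel()],
        "trial": trial_ix.ravel(),
        "response": ds.spine_responses.ravel(),
    }), resp_path)
    sb, nb = ds.blank_samples.shape
    bspine, bsample = np.meshgrid(np.arange(sb), np.arange(nb),
                                  indexing="ij")
    _write_csv(pd.DataFrame({
        "spine_id": bspine.ravel(),
        "sample": bsample.ravel(),
        "response": ds.blank_samples.ravel(),
    }), blank_path)
    dtrial, dstim = np.meshgrid(np.arange(ds.dendrite_signal.shape[0]),
                                np.arange(k), indexing="ij")
    _write_csv(pd.DataFrame({
        "trial": dtrial.ravel(),
        "stimulus_deg": ds.stimulus_grid[dstim.ravel()],
        "response": ds.dendrite_signal.ravel(),
    }), dend_path)
    _write_json({
        "seed": int(ds.seed),
        "stimulus_grid": list(map(float, ds.stimulus_grid)),
        "soma_tuning": list(map(float, ds.soma_tuning)),
        "ground_truth": ds.ground_truth.to_dict(orient="list"),
    }, truth_path)
    return [resp_path, blank_path, dend_path, truth_path]


def read_spine_dataset(stem: Path) -> SpineDataset:
    stem = Path(stem)
    resp = _read_csv(stem.with_suffix(".responses.csv"))
    blanks = _read_csv(stem.with_suffix(".blanks.csv"))
    dend = _read_csv(stem.with_suffix(".dendrite.csv"))
    meta = json.loads(stem.with_suffix(".truth.json").read_text())
    grid = np.array(meta["stimulus_grid"])
    stim_index = {th: j for j, th in enumerate(grid)}
    s = int(resp["spine_id"].max()) + 1
    t = int(resp["trial"].max()) + 1
    k = grid.size
    responses = np.empty((s, t, k))
    responses[resp["spine_id"], resp["trial"],
              resp["stimulus_deg"].map(stim_index)] = resp["response"]
    nb = int(blanks["sample"].max()) + 1
    blank_arr = np.empty((s, nb))
    blank_arr[blanks["spine_id"], blanks["sample"]] = blanks["response"]
    dt = int(dend["trial"].max()) + 1
    dend_arr = np.empty((dt, k))
    dend_arr[dend["trial"], dend["stimulus_deg"].map(stim_index)] = \
        dend["response"]
    return SpineDataset(
        stimulus_grid=grid,
        soma_tuning=np.array(meta["soma_tuning"]),
        spine_responses=responses,
        blank_samples=blank_arr,
        dendrite_signal=dend_arr,
        ground_truth=pd.DataFrame(meta["ground_truth"]),
        seed=meta["seed"],
    )
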