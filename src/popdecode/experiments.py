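"""End-to-end experiment drivers tying the pipeline stages together.

Three named experiments mirror the package's main analyses:

* ``weights`` — build a population, derive (optionally smooth) weights.
* ``accuracy-sweep`` — decoding performance over size/correlation/smoothing.
* ``synapse-comparison`` — repeated population -> weights -> synapses ->
  trials runs for both population kinds, with comparison statistics.

Each experiment takes a plain-dict config (loadable from YAML/JSON), writes
CSV artifacts plus a JSON run manifest, and is deterministic given the
master seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from ._seeding import derive_seed
from .compare import run_model_comparison, summarize_variability
from .decoder import accuracy_sweep, derive_weights, smooth_weights, summarize_sweep
from .io import RunManifest, write_population, write_weights
from .population import PopulationSpec, make_population

logger = logging.getLogger(__name__)

__all__ = ["run_experiment", "load_config", "EXPERIMENTS"]


def load_config(path) -> dict:
    """Load a YAML or JSON experiment config."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _run_weights(config: dict, outdir: Path, manifest: RunManifest) -> None:
    seed = derive_seed(config.get("seed", 0), "weights-pop")
    spec = PopulationSpec(
        n_neurons=config.get("n_neurons", 1000),
        kind=config.get("kind", "homogeneous"),
        max_correlation=config.get("c_o", 0.25),
        n_stimuli=config.get("n_stimuli", 16),
        seed=seed,
    )
    pop = make_population(spec)
    weights = derive_weights(pop)
    rho1, rho2 = config.get("smoothing", (0.0, 0.0))
    if (rho1, rho2) != (0.0, 0.0):
        weights = smooth_weights(weights, rho1, rho2, pop.preferences)
    paths = write_population(pop, outdir / "population")
    paths += write_weights(weights, outdir / "decoder")
    manifest.record("weights", seed, *paths)
    logger.info("weights experiment: wrote %d artifacts", len(paths))


def _run_accuracy_sweep(config: dict, outdir: Path,
                        manifest: RunManifest) -> None:
    seed = config.get("seed", 0)
    df = accuracy_sweep(
        kinds=tuple(config.get("kinds", ("homogeneous", "heterogeneous"))),
        n_grid=tuple(config.get("n_grid", (8, 32, 128, 512))),
        c_o_grid=tuple(config.get("c_o_grid", (0.0, 0.25, 0.5))),
        smoothing_grid=tuple(
            tuple(s) for s in config.get("smoothing_grid", ((0.0, 0.0),))),
        n_stimuli=config.get("n_stimuli", 16),
        n_eval_trials=config.get("n_eval_trials", 100),
        n_seeds=config.get("n_seeds", 5),
        master_seed=seed,
    )
    raw_path = outdir / "sweep_raw.csv"
    sum_path = outdir / "sweep_summary.csv"
    df.to_csv(raw_path, index=False)
    summarize_sweep(df).to_csv(sum_path, index=False)
    manifest.record("accuracy-sweep", seed, raw_path, sum_path)
    logger.info("accuracy sweep: %d cells", len(df))


def _run_synapse_comparison(config: dict, outdir: Path,
                            manifest: RunManifest) -> None:
    seed = config.get("seed", 0)
    results = run_model_comparison(
        kinds=tuple(config.get("kinds", ("homogeneous", "heterogeneous"))),
        n_runs=config.get("n_runs", 200),
        master_seed=seed,
        n_neurons=config.get("n_neurons", 1000),
        max_correlation=config.get("c_o", 0.20),
        n_synapses=config.get("n_synapses", 100),
        n_trials=config.get("n_trials", 10),
    )
    summary_rows = []
    paths = []
    for kind, res in results.items():
        p1 = outdir / f"per_synapse_{kind}.csv"
        p2 = outdir / f"per_cell_{kind}.csv"
        res.per_input_r.to_csv(p1, index=False)
        res.per_cell.to_csv(p2, index=False)
        paths += [p1, p2]
        row = {
            "kind": kind,
            "pooled_median_r": res.pooled_median_r,
            "per_cell_median_r": res.per_cell_median_r,
            "n_runs": res.extras["n_runs"],
        }
        if res.variability is not None and len(res.variability):
            row.update(summarize_variability(res.variability))
        summary_rows.append(row)
    sum_path = outdir / "comparison_summary.csv"
    pd.DataFrame(summary_rows).to_csv(sum_path, index=False)
    paths.append(sum_path)
    manifest.record("synapse-comparison", seed, *paths)
    logger.info("synapse comparison: %s",
                {r["kind"]: round(r["pooled_median_r"], 3)
                 for r in summary_rows})


EXPERIMENTS = {
    "weights": _run_weights,
    "accuracy-sweep": _run_accuracy_sweep,
    "synapse-comparison": _run_synapse_comparison,
}


def run_experiment(config: dict, outdir) -> RunManifest:
    """Run a named experiment (or a custom stage list) from a config dict.

    ``config["experiment"]`` names one of :data:`EXPERIMENTS`, or
    ``config["stages"]`` lists several.  Artifacts and a JSON manifest are
    written under ``outdir``; a stage failure aborts with the stage name
    after writing the partial manifest for replay.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages") or [config["experiment"]]
    manifest = RunManifest(
        experiment="+".join(stages),
        master_seed=int(config.get("seed", 0)),
        config=config,
    )
    for stage in stages:
        if stage not in EXPERIMENTS:
            raise ValueError(f"unknown experiment stage {stage!r}; "
                             f"choose from {sorted(EXPERIMENTS)}")
        try:
            EXPERIMENTS[stage](config, outdir, manifest)
        except Exception as exc:
            manifest.write(outdir / "manifest.partial.json")
            raise RuntimeError(
                f"stage {stage!r} failed: {exc}; partial manifest written"
            ) from exc
    manifest.write(outdir / "manifest.json")
    return manifest
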