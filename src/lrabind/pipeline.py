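"""End-to-end orchestration: energies → LRA → metrics → interactions → report.

A single YAML config names the run manifests of the three ensembles the
estimator needs (bound/charged, bound/zero-charge, free/charged), the
coefficients, detection criteria and output directory.  The pipeline is a
pure function of its inputs: rerunning on identical files yields an
identical results file (no timestamps in outputs; the log carries them).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .energetics import EnergySeries, StateEnergySummary, ensemble_energy_series
from .interactions import (
    InteractionCriteria,
    format_binding_summary,
    interaction_occupancy,
    occupancy_table,
)
from .io import RunManifest, read_parameters, read_structure
from .lra import AggregateResult, LRAParams, aggregate_runs, cycle_residual, lra_binding
from .metrics import aggregate_metric, rmsd_series, rmsf
from .selections import make_selection
from .topology import Topology, Trajectory

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "ConfigError"]

logger = logging.getLogger("lrabind.pipeline")

#: manifest keys the estimator requires
REQUIRED_CONDITIONS = ("bound_q", "bound_zero", "free_q")


class ConfigError(ValueError):
    """Invalid pipeline configuration (caught before any computation)."""


@dataclass
class PipelineConfig:
    """Validated pipeline inputs; paths are absolute after loading."""

    manifests: dict
    output_dir: Path
    lra_params: LRAParams = field(default_factory=LRAParams)
    criteria: InteractionCriteria = field(default_factory=InteractionCriteria)
    environment: str = "all"
    fit_selection: str = "backbone"
    ligand_selection: str = "ligand"
    rounding: int = 2

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        base = path.parent
        try:
            manifests = {
                key: (base / value).resolve()
                for key, value in doc["manifests"].items()
            }
            output_dir = (base / doc["output_dir"]).resolve()
        except KeyError as exc:
            raise ConfigError(f"{path}: missing required key {exc}") from exc
        lra_params = LRAParams(**doc.get("lra", {}))
        criteria = InteractionCriteria(**doc.get("criteria", {}))
        config = cls(
            manifests=manifests,
            output_dir=output_dir,
            lra_params=lra_params,
            criteria=criteria,
            environment=doc.get("environment", "all"),
            fit_selection=doc.get("fit_selection", "backbone"),
            ligand_selection=doc.get("ligand_selection", "ligand"),
            rounding=int(doc.get("rounding", 2)),
        )
        config.validate()
        return config

    def validate(self) -> None:
        missing = [c for c in REQUIRED_CONDITIONS if c not in self.manifests]
        if missing:
            raise ConfigError(f"config lacks manifests for: {missing}")
        for key, mpath in self.manifests.items():
            mpath = Path(mpath)
            if not mpath.exists():
                raise ConfigError(f"manifest '{key}' not found: {mpath}")
            manifest = RunManifest.load(mpath).resolve(mpath.parent)
            if not Path(manifest.parameters).exists():
                raise ConfigError(
                    f"parameter file missing for '{key}': {manifest.parameters}"
                )
            for run in manifest.runs:
                if not Path(run.trajectory).exists():
                    raise ConfigError(
                        f"trajectory missing for '{key}': {run.trajectory}"
                    )


@dataclass
class _Condition:
    manifest: RunManifest
    topology: Topology
    trajectories: list


def _load_condition(mpath: Path) -> _Condition:
    manifest = RunManifest.load(mpath).resolve(Path(mpath).parent)
    trajectories = []
    topology = None
    for run in manifest.runs:
        skeleton, trajectory = read_structure(run.trajectory)
        if topology is None:
            topology = read_parameters(manifest.parameters, skeleton)
        trajectory.run_id = Path(run.trajectory).stem
        trajectories.append(trajectory)
    return _Condition(manifest=manifest, topology=topology,
                      trajectories=trajectories)


@dataclass
class PipelineResult:
    """Everything the pipeline computed, plus where it was written."""

    aggregate: AggregateResult
    cycle_residuals: list
    metrics: dict
    occupancy: list
    paths: dict


def compute_energy_series(config: PipelineConfig, condition_key: str,
                          condition: _Condition) -> list[EnergySeries]:
    state = condition.manifest.state
    charge_state = condition.manifest.charge_state
    series = []
    for trajectory in condition.trajectories:
        series.append(
            ensemble_energy_series(
                trajectory, condition.topology,
                state=state, charge_state=charge_state,
                run_id=trajectory.run_id, environment=config.environment,
            )
        )
    return series


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the report bundle under ``output_dir``."""
    config.validate()
    out = Path(config.output_dir)
    for sub in ("energies", "lra", "metrics", "interactions"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    logger.info("lrabind %s starting; output -> %s", __version__, out)

    # --- stage 1: ensemble energies ------------------------------------
    conditions: dict[str, _Condition] = {}
    series: dict[str, list[EnergySeries]] = {}
    for key in REQUIRED_CONDITIONS:
        logger.info("stage energies: %s", key)
        condition = _load_condition(config.manifests[key])
        conditions[key] = condition
        series[key] = compute_energy_series(config, key, condition)
        for s in series[key]:
            s.write_tsv(out / "energies" / f"{s.run_id}.tsv")

    n_runs = {key: len(s) for key, s in series.items()}
    if len(set(n_runs.values())) != 1:
        raise ConfigError(f"conditions have unequal run counts: {n_runs}")

    # --- stage 2: LRA assembly ------------------------------------------
    logger.info("stage lra: %d runs", n_runs["bound_q"])
    results = []
    for i in range(n_runs["bound_q"]):
        bound = StateEnergySummary.from_series(
            series["bound_q"][i], series["bound_zero"][i]
        )
        free = StateEnergySummary.from_series(series["free_q"][i])
        results.append(
            lra_binding(bound, free, config.lra_params, run_id=f"run{i + 1}")
        )
    aggregate = aggregate_runs(results)
    residuals = [cycle_residual(r) for r in results]
    aggregate.to_frame(config.rounding).to_csv(
        out / "lra" / "summary.tsv", sep="\t", index=False
    )
    aggregate.to_frame(None).to_csv(
        out / "lra" / "summary_full_precision.tsv", sep="\t", index=False,
        float_format="%.10g",
    )

    # --- stage 3: stability metrics (bound, charged ensemble) -----------
    logger.info("stage metrics")
    bound_cond = conditions["bound_q"]
    top = bound_cond.topology
    frame0 = bound_cond.trajectories[0].frame(0)
    fit_sel = make_selection(top, config.fit_selection, coords=frame0)
    lig_sel = make_selection(top, config.ligand_selection, coords=frame0)
    lig_rmsd, bb_rmsd, lig_rmsf = [], [], []
    for trajectory in bound_cond.trajectories:
        reference = trajectory.frame(0)
        lig_rmsd.append(
            rmsd_series(trajectory, reference, fit_sel, lig_sel,
                        kind="rmsd_ligand", run_id=trajectory.run_id)
        )
        bb_rmsd.append(
            rmsd_series(trajectory, reference, fit_sel, fit_sel,
                        kind="rmsd_backbone", run_id=trajectory.run_id)
        )
        lig_rmsf.append(
            rmsf(trajectory, fit_sel, lig_sel, run_id=trajectory.run_id)
        )
    metrics = {
        "rmsd_ligand": aggregate_metric(lig_rmsd),
        "rmsd_backbone": aggregate_metric(bb_rmsd),
        "rmsf_ligand": aggregate_metric(lig_rmsf),
    }
    for name, per_run in (("rmsd_ligand", lig_rmsd),
                          ("rmsd_backbone", bb_rmsd),
                          ("rmsf_ligand", lig_rmsf)):
        pd.concat([s.to_frame() for s in per_run]).to_csv(
            out / "metrics" / f"{name}.tsv", sep="\t", index=False,
            float_format="%.6g",
        )
    pd.concat([m.to_frame() for m in metrics.values()]).to_csv(
        out / "metrics" / "summary.tsv", sep="\t", index=False,
        float_format="%.6g",
    )

    # --- stage 4: interaction profile ------------------------------------
    logger.info("stage interactions")
    all_coords = np.concatenate(
        [t.coords for t in bound_cond.trajectories], axis=0
    )
    occupancy = interaction_occupancy(
        Trajectory(coords=all_coords, run_id="all_runs"),
        top, config.criteria,
    )
    occupancy_table(occupancy).to_csv(
        out / "interactions" / "occupancy.tsv", sep="\t", index=False,
        float_format="%.6g",
    )
    (out / "interactions" / "summary.txt").write_text(
        format_binding_summary(occupancy) + "\n"
    )

    # --- machine-readable results ----------------------------------------
    results_doc = {
        "version": __version__,
        "config": _config_fingerprint(config),
        "lra": {
            "params": asdict(config.lra_params),
            "per_run": [
                {"run_id": r.run_id, **r.components,
                 "dG_solv_W": r.dG_solv_W, "dG_solv_P": r.dG_solv_P,
                 "dG_binding": r.dG_binding}
                for r in aggregate.per_run
            ],
            "mean": aggregate.mean,
            "sd": aggregate.sd,
            "n_runs": aggregate.n_runs,
            "cycle_residuals": residuals,
        },
        "metrics": {
            name: {"per_run_means": list(m.per_run_means),
                   "mean": m.mean, "sd": m.sd}
            for name, m in metrics.items()
        },
        "interactions": occupancy_table(occupancy).to_dict(orient="records"),
    }
    results_path = out / "results.json"
    with open(results_path, "w") as fh:
        json.dump(results_doc, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", results_path)

    return PipelineResult(
        aggregate=aggregate,
        cycle_residuals=residuals,
        metrics=metrics,
        occupancy=occupancy,
        paths={
            "results": str(results_path),
            "lra_summary": str(out / "lra" / "summary.tsv"),
            "metrics_summary": str(out / "metrics" / "summary.tsv"),
            "occupancy": str(out / "interactions" / "occupancy.tsv"),
        },
    )


def _config_fingerprint(config: PipelineConfig) -> dict:
    """Config echo with a content hash of the input files (no timestamps)."""
    digest = hashlib.sha256()
    for key in sorted(config.manifests):
        digest.update(Path(config.manifests[key]).read_bytes())
    return {
        "manifests": {k: str(v) for k, v in sorted(config.manifests.items())},
        "environment": config.environment,
        "lra": asdict(config.lra_params),
        "criteria": asdict(config.criteria),
        "manifest_sha256": digest.hexdigest(),
    }
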