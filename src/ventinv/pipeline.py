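"""File-staged orchestration: simulate -> prune -> train -> invert -> report.

Stages communicate only through files in the artifact directory (CSV for
cohorts, JSON for models and reports), so each stage is individually
resumable and every output is a pure function of (inputs, config, seed).
Every JSON artifact is stamped with the seed and a hash of the canonical
config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dataprep, gpso, inverse, surrogate, synthetic
from .schema import DATA_COLUMNS, KNOWN_SETTINGS, OBSERVATION_COLUMNS, SETTINGS_COLUMNS

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PROFILES", "run_pipeline"]

#: Scale profiles.  "table2" and "text" are the full-scale protocols
#: (population 2000 in 50 groups, 200 candidate networks keeping 10, 100
#: trials) differing only in termination; "desk" scales population, trials
#: and candidates down ~10x for a single workstation.
PROFILES: dict[str, dict] = {
    "table2": {
        "population": 2000, "n_groups": 50, "max_iterations": 100,
        "fitness_tolerance": 1e-2, "n_candidates": 200, "ensemble_k": 10,
        "n_trials": 100,
    },
    "text": {
        "population": 2000, "n_groups": 50, "max_iterations": 1000,
        "fitness_tolerance": 1e-4, "n_candidates": 200, "ensemble_k": 10,
        "n_trials": 100,
    },
    "desk": {
        "population": 200, "n_groups": 10, "max_iterations": 150,
        "fitness_tolerance": 1e-5, "n_candidates": 20, "ensemble_k": 3,
        "n_trials": 10,
    },
}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to run the whole flow end to end."""

    out_dir: str = "artifacts"
    seed: int = 0
    profile: str = "desk"
    # simulate
    n_patients: int = 24
    records_per_patient: int = 30
    missing_fraction: float = 0.10
    sigma: float = 0.02
    healthy_fraction: float = 0.25
    # prune
    max_missing: int = 7
    # segregate
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    n_holdout: int = 10
    # train
    topology: tuple[int, ...] = surrogate.DEFAULT_TOPOLOGY
    n_candidates: int | None = None
    ensemble_k: int | None = None
    # invert
    population: int | None = None
    n_groups: int | None = None
    max_iterations: int | None = None
    fitness_tolerance: float | None = None
    omega: float = 0.8
    c1: float = 1.2
    c2: float = 1.2
    c3: float = 1.2
    n_trials: int | None = None
    enforce_pressure_identity: bool = False

    def resolved(self) -> dict:
        """Profile defaults overlaid with any explicit overrides."""
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}; choose from {sorted(PROFILES)}")
        merged = dict(PROFILES[self.profile])
        for key in merged:
            value = getattr(self, key)
            if value is not None:
                merged[key] = value
        if merged["ensemble_k"] > merged["n_candidates"]:
            raise ValueError(
                f"ensemble_k {merged['ensemble_k']} exceeds n_candidates {merged['n_candidates']}"
            )
        return merged

    def gpso_config(self) -> gpso.GPSOConfig:
        r = self.resolved()
        return gpso.GPSOConfig(
            population=r["population"], n_groups=r["n_groups"],
            omega=self.omega, c1=self.c1, c2=self.c2, c3=self.c3,
            max_iterations=r["max_iterations"], fitness_tolerance=r["fitness_tolerance"],
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["split_fractions"] = list(self.split_fractions)
        out["topology"] = list(self.topology)
        return out

    def config_hash(self) -> str:
        """Hash of the canonical config, excluding filesystem paths."""
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        canonical = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("split_fractions", "topology"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")


def _stamp(config: PipelineConfig) -> dict:
    return {"seed": config.seed, "config_hash": config.config_hash()}


def stage_simulate(config: PipelineConfig, out: Path, force: bool = False) -> Path:
    cohort_path = out / "cohort.csv"
    if cohort_path.exists() and not force:
        logger.info("simulate: %s exists, skipping", cohort_path)
        return cohort_path
    spec = synthetic.SyntheticCohortSpec(
        n_patients=config.n_patients,
        records_per_patient=config.records_per_patient,
        missing_fraction=config.missing_fraction,
        sigma=config.sigma,
        seed=config.seed,
        healthy_fraction=config.healthy_fraction,
    )
    observable, truth = synthetic.generate_cohort(spec)
    observable.to_csv(cohort_path, index=False)
    truth.to_csv(out / "truth.csv", index=False)
    _write_json(out / "simulate.json", {**_stamp(config), "rows": len(observable)})
    return cohort_path


def stage_prune(config: PipelineConfig, out: Path, force: bool = False) -> Path:
    pruned_path = out / "pruned.csv"
    if pruned_path.exists() and not force:
        logger.info("prune: %s exists, skipping", pruned_path)
        return pruned_path
    raw = pd.read_csv(out / "cohort.csv")
    result = dataprep.prune_cohort(
        raw, dataprep.PrunePolicy(max_missing=config.max_missing, seed=config.seed)
    )
    result.frame.to_csv(pruned_path, index=False)
    _write_json(out / "prune_report.json", {**_stamp(config), **result.report})
    return pruned_path


def stage_train(config: PipelineConfig, out: Path, force: bool = False) -> Path:
    models_dir = out / "models"
    if (models_dir / "ensemble.json").exists() and not force:
        logger.info("train: %s exists, skipping", models_dir)
        return models_dir
    r = config.resolved()
    pruned = pd.read_csv(out / "pruned.csv")
    plan = dataprep.segregate(
        pruned, fractions=config.split_fractions, n_holdout=config.n_holdout, seed=config.seed
    )
    _write_json(out / "segregation.json", {**_stamp(config), **plan.to_dict()})
    modelling = pruned.iloc[np.concatenate([plan.train, plan.validation, plan.test])]
    ensemble = surrogate.train_ensemble(
        modelling,
        n_candidates=r["n_candidates"],
        k=r["ensemble_k"],
        topology=config.topology,
        seed=config.seed,
    )
    ensemble.save(models_dir)
    return models_dir


def _holdout_targets(out: Path) -> pd.DataFrame:
    pruned = pd.read_csv(out / "pruned.csv")
    plan = json.loads((out / "segregation.json").read_text())
    holdout = pruned.iloc[plan["holdout"]]
    return holdout[list(OBSERVATION_COLUMNS) + list(KNOWN_SETTINGS)].reset_index(drop=True)


def stage_invert(config: PipelineConfig, out: Path, force: bool = False) -> Path:
    reports_dir = out / "reports"
    if (reports_dir / "targets.csv").exists() and not force:
        logger.info("invert: %s exists, skipping", reports_dir)
        return reports_dir
    reports_dir.mkdir(parents=True, exist_ok=True)
    r = config.resolved()
    targets = _holdout_targets(out)
    targets.to_csv(reports_dir / "targets.csv", index=False)
    ensemble = surrogate.EnsembleSelection.load(out / "models")
    pruned = pd.read_csv(out / "pruned.csv")
    field_bounds = dataprep.FieldBounds.from_frame(pruned)
    bounds = gpso.Bounds(
        [field_bounds.lower[c] for c in SETTINGS_COLUMNS],
        [field_bounds.upper[c] for c in SETTINGS_COLUMNS],
    )
    gcfg = config.gpso_config()
    for i, row in targets.iterrows():
        target = inverse.InversionTarget(
            observation=row[list(OBSERVATION_COLUMNS)].to_numpy(dtype=float),
            known_inputs={k: float(row[k]) for k in KNOWN_SETTINGS},
        )
        report = inverse.run_campaign(
            target, ensemble, gcfg, bounds,
            n_trials=r["n_trials"],
            seed=config.seed + i,
            enforce_pressure_identity=config.enforce_pressure_identity,
        )
        _write_json(reports_dir / f"target_{i:02d}.json", {**_stamp(config), **report.to_dict()})
        report.trials_frame().to_csv(reports_dir / f"target_{i:02d}_trials.csv", index=False)
    return reports_dir


def stage_report(config: PipelineConfig, out: Path, force: bool = False) -> Path:
    summary_path = out / "inversion_report.json"
    if summary_path.exists() and not force:
        logger.info("report: %s exists, skipping", summary_path)
        return summary_path
    reports_dir = out / "reports"
    targets = sorted(reports_dir.glob("target_*.json"))
    if not targets:
        raise RuntimeError("no per-target reports found; run the invert stage first")
    summary = {
        "targets": {p.stem: json.loads(p.read_text()) for p in targets},
        **_stamp(config),
    }
    _write_json(summary_path, summary)
    return summary_path


STAGES = {
    "simulate": stage_simulate,
    "prune": stage_prune,
    "train": stage_train,
    "invert": stage_invert,
    "report": stage_report,
}


def run_pipeline(config: PipelineConfig, force: bool = False) -> Path:
    """Execute every stage in order; returns the artifact directory."""
    config.resolved()  # validate before any work
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_json(out / "config.json", {**config.to_dict(), "config_hash": config.config_hash()})
    for name, stage in STAGES.items():
        try:
            stage(config, out, force=force)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return out
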