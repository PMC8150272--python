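"""Inverse mapping: search settings-space so the surrogate matches a target.

For a target observation the graded swarm minimizes

    fitness = 1/2 * sum_i (OutputN_i - TargetN_i)^2

over the bounded settings box, where OutputN/TargetN are surrogate
prediction and target normalized by the surrogate's output bounds.  The
patient demographics (age, weight) are known beforehand and frozen during
the search.  A campaign repeats the search over many trials and every
ensemble member and aggregates per-parameter statistics; because the search
is stochastic, the spread across trials is itself the deliverable — a range
of plausible settings rather than a single point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import gpso
from .schema import (
    OBSERVATION_COLUMNS,
    PEEP_INDEX,
    PIP_INDEX,
    SETP_INDEX,
    SETTINGS_COLUMNS,
    settings_index,
)
from .surrogate import EnsembleSelection, SurrogateModel, normalize

logger = logging.getLogger(__name__)

__all__ = [
    "InversionReport",
    "InversionTarget",
    "TrialResult",
    "fitness",
    "fitness_batch",
    "run_campaign",
    "run_trial",
]


@dataclass(frozen=True)
class InversionTarget:
    """A desired patient observation plus the settings known in advance."""

    observation: np.ndarray               # (7,) raw scale
    known_inputs: dict[str, float]        # e.g. {"age": 4.0, "weight": 21.5}

    def __post_init__(self) -> None:
        obs = np.asarray(self.observation, dtype=float)
        if obs.shape != (len(OBSERVATION_COLUMNS),):
            raise ValueError(f"observation must have {len(OBSERVATION_COLUMNS)} components")
        if not np.all(np.isfinite(obs)):
            raise ValueError("observation must be finite in all components")
        object.__setattr__(self, "observation", obs)
        for name in self.known_inputs:
            settings_index(name)  # raises on unknown fields

    def fixed_dims(self) -> dict[int, float]:
        return {settings_index(k): float(v) for k, v in self.known_inputs.items()}


def _normalized_target(model: SurrogateModel, target: InversionTarget) -> np.ndarray:
    tn = normalize(target.observation, model.output_bounds)
    if np.any(tn < 0) or np.any(tn > 1):
        logger.warning(
            "target observation outside the surrogate's output bounds "
            "(normalized components span [%.3f, %.3f])", float(tn.min()), float(tn.max()),
        )
    return tn


def fitness(settings: np.ndarray, model: SurrogateModel, target: InversionTarget) -> float:
    """Half the sum of squared normalized residuals for one settings vector."""
    settings = np.asarray(settings, dtype=float)
    yn = model.predict_normalized_batch(settings[None, :])[0]
    tn = _normalized_target(model, target)
    resid = yn - tn
    return 0.5 * float(np.sum(resid * resid))


def fitness_batch(settings: np.ndarray, model: SurrogateModel, target_normalized: np.ndarray) -> np.ndarray:
    """Vectorized fitness for an ``(n, 8)`` settings matrix."""
    yn = model.predict_normalized_batch(settings)
    resid = yn - target_normalized
    return 0.5 * np.sum(resid * resid, axis=1)


def _pressure_identity_projection(bounds: gpso.Bounds):
    """Project PIP onto SetP + PEEP (then the caller re-clamps)."""

    def project(x: np.ndarray) -> np.ndarray:
        x = x.copy()
        x[:, PIP_INDEX] = x[:, SETP_INDEX] + x[:, PEEP_INDEX]
        return x

    return project


@dataclass
class TrialResult:
    """Best settings found by one swarm run against one surrogate."""

    best_settings: np.ndarray
    best_fitness: float
    trace: gpso.OptimizationTrace
    network_id: int
    trial_id: int
    seed: int
    top_settings: np.ndarray | None = None  # (top_k, 8) when top_k > 1


def run_trial(
    target: InversionTarget,
    model: SurrogateModel,
    gpso_config: gpso.GPSOConfig,
    bounds: gpso.Bounds,
    seed: int,
    network_id: int = 0,
    trial_id: int = 0,
    enforce_pressure_identity: bool = False,
    top_k: int = 1,
) -> TrialResult:
    """One seeded swarm search for settings reproducing the target."""
    tn = _normalized_target(model, target)
    fixed = target.fixed_dims()
    transform = _pressure_identity_projection(bounds) if enforce_pressure_identity else None
    config = replace(gpso_config, seed=int(seed))
    trace = gpso.optimize(
        lambda x: fitness_batch(x, model, tn),
        bounds,
        config,
        fixed_dims=fixed,
        vectorized=True,
        position_transform=transform,
    )
    top = None
    if top_k > 1:
        order = np.argsort(trace.final_pbest_fitness, kind="stable")[:top_k]
        top = trace.final_pbest_positions[order]
    return TrialResult(
        best_settings=trace.final_best_position,
        best_fitness=trace.final_best_fitness,
        trace=trace,
        network_id=network_id,
        trial_id=trial_id,
        seed=int(seed),
        top_settings=top,
    )


def _derive_seed(campaign_seed: int, network_id: int, trial_id: int) -> int:
    ss = np.random.SeedSequence([int(campaign_seed), int(network_id), int(trial_id)])
    return int(ss.generate_state(1)[0])


@dataclass
class InversionReport:
    """Per-parameter statistics over all trials x ensemble members."""

    parameters: tuple[str, ...]
    stats: pd.DataFrame                  # index: parameter, cols: min/max/mean/sd
    best_settings: np.ndarray
    best_fitness: float
    best_network_id: int
    best_trial_id: int
    n_trials: int
    n_networks: int
    seed: int
    trials: list[TrialResult] = field(default_factory=list)
    per_network_stats: dict[int, pd.DataFrame] = field(default_factory=dict)
    fitness_summary: dict[str, float] = field(default_factory=dict)

    def trials_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            row = {"network_id": t.network_id, "trial_id": t.trial_id, "seed": t.seed,
                   "fitness": t.best_fitness}
            row.update(dict(zip(self.parameters, t.best_settings.tolist())))
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "parameters": list(self.parameters),
            "statistics": {
                p: {k: float(self.stats.loc[p, k]) for k in ("min", "max", "mean", "sd")}
                for p in self.parameters
            },
            "best": {
                "settings": dict(zip(self.parameters, self.best_settings.tolist())),
                "fitness": float(self.best_fitness),
                "network_id": int(self.best_network_id),
                "trial_id": int(self.best_trial_id),
            },
            "per_network": {
                str(nid): {
                    p: {k: float(df.loc[p, k]) for k in ("min", "max", "mean", "sd")}
                    for p in self.parameters
                }
                for nid, df in self.per_network_stats.items()
            },
            "fitness_summary": {k: float(v) for k, v in self.fitness_summary.items()},
            "n_trials": self.n_trials,
            "n_networks": self.n_networks,
            "seed": self.seed,
        }


def _settings_stats(matrix: np.ndarray, parameters: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "min": matrix.min(axis=0),
            "max": matrix.max(axis=0),
            "mean": matrix.mean(axis=0),
            "sd": matrix.std(axis=0),
        },
        index=list(parameters),
    )


def run_campaign(
    target: InversionTarget,
    ensemble: EnsembleSelection,
    gpso_config: gpso.GPSOConfig,
    bounds: gpso.Bounds,
    n_trials: int = 100,
    seed: int = 0,
    enforce_pressure_identity: bool = False,
    top_k: int = 1,
) -> InversionReport:
    """Repeat the inversion over trials and ensemble members, then aggregate.

    Per-trial seeds are derived deterministically from (campaign seed,
    network index, trial index), so the whole campaign is reproducible and
    trials are mutually independent.  Failed trials are logged and
    excluded; statistics pool every successful trial across all networks,
    with a per-network breakdown kept for diagnostics.
    """
    if not ensemble.models:
        raise ValueError("ensemble is empty")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    results: list[TrialResult] = []
    for network_id, model in enumerate(ensemble.models):
        for trial_id in range(n_trials):
            trial_seed = _derive_seed(seed, network_id, trial_id)
            try:
                results.append(
                    run_trial(
                        target, model, gpso_config, bounds, trial_seed,
                        network_id=network_id, trial_id=trial_id,
                        enforce_pressure_identity=enforce_pressure_identity,
                        top_k=top_k,
                    )
                )
            except Exception:  # noqa: BLE001 - campaign survives single failures
                logger.exception("trial %d on network %d failed; excluded", trial_id, network_id)
    if not results:
        raise RuntimeError("every inversion trial failed")

    matrix = np.vstack([r.best_settings for r in results])
    fitnesses = np.array([r.best_fitness for r in results])
    best_idx = int(np.argmin(fitnesses))
    per_network = {}
    for network_id in sorted({r.network_id for r in results}):
        sub = np.vstack([r.best_settings for r in results if r.network_id == network_id])
        per_network[network_id] = _settings_stats(sub, SETTINGS_COLUMNS)
    return InversionReport(
        parameters=SETTINGS_COLUMNS,
        stats=_settings_stats(matrix, SETTINGS_COLUMNS),
        best_settings=results[best_idx].best_settings,
        best_fitness=float(fitnesses[best_idx]),
        best_network_id=results[best_idx].network_id,
        best_trial_id=results[best_idx].trial_id,
        n_trials=n_trials,
        n_networks=len(ensemble.models),
        seed=int(seed),
        trials=results,
        per_network_stats=per_network,
        fitness_summary={
            "min": float(fitnesses.min()),
            "max": float(fitnesses.max()),
            "mean": float(fitnesses.mean()),
            "sd": float(fitnesses.std()),
        },
    )
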