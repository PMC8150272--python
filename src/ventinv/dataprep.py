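"""Cohort pruning: imputation of missing cells, truncation, and segregation.

Sporadically recorded clinical observations leave many empty cells.  Each
incomplete field is filled by a small regression network trained on the
fully complete records (all other fields in, the target field out), and
every imputed value is truncated to the field's observed minimum/maximum
computed from the initial data.  Where the compliance identity
``Cdyn = Vti / (PIP - PEEP)`` determines a missing cell exactly, it is
filled deterministically before any network runs.

Rows missing more than a configurable number of fields are dropped and
counted; the pruning report always satisfies original = final + dropped.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from .schema import DATA_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "FieldBounds",
    "PrunePolicy",
    "PruneResult",
    "SegregationPlan",
    "compute_cdyn",
    "impute_field",
    "prune_cohort",
    "segregate",
]


def compute_cdyn(vti, pip, peep):
    """Dynamic compliance Cdyn = Vti / (PIP - PEEP), in mL/cmH2O.

    Accepts scalars or arrays; raises if any PIP <= PEEP (compliance is
    undefined without a positive driving pressure).
    """
    vti = np.asarray(vti, dtype=float)
    pip = np.asarray(pip, dtype=float)
    peep = np.asarray(peep, dtype=float)
    if np.any(pip <= peep):
        raise ValueError("dynamic compliance undefined: PIP must exceed PEEP")
    out = vti / (pip - peep)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FieldBounds:
    """Observed per-field min/max, computed from pre-imputation cells."""

    lower: dict[str, float]
    upper: dict[str, float]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, columns: Sequence[str] = DATA_COLUMNS) -> "FieldBounds":
        lower, upper = {}, {}
        for col in columns:
            values = pd.to_numeric(frame[col], errors="coerce").dropna()
            if values.empty:
                raise ValueError(f"field {col!r} has no observed values to bound")
            lower[col] = float(values.min())
            upper[col] = float(values.max())
        return cls(lower=lower, upper=upper)

    def clamp(self, fieldname: str, values):
        return np.clip(values, self.lower[fieldname], self.upper[fieldname])

    def to_dict(self) -> dict:
        return {c: [self.lower[c], self.upper[c]] for c in self.lower}


def _normalize_columns(frame: pd.DataFrame, bounds: FieldBounds, columns: Sequence[str]) -> np.ndarray:
    out = np.empty((len(frame), len(columns)))
    for j, col in enumerate(columns):
        lo, up = bounds.lower[col], bounds.upper[col]
        span = (up - lo) or 1.0
        out[:, j] = (frame[col].to_numpy(dtype=float) - lo) / span
    return out


@dataclass
class ImputationOutcome:
    frame: pd.DataFrame
    n_imputed: int
    status: str  # "filled" | "noop" | "unimputable"


def impute_field(
    records: pd.DataFrame,
    target_field: str,
    bounds: FieldBounds | None = None,
    seed: int = 0,
    min_complete: int = 20,
    hidden_layers: tuple[int, ...] = (16, 8),
    max_iter: int = 1000,
    n_restarts: int = 5,
    alpha: float = 1e-3,
) -> ImputationOutcome:
    """Fill missing cells of one field with networks trained on complete rows.

    The imputer maps the other 14 (normalized) fields to the target field
    and is trained on records complete in all 15 fields.  Training sets are
    small, so ``n_restarts`` independently initialized networks are averaged
    to damp initialization variance.  Remaining NaNs in the predictors of a
    row being filled are temporarily median-filled.  Every imputed value is
    clamped to the field's observed bounds.
    """
    if target_field not in DATA_COLUMNS:
        raise ValueError(f"unknown field: {target_field!r}")
    missing_mask = records[target_field].isna()
    if not missing_mask.any():
        return ImputationOutcome(records, 0, "noop")
    if bounds is None:
        bounds = FieldBounds.from_frame(records)

    predictors = [c for c in DATA_COLUMNS if c != target_field]
    complete = records.dropna(subset=list(DATA_COLUMNS))
    if len(complete) < min_complete:
        logger.warning(
            "field %s un-imputable: only %d complete records (< %d)",
            target_field, len(complete), min_complete,
        )
        return ImputationOutcome(records, 0, "unimputable")

    X_train = _normalize_columns(complete, bounds, predictors)
    lo, up = bounds.lower[target_field], bounds.upper[target_field]
    span = (up - lo) or 1.0
    y_train = (complete[target_field].to_numpy(dtype=float) - lo) / span

    rows = records.loc[missing_mask, predictors].copy()
    medians = complete[predictors].median()
    rows = rows.fillna(medians)
    X_pred = _normalize_columns(rows, bounds, predictors)

    committee = np.zeros(len(rows))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for restart in range(n_restarts):
            mlp = MLPRegressor(
                hidden_layer_sizes=hidden_layers,
                activation="tanh",
                solver="lbfgs",
                alpha=alpha,
                max_iter=max_iter,
                random_state=(int(seed) + restart) % (2**32),
            )
            mlp.fit(X_train, y_train)
            committee += mlp.predict(X_pred)
    predicted = (committee / n_restarts) * span + lo

    out = records.copy()
    out.loc[missing_mask, target_field] = bounds.clamp(target_field, predicted)
    return ImputationOutcome(out, int(missing_mask.sum()), "filled")


@dataclass(frozen=True)
class PrunePolicy:
    """Knobs of the pruning pipeline."""

    max_missing: int = 7          # rows missing more than this many fields are dropped
    min_complete: int = 20        # complete rows needed to train an imputer
    seed: int = 0
    imputer_hidden: tuple[int, ...] = (16, 8)
    imputer_max_iter: int = 1000
    cdyn_conflict_tolerance: float = 0.05


@dataclass
class PruneResult:
    frame: pd.DataFrame
    report: dict


def _fill_compliance_identity(frame: pd.DataFrame, bounds: FieldBounds) -> dict[str, int]:
    """Deterministic fills from Cdyn = Vti / (PIP - PEEP) where it applies."""
    counts = {"Cdyn": 0, "Vti": 0}
    dp_ok = (frame["PIP"] - frame["PEEP"]) > 0

    can_cdyn = frame["Cdyn"].isna() & frame["Vti"].notna() & frame["PIP"].notna() & frame["PEEP"].notna() & dp_ok
    if can_cdyn.any():
        values = compute_cdyn(
            frame.loc[can_cdyn, "Vti"], frame.loc[can_cdyn, "PIP"], frame.loc[can_cdyn, "PEEP"]
        )
        frame.loc[can_cdyn, "Cdyn"] = bounds.clamp("Cdyn", values)
        counts["Cdyn"] = int(can_cdyn.sum())

    can_vti = frame["Vti"].isna() & frame["Cdyn"].notna() & frame["PIP"].notna() & frame["PEEP"].notna() & dp_ok
    if can_vti.any():
        values = frame.loc[can_vti, "Cdyn"] * (frame.loc[can_vti, "PIP"] - frame.loc[can_vti, "PEEP"])
        frame.loc[can_vti, "Vti"] = bounds.clamp("Vti", values)
        counts["Vti"] = int(can_vti.sum())
    return counts


def prune_cohort(raw: pd.DataFrame, policy: PrunePolicy | None = None) -> PruneResult:
    """Run the full pruning pipeline and emit a bookkeeping report.

    Steps: observed field bounds from the initial data, drop rows missing
    too many fields, deterministic compliance fills, then per-field network
    imputation in descending order of field completeness.  The report
    counts every dropped row and imputed cell.
    """
    policy = policy or PrunePolicy()
    missing_cols = [c for c in DATA_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"cohort is missing columns: {missing_cols}")
    n_original = len(raw)
    bounds = FieldBounds.from_frame(raw)

    n_missing = raw[list(DATA_COLUMNS)].isna().sum(axis=1)
    kept = raw.loc[n_missing <= policy.max_missing].copy()
    dropped_overfull = int(n_original - len(kept))

    conflicts = _count_cdyn_conflicts(kept, policy.cdyn_conflict_tolerance)
    derived_fills = _fill_compliance_identity(kept, bounds)

    completeness = kept[list(DATA_COLUMNS)].notna().sum()
    order = sorted(DATA_COLUMNS, key=lambda c: (-int(completeness[c]), DATA_COLUMNS.index(c)))
    imputed_counts: dict[str, int] = {}
    dropped_unimputable = 0
    for i, fieldname in enumerate(order):
        if not kept[fieldname].isna().any():
            continue
        outcome = impute_field(
            kept,
            fieldname,
            bounds=bounds,
            seed=policy.seed + i,
            min_complete=policy.min_complete,
            hidden_layers=policy.imputer_hidden,
            max_iter=policy.imputer_max_iter,
        )
        if outcome.status == "unimputable":
            bad = kept[fieldname].isna()
            dropped_unimputable += int(bad.sum())
            logger.warning("dropping %d records missing un-imputable field %s", int(bad.sum()), fieldname)
            kept = kept.loc[~bad]
        else:
            kept = outcome.frame
            imputed_counts[fieldname] = outcome.n_imputed

    report = {
        "original": n_original,
        "dropped_overfull_rows": dropped_overfull,
        "dropped_unimputable_rows": dropped_unimputable,
        "dropped": dropped_overfull + dropped_unimputable,
        "final": len(kept),
        "derived_compliance_fills": derived_fills,
        "imputed_cells": imputed_counts,
        "cdyn_conflicts": conflicts,
        "field_bounds": bounds.to_dict(),
        "seed": policy.seed,
    }
    assert report["original"] == report["final"] + report["dropped"]
    return PruneResult(frame=kept.reset_index(drop=True), report=report)


def _count_cdyn_conflicts(frame: pd.DataFrame, tolerance: float) -> int:
    """Count recorded Cdyn values conflicting with the compliance identity.

    The recorded observation wins (it is the measurement); conflicts are
    only logged.
    """
    ok = (
        frame["Cdyn"].notna()
        & frame["Vti"].notna()
        & frame["PIP"].notna()
        & frame["PEEP"].notna()
        & ((frame["PIP"] - frame["PEEP"]) > 0)
    )
    if not ok.any():
        return 0
    recorded = frame.loc[ok, "Cdyn"].to_numpy(dtype=float)
    recomputed = compute_cdyn(frame.loc[ok, "Vti"], frame.loc[ok, "PIP"], frame.loc[ok, "PEEP"])
    rel = np.abs(recomputed - recorded) / np.maximum(np.abs(recorded), 1e-12)
    n = int((rel > tolerance).sum())
    if n:
        logger.info("%d recorded Cdyn values conflict with Vti/(PIP-PEEP) by > %.0f%%", n, 100 * tolerance)
    return n


@dataclass(frozen=True)
class SegregationPlan:
    """Disjoint, exhaustive split of a pruned cohort.

    Indices are positions into the pruned frame: a holdout set reserved for
    inverse-mapping tests plus train/validation/test partitions of the rest.
    """

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    holdout: np.ndarray
    seed: int
    fractions: tuple[float, float, float]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "training": int(self.train.size),
            "validation": int(self.validation.size),
            "testing": int(self.test.size),
            "inverse_testing": int(self.holdout.size),
        }

    def to_dict(self) -> dict:
        return {
            "train": self.train.tolist(),
            "validation": self.validation.tolist(),
            "test": self.test.tolist(),
            "holdout": self.holdout.tolist(),
            "seed": self.seed,
            "fractions": list(self.fractions),
            "counts": self.counts,
        }


def segregate(
    pruned: pd.DataFrame,
    fractions: Sequence[float] = (0.70, 0.15, 0.15),
    n_holdout: int = 10,
    seed: int = 0,
) -> SegregationPlan:
    """Randomly reserve inverse-mapping holdout records, split the rest."""
    if len(fractions) != 3 or not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError("fractions must be three values summing to 1")
    n = len(pruned)
    if not 0 <= n_holdout < n:
        raise ValueError("n_holdout must be smaller than the cohort")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    holdout = np.sort(perm[:n_holdout])
    rest = perm[n_holdout:]
    n_rest = rest.size
    n_train = int(round(fractions[0] * n_rest))
    n_val = int(round(fractions[1] * n_rest))
    return SegregationPlan(
        train=np.sort(rest[:n_train]),
        validation=np.sort(rest[n_train : n_train + n_val]),
        test=np.sort(rest[n_train + n_val :]),
        holdout=holdout,
        seed=seed,
        fractions=tuple(float(f) for f in fractions),
    )
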