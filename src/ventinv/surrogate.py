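"""Forward surrogate: networks mapping ventilator settings to patient response.

Networks are trained with scikit-learn's ``MLPRegressor`` on min-max
normalized features, then frozen into :class:`SurrogateModel`, a plain
numpy forward pass (tanh hidden layers, linear output).  Freezing makes
prediction fast enough to sit inside a swarm-optimization loop and makes
models serializable as portable JSON archives.

Many candidate networks are trained with independently re-randomized
train/validation/test splits; the candidates with the smallest total error
(sum of squared normalized errors over all three partitions) form the
ensemble used by the inverse mapper.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from .gpso import Bounds
from .schema import DATA_COLUMNS, OBSERVATION_COLUMNS, SETTINGS_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_TOPOLOGY",
    "EnsembleSelection",
    "SurrogateModel",
    "denormalize",
    "normalize",
    "train_ensemble",
    "train_network",
]

#: Hidden-layer widths of the forward network (a 7-unit linear output
#: layer follows the last hidden layer).
DEFAULT_TOPOLOGY: tuple[int, ...] = (8, 16, 14, 7)

DEFAULT_SPLIT_FRACTIONS: tuple[float, float, float] = (0.70, 0.15, 0.15)


def normalize(x: np.ndarray, bounds: Bounds) -> np.ndarray:
    """Map each feature onto [0, 1] by its bounds.

    A degenerate feature (lower == upper) maps to 0.5 by convention.
    Out-of-bounds inputs produce values outside [0, 1]; callers clamp when
    they need to.
    """
    x = np.asarray(x, dtype=float)
    span = bounds.span
    safe = np.where(span > 0, span, 1.0)
    out = (x - bounds.lower) / safe
    return np.where(span > 0, out, 0.5)


def denormalize(x: np.ndarray, bounds: Bounds) -> np.ndarray:
    """Inverse of :func:`normalize`; degenerate features return their bound."""
    x = np.asarray(x, dtype=float)
    span = bounds.span
    return np.where(span > 0, bounds.lower + x * span, bounds.lower)


@dataclass
class SurrogateModel:
    """A trained forward network with its normalization bounds.

    ``weights``/``biases`` include the final linear layer, so there are
    ``len(topology) + 1`` of each.
    """

    topology: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    input_bounds: Bounds
    output_bounds: Bounds
    split_seed: int
    total_error: float
    error_breakdown: dict[str, float] = field(default_factory=dict)

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[0]

    @property
    def n_outputs(self) -> int:
        return self.weights[-1].shape[1]

    def _forward(self, zn: np.ndarray) -> np.ndarray:
        h = zn
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.tanh(h @ w + b)
        return h @ self.weights[-1] + self.biases[-1]

    def predict_normalized_batch(self, settings: np.ndarray) -> np.ndarray:
        """Raw settings ``(n, 8)`` -> normalized predictions ``(n, 7)``."""
        settings = np.asarray(settings, dtype=float)
        if settings.ndim != 2 or settings.shape[1] != self.n_inputs:
            raise ValueError(f"expected (n, {self.n_inputs}) settings matrix")
        return self._forward(normalize(settings, self.input_bounds))

    def predict_batch(self, settings: np.ndarray) -> np.ndarray:
        """Raw settings ``(n, 8)`` -> raw-scale predictions ``(n, 7)``."""
        return denormalize(self.predict_normalized_batch(settings), self.output_bounds)

    def predict(self, settings: np.ndarray) -> np.ndarray:
        """Predict the 7 responses for a single settings vector."""
        settings = np.asarray(settings, dtype=float)
        if settings.shape != (self.n_inputs,):
            raise ValueError(f"expected a {self.n_inputs}-vector of settings")
        if not np.all(np.isfinite(settings)):
            raise ValueError("settings must be finite")
        return self.predict_batch(settings[None, :])[0]

    def to_dict(self) -> dict:
        return {
            "topology": list(self.topology),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "input_lower": self.input_bounds.lower.tolist(),
            "input_upper": self.input_bounds.upper.tolist(),
            "output_lower": self.output_bounds.lower.tolist(),
            "output_upper": self.output_bounds.upper.tolist(),
            "split_seed": int(self.split_seed),
            "total_error": float(self.total_error),
            "error_breakdown": {k: float(v) for k, v in self.error_breakdown.items()},
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SurrogateModel":
        return cls(
            topology=tuple(payload["topology"]),
            weights=[np.asarray(w, dtype=float) for w in payload["weights"]],
            biases=[np.asarray(b, dtype=float) for b in payload["biases"]],
            input_bounds=Bounds(payload["input_lower"], payload["input_upper"]),
            output_bounds=Bounds(payload["output_lower"], payload["output_upper"]),
            split_seed=int(payload["split_seed"]),
            total_error=float(payload["total_error"]),
            error_breakdown=dict(payload.get("error_breakdown", {})),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "SurrogateModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _split_indices(
    n: int, fractions: Sequence[float], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if len(fractions) != 3 or not np.isclose(sum(fractions), 1.0):
        raise ValueError("split_fractions must be three values summing to 1")
    perm = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


def _cohort_matrices(cohort: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in DATA_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing columns: {missing}")
    data = cohort[list(DATA_COLUMNS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("cohort contains missing or non-finite cells; prune it first")
    k = len(SETTINGS_COLUMNS)
    return data[:, :k], data[:, k:]


def train_network(
    cohort: pd.DataFrame,
    topology: tuple[int, ...] = DEFAULT_TOPOLOGY,
    split_fractions: Sequence[float] = DEFAULT_SPLIT_FRACTIONS,
    seed: int = 0,
    solver: str = "lbfgs",
    max_iter: int = 600,
    alpha: float = 1e-4,
) -> SurrogateModel:
    """Train one forward network on a complete cohort.

    The cohort is min-max normalized feature-wise; the record split is
    re-randomized from ``seed``.  ``total_error`` is the sum of squared
    prediction errors on the normalized scale over the training, validation
    and testing partitions together.
    """
    X, Y = _cohort_matrices(cohort)
    if X.shape[0] < 20:
        raise ValueError("cohort too small to train a surrogate (need >= 20 records)")
    input_bounds = Bounds(X.min(axis=0), X.max(axis=0))
    output_bounds = Bounds(Y.min(axis=0), Y.max(axis=0))
    Xn = normalize(X, input_bounds)
    Yn = normalize(Y, output_bounds)

    rng = np.random.default_rng(seed)
    idx_train, idx_val, idx_test = _split_indices(X.shape[0], split_fractions, rng)

    mlp = MLPRegressor(
        hidden_layer_sizes=tuple(topology),
        activation="tanh",
        solver=solver,
        alpha=alpha,
        max_iter=max_iter,
        random_state=int(seed) % (2**32),
        early_stopping=(solver in ("adam", "sgd")),
        n_iter_no_change=25,
        tol=1e-7,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        mlp.fit(Xn[idx_train], Yn[idx_train])

    model = SurrogateModel(
        topology=tuple(topology),
        weights=[np.asarray(w, dtype=float) for w in mlp.coefs_],
        biases=[np.asarray(b, dtype=float) for b in mlp.intercepts_],
        input_bounds=input_bounds,
        output_bounds=output_bounds,
        split_seed=int(seed),
        total_error=0.0,
    )
    breakdown = {}
    for name, idx in (("training", idx_train), ("validation", idx_val), ("testing", idx_test)):
        if idx.size:
            resid = model._forward(Xn[idx]) - Yn[idx]
            breakdown[name] = float(np.sum(resid**2))
        else:
            breakdown[name] = 0.0
    model.error_breakdown = breakdown
    model.total_error = float(sum(breakdown.values()))
    return model


@dataclass
class EnsembleSelection:
    """The ``k`` best candidate networks, ranked by ascending total error."""

    models: list[SurrogateModel]
    k: int
    candidate_errors: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.models) != self.k:
            raise ValueError("ensemble size does not match k")
        errs = [m.total_error for m in self.models]
        if errs != sorted(errs):
            raise ValueError("ensemble models must be sorted by total_error")

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, model in enumerate(self.models):
            model.save(directory / f"model_{i:03d}.json")
        meta = {
            "k": self.k,
            "candidate_errors": [float(e) for e in self.candidate_errors],
            "model_files": [f"model_{i:03d}.json" for i in range(self.k)],
        }
        (directory / "ensemble.json").write_text(json.dumps(meta, sort_keys=True, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "EnsembleSelection":
        directory = Path(directory)
        meta = json.loads((directory / "ensemble.json").read_text())
        models = [SurrogateModel.load(directory / name) for name in meta["model_files"]]
        return cls(models=models, k=int(meta["k"]), candidate_errors=meta["candidate_errors"])


def train_ensemble(
    cohort: pd.DataFrame,
    n_candidates: int = 200,
    k: int = 10,
    topology: tuple[int, ...] = DEFAULT_TOPOLOGY,
    seed: int = 0,
    **train_kwargs,
) -> EnsembleSelection:
    """Train ``n_candidates`` networks and keep the ``k`` with least error.

    Each candidate gets an independently derived seed, re-randomizing both
    its data split and its weight initialization.  Individual training
    failures are logged and skipped; fewer than ``k`` successes is an error.
    """
    if not 1 <= k <= n_candidates:
        raise ValueError("need n_candidates >= k >= 1")
    candidates: list[SurrogateModel] = []
    errors: list[float] = []
    for i in range(n_candidates):
        candidate_seed = int(np.random.SeedSequence([int(seed), i]).generate_state(1)[0])
        try:
            model = train_network(cohort, topology=topology, seed=candidate_seed, **train_kwargs)
        except Exception:  # noqa: BLE001 - any single failure is survivable
            logger.exception("candidate network %d failed to train; skipping", i)
            continue
        candidates.append(model)
        errors.append(model.total_error)
    if len(candidates) < k:
        raise RuntimeError(f"only {len(candidates)} of {n_candidates} candidates trained; need {k}")
    order = np.argsort([m.total_error for m in candidates], kind="stable")
    selected = [candidates[int(i)] for i in order[:k]]
    return EnsembleSelection(models=selected, k=k, candidate_errors=errors)
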