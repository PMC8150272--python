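"""Synthetic ventilated-patient cohorts with a known ground-truth response map.

The generator stands in for clinical data that cannot be redistributed.  It
samples patients (age, weight, lung status), draws ventilator settings
uniformly within physiologic bounds with the pressure identity
``PIP = SetP + PEEP`` enforced, pushes them through a smooth, monotone
response map, and optionally adds multiplicative observation noise and
missing-at-random cells.  The map is deliberately simple scaffolding, not a
mechanistic lung model, but it honours the constraints the pipeline relies
on — most importantly the exact compliance identity
``Vti = Cdyn * (PIP - PEEP)`` — so that training, imputation and inversion
can all be tested against known answers.

All functional forms and coefficients live in :data:`DEFAULT_COEFFS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .gpso import Bounds
from .schema import (
    DATA_COLUMNS,
    KNOWN_SETTINGS,
    OBSERVATION_COLUMNS,
    SETTINGS_COLUMNS,
)

__all__ = [
    "DEFAULT_COEFFS",
    "DEFAULT_NOISE_WEIGHTS",
    "DEFAULT_OUTPUT_BOUNDS",
    "DEFAULT_SETTING_BOUNDS",
    "GroundTruthModel",
    "InversionFixture",
    "SyntheticCohortSpec",
    "generate_cohort",
    "ground_truth_response",
    "make_inversion_fixture",
]

#: Sampling bounds for the independent settings; PIP bounds follow from the
#: identity PIP = SetP + PEEP.
DEFAULT_SETTING_BOUNDS: dict[str, tuple[float, float]] = {
    "SetP": (5.0, 30.0),
    "PEEP": (0.0, 12.0),
    "PSV": (0.0, 20.0),
    "RR": (8.0, 40.0),
    "FiO2": (21.0, 100.0),
    "age": (0.5, 15.0),
    "weight": (2.0, 60.0),
}

#: Declared bounds for the noiseless response map (outputs are clipped here).
DEFAULT_OUTPUT_BOUNDS: dict[str, tuple[float, float]] = {
    "Vti": (0.0, 2200.0),
    "Cdyn": (0.0, 70.0),
    "EtCO2": (5.0, 95.0),
    "SpO2": (0.0, 100.0),
    "HR": (40.0, 260.0),
    "BP": (40.0, 140.0),
    "Temp": (35.5, 40.5),
}

#: Relative observation-noise weight per output; the effective noise std of
#: output y is sigma * weight * |y|.  Pulse-oximetry and thermometry are far
#: less noisy in relative terms than flow-derived quantities.
DEFAULT_NOISE_WEIGHTS: dict[str, float] = {
    "Vti": 1.0,
    "Cdyn": 1.0,
    "EtCO2": 1.0,
    "SpO2": 0.15,
    "HR": 0.5,
    "BP": 0.5,
    "Temp": 0.02,
}

#: Every coefficient of the ground-truth response map, in one place.
DEFAULT_COEFFS: dict[str, float] = {
    # dynamic compliance (mL/cmH2O): linear in weight, mild decline with age
    "cdyn_per_kg": 1.0,
    "cdyn_age_slope": 0.01,
    "cdyn_unhealthy_mult": 0.45,
    # ventilation/EtCO2: log response to weight-scaled alveolar minute volume
    "deadspace_per_kg": 2.2,
    "psv_vent_gain": 0.015,
    "et_base": 40.0,
    "et_slope": 12.0,
    "et_ref": 5.5,
    # oxygenation: saturating in FiO2 and PEEP, depressed by unhealthy lungs
    "spo2_deficit_healthy": 6.0,
    "spo2_deficit_unhealthy": 30.0,
    "spo2_fio2_gain": 2.2,
    "spo2_peep_gain": 0.12,
    # weakly coupled vitals
    "hr_base": 160.0,
    "hr_weight": 1.5,
    "hr_setp": 0.8,
    "hr_psv": 1.0,
    "hr_unhealthy": 15.0,
    "bp_base": 92.0,
    "bp_weight": 0.15,
    "bp_peep": 1.3,
    "bp_unhealthy": 8.0,
    "temp_base": 39.0,
    "temp_psv": 0.06,
    "temp_rr": 0.02,
    "temp_weight": 0.004,
}


@dataclass(frozen=True)
class GroundTruthModel:
    """Deterministic response map plus its noise model, for one lung status."""

    lung_status: str = "unhealthy"  # "healthy" | "unhealthy"
    sigma: float = 0.0
    noise_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_WEIGHTS)
    )
    setting_bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SETTING_BOUNDS)
    )
    output_bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_OUTPUT_BOUNDS)
    )
    coeffs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_COEFFS))

    def __post_init__(self) -> None:
        if self.lung_status not in ("healthy", "unhealthy"):
            raise ValueError("lung_status must be 'healthy' or 'unhealthy'")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def compliance(self, age: np.ndarray, weight: np.ndarray) -> np.ndarray:
        """True dynamic compliance as a function of demographics and status."""
        c = self.coeffs
        mult = c["cdyn_unhealthy_mult"] if self.lung_status == "unhealthy" else 1.0
        return mult * c["cdyn_per_kg"] * np.asarray(weight) * (
            1.0 - c["cdyn_age_slope"] * np.asarray(age)
        )

    def settings_bounds(self) -> Bounds:
        """Box bounds for the full 8-dimensional settings vector."""
        lo, up = [], []
        for name in SETTINGS_COLUMNS:
            if name == "PIP":
                lo.append(self.setting_bounds["SetP"][0] + self.setting_bounds["PEEP"][0])
                up.append(self.setting_bounds["SetP"][1] + self.setting_bounds["PEEP"][1])
            else:
                lo.append(self.setting_bounds[name][0])
                up.append(self.setting_bounds[name][1])
        return Bounds(np.array(lo), np.array(up))

    def noise_weight_vector(self) -> np.ndarray:
        return np.array([self.noise_weights[name] for name in OBSERVATION_COLUMNS])


def _smooth_positive(x: np.ndarray, scale: float = 20.0) -> np.ndarray:
    """Smooth, strictly increasing surrogate for max(x, 0)."""
    return 0.5 * (x + np.sqrt(x * x + scale * scale))


def _response_batch(settings: np.ndarray, model: GroundTruthModel) -> np.ndarray:
    """Vectorized noiseless response for a matrix of in-bounds settings."""
    c = model.coeffs
    s = {name: settings[:, i] for i, name in enumerate(SETTINGS_COLUMNS)}
    dp = s["PIP"] - s["PEEP"]
    if np.any(dp <= 0):
        raise ValueError("PIP must exceed PEEP for a defined tidal volume")

    cdyn = model.compliance(s["age"], s["weight"])
    vti = cdyn * dp

    deadspace = c["deadspace_per_kg"] * s["weight"]
    alveolar = _smooth_positive(vti - deadspace)
    minute_vent = s["RR"] * alveolar * (1.0 + c["psv_vent_gain"] * s["PSV"])
    etco2 = c["et_base"] + c["et_slope"] * (
        c["et_ref"] - np.log(minute_vent / s["weight"] ** 0.75)
    )

    deficit = (
        c["spo2_deficit_unhealthy"]
        if model.lung_status == "unhealthy"
        else c["spo2_deficit_healthy"]
    )
    spo2 = 100.0 - deficit * np.exp(
        -(c["spo2_fio2_gain"] * (s["FiO2"] - 21.0) / 79.0 + c["spo2_peep_gain"] * s["PEEP"])
    )

    unhealthy = 1.0 if model.lung_status == "unhealthy" else 0.0
    hr = (
        c["hr_base"]
        - c["hr_weight"] * s["weight"]
        + c["hr_setp"] * s["SetP"]
        + c["hr_psv"] * s["PSV"]
        + c["hr_unhealthy"] * unhealthy
    )
    bp = (
        c["bp_base"]
        + c["bp_weight"] * s["weight"]
        - c["bp_peep"] * s["PEEP"]
        - c["bp_unhealthy"] * unhealthy
    )
    temp = (
        c["temp_base"]
        - c["temp_psv"] * s["PSV"]
        - c["temp_rr"] * s["RR"]
        + c["temp_weight"] * s["weight"]
    )

    out = np.column_stack([vti, cdyn, etco2, spo2, hr, bp, temp])
    # Clip to the declared output box, except the compliance identity pair:
    # Vti and Cdyn must keep Vti = Cdyn * (PIP - PEEP) exact.
    for j, name in enumerate(OBSERVATION_COLUMNS):
        if name in ("Vti", "Cdyn"):
            continue
        lo, up = model.output_bounds[name]
        out[:, j] = np.clip(out[:, j], lo, up)
    return out


def ground_truth_response(settings: np.ndarray, model: GroundTruthModel) -> np.ndarray:
    """Noiseless 7-component response for one in-bounds settings vector."""
    settings = np.asarray(settings, dtype=float)
    if settings.shape != (len(SETTINGS_COLUMNS),):
        raise ValueError(f"expected a {len(SETTINGS_COLUMNS)}-vector of settings")
    if not model.settings_bounds().contains(settings):
        raise ValueError("settings outside the model's declared bounds")
    return _response_batch(settings[None, :], model)[0]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Size, noise and missingness profile of a generated cohort."""

    n_patients: int = 24
    records_per_patient: int = 30
    missing_fraction: float = 0.0
    sigma: float = 0.0
    seed: int = 0
    healthy_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.records_per_patient < 1:
            raise ValueError("counts must be >= 1")
        for name in ("missing_fraction", "healthy_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def _sample_patients(spec: SyntheticCohortSpec, rng: np.random.Generator,
                     bounds: Mapping[str, tuple[float, float]]) -> pd.DataFrame:
    n = spec.n_patients
    n_healthy = int(round(spec.healthy_fraction * n))
    status = np.array(["healthy"] * n_healthy + ["unhealthy"] * (n - n_healthy))
    rng.shuffle(status)
    age = rng.uniform(*bounds["age"], size=n)
    weight = rng.uniform(*bounds["weight"], size=n)
    species = np.where(weight < 6.5, "feline", "canine")
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "species": species,
            "lung_status": status,
            "age": age,
            "weight": weight,
        }
    )


def generate_cohort(
    spec: SyntheticCohortSpec,
    model: GroundTruthModel | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an observable cohort and its hidden truth table.

    Returns ``(observable, truth)``: identically shaped frames with the
    metadata columns plus the 15 canonical data columns.  The observable
    frame carries noise and NaNs for masked cells; the truth table is the
    noiseless, complete version.  Demographics (age, weight) are never
    masked.  ``model`` supplies bounds/coefficients; its ``lung_status`` and
    ``sigma`` fields are overridden per patient and from the spec.
    """
    base = model if model is not None else GroundTruthModel()
    rng = np.random.default_rng(spec.seed)
    patients = _sample_patients(spec, rng, base.setting_bounds)
    models = {
        status: replace(base, lung_status=status, sigma=spec.sigma)
        for status in ("healthy", "unhealthy")
    }

    rows_meta, truth_blocks, noisy_blocks = [], [], []
    m = spec.records_per_patient
    for _, patient in patients.iterrows():
        sb = base.setting_bounds
        setp = rng.uniform(*sb["SetP"], size=m)
        peep = rng.uniform(*sb["PEEP"], size=m)
        psv = rng.uniform(*sb["PSV"], size=m)
        rr = rng.uniform(*sb["RR"], size=m)
        fio2 = rng.uniform(*sb["FiO2"], size=m)
        settings = np.column_stack(
            [
                setp,
                setp + peep,  # PIP = SetP + PEEP by construction
                peep,
                psv,
                rr,
                fio2,
                np.full(m, patient["age"]),
                np.full(m, patient["weight"]),
            ]
        )
        pmodel = models[patient["lung_status"]]
        response = _response_batch(settings, pmodel)
        noise = rng.standard_normal(response.shape)
        noisy = response * (1.0 + spec.sigma * pmodel.noise_weight_vector() * noise)
        # physical ceiling for saturation survives the noise
        spo2_col = OBSERVATION_COLUMNS.index("SpO2")
        noisy[:, spo2_col] = np.clip(noisy[:, spo2_col], 0.0, 100.0)

        for t in range(m):
            rows_meta.append(
                {
                    "patient_id": patient["patient_id"],
                    "species": patient["species"],
                    "lung_status": patient["lung_status"],
                    "timestamp": t,
                }
            )
        truth_blocks.append(np.hstack([settings, response]))
        noisy_blocks.append(np.hstack([settings, noisy]))

    meta = pd.DataFrame(rows_meta)
    truth = pd.concat(
        [meta, pd.DataFrame(np.vstack(truth_blocks), columns=list(DATA_COLUMNS))], axis=1
    )
    observable = pd.concat(
        [meta.copy(), pd.DataFrame(np.vstack(noisy_blocks), columns=list(DATA_COLUMNS))], axis=1
    )

    if spec.missing_fraction > 0:
        maskable = [c for c in DATA_COLUMNS if c not in KNOWN_SETTINGS]
        mask = rng.random((len(observable), len(maskable))) < spec.missing_fraction
        block = observable[maskable].to_numpy(dtype=float)
        block[mask] = np.nan
        observable[maskable] = block
    return observable, truth


@dataclass(frozen=True)
class InversionFixture:
    """A test case with a known correct inversion answer."""

    settings: dict[str, float]       # the true settings s*
    observation: dict[str, float]    # g(s*), noiseless
    known_inputs: dict[str, float]   # demographics fixed during inversion
    lung_status: str


def make_inversion_fixture(
    model: GroundTruthModel,
    seed: int = 0,
    age: float | None = None,
    weight: float | None = None,
) -> InversionFixture:
    """Draw one settings vector and its exact response as an inversion target."""
    rng = np.random.default_rng(seed)
    sb = model.setting_bounds
    age = float(rng.uniform(*sb["age"])) if age is None else float(age)
    weight = float(rng.uniform(*sb["weight"])) if weight is None else float(weight)
    setp = rng.uniform(*sb["SetP"])
    peep = rng.uniform(*sb["PEEP"])
    settings = np.array(
        [
            setp,
            setp + peep,
            peep,
            rng.uniform(*sb["PSV"]),
            rng.uniform(*sb["RR"]),
            rng.uniform(*sb["FiO2"]),
            age,
            weight,
        ]
    )
    observation = ground_truth_response(settings, model)
    return InversionFixture(
        settings=dict(zip(SETTINGS_COLUMNS, settings.tolist())),
        observation=dict(zip(OBSERVATION_COLUMNS, observation.tolist())),
        known_inputs={"age": age, "weight": weight},
        lung_status=model.lung_status,
    )
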