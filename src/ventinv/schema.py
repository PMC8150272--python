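"""Canonical column layout shared by every stage of the pipeline.

A cohort table carries 8 setting columns (ventilator knobs plus the two
patient demographics) followed by 7 observed-response columns.  All modules
address features positionally through these tuples, never by hard-coded
indices.
"""

from __future__ import annotations

#: Ventilator settings and demographics, in search-space order.
SETTINGS_COLUMNS: tuple[str, ...] = (
    "SetP",    # set inspiratory pressure above PEEP, cmH2O
    "PIP",     # peak inspiratory pressure, cmH2O
    "PEEP",    # positive end-expiratory pressure, cmH2O
    "PSV",     # pressure-support level, cmH2O
    "RR",      # mandatory respiratory rate, breaths/min
    "FiO2",    # inspired-oxygen fraction, %
    "age",     # years
    "weight",  # kg
)

#: Patient responses predicted by the forward surrogate.
OBSERVATION_COLUMNS: tuple[str, ...] = (
    "Vti",    # inspiratory tidal volume, mL
    "Cdyn",   # dynamic compliance, mL/cmH2O
    "EtCO2",  # end-tidal CO2, mmHg
    "SpO2",   # oxygen saturation, %
    "HR",     # heart rate, beats/min
    "BP",     # mean blood pressure, mmHg
    "Temp",   # body temperature, degrees C
)

#: The 15 data-bearing columns, in canonical order.
DATA_COLUMNS: tuple[str, ...] = SETTINGS_COLUMNS + OBSERVATION_COLUMNS

#: Optional bookkeeping columns carried alongside the data.
METADATA_COLUMNS: tuple[str, ...] = ("patient_id", "species", "lung_status", "timestamp")

#: Demographics are always known for a patient and never searched over.
KNOWN_SETTINGS: tuple[str, ...] = ("age", "weight")

SETP_INDEX = SETTINGS_COLUMNS.index("SetP")
PIP_INDEX = SETTINGS_COLUMNS.index("PIP")
PEEP_INDEX = SETTINGS_COLUMNS.index("PEEP")


def settings_index(field: str) -> int:
    """Position of ``field`` in the 8-dimensional settings vector."""
    try:
        return SETTINGS_COLUMNS.index(field)
    except ValueError:
        raise KeyError(f"unknown settings field: {field!r}") from None
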