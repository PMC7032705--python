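"""Canonical column schema for ED encounter tables.

One row per encounter; any field other than ``id`` may be missing (empty CSV
cell).  Units: age years, respiratory_rate breaths/min, sao2 fraction 0-1,
sbp/dbp mmHg, heart_rate beats/min, temperature Celsius, mental_status
ordinal 1-5 (normal, agitated, confused, drowsy, unconscious), hbp ng/mL,
lactate mmol/L, creatinine umol/L, bilirubin umol/L, platelets 1e9/L, fio2
fraction.
"""

from __future__ import annotations

ID_COLUMN = "id"

NUMERIC_COLUMNS = (
    "age",
    "respiratory_rate",
    "sao2",
    "sbp",
    "dbp",
    "heart_rate",
    "temperature",
    "hbp",
    "lactate",
    "creatinine",
    "bilirubin",
    "platelets",
    "fio2",
)

ORDINAL_COLUMNS = ("mental_status",)

BOOLEAN_COLUMNS = (
    "on_oxygen",
    "infected",
    "diabetes",
    "cardiovascular_disease",
    "renal_disease",
    "liver_disease",
    "malignancy",
    "immunodeficiency",
    "respiratory_disease",
    "copd",
    "icu_72h",
    "death_72h",
    "mortality_30d",
)

CATEGORICAL_COLUMNS = ("sex",)  # female | male

COLUMNS = (
    (ID_COLUMN,)
    + ("age", "sex")
    + tuple(c for c in NUMERIC_COLUMNS if c != "age")
    + ORDINAL_COLUMNS
    + BOOLEAN_COLUMNS
)

#: every field a score definition may reference
SCOREABLE_FIELDS = frozenset(NUMERIC_COLUMNS) | set(ORDINAL_COLUMNS) | set(BOOLEAN_COLUMNS) | {"sex"}
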