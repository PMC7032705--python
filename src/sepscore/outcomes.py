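"""Combined sepsis outcome: infection-related organ dysfunction, ICU or death.

The primary endpoint labels an ED encounter as sepsis when the patient is
infected and, within 72 h of admission, has at least one acute organ
dysfunction, is treated in intensive care, or dies.  Organ dysfunction uses
sepsis-2-style single-organ criteria; acute neurologic dysfunction is
excluded from the sepsis-defining set because mental status is itself an
input of every score under evaluation.

Respiratory dysfunction is assessed through the PaO2/FiO2 ratio estimated
from pulse oximetry by numerically inverting the Severinghaus oxygen
dissociation equation

    SaO2 = (23400 / (PaO2^3 + 150 PaO2) + 1)^-1 ,

restricted to the saturation windows where the inversion is informative:
SaO2 90-94% for non-COPD patients, and SaO2 87-95% with simultaneous oxygen
supply for COPD patients.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib.resources import files
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

__all__ = [
    "severinghaus_sao2",
    "severinghaus_pao2",
    "pf_ratio",
    "DysfunctionThresholds",
    "OrganDysfunctionPanel",
    "OutcomeLabel",
    "classify_organ_dysfunction",
    "combined_sepsis_outcome",
    "label_cohort",
]

# sepsis-defining organ systems; neurologic is tracked but excluded
ORGAN_SYSTEMS = ("neurologic", "cardiovascular", "respiratory", "renal", "hematological", "hepatic")
SEPSIS_DEFINING = tuple(s for s in ORGAN_SYSTEMS if s != "neurologic")


def severinghaus_sao2(pao2: float) -> float:
    """Forward Severinghaus equation: arterial O2 saturation from PaO2 (mmHg)."""
    if pao2 <= 0:
        raise ValueError("pao2 must be positive")
    return 1.0 / (23400.0 / (pao2 ** 3 + 150.0 * pao2) + 1.0)


def severinghaus_pao2(sao2: float) -> float:
    """Invert the Severinghaus equation: PaO2 (mmHg) from SaO2 (fraction).

    The forward relation is strictly increasing, so the inverse is found by
    root bracketing on [1, 700] mmHg.

    Raises
    ------
    ValueError
        If ``sao2`` is outside the open interval (0, 1), where the equation
        is not invertible.
    """
    if not 0.0 < sao2 < 1.0:
        raise ValueError(f"sao2 must lie strictly between 0 and 1, got {sao2!r}")
    lo, hi = 1.0, 700.0
    if severinghaus_sao2(hi) < sao2:  # pragma: no cover - sao2<1 always bracketed
        raise ValueError(f"sao2={sao2} not attainable below {hi} mmHg")
    return brentq(lambda p: severinghaus_sao2(p) - sao2, lo, hi, xtol=1e-10, rtol=8.9e-16)


def _get(record: Mapping, key: str):
    """Missing-aware field access on a mapping / pandas row."""
    try:
        v = record[key]
    except (KeyError, IndexError):
        return None
    if v is None or v is pd.NA:
        return None
    if isinstance(v, float) and math.isnan(v):
        return None
    return v


def pf_ratio(record: Mapping) -> float | None:
    """Estimated PaO2/FiO2 ratio (mmHg), or ``None`` outside the eligibility window.

    The Severinghaus conversion is applied only where pulse oximetry carries
    information about PaO2: SaO2 90-94% (no COPD), or 87-95% with ongoing
    oxygen therapy for COPD patients.  ``fio2`` defaults to room air (0.21)
    when absent.
    """
    sao2 = _get(record, "sao2")
    if sao2 is None:
        return None
    fio2 = _get(record, "fio2")
    if fio2 is None:
        fio2 = 0.21
    if fio2 <= 0:
        raise ValueError(f"fio2 must be positive, got {fio2!r}")
    copd = bool(_get(record, "copd") or False)
    on_oxygen = bool(_get(record, "on_oxygen") or False)
    if copd and on_oxygen:
        eligible = 0.87 <= sao2 <= 0.95
    else:
        eligible = 0.90 <= sao2 <= 0.94
    if not eligible:
        return None
    return severinghaus_pao2(sao2) / fio2


def _default_thresholds_dict() -> dict:
    with (files("sepscore") / "fixtures" / "organ_dysfunction.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class DysfunctionThresholds:
    """Numeric cut-offs for the single-organ dysfunction criteria.

    Defaults are standard sepsis-2-style values shipped as an editable YAML
    fixture (``fixtures/organ_dysfunction.yaml``); any cut-off can be
    overridden for sensitivity analyses.
    """

    sbp_hypotension: float = 90.0  # mmHg; cardiovascular if SBP below
    pf_respiratory: float = 300.0  # mmHg; respiratory if PaO2/FiO2 below
    creatinine_renal: float = 177.0  # umol/L; renal if above
    platelets_hematological: float = 100.0  # 1e9/L; hematological if below
    bilirubin_hepatic: float = 34.0  # umol/L; hepatic if above
    mental_status_neurologic: int = 4  # ordinal; neurologic if at or above (drowsy/unconscious)

    @classmethod
    def from_yaml(cls, path=None) -> "DysfunctionThresholds":
        if path is None:
            raw = _default_thresholds_dict()
        else:
            with open(path) as fh:
                raw = yaml.safe_load(fh)
        flat = {}
        for block in raw.values():
            if not isinstance(block, dict):
                raise ValueError("malformed threshold config: each organ system must be a mapping")
            flat.update(block)
        unknown = set(flat) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"malformed threshold config: unknown cut-offs {sorted(unknown)}")
        return cls(**flat)


@dataclass
class OrganDysfunctionPanel:
    """Per-system dysfunction flags for one encounter."""

    neurologic: bool = False
    cardiovascular: bool = False
    respiratory: bool = False
    renal: bool = False
    hematological: bool = False
    hepatic: bool = False
    pf_ratio: float | None = None
    thresholds: DysfunctionThresholds = field(default_factory=DysfunctionThresholds)

    def any_sepsis_defining(self) -> bool:
        return any(getattr(self, s) for s in SEPSIS_DEFINING)


@dataclass(frozen=True)
class OutcomeLabel:
    sepsis_combined: bool
    reason: str  # organ_dysfunction | icu_72h | death_72h | none


def classify_organ_dysfunction(
    record: Mapping, thresholds: DysfunctionThresholds | None = None
) -> OrganDysfunctionPanel:
    """Flag each organ system by comparing the record against its cut-off.

    A missing input never raises: the flag stays ``False`` and a warning is
    emitted, mirroring a chart review that cannot adjudicate an organ system
    without the supporting measurement.
    """
    thr = thresholds or DysfunctionThresholds()
    panel = OrganDysfunctionPanel(thresholds=thr)

    def _flag(system: str, value, test) -> bool:
        if value is None:
            warnings.warn(f"missing input for {system} dysfunction; flag set to False", stacklevel=3)
            return False
        return bool(test(value))

    panel.cardiovascular = _flag("cardiovascular", _get(record, "sbp"), lambda v: v < thr.sbp_hypotension)
    panel.renal = _flag("renal", _get(record, "creatinine"), lambda v: v > thr.creatinine_renal)
    panel.hematological = _flag(
        "hematological", _get(record, "platelets"), lambda v: v < thr.platelets_hematological
    )
    panel.hepatic = _flag("hepatic", _get(record, "bilirubin"), lambda v: v > thr.bilirubin_hepatic)
    ms = _get(record, "mental_status")
    panel.neurologic = ms is not None and int(ms) >= thr.mental_status_neurologic
    pf = pf_ratio(record)
    panel.pf_ratio = pf
    panel.respiratory = pf is not None and pf < thr.pf_respiratory
    return panel


def combined_sepsis_outcome(record: Mapping, panel: OrganDysfunctionPanel) -> OutcomeLabel:
    """Combined endpoint: infection and (non-neurologic dysfunction | ICU | death 72 h).

    Neurologic dysfunction alone never triggers the label.  ``reason``
    reports the first qualifying route in the order organ dysfunction, ICU,
    death.
    """
    infected = bool(_get(record, "infected") or False)
    icu = bool(_get(record, "icu_72h") or False)
    death = bool(_get(record, "death_72h") or False)
    if infected and panel.any_sepsis_defining():
        return OutcomeLabel(True, "organ_dysfunction")
    if infected and icu:
        return OutcomeLabel(True, "icu_72h")
    if infected and death:
        return OutcomeLabel(True, "death_72h")
    return OutcomeLabel(False, "none")


def label_cohort(df: pd.DataFrame, thresholds: DysfunctionThresholds | None = None) -> pd.DataFrame:
    """Vectorized outcome labelling for a whole cohort.

    Returns a frame indexed like ``df`` with one boolean column per organ
    system, the estimated ``pf_ratio`` where eligible, and the combined
    ``sepsis`` label with its ``reason``.
    """
    thr = thresholds or DysfunctionThresholds()
    n = len(df)

    def col(name, default=np.nan):
        if name in df.columns:
            return pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
        return np.full(n, default)

    sbp = col("sbp")
    creat = col("creatinine")
    plate = col("platelets")
    bili = col("bilirubin")
    mental = col("mental_status")
    sao2 = col("sao2")
    fio2 = col("fio2")
    fio2 = np.where(np.isnan(fio2), 0.21, fio2)
    copd = col("copd", 0.0) == 1
    on_ox = col("on_oxygen", 0.0) == 1

    out = pd.DataFrame(index=df.index)
    out["cardiovascular"] = ~np.isnan(sbp) & (sbp < thr.sbp_hypotension)
    out["renal"] = ~np.isnan(creat) & (creat > thr.creatinine_renal)
    out["hematological"] = ~np.isnan(plate) & (plate < thr.platelets_hematological)
    out["hepatic"] = ~np.isnan(bili) & (bili > thr.bilirubin_hepatic)
    out["neurologic"] = ~np.isnan(mental) & (mental >= thr.mental_status_neurologic)

    window = np.where(
        copd & on_ox,
        (sao2 >= 0.87) & (sao2 <= 0.95),
        (sao2 >= 0.90) & (sao2 <= 0.94),
    ) & ~np.isnan(sao2)
    pf = np.full(n, np.nan)
    idx = np.nonzero(window)[0]
    for i in idx:
        pf[i] = severinghaus_pao2(sao2[i]) / fio2[i]
    out["pf_ratio"] = pf
    out["respiratory"] = window & (pf < thr.pf_respiratory)

    any_dys = out[list(SEPSIS_DEFINING)].any(axis=1).to_numpy()
    infected = col("infected", 0.0) == 1
    icu = col("icu_72h", 0.0) == 1
    death = col("death_72h", 0.0) == 1
    sepsis = infected & (any_dys | icu | death)
    reason = np.where(
        infected & any_dys,
        "organ_dysfunction",
        np.where(infected & icu, "icu_72h", np.where(infected & death, "death_72h", "none")),
    )
    out["sepsis"] = sepsis
    out["reason"] = reason
    return out
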