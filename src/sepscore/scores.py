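"""Banded integer early warning scores: NEWS2, RETTS, SEWS and SHEWS.

Every score here shares one structure: per variable, an ordered list of
bands (threshold, direction, points); a record is awarded the points of the
most severe band its value satisfies (never the sum of all satisfied bands),
and the totals are compared against an integer decision cut-off.  RETTS is
the exception — a four-level triage (red/orange/yellow/green) taking the
worst level triggered by any vital sign, with an optional symptom-based red
override (the infection algorithm escalates on petechiae with signs of
infection).

Shipped definitions (YAML under ``fixtures/``):

* ``news2`` — the published NEWS2 chart (SpO2 scale 1 by default, scale 2
  available for hypercapnic respiratory failure), cut-off >= 5.
* ``sews`` — derived vital-sign score, cut-off >= 7.
* ``shews`` — derived score adding heparin-binding protein, cut-off >= 10.
* ``retts`` — editable vital-sign triage limits.

A missing input never raises: it contributes 0 points and is recorded in
``ScoreResult.missing_inputs`` so that complete-case filtering is an
explicit downstream decision rather than a scoring failure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib.resources import files
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._schema import SCOREABLE_FIELDS

__all__ = [
    "Band",
    "ScoreDefinition",
    "ScoreResult",
    "BandedScorer",
    "compute_points",
    "news2",
    "sews",
    "shews",
    "retts",
    "RettsTriage",
    "load_definition",
    "score_cohort",
]

_DIRECTIONS = {"<", ">", "<=", ">=", "in"}
_ALIASES = {"≤": "<=", "≥": ">=", "category": "in"}

TRIAGE_LEVELS = ("green", "yellow", "orange", "red")


@dataclass(frozen=True)
class Band:
    """One severity band: points awarded when ``value <dir> threshold`` holds."""

    threshold: float | int | tuple
    direction: str
    points: int

    def __post_init__(self):
        d = _ALIASES.get(self.direction, self.direction)
        object.__setattr__(self, "direction", d)
        if d not in _DIRECTIONS:
            raise ValueError(f"unknown band direction {self.direction!r}")
        if self.points < 0:
            raise ValueError("band points must be non-negative")
        if d == "in":
            object.__setattr__(self, "threshold", tuple(np.atleast_1d(self.threshold).tolist()))

    def satisfied(self, value) -> bool:
        if self.direction == "in":
            return value in self.threshold
        value = float(value)
        thr = float(self.threshold)
        return {
            "<": value < thr,
            ">": value > thr,
            "<=": value <= thr,
            ">=": value >= thr,
        }[self.direction]


@dataclass
class ScoreDefinition:
    """A named banded score with a decision cut-off.

    ``combination_rule`` is ``max_band`` (points of the most severe
    satisfied band per variable — the convention of the NEWS family) or
    ``cumulative`` (sum of all satisfied bands, available for sensitivity
    analysis).
    """

    name: str
    bands: dict[str, list[Band]]
    cutoff: int
    combination_rule: str = "max_band"

    def __post_init__(self):
        if self.cutoff < 1:
            raise ValueError("cutoff must be >= 1")
        if self.combination_rule not in ("max_band", "cumulative"):
            raise ValueError(f"unknown combination rule {self.combination_rule!r}")
        for var, bands in self.bands.items():
            if var not in SCOREABLE_FIELDS:
                raise ValueError(f"unknown variable {var!r} in score definition {self.name!r}")
            self.bands[var] = [b if isinstance(b, Band) else Band(**b) for b in bands]

    def variable_points(self, variable: str, value) -> int:
        """Points contributed by one variable (0 when no band is satisfied)."""
        pts = [b.points for b in self.bands[variable] if b.satisfied(value)]
        if not pts:
            return 0
        return max(pts) if self.combination_rule == "max_band" else sum(pts)

    def max_single_variable(self) -> int:
        """Largest total a single variable can contribute."""
        out = 0
        for var, bands in self.bands.items():
            if self.combination_rule == "max_band":
                out = max(out, max(b.points for b in bands))
            else:
                out = max(out, sum(b.points for b in bands))
        return out

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "cutoff": int(self.cutoff),
            "combination_rule": self.combination_rule,
            "bands": {
                var: [
                    {
                        "threshold": list(b.threshold) if b.direction == "in" else b.threshold,
                        "direction": b.direction,
                        "points": int(b.points),
                    }
                    for b in bands
                ]
                for var, bands in self.bands.items()
            },
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, raw: dict) -> "ScoreDefinition":
        return cls(
            name=raw["name"],
            bands={v: [Band(**b) for b in bl] for v, bl in raw["bands"].items()},
            cutoff=raw["cutoff"],
            combination_rule=raw.get("combination_rule", "max_band"),
        )

    @classmethod
    def from_yaml(cls, path) -> "ScoreDefinition":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class ScoreResult:
    total: int
    per_variable_points: dict
    positive: bool
    missing_inputs: tuple


def _is_missing(v) -> bool:
    if v is None or v is pd.NA:
        return True
    return isinstance(v, float) and math.isnan(v)


def compute_points(record: Mapping, definition: ScoreDefinition) -> ScoreResult:
    """Score one record against a banded definition.

    Missing variables contribute 0 points and are listed in
    ``missing_inputs``; the total is compared against the cut-off.
    """
    per_var: dict[str, int] = {}
    missing: list[str] = []
    for var in definition.bands:
        try:
            value = record[var]
        except (KeyError, IndexError):
            value = None
        if _is_missing(value):
            per_var[var] = 0
            missing.append(var)
            continue
        if isinstance(value, (bool, np.bool_)):
            value = bool(value)
        per_var[var] = definition.variable_points(var, value)
    total = int(sum(per_var.values()))
    return ScoreResult(total, per_var, total >= definition.cutoff, tuple(missing))


@lru_cache(maxsize=None)
def load_definition(name: str) -> ScoreDefinition:
    """Load a shipped score definition (``news2``, ``sews``, ``shews``)."""
    path = files("sepscore") / "fixtures" / f"{name}.yaml"
    with path.open() as fh:
        return ScoreDefinition.from_dict(yaml.safe_load(fh))


def _news2_scale2(record: Mapping) -> ScoreDefinition:
    """NEWS2 with the SpO2 scale-2 bands (target saturation 88-92%)."""
    base = load_definition("news2")
    bands = dict(base.bands)
    on_ox = bool(record.get("on_oxygen") or False)
    sat_bands = [Band(0.83, "<=", 3), Band(0.85, "<=", 2), Band(0.87, "<=", 1)]
    if on_ox:
        sat_bands += [Band(0.97, ">=", 3), Band(0.95, ">=", 2), Band(0.93, ">=", 1)]
    bands["sao2"] = sat_bands
    return ScoreDefinition(base.name + "-scale2", bands, base.cutoff, base.combination_rule)


def news2(record: Mapping, spo2_scale: int = 1) -> ScoreResult:
    """NEWS2 total for one record; positive at >= 5.

    ``spo2_scale=2`` switches the oxygen-saturation bands to the scale used
    for patients with hypercapnic respiratory failure.
    """
    if spo2_scale == 1:
        return compute_points(record, load_definition("news2"))
    if spo2_scale == 2:
        return compute_points(record, _news2_scale2(record))
    raise ValueError("spo2_scale must be 1 or 2")


def sews(record: Mapping) -> ScoreResult:
    """Derived vital-sign score; positive at >= 7."""
    return compute_points(record, load_definition("sews"))


def shews(record: Mapping) -> ScoreResult:
    """Derived vital-sign + heparin-binding-protein score; positive at >= 10."""
    return compute_points(record, load_definition("shews"))


class RettsTriage:
    """Four-level vital-sign triage with an optional symptom red override.

    The level is the worst (highest-priority) level whose criteria list has
    at least one satisfied entry; criteria live in an editable YAML fixture.
    A criterion may be conditional on oxygen therapy (``oxygen: true/false``).
    Missing vitals are treated as normal with a warning.
    """

    def __init__(self, config: dict | None = None):
        if config is None:
            with (files("sepscore") / "fixtures" / "retts.yaml").open() as fh:
                config = yaml.safe_load(fh)
        self.config = config

    def level(self, record: Mapping, ess_red_override: bool = False) -> str:
        if ess_red_override:
            return "red"
        on_ox = bool(record.get("on_oxygen") if not _is_missing(record.get("on_oxygen")) else False)
        for lvl in ("red", "orange", "yellow"):
            for crit in self.config.get(lvl, []):
                cond = crit.get("oxygen")
                if cond is not None and bool(cond) != on_ox:
                    continue
                try:
                    value = record[crit["variable"]]
                except (KeyError, IndexError):
                    value = None
                if _is_missing(value):
                    warnings.warn(
                        f"missing {crit['variable']} treated as normal in triage", stacklevel=2
                    )
                    continue
                if Band(crit["threshold"], crit["direction"], 0).satisfied(value):
                    return lvl
        return "green"


def retts(record: Mapping, ess_red_override: bool = False, config: dict | None = None) -> str:
    """RETTS triage level for one record (``red``/``orange``/``yellow``/``green``).

    The evaluation surface uses only the red/not-red dichotomy (screen
    positive = red); ``ess_red_override`` escalates straight to red, as the
    infection symptom algorithm does for petechiae with concomitant signs of
    infection.
    """
    return RettsTriage(config).level(record, ess_red_override)


class BandedScorer:
    """Vectorized application of a :class:`ScoreDefinition` to a cohort frame.

    A prefit, stateless transformer: ``transform`` appends
    ``<name>_total`` and ``<name>_positive`` columns; ``decision_function``
    returns the totals; ``predict`` the positivity flags.
    """

    def __init__(self, definition: ScoreDefinition | str):
        self.definition = load_definition(definition) if isinstance(definition, str) else definition

    def get_params(self, deep=True):  # sklearn-compatible plumbing
        return {"definition": self.definition}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def decision_function(self, df: pd.DataFrame) -> np.ndarray:
        d = self.definition
        n = len(df)
        total = np.zeros(n, dtype=int)
        for var, bands in d.bands.items():
            if var not in df.columns:
                total += 0
                continue
            col = df[var]
            if col.dtype == object or str(col.dtype) in ("boolean", "category"):
                values = col.to_numpy(dtype=object)
                present = np.array([not _is_missing(v) for v in values])
                pts = np.zeros(n, dtype=int)
                for b in bands:
                    hit = np.array([(not _is_missing(v)) and b.satisfied(v) for v in values])
                    if d.combination_rule == "max_band":
                        pts = np.where(hit, np.maximum(pts, b.points), pts)
                    else:
                        pts = pts + np.where(hit, b.points, 0)
            else:
                values = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
                present = ~np.isnan(values)
                pts = np.zeros(n, dtype=int)
                for b in bands:
                    if b.direction == "in":
                        hit = np.isin(values, [float(t) for t in b.threshold])
                    else:
                        thr = float(b.threshold)
                        hit = {
                            "<": values < thr,
                            ">": values > thr,
                            "<=": values <= thr,
                            ">=": values >= thr,
                        }[b.direction]
                    hit = hit & present
                    if d.combination_rule == "max_band":
                        pts = np.where(hit, np.maximum(pts, b.points), pts)
                    else:
                        pts = pts + np.where(hit, b.points, 0)
            total += pts
        return total

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        return self.decision_function(df) >= self.definition.cutoff

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        total = self.decision_function(df)
        out[f"{self.definition.name}_total"] = total
        out[f"{self.definition.name}_positive"] = total >= self.definition.cutoff
        return out


def score_cohort(
    df: pd.DataFrame,
    score: str,
    ess_red_override: Sequence[bool] | None = None,
) -> pd.DataFrame:
    """Append score columns for one of ``news2``/``sews``/``shews``/``retts``.

    For ``retts`` the appended columns are ``retts_level`` and
    ``retts_positive`` (positive = red).
    """
    if score == "retts":
        triage = RettsTriage()
        override = ess_red_override if ess_red_override is not None else [False] * len(df)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            levels = [
                triage.level(row, ess_red_override=bool(ov))
                for (_, row), ov in zip(df.iterrows(), override)
            ]
        out = df.copy()
        out["retts_level"] = levels
        out["retts_positive"] = [lv == "red" for lv in levels]
        return out
    return BandedScorer(score).transform(df)
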