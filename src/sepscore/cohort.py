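"""Synthetic ED cohort generator with planted threshold effects and MAR missingness.

The generator emulates the statistical structure that score derivation and
validation assume, without any real patient data:

* vital signs from truncated-normal marginals (diastolic pressure drawn as a
  fraction of systolic so that ``sbp > dbp > 0`` always holds), mental
  status as an ordinal 1-5, plus comorbidity flags;
* a planted sepsis outcome drawn from a logistic model over binary
  threshold indicators of the vitals (the same kind of threshold effects a
  banded score is meant to capture), with the intercept calibrated so the
  realized prevalence matches the requested one;
* right-skewed biomarkers (heparin-binding protein, lactate) drawn
  log-normally conditional on the outcome class;
* organ-dysfunction-supporting labs arranged so that the outcome labels
  recomputed by :mod:`sepscore.outcomes` agree with the planted labels
  end-to-end (a sepsis case without a vitals-driven dysfunction gets a lab
  dysfunction planted; an infected non-case is kept free of qualifying
  dysfunction);
* missing-at-random missingness whose probability depends only on observed
  age and the outcome, with the intercept calibrated to the requested
  marginal rate.

Reproducibility: one master seed; per-stage generators are spawned from
``numpy.random.SeedSequence(seed)`` in a fixed order (demography, vitals,
outcome, biomarkers, labs, events, mortality, missingness), so identical
configs give byte-identical cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib.resources import files
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.stats import truncnorm

from . import outcomes
from ._schema import BOOLEAN_COLUMNS, COLUMNS

__all__ = [
    "ThresholdEffect",
    "SimConfig",
    "Cohort",
    "generate_cohort",
    "inject_missingness",
    "write_cohort",
    "read_cohort",
    "load_preset",
]

_EXPIT = lambda x: 1.0 / (1.0 + np.exp(-x))

#: default truncated-normal marginals: (mean, sd, low, high)
DEFAULT_MARGINALS = {
    "age": (62.0, 18.0, 18.0, 100.0),
    "respiratory_rate": (20.0, 6.0, 8.0, 60.0),
    "sao2": (0.955, 0.03, 0.70, 0.999),
    "sbp": (127.0, 26.0, 60.0, 230.0),
    "heart_rate": (95.0, 22.0, 30.0, 190.0),
    "temperature": (37.6, 1.0, 34.0, 42.0),
    "creatinine": (90.0, 30.0, 30.0, 176.0),
    "bilirubin": (14.0, 7.0, 2.0, 33.0),
    "platelets": (250.0, 70.0, 105.0, 800.0),
}

DEFAULT_MENTAL_PROBS = (0.82, 0.05, 0.07, 0.04, 0.02)

DEFAULT_COMORBIDITY_PROBS = {
    "diabetes": 0.15,
    "cardiovascular_disease": 0.30,
    "renal_disease": 0.09,
    "liver_disease": 0.02,
    "malignancy": 0.10,
    "immunodeficiency": 0.02,
    "respiratory_disease": 0.17,
}


@dataclass(frozen=True)
class ThresholdEffect:
    """One planted effect: crossing ``cut`` in ``direction`` adds ``weight`` log-odds."""

    variable: str
    cut: float
    direction: str  # '<', '>', '>=', '<='
    weight: float

    def indicator(self, values: np.ndarray) -> np.ndarray:
        return {
            "<": values < self.cut,
            ">": values > self.cut,
            "<=": values <= self.cut,
            ">=": values >= self.cut,
        }[self.direction].astype(float)


@dataclass
class SimConfig:
    """Full specification of one synthetic cohort."""

    n: int = 500
    sepsis_prevalence: float = 0.45
    true_thresholds: list = field(default_factory=list)
    baseline_log_odds: float | None = None  # None => calibrated to prevalence
    hbp_lognormal: dict = field(
        default_factory=lambda: {"nonsepsis": [2.7, 0.7], "sepsis": [3.7, 0.8]}
    )
    lactate_lognormal: dict = field(
        default_factory=lambda: {"nonsepsis": [0.26, 0.45], "sepsis": [0.85, 0.55]}
    )
    missing_rates: dict = field(default_factory=dict)
    mar_dependence: dict = field(default_factory=lambda: {"age": 0.0, "outcome": 0.0})
    mortality_model: dict = field(
        default_factory=lambda: {"intercept": -4.0, "severity": 0.5, "age": 0.45}
    )
    marginals: dict = field(default_factory=dict)  # overrides of DEFAULT_MARGINALS
    mental_probs: Sequence[float] = DEFAULT_MENTAL_PROBS
    comorbidity_probs: dict = field(default_factory=lambda: dict(DEFAULT_COMORBIDITY_PROBS))
    infected_nonsepsis_rate: float = 1.0  # infection prevalence among non-cases
    icu_rate_sepsis: float = 0.05
    death_rate_sepsis: float = 0.02
    dysfunction_free_sepsis_rate: float = 0.0  # cases qualifying via ICU/death only
    event_rate_noninfected: float = 0.05  # ICU within 72 h among non-infected
    copd_prob: float = 0.10
    on_oxygen_prob: float = 0.15
    female_prob: float = 0.47
    label: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        self.mental_probs = tuple(self.mental_probs)
        self.true_thresholds = [
            t if isinstance(t, ThresholdEffect) else ThresholdEffect(*t)
            if isinstance(t, (list, tuple))
            else ThresholdEffect(**t)
            for t in self.true_thresholds
        ]

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError(f"invalid SimConfig field 'n': must be >= 0, got {self.n}")
        if not 0.0 <= self.sepsis_prevalence <= 1.0:
            raise ValueError(
                f"invalid SimConfig field 'sepsis_prevalence': must be in [0, 1], got {self.sepsis_prevalence}"
            )
        for var, rate in self.missing_rates.items():
            if not 0.0 <= rate <= 0.5:
                raise ValueError(
                    f"invalid SimConfig field 'missing_rates[{var}]': must be in [0, 0.5], got {rate}"
                )
        for t in self.true_thresholds:
            if t.variable not in DEFAULT_MARGINALS and t.variable not in ("mental_status", "dbp", "hbp", "lactate"):
                raise ValueError(f"invalid SimConfig field 'true_thresholds': unknown variable {t.variable!r}")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["true_thresholds"] = [dataclasses.asdict(t) for t in self.true_thresholds]
        d["mental_probs"] = list(self.mental_probs)
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class Cohort:
    """An ordered patient table plus its provenance."""

    df: pd.DataFrame
    label: str = ""
    provenance: SimConfig | str | None = None

    def __len__(self) -> int:
        return len(self.df)

    def outcome(self, thresholds: outcomes.DysfunctionThresholds | None = None) -> pd.Series:
        """Combined sepsis label recomputed from the records."""
        return outcomes.label_cohort(self.df, thresholds)["sepsis"]


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept b such that mean(expit(b + eta)) == target."""
    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf
    return brentq(lambda b: _EXPIT(b + eta).mean() - target, -40.0, 40.0, xtol=1e-12)


def generate_cohort(config: SimConfig, seed: int | None = None) -> Cohort:
    """Draw a complete synthetic cohort (no missing values) from ``config``.

    ``seed`` overrides ``config.seed``.  The returned table is in canonical
    dtypes (float64, ``Int64`` for mental status, ``boolean`` flags) so that
    CSV round-trips are lossless.
    """
    config.validate()
    n = config.n
    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    r_demo, r_vital, r_out, r_bio, r_lab, r_event, r_mort, _r_miss = (
        np.random.default_rng(c) for c in ss.spawn(8)
    )
    marg = {**DEFAULT_MARGINALS, **config.marginals}

    if n == 0:
        df = pd.DataFrame(columns=list(COLUMNS))
        return Cohort(_canonical(df), config.label, config)

    # demography
    age = _truncnorm(r_demo, *marg["age"], n)
    sex = np.where(r_demo.random(n) < config.female_prob, "female", "male")

    # vitals; dbp drawn as a fraction of sbp so sbp > dbp > 0 by construction
    rr = _truncnorm(r_vital, *marg["respiratory_rate"], n)
    sao2 = _truncnorm(r_vital, *marg["sao2"], n)
    sbp = _truncnorm(r_vital, *marg["sbp"], n)
    dbp = sbp * _truncnorm(r_vital, 0.58, 0.08, 0.30, 0.85, n)
    hr = _truncnorm(r_vital, *marg["heart_rate"], n)
    temp = _truncnorm(r_vital, *marg["temperature"], n)
    mental = r_vital.choice(
        np.arange(1, 6), size=n, p=np.asarray(config.mental_probs) / np.sum(config.mental_probs)
    )
    copd = r_vital.random(n) < config.copd_prob
    on_ox = r_vital.random(n) < config.on_oxygen_prob
    fio2 = np.where(on_ox, r_vital.choice([0.28, 0.36, 0.44], size=n), 0.21)

    values = {
        "age": age,
        "respiratory_rate": rr,
        "sao2": sao2,
        "sbp": sbp,
        "dbp": dbp,
        "heart_rate": hr,
        "temperature": temp,
        "mental_status": mental.astype(float),
    }

    # planted logistic outcome over threshold indicators
    eta = np.zeros(n)
    for t in config.true_thresholds:
        eta += t.weight * t.indicator(values[t.variable])
    if config.baseline_log_odds is None:
        b0 = _calibrate_intercept(eta, config.sepsis_prevalence)
    else:
        b0 = config.baseline_log_odds
    with np.errstate(over="ignore"):
        p_sepsis = _EXPIT(b0 + eta)
    sepsis = r_out.random(n) < p_sepsis

    infected = sepsis | (r_out.random(n) < config.infected_nonsepsis_rate)

    # class-conditional biomarkers
    def _biomarker(params):
        mu = np.where(sepsis, params["sepsis"][0], params["nonsepsis"][0])
        sg = np.where(sepsis, params["sepsis"][1], params["nonsepsis"][1])
        return np.exp(r_bio.normal(mu, sg))

    hbp = _biomarker(config.hbp_lognormal)
    lactate = _biomarker(config.lactate_lognormal)

    # labs start in normal ranges for everyone
    creat = _truncnorm(r_lab, *marg["creatinine"], n)
    bili = _truncnorm(r_lab, *marg["bilirubin"], n)
    plate = _truncnorm(r_lab, *marg["platelets"], n)

    thr = outcomes.DysfunctionThresholds()

    # infected non-cases must not carry a qualifying dysfunction or event;
    # the (rare) conflicting vitals are nudged out of the dysfunction range
    clean = infected & ~sepsis
    low_sbp = clean & (sbp < thr.sbp_hypotension)
    sbp[low_sbp] = thr.sbp_hypotension + np.abs(r_lab.normal(6.0, 4.0, low_sbp.sum()))
    dbp[low_sbp] = np.minimum(dbp[low_sbp], 0.8 * sbp[low_sbp])
    in_window = np.where(
        copd & on_ox, (sao2 >= 0.87) & (sao2 <= 0.95), (sao2 >= 0.90) & (sao2 <= 0.94)
    )
    bump = clean & in_window
    sao2[bump] = r_lab.uniform(0.955, 0.985, bump.sum())

    icu = np.zeros(n, dtype=bool)
    death = np.zeros(n, dtype=bool)

    # sepsis cases without a vitals-driven dysfunction get one planted
    frame = pd.DataFrame(
        {
            "sbp": sbp,
            "sao2": sao2,
            "fio2": fio2,
            "copd": copd,
            "on_oxygen": on_ox,
            "creatinine": creat,
            "bilirubin": bili,
            "platelets": plate,
            "mental_status": mental,
            "infected": infected,
            "icu_72h": icu,
            "death_72h": death,
        }
    )
    panel = outcomes.label_cohort(frame, thr)
    has_dys = panel[list(outcomes.SEPSIS_DEFINING)].any(axis=1).to_numpy()
    needs = sepsis & ~has_dys
    via_event = needs & (r_event.random(n) < config.dysfunction_free_sepsis_rate)
    plant = np.nonzero(needs & ~via_event)[0]
    route = r_lab.integers(0, 3, plant.size)
    renal_i = plant[route == 0]
    hema_i = plant[route == 1]
    hepa_i = plant[route == 2]
    creat[renal_i] = r_lab.uniform(thr.creatinine_renal + 10, 400.0, renal_i.size)
    plate[hema_i] = r_lab.uniform(25.0, thr.platelets_hematological - 5, hema_i.size)
    bili[hepa_i] = r_lab.uniform(thr.bilirubin_hepatic + 2, 90.0, hepa_i.size)
    icu[via_event] = True
    death[via_event] |= r_event.random(via_event.sum()) < 0.3

    # 72 h events: additional ICU/death among cases, events among non-infected
    icu |= sepsis & (r_event.random(n) < config.icu_rate_sepsis)
    death |= sepsis & (r_event.random(n) < config.death_rate_sepsis)
    noninf = ~infected
    icu |= noninf & (r_event.random(n) < config.event_rate_noninfected)

    # 30-day mortality: logistic in severity (centred linear predictor) and age
    mm = config.mortality_model
    eta_m = mm["intercept"] + mm["severity"] * (eta - eta.mean()) + mm["age"] * (age - 70.0) / 10.0
    mort = (r_mort.random(n) < _EXPIT(eta_m)) | death

    df = pd.DataFrame(
        {
            "id": [f"{config.label or 'pt'}-{i:05d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "respiratory_rate": rr,
            "sao2": sao2,
            "sbp": sbp,
            "dbp": dbp,
            "heart_rate": hr,
            "temperature": temp,
            "hbp": hbp,
            "lactate": lactate,
            "creatinine": creat,
            "bilirubin": bili,
            "platelets": plate,
            "fio2": fio2,
            "mental_status": mental,
            "on_oxygen": on_ox,
            "infected": infected,
            "copd": copd,
            "icu_72h": icu,
            "death_72h": death,
            "mortality_30d": mort,
        }
    )
    for name, p in config.comorbidity_probs.items():
        df[name] = r_demo.random(n) < p
    df = df[[c for c in COLUMNS if c in df.columns]]
    return Cohort(_canonical(df), config.label, config)


def _canonical(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if c in BOOLEAN_COLUMNS:
            out[c] = out[c].astype("boolean")
        elif c == "mental_status":
            out[c] = out[c].astype("Int64")
        elif c in ("id", "sex"):
            out[c] = out[c].astype(object)
        else:
            out[c] = out[c].astype(float)
    return out


def inject_missingness(cohort: Cohort, config: SimConfig, seed: int | None = None) -> Cohort:
    """Blank out values MAR-style according to ``config.missing_rates``.

    Missingness probability for a cell follows a logistic model in observed
    age (per decade above/below 60) and the combined outcome label, with
    the intercept calibrated so the marginal rate matches the requested one.
    Rates above 0.5 are rejected.
    """
    config.validate()
    if not config.missing_rates or all(r == 0 for r in config.missing_rates.values()):
        return Cohort(cohort.df.copy(), cohort.label, cohort.provenance)
    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    r_miss = np.random.default_rng(ss.spawn(8)[7])
    df = cohort.df.copy()
    n = len(df)
    age = pd.to_numeric(df["age"], errors="coerce").fillna(60.0).to_numpy(dtype=float)
    y = cohort.outcome().to_numpy(dtype=float)
    a = float(config.mar_dependence.get("age", 0.0))
    o = float(config.mar_dependence.get("outcome", 0.0))
    shift = a * (age - 60.0) / 10.0 + o * y
    for var, rate in config.missing_rates.items():
        if rate == 0:
            continue
        if var not in df.columns or var == "id":
            raise ValueError(f"cannot inject missingness into {var!r}")
        b0 = _calibrate_intercept(shift, rate)
        mask = r_miss.random(n) < _EXPIT(b0 + shift)
        df.loc[mask, var] = np.nan if df[var].dtype == float else pd.NA
    return Cohort(df, cohort.label, cohort.provenance)


def write_cohort(cohort: Cohort | pd.DataFrame, path) -> None:
    """Write a cohort CSV: one header row, one row per patient, empty cell = missing.

    Boolean flags are stored as 0/1 so the file has no locale-dependent
    tokens; the round-trip through :func:`read_cohort` is lossless.
    """
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    out = df.copy()
    for c in out.columns:
        if str(out[c].dtype) == "boolean":
            out[c] = out[c].astype("Int64")
    out.to_csv(path, index=False)


def read_cohort(path, label: str | None = None) -> Cohort:
    """Read a cohort CSV written by :func:`write_cohort` (canonical dtypes)."""
    df = pd.read_csv(path, dtype={"id": str, "sex": str})
    for c in df.columns:
        if c in BOOLEAN_COLUMNS:
            df[c] = df[c].astype("Int64").astype("boolean")
        elif c == "mental_status":
            df[c] = df[c].astype("Int64")
        elif c not in ("id", "sex"):
            df[c] = pd.to_numeric(df[c], errors="coerce").astype(float)
        else:
            df[c] = df[c].astype(object)
    return Cohort(df, label or str(path), provenance=str(path))


def load_preset(name: str) -> SimConfig:
    """Load a shipped cohort preset (``cohort_a`` or ``cohort_b``)."""
    path = files("sepscore") / "fixtures" / f"{name}.yaml"
    with path.open() as fh:
        return SimConfig.from_dict(yaml.safe_load(fh))
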