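import numpy as np
import pandas as pd
import pytest

from sepscore import cohort, outcomes


def normal_record(**overrides):
    """A fully normal young adult; override individual fields per test."""
    rec = dict(
        age=30,
        sex="female",
        respiratory_rate=14.0,
        sao2=0.98,
        on_oxygen=False,
        sbp=120.0,
        dbp=80.0,
        heart_rate=70.0,
        temperature=37.0,
        mental_status=1,
        hbp=5.0,
        lactate=1.0,
        creatinine=80.0,
        bilirubin=10.0,
        platelets=250.0,
        fio2=0.21,
        copd=False,
        infected=False,
        icu_72h=False,
        death_72h=False,
        mortality_30d=False,
    )
    rec.update(overrides)
    return rec


@pytest.fixture
def record():
    return normal_record


@pytest.fixture(scope="session")
def planted_cohort():
    """Mid-size cohort with known threshold effects (hbp is pure noise)."""
    thr = [
        ("age", 60, ">", 1.2),
        ("sbp", 100, "<", 1.2),
        ("respiratory_rate", 24, ">", 1.2),
        ("mental_status", 3, ">=", 1.0),
    ]
    cfg = cohort.SimConfig(
        n=2000,
        sepsis_prevalence=0.35,
        true_thresholds=[
            dict(variable=v, cut=c, direction=d, weight=w) for v, c, d, w in thr
        ],
        hbp_lognormal={"nonsepsis": [3.0, 0.7], "sepsis": [3.0, 0.7]},
        label="planted",
        seed=21,
    )
    ch = cohort.generate_cohort(cfg)
    y = outcomes.label_cohort(ch.df)["sepsis"].to_numpy()
    return ch, y, {"age>60", "sbp<100", "respiratory_rate>24", "mental_status>=3"}


@pytest.fixture(scope="session")
def cohort_a():
    cfg = cohort.load_preset("cohort_a")
    return cohort.generate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort_b():
    cfg = cohort.load_preset("cohort_b")
    return cohort.generate_cohort(cfg)
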