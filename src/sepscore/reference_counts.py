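"""Published validation counts used as worked-example fixtures.

The derivation/validation study behind the SEWS/SHEWS scores reports its
score-versus-outcome cross-tabulations as raw counts for two ED cohorts
(cohort A: 506 infected patients; cohort B: 435 undifferentiated acute
patients).  Those printed 2x2 counts are inputs here: expanding them into
labelled vectors lets every confusion-table statistic (sensitivity,
specificity, odds ratios, chi-square) be recomputed by the evaluation
module without any patient-level data.

Sepsis tables are (tp, fn, fp, tn): screen-positive/negative by sepsis
status.  Mortality tables are (deaths among screen-positive, survivors
among screen-positive, deaths among screen-negative, survivors among
screen-negative).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "SEPSIS_TABLES",
    "MORTALITY_TABLES",
    "DIABETES_TABLE",
    "expand_confusion",
]

SEPSIS_TABLES = {
    "cohort_a": {
        "retts": (66, 167, 12, 261),
        "news2": (152, 81, 55, 219),
    },
    "cohort_b": {
        "retts": (74, 55, 149, 157),
        "news2": (108, 21, 198, 108),
        "sews": (108, 21, 212, 94),
        "shews": (107, 22, 162, 144),
    },
}

MORTALITY_TABLES = {
    "cohort_a": {
        "retts": (4, 74, 10, 418),
        "news2": (10, 197, 4, 295),
        "sews": (12, 146, 2, 346),
        "shews": (11, 257, 3, 235),
    },
    "cohort_b": {
        "retts": (20, 158, 8, 166),
        "news2": (26, 221, 2, 103),
        "sews": (26, 240, 2, 84),
        "shews": (27, 186, 1, 138),
    },
}

#: diabetes prevalence without/with sepsis in cohort A: (29 of 273, 45 of 233)
DIABETES_TABLE = ((29, 244), (45, 188))


def expand_confusion(tp: int, fn: int, fp: int, tn: int) -> tuple[np.ndarray, np.ndarray]:
    """Expand 2x2 counts into (screen_positive, outcome) boolean vectors."""
    pred = np.concatenate(
        [np.ones(tp + fp, dtype=bool), np.zeros(fn + tn, dtype=bool)]
    )
    truth = np.concatenate(
        [np.ones(tp, dtype=bool), np.zeros(fp, dtype=bool),
         np.ones(fn, dtype=bool), np.zeros(tn, dtype=bool)]
    )
    return pred, truth
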