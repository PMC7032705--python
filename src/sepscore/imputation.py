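"""Multiple imputation by chained predictive mean matching.

Missing vitals and biomarkers are imputed with a chained-equations loop:
continuous variables by predictive mean matching (PMM — a Bayesian linear
regression predicts the mean for each missing cell, and the imputed value
is drawn from the *observed* values of the k nearest-predicted donors, so
imputations are always physiologically attainable values), binary variables
by a logistic-regression posterior draw.  Comorbidity flags and the outcome
are always in the predictor set although never imputed themselves, which is
what makes the missing-at-random assumption plausible for ED vitals.

Defaults follow common multiple-imputation practice: m = 20 completed data
sets, donor pool k = 5, 10 chained iterations, visit order by increasing
missingness.  Per-iteration means of the imputed cells are recorded per
variable and data set so convergence can be inspected by plotting chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from . import outcomes
from ._schema import BOOLEAN_COLUMNS
from .evaluation import MetricWithCI, auc
from .scores import BandedScorer

__all__ = ["ImputationResult", "PMMImputer", "pmm_impute", "pooled_evaluation"]

#: variables the sensitivity analysis may impute
IMPUTABLE = (
    "sbp",
    "dbp",
    "heart_rate",
    "respiratory_rate",
    "temperature",
    "mental_status",
    "sao2",
    "on_oxygen",
    "lactate",
    "age",
    "hbp",
)

_COMORBIDITIES = (
    "diabetes",
    "cardiovascular_disease",
    "renal_disease",
    "liver_disease",
    "malignancy",
    "immunodeficiency",
    "respiratory_disease",
)


@dataclass
class ImputationResult:
    """m completed cohorts plus per-variable method and chain diagnostics."""

    datasets: list
    methods: dict
    chain_means: dict  # variable -> (m, iterations) array of imputed-cell means
    m: int
    iterations: int
    variables: tuple

    def __post_init__(self):
        assert len(self.datasets) == self.m


def _design(df: pd.DataFrame, cols: Sequence[str], extra: pd.DataFrame | None) -> np.ndarray:
    """Numeric design matrix with intercept from current working values."""
    parts = [np.ones((len(df), 1))]
    for c in cols:
        v = pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float)
        parts.append(v[:, None])
    if extra is not None:
        parts.append(extra.to_numpy(dtype=float))
    return np.hstack(parts)


def _bayes_linear_draw(X, y, rng):
    """Posterior draw (beta, sigma) for a ridge-stabilized linear model."""
    p = X.shape[1]
    gram = X.T @ X + 1e-6 * np.eye(p)
    chol_inv = np.linalg.inv(np.linalg.cholesky(gram))
    gram_inv = chol_inv.T @ chol_inv
    beta_hat = gram_inv @ (X.T @ y)
    resid = y - X @ beta_hat
    dof = max(X.shape[0] - p, 1)
    sigma2 = float(resid @ resid) / dof
    sigma2_draw = float(resid @ resid) / max(rng.chisquare(dof), 1e-8)
    beta_draw = beta_hat + np.linalg.cholesky(sigma2_draw * gram_inv) @ rng.standard_normal(p)
    return beta_hat, beta_draw, sigma2


def _logistic_draw(X, y, rng, n_iter: int = 25):
    """Newton-fitted ridge logistic model and an approximate posterior draw."""
    p = X.shape[1]
    beta = np.zeros(p)
    for _ in range(n_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-6)
        gram = X.T @ (X * w[:, None]) + 1e-4 * np.eye(p)
        step = np.linalg.solve(gram, X.T @ (y - mu) - 1e-4 * beta)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    mu = expit(X @ beta)
    w = np.maximum(mu * (1 - mu), 1e-6)
    cov = np.linalg.inv(X.T @ (X * w[:, None]) + 1e-4 * np.eye(p))
    beta_draw = beta + np.linalg.cholesky(cov) @ rng.standard_normal(p)
    return beta_draw


class PMMImputer:
    """Chained-equations multiple imputer (PMM + logistic draws).

    Parameters
    ----------
    variables : sequence of str or None
        Variables to impute; ``None`` means every imputable variable that
        actually has missing values.
    m : int
        Number of completed data sets.
    donors : int
        PMM donor pool size.
    iterations : int
        Chained-equation sweeps per data set.
    outcome : str or None
        Column holding the outcome predictor; ``None`` recomputes the
        combined sepsis label from the records.
    random_state : int
        Master seed; each data set gets an independently spawned stream.
    """

    def __init__(
        self,
        variables: Sequence[str] | None = None,
        m: int = 20,
        donors: int = 5,
        iterations: int = 10,
        outcome: str | None = None,
        random_state: int = 0,
    ):
        self.variables = variables
        self.m = m
        self.donors = donors
        self.iterations = iterations
        self.outcome = outcome
        self.random_state = random_state

    def get_params(self, deep=True):
        return {
            "variables": self.variables,
            "m": self.m,
            "donors": self.donors,
            "iterations": self.iterations,
            "outcome": self.outcome,
            "random_state": self.random_state,
        }

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit_transform(self, df: pd.DataFrame) -> ImputationResult:
        if self.variables is None:
            variables = tuple(
                v for v in IMPUTABLE if v in df.columns and df[v].isna().any()
            )
        else:
            variables = tuple(self.variables)
        for v in variables:
            n_miss = int(df[v].isna().sum())
            if n_miss == len(df):
                raise ValueError(f"variable {v!r} is entirely missing; cannot impute")
            if n_miss > 0.5 * len(df):
                raise ValueError(f"variable {v!r} exceeds 50% missingness")
        if not variables:
            res = ImputationResult(
                [df.copy() for _ in range(self.m)], {}, {}, self.m, self.iterations, ()
            )
            return res

        # fixed predictors: comorbidities and the outcome, never imputed
        fixed_cols = [c for c in _COMORBIDITIES if c in df.columns]
        fixed = pd.DataFrame(index=df.index)
        for c in fixed_cols:
            fixed[c] = df[c].astype(float)
        if self.outcome is not None:
            fixed["outcome"] = df[self.outcome].astype(float)
        else:
            fixed["outcome"] = outcomes.label_cohort(df)["sepsis"].astype(float)

        miss_masks = {v: df[v].isna().to_numpy() for v in variables}
        order = sorted(variables, key=lambda v: miss_masks[v].sum())
        methods = {
            v: ("logistic" if v in BOOLEAN_COLUMNS else "pmm") for v in variables
        }
        chain = {v: np.full((self.m, self.iterations), np.nan) for v in variables}

        ss = np.random.SeedSequence(self.random_state)
        datasets = []
        for d, child in enumerate(ss.spawn(self.m)):
            rng = np.random.default_rng(child)
            work = df.copy()
            num = {
                v: pd.to_numeric(work[v], errors="coerce").to_numpy(dtype=float)
                for v in variables
            }
            for v in variables:
                mask = miss_masks[v]
                obs = num[v][~mask]
                num[v][mask] = rng.choice(obs, size=mask.sum(), replace=True)

            for it in range(self.iterations):
                for v in order:
                    mask = miss_masks[v]
                    if not mask.any():
                        continue
                    others = [u for u in variables if u != v]
                    Xall = np.hstack(
                        [np.ones((len(df), 1))]
                        + [num[u][:, None] for u in others]
                        + [fixed.to_numpy(dtype=float)]
                    )
                    Xobs, Xmis = Xall[~mask], Xall[mask]
                    yobs = num[v][~mask]
                    if methods[v] == "logistic":
                        beta_draw = _logistic_draw(Xobs, yobs, rng)
                        pm = expit(Xmis @ beta_draw)
                        num[v][mask] = (rng.random(mask.sum()) < pm).astype(float)
                    else:
                        beta_hat, beta_draw, _ = _bayes_linear_draw(Xobs, yobs, rng)
                        pred_obs = Xobs @ beta_hat
                        pred_mis = Xmis @ beta_draw
                        k = min(self.donors, yobs.size)
                        dist = np.abs(pred_obs[None, :] - pred_mis[:, None])
                        part = np.argpartition(dist, k - 1, axis=1)[:, :k]
                        pick = part[np.arange(part.shape[0]), rng.integers(0, k, part.shape[0])]
                        num[v][mask] = yobs[pick]
                    chain[v][d, it] = num[v][mask].mean()

            for v in variables:
                if str(df[v].dtype) == "boolean":
                    work[v] = pd.array(num[v] == 1.0, dtype="boolean")
                elif str(df[v].dtype) == "Int64":
                    work[v] = pd.array(np.round(num[v]).astype("int64"), dtype="Int64")
                else:
                    work[v] = num[v]
            datasets.append(work)

        return ImputationResult(datasets, methods, chain, self.m, self.iterations, variables)


def pmm_impute(
    cohort: pd.DataFrame,
    variables: Sequence[str] | None = None,
    m: int = 20,
    donors: int = 5,
    iterations: int = 10,
    seed: int = 0,
    outcome: str | None = None,
) -> ImputationResult:
    """Functional wrapper around :class:`PMMImputer`."""
    return PMMImputer(
        variables=variables,
        m=m,
        donors=donors,
        iterations=iterations,
        outcome=outcome,
        random_state=seed,
    ).fit_transform(cohort)


def pooled_evaluation(
    result: ImputationResult,
    score: str | Callable[[pd.DataFrame], np.ndarray],
    outcome: Sequence | Callable[[pd.DataFrame], np.ndarray] | str = "sepsis",
    pooling: str = "median",
) -> MetricWithCI:
    """Pooled AUC of a score over the completed data sets.

    ``pooling='median'`` takes the median AUC and the medians of the
    per-set DeLong CI bounds across the m sets (the literal pooling the
    sensitivity analysis describes); ``pooling='rubin'`` applies Rubin's
    rules (mean estimate; within+between variance) as the principled
    alternative.
    """
    if isinstance(score, str):
        scorer = BandedScorer(score)
        score_fn = scorer.decision_function
    else:
        score_fn = score
    ests, los, his = [], [], []
    for ds in result.datasets:
        if callable(outcome):
            y = np.asarray(outcome(ds), dtype=bool)
        elif isinstance(outcome, str):
            if outcome in ds.columns:
                y = ds[outcome].to_numpy(dtype=bool)
            else:
                y = outcomes.label_cohort(ds)["sepsis"].to_numpy(dtype=bool)
        else:
            y = np.asarray(outcome, dtype=bool)
        s = np.asarray(score_fn(ds), dtype=float)
        res = auc(s, y)
        ests.append(res.estimate)
        los.append(res.ci_low)
        his.append(res.ci_high)
    n = len(result.datasets[0])
    if pooling == "median":
        return MetricWithCI(
            float(np.median(ests)),
            float(np.median(los)),
            float(np.median(his)),
            "pooled AUC (median of sets)",
            n,
        )
    if pooling == "rubin":
        m = len(ests)
        est = float(np.mean(ests))
        z = norm.ppf(0.975)
        within = np.mean([((h - l) / (2 * z)) ** 2 for l, h in zip(los, his)])
        between = np.var(ests, ddof=1) if m > 1 else 0.0
        total = within + (1 + 1 / m) * between
        half = z * np.sqrt(total)
        return MetricWithCI(
            est, max(est - half, 0.0), min(est + half, 1.0), "pooled AUC (Rubin)", n
        )
    raise ValueError(f"unknown pooling {pooling!r}")
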