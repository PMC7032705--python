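"""Data-driven derivation of banded integer risk scores.

The construction pipeline:

1. **LOWESS screening** — smooth the binary outcome against each candidate
   vital sign to locate the range where risk departs from baseline.
2. **Candidate grid** — discretize that range into ordered cut-points (a
   fixed published grid is also shipped: 5-year age groups 40-90, heart
   rate 60-140 by 5, systolic pressure 70-120 by 2, diastolic 40-90 by 2,
   respiratory rate 20-40 by 2, mental-status ordinal levels).
3. **Dichotomization** — one binary indicator per (variable, cut-point),
   risk-increasing side taken from the smooth's slope.
4. **Stage-1 stability selection** — L1-penalized logistic regression with
   10-fold cross-validation, the penalty chosen by maximizing CV-AUC,
   repeated over fresh fold splits; keep indicators selected (refit
   coefficient >= 0.05) in more than half the repeats.
5. **Adjacency collapsing** — among surviving indicators on consecutive
   cut-points of one variable, keep the highest-coefficient one.
6. **Stage-2 stability selection** — as stage 1 on the survivors, with the
   penalty chosen by the one-standard-error rule on the CV-AUC curve.
7. **Point assignment** — integer points proportional to the stage-2
   coefficients (smallest retained coefficient maps to 1 point).
8. **Cut-off selection** — require contributions from more than one
   variable: cut-off = (largest single-variable points) + 2.

:class:`ScoreDeriver` packages steps 2-8 as a scikit-learn style estimator;
the module-level functions expose each step individually.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from ._solver import lambda_grid, logistic_lasso_path
from .scores import Band, BandedScorer, ScoreDefinition

__all__ = [
    "CandidateGrid",
    "IndicatorMatrix",
    "StabilitySummary",
    "DerivedScore",
    "lowess_smooth",
    "published_grid",
    "select_grid",
    "dichotomize",
    "lasso_stage",
    "collapse_adjacent",
    "assign_points",
    "select_cutoff",
    "derive_score",
    "ScoreDeriver",
]

#: risk-increasing side per variable (slope sign of the published smooths)
DEFAULT_DIRECTIONS = {
    "age": ">",
    "heart_rate": ">",
    "respiratory_rate": ">",
    "mental_status": ">=",
    "sbp": "<",
    "dbp": "<",
    "hbp": ">",
    "lactate": ">",
}

#: the published candidate grids (variable -> ordered cut-points)
_PUBLISHED_CUTS = {
    "age": np.arange(40, 95, 5),
    "heart_rate": np.arange(60, 145, 5),
    "sbp": np.arange(70, 122, 2),
    "dbp": np.arange(40, 92, 2),
    "respiratory_rate": np.arange(20, 42, 2),
    "mental_status": np.arange(2, 6),
}

#: grid used for the heparin-binding-protein biomarker when requested
# (no published grid; spans the clinically used 20-60 ng/mL decision range)
_HBP_CUTS = np.arange(20, 62, 2)


@dataclass
class CandidateGrid:
    """Per-variable ordered cut-points with a risk direction."""

    cuts: dict[str, np.ndarray]
    directions: dict[str, str]
    provenance: str = "published_fixture"

    def __post_init__(self):
        for var, c in self.cuts.items():
            c = np.asarray(c, dtype=float)
            if c.size > 1 and not np.all(np.diff(c) > 0):
                raise ValueError(f"cut-points for {var!r} must be strictly increasing")
            self.cuts[var] = c

    def items(self):
        for var, cuts in self.cuts.items():
            d = self.directions[var]
            for i, c in enumerate(cuts):
                yield var, i, float(c), d

    @property
    def n_indicators(self) -> int:
        return sum(len(c) for c in self.cuts.values())


@dataclass
class IndicatorMatrix:
    """Binary design matrix: one column per (variable, cut-point) indicator."""

    X: np.ndarray  # (n, p) in {0, 1}
    names: list  # "sbp<100"-style labels
    items: list  # (variable, grid position, cut, direction)

    def subset(self, mask: np.ndarray) -> "IndicatorMatrix":
        idx = np.nonzero(mask)[0]
        return IndicatorMatrix(
            self.X[:, idx], [self.names[i] for i in idx], [self.items[i] for i in idx]
        )


@dataclass
class StabilitySummary:
    """Aggregate of repeated cross-validated penalized fits."""

    names: list
    items: list
    frequency: np.ndarray  # selection frequency over repeats, in [0, 1]
    mean_coef: np.ndarray  # mean refit coefficient over selecting repeats
    included: np.ndarray  # frequency > 0.5 and mean coefficient >= 0.05
    n_repeats: int
    chosen_lambdas: np.ndarray
    cv_auc_at_chosen: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "indicator": self.names,
                "frequency": self.frequency,
                "mean_coef": self.mean_coef,
                "included": self.included,
            }
        )


@dataclass
class DerivedScore:
    """A derived ScoreDefinition plus its full audit trail."""

    definition: ScoreDefinition
    stage1: StabilitySummary
    stage2: StabilitySummary
    scale: float
    grid: CandidateGrid
    points: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# LOWESS screening and candidate grids
# ---------------------------------------------------------------------------

def lowess_smooth(x: np.ndarray, y: np.ndarray, bandwidth: float = 2.0 / 3.0) -> np.ndarray:
    """Tricube-weighted local-linear smooth of ``y`` against ``x``.

    Returns an ``(k, 2)`` array of (x, smooth) pairs at the distinct x
    values, sorted by x.  ``bandwidth`` is the fraction of points entering
    each local fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    if x.size < 10:
        raise ValueError("need at least 10 observations to smooth")
    if not 0.0 < bandwidth <= 1.0:
        raise ValueError("bandwidth must be in (0, 1]")
    if np.all(x == x[0]):
        raise ValueError("degenerate input: all x values identical")
    out = _sm_lowess(y, x, frac=bandwidth, it=0, return_sorted=True)
    xs, idx = np.unique(out[:, 0], return_index=True)
    # duplicate x values share one fitted value; keep the first of each run
    return np.column_stack([xs, out[idx, 1]])


def published_grid(include_hbp: bool = False) -> CandidateGrid:
    """The fixed published candidate grid (optionally with the HBP grid)."""
    cuts = {v: c.copy() for v, c in _PUBLISHED_CUTS.items()}
    if include_hbp:
        cuts["hbp"] = _HBP_CUTS.copy()
    dirs = {v: DEFAULT_DIRECTIONS[v] for v in cuts}
    return CandidateGrid(cuts, dirs, provenance="published_fixture")


def select_grid(
    curves: Mapping[str, np.ndarray] | None = None,
    rules: Mapping | None = None,
) -> CandidateGrid:
    """Build a candidate grid, either the published fixture or LOWESS-derived.

    ``rules['provenance']`` selects the mode.  ``published_fixture`` ignores
    the curves and returns the published grids.  ``lowess_derived`` takes, per
    variable, the x-range where the smooth departs from its baseline (the
    smooth's minimum) by more than ``rules['delta']`` (default 0.05) and
    discretizes it at ``rules['steps'][variable]``; a flat smooth yields an
    empty grid with a warning.
    """
    rules = dict(rules or {})
    mode = rules.get("provenance", "published_fixture")
    if mode in ("published_fixture", "paper_fixture"):  # legacy alias accepted
        return published_grid(include_hbp=bool(rules.get("include_hbp", False)))
    if mode != "lowess_derived":
        raise ValueError(f"unknown grid provenance {mode!r}")
    if not curves:
        raise ValueError("lowess_derived grids need smoothed curves")
    delta = float(rules.get("delta", 0.05))
    steps = rules.get("steps", {})
    cuts: dict[str, np.ndarray] = {}
    dirs: dict[str, str] = {}
    for var, curve in curves.items():
        curve = np.asarray(curve, dtype=float)
        xs, s = curve[:, 0], curve[:, 1]
        slope = np.polyfit(xs, s, 1)[0] if xs.size > 1 else 0.0
        direction = rules.get("directions", {}).get(
            var, DEFAULT_DIRECTIONS.get(var, ">" if slope >= 0 else "<")
        )
        baseline = s.min()
        active = np.abs(s - baseline) > delta
        if not active.any():
            warnings.warn(f"flat smooth for {var!r}: empty grid", stacklevel=2)
            cuts[var] = np.array([])
            dirs[var] = direction
            continue
        lo, hi = xs[active].min(), xs[active].max()
        step = float(steps.get(var, max((hi - lo) / 10.0, 1e-9)))
        start = np.ceil(lo / step) * step
        grid = np.arange(start, hi + 1e-9, step)
        cuts[var] = grid
        dirs[var] = direction
    return CandidateGrid(cuts, dirs, provenance="lowess_derived")


# ---------------------------------------------------------------------------
# Dichotomization
# ---------------------------------------------------------------------------

def dichotomize(df: pd.DataFrame, grid: CandidateGrid) -> IndicatorMatrix:
    """Binary indicator matrix over the grid; constant columns are dropped."""
    if grid.n_indicators == 0:
        raise ValueError("empty candidate grid")
    cols, names, items = [], [], []
    n = len(df)
    for var, pos, cut, d in grid.items():
        values = pd.to_numeric(df[var], errors="coerce").to_numpy(dtype=float)
        ind = {
            "<": values < cut,
            ">": values > cut,
            "<=": values <= cut,
            ">=": values >= cut,
        }[d].astype(np.int8)
        if ind.sum() in (0, n):  # constant after construction
            continue
        cols.append(ind)
        names.append(f"{var}{d}{cut:g}")
        items.append((var, pos, cut, d))
    X = np.column_stack(cols) if cols else np.empty((n, 0), dtype=np.int8)
    return IndicatorMatrix(X, names, items)


# ---------------------------------------------------------------------------
# Repeated cross-validated penalized selection
# ---------------------------------------------------------------------------

def _auc_columns(y: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Tie-corrected Mann-Whitney AUC of each column of ``scores`` against y."""
    m = int(y.sum())
    n_neg = y.size - m
    ranks = rankdata(scores, axis=0)
    pos_rank_sum = ranks[y == 1].sum(axis=0)
    return (pos_rank_sum - m * (m + 1) / 2.0) / (m * n_neg)


def lasso_stage(
    indicators: IndicatorMatrix,
    y: np.ndarray,
    n_repeats: int = 50,
    n_folds: int = 10,
    lambda_rule: str = "max_auc",
    seed: int | np.random.SeedSequence = 0,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 0.01,
    coef_threshold: float = 0.05,
    freq_threshold: float = 0.5,
) -> StabilitySummary:
    """One stage of repeated cross-validated L1-logistic stability selection.

    Each repeat draws a fresh stratified fold split, picks the penalty on
    the mean CV-AUC curve (``max_auc`` or ``one_se`` — the most penalized
    model within one standard error of the maximum), refits on the full
    data at that penalty, and records every indicator whose refit
    coefficient magnitude is at least ``coef_threshold``.  An indicator is
    *included* when recorded in more than ``freq_threshold`` of repeats and
    its mean recorded coefficient is at least ``coef_threshold``.
    """
    if lambda_rule not in ("max_auc", "one_se"):
        raise ValueError(f"unknown lambda rule {lambda_rule!r}")
    X = indicators.X.astype(np.float64)
    y = np.asarray(y, dtype=np.float64)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("degenerate outcome: a single class cannot be cross-validated")
    if counts.min() < n_folds:
        raise ValueError(
            f"n_folds={n_folds} exceeds the minority class count ({counts.min()})"
        )
    n, p = X.shape
    lams = lambda_grid(X, y, n_lambdas, lambda_min_ratio)
    full_betas, _full_b0 = logistic_lasso_path(X, y, lams)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    repeat_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n_repeats)]

    counts_sel = np.zeros(p)
    coef_sums = np.zeros(p)
    chosen = np.zeros(n_repeats)
    auc_at_chosen = np.zeros(n_repeats)
    for rep, rs in enumerate(repeat_seeds):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rs)
        aucs = np.zeros((n_folds, lams.size))
        for k, (tr, te) in enumerate(skf.split(X, y)):
            # fold paths only feed rank-based AUCs; a looser tolerance than
            # the full-data refit path changes no ordering that matters
            betas, b0s = logistic_lasso_path(X[tr], y[tr], lams, tol=1e-6)
            scores = X[te] @ betas.T + b0s
            aucs[k] = _auc_columns(y[te], scores)
        mean_auc = aucs.mean(axis=0)
        se = aucs.std(axis=0, ddof=1) / np.sqrt(n_folds)
        i_max = int(np.argmax(mean_auc))
        if lambda_rule == "max_auc":
            i_sel = i_max
        else:  # most penalized lambda within one SE of the maximum
            ok = np.nonzero(mean_auc >= mean_auc[i_max] - se[i_max])[0]
            i_sel = int(ok[0])
        coefs = full_betas[i_sel]
        hit = np.abs(coefs) >= coef_threshold
        counts_sel += hit
        coef_sums += np.where(hit, coefs, 0.0)
        chosen[rep] = lams[i_sel]
        auc_at_chosen[rep] = mean_auc[i_sel]

    frequency = counts_sel / n_repeats
    mean_coef = coef_sums / np.maximum(counts_sel, 1)
    included = (frequency > freq_threshold) & (mean_coef >= coef_threshold)
    return StabilitySummary(
        names=list(indicators.names),
        items=list(indicators.items),
        frequency=frequency,
        mean_coef=mean_coef,
        included=included,
        n_repeats=n_repeats,
        chosen_lambdas=chosen,
        cv_auc_at_chosen=auc_at_chosen,
    )


def collapse_adjacent(summary: StabilitySummary, grid: CandidateGrid) -> StabilitySummary:
    """Resolve runs of included indicators on consecutive grid cut-points.

    While any two included indicators of one variable sit on adjacent grid
    positions, drop the one with the smaller mean coefficient.  Idempotent.
    """
    included = summary.included.copy()
    by_var: dict[str, list[int]] = {}
    for i, (var, pos, _cut, _d) in enumerate(summary.items):
        by_var.setdefault(var, []).append(i)
    changed = True
    while changed:
        changed = False
        for var, idxs in by_var.items():
            act = [i for i in idxs if included[i]]
            act.sort(key=lambda i: summary.items[i][1])
            for a, b in zip(act, act[1:]):
                if summary.items[b][1] - summary.items[a][1] == 1:
                    drop = a if summary.mean_coef[a] <= summary.mean_coef[b] else b
                    included[drop] = False
                    changed = True
                    break
    return dataclasses.replace(summary, included=included)


def assign_points(coefficients: Mapping[str, float], scale: float | None = None) -> dict[str, int]:
    """Integer points proportional to coefficients.

    By default the scale is ``1 / min(coefficient)`` so the smallest
    retained coefficient maps to exactly one point; points are rounded half
    away from zero and are always >= 1.
    """
    if not coefficients:
        raise ValueError("cannot assign points to an empty coefficient set")
    vals = np.asarray(list(coefficients.values()), dtype=float)
    if np.any(vals <= 0):
        raise ValueError("all retained coefficients must be positive")
    k = (1.0 / vals.min()) if scale is None else float(scale)
    points = {name: int(np.floor(c * k + 0.5)) for name, c in coefficients.items()}
    return {name: max(p, 1) for name, p in points.items()}


def select_cutoff(
    definition: ScoreDefinition, rule: str | Callable[[ScoreDefinition], int] = "max_single_plus_2"
) -> int:
    """Decision cut-off requiring contributions from more than one variable.

    The default rule is (largest points any single variable can score) + 2,
    which regenerates the shipped cut-offs 7 and 10 from the published point
    sets; ``max_single_plus_1`` is the stricter alternative and any callable
    is accepted.
    """
    if len(definition.bands) < 2:
        raise ValueError("cut-off selection needs a score with at least two variables")
    if callable(rule):
        return int(rule(definition))
    base = definition.max_single_variable()
    if rule == "max_single_plus_2":
        return base + 2
    if rule == "max_single_plus_1":
        return base + 1
    raise ValueError(f"unknown cut-off rule {rule!r}")


# ---------------------------------------------------------------------------
# End-to-end estimator
# ---------------------------------------------------------------------------

class ScoreDeriver(BaseEstimator):
    """Derive a banded integer score by two-stage penalized stability selection.

    Parameters
    ----------
    grid : "published" or CandidateGrid
        Candidate cut-points; ``"published"`` uses the published fixture.
    include_hbp : bool
        Whether heparin-binding protein enters the candidate set.
    n_repeats, n_folds : int
        Repeated cross-validation layout for both stages.
    stage2_repeats : int or None
        Repeats for the second stage (defaults to ``n_repeats``).
    coef_threshold, freq_threshold : float
        Inclusion filters applied to both stages.
    n_lambdas, lambda_min_ratio : penalty path geometry.
    scale : float or None
        Point-assignment scale; ``None`` maps the smallest stage-2
        coefficient to one point.
    cutoff_rule : str or callable
        See :func:`select_cutoff`.
    random_state : int
        Master seed; stage seeds are spawned from it.

    Attributes (after ``fit``)
    --------------------------
    grid_, indicators_, stability_stage1_, stability_stage2_,
    points_, scale_, score_definition_, cutoff_, derived_ (full audit trail).
    """

    def __init__(
        self,
        grid="published",
        include_hbp: bool = True,
        n_repeats: int = 50,
        stage2_repeats: int | None = None,
        n_folds: int = 10,
        coef_threshold: float = 0.05,
        freq_threshold: float = 0.5,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 0.01,
        scale: float | None = None,
        cutoff_rule="max_single_plus_2",
        name: str = "derived",
        random_state: int = 0,
    ):
        self.grid = grid
        self.include_hbp = include_hbp
        self.n_repeats = n_repeats
        self.stage2_repeats = stage2_repeats
        self.n_folds = n_folds
        self.coef_threshold = coef_threshold
        self.freq_threshold = freq_threshold
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.scale = scale
        self.cutoff_rule = cutoff_rule
        self.name = name
        self.random_state = random_state

    def _resolve_grid(self) -> CandidateGrid:
        if isinstance(self.grid, CandidateGrid):
            g = self.grid
            if not self.include_hbp and "hbp" in g.cuts:
                cuts = {v: c for v, c in g.cuts.items() if v != "hbp"}
                dirs = {v: d for v, d in g.directions.items() if v != "hbp"}
                return CandidateGrid(cuts, dirs, g.provenance)
            return g
        if self.grid in ("published", "paper"):  # legacy alias accepted
            return published_grid(include_hbp=self.include_hbp)
        raise ValueError(f"unknown grid {self.grid!r}")

    def fit(self, X: pd.DataFrame, y: Sequence) -> "ScoreDeriver":
        y = np.asarray(y, dtype=float)
        grid = self._resolve_grid()
        missing = X[list(grid.cuts)].isna().any(axis=1).to_numpy()
        if missing.any():
            raise ValueError(
                "derivation requires complete cases on the grid variables; "
                f"{int(missing.sum())} rows have missing values (filter first)"
            )
        ind = dichotomize(X, grid)
        ss = np.random.SeedSequence(self.random_state)
        s1_seed, s2_seed = ss.spawn(2)
        common = dict(
            n_folds=self.n_folds,
            n_lambdas=self.n_lambdas,
            lambda_min_ratio=self.lambda_min_ratio,
            coef_threshold=self.coef_threshold,
            freq_threshold=self.freq_threshold,
        )
        stage1 = lasso_stage(
            ind, y, n_repeats=self.n_repeats, lambda_rule="max_auc", seed=s1_seed, **common
        )
        stage1 = collapse_adjacent(stage1, grid)
        if not stage1.included.any():
            raise ValueError("no indicator survived stage-1 stability selection")
        surviv = ind.subset(stage1.included)
        stage2 = lasso_stage(
            surviv,
            y,
            n_repeats=self.stage2_repeats or self.n_repeats,
            lambda_rule="one_se",
            seed=s2_seed,
            **common,
        )
        if not stage2.included.any():
            raise ValueError("no indicator survived stage-2 stability selection")
        retained = {
            stage2.names[i]: float(stage2.mean_coef[i])
            for i in np.nonzero(stage2.included)[0]
        }
        points = assign_points(retained, scale=self.scale)
        scale_ = (1.0 / min(retained.values())) if self.scale is None else float(self.scale)

        bands: dict[str, list[Band]] = {}
        for i in np.nonzero(stage2.included)[0]:
            var, _pos, cut, d = stage2.items[i]
            bands.setdefault(var, []).append(Band(cut, d, points[stage2.names[i]]))
        for var in bands:
            bands[var].sort(key=lambda b: float(b.threshold))
        definition = ScoreDefinition(self.name, bands, cutoff=1)
        definition.cutoff = select_cutoff(definition, self.cutoff_rule)

        self.grid_ = grid
        self.indicators_ = ind
        self.stability_stage1_ = stage1
        self.stability_stage2_ = stage2
        self.points_ = points
        self.scale_ = scale_
        self.score_definition_ = definition
        self.cutoff_ = definition.cutoff
        self.classes_ = np.array([0, 1])
        self.derived_ = DerivedScore(definition, stage1, stage2, scale_, grid, points)
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        return BandedScorer(self.score_definition_).decision_function(X)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return BandedScorer(self.score_definition_).predict(X)


def derive_score(
    cohort: pd.DataFrame,
    outcome: Sequence,
    grid="published",
    include_hbp: bool = True,
    **config,
) -> DerivedScore:
    """Functional wrapper around :class:`ScoreDeriver` returning the audit trail.

    Rows with missing values on the grid variables are excluded first
    (complete-case primary analysis).
    """
    deriver = ScoreDeriver(grid=grid, include_hbp=include_hbp, **config)
    g = deriver._resolve_grid()
    y = np.asarray(outcome, dtype=float)
    keep = ~cohort[list(g.cuts)].isna().any(axis=1).to_numpy()
    deriver.fit(cohort.loc[keep], y[keep])
    return deriver.derived_
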