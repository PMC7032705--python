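"""Score derivation: LOWESS, grids, stability selection, points, cut-offs."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from sepscore import derivation
from sepscore.derivation import (
    CandidateGrid,
    IndicatorMatrix,
    ScoreDeriver,
    StabilitySummary,
    assign_points,
    collapse_adjacent,
    dichotomize,
    lasso_stage,
    lowess_smooth,
    published_grid,
    select_cutoff,
    select_grid,
)
from sepscore.scores import load_definition
from sepscore._solver import lambda_grid, logistic_lasso_path


class TestLowess:
    def test_constant_response_is_constant(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 50)
        out = lowess_smooth(x, np.ones(50))
        assert np.allclose(out[:, 1], 1.0)

    def test_recovers_linear_probability(self):
        rng = np.random.default_rng(1)
        n = 5000
        x = rng.uniform(0, 1, n)
        p = 0.1 + 0.7 * x
        y = (rng.random(n) < p).astype(float)
        out = lowess_smooth(x, y, bandwidth=0.3)
        interior = (out[:, 0] > 0.1) & (out[:, 0] < 0.9)
        truth = 0.1 + 0.7 * out[interior, 0]
        assert np.max(np.abs(out[interior, 1] - truth)) < 0.05

    def test_full_bandwidth_reproduces_exact_line(self):
        # weighted local-linear fits reproduce exactly linear data whatever the weights
        x = np.linspace(0, 10, 40)
        y = 2.0 + 0.5 * x
        out = lowess_smooth(x, y, bandwidth=1.0)
        assert np.allclose(out[:, 1], 2.0 + 0.5 * out[:, 0], atol=1e-8)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            lowess_smooth(np.ones(20), np.zeros(20))
        with pytest.raises(ValueError, match="at least 10"):
            lowess_smooth(np.arange(5.0), np.arange(5.0))
        with pytest.raises(ValueError, match="bandwidth"):
            lowess_smooth(np.arange(20.0), np.zeros(20), bandwidth=0.0)


class TestGrid:
    def test_paper_fixture_grids(self):
        g = select_grid(rules={"provenance": "published_fixture"})
        assert list(g.cuts["sbp"]) == list(range(70, 122, 2))
        assert len(g.cuts["sbp"]) == 26
        assert list(g.cuts["age"]) == list(range(40, 95, 5))
        assert list(g.cuts["heart_rate"]) == list(range(60, 145, 5))
        assert list(g.cuts["dbp"]) == list(range(40, 92, 2))
        assert list(g.cuts["respiratory_rate"]) == list(range(20, 42, 2))
        assert list(g.cuts["mental_status"]) == [2, 3, 4, 5]
        assert "hbp" not in g.cuts
        assert "hbp" in published_grid(include_hbp=True).cuts

    def test_flat_smooth_yields_empty_grid(self):
        curve = np.column_stack([np.linspace(0, 1, 50), np.full(50, 0.3)])
        with pytest.warns(UserWarning, match="flat smooth"):
            g = select_grid({"sbp": curve}, {"provenance": "lowess_derived"})
        assert g.cuts["sbp"].size == 0

    def test_step_function_grid_brackets_the_step(self):
        rng = np.random.default_rng(3)
        n = 4000
        x = rng.uniform(70, 130, n)
        y = (rng.random(n) < np.where(x < 100, 0.5, 0.15)).astype(float)
        curve = lowess_smooth(x, y, bandwidth=0.3)
        g = select_grid(
            {"sbp": curve},
            {"provenance": "lowess_derived", "steps": {"sbp": 2}, "delta": 0.05},
        )
        assert g.cuts["sbp"].size > 0
        assert g.cuts["sbp"].min() < 100 < g.cuts["sbp"].max()
        assert g.directions["sbp"] == "<"

    def test_cut_points_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            CandidateGrid({"sbp": np.array([100, 90])}, {"sbp": "<"})


class TestDichotomize:
    def test_direct_comparisons(self):
        df = pd.DataFrame({"age": [50.0, 30.0, 90.0], "sbp": [95.0, 120.0, 80.0]})
        g = CandidateGrid(
            {"age": np.array([45, 60, 80]), "sbp": np.array([100, 106])},
            {"age": ">", "sbp": "<"},
        )
        ind = dichotomize(df, g)
        row = ind.X[0]
        named = dict(zip(ind.names, row))
        assert named["age>45"] == 1 and named["age>60"] == 0 and named["age>80"] == 0
        assert named["sbp<100"] == 1 and named["sbp<106"] == 1

    def test_column_count_and_constant_filter(self, planted_cohort):
        ch, _, _ = planted_cohort
        g = published_grid()
        ind = dichotomize(ch.df, g)
        assert ind.X.shape[1] <= g.n_indicators
        assert not any((c == c[0]).all() for c in ind.X.T)


def _make_summary(items, coefs, included=None):
    n = len(items)
    freq = np.ones(n)
    inc = np.ones(n, dtype=bool) if included is None else np.asarray(included)
    names = [f"{v}{d}{c:g}" for (v, _p, c, d) in items]
    return StabilitySummary(names, list(items), freq, np.asarray(coefs, float),
                            inc, 50, np.zeros(50), np.zeros(50))


class TestCollapseAdjacent:
    grid = CandidateGrid({"sbp": np.arange(90, 112, 2)}, {"sbp": "<"})

    def test_adjacent_pair_keeps_higher_coefficient(self):
        items = [("sbp", 5, 100.0, "<"), ("sbp", 6, 102.0, "<")]
        s = collapse_adjacent(_make_summary(items, [0.30, 0.10]), self.grid)
        assert list(s.included) == [True, False]

    def test_no_adjacency_identity(self):
        items = [("sbp", 2, 94.0, "<"), ("sbp", 5, 100.0, "<")]
        s0 = _make_summary(items, [0.2, 0.3])
        s = collapse_adjacent(s0, self.grid)
        assert list(s.included) == [True, True]

    def test_three_consecutive_keeps_middle(self):
        items = [("sbp", 4, 98.0, "<"), ("sbp", 5, 100.0, "<"), ("sbp", 6, 102.0, "<")]
        s = collapse_adjacent(_make_summary(items, [0.1, 0.5, 0.2]), self.grid)
        assert list(s.included) == [False, True, False]

    def test_idempotent(self):
        items = [("sbp", 4, 98.0, "<"), ("sbp", 5, 100.0, "<"), ("sbp", 6, 102.0, "<")]
        once = collapse_adjacent(_make_summary(items, [0.1, 0.5, 0.2]), self.grid)
        twice = collapse_adjacent(once, self.grid)
        assert list(once.included) == list(twice.included)


class TestAssignPoints:
    def test_proportional_with_explicit_scale(self):
        pts = assign_points({"a": 0.5, "b": 1.0, "c": 2.5}, scale=2)
        assert pts == {"a": 1, "b": 2, "c": 5}

    def test_single_coefficient_self_scales_to_one(self):
        assert assign_points({"a": 0.07}) == {"a": 1}

    def test_scale_invariance_under_doubling(self):
        base = {"a": 0.3, "b": 0.6, "c": 1.2}
        doubled = {k: 2 * v for k, v in base.items()}
        assert assign_points(base) == assign_points(doubled)

    def test_ordering_preserved(self):
        pts = assign_points({"a": 0.31, "b": 0.29, "c": 0.9})
        assert pts["c"] >= pts["a"] >= pts["b"] >= 1

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            assign_points({})


class TestSelectCutoff:
    def test_published_point_sets_regenerate_7_and_10(self):
        assert select_cutoff(load_definition("sews")) == 7
        assert select_cutoff(load_definition("shews")) == 10

    def test_strict_alternative_rule(self):
        assert select_cutoff(load_definition("sews"), "max_single_plus_1") == 6

    def test_single_variable_score_rejected(self):
        from sepscore.scores import Band, ScoreDefinition

        d = ScoreDefinition("solo", {"age": [Band(60, ">", 3)]}, cutoff=1)
        with pytest.raises(ValueError, match="two variables"):
            select_cutoff(d)


def _noise_design(seed, n=2000, p_noise=10, weight=2.0):
    rng = np.random.default_rng(seed)
    planted = (rng.random(n) < 0.35).astype(np.int8)
    noise = (rng.random((n, p_noise)) < rng.uniform(0.2, 0.5, p_noise)).astype(np.int8)
    X = np.column_stack([planted[:, None], noise])
    y = (rng.random(n) < 1 / (1 + np.exp(-(-1.2 + weight * planted)))).astype(float)
    names = ["planted"] + [f"noise{i}" for i in range(p_noise)]
    items = [(f"v{j}", j, float(j), ">") for j in range(p_noise + 1)]
    return IndicatorMatrix(X, names, items), y


class TestLassoStage:
    def test_solver_matches_sklearn_saga(self):
        rng = np.random.default_rng(11)
        X = (rng.random((600, 15)) < 0.3).astype(float)
        beta = np.zeros(15)
        beta[[2, 7]] = 1.5
        y = (rng.random(600) < 1 / (1 + np.exp(-(X @ beta - 1.0)))).astype(float)
        lams = lambda_grid(X, y, 20, 0.02)
        betas, b0s = logistic_lasso_path(X, y, lams)
        from sklearn.linear_model import LogisticRegression

        for il in (5, 12, 19):
            sk = LogisticRegression(
                l1_ratio=1, solver="saga", C=1 / (600 * lams[il]), tol=1e-8, max_iter=20000
            ).fit(X, y)
            assert np.abs(sk.coef_[0] - betas[il]).max() < 5e-3
            assert abs(sk.intercept_[0] - b0s[il]) < 5e-3

    def test_planted_strong_indicator_always_selected(self):
        ind, y = _noise_design(0)
        s = lasso_stage(ind, y, n_repeats=20, n_folds=10, lambda_rule="max_auc", seed=0)
        assert s.frequency[0] == 1.0
        assert s.included[0]
        # ordering-invariance of AUC can place the optimum at heavy penalty,
        # so the refit coefficient need only clear the inclusion threshold
        assert s.mean_coef[0] >= 0.05

    def test_two_stage_excludes_noise(self):
        """Noise may leak through stage 1 but never survives the one-SE stage 2."""
        for seed in (0, 2):
            ind, y = _noise_design(seed)
            s1 = lasso_stage(ind, y, n_repeats=20, lambda_rule="max_auc", seed=seed)
            surv = ind.subset(s1.included)
            s2 = lasso_stage(surv, y, n_repeats=20, lambda_rule="one_se", seed=seed + 100)
            freq2 = dict(zip(s2.names, s2.frequency))
            assert freq2["planted"] > 0.9
            for nm in s1.names[1:]:
                assert freq2.get(nm, 0.0) < 0.5, nm

    def test_single_repeat_limiting_case(self):
        ind, y = _noise_design(1)
        s = lasso_stage(ind, y, n_repeats=1, n_folds=5, seed=3)
        assert s.n_repeats == 1
        assert set(np.unique(s.frequency)) <= {0.0, 1.0}

    def test_signal_beats_null_model(self):
        ind, y = _noise_design(4)
        s = lasso_stage(ind, y, n_repeats=3, seed=4)
        assert (s.cv_auc_at_chosen > 0.55).all()

    def test_degenerate_outcome_rejected(self):
        ind, _ = _noise_design(5)
        with pytest.raises(ValueError, match="single class"):
            lasso_stage(ind, np.ones(ind.X.shape[0]), n_repeats=1)

    def test_folds_capped_by_minority_class(self):
        ind, y = _noise_design(6, n=60)
        y[:] = 0.0
        y[:5] = 1.0
        with pytest.raises(ValueError, match="minority"):
            lasso_stage(ind, y, n_folds=10, n_repeats=1)


class TestScoreDeriver:
    def test_end_to_end_recovery(self, planted_cohort):
        ch, y, planted = planted_cohort
        d = ScoreDeriver(
            grid="published", include_hbp=True, n_repeats=10, random_state=5
        ).fit(ch.df, y)
        kept = set(d.points_)
        # each planted cut recovered exactly or by an immediate grid neighbour
        grid = d.grid_
        recovered = 0
        for name in planted:
            if name in kept:
                recovered += 1
                continue
            var = name.rstrip("0123456789=<>.")
            sep = name[len(var):]
            cut = float(sep.lstrip("<>="))
            step = np.diff(grid.cuts[var]).min() if grid.cuts[var].size > 1 else 0
            if any(k.startswith(var) and abs(float(k[len(var):].lstrip("<>=")) - cut) <= step
                   for k in kept):
                recovered += 1
        assert recovered >= 3
        # the pure-noise heart-rate and biomarker indicators never enter the score
        assert not any(k.startswith(("heart_rate", "hbp")) for k in kept)
        assert d.cutoff_ == d.score_definition_.max_single_variable() + 2
        assert all(p >= 1 for p in d.points_.values())

    def test_without_hbp_excludes_biomarker(self, planted_cohort):
        ch, y, _ = planted_cohort
        deriver = ScoreDeriver(grid="published", include_hbp=False, n_repeats=2, random_state=1)
        assert "hbp" not in deriver._resolve_grid().cuts

    def test_deterministic_given_seed(self, planted_cohort):
        ch, y, _ = planted_cohort
        sub = ch.df.head(800)
        ysub = y[:800]
        kw = dict(grid="published", include_hbp=False, n_repeats=3, random_state=7)
        a = ScoreDeriver(**kw).fit(sub, ysub)
        b = ScoreDeriver(**kw).fit(sub, ysub)
        assert a.points_ == b.points_ and a.cutoff_ == b.cutoff_
        assert a.score_definition_ == b.score_definition_

    def test_missing_grid_values_rejected(self, planted_cohort):
        ch, y, _ = planted_cohort
        df = ch.df.head(100).copy()
        df.loc[df.index[:5], "sbp"] = np.nan
        with pytest.raises(ValueError, match="complete cases"):
            ScoreDeriver(n_repeats=1, random_state=0).fit(df, y[:100])

    def test_sklearn_params_round_trip(self):
        d = ScoreDeriver(n_repeats=7)
        assert d.get_params()["n_repeats"] == 7
        d.set_params(n_repeats=3)
        assert d.n_repeats == 3
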