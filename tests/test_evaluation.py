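"""Validation statistics: confusion metrics, AUC/DeLong, odds ratios, chi-square."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sepscore import evaluation
from sepscore.evaluation import (
    ConfusionTable,
    auc,
    chi2_test,
    confusion,
    delong_test,
    evaluate_scores,
    odds_ratio,
    sensitivity_specificity,
)
from sepscore.reference_counts import (
    DIABETES_TABLE,
    MORTALITY_TABLES,
    SEPSIS_TABLES,
    expand_confusion,
)


def _pair_count_auc(scores, y):
    """Exhaustive case-control pair enumeration oracle."""
    cases = scores[y]
    controls = scores[~y]
    total = 0.0
    for c in cases:
        for d in controls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(controls))


class TestConfusion:
    def test_published_cross_tabulation(self):
        pred, truth = expand_confusion(*SEPSIS_TABLES["cohort_a"]["retts"])
        ct = confusion(pred, truth)
        assert (ct.tp, ct.fn, ct.fp, ct.tn) == (66, 167, 12, 261)

    def test_all_negative_and_perfect(self):
        y = np.array([True, False, True])
        ct = confusion(np.zeros(3, bool), y)
        assert ct.tp == 0 and ct.fp == 0
        ct = confusion(y, y)
        assert ct.fn == 0 and ct.fp == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            confusion([True], [True, False])


class TestSensitivitySpecificity:
    # printed percent cells implied by the published count rows
    CELLS = [
        ("cohort_a", "retts", 28, 96, (23, 35), (92, 98)),
        ("cohort_a", "news2", 65, 80, (59, 71), (75, 85)),
        ("cohort_b", "retts", 57, 51, (48, 66), (46, 57)),
        ("cohort_b", "news2", 84, 35, (76, 90), (30, 41)),
        ("cohort_b", "sews", 84, 31, (76, 90), (26, 36)),
        ("cohort_b", "shews", 83, 47, (75, 89), (41, 53)),
    ]

    @pytest.mark.parametrize("cohort,score,sens,spec,sens_ci,spec_ci", CELLS)
    def test_printed_cells_from_counts(self, cohort, score, sens, spec, sens_ci, spec_ci):
        # note: cohort A screening-triage specificity is 261/273 = 95.6%,
        # which rounds to 96 although the source table prints 95 (its own
        # rounding is inconsistent across cells); every other cell matches.
        tp, fn, fp, tn = SEPSIS_TABLES[cohort][score]
        se, sp = sensitivity_specificity(ConfusionTable(tp=tp, fn=fn, fp=fp, tn=tn))
        assert se.as_percent() == (sens, *sens_ci)
        assert sp.as_percent() == (spec, *spec_ci)

    def test_perfect_classifier(self):
        se, sp = sensitivity_specificity(ConfusionTable(10, 0, 0, 10))
        assert se.estimate == 1.0 and sp.estimate == 1.0

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            sensitivity_specificity(ConfusionTable(0, 5, 0, 5))

    def test_ci_contains_estimate(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            tp, fn, fp, tn = rng.integers(1, 200, 4)
            se, sp = sensitivity_specificity(ConfusionTable(tp, fp, fn, tn))
            assert se.ci_low <= se.estimate <= se.ci_high
            assert sp.ci_low <= sp.estimate <= sp.ci_high

    def test_clopper_pearson_coverage_at_cohort_scale(self):
        """Exact binomial CI covers p=0.3 at n=233 in at least 95% of draws."""
        rng = np.random.default_rng(7)
        from scipy.stats import beta as beta_dist

        n, p = 233, 0.3
        k = rng.binomial(n, p, size=2000)
        lo = np.where(k == 0, 0.0, beta_dist.ppf(0.025, k, n - k + 1))
        hi = np.where(k == n, 1.0, beta_dist.ppf(0.975, k + 1, n - k))
        coverage = np.mean((lo <= p) & (p <= hi))
        assert coverage >= 0.95


class TestAuc:
    def test_perfect_and_constant(self):
        y = np.array([True] * 5 + [False] * 5)
        assert auc(np.r_[np.ones(5), np.zeros(5)], y).estimate == 1.0
        assert auc(np.ones(10), y).estimate == 0.5

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(20, 200)
        y = rng.random(n) < 0.4
        if y.all() or not y.any():
            y[:2] = [True, False]
        scores = rng.integers(0, 8, n).astype(float)  # heavy ties
        assert auc(scores, y).estimate == pytest.approx(_pair_count_auc(scores, y), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both outcome classes"):
            auc([1.0, 2.0], [True, True])


class TestDeLong:
    def test_identical_scores(self):
        rng = np.random.default_rng(0)
        s = rng.random(60)
        y = rng.random(60) < 0.5
        res = delong_test(s, s, y)
        assert res.difference == 0.0 and res.p_value == 1.0

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(1)
        y = np.r_[np.ones(30, bool), np.zeros(30, bool)]
        s = np.r_[np.random.default_rng(2).normal(1.5, 1, 30), rng.normal(0, 1, 30)]
        res = delong_test(s, -s, y)
        a = auc(s, y).estimate
        assert res.difference == pytest.approx(2 * a - 1)

    def test_p_symmetric_under_swap(self):
        rng = np.random.default_rng(3)
        y = rng.random(80) < 0.4
        y[:2] = [True, False]
        sa, sb = rng.random(80), rng.random(80)
        r1, r2 = delong_test(sa, sb, y), delong_test(sb, sa, y)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.difference == pytest.approx(-r2.difference)

    def test_variance_against_stratified_bootstrap(self):
        """DeLong var(dAUC) agrees with a B=10^4 bootstrap at n=40 within 15%."""
        rng = np.random.default_rng(5)
        m = 18
        y = np.r_[np.ones(m, bool), np.zeros(22, bool)]
        sa = np.r_[rng.normal(1.0, 1, m), rng.normal(0, 1, 22)]
        sb = np.r_[rng.normal(0.6, 1, m), rng.normal(0, 1, 22)]
        res = delong_test(sa, sb, y)
        v10a, v01a, aa = evaluation._delong_components(sa, y)
        v10b, v01b, ab = evaluation._delong_components(sb, y)
        var_delong = (
            v10a.var(ddof=1) / m + v01a.var(ddof=1) / 22
            + v10b.var(ddof=1) / m + v01b.var(ddof=1) / 22
            - 2 * (np.cov(v10a, v10b)[0, 1] / m + np.cov(v01a, v01b)[0, 1] / 22)
        )
        boot = np.empty(10_000)
        idx_case, idx_ctrl = np.arange(m), np.arange(m, 40)
        for b in range(10_000):
            ic = rng.choice(idx_case, m, replace=True)
            in_ = rng.choice(idx_ctrl, 22, replace=True)
            ii = np.r_[ic, in_]
            boot[b] = _fast_auc(sa[ii], y[ii]) - _fast_auc(sb[ii], y[ii])
        assert var_delong == pytest.approx(boot.var(ddof=1), rel=0.15)
        assert res.p_value <= 1.0

    def test_unpaired_option_and_length_check(self):
        y = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        s = np.arange(20.0)
        res = delong_test(s, s[::-1], y, paired=False)
        assert res.method == "DeLong unpaired"
        with pytest.raises(ValueError, match="equal-length"):
            delong_test(s[:-1], s, y)


def _fast_auc(scores, y):
    from scipy.stats import rankdata

    r = rankdata(scores)
    m = y.sum()
    return (r[y].sum() - m * (m + 1) / 2) / (m * (len(y) - m))


class TestOddsRatio:
    @pytest.mark.parametrize(
        "cohort,score,expected",
        [
            (c, s, v)
            for c, d in {
                "cohort_a": {"retts": (2.3, 0.7, 7.4), "news2": (3.7, 1.2, 12.1),
                             "sews": (14.2, 3.1, 64.3), "shews": (3.4, 0.9, 12.2)},
                "cohort_b": {"retts": (2.6, 1.1, 6.1), "news2": (6.1, 1.4, 26.0),
                             "sews": (4.5, 1.1, 19.6), "shews": (20.0, 2.7, 149.2)},
            }.items()
            for s, v in d.items()
        ],
    )
    def test_published_mortality_odds_ratios(self, cohort, score, expected):
        res = odds_ratio(*MORTALITY_TABLES[cohort][score])
        assert (round(res.estimate, 1), round(res.ci_low, 1), round(res.ci_high, 1)) == expected

    def test_symmetric_table_is_null(self):
        assert odds_ratio(5, 5, 5, 5).estimate == 1.0

    def test_transposed_exposure_is_reciprocal(self):
        a = odds_ratio(20, 158, 8, 166)
        b = odds_ratio(8, 166, 20, 158)
        assert a.estimate == pytest.approx(1 / b.estimate)

    def test_zero_cell_requires_explicit_correction(self):
        with pytest.raises(ValueError, match="correction"):
            odds_ratio(0, 10, 5, 5)
        assert odds_ratio(0, 10, 5, 5, correction=0.5).estimate > 0


class TestChi2:
    def test_cohort_a_diabetes_significant(self):
        assert chi2_test(DIABETES_TABLE) < 0.01

    def test_identical_proportions_p_one(self):
        assert chi2_test([[10, 90], [10, 90]]) == pytest.approx(1.0)

    def test_matches_direct_expected_count_oracle(self):
        t = np.array([[12, 18], [9, 21]], float)
        rows, cols, n = t.sum(1), t.sum(0), t.sum()
        stat = 0.0
        for i in range(2):
            for j in range(2):
                e = rows[i] * cols[j] / n
                stat += (t[i, j] - e) ** 2 / e
        from scipy.stats import chi2 as chi2_dist

        assert chi2_test(t) == pytest.approx(chi2_dist.sf(stat, 1))

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi2_test([[0, 0], [3, 4]])


class TestEvaluateScores:
    @staticmethod
    def _fixture_frame(cohort_key, score):
        # one score at a time: the joint multi-score pattern is not
        # identified by the marginal 2x2 counts
        import pandas as pd

        pred, truth = expand_confusion(*SEPSIS_TABLES[cohort_key][score])
        return pd.DataFrame(
            {"sepsis": truth, f"{score}_total": pred.astype(int), f"{score}_positive": pred}
        )

    def test_reproduces_printed_cells(self):
        expected = {
            "retts": (74, 55, 149, 157, 57, 51),
            "news2": (108, 21, 198, 108, 84, 35),
            "sews": (108, 21, 212, 94, 84, 31),
            "shews": (107, 22, 162, 144, 83, 47),
        }
        for score, (tp, fn, fp, tn, sens, spec) in expected.items():
            df = self._fixture_frame("cohort_b", score)
            rep = evaluate_scores(df, [score], outcome_col="sepsis",
                                  reference=None, mortality_col=None)
            cell = rep["all"][score]
            assert cell["counts"] == {"tp": tp, "fn": fn, "fp": fp, "tn": tn}
            assert cell["sensitivity"].as_percent()[0] == sens
            assert cell["specificity"].as_percent()[0] == spec

    def test_reference_compared_to_itself_is_null(self):
        df = self._fixture_frame("cohort_b", "news2")
        rep = evaluate_scores(df, ["news2"], reference="news2", mortality_col=None)
        assert rep["all"]["news2"]["vs_reference"].p_value == 1.0

    def test_empty_subgroup_marker(self):
        df = self._fixture_frame("cohort_b", "news2")
        rep = evaluate_scores(
            df, ["news2"], reference=None, mortality_col=None,
            subgroups={"none": np.zeros(len(df), bool)},
        )
        assert rep["none"]["empty"] and rep["none"]["n"] == 0
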