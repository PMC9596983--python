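import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from vesseltort.cohort import make_cohort
from vesseltort.inference import (
    collinearity_filter,
    fit_logistic,
    roc_evaluate,
    univariate_screen,
)


def fisher_two_sided_by_enumeration(table):
    """Exhaustive hypergeometric enumeration over all tables with the
    observed margins: sum P(x) over tables no more probable than observed."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    xs = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    probs = stats.hypergeom.pmf(xs, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    return float(probs[probs <= p_obs * (1 + 1e-7)].sum())


def auc_by_pair_counting(scores, labels):
    """Concordant-pair fraction with half credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestUnivariateScreen:
    def test_hypertension_table_chi_square(self):
        # 13/22 ISS patients vs 14/40 non-ISS patients hypertensive
        df = pd.DataFrame(
            {
                "hypertension": [1] * 13 + [0] * 9 + [1] * 14 + [0] * 26,
                "iss": [1] * 22 + [0] * 40,
            }
        )
        res = univariate_screen(df, "iss")[0]
        assert res.test == "chi-square"
        assert res.p_value == pytest.approx(0.067, abs=5e-4)
        assert res.flagged  # 0.067 < 0.1

    def test_identical_groups_give_p_one(self):
        df = pd.DataFrame({"x": [3.0, 7.0, 3.0, 7.0], "iss": [0, 0, 1, 1]})
        res = univariate_screen(df, "iss")[0]
        assert res.test == "t-test"
        assert res.p_value == pytest.approx(1.0)

    def test_constant_variable_warns(self):
        df = make_cohort(30, 0.4, seed=0)
        df["const"] = 1.0
        with pytest.warns(RuntimeWarning, match="constant"):
            res = univariate_screen(df, "iss", variables=["const"])
        assert res[0].p_value == 1.0

    def test_small_expected_counts_switch_to_fisher(self):
        df = pd.DataFrame(
            {"x": [1] * 1 + [0] * 9 + [1] * 2 + [0] * 8, "iss": [1] * 10 + [0] * 10}
        )
        res = univariate_screen(df, "iss")[0]
        assert res.test == "fisher"
        expected = fisher_two_sided_by_enumeration([[9, 1], [8, 2]])
        assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_fisher_matches_enumeration_on_random_small_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(8, 41)
            y = np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]
            x = rng.integers(0, 2, n)
            table = [
                [np.sum((y == 1) & (x == 0)), np.sum((y == 1) & (x == 1))],
                [np.sum((y == 0) & (x == 0)), np.sum((y == 0) & (x == 1))],
            ]
            _, p = stats.fisher_exact(np.array(table))
            assert p == pytest.approx(fisher_two_sided_by_enumeration(table), rel=1e-9)

    def test_chi_square_matches_survival_function(self):
        table = np.array([[13.0, 9.0], [14.0, 26.0]])
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        n = table.sum()
        a, b = table[0]
        c, d = table[1]
        chi2_direct = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        assert p == pytest.approx(float(stats.chi2.sf(chi2_direct, 1)), abs=1e-10)


class TestCollinearityFilter:
    def test_duplicated_tortuosity_columns_collapse(self):
        df = make_cohort(62, 0.355, seed=2)
        kept = collinearity_filter(
            df, ["max_curvature", "range_curvature", "dm", "hypertension"]
        )
        assert len([c for c in kept if "curvature" in c]) == 1
        assert "dm" in kept and "hypertension" in kept

    def test_orthogonal_features_all_retained(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(100, 3)), columns=["a", "b", "c"])
        df["iss"] = rng.integers(0, 2, 100)
        assert collinearity_filter(df, ["a", "b", "c"]) == ["a", "b", "c"]

    def test_three_mutually_collinear_keep_exactly_one(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=120)
        df = pd.DataFrame({"a": base, "b": 2 * base + 1, "c": -base})
        df["iss"] = (base + rng.normal(0, 1, 120) > 0).astype(int)
        kept = collinearity_filter(df, ["a", "b", "c"])
        assert len(kept) == 1

    def test_single_candidate_passthrough(self):
        df = make_cohort(30, 0.4, seed=0)
        assert collinearity_filter(df, ["dm"]) == ["dm"]


class TestLogistic:
    def test_parameter_recovery_at_large_n(self):
        df = make_cohort(2000, 0.355, seed=0)
        res = {r.variable: r for r in fit_logistic(df, ["max_curvature", "dm", "hypertension"])}
        assert 1.05 < res["max_curvature"].odds_ratio < 1.12  # truth 1.084
        assert res["dm"].odds_ratio < 1.0
        assert res["hypertension"].odds_ratio > 1.0
        r = res["max_curvature"]
        assert r.ci_low < r.odds_ratio < r.ci_high

    def test_wald_z_calibrated_under_null(self):
        # ~95% of null replicates keep |z| < 1.96
        inside = total = 0
        for s in range(200):
            df = make_cohort(200, 0.355, coef={}, seed=s)
            res = fit_logistic(df, ["max_curvature"])[0]
            total += 1
            inside += res.p_value >= 0.05
        assert 0.90 <= inside / total <= 0.99

    def test_ci_coverage_at_n500(self):
        true_or = np.exp(0.08)
        covered = 0
        reps = 200
        for s in range(reps):
            df = make_cohort(500, 0.355, coef={"max_curvature": 0.08}, seed=1000 + s)
            r = fit_logistic(df, ["max_curvature"])[0]
            covered += r.ci_low <= true_or <= r.ci_high
        assert covered / reps >= 0.90

    def test_single_binary_predictor_or_equals_cross_product_ratio(self):
        df = pd.DataFrame(
            {"x": [1] * 20 + [0] * 30 + [1] * 10 + [0] * 40, "iss": [1] * 50 + [0] * 50}
        )
        r = fit_logistic(df, ["x"])[0]
        a, b = 20, 30  # exposed/unexposed among cases
        c, d = 10, 40  # exposed/unexposed among controls
        assert r.odds_ratio == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_perfect_separation_names_variable(self):
        df = pd.DataFrame(
            {"sep": np.r_[np.zeros(20), np.ones(20)],
             "noise": np.random.default_rng(0).normal(size=40),
             "iss": np.r_[np.zeros(20, int), np.ones(20, int)]}
        )
        with pytest.raises(ValueError, match="sep"):
            fit_logistic(df, ["sep", "noise"])

    def test_small_n_warns(self):
        df = make_cohort(20, 0.4, seed=3)
        with pytest.warns(RuntimeWarning, match="small"):
            fit_logistic(df, ["max_curvature", "dm", "hypertension", "age"])


class TestRoc:
    def test_perfect_separation(self):
        r = roc_evaluate(np.r_[np.zeros(10), np.ones(10)], np.r_[np.zeros(10, int), np.ones(10, int)])
        assert r.auc == 1.0 and r.sensitivity == 1.0 and r.specificity == 1.0

    def test_four_point_example(self):
        r = roc_evaluate(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1]))
        assert r.auc == pytest.approx(0.75)

    def test_null_scores_auc_near_half(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, 2000)
        assert abs(roc_evaluate(scores, labels).auc - 0.5) < 0.03

    def test_auc_equals_pair_counting_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = rng.integers(10, 51)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = rng.integers(0, 5, n).astype(float)  # heavy ties
            r = roc_evaluate(scores, labels)
            assert r.auc == pytest.approx(auc_by_pair_counting(scores, labels), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_evaluate(np.arange(5.0), np.ones(5, int))

    def test_youden_cutoff_on_logistic_scores(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=1000)
        y = (rng.uniform(size=1000) < expit(2 * x)).astype(int)
        r = roc_evaluate(x, y)
        assert r.sensitivity + r.specificity - 1 > 0.2
        # the reported pair is attained at the reported cutoff
        sens = np.mean(x[y == 1] >= r.cutoff)
        spec = np.mean(x[y == 0] < r.cutoff)
        assert sens == pytest.approx(r.sensitivity, abs=1e-12)
        assert spec == pytest.approx(r.specificity, abs=1e-12)
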