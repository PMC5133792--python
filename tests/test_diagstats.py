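"""Unit and property tests for the diagnostic-statistics layer."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom
from sklearn.metrics import roc_auc_score

from plaquecr import diagstats


def brute_force_auc(scores, labels):
    """Exhaustive pair counting over all positive-negative pairs (ties 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert diagstats.auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_pure_ties(self):
        assert diagstats.auc([2.0] * 6, [0, 0, 0, 1, 1, 1]) == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        scores = [3, 1, 2, 4, 2]
        labels = [1, 0, 0, 1, 1]
        assert diagstats.auc(scores, labels) == brute_force_auc(scores, labels)
        for _ in range(20):
            s = rng.integers(0, 8, size=25).astype(float)  # heavy ties
            y = rng.integers(0, 2, size=25)
            if y.sum() in (0, 25):
                continue
            assert diagstats.auc(s, y) == pytest.approx(
                brute_force_auc(s, y), abs=1e-12
            )

    def test_matches_sklearn(self, rng):
        s = rng.normal(size=60)
        y = rng.integers(0, 2, size=60)
        assert diagstats.auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            diagstats.auc([1.0, 2.0], [1, 1])

    @given(st.integers(0, 2**32 - 1))
    def test_rank_formula_equals_trapezoid(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        scores = np.round(rng.normal(size=n), 1)  # rounding induces ties
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            return
        roc = diagstats.roc_points(scores, labels).sort_values("fpr")
        area = np.trapezoid(roc["tpr"], roc["fpr"])
        assert diagstats.auc(scores, labels) == pytest.approx(area, abs=1e-12)

    @given(st.integers(0, 2**32 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        if labels.sum() in (0, 30):
            return
        transformed = np.exp(2.0 * scores) + 1.0
        assert diagstats.auc(scores, labels) == diagstats.auc(transformed, labels)


class TestCutoff:
    def test_perfectly_separated_returns_smallest_positive_score(self):
        scores = np.array([0.1, 0.3, 1.5, 1.8, 2.0])
        labels = np.array([0, 0, 1, 1, 1])
        roc = diagstats.roc_points(scores, labels)
        assert diagstats.closest_corner_cutoff(roc) == 1.5

    def test_degenerate_single_threshold(self):
        roc = diagstats.roc_points([1.0, 1.0, 1.0], [0, 1, 1])
        assert diagstats.closest_corner_cutoff(roc) == 1.0

    def test_matches_brute_force_distance_search(self, rng):
        for _ in range(10):
            scores = rng.normal(size=20)
            labels = rng.integers(0, 2, size=20)
            if labels.sum() in (0, 20):
                continue
            roc = diagstats.roc_points(scores, labels)
            pts = roc[np.isfinite(roc["threshold"])]
            d = np.sqrt(pts["fpr"] ** 2 + (1 - pts["tpr"]) ** 2)
            best = pts["threshold"][d == d.min()]
            assert diagstats.closest_corner_cutoff(roc) in set(best)

    def test_cutoff_performance_reproduces_roc_point(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        r = diagstats.roc_analysis(scores, labels)
        row = r.roc[r.roc["threshold"] == r.cutoff].iloc[0]
        assert r.performance["sensitivity"].value == pytest.approx(row["tpr"], abs=0)
        assert r.performance["specificity"].value == pytest.approx(
            1 - row["fpr"], abs=1e-12
        )


class TestDiagnosticPerformance:
    def test_perfect_classifier(self):
        perf = diagstats.diagnostic_performance(
            [1, 2, 8, 9], [0, 0, 1, 1], cutoff=5.0
        )
        assert all(perf[m].value == 1.0 for m in perf)

    def test_sensitivity_nine_of_eleven(self):
        # 9 of 11 positives above the cutoff -> 81.8%
        pos = np.r_[np.full(9, 2.0), np.full(2, 0.5)]
        neg = np.full(30, 0.4)
        scores = np.r_[pos, neg]
        labels = np.r_[np.ones(11), np.zeros(30)].astype(int)
        perf = diagstats.diagnostic_performance(scores, labels, cutoff=1.0)
        assert perf["sensitivity"].value == pytest.approx(9 / 11)
        assert round(perf["sensitivity"].value * 100) == 82

    def test_zero_sensitivity_boundary(self):
        perf = diagstats.diagnostic_performance(
            np.r_[np.zeros(5), np.ones(5)], np.r_[np.ones(5), np.zeros(5)], 0.5
        )
        assert perf["sensitivity"].value == 0.0
        assert perf["sensitivity"].ci[0] == 0.0

    def test_empty_margin_flagged_undefined(self):
        perf = diagstats.diagnostic_performance([0.1, 0.2, 0.3], [1, 0, 0], 5.0)
        assert not perf["ppv"].defined
        assert np.isnan(perf["ppv"].value)


class TestClopperPearson:
    def test_matches_statsmodels_beta_interval(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(0, 19), (9, 11), (17, 19), (28, 56), (56, 56)]:
            lo, hi = diagstats.clopper_pearson(k, n)
            slo, shi = proportion_confint(k, n, method="beta")
            assert lo == pytest.approx(slo, abs=1e-12)
            assert hi == pytest.approx(shi, abs=1e-12)

    def test_coverage_at_study_sample_sizes(self, rng):
        # exact intervals must cover the true proportion >= 95% of the time
        for n, p in [(19, 0.6), (56, 0.3)]:
            ks = rng.binomial(n, p, size=5000)
            lo = np.where(ks > 0, diagstats.stats.beta.ppf(0.025, ks, n - ks + 1), 0.0)
            hi = np.where(
                ks < n, diagstats.stats.beta.ppf(0.975, ks + 1, n - ks), 1.0
            )
            assert np.mean((lo <= p) & (p <= hi)) >= 0.95


class TestPairedAUC:
    def test_identical_scores_give_zero_delta_unit_p(self):
        scores = np.r_[np.random.default_rng(0).normal(size=30)]
        labels = np.r_[np.ones(10), np.zeros(20)].astype(int)
        res = diagstats.compare_auc_paired(scores, scores, labels)
        assert res.delta == 0.0
        assert res.p == 1.0

    def test_variance_matches_jackknife_oracle(self, rng):
        m, n = 8, 13
        labels = np.r_[np.ones(m), np.zeros(n)].astype(int)
        a = rng.normal(size=m + n)
        b = 0.5 * a + rng.normal(size=m + n)
        res = diagstats.compare_auc_paired(a, b, labels)

        def delta(ii):
            keep = np.setdiff1d(np.arange(m + n), [ii])
            return diagstats.auc(a[keep], labels[keep]) - diagstats.auc(
                b[keep], labels[keep]
            )

        jvar = 0.0
        for grp, size in ((1, m), (0, n)):
            loo = np.array([delta(i) for i in np.flatnonzero(labels == grp)])
            jvar += (size - 1) / size * np.sum((loo - loo.mean()) ** 2)
        assert res.var == pytest.approx(jvar, abs=1e-9)

    def test_agrees_with_r_proc_delong(self, tmp_path):
        rng = np.random.default_rng(7)
        m, n = 12, 18
        labels = np.r_[np.ones(m), np.zeros(n)].astype(int)
        shared = rng.normal(size=m + n) + 0.8 * labels
        a = shared + 0.5 * rng.normal(size=m + n)
        b = shared + 0.7 * rng.normal(size=m + n)
        res = diagstats.compare_auc_paired(a, b, labels)
        csv = tmp_path / "d.csv"
        pd.DataFrame({"y": labels, "a": a, "b": b}).to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(pROC))
            d <- read.csv("{csv}")
            ra <- roc(d$y, d$a, quiet=TRUE, direction="<")
            rb <- roc(d$y, d$b, quiet=TRUE, direction="<")
            t <- roc.test(ra, rb, method="delong", paired=TRUE)
            cat(sprintf("%.12f %.12f %.12f", auc(ra), auc(rb), t$p.value))
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        auc_a, auc_b, p = map(float, out.stdout.split())
        assert res.auc_a == pytest.approx(auc_a, abs=1e-9)
        assert res.auc_b == pytest.approx(auc_b, abs=1e-9)
        assert res.p == pytest.approx(p, abs=1e-6)

    def test_bootstrap_agrees_in_sign_and_rough_scale(self, rng):
        m, n = 15, 30
        labels = np.r_[np.ones(m), np.zeros(n)].astype(int)
        a = rng.normal(size=m + n) + 1.2 * labels
        b = rng.normal(size=m + n) + 0.3 * labels
        d = diagstats.compare_auc_paired(a, b, labels)
        bt = diagstats.compare_auc_paired(
            a, b, labels, method="bootstrap", n_boot=500, rng=rng
        )
        assert bt.delta == d.delta
        assert bt.ci[0] < d.delta < bt.ci[1]


def enumerate_fisher(table):
    """Independent two-sided Fisher p by full hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    n = a + b + c + d
    row1, col1 = a + b, a + c
    support = range(max(0, row1 + col1 - n), min(row1, col1) + 1)
    probs = {x: hypergeom.pmf(x, n, col1, row1) for x in support}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


class TestExactTests:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[2, 10], [0, 40]], 0.0498),  # ulceration contrast, low-CR subgroup
            ([[6, 2], [6, 2]], 1.0),  # equal incidence in CR subgroups
            ([[1, 0], [0, 1]], 1.0),
        ],
    )
    def test_fisher_worked_examples(self, table, expected):
        assert diagstats.fisher_exact_2x2(table) == pytest.approx(expected, abs=5e-5)

    def test_fisher_zero_margin_is_one(self):
        assert diagstats.fisher_exact_2x2([[0, 0], [3, 5]]) == 1.0

    @given(st.lists(st.integers(0, 12), min_size=4, max_size=4))
    def test_fisher_equals_hypergeometric_enumeration(self, cells):
        table = [cells[:2], cells[2:]]
        if sum(cells) == 0 or sum(cells) > 30:
            return
        assert diagstats.fisher_exact_2x2(table) == pytest.approx(
            min(enumerate_fisher(table), 1.0), abs=1e-9
        )

    def test_chi2_balanced_table(self):
        stat, p = diagstats.chi_square_2x2([[10, 10], [10, 10]])
        assert stat == 0.0
        assert p == 1.0

    def test_chi2_longhand_formula(self):
        a, b, c, d = 16, 3, 31, 25
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        stat, _ = diagstats.chi_square_2x2([[a, b], [c, d]])
        assert stat == pytest.approx(expected, rel=1e-12)

    def test_chi2_doubling_cells_doubles_statistic(self):
        t = np.array([[16, 3], [31, 25]])
        s1, _ = diagstats.chi_square_2x2(t)
        s2, _ = diagstats.chi_square_2x2(2 * t)
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    def test_chi2_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            diagstats.chi_square_2x2([[0, 0], [3, 5]])


class TestMannWhitney:
    def test_identical_samples_p_near_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        _, p = diagstats.mann_whitney_u(x, x)
        assert p > 0.9

    def test_fully_separated_u_zero(self):
        u, p = diagstats.mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p < 0.2

    def test_u_matches_pair_counting(self):
        x, y = [1, 2, 3], [2, 3, 4]
        u = sum(
            1.0 if xi > yi else (0.5 if xi == yi else 0.0) for xi in x for yi in y
        )
        assert diagstats.mann_whitney_u(x, y)[0] == u


class TestUnivariateScreen:
    def test_covariate_identical_to_label_included(self):
        df = pd.DataFrame({"mes": [0] * 20 + [1] * 10})
        df["mirror"] = df["mes"]
        out = diagstats.univariate_screen(df, ["mirror"])
        assert bool(out.loc[0, "included"])

    def test_constant_covariate_skipped_with_warning(self):
        df = pd.DataFrame({"mes": [0, 1, 0, 1], "flat": [3.0] * 4})
        with pytest.warns(UserWarning, match="constant"):
            out = diagstats.univariate_screen(df, ["flat"])
        assert out.empty

    def test_null_continuous_covariate_excluded_about_80pct(self, rng):
        # under independence, p < 0.2 occurs with probability ~ alpha = 0.2
        labels = np.r_[np.ones(40), np.zeros(60)].astype(int)
        excluded = 0
        reps = 800
        for _ in range(reps):
            df = pd.DataFrame({"mes": labels, "x": rng.normal(size=100)})
            out = diagstats.univariate_screen(df, ["x"])
            excluded += not bool(out.loc[0, "included"])
        assert 0.72 < excluded / reps < 0.88

    def test_table_calibrated_cohort_flags_symptomatic_and_ulceration(self, rng):
        from plaquecr import synth

        labels = np.r_[np.ones(190), np.zeros(560)].astype(int)
        cov = synth.simulate_covariates(synth.DEFAULT_COVARIATES, labels, seed=rng)
        cov["mes"] = labels
        out = diagstats.univariate_screen(
            cov, list(synth.DEFAULT_COVARIATES)
        ).set_index("covariate")
        assert bool(out.loc["symptomatic_lesion", "included"])
        assert bool(out.loc["ulceration", "included"])


class TestLogistic:
    def test_single_binary_covariate_or_equals_cross_product(self):
        a, b, c, d = 9, 10, 8, 29  # exposed/unexposed x outcome
        x = np.r_[np.ones(a + c), np.zeros(b + d)]
        y = np.r_[np.ones(a), np.zeros(c), np.ones(b), np.zeros(d)]
        fit = diagstats.logistic_fit(pd.DataFrame({"x": x}), y)
        assert fit.loc["x", "odds_ratio"] == pytest.approx(a * d / (b * c), rel=1e-6)

    def test_intercept_only_balanced_or_one(self):
        y = np.r_[np.ones(25), np.zeros(25)]
        fit = diagstats.logistic_fit(pd.DataFrame(index=range(50)), y)
        assert fit.loc["const", "odds_ratio"] == pytest.approx(1.0, abs=1e-8)

    def test_parameter_recovery_within_three_se(self, rng):
        n = 2000
        beta = np.array([-1.0, 1.0, 0.5])
        x1 = rng.normal(size=n)
        x2 = rng.integers(0, 2, size=n).astype(float)
        eta = beta[0] + beta[1] * x1 + beta[2] * x2
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        fit = diagstats.logistic_fit(pd.DataFrame({"x1": x1, "x2": x2}), y)
        se = np.log(fit["or_ci_high"] / fit["odds_ratio"]) / 1.959964
        for name, true in zip(["const", "x1", "x2"], beta):
            assert abs(fit.loc[name, "coef"] - true) < 3 * se[name]

    def test_complete_separation_flagged(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = x.copy()
        with pytest.raises(diagstats.SeparationError):
            diagstats.logistic_fit(pd.DataFrame({"x": x}), y)

    def test_rank_deficient_design_rejected(self):
        x = np.arange(20, dtype=float)
        y = (x > 10).astype(int) ^ (x % 3 == 0).astype(int)
        with pytest.raises(ValueError):
            diagstats.logistic_fit(pd.DataFrame({"x": x, "x2": 2 * x}), y)


class TestHistoricalComparison:
    def test_disjoint_cis_significant(self):
        assert (
            diagstats.compare_to_historical((0.95, (0.85, 0.99)), (0.49, (0.36, 0.63)))
            == "significant"
        )

    def test_identical_cis_ns(self):
        assert diagstats.compare_to_historical((0.9, (0.8, 1.0)), (0.9, (0.8, 1.0))) == "NS"

    def test_touching_cis_ns(self):
        assert diagstats.compare_to_historical((15, (10, 20)), (25, (20, 30))) == "NS"

    def test_malformed_ci_rejected(self):
        with pytest.raises(ValueError):
            diagstats.compare_to_historical((0.5, (0.6, 0.4)), (0.5, (0.4, 0.6)))
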