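"""Diagnostic statistics for contrast-ratio scores against a binary outcome.

The outcome label is the intraoperative detection of microembolic signals
(MES) on transcranial Doppler; the scores are plaque contrast ratios.  The
layer provides:

* rank-based (Mann-Whitney) AUC with a DeLong variance and Wald CI;
* empirical ROC operating points with the cutoff closest to the upper-left
  corner, positivity defined as score >= cutoff;
* sensitivity / specificity / PPV / NPV with Clopper-Pearson exact CIs;
* paired AUC comparison by the structural-components (DeLong) procedure,
  with a paired-bootstrap alternative;
* exact and chi-square 2x2 tests, the Mann-Whitney U test;
* univariate screening at p < 0.2 feeding a multivariate logistic model.

All p-values are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

__all__ = [
    "Metric",
    "ROCAnalysis",
    "PairedAUCResult",
    "SeparationError",
    "auc",
    "roc_points",
    "roc_analysis",
    "closest_corner_cutoff",
    "clopper_pearson",
    "diagnostic_performance",
    "compare_auc_paired",
    "fisher_exact_2x2",
    "chi_square_2x2",
    "mann_whitney_u",
    "univariate_screen",
    "logistic_fit",
    "compare_to_historical",
]


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation in the logistic model."""


def _split(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    uniq = set(np.unique(labels).tolist())
    if not uniq <= {0, 1, False, True}:
        raise ValueError("labels must be binary (0/1)")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both outcome classes must be present")
    return pos, neg


def _placements(pos: np.ndarray, neg: np.ndarray):
    """Mid-rank placement values V10 (per positive), V01 (per negative).

    V10_i = fraction of negatives a positive outranks (ties count 1/2);
    the AUC is the mean of either vector.
    """
    m, n = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    r_all = stats.rankdata(combined)
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return v10, v01


def auc(scores, labels) -> float:
    """Rank-based AUC: P(score_pos > score_neg) + 0.5 P(tie).

    Identical to the trapezoidal area under the empirical ROC curve.
    """
    pos, neg = _split(scores, labels)
    v10, _ = _placements(pos, neg)
    return float(np.mean(v10))


def _delong_variance(v10s, v01s) -> np.ndarray:
    """Covariance matrix of a vector of correlated AUCs (structural components)."""
    m = v10s.shape[1]
    n = v01s.shape[1]
    s10 = np.atleast_2d(np.cov(v10s, ddof=1)) if m > 1 else np.zeros((len(v10s),) * 2)
    s01 = np.atleast_2d(np.cov(v01s, ddof=1)) if n > 1 else np.zeros((len(v01s),) * 2)
    return s10 / m + s01 / n


def auc_variance(scores, labels) -> float:
    """DeLong variance of a single AUC estimate."""
    pos, neg = _split(scores, labels)
    v10, v01 = _placements(pos, neg)
    return float(
        _delong_variance(v10[None, :], v01[None, :])[0, 0]
    )


def roc_points(scores, labels) -> pd.DataFrame:
    """Empirical ROC operating points at every observed threshold.

    Positivity is score >= threshold; thresholds are the sorted unique
    observed scores (descending), so TPR and FPR are non-increasing in the
    threshold.  A leading +inf row anchors the (0, 0) corner.
    """
    pos, neg = _split(scores, labels)
    thresholds = np.concatenate([[np.inf], np.unique(np.concatenate([pos, neg]))[::-1]])
    tpr = (pos[None, :] >= thresholds[:, None]).mean(axis=1)
    fpr = (neg[None, :] >= thresholds[:, None]).mean(axis=1)
    return pd.DataFrame({"threshold": thresholds, "tpr": tpr, "fpr": fpr})


def closest_corner_cutoff(roc: pd.DataFrame) -> float:
    """Observed threshold minimizing the distance to the ROC upper-left corner.

    Distance is sqrt(FPR^2 + (1 - TPR)^2) over finite observed thresholds.
    Ties break toward higher specificity (lower FPR), then higher threshold.
    """
    pts = roc[np.isfinite(roc["threshold"])]
    d = np.hypot(pts["fpr"].to_numpy(), 1.0 - pts["tpr"].to_numpy())
    best = d.min()
    cand = pts[d <= best + 1e-12]
    cand = cand[cand["fpr"] <= cand["fpr"].min() + 1e-12]
    return float(cand["threshold"].max())


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for k/n."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError("need 0 <= k <= n, n > 0")
    alpha = 1.0 - level
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


@dataclass
class Metric:
    """A proportion with its exact CI; ``defined`` is False on an empty margin."""

    value: float
    ci: tuple[float, float]
    k: int
    n: int
    defined: bool = True

    @staticmethod
    def from_counts(k: int, n: int) -> "Metric":
        if n == 0:
            return Metric(np.nan, (np.nan, np.nan), 0, 0, defined=False)
        return Metric(k / n, clopper_pearson(k, n), k, n)


def diagnostic_performance(scores, labels, cutoff: float) -> dict[str, Metric]:
    """Sensitivity, specificity, PPV, NPV at ``cutoff`` (positive = score >= cutoff).

    Metrics with an empty margin (e.g. PPV with no test-positives) are
    returned flagged undefined rather than as 0.
    """
    pos, neg = _split(scores, labels)
    tp = int(np.sum(pos >= cutoff))
    fn = len(pos) - tp
    fp = int(np.sum(neg >= cutoff))
    tn = len(neg) - fp
    return {
        "sensitivity": Metric.from_counts(tp, tp + fn),
        "specificity": Metric.from_counts(tn, tn + fp),
        "ppv": Metric.from_counts(tp, tp + fp),
        "npv": Metric.from_counts(tn, tn + fn),
    }


@dataclass
class ROCAnalysis:
    """Full ROC summary for one score: curve, AUC with CI, cutoff, performance."""

    roc: pd.DataFrame
    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    performance: dict[str, Metric]
    n_pos: int
    n_neg: int


def roc_analysis(scores, labels, level: float = 0.95) -> ROCAnalysis:
    """Compute the ROC curve, DeLong-Wald AUC CI, closest-corner cutoff and
    the diagnostic performance at that cutoff."""
    pos, neg = _split(scores, labels)
    curve = roc_points(scores, labels)
    a = auc(scores, labels)
    se = np.sqrt(max(auc_variance(scores, labels), 0.0))
    zq = stats.norm.ppf(0.5 + level / 2)
    ci = (max(a - zq * se, 0.0), min(a + zq * se, 1.0))
    cutoff = closest_corner_cutoff(curve)
    perf = diagnostic_performance(scores, labels, cutoff)
    return ROCAnalysis(curve, a, ci, cutoff, perf, len(pos), len(neg))


@dataclass
class PairedAUCResult:
    auc_a: float
    auc_b: float
    delta: float
    var: float
    ci: tuple[float, float]
    p: float
    method: str = "delong"


def compare_auc_paired(
    scores_a,
    scores_b,
    labels,
    method: str = "delong",
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
    level: float = 0.95,
) -> PairedAUCResult:
    """Compare two AUCs measured on the same patients.

    ``method="delong"``: structural-components variance of the paired AUC
    difference with a normal reference (two-sided).  ``method="bootstrap"``:
    percentile CI and p from paired resampling of patients.  When both scores
    are identical the difference is exactly 0 and p = 1.
    """
    labels = np.asarray(labels)
    pos_a, neg_a = _split(scores_a, labels)
    pos_b, neg_b = _split(scores_b, labels)
    v10 = np.vstack([_placements(pos_a, neg_a)[0], _placements(pos_b, neg_b)[0]])
    v01 = np.vstack([_placements(pos_a, neg_a)[1], _placements(pos_b, neg_b)[1]])
    auc_a = float(v10[0].mean())
    auc_b = float(v10[1].mean())
    delta = auc_a - auc_b
    cov = _delong_variance(v10, v01)
    var = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])

    zq = stats.norm.ppf(0.5 + level / 2)
    if method == "delong":
        if var <= 0:
            p = 1.0 if abs(delta) < 1e-12 else 0.0
            ci = (delta, delta)
        else:
            z = delta / np.sqrt(var)
            p = float(2 * stats.norm.sf(abs(z)))
            ci = (delta - zq * np.sqrt(var), delta + zq * np.sqrt(var))
    elif method == "bootstrap":
        rng = np.random.default_rng(rng)
        sa = np.asarray(scores_a, dtype=float)
        sb = np.asarray(scores_b, dtype=float)
        ip = np.flatnonzero(labels == 1)
        ineg = np.flatnonzero(labels == 0)
        deltas = np.empty(n_boot)
        for b in range(n_boot):
            # stratified paired resample keeps both classes present
            take = np.concatenate(
                [rng.choice(ip, len(ip)), rng.choice(ineg, len(ineg))]
            )
            lb = labels[take]
            deltas[b] = auc(sa[take], lb) - auc(sb[take], lb)
        alpha = 1.0 - level
        ci = (
            float(np.quantile(deltas, alpha / 2)),
            float(np.quantile(deltas, 1 - alpha / 2)),
        )
        # symmetric tail p against the null of zero difference
        frac = np.mean(deltas <= 0) if delta > 0 else np.mean(deltas >= 0)
        p = float(min(1.0, 2 * frac)) if abs(delta) > 1e-12 else 1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    return PairedAUCResult(auc_a, auc_b, delta, var, ci, p, method)


def _as_2x2(table) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.rint(t)):
            raise ValueError("cells must be non-negative integers")
        t = t.astype(int)
    return t


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of all
    tables with the observed margins whose probability <= the observed one.

    A zero margin makes the table the only one in its support, so p = 1.
    """
    t = _as_2x2(table)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def chi_square_2x2(table, continuity: bool = False) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table (optional Yates correction), df = 1."""
    t = _as_2x2(table)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square undefined for a table with a zero margin")
    res = stats.chi2_contingency(t, correction=continuity)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U (of x, mid-rank ties) with a two-sided p.

    Exact enumeration when n_x * n_y <= 400 and the pooled sample is
    tie-free; otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) * len(y) <= 400 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    # U for x: number of (x, y) pairs with x > y, ties counted 1/2
    return float(res.statistic), float(min(res.pvalue, 1.0))


def univariate_screen(
    cohort: pd.DataFrame,
    covariates: list[str],
    label_col: str = "mes",
    alpha: float = 0.2,
    binary_test: str = "fisher",
) -> pd.DataFrame:
    """Per-covariate univariate test against the outcome label.

    Binary covariates (two distinct values) get Fisher's exact test by
    default (``binary_test="chi2"`` switches to Pearson chi-square);
    continuous covariates get the Mann-Whitney U test.  Returns one row per
    covariate with the test used, p-value, and the p < alpha inclusion flag;
    constant covariates are skipped with a warning.
    """
    y = np.asarray(cohort[label_col]).astype(int)
    rows = []
    for name in covariates:
        x = np.asarray(cohort[name], dtype=float)
        values = np.unique(x)
        if len(values) < 2:
            warnings.warn(f"covariate {name!r} is constant; skipped", stacklevel=2)
            continue
        if len(values) == 2:
            table = np.array(
                [
                    [np.sum((x == values[1]) & (y == 1)), np.sum((x == values[0]) & (y == 1))],
                    [np.sum((x == values[1]) & (y == 0)), np.sum((x == values[0]) & (y == 0))],
                ]
            )
            if binary_test == "fisher":
                p = fisher_exact_2x2(table)
                test = "fisher"
            else:
                p = chi_square_2x2(table)[1]
                test = "chi2"
        else:
            p = mann_whitney_u(x[y == 1], x[y == 0])[1]
            test = "mann-whitney"
        rows.append({"covariate": name, "test": test, "p": p, "included": p < alpha})
    return pd.DataFrame(rows, columns=["covariate", "test", "p", "included"])


def logistic_fit(
    X: pd.DataFrame,
    y,
    add_intercept: bool = True,
    level: float = 0.95,
) -> pd.DataFrame:
    """Maximum-likelihood logistic fit; odds ratios with Wald CIs.

    Converges by Newton iterations to a relative log-likelihood change below
    1e-10.  Complete or quasi-complete separation is detected and raised as
    :class:`SeparationError` — no estimates are returned in that case.
    """
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y).astype(int)
    design = sm.add_constant(X, has_constant="add") if add_intercept else X
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    with warnings.catch_warnings():
        for cat in (RuntimeWarning, PerfectSeparationWarning, ConvergenceWarning):
            warnings.simplefilter("error", category=cat)
        try:
            fit = sm.Logit(y, design).fit(
                method="newton", tol=1e-10, maxiter=200, disp=0
            )
        except (
            PerfectSeparationError,
            PerfectSeparationWarning,
            ConvergenceWarning,
            RuntimeWarning,
            np.linalg.LinAlgError,
        ) as exc:
            raise SeparationError(str(exc)) from exc
    if not fit.mle_retvals.get("converged", True) or np.any(
        np.abs(fit.params.to_numpy()) > 30
    ):
        raise SeparationError("quasi-complete separation: diverging coefficients")
    zq = stats.norm.ppf(0.5 + level / 2)
    params = fit.params
    se = fit.bse
    out = pd.DataFrame(
        {
            "coef": params,
            "odds_ratio": np.exp(params),
            "or_ci_low": np.exp(params - zq * se),
            "or_ci_high": np.exp(params + zq * se),
            "p": fit.pvalues,
        }
    )
    out.index.name = "variable"
    return out


def compare_to_historical(
    metric: tuple[float, tuple[float, float]],
    historical: tuple[float, tuple[float, float]],
) -> str:
    """CI-overlap verdict between a cohort metric and a historical-control one.

    Returns ``"significant"`` only when the two 95% CIs are strictly
    disjoint; CIs that touch at a point overlap and give ``"NS"``.
    """
    for _, (lo, hi) in (metric, historical):
        if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
            raise ValueError("malformed confidence interval")
    (_, (lo_a, hi_a)), (_, (lo_b, hi_b)) = metric, historical
    return "significant" if (hi_a < lo_b or hi_b < lo_a) else "NS"
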