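"""Univariate screening, collinearity filtering, multivariable logistic
regression and ROC evaluation for a cohort table.

The screening stage mirrors conventional clinical-paper practice: pooled
two-sample t-tests for continuous variables, Pearson chi-square (without
continuity correction) for binary ones, switching to Fisher's exact test
when any expected cell count falls below 5; variables with p < 0.1 advance.
Collinear pairs (|Pearson r| > 0.9) are collapsed before the multivariable
binary logistic model, which reports odds ratios with Wald 95% CIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "UnivariateResult",
    "AssociationResult",
    "RocResult",
    "univariate_screen",
    "collinearity_filter",
    "fit_logistic",
    "roc_evaluate",
]


@dataclass(frozen=True)
class UnivariateResult:
    variable: str
    test: str  # "t-test" | "chi-square" | "fisher"
    group_summary: dict = field(compare=False)
    p_value: float = 1.0
    flagged: bool = False  # p below the screening threshold

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value out of [0, 1]")


@dataclass(frozen=True)
class AssociationResult:
    variable: str
    coefficient: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    converged: bool = True


@dataclass(frozen=True)
class RocResult:
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float


def _is_binary(x: pd.Series) -> bool:
    vals = set(pd.unique(x.dropna()))
    return vals <= {0, 1, 0.0, 1.0, True, False}


def univariate_screen(
    cohort: pd.DataFrame,
    outcome: str = "iss",
    variables: Optional[Sequence[str]] = None,
    screen_p: float = 0.1,
) -> list[UnivariateResult]:
    """Per-variable two-group tests against a binary outcome.

    Continuous variables get a two-sided pooled-variance t-test; binary
    variables a Pearson chi-square without continuity correction, replaced
    by Fisher's exact test if any expected cell count is below 5.
    """
    if outcome not in cohort.columns:
        raise ValueError(f"outcome column {outcome!r} missing")
    y = cohort[outcome].to_numpy()
    if variables is None:
        variables = [c for c in cohort.columns if c not in ("iss", "co")]
    results = []
    for var in variables:
        x = cohort[var]
        g0, g1 = x[y == 0], x[y == 1]
        if x.nunique() <= 1:
            warnings.warn(f"{var} is constant; p set to 1", RuntimeWarning)
            results.append(UnivariateResult(var, "t-test", {}, 1.0, False))
            continue
        if _is_binary(x):
            table = np.array(
                [
                    [(g0 == 0).sum(), (g0 == 1).sum()],
                    [(g1 == 0).sum(), (g1 == 1).sum()],
                ],
                dtype=float,
            )
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            summary = {
                "n0": int(len(g0)),
                "n1": int(len(g1)),
                "count0": int((g0 == 1).sum()),
                "count1": int((g1 == 1).sum()),
            }
            if (expected < 5).any():
                _, p = stats.fisher_exact(table, alternative="two-sided")
                test = "fisher"
            else:
                chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
                test = "chi-square"
        else:
            t, p = stats.ttest_ind(g1, g0, equal_var=True)
            if np.isnan(p):
                p = 1.0
            test = "t-test"
            summary = {
                "mean0": float(g0.mean()),
                "sd0": float(g0.std(ddof=1)),
                "mean1": float(g1.mean()),
                "sd1": float(g1.std(ddof=1)),
            }
        results.append(UnivariateResult(var, test, summary, float(p), p < screen_p))
    return results


def collinearity_filter(
    cohort: pd.DataFrame,
    candidates: Sequence[str],
    outcome: str = "iss",
    threshold: float = 0.9,
    p_values: Optional[dict] = None,
) -> list[str]:
    """Drop one variable of each highly correlated pair (|r| > threshold).

    The member with the smaller univariate p-value is kept; ties keep the
    earlier candidate.  Pairs are visited in candidate order, so the result
    is deterministic.
    """
    if len(candidates) < 2:
        return list(candidates)
    if p_values is None:
        p_values = {
            r.variable: r.p_value
            for r in univariate_screen(cohort, outcome, variables=candidates)
        }
    dropped: set[str] = set()
    cand = list(candidates)
    corr = cohort[cand].corr().to_numpy()
    for i in range(len(cand)):
        if cand[i] in dropped:
            continue
        for j in range(i + 1, len(cand)):
            if cand[j] in dropped:
                continue
            if abs(corr[i, j]) > threshold:
                pi = p_values.get(cand[i], 1.0)
                pj = p_values.get(cand[j], 1.0)
                dropped.add(cand[j] if pj >= pi else cand[i])
                if cand[i] in dropped:
                    break
    return [c for c in cand if c not in dropped]


def _separating_variable(X: pd.DataFrame, y: np.ndarray) -> Optional[str]:
    """Name a single variable that completely separates the outcome."""
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        lo1, hi1 = x[y == 1].min(), x[y == 1].max()
        lo0, hi0 = x[y == 0].min(), x[y == 0].max()
        if hi0 <= lo1 or hi1 <= lo0:
            if hi0 < lo1 or hi1 < lo0 or _is_binary(X[col]):
                return col
    return None


def fit_logistic(
    cohort: pd.DataFrame,
    retained: Sequence[str],
    outcome: str = "iss",
) -> list[AssociationResult]:
    """Maximum-likelihood binary logistic regression with Wald 95% CIs.

    Raises on perfect separation, naming the separating variable when one
    variable alone accounts for it.
    """
    y = cohort[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    X = cohort[list(retained)].astype(float)
    if len(cohort) <= 5 * len(retained):
        warnings.warn(
            f"n = {len(cohort)} is small for {len(retained)} predictors",
            RuntimeWarning,
        )
    design = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except (sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning) as err:
        culprit = _separating_variable(X, y.astype(int))
        raise ValueError(
            f"perfect separation detected"
            + (f" (separating variable: {culprit})" if culprit else "")
        ) from err
    converged = bool(fit.mle_retvals.get("converged", True))
    ci = fit.conf_int(alpha=0.05)
    out = []
    for var in retained:
        beta = float(fit.params[var])
        out.append(
            AssociationResult(
                variable=var,
                coefficient=beta,
                odds_ratio=float(np.exp(beta)),
                ci_low=float(np.exp(ci.loc[var, 0])),
                ci_high=float(np.exp(ci.loc[var, 1])),
                p_value=float(fit.pvalues[var]),
                converged=converged,
            )
        )
    return out


def roc_evaluate(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """AUC (trapezoid over all thresholds, midrank ties) and the Youden-J
    optimal cutoff with its sensitivity/specificity."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("labels must contain both classes")
    n1, n0 = (labels == 1).sum(), (labels == 0).sum()
    # Mann-Whitney with midranks, identical to the trapezoidal ROC area
    ranks = stats.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    fpr, tpr, thresholds = roc_curve(labels, scores)
    j = tpr - fpr
    k = int(np.argmax(j))
    return RocResult(
        auc=float(auc),
        cutoff=float(thresholds[k]),
        sensitivity=float(tpr[k]),
        specificity=float(1.0 - fpr[k]),
    )
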