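"""Univariate group comparison of every analyzed parameter.

For each parameter the test is routed by distributional gates: Student's
t-test is used only when Shapiro-Wilk does not reject normality in either
group (p > 0.1 in both) and Levene's test does not declare the variances
unequal (p >= 0.05); otherwise the two-sided Wilcoxon rank-sum
(Mann-Whitney) test is used.  Raw two-sided p-values are reported and ranked
as -log10(p) against the 5% line; an optional Benjamini-Hochberg adjustment
is available but off by default, matching the raw-threshold convention of
the screening figure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .synth import GROUP_HEALTHY, GROUP_MDS, cohort_parameters

TEST_STUDENT = "student"
TEST_WILCOXON = "wilcoxon"

SHAPIRO_P = 0.1
LEVENE_P = 0.05


class RoutingError(ValueError):
    """Raised when a sample is too small for test routing."""


@dataclass(frozen=True)
class ScreeningResult:
    parameter_name: str
    test_used: str
    p_value: float
    neg_log10_p: float
    mds_mean: float
    healthy_mean: float
    direction: int
    degenerate: bool = False


def route_test(group_a: np.ndarray, group_b: np.ndarray) -> str:
    """Choose Student vs Wilcoxon from the normality/homoscedasticity gates."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise RoutingError("each group needs at least 3 values for routing")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return TEST_WILCOXON  # Shapiro is undefined on a constant sample
    if stats.shapiro(a).pvalue <= SHAPIRO_P:
        return TEST_WILCOXON
    if stats.shapiro(b).pvalue <= SHAPIRO_P:
        return TEST_WILCOXON
    if stats.levene(a, b).pvalue < LEVENE_P:
        return TEST_WILCOXON
    return TEST_STUDENT


def _compare(a: np.ndarray, b: np.ndarray) -> tuple[str, float, bool]:
    """Return (test, two-sided p, degenerate) for one parameter."""
    if np.ptp(np.concatenate([a, b])) == 0:
        return TEST_WILCOXON, 1.0, True
    test = route_test(a, b)
    if test == TEST_STUDENT:
        p = stats.ttest_ind(a, b).pvalue
    else:
        method = "exact" if min(a.size, b.size) <= 25 else "asymptotic"
        p = stats.mannwhitneyu(a, b, alternative="two-sided",
                               method=method).pvalue
    return test, float(p), False


class UnivariateScreener(BaseEstimator):
    """Screen every parameter for a group difference.

    Parameters
    ----------
    adjust : bool, default False
        Apply Benjamini-Hochberg across parameters (adds ``p_adjusted``).

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per parameter: test used, p-value, -log10 p, group means,
        direction of the MDS shift, degeneracy marker.
    """

    def __init__(self, adjust: bool = False):
        self.adjust = adjust

    def fit(self, X: pd.DataFrame, y) -> "UnivariateScreener":
        y = np.asarray(y)
        mds_mask = y == GROUP_MDS
        healthy_mask = y == GROUP_HEALTHY
        if not mds_mask.any() or not healthy_mask.any():
            raise ValueError("both groups must be present")
        rows = []
        for name in X.columns:
            col = X[name].to_numpy(dtype=float)
            a, b = col[mds_mask], col[healthy_mask]
            test, p, degenerate = _compare(a, b)
            p = min(max(p, np.finfo(float).tiny), 1.0)
            rows.append(ScreeningResult(
                parameter_name=name, test_used=test, p_value=p,
                neg_log10_p=-np.log10(p), mds_mean=float(a.mean()),
                healthy_mean=float(b.mean()),
                direction=int(np.sign(a.mean() - b.mean())),
                degenerate=degenerate,
            ))
        frame = pd.DataFrame([r.__dict__ for r in rows])
        if self.adjust:
            frame["p_adjusted"] = _benjamini_hochberg(
                frame["p_value"].to_numpy())
        self.results_ = frame
        return self

    def top_k(self, k: int = 12) -> list[str]:
        return top_k_by_p(self.results_, k)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def screen_all(cohort: pd.DataFrame,
               parameters: list[str] | None = None,
               adjust: bool = False) -> pd.DataFrame:
    """Screen ``parameters`` (default: all parameter columns) of a labelled
    cohort table; returns the results frame."""
    parameters = parameters or cohort_parameters(cohort)
    screener = UnivariateScreener(adjust=adjust)
    screener.fit(cohort[parameters], cohort["group"])
    return screener.results_


def top_k_by_p(results: pd.DataFrame, k: int = 12) -> list[str]:
    """Names of the ``k`` smallest p-values; ties broken lexicographically."""
    if len(results) == 0:
        raise ValueError("no screening results")
    if k > len(results):
        raise ValueError(f"k={k} exceeds {len(results)} results")
    ordered = results.sort_values(
        ["p_value", "parameter_name"], kind="mergesort")
    return ordered["parameter_name"].head(k).tolist()
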