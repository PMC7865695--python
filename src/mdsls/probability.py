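"""Score-to-probability mapping.

A three-parameter logistic form

    P(MDS | score = x) = a / (1 + exp((b - x) / c)),   c < 0, 0 < a <= 1,

is fitted to the empirical conditional probability of MDS among subjects
with scores at or below each observed score,
P(MDS | score <= s) = #{MDS, score <= s} / #{score <= s}, evaluated on the
grid of observed scores.  The plateau ``a`` is the limiting probability at
very negative scores, ``b`` the midpoint (probability a/2) and ``c`` the
(negative) slope scale in score units: probability decreases as the score
rises.

The constants published for the original clinical cohort
(a = 0.957, b = -13.11, c = -15) ship as :data:`PUBLISHED_CURVE`, so new
records can be mapped to probabilities without refitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .synth import GROUP_MDS

_EXP_CLIP = 700.0  # saturate the exponent instead of overflowing


@dataclass(frozen=True)
class ProbabilityCurve:
    """Constants of the logistic score-to-probability form."""

    plateau_a: float
    midpoint_b: float
    slope_c: float

    def __post_init__(self) -> None:
        if not 0 < self.plateau_a <= 1:
            raise ValueError("plateau_a must be in (0, 1]")
        if self.slope_c >= 0:
            raise ValueError("slope_c must be negative")

    def __call__(self, score) -> np.ndarray | float:
        return predict_probability(score, self)

    def to_document(self) -> dict:
        return {"plateau_a": self.plateau_a, "midpoint_b": self.midpoint_b,
                "slope_c": self.slope_c}

    @classmethod
    def from_document(cls, doc: dict) -> "ProbabilityCurve":
        return cls(doc["plateau_a"], doc["midpoint_b"], doc["slope_c"])


#: Curve constants published for the original 189-subject clinical cohort.
PUBLISHED_CURVE = ProbabilityCurve(plateau_a=0.957, midpoint_b=-13.11,
                                   slope_c=-15.0)


def predict_probability(score, curve: ProbabilityCurve = PUBLISHED_CURVE):
    """Probability of MDS at the given score(s)."""
    x = np.asarray(score, dtype=float)
    z = np.clip((curve.midpoint_b - x) / curve.slope_c, -_EXP_CLIP, _EXP_CLIP)
    prob = curve.plateau_a / (1.0 + np.exp(z))
    return float(prob) if np.isscalar(score) else prob


def _empirical_target(scores: np.ndarray,
                      labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """P(MDS | score <= s) on the sorted grid of observed scores."""
    order = np.argsort(scores, kind="mergesort")
    sorted_scores = scores[order]
    is_mds = (labels[order] == GROUP_MDS).astype(float)
    cum_mds = np.cumsum(is_mds)
    cum_n = np.arange(1, scores.size + 1)
    prob = cum_mds / cum_n
    # collapse tied scores to the last (complete) count at each value
    keep = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    return sorted_scores[keep], prob[keep]


class ScoreProbabilityCurve(BaseEstimator):
    """Least-squares fit of the logistic probability curve.

    Attributes
    ----------
    curve_ : ProbabilityCurve
    grid_ : ndarray
        Score grid the empirical target was evaluated on.
    target_ : ndarray
        Empirical P(MDS | score <= s) at each grid point.
    """

    def fit(self, scores, labels) -> "ScoreProbabilityCurve":
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels)
        if not np.isfinite(scores).all():
            raise ValueError("scores must be finite")
        if (labels == GROUP_MDS).all() or not (labels == GROUP_MDS).any():
            raise ValueError("both groups must be present")
        grid, target = _empirical_target(scores, labels)
        if grid.size < 3:
            raise ValueError("degenerate score grid: too few distinct scores")
        self.curve_ = _fit_curve(grid, target)
        self.grid_ = grid
        self.target_ = target
        return self

    def predict(self, scores):
        return predict_probability(scores, self.curve_)


def _fit_curve(grid: np.ndarray, target: np.ndarray) -> ProbabilityCurve:
    # deterministic starting point: plateau at max observed probability,
    # midpoint where the target first falls below half-max, slope -IQR/2
    a0 = min(max(target.max(), 1e-3), 1.0)
    below = np.flatnonzero(target <= a0 / 2)
    b0 = grid[below[-1]] if below.size else float(np.median(grid))
    iqr = float(np.subtract(*np.percentile(grid, [75, 25])))
    c0 = -max(iqr / 2, 1e-6)

    def residual(theta):
        a, b, c = theta
        z = np.clip((b - grid) / c, -_EXP_CLIP, _EXP_CLIP)
        return a / (1.0 + np.exp(z)) - target

    fit = least_squares(
        residual, x0=[a0, b0, c0],
        bounds=([1e-9, -np.inf, -np.inf], [1.0, np.inf, -1e-9]),
        method="trf",
    )
    a, b, c = fit.x
    return ProbabilityCurve(plateau_a=float(a), midpoint_b=float(b),
                            slope_c=float(c))


def fit_probability_curve(scores, labels) -> ProbabilityCurve:
    """Fit the logistic curve to per-subject scores and group labels."""
    return ScoreProbabilityCurve().fit(scores, labels).curve_


def inverse_sample_scores(curve: ProbabilityCurve, low: float = -150.0,
                          high: float = 17.0, max_step: float = 1.0,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Construct (scores, labels) whose empirical cumulative-MDS ratio
    tracks ``curve``; used for parameter-recovery checks.

    The cumulative MDS count among the first k sorted scores is a
    non-decreasing integer with 0/1 increments, which is only achievable
    when ``k * y(s_k)`` never decreases.  The grid is therefore built
    adaptively: each step is capped at ``0.9 / (k * r(s))`` where
    ``r = -d(log y)/ds`` is the curve's local decay rate, and labels are
    the rounded increments of ``k * y(s_k)``.
    """
    inv_c = 1.0 / abs(curve.slope_c)
    grid = [low]
    s = low
    while s < high:
        z = np.clip((curve.midpoint_b - s) / curve.slope_c,
                    -_EXP_CLIP, _EXP_CLIP)
        rate = inv_c / (1.0 + np.exp(-z))  # -d(log y)/ds at s
        step = max_step if rate <= 0 else min(max_step,
                                              0.9 / (len(grid) * rate))
        s += step
        grid.append(s)
    grid = np.asarray(grid)
    y = predict_probability(grid, curve)
    cum = np.round(np.arange(1, grid.size + 1) * y).astype(int)
    cum = np.maximum.accumulate(cum)
    increments = np.clip(np.diff(np.r_[0, cum]), 0, 1)
    labels = np.where(increments > 0, GROUP_MDS, "HEALTHY")
    return grid, labels
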