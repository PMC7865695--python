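"""Split-sample construction of the MDS-likelihood score (MDS-LS).

The score is a linear combination of the ten critical research parameters,

    MDS-LS = sum_i C_i * P_i + intercept,

whose weights are aggregated over a split-sample cross-validation: at each
iteration the cohort (189 subjects at the defaults) is split at random into a
learning set of 130 and a testing set of 59; a binomial logistic regression
of group on the raw parameter values is fitted on the learning set with the
healthy group coded 1, and its test-set efficiency (fraction of test
subjects correctly classified under the score<0 => MDS rule) is recorded.
After 10,000 iterations each C_i — and the intercept — is the median of its
per-iteration draws.  A subject with a negative score is classified MDS and
would trigger a blood smear review.

Per-iteration fits carry a vanishingly small ridge penalty on the slopes
(none on the intercept) so that quasi-separated learning splits, common when
the groups are well separated, yield finite coefficients; the median across
iterations further tames any remaining outliers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression

from .synth import GROUP_HEALTHY, GROUP_MDS

DEFAULT_ITERATIONS = 10_000
DEFAULT_LEARN_SIZE = 130
#: learning fraction 130/189, reused for non-default cohort sizes
LEARN_FRACTION = 130 / 189
_RIDGE_C = 1e6  # L2 strength 1e-6 on slopes; sklearn leaves intercept free


@dataclass
class ScoreResult:
    subject_id: str
    mds_ls: float
    predicted_group: str


class MDSLikelihoodScore(ClassifierMixin, BaseEstimator):
    """Median-coefficient split-sample logistic score.

    Parameters
    ----------
    n_iterations : int, default 10000
        Number of random learning/testing splits.
    learn_size : int or None, default None
        Learning-set size; ``None`` keeps the 130/189 ratio of the design
        (130 exactly at the default cohort size of 189).
    standardize : bool, default False
        Z-score the parameters before each fit.  Off by default: the score
        is defined on raw parameter values.
    random_state : int, default 0

    Attributes
    ----------
    parameters_ : list of str
        Ordered parameter names P_i.
    coef_ : ndarray of shape (n_parameters,)
        Median weighting coefficients C_i.
    intercept_ : float
        Median per-iteration intercept.
    efficiencies_ : ndarray of shape (n_iterations,)
        Per-iteration fraction of test subjects correctly classified.
    coefficient_draws_ : ndarray of shape (n_iterations, n_parameters + 1)
        Per-iteration slopes and intercept (last column), for diagnostics.
    n_resampled_ : int
        Splits redrawn because the learning set lacked one group.
    """

    def __init__(self, n_iterations: int = DEFAULT_ITERATIONS,
                 learn_size: int | None = None, standardize: bool = False,
                 random_state: int = 0):
        self.n_iterations = n_iterations
        self.learn_size = learn_size
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y) -> "MDSLikelihoodScore":
        X = self._validate_frame(X)
        y = np.asarray(y)
        labels = set(np.unique(y))
        if labels != {GROUP_MDS, GROUP_HEALTHY}:
            raise ValueError(
                f"labels must be exactly {{MDS, HEALTHY}}, got {sorted(labels)}")
        n = X.shape[0]
        learn_size = self.learn_size
        if learn_size is None:
            learn_size = int(round(LEARN_FRACTION * n))
        if not 0 < learn_size < n:
            raise ValueError(f"learn_size {learn_size} not in (0, {n})")

        values = X.to_numpy(dtype=float)
        if self.standardize:
            self.scale_mean_ = values.mean(axis=0)
            self.scale_sd_ = values.std(axis=0, ddof=0)
            values = (values - self.scale_mean_) / self.scale_sd_
        healthy = (y == GROUP_HEALTHY).astype(int)  # HEALTHY coded 1

        rng = np.random.default_rng(self.random_state)
        p = values.shape[1]
        draws = np.empty((self.n_iterations, p + 1))
        efficiencies = np.empty(self.n_iterations)
        resampled = 0
        # default L2 penalty at C=1e6 ~ ridge 1e-6 on slopes, intercept free
        model = LogisticRegression(C=_RIDGE_C, solver="lbfgs", max_iter=1000)
        for it in range(self.n_iterations):
            while True:
                idx = rng.permutation(n)
                learn, test = idx[:learn_size], idx[learn_size:]
                if 0 < healthy[learn].sum() < learn_size:
                    break
                resampled += 1
            model.fit(values[learn], healthy[learn])
            draws[it, :p] = model.coef_[0]
            draws[it, p] = model.intercept_[0]
            scores = values[test] @ model.coef_[0] + model.intercept_[0]
            predicted_healthy = scores > 0  # score <= 0 => MDS
            efficiencies[it] = np.mean(predicted_healthy == healthy[test])

        self.parameters_ = list(X.columns)
        self.coefficient_draws_ = draws
        self.coef_ = np.median(draws[:, :p], axis=0)
        self.intercept_ = float(np.median(draws[:, p]))
        self.efficiencies_ = efficiencies
        self.n_resampled_ = resampled
        self.learn_size_ = learn_size
        self.classes_ = np.array([GROUP_HEALTHY, GROUP_MDS])
        return self

    @staticmethod
    def _validate_frame(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"P{i + 1}" for i in range(X.shape[1])]
        if X.isna().any().any():
            missing = X.columns[X.isna().any()][0]
            raise ValueError(f"missing value in parameter {missing!r}")
        return X

    def decision_function(self, X) -> np.ndarray:
        """MDS-LS for each row (positive-leaning for healthy subjects)."""
        if isinstance(X, pd.DataFrame):
            missing = [p for p in self.parameters_ if p not in X.columns]
            if missing:
                raise ValueError(f"missing parameter {missing[0]!r}")
            values = X[self.parameters_].to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
        if self.standardize:
            values = (values - self.scale_mean_) / self.scale_sd_
        return values @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return np.where(scores <= 0, GROUP_MDS, GROUP_HEALTHY)

    def to_document(self) -> dict:
        """JSON-serializable model document (parameters, C_i, intercept)."""
        doc = {
            "parameters": self.parameters_,
            "coefficients": [float(c) for c in self.coef_],
            "intercept": self.intercept_,
            "n_iterations": self.n_iterations,
            "learn_size": getattr(self, "learn_size_", None),
            "random_state": self.random_state,
            "standardize": self.standardize,
        }
        if hasattr(self, "efficiencies_"):
            doc["mean_efficiency"] = float(self.efficiencies_.mean())
        if self.standardize and hasattr(self, "scale_mean_"):
            doc["scale_mean"] = [float(v) for v in self.scale_mean_]
            doc["scale_sd"] = [float(v) for v in self.scale_sd_]
        return doc

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_document(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_document(cls, doc: dict) -> "MDSLikelihoodScore":
        model = cls(n_iterations=doc.get("n_iterations", DEFAULT_ITERATIONS),
                    learn_size=doc.get("learn_size"),
                    standardize=doc.get("standardize", False),
                    random_state=doc.get("random_state", 0))
        model.parameters_ = list(doc["parameters"])
        model.coef_ = np.asarray(doc["coefficients"], dtype=float)
        model.intercept_ = float(doc["intercept"])
        model.classes_ = np.array([GROUP_HEALTHY, GROUP_MDS])
        model.learn_size_ = doc.get("learn_size")
        if model.standardize:
            model.scale_mean_ = np.asarray(doc["scale_mean"], dtype=float)
            model.scale_sd_ = np.asarray(doc["scale_sd"], dtype=float)
        return model

    @classmethod
    def load(cls, path) -> "MDSLikelihoodScore":
        with open(path) as fh:
            return cls.from_document(json.load(fh))


@dataclass
class PerformanceReport:
    """Confusion counts and derived metrics with MDS as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float | None:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else None

    @property
    def specificity(self) -> float | None:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else None

    @property
    def ppv(self) -> float | None:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else None

    @property
    def npv(self) -> float | None:
        return self.tn / (self.tn + self.fn) if self.tn + self.fn else None

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def fit_score_model(cohort: pd.DataFrame, parameters: list[str],
                    n_iterations: int = DEFAULT_ITERATIONS,
                    learn_size: int | None = DEFAULT_LEARN_SIZE,
                    seed: int = 0,
                    standardize: bool = False) -> MDSLikelihoodScore:
    """Fit the split-sample score on a labelled cohort table."""
    n = len(cohort)
    if learn_size == DEFAULT_LEARN_SIZE and n != 189:
        learn_size = None  # keep the 130/189 ratio for other cohort sizes
    model = MDSLikelihoodScore(n_iterations=n_iterations,
                               learn_size=learn_size,
                               standardize=standardize, random_state=seed)
    return model.fit(cohort[parameters], cohort["group"])


def compute_score(record: pd.Series | dict,
                  model: MDSLikelihoodScore) -> ScoreResult:
    """MDS-LS of a single subject record."""
    if isinstance(record, dict):
        record = pd.Series(record)
    for p in model.parameters_:
        if p not in record.index or pd.isna(record[p]):
            raise ValueError(f"missing parameter {p!r}")
    row = record[model.parameters_].astype(float).to_frame().T
    score = float(model.decision_function(row)[0])
    return ScoreResult(
        subject_id=str(record.get("subject_id", "")),
        mds_ls=score,
        predicted_group=GROUP_MDS if score <= 0 else GROUP_HEALTHY,
    )


def score_cohort(cohort: pd.DataFrame,
                 model: MDSLikelihoodScore) -> pd.DataFrame:
    """Score every subject; returns subject_id, group (if present),
    mds_ls, predicted_group."""
    scores = model.decision_function(cohort)
    out = pd.DataFrame({
        "subject_id": cohort.get(
            "subject_id", pd.RangeIndex(len(cohort)).astype(str)),
        "mds_ls": scores,
        "predicted_group": np.where(scores <= 0, GROUP_MDS, GROUP_HEALTHY),
    })
    if "group" in cohort.columns:
        out.insert(1, "group", cohort["group"].to_numpy())
    return out


def evaluate(cohort: pd.DataFrame,
             model: MDSLikelihoodScore) -> PerformanceReport:
    """Confusion-matrix performance at the score-zero threshold."""
    truth = cohort["group"].to_numpy()
    predicted = model.predict(cohort)
    return PerformanceReport(
        tp=int(np.sum((truth == GROUP_MDS) & (predicted == GROUP_MDS))),
        fn=int(np.sum((truth == GROUP_MDS) & (predicted == GROUP_HEALTHY))),
        tn=int(np.sum((truth == GROUP_HEALTHY) & (predicted == GROUP_HEALTHY))),
        fp=int(np.sum((truth == GROUP_HEALTHY) & (predicted == GROUP_MDS))),
    )
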