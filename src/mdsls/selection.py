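"""PCA-based selection criteria and the three-list intersection.

The critical parameter set is built from three ranked lists over the
analyzed parameters:

(i)   the 12 smallest univariate p-values,
(ii)  the 12 largest contributions to PCA dimension 1,
(iii) the parameters whose quality of representation on the first factorial
      plane (cos^2 summed over dimensions 1 and 2) exceeds 0.6.

Parameters appearing in at least two of the three lists form the critical
set.  PCA is computed on column-standardized data so the mixed clinical
units of the CBC panel cannot dominate the decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.feature_selection import SelectorMixin

from .screening import UnivariateScreener, top_k_by_p
from .synth import cohort_parameters

COS2_THRESHOLD = 0.6
TOP_K = 12


@dataclass
class PCAResult:
    """Variable-level PCA summaries.

    ``contributions`` holds percent contributions (each dimension sums to
    100); ``cos2`` the squared correlation of each variable with each
    component; ``scores`` the subject coordinates.
    """

    variance_explained: np.ndarray
    contributions: pd.DataFrame
    cos2: pd.DataFrame
    scores: np.ndarray


@dataclass
class SelectionLists:
    mono_top12: list[str]
    contrib_top12: list[str]
    cos2_selected: list[str]
    intersection: list[str]

    def membership_table(self) -> pd.DataFrame:
        """Three-set membership table (Venn input)."""
        union = sorted(set(self.mono_top12) | set(self.contrib_top12)
                       | set(self.cos2_selected))
        return pd.DataFrame({
            "parameter_name": union,
            "monoparametric": [p in self.mono_top12 for p in union],
            "pca_contribution": [p in self.contrib_top12 for p in union],
            "pca_cos2": [p in self.cos2_selected for p in union],
            "selected": [p in self.intersection for p in union],
        })


def run_pca(cohort: pd.DataFrame, parameters: list[str] | None = None,
            n_components: int | None = None) -> PCAResult:
    """PCA of the standardized parameter block.

    Contributions are ``100 * loading^2`` of the unit eigenvectors (summing
    to 100 per dimension); cos2 is the squared correlation between each
    variable and each component score.
    """
    parameters = parameters or cohort_parameters(cohort)
    X = cohort[parameters].to_numpy(dtype=float)
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 3 subjects and 2 parameters")
    if np.isnan(X).any():
        raise ValueError("PCA input contains missing values")
    sd = X.std(axis=0, ddof=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance column: {parameters[zero[0]]!r}")
    Z = (X - X.mean(axis=0)) / sd

    n_components = n_components or min(Z.shape)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z)
    # rows of components_ are unit eigenvectors: squares sum to 1 per dim
    v2 = pca.components_ ** 2
    contributions = pd.DataFrame(100.0 * v2.T, index=parameters)
    eigvals = pca.explained_variance_ * (Z.shape[0] - 1) / Z.shape[0]
    # standardized columns: cor(x_j, F_d) = v_jd * sqrt(lambda_d)
    cos2 = pd.DataFrame((pca.components_.T * np.sqrt(eigvals)) ** 2,
                        index=parameters)
    return PCAResult(
        variance_explained=pca.explained_variance_ratio_,
        contributions=contributions, cos2=cos2, scores=scores,
    )


def contrib_top_k(pca: PCAResult, k: int = TOP_K) -> list[str]:
    """``k`` largest dimension-1 contributions; ties lexicographic."""
    contrib = pca.contributions[0]
    if k > len(contrib):
        raise ValueError(f"k={k} exceeds {len(contrib)} parameters")
    ordered = contrib.to_frame("contrib").reset_index(names="name")
    ordered = ordered.sort_values(["contrib", "name"],
                                  ascending=[False, True], kind="mergesort")
    return ordered["name"].head(k).tolist()


def cos2_select(pca: PCAResult, threshold: float = COS2_THRESHOLD,
                mode: str = "sum", max_size: int = TOP_K) -> list[str]:
    """Parameters well represented on the first factorial plane.

    ``mode="sum"`` thresholds cos2(dim1)+cos2(dim2); ``mode="max"`` the
    larger of the two.  If more than ``max_size`` pass, the ``max_size``
    best are kept.
    """
    if pca.cos2.shape[1] < 2:
        raise ValueError("need at least 2 PCA dimensions")
    plane = pca.cos2[[0, 1]]
    quality = plane.sum(axis=1) if mode == "sum" else plane.max(axis=1)
    passed = quality[quality > threshold]
    ordered = passed.to_frame("q").reset_index(names="name")
    ordered = ordered.sort_values(["q", "name"], ascending=[False, True],
                                  kind="mergesort")
    if max_size is not None:
        ordered = ordered.head(max_size)
    return ordered["name"].tolist()


def intersect_lists(lists: "SelectionLists | tuple[list, list, list]") -> list[str]:
    """Names present in at least two of the three lists, sorted by name."""
    if isinstance(lists, SelectionLists):
        triple = (lists.mono_top12, lists.contrib_top12, lists.cos2_selected)
    else:
        triple = lists
    sets = [set(lst) for lst in triple]
    tally: dict[str, int] = {}
    for s in sets:
        for name in s:
            tally[name] = tally.get(name, 0) + 1
    return sorted(name for name, n in tally.items() if n >= 2)


class CriticalParameterSelector(SelectorMixin, BaseEstimator):
    """Three-criterion feature selector over analyzed parameters.

    Parameters
    ----------
    k : int, default 12
        Length of the ranked lists for criteria (i) and (ii).
    cos2_threshold : float, default 0.6
        Quality-of-representation cutoff for criterion (iii).
    cos2_mode : {"sum", "max"}, default "sum"
        How cos^2 over the first two axes is combined.

    Attributes
    ----------
    lists_ : SelectionLists
    selected_parameters_ : list of str
        The >=2-of-3 intersection, sorted by name.
    """

    def __init__(self, k: int = TOP_K, cos2_threshold: float = COS2_THRESHOLD,
                 cos2_mode: str = "sum"):
        self.k = k
        self.cos2_threshold = cos2_threshold
        self.cos2_mode = cos2_mode

    def fit(self, X: pd.DataFrame, y) -> "CriticalParameterSelector":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        screener = UnivariateScreener().fit(X, y)
        mono = top_k_by_p(screener.results_, self.k)
        pca = run_pca(X, list(X.columns))
        contrib = contrib_top_k(pca, self.k)
        cos2 = cos2_select(pca, self.cos2_threshold, self.cos2_mode,
                           max_size=self.k)
        lists = SelectionLists(mono, contrib, cos2, [])
        lists.intersection = intersect_lists(lists)
        self.lists_ = lists
        self.screening_ = screener.results_
        self.pca_ = pca
        self.selected_parameters_ = lists.intersection
        return self

    def _get_support_mask(self) -> np.ndarray:
        selected = set(self.selected_parameters_)
        return np.array([name in selected for name in self.feature_names_in_])
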