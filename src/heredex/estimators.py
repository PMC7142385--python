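"""Scikit-learn style estimators for the heredity indices.

Both estimators consume a two-column array ``X`` of relative/proband pair
values (column 0: relative, column 1: proband) and expose the fitted index
through trailing-underscore attributes.  They are stateless before ``fit``,
support ``get_params``/``set_params``/``clone``, and validate their input
with the scikit-learn utilities, so they compose with sklearn model
selection.  ``y`` is accepted and ignored (the index is an unsupervised
statistic of the pairs).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .exceptions import DomainError
from .indices import (
    ContingencyTable2x2,
    IndexResult,
    compute_hib,
    compute_hic,
    pearson_correlation,
    phi_correlation,
)
from .simulate import PARENT_CHILD

__all__ = ["HICEstimator", "HIBEstimator"]


def _check_pairs(X) -> np.ndarray:
    X = check_array(X, ensure_min_samples=3, ensure_min_features=2)
    if X.shape[1] != 2:
        raise DomainError(
            f"expected a two-column (relative, proband) array, got {X.shape[1]} columns"
        )
    return X


class HICEstimator(BaseEstimator):
    """Heredity index for continuous traits, HIC = 2 * corr(relative, proband).

    Attributes (after ``fit``)
    --------------------------
    ro_ : float
        Observed Pearson correlation of the pairs.
    re_used_ : float
        The expected correlation in the denominator (always 0.5).
    index_ : float
        The fitted HIC.
    result_ : IndexResult
        Full structured result.
    n_pairs_ : int
        Number of pairs used.
    """

    def fit(self, X, y=None):
        X = _check_pairs(X)
        ro = pearson_correlation(X[:, 0], X[:, 1])
        result = compute_hic(ro, n=X.shape[0])
        self.n_pairs_ = X.shape[0]
        self.ro_ = result.ro
        self.re_used_ = result.re_used
        self.index_ = result.value
        self.result_ = result
        return self

    def score(self, X=None, y=None) -> float:
        check_is_fitted(self, "index_")
        return self.index_


class HIBEstimator(BaseEstimator):
    """Heredity index for binary traits, HIB = phi / Re(K, relationship).

    Parameters
    ----------
    incidence : float or None
        Population incidence K of the trait.  When None, the pooled observed
        prevalence of the pairs is used (and recorded); supply the population
        value whenever it is known.
    relationship : {"parent_child", "sibling"}
        Which expected-correlation model to use in the denominator.
    re_source : {"analytic", "simulation", "lookup"}
        How Re is obtained; ``lookup`` selects the nearest tabulated K in
        the frozen reference table.

    Attributes (after ``fit``): ``ro_``, ``re_used_``, ``index_``,
    ``result_``, ``table_`` (the 2x2 counts), ``incidence_used_``.
    """

    def __init__(
        self,
        incidence: float | None = None,
        relationship: str = PARENT_CHILD,
        re_source: str = "analytic",
    ):
        self.incidence = incidence
        self.relationship = relationship
        self.re_source = re_source

    def fit(self, X, y=None):
        X = _check_pairs(X)
        table = ContingencyTable2x2.from_pairs(X[:, 0], X[:, 1])
        return self._fit_table(table)

    def fit_contingency(self, table: ContingencyTable2x2):
        """Fit directly from a 2x2 count table instead of raw pairs."""
        return self._fit_table(table)

    def _fit_table(self, table: ContingencyTable2x2):
        K = self.incidence
        if K is None:
            # pooled prevalence over both members of each pair
            K = (2 * table.n11 + table.n10 + table.n01) / (2 * table.total)
        ro = phi_correlation(table)
        result = compute_hib(
            ro,
            K,
            relationship=self.relationship,
            re_source=self.re_source,
            n=table.total,
        )
        self.table_ = table
        self.n_pairs_ = table.total
        self.incidence_used_ = float(K)
        self.ro_ = result.ro
        self.re_used_ = result.re_used
        self.index_ = result.value
        self.result_ = result
        return self

    def score(self, X=None, y=None) -> float:
        check_is_fitted(self, "index_")
        return self.index_
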