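"""Heredity indices HIC and HIB.

HIC (continuous traits) compares the observed relative-proband correlation
Ro with the Mendelian expectation of 0.5 for first-degree relatives:

    HIC = Ro / 0.5  (equivalently 2 Ro).

HIB (binary traits) compares the observed phi coefficient of the 2x2
relative-by-proband status table with the expected correlation Re of a pure
polygenic trait dichotomized at the trait's population incidence K:

    HIB = Ro / Re(K, relationship).

Values near 1 are consistent with fully genetic determination; values below
1 indicate a nongenetic contribution (for a purely additive polygenic trait
with heritability h^2, HIC estimates h^2 itself); values above 1 suggest a
few strong genes rather than many weak ones.

The module-level functions here are thin wrappers over the scikit-learn
style estimators in :mod:`heredex.estimators`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    DomainError,
    ShapeError,
    UndefinedCorrelationError,
    UsageError,
)
from .simulate import PARENT_CHILD

__all__ = [
    "HIC_EXPECTED_CORRELATION",
    "ContingencyTable2x2",
    "IndexResult",
    "pearson_correlation",
    "phi_correlation",
    "compute_hic",
    "compute_hib",
    "estimate_index_from_pairs",
]

#: Expected first-degree-relative correlation for a fully genetic continuous trait.
HIC_EXPECTED_CORRELATION = 0.5


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of relative status x proband status (1 = affected).

    n11: both affected; n10: relative affected, proband not;
    n01: proband affected, relative not; n00: neither.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        for name in ("n11", "n10", "n01", "n00"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise DomainError(f"count {name} must be a nonnegative integer, got {v!r}")
        if self.total == 0:
            raise ShapeError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @classmethod
    def from_pairs(cls, relative_status, proband_status) -> "ContingencyTable2x2":
        r = np.asarray(relative_status)
        p = np.asarray(proband_status)
        if r.shape != p.shape:
            raise ShapeError("status arrays differ in shape")
        if not (np.isin(r, (0, 1)).all() and np.isin(p, (0, 1)).all()):
            raise DomainError("binary status arrays may contain only 0 and 1")
        return cls(
            n11=int(np.sum((r == 1) & (p == 1))),
            n10=int(np.sum((r == 1) & (p == 0))),
            n01=int(np.sum((r == 0) & (p == 1))),
            n00=int(np.sum((r == 0) & (p == 0))),
        )

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Expand back to paired 0/1 indicator arrays."""
        r = np.concatenate(
            [
                np.ones(self.n11 + self.n10, dtype=np.int8),
                np.zeros(self.n01 + self.n00, dtype=np.int8),
            ]
        )
        p = np.concatenate(
            [
                np.ones(self.n11, dtype=np.int8),
                np.zeros(self.n10, dtype=np.int8),
                np.ones(self.n01, dtype=np.int8),
                np.zeros(self.n00, dtype=np.int8),
            ]
        )
        return r, p


@dataclass(frozen=True)
class IndexResult:
    """An estimated heredity index with its ingredients.

    ``value`` is always exactly ``ro / re_used``; rounding to two decimals
    happens only at presentation (:meth:`rounded`).
    """

    index_kind: str  # "HIC" | "HIB"
    ro: float
    re_used: float
    value: float
    relationship: str | None = None
    incidence: float | None = None
    re_source: str | None = None
    n: int | None = None
    note: str | None = field(default=None, compare=False)

    def rounded(self, ndigits: int = 2) -> float:
        return round(self.value, ndigits)

    def to_dict(self) -> dict:
        return {
            "index_kind": self.index_kind,
            "ro": self.ro,
            "re_used": self.re_used,
            "re_source": self.re_source,
            "incidence": self.incidence,
            "relationship": self.relationship,
            "value": self.value,
            "n": self.n,
        }


def pearson_correlation(x, y) -> float:
    """Product-moment correlation of two equal-length arrays (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ShapeError(f"arrays differ in shape: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ShapeError(f"need at least 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant array")
    return float(np.corrcoef(x, y)[0, 1])


def phi_correlation(t: ContingencyTable2x2) -> float:
    """Phi coefficient of a 2x2 table.

    phi = (n11 n00 - n10 n01) / sqrt(r1 r0 c1 c0) with r/c the margins;
    identical to the Pearson (and Spearman) correlation of the expanded 0/1
    indicator arrays.
    """
    r1 = t.n11 + t.n10
    r0 = t.n01 + t.n00
    c1 = t.n11 + t.n01
    c0 = t.n10 + t.n00
    if min(r1, r0, c1, c0) == 0:
        raise UndefinedCorrelationError(
            "phi undefined: a margin of the 2x2 table is zero"
        )
    num = t.n11 * t.n00 - t.n10 * t.n01
    return float(num / np.sqrt(float(r1) * r0 * c1 * c0))


def _check_ro(ro: float) -> float:
    if not (-1.0 <= ro <= 1.0):
        raise DomainError(f"observed correlation must lie in [-1, 1], got {ro!r}")
    if ro < 0:
        warnings.warn(
            "negative observed correlation: the polygenic model presumes positive "
            "familial resemblance; the index is reported but should be interpreted "
            "with caution",
            stacklevel=3,
        )
    return float(ro)


def compute_hic(ro: float, n: int | None = None) -> IndexResult:
    """HIC = Ro / 0.5 from an observed continuous-trait correlation."""
    ro = _check_ro(ro)
    return IndexResult(
        index_kind="HIC",
        ro=ro,
        re_used=HIC_EXPECTED_CORRELATION,
        value=ro / HIC_EXPECTED_CORRELATION,
        relationship=PARENT_CHILD,
        re_source="analytic",
        n=n,
        note="HIC < 1 indicates a nongenetic contribution; HIC > 1 suggests a few strong genes",
    )


def compute_hib(
    ro: float,
    K: float,
    relationship: str = PARENT_CHILD,
    re_source: str = "analytic",
    n: int | None = None,
) -> IndexResult:
    """HIB = Ro / Re(K, relationship) from an observed phi coefficient.

    ``re_source`` selects how Re is obtained: ``analytic`` (quadrant
    probability at the exact K; the default), ``simulation`` (Monte Carlo at
    the exact K), or ``lookup`` (nearest tabulated K in the frozen reference
    table).  The source actually used is recorded in the result.
    """
    from . import expectation  # local import to keep module load cheap

    ro = _check_ro(ro)
    if not (0.0 < K < 1.0):
        raise DomainError(f"incidence K must lie in (0, 1), got {K!r}")
    if re_source not in expectation.METHODS:
        raise UsageError(
            f"unknown re_source {re_source!r}; expected one of {expectation.METHODS}"
        )
    re = expectation.expected_phi(K, relationship, method=re_source)
    if re <= 0:
        raise DomainError(f"expected correlation Re={re} is not positive")
    return IndexResult(
        index_kind="HIB",
        ro=ro,
        re_used=float(re),
        value=ro / re,
        relationship=relationship,
        incidence=float(K),
        re_source=re_source,
        n=n,
    )


def estimate_index_from_pairs(
    relative,
    proband,
    mode: str = "continuous",
    K: float | None = None,
    relationship: str = PARENT_CHILD,
    re_source: str = "analytic",
) -> IndexResult:
    """Estimate HIC (continuous mode) or HIB (binary mode) from paired data.

    Thin wrapper over :class:`heredex.estimators.HICEstimator` /
    :class:`heredex.estimators.HIBEstimator`.
    """
    from .estimators import HIBEstimator, HICEstimator

    X = np.column_stack([np.asarray(relative), np.asarray(proband)])
    if mode == "continuous":
        est = HICEstimator().fit(X)
    elif mode == "binary":
        est = HIBEstimator(
            incidence=K, relationship=relationship, re_source=re_source
        ).fit(X)
    else:
        raise UsageError(f"unknown mode {mode!r}; expected 'continuous' or 'binary'")
    return est.result_
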