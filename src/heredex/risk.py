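"""Recurrence-risk estimates from population prevalence and one relative.

Given a trait's population prevalence K and the affected/unaffected status of
a single first-degree relative (a parent or a sibling), the recurrence risk
for the proband under pure polygenic inheritance is the conditional
incidence of :mod:`heredex.expectation`:

    relative affected   -> P11(K) / K
    relative unaffected -> (K - P11(K)) / (1 - K)

No attenuation by an observed HIC/HIB is applied: the estimates assume a
fully genetic trait and therefore bound the familial risk attributable to
additive polygenes.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import expectation
from .exceptions import DomainError
from .simulate import PARENT_CHILD, RELATIONSHIPS, SimulationConfig

__all__ = ["RiskEstimate", "recurrence_risk", "risk_table"]


@dataclass(frozen=True)
class RiskEstimate:
    """Recurrence risk for a proband given one relative's status."""

    incidence: float
    relationship: str
    relative_affected: bool
    risk: float
    method: str

    def to_dict(self) -> dict:
        return {
            "incidence": self.incidence,
            "relationship": self.relationship,
            "relative_affected": self.relative_affected,
            "risk": self.risk,
            "method": self.method,
        }


def recurrence_risk(
    K: float,
    relationship: str = PARENT_CHILD,
    relative_affected: bool = True,
    method: str = "analytic",
    config: SimulationConfig | None = None,
) -> RiskEstimate:
    """Risk that the proband is affected, given the relative's status.

    ``method="lookup"`` reads the frozen reference table (nearest tabulated
    K), reproducing the published lookup workflow exactly; ``analytic`` is
    the noise-free quadrant-probability value; ``simulation`` is Monte
    Carlo under ``config``.
    """
    if not (0.0 < K < 1.0):
        raise DomainError(f"prevalence K must lie in (0, 1), got {K!r}")
    onset, nodisease = expectation.conditional_incidences(
        K, relationship, method=method, config=config
    )
    return RiskEstimate(
        incidence=float(K),
        relationship=relationship,
        relative_affected=bool(relative_affected),
        risk=float(onset if relative_affected else nodisease),
        method=method,
    )


def risk_table(
    K_list,
    relationships=RELATIONSHIPS,
    method: str = "analytic",
    config: SimulationConfig | None = None,
) -> list[RiskEstimate]:
    """Cartesian grid of risk estimates: K x relationship x relative status."""
    estimates = []
    for K in K_list:
        for rel in relationships:
            for affected in (True, False):
                estimates.append(
                    recurrence_risk(K, rel, affected, method=method, config=config)
                )
    return estimates
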