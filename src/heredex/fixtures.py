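"""Worked-example fixtures, reconstructed programmatically.

Two example datasets accompany the method:

* ``fixture_hammer`` — a real 2x2 table of hand preference when holding a
  hammer for 121 father/child pairs, reconstructed from the published
  margins and percentages.
* ``fixture_lunula_synthetic`` — a SYNTHETIC stand-in for the fingernail
  lunula-count study (total lunula count over ten fingertips for
  father/child pairs).  The original raw pairs were never published, only
  group means and the correlation 0.549; this generator produces
  lunula-like integer pair data from the liability simulator so the HIC
  workflow can be demonstrated end-to-end.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .indices import ContingencyTable2x2
from .io import PairData
from .simulate import PARENT_CHILD, SimulationConfig, simulate_family

__all__ = [
    "fixture_hammer",
    "fixture_lunula_synthetic",
    "lunula_group_means",
]

# Published hammer-handedness margins: 20 left-hand fathers of whom 65.0% of
# children hold left, 101 right-hand fathers of whom 27.7% hold left.
_LEFT_FATHERS = 20
_LEFT_PCT = 65.0
_RIGHT_FATHERS = 101
_RIGHT_PCT = 27.7


def fixture_hammer() -> ContingencyTable2x2:
    """The hammer-handedness 2x2 table (left hand = affected).

    Children counts are reconstructed from the printed percentages by
    nearest-integer rounding: round(20 * 0.650) = 13 and
    round(101 * 0.277) = 28, the unique integer counts consistent with the
    printed correlation.
    """
    n11 = int(round(_LEFT_FATHERS * _LEFT_PCT / 100.0))
    n01 = int(round(_RIGHT_FATHERS * _RIGHT_PCT / 100.0))
    return ContingencyTable2x2(
        n11=n11,
        n10=_LEFT_FATHERS - n11,
        n01=n01,
        n00=_RIGHT_FATHERS - n01,
    )


def _liability_to_count(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    # monotone map of liability onto integer counts 0..10, centred at 5
    return np.clip(np.rint(5.0 + 2.0 * (x - mean) / sd), 0, 10).astype(int)


def fixture_lunula_synthetic(config: SimulationConfig | None = None) -> PairData:
    """SYNTHETIC lunula-count pair data (father, child), integer 0-10.

    Father and child liabilities from :func:`simulate_family` are mapped
    monotonically onto counts 0-10 (about two counts per observed-liability
    standard deviation, centred at 5).  At heritability 1 the father-child
    count correlation is close to 0.5, so HIC is close to 1; with
    heritability h^2 it attenuates to about h^2/2, recovering HIC of about
    h^2.  Being a monotone discretisation, the count correlation is very
    slightly below the latent one.
    """
    config = config or SimulationConfig()
    fam = simulate_family(config, PARENT_CHILD)
    mean = 2.0 * config.effect_mean
    sd = float(np.sqrt(2.0 * config.effect_sd**2 / config.heritability))
    father = _liability_to_count(fam.relative_liability, mean, sd)
    child = _liability_to_count(fam.proband_liability, mean, sd)
    ids = np.array([f"fam{i:06d}" for i in range(config.n_families)])
    return PairData(mode="continuous", family_id=ids, relative=father, proband=child)


def lunula_group_means(pairs: PairData) -> pd.DataFrame:
    """Mean child count per father-count group (0-10), for trend inspection."""
    df = pd.DataFrame({"father_count": pairs.relative, "child_count": pairs.proband})
    out = (
        df.groupby("father_count")["child_count"]
        .agg(children_mean="mean", n="size")
        .reset_index()
    )
    return out
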