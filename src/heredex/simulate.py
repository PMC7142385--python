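"""Mendelian gamete-transmission simulator for polygenic liabilities.

The model: each parent carries two "chromosomes" whose additive effect sizes
are drawn i.i.d. from Normal(effect_mean, effect_sd^2) per family.  The
father's liability is A + B, the mother's C + D.  A child receives exactly one
paternal and one maternal chromosome, each chosen uniformly at random, so the
child's liability is one of {A+C, A+D, B+C, B+D} with probability 1/4 each.  A
second sibling of a proband with liability A + B likewise ends up sharing 2,
1, 1 or 0 chromosomes identical by descent, i.e. his liability is one of
{A+B, A+C, B+D, C+D}.

With pure genetic determination the parent-offspring (and sibling-pair)
liability correlation is exactly 1/2.  An optional ``heritability`` parameter
h^2 < 1 adds independent Gaussian environmental noise to every individual so
that the genetic share of the observed liability variance is h^2; the
observed parent-offspring correlation is then h^2 / 2.

Binary (affected / unaffected) traits are obtained by marking the top-K
fraction of a liability array as affected, where K is the population
incidence of the trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .exceptions import ConfigError, DomainError, ShapeError, UsageError

__all__ = [
    "DEFAULT_SEED",
    "PARENT_CHILD",
    "SIBLING",
    "RELATIONSHIPS",
    "SimulationConfig",
    "GameteEffects",
    "FamilySample",
    "BinaryTraitSample",
    "generate_gametes",
    "transmit_child",
    "transmit_sibling",
    "simulate_family",
    "threshold_binary",
    "dichotomize",
]

#: Documented default seed used whenever the caller does not supply one.
DEFAULT_SEED = 1729

PARENT_CHILD = "parent_child"
SIBLING = "sibling"
RELATIONSHIPS = (PARENT_CHILD, SIBLING)

Relationship = Literal["parent_child", "sibling"]


def _check_relationship(relationship: str) -> str:
    if relationship not in RELATIONSHIPS:
        raise UsageError(
            f"unknown relationship {relationship!r}; expected one of {RELATIONSHIPS}"
        )
    return relationship


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated cohort.

    Parameters
    ----------
    n_families:
        Number of independent families (pairs) to simulate.
    effect_mean, effect_sd:
        Mean and standard deviation of each per-chromosome effect score.
        These are pure location/scale parameters: every correlation and
        every conditional incidence is invariant to them.
    heritability:
        Fraction h^2 in (0, 1] of the observed-liability variance that is
        genetic.  h^2 = 1 (the default) is the pure-genetic model.
    seed:
        Seed for the pseudo-random stream; fixed seed gives bit-identical
        output.
    """

    n_families: int = 10_000
    effect_mean: float = 100.0
    effect_sd: float = 30.0
    heritability: float = 1.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if not isinstance(self.n_families, (int, np.integer)) or self.n_families < 2:
            raise ConfigError(f"n_families must be an integer >= 2, got {self.n_families!r}")
        if not np.isfinite(self.effect_mean):
            raise ConfigError(f"effect_mean must be finite, got {self.effect_mean!r}")
        if not (self.effect_sd > 0):
            raise ConfigError(f"effect_sd must be > 0, got {self.effect_sd!r}")
        if not (0.0 < self.heritability <= 1.0):
            raise ConfigError(
                f"heritability must lie in (0, 1], got {self.heritability!r}"
            )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class GameteEffects:
    """The four chromosome-effect arrays underlying one cohort.

    A and B are the father's chromosomes, C and D the mother's; each array
    holds one independent draw per family.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.A)
        for name in "BCD":
            if len(getattr(self, name)) != n:
                raise ShapeError(
                    f"gamete array {name} has length {len(getattr(self, name))}, expected {n}"
                )

    @property
    def n_families(self) -> int:
        return len(self.A)

    @property
    def father(self) -> np.ndarray:
        return self.A + self.B

    @property
    def mother(self) -> np.ndarray:
        return self.C + self.D


@dataclass(frozen=True)
class FamilySample:
    """Paired observed liabilities for one cohort of relative-proband pairs.

    ``relative_liability`` is the father (parent-child) or the elder sibling;
    ``proband_liability`` is the child or the younger sibling.  For
    parent-child cohorts the mother's liability is carried along.  For
    sibling cohorts ``combination`` records, per family, which of the four
    gamete combinations the younger sibling received (0: A+B, 1: A+C,
    2: B+D, 3: C+D — sharing 2, 1, 1, 0 chromosomes with the elder).
    """

    relationship: str
    relative_liability: np.ndarray
    proband_liability: np.ndarray
    mother_liability: np.ndarray | None = None
    combination: np.ndarray | None = None
    config: SimulationConfig | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        _check_relationship(self.relationship)
        if len(self.relative_liability) != len(self.proband_liability):
            raise ShapeError(
                "relative and proband liability arrays differ in length: "
                f"{len(self.relative_liability)} vs {len(self.proband_liability)}"
            )

    @property
    def n_families(self) -> int:
        return len(self.relative_liability)


@dataclass(frozen=True)
class BinaryTraitSample:
    """Dichotomized relative/proband status arrays at incidence K."""

    relative_status: np.ndarray
    proband_status: np.ndarray
    incidence: float
    relationship: str | None = None

    def __post_init__(self) -> None:
        if len(self.relative_status) != len(self.proband_status):
            raise ShapeError("status arrays differ in length")
        if not (0.0 < self.incidence < 1.0):
            raise DomainError(f"incidence must lie in (0, 1), got {self.incidence!r}")


def generate_gametes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GameteEffects:
    """Draw the four chromosome-effect arrays A, B, C, D.

    Each array is an independent Normal(effect_mean, effect_sd^2) sample of
    length ``n_families``; a fixed config seed reproduces the draw exactly.
    """
    if rng is None:
        rng = config.rng()
    shape = (4, config.n_families)
    A, B, C, D = rng.normal(config.effect_mean, config.effect_sd, size=shape)
    return GameteEffects(A=A, B=B, C=C, D=D)


def _pick_one_of_four(
    combos: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    # combos: shape (4, n); one uniform pick per family
    n = combos.shape[1]
    choice = rng.integers(0, 4, size=n)
    return combos[choice, np.arange(n)], choice


def transmit_child(
    g: GameteEffects,
    rng: np.random.Generator,
    return_choice: bool = False,
):
    """Transmit one paternal and one maternal chromosome to each child.

    Per family the child's liability is one of {A+C, A+D, B+C, B+D}, chosen
    uniformly — the Mendelian one-of-four selection, under which
    corr(child, father) = 1/2 exactly in the population.
    """
    combos = np.stack([g.A + g.C, g.A + g.D, g.B + g.C, g.B + g.D])
    child, choice = _pick_one_of_four(combos, rng)
    return (child, choice) if return_choice else child


def transmit_sibling(
    g: GameteEffects,
    rng: np.random.Generator,
    return_choice: bool = False,
):
    """Draw the younger sibling of a proband whose liability is A + B.

    The younger sibling's liability is one of {A+B, A+C, B+D, C+D} uniformly,
    sharing respectively 2, 1, 1, 0 chromosomes identical by descent with the
    elder sibling (pairwise liability correlation 1, 1/2, 1/2, 0); the
    mixture again gives corr = 1/2 overall.
    """
    combos = np.stack([g.A + g.B, g.A + g.C, g.B + g.D, g.C + g.D])
    sib, choice = _pick_one_of_four(combos, rng)
    return (sib, choice) if return_choice else sib


def _environmental_sd(config: SimulationConfig) -> float:
    # genetic liability variance is 2 sigma^2 (sum of two chromosome effects)
    h2 = config.heritability
    return float(np.sqrt(2.0 * config.effect_sd**2 * (1.0 - h2) / h2))


def simulate_family(
    config: SimulationConfig,
    relationship: str = PARENT_CHILD,
    rng: np.random.Generator | None = None,
) -> FamilySample:
    """Simulate one cohort of relative-proband pairs.

    When ``heritability`` < 1 each individual's observed liability is their
    genetic liability plus independent Normal(0, sigma_e^2) noise with
    sigma_e^2 = Var(genetic) (1 - h^2)/h^2, so the genetic variance share is
    h^2 and the pair correlation attenuates from 1/2 to h^2/2.
    """
    _check_relationship(relationship)
    if rng is None:
        rng = config.rng()
    g = generate_gametes(config, rng)
    if relationship == PARENT_CHILD:
        relative = g.father
        mother = g.mother
        proband, choice = transmit_child(g, rng, return_choice=True)
    else:
        relative = g.father  # elder sibling: A + B
        mother = None
        proband, choice = transmit_sibling(g, rng, return_choice=True)

    if config.heritability < 1.0:
        sd_e = _environmental_sd(config)
        relative = relative + rng.normal(0.0, sd_e, size=config.n_families)
        proband = proband + rng.normal(0.0, sd_e, size=config.n_families)
        if mother is not None:
            mother = mother + rng.normal(0.0, sd_e, size=config.n_families)

    return FamilySample(
        relationship=relationship,
        relative_liability=relative,
        proband_liability=proband,
        mother_liability=mother,
        combination=choice,
        config=config,
    )


def threshold_binary(liabilities: np.ndarray, K: float) -> np.ndarray:
    """Mark the top-K fraction of liabilities as affected (1), the rest 0.

    Rank-based: exactly ``round(n * K)`` entries are 1, taken from the
    highest liabilities; among ties the lower original index wins, so the
    observed incidence is exact and the output deterministic.  Any strictly
    increasing transform of the input yields the identical binary array.
    """
    liabilities = np.asarray(liabilities, dtype=float)
    if liabilities.size == 0:
        raise ShapeError("cannot threshold an empty liability array")
    if not (0.0 < K < 1.0):
        raise DomainError(f"incidence K must lie in (0, 1), got {K!r}")
    n = liabilities.size
    n_affected = int(round(n * K))
    status = np.zeros(n, dtype=np.int8)
    if n_affected > 0:
        # stable sort of the negated values: ties keep original index order
        order = np.argsort(-liabilities, kind="stable")
        status[order[:n_affected]] = 1
    return status


def dichotomize(sample: FamilySample, K: float) -> BinaryTraitSample:
    """Apply :func:`threshold_binary` at incidence K to both members."""
    return BinaryTraitSample(
        relative_status=threshold_binary(sample.relative_liability, K),
        proband_status=threshold_binary(sample.proband_liability, K),
        incidence=float(K),
        relationship=sample.relationship,
    )
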