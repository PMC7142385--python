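# Methods

## The liability-threshold model

heredex implements a polygenic liability-threshold model of familial traits.
Each individual's latent liability is the sum of many small additive gene
effects; in the simulator this is collapsed onto two "chromosomes" per
parent, with per-chromosome effect scores drawn i.i.d. per family from
Normal(μ, σ²) (defaults μ = 100, σ = 30 — pure location/scale parameters
that never affect a correlation or a conditional incidence). The father's
liability is A + B, the mother's C + D. Transmission is Mendelian: the child
receives one paternal and one maternal chromosome, each chosen uniformly at
random, so the child's liability is one of {A+C, A+D, B+C, B+D} with
probability 1/4 each. A sibling of a proband with liability A + B likewise
shares 2, 1, 1 or 0 chromosomes identical by descent (probabilities 1/4,
1/2, 1/4 summing the two single-share cases), i.e. the sibling pair is an
equal mixture of liability correlations {1, 1/2, 1/2, 0}.

Under this construction the parent–offspring and sibling liability
correlations are exactly 1/2. An important reading decision: the
transmission rule is *random one-of-four selection per family*, not a
deterministic weighted average of the four sums. The average ½(A+B+C+D)
would correlate 1/√2 ≈ 0.707 with the father, contradicting both the
Mendelian framing and the observed simulated correlation of ≈ 0.51; random
selection gives exactly 0.5.

A binary (affected/unaffected) trait with population incidence K is obtained
by marking the top-K fraction of a liability array as affected.
Thresholding is rank-based: exactly round(nK) individuals are affected, ties
resolved toward the lower index, so the observed incidence is exact, the
output is deterministic, and any strictly increasing transform of the
liabilities yields the identical binary array.

### Heritability extension

`SimulationConfig.heritability` (h², default 1) adds independent
environmental noise e ~ Normal(0, σ_e²) to every individual, with
σ_e² = Var(genetic)·(1 − h²)/h², so the genetic share of observed-liability
variance is h² and the pair correlation attenuates from 1/2 to h²/2. The
pure-genetic model is the h² = 1 special case. This extension exists to
support parameter-recovery testing (HIC ≈ h²); it adds no dominance, shared
environment, or assortative mating.

## The analytic oracle

Every simulated quantity has a noise-free analytic counterpart. For
standardized bivariate-normal liabilities with correlation ρ, dichotomized
at the upper-K quantile z = Φ⁻¹(1 − K), the quadrant probability is

    P11(K, ρ) = P(X > z, Y > z) = ∫_z^∞ φ(x) Φ̄((z − ρx)/√(1 − ρ²)) dx,

evaluated by adaptive quadrature (scipy `quad`, absolute tolerance 1e−12;
the documented contract is 1e−10). The ρ = 0 and ρ = 1 endpoints are exact
(K² and K), and at K = 1/2 the closed form 1/4 + arcsin(ρ)/(2π) provides an
independent anchor; the test suite also cross-checks against scipy's
bivariate-normal CDF, a different integration routine. Parent–child pairs
use ρ = 1/2; sibling pairs use the IBD mixture
P11 = K/4 + P11(K, ½)/2 + K²/4. From P11 follow the conditional incidences

    onset      = P11 / K                 (proband risk, relative affected)
    no-disease = (K − P11) / (1 − K)     (proband risk, relative unaffected)

and the expected correlation of the dichotomized pair

    Re = (P11 − K²) / (K (1 − K)),

the phi coefficient, which on binary data equals the Spearman coefficient —
so "Spearman" expectations are honored with no rank machinery.

## Heredity indices

For continuous traits, HIC = Ro/0.5 = 2Ro, where Ro is the observed
first-degree pair correlation; for a purely additive polygenic trait HIC
estimates h². For binary traits, HIB = Ro/Re(K, relationship), with Ro the
observed phi of the 2×2 status table. Three sources for Re are supported
and always recorded in the result: `analytic` (default; exact K),
`simulation` (Monte Carlo at exact K), and `lookup` (the frozen reference
table at the nearest tabulated K — the workflow by which a ~15%-prevalence
trait is served by the K = 0.125 row, Re = 0.272). Indices are kept at full
precision internally and rounded to two decimals only for presentation.
Negative Ro yields a negative index plus a warning, since the model presumes
positive familial resemblance.

## The frozen reference table and its noise

The package ships the published reference table of conditional incidences
and Re at K ∈ {0.5, 0.25, 0.125, 0.0625, 0.010} for parent–child and
sibling pairs. That table is a single Monte Carlo realisation at n = 10,000
and carries visible sampling noise; the analytic oracle exists precisely to
distinguish that noise from implementation error.
`expectation.flag_anomalous_reference_rows()` compares every tabulated entry
with the oracle using delta-method Monte Carlo standard errors
(SE(phi) ≈ √(P11(1−P11)/n)/(K(1−K)) with margins fixed by rank
thresholding). Findings, computed rather than asserted:

- The only entries beyond 3 SE are the sibling K = 0.125 row (onset 0.298
  vs analytic 0.459; Re 0.303 vs 0.382). That row also violates the law of
  total probability internally (0.125·0.298 + 0.875·0.067 = 0.096 ≠ 0.125),
  so it is treated as an aberrant draw or misprint; simulated values there
  are validated against the analytic band instead, and the total-probability
  invariant test exempts exactly the flagged row.
- At K = 0.01 the tabulated parent–child onset (0.170) sits ≈1.2 SE above
  the analytic 0.1294 (only ~100 affected relatives at n = 10,000), and the
  tabulated no-disease incidence 0.008 is below the analytic 0.00879.
  Consequently the well-known "1% prevalence → 17% risk with an affected
  parent, 34% with an affected sibling, at most 0.8% with an unaffected
  parent" numbers are *table lookups*: the `lookup` risk method reproduces
  them exactly, while the analytic method gives 12.9%, 31.7% and 0.88%.
  Both are reported, with the method recorded in every `RiskEstimate`.
- The worked hammer-handedness example divides Ro = 0.293 by the tabulated
  Re = 0.272, giving 1.077 (the published rounding to 1.10 is not
  arithmetically reproducible from its own inputs; the package reports the
  exact ratio and the ingredients separately).

## Fixtures

The hammer-handedness 2×2 table (121 father/child pairs; left hand =
affected) is reconstructed from the published margins and percentages by
nearest-integer rounding: round(20·0.650) = 13 and round(101·0.277) = 28,
the unique integer counts consistent with the published phi of 0.293. The
father is the canonical "relative" column by convention, not enforcement.

The lunula-count example (total fingernail lunulae over ten fingertips) has
no published raw pairs, only group means and the correlation 0.549, so only
the HIC-from-Ro step is reproducible. `fixture_lunula_synthetic` is a
clearly-labelled synthetic stand-in: simulated liabilities mapped
monotonically onto integer counts 0–10 (two counts per observed-liability
SD, centred at 5, clipped at the ends). The discretisation attenuates the
count correlation slightly below the latent one, so recovery tests use a
±0.05 band rather than the ±0.03 used for continuous liabilities.

## What the generator does and does not emulate

The simulator reproduces the model's own assumptions: additive effects, two
freely recombining chromosomes per parent, no linkage within chromosomes, no
dominance or epistasis, no assortative mating, environmental noise (when
enabled) independent across relatives. Real family data violate several of
these (shared environment inflates Ro; ascertainment distorts K), so
passing tests demonstrate correctness of the method under its stated model,
not unbiasedness of HIC/HIB as heritability estimates in field data — the
indices are deliberately called indices, not heritabilities.

## Numerical choices and problem sizes

- Quadrature: adaptive `quad` on [z, ∞), epsabs 1e−12, limit 300.
- Thresholding tie-break: stable argsort of negated liabilities (lower index
  wins); observed incidence exact at round(nK)/n.
- Default seed 1729, fixed and documented; every stochastic output records
  its seed, and a fixed seed is bit-reproducible.
- Test problem sizes: 10,000 families for distribution checks (matching the
  reference-table protocol); 100,000 for heritability-recovery and IBD
  stratum checks; 4,000,000 for table-regeneration checks, where the
  simulation's own Monte Carlo error (<0.001) must be negligible relative to
  the reference table's ±0.03 bands because the analytic limit already sits
  within 0.002 of a band edge at K = 0.25. The reproduction script uses
  400,000-family cohorts (MC SE < 0.005) for the same reason.
- Degenerate inputs: constant arrays and zero table margins raise
  `UndefinedCorrelationError`; K outside (0,1) raises `DomainError`; config
  errors name the offending field.

## Known limitations

Single-relative conditioning only (no joint conditioning on both parents or
multiple siblings); no confidence intervals for HIC/HIB; no multi-generation
pedigrees; tetrachoric correlation is out of scope (phi is used throughout,
matching the method's definition); the lunula correlation 0.549 itself is
not recomputable from published data.
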