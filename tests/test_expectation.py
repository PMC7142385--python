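"""Tests for the analytic expected-correlation oracle and the Re tables.

The quadrant probability has two independent checks: the closed form
P11(0.5, rho) = 1/4 + arcsin(rho)/(2 pi) at the median threshold, and
scipy's bivariate-normal CDF (a different integration routine).
"""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from heredex import (
    DomainError,
    SimulationConfig,
    UsageError,
    build_re_table,
    bvn_upper_quadrant,
    conditional_incidences,
    expected_phi,
    lookup_re,
    pair_quadrant,
)
from heredex.expectation import (
    REFERENCE_INCIDENCES,
    flag_anomalous_reference_rows,
    lookup_row,
)

K_GRID = [0.5, 0.25, 0.125, 0.0625, 0.010]


def scipy_quadrant(K, rho):
    """Independent oracle: P(X>z, Y>z) via scipy's mvn CDF."""
    z = norm.isf(K)
    mvn = multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])
    return 1.0 - 2.0 * (1.0 - K) + mvn.cdf([z, z])


class TestQuadrantProbability:
    def test_median_threshold_closed_form(self):
        for rho in (0.1, 0.3, 0.5, 0.7, 0.9):
            closed = 0.25 + np.arcsin(rho) / (2 * np.pi)
            assert bvn_upper_quadrant(0.5, rho) == pytest.approx(closed, abs=1e-10)

    def test_anchor_half_half_is_one_third(self):
        assert bvn_upper_quadrant(0.5, 0.5) == pytest.approx(1 / 3, abs=1e-8)

    @pytest.mark.parametrize("K", K_GRID)
    def test_independence_and_perfect_dependence_endpoints(self, K):
        assert bvn_upper_quadrant(K, 0.0) == pytest.approx(K * K, abs=1e-12)
        assert bvn_upper_quadrant(K, 1.0) == pytest.approx(K, abs=1e-12)

    @pytest.mark.parametrize("K", [0.3, 0.125, 0.01])
    @pytest.mark.parametrize("rho", [0.2, 0.5, 0.8])
    def test_against_scipy_mvn_cdf(self, K, rho):
        assert bvn_upper_quadrant(K, rho) == pytest.approx(
            scipy_quadrant(K, rho), abs=1e-8
        )

    @pytest.mark.parametrize("K", [0.4, 0.1, 0.02])
    def test_monotone_in_rho_and_bounded(self, K):
        values = [bvn_upper_quadrant(K, r) for r in np.linspace(0, 1, 11)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
        assert all(K * K - 1e-12 <= v <= K + 1e-12 for v in values)

    @pytest.mark.parametrize("K,rho", [(0.0, 0.5), (1.0, 0.5), (0.3, -0.1), (0.3, 1.1)])
    def test_domain_errors(self, K, rho):
        with pytest.raises(DomainError):
            bvn_upper_quadrant(K, rho)


class TestPairQuadrant:
    def test_parent_child_is_rho_half(self):
        assert pair_quadrant(0.5, "parent_child") == pytest.approx(1 / 3, abs=1e-10)

    def test_sibling_mixture_at_median(self):
        # 1/4 K + 1/2 * 1/3 + 1/4 K^2 at K = 0.5
        expected = 1 / 8 + 1 / 6 + 1 / 16
        assert pair_quadrant(0.5, "sibling") == pytest.approx(expected, abs=1e-10)

    def test_sibling_recurrence_near_published_one_percent(self):
        # P11/K for siblings at 1% prevalence is close to the published 34%
        assert pair_quadrant(0.01, "sibling") / 0.01 == pytest.approx(0.34, abs=0.06)

    def test_unknown_relationship(self):
        with pytest.raises(UsageError):
            pair_quadrant(0.2, "uncle")


class TestConditionalIncidences:
    def test_median_threshold_parent_child(self):
        onset, nodis = conditional_incidences(0.5, "parent_child")
        assert onset == pytest.approx(0.673, abs=0.03)
        assert nodis == pytest.approx(0.327, abs=0.03)

    def test_one_percent_onset_within_published_band(self):
        onset, _ = conditional_incidences(0.01, "parent_child")
        assert onset == pytest.approx(0.17, abs=0.06)

    def test_independent_pair_equals_prevalence(self):
        # rho = 0 degenerates to (K, K); exercised via the quadrant identity
        K = 0.3
        p11 = bvn_upper_quadrant(K, 0.0)
        assert p11 / K == pytest.approx(K)
        assert (K - p11) / (1 - K) == pytest.approx(K)

    def test_simulation_agrees_with_analytic(self, default_config):
        a = conditional_incidences(0.25, "parent_child", "analytic")
        s = conditional_incidences(
            0.25, "parent_child", "simulation", config=default_config
        )
        assert s == pytest.approx(a, abs=0.03)


class TestExpectedPhi:
    def test_analytic_median_is_one_third(self):
        assert expected_phi(0.5, "parent_child") == pytest.approx(1 / 3, abs=1e-10)

    def test_sibling_median_is_five_twelfths(self):
        assert expected_phi(0.5, "sibling") == pytest.approx(5 / 12, abs=1e-10)

    def test_simulation_near_published_value(self, default_config):
        re = expected_phi(0.5, "parent_child", "simulation", config=default_config)
        assert re == pytest.approx(0.345, abs=0.03)

    @pytest.mark.parametrize("K", [0.1, 0.25, 0.4])
    def test_label_flip_symmetry(self, K):
        assert expected_phi(K, "parent_child") == pytest.approx(
            expected_phi(1 - K, "parent_child"), abs=1e-8
        )

    @pytest.mark.parametrize("K", K_GRID)
    def test_sibling_re_dominates_parent_child(self, K):
        assert expected_phi(K, "sibling") > expected_phi(K, "parent_child")

    @pytest.mark.parametrize("K", [0.5, 0.25, 0.125])
    def test_simulation_within_monte_carlo_band_of_analytic(self, K, default_config):
        sim = expected_phi(K, "parent_child", "simulation", config=default_config)
        ana = expected_phi(K, "parent_child", "analytic")
        assert abs(sim - ana) <= 3.0 / np.sqrt(default_config.n_families)

    def test_monte_carlo_error_shrinks_with_n(self):
        ana = expected_phi(0.25, "parent_child")
        errs = []
        for n in (10_000, 1_000_000):
            sim = expected_phi(
                0.25,
                "parent_child",
                "simulation",
                config=SimulationConfig(n_families=n, seed=5150),
            )
            errs.append(abs(sim - ana))
        assert errs[1] < errs[0]


class TestReTable:
    def test_total_probability_identity_every_row(self, default_config):
        # the aberrant published sibling K=0.125 lookup row breaks the
        # identity itself (0.125*0.298 + 0.875*0.067 = 0.096) and is the
        # documented exception
        anomalous = {(rel, K) for rel, K, _, _ in flag_anomalous_reference_rows()}
        for method in ("analytic", "simulation", "lookup"):
            for rel in ("parent_child", "sibling"):
                rows = build_re_table(K_GRID, rel, method, default_config)
                for row in rows:
                    if method == "lookup" and (rel, row.incidence) in anomalous:
                        continue
                    total = (
                        row.incidence * row.incidence_onset
                        + (1 - row.incidence) * row.incidence_nodisease
                    )
                    tol = 1e-9 if method == "analytic" else 0.02
                    assert total == pytest.approx(row.incidence, abs=tol)

    def test_rows_ordered_and_bounded(self):
        rows = build_re_table(K_GRID, "parent_child", "analytic")
        for row in rows:
            assert row.incidence_nodisease <= row.incidence <= row.incidence_onset
            assert 0.0 <= row.re <= 1.0

    def test_simulation_mode_is_deterministic(self, default_config):
        r1 = build_re_table([0.25], "sibling", "simulation", default_config)
        r2 = build_re_table([0.25], "sibling", "simulation", default_config)
        assert r1 == r2

    def test_empty_grid_rejected(self):
        with pytest.raises(UsageError):
            build_re_table([], "parent_child")


class TestReferenceLookup:
    def test_nearest_row_serves_fifteen_percent(self):
        assert lookup_row(0.15, "parent_child").incidence == 0.125
        assert lookup_re(0.15, "parent_child") == 0.272

    def test_exact_grid_points_round_trip(self):
        for K in REFERENCE_INCIDENCES:
            assert lookup_row(K, "sibling").incidence == K

    def test_only_sibling_eighth_row_is_anomalous(self):
        flagged = flag_anomalous_reference_rows()
        assert flagged, "the published sibling K=0.125 row should be flagged"
        assert {(rel, K) for rel, K, _, _ in flagged} == {("sibling", 0.125)}
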