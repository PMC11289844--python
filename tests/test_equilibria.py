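"""Equilibrium enumeration, Jacobian, stability rule and scenario taxonomy."""

import numpy as np
import pytest

from settlegame import (
    PopulationState,
    analytic_jacobian,
    classify_scenario,
    classify_stability,
    corner_stability_table,
    enumerate_equilibria,
    find_ess,
)
from settlegame.equilibria import SCENARIO_ESS
from settlegame.fixtures import FixtureRequest, generate_random_parameters
from settlegame.model import rhs


def _finite_difference_jacobian(params, x, y, h=1e-6):
    fx_p, fy_p = rhs(params, x + h, y)
    fx_m, fy_m = rhs(params, x - h, y)
    col_x = ((fx_p - fx_m) / (2 * h), (fy_p - fy_m) / (2 * h))
    fx_p, fy_p = rhs(params, x, y + h)
    fx_m, fy_m = rhs(params, x, y - h)
    col_y = ((fx_p - fx_m) / (2 * h), (fy_p - fy_m) / (2 * h))
    return np.array([[col_x[0], col_y[0]], [col_x[1], col_y[1]]])


class TestEnumerateEquilibria:
    def test_always_five_candidates_with_four_corners(self, baseline):
        points = enumerate_equilibria(baseline)
        assert len(points) == 5
        corners = {p.coords for p in points if p.kind == "corner"}
        assert corners == {(0, 0), (1, 0), (0, 1), (1, 1)}
        assert all(p.exists for p in points if p.kind == "corner")

    def test_baseline_interior_candidate_outside_square(self, baseline):
        d = [p for p in enumerate_equilibria(baseline) if p.kind == "interior"][0]
        assert d.coords == pytest.approx((4 / 3, -4.0))
        assert not d.exists

    def test_interior_candidate_formulas(self, baseline):
        d = [
            p
            for p in enumerate_equilibria(baseline.replace(c3=1.5, s2=6.0))
            if p.kind == "interior"
        ][0]
        assert d.coords == pytest.approx((0.5, -8.0))
        assert not d.exists

    def test_existing_interior_candidate(self, baseline):
        # Chosen so that both defining fractions land strictly inside (0, 1).
        params = baseline.replace(c1=2.5, c2=3.5, c3=1.5)
        d = [p for p in enumerate_equilibria(params) if p.kind == "interior"][0]
        assert d.exists
        assert 0 < d.coords[0] < 1 and 0 < d.coords[1] < 1
        # It really is a fixed point.
        assert rhs(params, *d.coords) == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_degenerate_denominator_flagged_not_raised(self, baseline):
        params = baseline.replace(p1=5.0, p2=1.0, p3=6.0)  # p1+p2-p3 == 0
        d = [p for p in enumerate_equilibria(params) if p.kind == "interior"][0]
        assert d.degenerate_denominator and not d.exists
        params = baseline.replace(c1=1.0)  # c2 - c1 == 0
        d = [p for p in enumerate_equilibria(params) if p.kind == "interior"][0]
        assert d.degenerate_denominator and not d.exists


class TestAnalyticJacobian:
    def test_baseline_corner_values(self, baseline):
        j_a = analytic_jacobian(baseline, PopulationState(1.0, 0.0))
        assert np.allclose(j_a, np.diag([-2.0, -1.0]))
        j_o = analytic_jacobian(baseline, PopulationState(0.0, 0.0))
        assert np.allclose(j_o, np.diag([2.0, -4.0]))

    def test_corner_off_diagonals_exactly_zero_for_random_parameters(self):
        sets = generate_random_parameters(FixtureRequest(count=25, seed=11))
        for params in sets:
            for corner in [(0, 0), (1, 0), (0, 1), (1, 1)]:
                j = analytic_jacobian(params, PopulationState(*corner))
                assert j[0, 1] == 0.0 and j[1, 0] == 0.0

    def test_matches_central_finite_differences(self):
        """Analytic Jacobian vs central differences of the replicator RHS,
        over >= 1000 randomized (parameters, state) draws."""
        rng = np.random.default_rng(7)
        sets = generate_random_parameters(FixtureRequest(count=100, seed=7))
        checked = 0
        for params in sets:
            for _ in range(10):
                x, y = rng.uniform(0, 1, size=2)
                state = PopulationState(float(x), float(y))
                j = analytic_jacobian(params, state)
                fd = _finite_difference_jacobian(params, state.x, state.y)
                assert np.allclose(j, fd, atol=1e-6)
                checked += 1
        assert checked >= 1000


class TestClassifyStability:
    @pytest.mark.parametrize(
        "det, trace, expected",
        [
            (2.0, -3.0, "ess"),
            (10.0, 6.5, "unstable"),
            (-8.0, 1.0, "saddle"),
            (-8.0, -1.0, "saddle"),
            (0.0, 0.0, "degenerate"),
            (5.0, 0.0, "degenerate"),  # zero trace is never an ESS
            (1e-15, -1.0, "degenerate"),
        ],
    )
    def test_det_trace_rule(self, det, trace, expected):
        assert classify_stability(det, trace) == expected

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            classify_stability(1.0, -1.0, tol=-1e-3)


class TestCornerStabilityTable:
    def test_baseline_table(self, baseline):
        records = {r.point.name: r for r in corner_stability_table(baseline)}
        assert records["A"].det == pytest.approx(2.0)
        assert records["A"].trace == pytest.approx(-3.0)
        assert records["A"].classification == "ess"
        assert records["O"].det == pytest.approx(-8.0)
        assert records["O"].classification == "saddle"
        assert records["B"].det == pytest.approx(10.0)
        assert records["B"].trace == pytest.approx(6.5)
        assert records["B"].classification == "unstable"
        assert records["C"].classification == "saddle"

    def test_det_and_trace_come_from_diagonal(self, baseline):
        for r in corner_stability_table(baseline):
            assert r.det == r.jacobian[0, 0] * r.jacobian[1, 1]
            assert r.trace == r.jacobian[0, 0] + r.jacobian[1, 1]


class TestScenarioTaxonomy:
    def test_baseline_is_scenario_six(self, baseline):
        sc = classify_scenario(baseline)
        assert sc.scenario_id == 6
        assert sc.predicted_ess == ((1.0, 0.0),)
        assert sc.condition_values["patient_advantage_indirect"] == pytest.approx(2.0)
        assert sc.condition_values["hospital_advantage_full_uptake"] == pytest.approx(-1.0)

    def test_raising_hospital_benefit_reaches_scenario_seven(self, baseline):
        sc = classify_scenario(baseline.replace(p1=9.0))
        assert sc.scenario_id == 7
        assert sc.predicted_ess == ((1.0, 1.0),)

    def test_exact_boundary_yields_none_with_flag(self, baseline):
        sc = classify_scenario(baseline.replace(p1=8.0))  # h1 == 0 exactly
        assert sc.scenario_id is None
        assert sc.boundary

    def test_taxonomy_has_seven_scenarios(self):
        assert set(SCENARIO_ESS) == set(range(1, 8))
        singletons = {1, 2, 3, 5, 6, 7}
        for k, ess in SCENARIO_ESS.items():
            assert len(ess) == (2 if k == 4 else 1)
            if k in singletons:
                assert len(ess) == 1
        assert set(SCENARIO_ESS[4]) == {(0.0, 0.0), (1.0, 1.0)}

    def test_random_sets_match_at_most_one_scenario(self):
        """Strict sign patterns are mutually exclusive: the classifier is a
        function, and unmatched sets are boundary or the eighth pattern."""
        sets = generate_random_parameters(FixtureRequest(count=200, seed=5))
        for params in sets:
            sc = classify_scenario(params)
            assert sc.scenario_id in set(range(1, 8)) | {None}
            if sc.scenario_id is None:
                assert sc.boundary or (
                    sc.condition_values["patient_advantage_indirect"] > 0
                    and sc.condition_values["hospital_advantage_full_uptake"] > 0
                    and sc.condition_values["patient_advantage_direct"] < 0
                )


class TestFindEss:
    def test_baseline_single_ess(self, baseline):
        assert [p.coords for p in find_ess(baseline)] == [(1.0, 0.0)]

    def test_scenario_seven_ess(self, baseline):
        assert [p.coords for p in find_ess(baseline.replace(p1=9.0))] == [(1.0, 1.0)]

    def test_scenario_four_has_two_ess(self, baseline):
        params = baseline.replace(u1=5.0, c1=1.0, c2=3.0, c3=1.0)
        assert classify_scenario(params).scenario_id == 4
        assert {p.coords for p in find_ess(params)} == {(0.0, 0.0), (1.0, 1.0)}
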