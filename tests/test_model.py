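"""Payoff matrix, expected payoffs, replicator velocity and validation."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from settlegame import (
    DomainError,
    GameParameters,
    ParameterError,
    PopulationState,
    build_payoff_matrix,
    expected_payoffs,
    replicator_rhs,
    validate_parameters,
)

finite = st.floats(-10, 10, allow_nan=False, allow_infinity=False)
unit = st.floats(0, 1, allow_nan=False, allow_infinity=False)
params_strategy = st.builds(
    GameParameters,
    u1=finite, u2=finite, s1=finite, s2=finite,
    c1=finite, c2=finite, c3=finite,
    p1=finite, p2=finite, p3=finite,
)
state_strategy = st.builds(PopulationState, x=unit, y=unit)


class TestValidation:
    def test_baseline_is_in_regime(self, baseline):
        assert validate_parameters(baseline) == []

    @pytest.mark.parametrize(
        "changes, constraint",
        [
            ({"u1": 4.0}, "u1 > u2"),   # equal utilities break the strict gap
            ({"c3": -1.0}, "c3 > 0"),
            ({"s1": 4.0}, "s1 < s2"),
            ({"p3": 7.0}, "p1 > p3"),
            ({"p2": 0.0}, "p2 > 0"),
            ({"c1": 1.0}, "c1 < c2"),
        ],
    )
    def test_single_violations_reported(self, baseline, changes, constraint):
        violations = validate_parameters(baseline.replace(**changes))
        assert [v.constraint for v in violations] == [constraint]

    def test_strict_mode_raises(self, baseline):
        with pytest.raises(ParameterError, match="c3 > 0"):
            validate_parameters(baseline.replace(c3=-1.0), mode="strict")

    def test_warn_mode_returns_for_logging(self, baseline):
        out = validate_parameters(baseline.replace(u2=9.0), mode="warn")
        assert len(out) == 1 and "u1 > u2" in out[0].detail

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), "six"])
    def test_nonfinite_field_named_in_error(self, baseline, bad):
        with pytest.raises(ParameterError, match="u1"):
            baseline.replace(u1=bad)

    def test_from_dict_rejects_unknown_and_missing_keys(self, baseline):
        with pytest.raises(ParameterError, match="pi1"):
            GameParameters.from_dict({**baseline.as_dict(), "pi1": 1.0})
        partial = baseline.as_dict()
        del partial["c3"]
        with pytest.raises(ParameterError, match="c3"):
            GameParameters.from_dict(partial)


class TestPayoffMatrix:
    def test_baseline_cells(self, baseline):
        m = build_payoff_matrix(baseline)
        assert m.cells[("cross_regional", "direct")] == (2.5, 5.0)
        assert m.cells[("cross_regional", "indirect")] == (2.0, 6.0)
        assert m.cells[("in_area", "direct")] == (0.0, -4.0)
        assert m.cells[("in_area", "indirect")] == (0.0, 0.0)

    @given(params=params_strategy)
    def test_in_area_patient_payoff_independent_of_hospital(self, params):
        m = build_payoff_matrix(params)
        assert m.patient("in_area", "direct") == m.patient("in_area", "indirect")

    @given(params=params_strategy)
    def test_in_area_indirect_hospital_payoff_zero(self, params):
        assert build_payoff_matrix(params).hospital("in_area", "indirect") == 0.0


class TestExpectedPayoffs:
    @pytest.mark.parametrize(
        "y, ep1", [(0.0, 2.0), (1.0, 2.5), (0.5, 2.25)]
    )
    def test_baseline_patient_payoffs(self, baseline, y, ep1):
        ep = expected_payoffs(baseline, PopulationState(0.3, y))
        assert ep.ep1 == pytest.approx(ep1)
        assert ep.ep2 == 0.0

    @given(params=params_strategy, y=unit)
    def test_pure_patient_population_mean_equals_ep1(self, params, y):
        ep = expected_payoffs(params, PopulationState(1.0, y))
        assert ep.ep_mean == ep.ep1

    @given(params=params_strategy, state=state_strategy)
    def test_means_are_mixtures(self, params, state):
        ep = expected_payoffs(params, state)
        assert ep.ep_mean == pytest.approx(
            state.x * ep.ep1 + (1 - state.x) * ep.ep2, abs=1e-12
        )
        assert ep.eh_mean == pytest.approx(
            state.y * ep.eh1 + (1 - state.y) * ep.eh2, abs=1e-12
        )

    def test_state_outside_square_rejected(self):
        with pytest.raises(DomainError):
            PopulationState(1.2, 0.5)
        with pytest.raises(DomainError):
            PopulationState(0.5, -0.01)


class TestReplicatorRhs:
    def test_baseline_center_velocity(self, baseline):
        v = replicator_rhs(baseline, PopulationState(0.5, 0.5))
        assert v.dx_dt == pytest.approx(0.5625)
        assert v.dy_dt == pytest.approx(-0.625)

    @pytest.mark.parametrize("corner", [(0, 0), (1, 0), (0, 1), (1, 1)])
    def test_corners_are_fixed_points(self, baseline, corner):
        v = replicator_rhs(baseline, PopulationState(*corner))
        assert v.as_tuple() == (0.0, 0.0)

    def test_boundary_face_freezes_coordinate(self, baseline):
        v = replicator_rhs(baseline, PopulationState(1.0, 0.3))
        assert v.dx_dt == 0.0

    @given(params=params_strategy, state=state_strategy)
    def test_velocity_sign_tracks_payoff_advantage(self, params, state):
        ep = expected_payoffs(params, state)
        v = replicator_rhs(params, state)
        if 0 < state.x < 1 and ep.ep1 != ep.ep2:
            assert math.copysign(1, v.dx_dt) == math.copysign(1, ep.ep1 - ep.ep2)
        if 0 < state.y < 1 and ep.eh1 != ep.eh2:
            assert math.copysign(1, v.dy_dt) == math.copysign(1, ep.eh1 - ep.eh2)

    @given(params=params_strategy, state=state_strategy, delta=finite)
    def test_shift_invariance_of_dynamics(self, params, state, delta):
        """Common translations of (u1,u2), (s1,s2) or (p1,p3) leave the
        velocity unchanged: the dynamics depend only on payoff differences."""
        v = replicator_rhs(params, state)
        shifted = [
            params.replace(u1=params.u1 + delta, u2=params.u2 + delta),
            params.replace(s1=params.s1 + delta, s2=params.s2 + delta),
            params.replace(p1=params.p1 + delta, p3=params.p3 + delta),
        ]
        for p in shifted:
            w = replicator_rhs(p, state)
            assert w.dx_dt == pytest.approx(v.dx_dt, abs=1e-9)
            assert w.dy_dt == pytest.approx(v.dy_dt, abs=1e-9)

    @given(params=params_strategy, state=state_strategy)
    def test_matrix_form_agrees_with_expanded_polynomial(self, params, state):
        """The bimatrix route x(1-x)(EP1-EP2) and the expanded cubic
        polynomial route agree to near machine precision."""
        p, x, y = params, state.x, state.y
        expanded_x = x * (x - 1) * (
            p.c2 + p.s1 - p.s2 - p.u1 + p.u2 + (p.c1 - p.c2) * y
        )
        expanded_y = y * (y - 1) * (
            p.c3 - p.p1 * x - p.p2 * x + p.p3 * x
        )
        v = replicator_rhs(params, state)
        assert v.dx_dt == pytest.approx(expanded_x, abs=1e-12)
        assert v.dy_dt == pytest.approx(expanded_y, abs=1e-12)
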