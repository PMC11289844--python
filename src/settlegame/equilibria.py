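"""Equilibrium enumeration, Jacobian stability analysis and the scenario taxonomy.

The replicator system on the unit square always has the four corner
equilibria O(0,0), A(1,0), B(0,1), C(1,1) plus one interior candidate

    x0 = c3 / (p1 + p2 - p3),
    y0 = (c2 + s1 - s2 - u1 + u2) / (c2 - c1),

which counts as an equilibrium only when it lies strictly inside the open
square.  Local stability is read off the Jacobian: an equilibrium with
det(J) > 0 and tr(J) < 0 is an evolutionarily stable strategy (ESS);
det(J) < 0 is a saddle; det(J) > 0 with tr(J) > 0 is unstable.  The
interior candidate always has zero trace (it is a center of the linearised
flow) and is therefore never an ESS; it is reported but not classified
further.

The signs of three affine payoff-difference expressions,

    d1 = EP1 - EP2 at y = 0  (= s2 - s1 - c2 + u1 - u2),
    h1 = EH1 - EH2 at x = 1  (= p1 + p2 - p3 - c3),
    d2 = EP1 - EP2 at y = 1  (= s2 - s1 - c1 + u1 - u2),

fix the stability type of every corner.  Seven of the eight strict sign
patterns form the scenario taxonomy; the eighth pattern (d1 > 0, h1 > 0,
d2 < 0) requires c1 > c2 and has no scenario index, as does any parameter
set for which one of the expressions is exactly zero (a degenerate
boundary).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import GameParameters, PopulationState

__all__ = [
    "EquilibriumPoint",
    "StabilityRecord",
    "ScenarioClassification",
    "ConsistencyError",
    "CORNER_NAMES",
    "SCENARIO_ESS",
    "enumerate_equilibria",
    "analytic_jacobian",
    "classify_stability",
    "corner_stability_table",
    "classify_scenario",
    "find_ess",
    "scenario_conditions",
]

#: Corner labels in conventional order.
CORNER_NAMES: dict[tuple[float, float], str] = {
    (0.0, 0.0): "O",
    (1.0, 0.0): "A",
    (0.0, 1.0): "B",
    (1.0, 1.0): "C",
}

CORNERS: tuple[tuple[float, float], ...] = tuple(CORNER_NAMES)


class ConsistencyError(RuntimeError):
    """Jacobian-based ESS set disagrees with the scenario prediction."""


@dataclass(frozen=True)
class EquilibriumPoint:
    """A candidate equilibrium of the replicator system.

    ``coords`` may lie outside the unit square for the interior candidate
    (in which case ``exists`` is False).  ``degenerate_denominator`` marks
    an interior candidate whose defining fractions are 0/0 or a/0.
    """

    name: str
    coords: tuple[float, float]
    kind: str  # "corner" | "interior"
    exists: bool
    degenerate_denominator: bool = False

    @property
    def state(self) -> PopulationState:
        """The point as a validated state (raises if outside the square)."""
        return PopulationState(*self.coords)


def enumerate_equilibria(params: GameParameters) -> list[EquilibriumPoint]:
    """Return the four corners plus the interior candidate D(x0, y0).

    The candidate ``exists`` only when 0 < x0 < 1 and 0 < y0 < 1 with both
    inequalities strict.  A vanishing denominator (p1 + p2 = p3 or c1 = c2)
    is reported via ``degenerate_denominator`` rather than raised: along
    such a boundary one replicator equation loses its interior root.
    """
    p = params
    points = [
        EquilibriumPoint(name=CORNER_NAMES[c], coords=c, kind="corner", exists=True)
        for c in CORNERS
    ]
    denom_x = p.p1 + p.p2 - p.p3
    denom_y = p.c2 - p.c1
    degenerate = denom_x == 0.0 or denom_y == 0.0
    if degenerate:
        x0 = np.nan if denom_x == 0.0 else p.c3 / denom_x
        y0 = np.nan if denom_y == 0.0 else (p.c2 + p.s1 - p.s2 - p.u1 + p.u2) / denom_y
        exists = False
    else:
        x0 = p.c3 / denom_x
        y0 = (p.c2 + p.s1 - p.s2 - p.u1 + p.u2) / denom_y
        exists = 0.0 < x0 < 1.0 and 0.0 < y0 < 1.0
    points.append(
        EquilibriumPoint(
            name="D",
            coords=(float(x0), float(y0)),
            kind="interior",
            exists=exists,
            degenerate_denominator=degenerate,
        )
    )
    return points


def analytic_jacobian(params: GameParameters, state: PopulationState) -> np.ndarray:
    """Closed-form Jacobian of the replicator field at ``state``.

    With F(x) = x(x-1)(c2+s1-s2-u1+u2+(c1-c2)y) and
    F(y) = y(y-1)(c3-(p1+p2-p3)x), the four partials are

        dFx/dx = (2x-1)(c2+s1-s2-u1+u2+(c1-c2)y)
        dFx/dy = x(x-1)(c1-c2)
        dFy/dx = y(y-1)(p3-p1-p2)
        dFy/dy = (2y-1)(c3-(p1+p2-p3)x)

    Both off-diagonal entries vanish identically on the corners.
    """
    p, x, y = params, state.x, state.y
    gx = p.c2 + p.s1 - p.s2 - p.u1 + p.u2 + (p.c1 - p.c2) * y
    gy = p.c3 - (p.p1 + p.p2 - p.p3) * x
    return np.array(
        [
            [(2.0 * x - 1.0) * gx, x * (x - 1.0) * (p.c1 - p.c2)],
            [y * (y - 1.0) * (p.p3 - p.p1 - p.p2), (2.0 * y - 1.0) * gy],
        ]
    )


def classify_stability(det: float, trace: float, tol: float = 1e-12) -> str:
    """Apply the determinant/trace rule with an absolute degeneracy band.

    ess        det > tol and trace < -tol
    unstable   det > tol and trace > tol
    saddle     det < -tol
    degenerate |det| <= tol, or det > tol with |trace| <= tol
    """
    if tol < 0:
        raise ValueError("tolerance must be nonnegative")
    if det > tol:
        if trace < -tol:
            return "ess"
        if trace > tol:
            return "unstable"
        return "degenerate"
    if det < -tol:
        return "saddle"
    return "degenerate"


@dataclass(frozen=True)
class StabilityRecord:
    """An equilibrium with its Jacobian, invariants and classification."""

    point: EquilibriumPoint
    jacobian: np.ndarray
    det: float
    trace: float
    classification: str


def corner_stability_table(
    params: GameParameters, tol: float = 1e-12
) -> list[StabilityRecord]:
    """Stability records for the four corner equilibria.

    The Jacobian is diagonal at every corner, so the determinant is the
    product and the trace the sum of the two diagonal entries.  The interior
    candidate is excluded: its trace vanishes identically, so it is never an
    ESS and the det/trace rule yields no further information.
    """
    records = []
    for coords in CORNERS:
        point = EquilibriumPoint(
            name=CORNER_NAMES[coords], coords=coords, kind="corner", exists=True
        )
        jac = analytic_jacobian(params, point.state)
        det = jac[0, 0] * jac[1, 1]
        trace = jac[0, 0] + jac[1, 1]
        records.append(
            StabilityRecord(
                point=point,
                jacobian=jac,
                det=float(det),
                trace=float(trace),
                classification=classify_stability(det, trace, tol),
            )
        )
    return records


# Scenario taxonomy: sign pattern of (d1, h1, d2) -> scenario index.
_SCENARIO_SIGNS: dict[tuple[int, int, int], int] = {
    (-1, -1, -1): 1,
    (-1, -1, +1): 2,
    (-1, +1, -1): 3,
    (-1, +1, +1): 4,
    (+1, -1, -1): 5,
    (+1, -1, +1): 6,
    (+1, +1, +1): 7,
}

#: Corner ESS set predicted by the taxonomy for each scenario.
SCENARIO_ESS: dict[int, tuple[tuple[float, float], ...]] = {
    1: ((0.0, 0.0),),
    2: ((0.0, 0.0),),
    3: ((0.0, 0.0),),
    4: ((0.0, 0.0), (1.0, 1.0)),
    5: ((1.0, 0.0),),
    6: ((1.0, 0.0),),
    7: ((1.0, 1.0),),
}


def scenario_conditions(params: GameParameters) -> dict[str, float]:
    """The three signed expressions whose sign pattern fixes the scenario.

    ``patient_advantage_indirect`` is EP1-EP2 when no hospital settles
    directly (y=0); ``patient_advantage_direct`` the same at y=1;
    ``hospital_advantage_full_uptake`` is EH1-EH2 when every patient
    travels (x=1).
    """
    p = params
    d1 = p.s2 - p.s1 - p.c2 + p.u1 - p.u2
    d2 = p.s2 - p.s1 - p.c1 + p.u1 - p.u2
    h1 = p.p1 + p.p2 - p.p3 - p.c3
    return {
        "patient_advantage_indirect": d1,
        "hospital_advantage_full_uptake": h1,
        "patient_advantage_direct": d2,
    }


@dataclass(frozen=True)
class ScenarioClassification:
    """Outcome of matching a parameter set against the seven scenarios."""

    scenario_id: int | None
    condition_values: dict[str, float] = field(compare=False)
    predicted_ess: tuple[tuple[float, float], ...]
    boundary: bool = False


def classify_scenario(params: GameParameters) -> ScenarioClassification:
    """Match the strict sign pattern of (d1, h1, d2) against the taxonomy.

    A parameter set on a degenerate boundary (any expression exactly zero)
    matches no scenario and is flagged; the one strict pattern outside the
    taxonomy (d1 > 0, h1 > 0, d2 < 0, feasible only with c1 > c2) yields
    ``scenario_id`` None without the boundary flag.
    """
    conditions = scenario_conditions(params)
    values = (
        conditions["patient_advantage_indirect"],
        conditions["hospital_advantage_full_uptake"],
        conditions["patient_advantage_direct"],
    )
    if any(v == 0.0 for v in values):
        return ScenarioClassification(
            scenario_id=None,
            condition_values=conditions,
            predicted_ess=(),
            boundary=True,
        )
    pattern = tuple(1 if v > 0 else -1 for v in values)
    scenario = _SCENARIO_SIGNS.get(pattern)
    return ScenarioClassification(
        scenario_id=scenario,
        condition_values=conditions,
        predicted_ess=SCENARIO_ESS.get(scenario, ()) if scenario else (),
        boundary=False,
    )


def find_ess(params: GameParameters, tol: float = 1e-12) -> list[EquilibriumPoint]:
    """Corners classified ESS by the det/trace rule.

    When the parameter set matches a scenario, the Jacobian-based set is
    cross-checked against the taxonomy's prediction; a mismatch (possible
    only within ``tol`` of a degenerate boundary) raises
    :class:`ConsistencyError`.
    """
    records = corner_stability_table(params, tol)
    ess = [r.point for r in records if r.classification == "ess"]
    scenario = classify_scenario(params)
    if scenario.scenario_id is not None:
        got = {p.coords for p in ess}
        predicted = set(scenario.predicted_ess)
        if got != predicted:
            raise ConsistencyError(
                f"scenario {scenario.scenario_id} predicts ESS set {sorted(predicted)} "
                f"but the Jacobian rule found {sorted(got)}; the parameter set lies "
                f"within tol={tol:g} of a degenerate boundary"
            )
    return ess
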