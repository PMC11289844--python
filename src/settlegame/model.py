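"""Payoff model of the cross-regional settlement game.

Two boundedly rational populations interact repeatedly.  Patients with
malignant tumours choose between *cross-regional treatment* (seeking care
outside the region where their health insurance is pooled) and *in-area
medical care*; hospitals choose between *direct settlement* (real-time
insurance reimbursement of cross-regional claims at the point of care) and
*indirect settlement* (the patient advances the full cost and is reimbursed
later at home).

The game is described by ten dimensionless payoff coefficients:

================  =====================================================
``u1``            utility a patient derives from cross-regional treatment
``u2``            utility of in-area care (``u1 > u2``)
``s1``            patient medical cost after cross-regional treatment
``s2``            patient medical cost after in-area care (``s1 < s2``)
``c1``            patient nonmedical cost (travel, lodging, time) of a
                  cross-regional episode when the hospital settles directly
``c2``            the same cost without direct settlement (``c1 < c2``)
``c3``            hospital input cost of operating direct settlement
                  (IT upgrade, cash-flow pressure; ``c3 > 0``)
``p1``            hospital financial benefit of direct settlement
``p2``            hospital technological-advancement benefit (``p2 > 0``)
``p3``            hospital financial benefit without direct settlement
                  (``p1 > p3``)
================  =====================================================

With ``x`` the frequency of patients seeking cross-regional care and ``y``
the frequency of hospitals settling directly, the replicator dynamics read

.. math::

    \\dot x = x(1-x)\\,(EP_1 - EP_2), \\qquad
    \\dot y = y(1-y)\\,(EH_1 - EH_2),

where :math:`EP_1, EP_2` (:math:`EH_1, EH_2`) are the strategies' expected
payoffs against the current opponent mix.  Both payoff differences are
affine:

.. math::

    EP_1 - EP_2 = (u_1 - s_1 - c_2 - u_2 + s_2) + (c_2 - c_1)\\,y, \\qquad
    EH_1 - EH_2 = (p_1 + p_2 - p_3)\\,x - c_3 .
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Iterable, Literal, Mapping

__all__ = [
    "PARAM_NAMES",
    "PATIENT_STRATEGIES",
    "HOSPITAL_STRATEGIES",
    "ParameterError",
    "DomainError",
    "ConstraintViolation",
    "GameParameters",
    "PopulationState",
    "PayoffMatrix",
    "ExpectedPayoffs",
    "Velocity",
    "baseline_parameters",
    "validate_parameters",
    "build_payoff_matrix",
    "expected_payoffs",
    "replicator_rhs",
]

#: Canonical order of the ten game parameters.
PARAM_NAMES: tuple[str, ...] = (
    "u1", "u2", "s1", "s2", "c1", "c2", "c3", "p1", "p2", "p3",
)

PATIENT_STRATEGIES: tuple[str, str] = ("cross_regional", "in_area")
HOSPITAL_STRATEGIES: tuple[str, str] = ("direct", "indirect")

ValidationMode = Literal["strict", "warn"]


class ParameterError(ValueError):
    """Raised for malformed or (in strict mode) out-of-regime parameters."""


class DomainError(ValueError):
    """Raised when a population state leaves the unit square."""


@dataclass(frozen=True)
class ConstraintViolation:
    """One violated parameter-regime constraint.

    Attributes
    ----------
    constraint:
        The constraint in canonical notation, e.g. ``"u1 > u2"``.
    detail:
        Human-readable description including the offending values.
    """

    constraint: str
    detail: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.detail


@dataclass(frozen=True)
class GameParameters:
    """The ten scalar coefficients of the settlement game.

    All fields must be finite real numbers; construction fails otherwise.
    Whether the canonical regime constraints (``u1 > u2`` etc.) are enforced
    is governed separately by :func:`validate_parameters`, because
    sensitivity sweeps deliberately cross them.
    """

    u1: float
    u2: float
    s1: float
    s2: float
    c1: float
    c2: float
    c3: float
    p1: float
    p2: float
    p3: float

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise ParameterError(
                    f"parameter {f.name!r} must be a real number, got {value!r}"
                )
            if not math.isfinite(value):
                raise ParameterError(f"parameter {f.name!r} is not finite: {value!r}")
            object.__setattr__(self, f.name, float(value))

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "GameParameters":
        """Build from a flat mapping with exactly the ten canonical keys."""
        unknown = set(mapping) - set(PARAM_NAMES)
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        missing = set(PARAM_NAMES) - set(mapping)
        if missing:
            raise ParameterError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: mapping[k] for k in PARAM_NAMES})

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    def replace(self, **changes: float) -> "GameParameters":
        """Return a copy with the given parameters replaced."""
        unknown = set(changes) - set(PARAM_NAMES)
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        return replace(self, **changes)


def baseline_parameters() -> GameParameters:
    """Reference parameter set used throughout the documentation.

    The values respect every canonical regime constraint and serve as the
    default configuration for simulations and as the anchor point of the
    one-parameter sensitivity sweeps.
    """
    return GameParameters(
        u1=6.0, u2=4.0, s1=3.0, s2=4.0,
        c1=0.5, c2=1.0, c3=4.0,
        p1=7.0, p2=2.0, p3=6.0,
    )


#: The canonical regime constraints, as (label, predicate, describe) triples.
_CONSTRAINTS: tuple[tuple[str, ...], ...] = (
    ("u1 > u2", "u1", "u2"),
    ("s1 < s2", "s1", "s2"),
    ("c1 < c2", "c1", "c2"),
    ("p1 > p3", "p1", "p3"),
    ("p2 > 0", "p2", None),
    ("c3 > 0", "c3", None),
)


def _check_constraint(label: str, a: float, b: float | None) -> bool:
    if ">" in label and b is not None:
        return a > b
    if "<" in label:
        return a < b  # type: ignore[operator]
    return a > 0.0


def validate_parameters(
    params: GameParameters, mode: ValidationMode = "warn"
) -> list[ConstraintViolation]:
    """Check the canonical regime constraints of the game.

    Parameters
    ----------
    params:
        The parameter set to validate (all fields are guaranteed finite by
        construction).
    mode:
        ``"warn"`` (default) returns the violations for logging; ``"strict"``
        raises :class:`ParameterError` when any constraint fails.  The warn
        default exists because sensitivity sweeps intentionally drive single
        parameters outside the canonical regime.

    Returns
    -------
    list of :class:`ConstraintViolation`
        Empty iff all six canonical constraints hold.
    """
    if mode not in ("strict", "warn"):
        raise ValueError(f"unknown validation mode {mode!r}")
    violations: list[ConstraintViolation] = []
    for label, a_name, b_name in _CONSTRAINTS:
        a = getattr(params, a_name)
        b = getattr(params, b_name) if b_name else None
        if not _check_constraint(label, a, b):
            if b_name:
                detail = f"{label} violated: {a_name}={a:g}, {b_name}={b:g}"
            else:
                detail = f"{label} violated: {a_name}={a:g}"
            violations.append(ConstraintViolation(constraint=label, detail=detail))
    if mode == "strict" and violations:
        raise ParameterError(
            "parameter set violates canonical constraints: "
            + "; ".join(v.detail for v in violations)
        )
    return violations


@dataclass(frozen=True)
class PopulationState:
    """Strategy frequencies ``(x, y)`` on the unit square.

    ``x`` is the frequency of patients choosing cross-regional treatment,
    ``y`` the frequency of hospitals implementing direct settlement.
    """

    x: float
    y: float

    def __post_init__(self) -> None:
        for name in ("x", "y"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise DomainError(f"state coordinate {name!r} must be a number")
            if not math.isfinite(v) or not (0.0 <= v <= 1.0):
                raise DomainError(
                    f"state coordinate {name}={v!r} outside the unit interval"
                )
            object.__setattr__(self, name, float(v))

    def as_tuple(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class PayoffMatrix:
    """The 2x2 bimatrix of the stage game.

    ``cells`` maps ``(patient_strategy, hospital_strategy)`` to the pair
    ``(patient_payoff, hospital_payoff)``.  Strategy labels are the strings
    in :data:`PATIENT_STRATEGIES` and :data:`HOSPITAL_STRATEGIES`.
    """

    cells: Mapping[tuple[str, str], tuple[float, float]]

    def patient(self, patient_strategy: str, hospital_strategy: str) -> float:
        return self.cells[(patient_strategy, hospital_strategy)][0]

    def hospital(self, patient_strategy: str, hospital_strategy: str) -> float:
        return self.cells[(patient_strategy, hospital_strategy)][1]


def build_payoff_matrix(params: GameParameters) -> PayoffMatrix:
    """Assemble the stage-game bimatrix from the parameters.

    A travelling patient receives utility ``u1`` net of medical cost ``s1``
    and the nonmedical cost that applies under the hospital's settlement
    regime (``c1`` direct, ``c2`` indirect).  A patient staying in area
    receives ``u2 - s2`` regardless of the hospital's choice.  A hospital
    that settles directly pays ``c3`` and collects ``p1 + p2`` only when
    the patient actually travels; an indirect-settlement hospital collects
    ``p3`` from travelling patients and nothing otherwise.
    """
    p = params
    cells = {
        ("cross_regional", "direct"): (p.u1 - p.s1 - p.c1, p.p1 + p.p2 - p.c3),
        ("cross_regional", "indirect"): (p.u1 - p.s1 - p.c2, p.p3),
        ("in_area", "direct"): (p.u2 - p.s2, -p.c3),
        ("in_area", "indirect"): (p.u2 - p.s2, 0.0),
    }
    return PayoffMatrix(cells=cells)


@dataclass(frozen=True)
class ExpectedPayoffs:
    """Expected payoffs of the pure strategies and the population means."""

    ep1: float  #: patient payoff of cross-regional treatment
    ep2: float  #: patient payoff of in-area care
    ep_mean: float  #: x*ep1 + (1-x)*ep2
    eh1: float  #: hospital payoff of direct settlement
    eh2: float  #: hospital payoff of indirect settlement
    eh_mean: float  #: y*eh1 + (1-y)*eh2


def expected_payoffs(params: GameParameters, state: PopulationState) -> ExpectedPayoffs:
    """Expected payoffs of each pure strategy against the current mix."""
    p, x, y = params, state.x, state.y
    ep1 = y * (p.u1 - p.s1 - p.c1) + (1.0 - y) * (p.u1 - p.s1 - p.c2)
    ep2 = p.u2 - p.s2
    eh1 = x * (p.p1 + p.p2 - p.c3) + (1.0 - x) * (-p.c3)
    eh2 = x * p.p3
    return ExpectedPayoffs(
        ep1=ep1,
        ep2=ep2,
        ep_mean=x * ep1 + (1.0 - x) * ep2,
        eh1=eh1,
        eh2=eh2,
        eh_mean=y * eh1 + (1.0 - y) * eh2,
    )


@dataclass(frozen=True)
class Velocity:
    """Replicator velocity ``(dx/dt, dy/dt)`` at a population state."""

    dx_dt: float
    dy_dt: float

    def as_tuple(self) -> tuple[float, float]:
        return (self.dx_dt, self.dy_dt)


def patient_advantage(params: GameParameters, y: float) -> float:
    """``EP1 - EP2`` as a function of the hospital frequency ``y``."""
    p = params
    return (p.u1 - p.s1 - p.c2 - p.u2 + p.s2) + (p.c2 - p.c1) * y


def hospital_advantage(params: GameParameters, x: float) -> float:
    """``EH1 - EH2`` as a function of the patient frequency ``x``."""
    p = params
    return (p.p1 + p.p2 - p.p3) * x - p.c3


def rhs(params: GameParameters, x: float, y: float) -> tuple[float, float]:
    """Replicator right-hand side on raw floats (no state validation).

    Used by the ODE integrator, which momentarily steps outside the unit
    square by amounts bounded by the solver tolerance.
    """
    dx = x * (1.0 - x) * patient_advantage(params, y)
    dy = y * (1.0 - y) * hospital_advantage(params, x)
    return dx, dy


def replicator_rhs(params: GameParameters, state: PopulationState) -> Velocity:
    """Replicator velocity at a validated population state.

    Each strategy's frequency grows in proportion to the gap between its
    expected payoff and the population mean, which for two strategies
    reduces to ``x(1-x)(EP1-EP2)`` and ``y(1-y)(EH1-EH2)``.  The boundary
    faces of the unit square are therefore invariant.
    """
    dx, dy = rhs(params, state.x, state.y)
    return Velocity(dx_dt=dx, dy_dt=dy)


def iter_param_names() -> Iterable[str]:
    return iter(PARAM_NAMES)
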