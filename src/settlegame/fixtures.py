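"""Deterministic random parameter-set generators.

Used both as a CLI verb and as the fixture source for property tests:
`generate_random_parameters` rejection-samples the canonical parameter
regime, `generate_scenario_parameters` additionally targets one of the
seven scenario sign patterns.  Scenario 5 (and only scenario 5) requires
``c1 > c2``; for it the patient-side canonical constraints are relaxed and
the relaxation is recorded on the returned object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .equilibria import classify_scenario
from .model import GameParameters, PARAM_NAMES, validate_parameters

__all__ = [
    "FixtureRequest",
    "ScenarioFixtures",
    "GenerationError",
    "generate_random_parameters",
    "generate_scenario_parameters",
]

#: Default sampling box per parameter.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    name: (0.2, 10.0) for name in PARAM_NAMES
}


class GenerationError(RuntimeError):
    """Rejection sampling exhausted its attempt budget."""


@dataclass(frozen=True)
class FixtureRequest:
    """A request for sampled parameter sets.

    ``scenario`` is a scenario index 1..7 or None for unconstrained
    (canonical-regime) sampling.
    """

    count: int
    seed: int
    scenario: int | None = None
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    max_attempts: int = 200_000

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be at least 1")
        if self.scenario is not None and self.scenario not in range(1, 8):
            raise ValueError("scenario must be in 1..7 or None")
        unknown = set(self.bounds) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown bound keys: {sorted(unknown)}")
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")


@dataclass(frozen=True)
class ScenarioFixtures:
    """Sampled parameter sets targeting one scenario."""

    scenario: int
    parameters: tuple[GameParameters, ...]
    relaxed_constraints: tuple[str, ...] = ()
    note: str | None = None


def _propose(rng: np.random.Generator, bounds: dict[str, tuple[float, float]]) -> GameParameters:
    full = {**DEFAULT_BOUNDS, **bounds}
    return GameParameters(
        **{name: float(rng.uniform(*full[name])) for name in PARAM_NAMES}
    )


def generate_random_parameters(request: FixtureRequest) -> list[GameParameters]:
    """Sample ``count`` parameter sets satisfying all canonical constraints.

    Deterministic given the seed; raises :class:`GenerationError` if the
    attempt budget is exhausted.
    """
    rng = np.random.default_rng(request.seed)
    out: list[GameParameters] = []
    for _ in range(request.max_attempts):
        candidate = _propose(rng, request.bounds)
        if not validate_parameters(candidate):
            out.append(candidate)
            if len(out) == request.count:
                return out
    raise GenerationError(
        f"could not sample {request.count} canonical parameter sets in "
        f"{request.max_attempts} attempts"
    )


# Canonical constraints that scenario 5 is incompatible with: its sign
# pattern forces the patient advantage to *decrease* with y, i.e. c1 > c2.
_PATIENT_SIDE = ("u1 > u2", "s1 < s2", "c1 < c2", "p1 > p3")


def generate_scenario_parameters(request: FixtureRequest) -> ScenarioFixtures:
    """Sample parameter sets whose strict sign pattern matches a scenario.

    Canonical constraints are enforced whenever they are jointly satisfiable
    with the scenario conditions.  If the first half of the attempt budget
    produces nothing (scenario 5: provably infeasible with ``c1 < c2``), the
    patient-side canonical constraints are relaxed for the second half and
    the relaxation is recorded; ``c3 > 0`` and ``p2 > 0`` always hold.
    """
    if request.scenario is None:
        raise ValueError("request must name a scenario (1..7)")
    rng = np.random.default_rng(request.seed)
    out: list[GameParameters] = []
    # Scenario 5 needs the patient advantage positive at y=0 but negative at
    # y=1, and the advantage slope is c2 - c1: provably infeasible under the
    # canonical c1 < c2, so relax immediately rather than waste the budget.
    relaxed = request.scenario == 5
    half = request.max_attempts // 2
    for attempt in range(request.max_attempts):
        candidate = _propose(rng, request.bounds)
        if candidate.c3 <= 0 or candidate.p2 <= 0:
            continue
        if not relaxed and attempt >= half and not out:
            relaxed = True
        if not relaxed and validate_parameters(candidate):
            continue
        if classify_scenario(candidate).scenario_id == request.scenario:
            out.append(candidate)
            if len(out) == request.count:
                break
    if len(out) < request.count:
        raise GenerationError(
            f"could not sample {request.count} scenario-{request.scenario} "
            f"parameter sets in {request.max_attempts} attempts"
        )
    if relaxed:
        return ScenarioFixtures(
            scenario=request.scenario,
            parameters=tuple(out),
            relaxed_constraints=_PATIENT_SIDE,
            note=(
                f"scenario {request.scenario} is incompatible with the canonical "
                "patient-side constraints; sampling relaxed "
                + ", ".join(_PATIENT_SIDE)
            ),
        )
    return ScenarioFixtures(scenario=request.scenario, parameters=tuple(out))
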