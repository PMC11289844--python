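"""One-parameter sensitivity sweeps with switch-threshold detection.

A sweep varies a single payoff coefficient over an ordered grid (integers
by default), re-runs the equilibrium analysis and a basin scan at every
value, and locates the value at which the limiting strategy of one
population flips.  Because both payoff differences are affine in every
parameter, each sweep also carries the *exact* real-valued zero crossings
of the advantage expressions, which bracket-free verify the integer-grid
switches.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

from .equilibria import (
    ScenarioClassification,
    classify_scenario,
    find_ess,
)
from .model import GameParameters, PARAM_NAMES, baseline_parameters
from .dynamics import BasinScanResult, IntegrationSettings, basin_scan, interior_grid
from .model import PopulationState

__all__ = [
    "AffineAdvantage",
    "SweepSpec",
    "SweepRecord",
    "SweepResult",
    "Threshold",
    "analytic_advantage",
    "patient_drift_sign",
    "hospital_drift_sign",
    "sweep",
    "detect_threshold",
]


@dataclass(frozen=True)
class AffineAdvantage:
    """An affine payoff difference ``intercept + slope * z`` for z in [0, 1]."""

    intercept: float
    slope: float

    def value_at(self, z: float) -> float:
        return self.intercept + self.slope * z

    @property
    def endpoints(self) -> tuple[float, float]:
        return (self.intercept, self.intercept + self.slope)

    def sign_on_interval(self) -> int:
        """+1 / -1 if the expression keeps that sign on the open interval
        (and is not identically zero); 0 when it changes sign or vanishes."""
        v0, v1 = self.endpoints
        if v0 >= 0.0 and v1 >= 0.0 and (v0 > 0.0 or v1 > 0.0):
            return 1
        if v0 <= 0.0 and v1 <= 0.0 and (v0 < 0.0 or v1 < 0.0):
            return -1
        return 0


def analytic_advantage(
    params: GameParameters,
) -> tuple[AffineAdvantage, AffineAdvantage]:
    """The two advantage expressions in closed form.

    Returns ``(patient, hospital)`` where the patient advantage
    ``EP1 - EP2 = (u1-s1-c2-u2+s2) + (c2-c1) y`` is affine in the hospital
    frequency and the hospital advantage
    ``EH1 - EH2 = -c3 + (p1+p2-p3) x`` is affine in the patient frequency.
    """
    p = params
    patient = AffineAdvantage(
        intercept=p.u1 - p.s1 - p.c2 - p.u2 + p.s2, slope=p.c2 - p.c1
    )
    hospital = AffineAdvantage(intercept=-p.c3, slope=p.p1 + p.p2 - p.p3)
    return patient, hospital


def patient_drift_sign(params: GameParameters) -> int:
    """Sign of dx/dt throughout the open square (+1, -1, or 0 if mixed)."""
    return analytic_advantage(params)[0].sign_on_interval()


def hospital_drift_sign(params: GameParameters) -> int:
    """Sign of dy/dt throughout the open square (+1, -1, or 0 if mixed)."""
    return analytic_advantage(params)[1].sign_on_interval()


@dataclass(frozen=True)
class SweepSpec:
    """Specification of a one-parameter sweep.

    ``values`` must be strictly monotone and should start at the end whose
    behaviour serves as the reference for threshold detection.
    """

    parameter: str
    values: tuple[float, ...]
    baseline: GameParameters = dc_field(default_factory=baseline_parameters)
    starts: tuple[PopulationState, ...] | None = None
    settings: IntegrationSettings | None = None

    def __post_init__(self) -> None:
        if self.parameter not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        values = tuple(float(v) for v in self.values)
        if not values:
            raise ValueError("sweep needs at least one value")
        diffs = [b - a for a, b in zip(values, values[1:])]
        if diffs and not (all(d > 0 for d in diffs) or all(d < 0 for d in diffs)):
            raise ValueError("sweep values must be strictly monotone")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class SweepRecord:
    """Analysis outcome at one swept value."""

    value: float
    params: GameParameters
    scenario: ScenarioClassification
    ess: tuple[tuple[float, float], ...]
    basin: BasinScanResult
    patient_drift: int
    hospital_drift: int

    @property
    def basin_limit(self) -> tuple[float, float] | None:
        return self.basin.unanimous_limit


@dataclass(frozen=True)
class Threshold:
    """A detected strategy switch along a sweep."""

    value: float | None
    direction: str
    ambiguous: bool


@dataclass(frozen=True)
class SweepResult:
    """Per-value records plus detected switches and analytic crossings."""

    parameter: str
    values: tuple[float, ...]
    records: tuple[SweepRecord, ...]
    analytic_crossings: dict[str, float]
    notes: tuple[str, ...]
    patient_switch: Threshold
    hospital_switch: Threshold

    def _coords(self, player: str) -> list[float | None]:
        return _limit_coords(self.records, player)

    def values_with_coordinate(self, player: str, coordinate: float) -> list[float]:
        """Swept values whose unanimous basin limit has the given coordinate."""
        return [
            v for v, c in zip(self.values, self._coords(player)) if c == coordinate
        ]

    def largest_value_with_drift(self, player: str, sign: int) -> float | None:
        """Largest swept value whose analytic drift has the given sign."""
        picks = [
            r.value
            for r in self.records
            if (r.patient_drift if player == "patient" else r.hospital_drift) == sign
        ]
        return max(picks) if picks else None


def _advantage_crossings(spec: SweepSpec) -> dict[str, float]:
    """Exact zero crossings of the four advantage endpoints in the swept range.

    Every endpoint expression is affine in every single parameter, so two
    evaluations determine the root exactly.
    """
    lo, hi = min(spec.values), max(spec.values)
    crossings: dict[str, float] = {}
    names = (
        "patient_advantage_indirect",   # EP1-EP2 at y=0
        "patient_advantage_direct",     # EP1-EP2 at y=1
        "hospital_advantage_no_uptake",  # EH1-EH2 at x=0
        "hospital_advantage_full_uptake",  # EH1-EH2 at x=1
    )

    def endpoints(value: float) -> tuple[float, ...]:
        p = spec.baseline.replace(**{spec.parameter: value})
        pat, hosp = analytic_advantage(p)
        return (*pat.endpoints, *hosp.endpoints)

    at_lo = endpoints(lo)
    at_hi = endpoints(hi)
    for name, f_lo, f_hi in zip(names, at_lo, at_hi):
        slope = (f_hi - f_lo) / (hi - lo) if hi != lo else 0.0
        if slope == 0.0:
            continue
        root = lo - f_lo / slope
        if lo <= root <= hi:
            crossings[name] = root
    return crossings


def sweep(spec: SweepSpec) -> SweepResult:
    """Run the full analysis at every value of the sweep grid.

    At each value the scenario classification, the Jacobian-based ESS set,
    the analytic drift signs and a basin scan are recorded; canonical
    parameter constraints are intentionally not enforced, because sweeps
    routinely cross them.  Values landing exactly on a degenerate boundary
    classify to scenario None and typically yield a non-unanimous basin.
    """
    starts = spec.starts if spec.starts is not None else tuple(interior_grid())
    settings = spec.settings or IntegrationSettings()
    records = []
    for value in spec.values:
        params = spec.baseline.replace(**{spec.parameter: value})
        scenario = classify_scenario(params)
        ess = tuple(p.coords for p in find_ess(params))
        basin = basin_scan(params, starts, settings)
        records.append(
            SweepRecord(
                value=value,
                params=params,
                scenario=scenario,
                ess=ess,
                basin=basin,
                patient_drift=patient_drift_sign(params),
                hospital_drift=hospital_drift_sign(params),
            )
        )
    records = tuple(records)
    crossings = _advantage_crossings(spec)
    notes = tuple(
        f"{name} crosses zero at {spec.parameter} = {root:g}; the integer-grid "
        "switch brackets this analytic boundary"
        for name, root in sorted(crossings.items())
    )
    return SweepResult(
        parameter=spec.parameter,
        values=spec.values,
        records=records,
        analytic_crossings=crossings,
        notes=notes,
        patient_switch=_detect(spec.values, _limit_coords(records, "patient"), "up"),
        hospital_switch=_detect(spec.values, _limit_coords(records, "hospital"), "up"),
    )


def _limit_coords(records: tuple[SweepRecord, ...], player: str) -> list[float | None]:
    if player not in ("patient", "hospital"):
        raise ValueError(f"unknown player {player!r}")
    idx = 0 if player == "patient" else 1
    return [
        r.basin_limit[idx] if r.basin_limit is not None else None for r in records
    ]


def detect_threshold(
    result: SweepResult, player: str, direction: str = "up"
) -> Threshold:
    """Locate the swept value at which the player's limiting strategy flips.

    The reference coordinate is the unanimous basin limit at the first
    (reference-end) value of the sweep; scanning in list order, the first
    value whose unanimous coordinate differs is the switch.  ``direction``
    selects which side of the flip to report: ``"up"`` returns the first
    flipped value, ``"down"`` the last value before the flip.  Values
    without a unanimous limit (degenerate boundaries, unconverged runs) are
    skipped but set the ambiguity flag when they occur at or before the
    flip.
    """
    return _detect(result.values, _limit_coords(result.records, player), direction)


def _detect(
    values: tuple[float, ...], coords: list[float | None], direction: str
) -> Threshold:
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    reference: float | None = None
    ref_index = 0
    for i, c in enumerate(coords):
        if c is not None:
            reference, ref_index = c, i
            break
    if reference is None:
        return Threshold(value=None, direction=direction, ambiguous=True)
    flip_index: int | None = None
    for i in range(ref_index + 1, len(coords)):
        if coords[i] is not None and coords[i] != reference:
            flip_index = i
            break
    if flip_index is None:
        ambiguous = any(c is None for c in coords)
        return Threshold(value=None, direction=direction, ambiguous=ambiguous)
    ambiguous = any(c is None for c in coords[: flip_index + 1])
    if direction == "up":
        value = values[flip_index]
    else:
        value = values[flip_index - 1]
    return Threshold(value=value, direction=direction, ambiguous=ambiguous)
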