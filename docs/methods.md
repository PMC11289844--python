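# Methods

## The game and its assumptions

`settlegame` models the interaction between two large, boundedly rational
populations: patients with malignant tumours deciding where to seek care,
and hospitals deciding whether to operate direct (real-time) settlement of
cross-regional insurance claims.  Individuals revise strategies gradually
by payoff comparison rather than jumping to a best response, which is
exactly the regime replicator dynamics describes: a strategy's frequency
grows in proportion to the gap between its expected payoff and the
population average.

The stage game is a 2×2 bimatrix built from ten dimensionless
coefficients.  A travelling patient earns `u1 - s1 - c1` against a
direct-settlement hospital and `u1 - s1 - c2` otherwise (`c1 < c2`: direct
settlement removes the cash-advance and paperwork burden of a
cross-regional episode, not the travel itself).  A patient staying in
area earns `u2 - s2` either way.  A direct-settlement hospital pays the
input cost `c3` unconditionally and earns `p1 + p2` per travelling
patient; an indirect-settlement hospital earns `p3` per travelling
patient and nothing otherwise.  The canonical regime — `u1 > u2`,
`s1 < s2`, `c1 < c2`, `p1 > p3`, `p2 > 0`, `c3 > 0` — encodes the stylised
facts the model rests on: specialist regions offer higher treatment
utility and (through richer insurance catalogues) lower out-of-pocket
medical costs, direct settlement lowers nonmedical costs, and serving
cross-regional patients under direct settlement is more rewarding but
requires up-front investment.

Deliberately out of scope: pandemic-era mobility restrictions, hospital
tier or province heterogeneity, stochastic (Moran/Wright–Fisher) dynamics,
multi-population extensions, and any empirical calibration — the
coefficients are stylised, not estimated.

## Dynamics and stability analysis

Both payoff differences are affine, so the replicator field is a smooth
cubic polynomial on the unit square and every face of the square is
invariant.  The equilibrium structure is computed in closed form: the four
corners always; the interior candidate `D(x0, y0)` exists only when both
defining fractions lie strictly inside (0, 1), and a vanishing denominator
(`p1 + p2 = p3` or `c1 = c2`) is flagged rather than raised.  Stability is
classified from the analytic Jacobian by the determinant/trace rule with
an absolute degeneracy tolerance (default `1e-12`, appropriate for pure
algebra on user-supplied scalars): `det > tol` and `trace < -tol` is an
ESS, `det < -tol` a saddle, `det > tol` with `trace > tol` unstable, and
anything within the tolerance band — including the zero-trace interior
candidate — degenerate, never an ESS.  At corners the off-diagonal
Jacobian entries vanish identically, so determinant and trace are exactly
the product and sum of the diagonal entries.

The scenario taxonomy re-expresses the classification in terms of three
numbers: the patient advantage at `y = 0` (`d1`) and `y = 1` (`d2`) and
the hospital advantage at `x = 1` (`h1`).  Seven of the eight strict sign
patterns of `(d1, h1, d2)` form the named scenarios with their predicted
ESS sets; the eighth pattern (`d1 > 0, h1 > 0, d2 < 0`) requires
`c1 > c2` and carries no scenario index.  Because `d2 - d1 = c2 - c1`,
scenario 5 (`d1 > 0, d2 < 0`) is likewise infeasible in the canonical
regime; the scenario-targeted fixture generator therefore relaxes the
patient-side constraints for scenario 5 and records the relaxation.  Sign
comparisons are strict and exact: a parameter set with any expression
exactly zero is a degenerate boundary, classified as "no scenario" with a
boundary flag instead of being silently assigned.  `find_ess`
cross-checks the Jacobian-based ESS set against the taxonomy's prediction
whenever a scenario matches and raises on disagreement (possible only
within the degeneracy tolerance of a boundary).

## Numerical integration

The ODE solver is SciPy's adaptive explicit Runge–Kutta 4(5); the RHS is a
smooth cubic, so stiff methods are unnecessary.  Integration proceeds in
windows of 25 time units up to `t_max = 500`.  After each window the state
is clipped to the unit square — the square is exactly invariant, so raw
overshoot is bounded by the solver tolerance and is recorded on the
trajectory as a diagnostic (`max_overshoot`, asserted ≤ 1e-9 in the
tests).  Convergence is declared when the state lies within
`conv_eps = 1e-4` (max norm) of a corner *and* the velocity max norm is
below `stall_eps = 1e-9`; runs that reach `t_max` without meeting both
tests are reported unconverged with `limit = None`, never raised.

The solver tolerances default to `rel_tol = 1e-10`, `abs_tol = 1e-12`.
These are deliberately several orders below `stall_eps`: near an
attracting corner the numerical solution plateaus at a distance set by the
local truncation error, and the velocity there is roughly (plateau
distance × payoff advantage).  With looser tolerances (e.g. `1e-8`) the
plateau sits near `1e-9` and the stall test can never pass; at the chosen
defaults the plateau is ~`1e-12` and the stall velocity ~`1e-11`, well
under the threshold for advantage magnitudes up to the tested sampling
range.

Basin scans integrate from the interior lattice `{0.1, ..., 0.9}²` (81
starts) by default.  The boundary value 1.0 is excluded because the faces
`x = 1` and `y = 1` are invariant — a boundary start trivially freezes one
coordinate; `include_boundary=True` restores the full 10×10 lattice for
fidelity runs.  A scan is *unanimous* only when every run converged and
all share one corner limit.

## Sensitivity sweeps and switch detection

A sweep varies one coefficient over a strictly monotone grid (consecutive
integers by default, because the qualitative switches of interest happen
to land on integer trial values) with every other coefficient held at the
sweep's baseline, re-running the scenario classification, the ESS
computation, the analytic drift signs and a basin scan at each value.
Canonical constraints are intentionally not enforced here — one-parameter
sweeps routinely cross them.

Switch detection operates on unanimous basin limits, not single
trajectories: the reference coordinate is the unanimous limit at the first
swept value, and the switch is the first value whose unanimous coordinate
differs.  `direction="up"` reports that first flipped value,
`direction="down"` the last value before the flip.  Grid values without a
unanimous limit — typically degenerate boundaries, where an advantage is
zero on one edge of the square and trajectories settle on a non-corner
edge point — are skipped but raise an ambiguity flag when they occur at or
before the flip.  Because every advantage endpoint is affine in every
single coefficient, each sweep also reports the *exact* real-valued zero
crossings of the four endpoint expressions inside the swept range; these
bracket the integer-grid switches and expose cases where the analytic
boundary does not coincide with any simulated flip value (for the
hospital input-cost sweep the analytic switch is at `c3 = p1 + p2 - p3`,
i.e. 3 at the reference set, with the grid flipping between 2 and 4
around the degenerate value 3).

A separate drift criterion answers "does the whole interior still move
toward a strategy?": the patient drift sign is +1 when the advantage is
nonnegative at both edge values of `y` and positive at one of them.  This
distinguishes a value where the flow still points toward cross-regional
care everywhere in the open square (drift +1, even though the corner
itself is not reached because the hospital frequency collapses first)
from a value where the advantage genuinely changes sign.

## Fixture generators

`generate_random_parameters` rejection-samples uniform proposals from
per-parameter boxes (default `(0.2, 10)`) until the canonical regime
holds; `generate_scenario_parameters` additionally filters on one
scenario's strict sign pattern, keeping `c3 > 0` and `p2 > 0` always and
relaxing the patient-side canonical constraints only when the scenario
requires it (scenario 5, provably; or as a fallback after half the
attempt budget).  Both are deterministic given the seed.  These synthetic
parameter sets emulate the *structure* of the game — they exercise every
scenario and every stability type — but not empirical magnitudes: passing
tests demonstrate correctness of the algebra, classification and
integration, not that any particular real-world population sits in a
particular scenario.

## Known limitations

* The taxonomy classifies only strict-sign regimes; degenerate boundaries
  are detected and flagged but their centre-manifold dynamics are not
  analysed.
* Unconverged runs at degenerate values depend mildly on `t_max`; only
  their non-corner character, never their precise endpoint, is used by the
  threshold logic.
* The interior candidate is reported with its existence flag but is not
  stability-classified beyond "not an ESS" (zero trace).
* Replicator dynamics assumes infinitely large, well-mixed populations;
  finite-population or networked effects are out of scope.
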