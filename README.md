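# settlegame

Replicator-dynamics analysis of the two-population game between **patients
with malignant tumours** — who choose between *cross-regional treatment*
(seeking care outside the region where their health insurance is pooled)
and *in-area medical care* — and **hospitals**, who choose whether to
operate *direct settlement* (real-time insurance reimbursement of
cross-regional claims at the point of care) or leave patients to advance
the full cost and claim it back at home (*indirect settlement*).

The package is aimed at health-services researchers who want to study how
settlement policy and treatment-seeking behaviour co-evolve: it computes
payoffs and expected payoffs, enumerates equilibria, classifies their local
stability, simulates evolutionary trajectories, and sweeps single
parameters to locate the values at which the stable strategy of either
population switches.

## Model

Ten dimensionless coefficients describe the stage game: patient utilities
`u1 > u2` (cross-regional vs in-area), patient medical costs `s1 < s2`,
patient nonmedical costs `c1 < c2` (with vs without direct settlement),
hospital input cost `c3 > 0`, and hospital benefits `p1 > p3` (financial,
with vs without direct settlement) and `p2 > 0` (technological
advancement).  With `x` the frequency of patients who travel and `y` the
frequency of hospitals that settle directly, the replicator dynamics are

```
dx/dt = x(1-x) (EP1 - EP2),   EP1 - EP2 = (u1 - s1 - c2 - u2 + s2) + (c2 - c1) y
dy/dt = y(1-y) (EH1 - EH2),   EH1 - EH2 = (p1 + p2 - p3) x - c3
```

The system has the four corner equilibria plus one interior candidate
`D(x0, y0)` with `x0 = c3/(p1+p2-p3)` and
`y0 = (c2+s1-s2-u1+u2)/(c2-c1)`.  A corner is an evolutionarily stable
strategy (ESS) when its Jacobian has positive determinant and negative
trace; the interior candidate has zero trace and is never an ESS.  The
strict signs of three affine payoff differences — the patient advantage at
`y=0` and at `y=1`, and the hospital advantage at `x=1` — partition
parameter space into **seven scenarios**, each with a predicted ESS set
(two scenarios are bistable-free cooperation outcomes: scenario 4 admits
both `(0,0)` and `(1,1)`; only scenario 7 sustains `(1,1)` alone).

## Worked example

```
$ settlegame analyze --baseline
scenario: 6
ess: [[1.0, 0.0]]
basin unanimous limit: [1.0, 0.0]
```

At the reference coefficients (`u1=6, u2=4, s1=3, s2=4, c1=0.5, c2=1,
c3=4, p1=7, p2=2, p3=6`) the game sits in scenario 6: the patient
advantage `2 + 0.5y` is positive everywhere, the hospital advantage
`3x - 4` negative everywhere, so from every interior starting point the
population converges to `(1, 0)` — patients travel for treatment, while
hospitals decline to settle directly.  The same conclusion holds from all
81 initial conditions on the interior 0.1-step grid (`basin unanimous
limit` above).

Sensitivity sweeps locate the integer parameter values at which that
outcome flips, e.g. the hospitals' financial benefit:

```
$ settlegame sweep --baseline --parameter p1 --values 7:12
patient switch: Threshold(value=None, direction='up', ambiguous=True)
hospital switch: Threshold(value=9.0, direction='up', ambiguous=True)
note: hospital_advantage_full_uptake crosses zero at p1 = 8; the integer-grid switch brackets this analytic boundary
```

Hospitals begin to adopt direct settlement once `p1` reaches 9 (the
underlying analytic boundary is `p1 = 8`, where the advantage at full
patient uptake is exactly zero; the flag marks that degenerate grid
value).  Patients never change strategy along this sweep.

The same library surface is available from Python:

```python
from settlegame import baseline_parameters, classify_scenario, find_ess

params = baseline_parameters()
print(classify_scenario(params).scenario_id)   # 6
print([p.coords for p in find_ess(params)])    # [(1.0, 0.0)]
```

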