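# Methods

## The model

`chronicsim` simulates the management of a typical chronic-disease pathway
in a tax-financed (Beveridge-type) health system, at the level of a local
health authority. It is a deterministic stock-and-flow (system-dynamics)
model: a closed population moves through compartments

```
reference population ──incidence──▶ phase 1 ──progression──▶ phase 2
                                        ──hospitalisation──▶ inpatient
inpatient ──discharge──▶ reference population
```

with each chronic phase split into an *undetected* pool and an *in-care*
pool. Two capacity-constrained services act on the pathway:

* **Screening.** A campaign with capacity `screener_staff ×
  screener_productivity` screens the undiagnosed community (reference
  population plus undetected phase-1/2) at its prevalence, moving detected
  patients into the in-care pools. Detections in phase *i* are
  `capacity × phase_i_undetected / community`.
* **Primary care.** GPs can effectively take in charge `gp_staff ×
  gp_panel` patients. The *coverage* `min(1, GP capacity / in-care
  caseload)` determines, as a population-average blend, how much of the
  in-care pool actually enjoys the slowed disease course: an in-care
  phase-1 patient progresses at `coverage·p1_c + (1−coverage)·p1_u`, and
  analogously for phase-2 admission rates (`h2_c` vs `h2_u`). Blending
  (rather than triaging named individuals) is the natural aggregate-SD
  reading of partial capacity.

Hospitalisation is the acute manifestation of the disease and the
system's negative outcome; admissions are costed at a DRG tariff, and
screening staff and GPs at annual unit costs. Three cumulative cost
stocks and a cumulative admissions stock run alongside the population.

### Discharge routing

What happens after the acute episode is a genuinely open structural
choice. The package supports both routings via
`disease.discharge_destination`:

* `reference_population` (default): the episode resolves and the patient
  re-enters the community, where they remain exposed to incidence and
  re-screening. This keeps the diseased pool non-absorbing, which is what
  makes the extreme-condition validation meaningful (with incidence zero
  the diseased total must drain monotonically to zero — impossible if
  phase 2 is absorbing) and keeps the standing GP caseload bounded.
* `phase2_in_care`: hospitalisation entails diagnosis and structured
  follow-up. Under this routing phase 2 is absorbing: every patient who
  ever progresses eventually accumulates in the in-care pool. It is kept
  as an option for sensitivity analysis.

A useful consequence of the default routing: each phase-2 patient exits
the diseased pool through exactly one admission, so the *cumulative*
admission count over a long horizon is driven by how many people ever
reach phase 2 — i.e. by slowed phase-1 progression — while the cared
admission rate `h2_c` mostly shifts admissions in time. This is why
expanding primary care alone (without finding patients to care for) buys
little outcome and little cost relief, whereas expanding screening does:
the two staffing levers are structurally asymmetric.

## Staffing policies

* **Fixed** (stage-1 scenarios): screener and GP head counts are
  exogenous constants.
* **Endogenous** (stage-2): desired head counts are computed from the
  system's own state — screening demand (`community /
  screening_interval`) over productivity, and the in-care caseload over
  the GP panel — and actual staffing adjusts toward them with a
  first-order exponential lag (the classical SMOOTH construct). Staff
  counts are continuous; downsizing is allowed by default and can be
  disabled.

Two adjustment times are used: `adjustment_time = 0.25` yr for screening
staff (short-contract public-health hires, filled within a quarter) and
`adjustment_time_gps = 1.75` yr for GP capacity (expanding GP
conventions is a multi-year negotiation). The asymmetry matters for the
short-run cost signature of the endogenised policy: the immediate
spending bump comes from rapid screening recruitment, while GP capacity
— whose marginal patient-level value is realised as soon as capacity
exists — expands slowly enough that total spending rises before it
falls.

## Performance indicators

| Indicator | Definition | Target |
|---|---|---|
| Outcome PI | inpatients / total population (hospitalisation rate) | the endogenised-run benchmark trajectory |
| Screening PI | screening capacity / screening demand | 1 |
| Primary-care PI | GP capacity / in-care population | 1 |

Capacity = demand is exactly the fixed point of the endogenous policy,
so the two capacity indicators tend to 1 under it, up to the first-order
lag. The Screening PI denominator converts the eligible population into
a per-year throughput need via the target re-screening interval (default
5 yr), making the indicator dimensionless. The Primary-care PI
denominator is the *standing* in-care caseload, not the historical count
of screening events: capacity must serve the people currently in care. A
secondary column, annualised admissions per 1,000 population, is emitted
with every KPI series. Observed outcome series can be benchmarked
against a stored reference (typically the endogenised run) with signed
relative deviations and a configurable flagging tolerance (default 10%).

## Numerics

Explicit Euler integration with synchronous rate evaluation (all rates
computed on the start-of-step state, then applied), default step dt =
1/12 yr over a 4-year horizon. First-order convergence is verified
against the exponential-decay closed form. Every flow is donor-limited:
an outflow cannot exceed `donor stock / dt`, and when several outflows
compete for one stock they are scaled proportionally so the stock
empties exactly rather than going negative. Consequently all stocks stay
nonnegative for any step size, and closed sub-systems conserve mass to
1e-9 relative. Flows are unidirectional (negative rates abort with a
diagnostic naming the flow), except the staffing adjustment flows, which
carry a signed net rate whose negative side is donor-limited against the
staffing stock. Auxiliaries are evaluated in declaration order, which
must be a topological order (no algebraic loops). Units are carried as
strings and flows are rejected at build time unless their declared unit
is `<stock unit>/year`. The engine uses no random numbers; identical
inputs give bit-identical trajectories, and a run can be replayed
exactly from its config snapshot.

One discretisation artifact is worth knowing: with the default length of
stay (10 days, discharge rate 36.5/yr) the discharge flow is
donor-limited at a monthly step, so the inpatient stock behaves as if
the stay lasted one step. The hospitalisation *rate* and all cost and
cumulative quantities are unaffected; only the instantaneous inpatient
census (and hence the Outcome PI level, not its scenario ordering)
scales with dt. Use a finer dt if the census level itself matters.

## Default parameter ledger

All values are plain-text config keys; units in parentheses.

| Parameter | Default | Meaning |
|---|---|---|
| initial stocks | 859,000 / 30,000 / 50,000 / 10,000 / 30,000 / 1,000 | reference, phase1 u/c, phase2 u/c, inpatient (persons; total 980,000) |
| incidence_rate | 0.01 /yr | disease onset from the reference population |
| p1_u, p1_c | 0.15, 0.05 /yr | phase-1→2 progression, natural vs properly cared |
| h2_u, h2_c | 0.35, 0.10 /yr | phase-2 admission rate, natural vs properly cared |
| discharge_rate | 36.5 /yr | 1 / mean length of stay (10 days) |
| screener_productivity | 4,000 screens/staff/yr | |
| screening_interval | 5 yr | target re-screening period of the community |
| gp_panel | 100 patients/GP | chronic patients effectively taken in charge |
| screener_salary / gp_cost / drg_tariff | €35,000 / €15,000 / €8,000 | unit costs (GP figure: chronic-care share) |
| adjustment_time / adjustment_time_gps | 0.25 / 1.75 yr | hiring lags under the endogenous policy |

Only the scenario staffing levels (5 vs 15 screeners, 700 vs 1,000 GPs)
and the 4-year horizon are externally fixed; the epidemiological and
cost values are a documented calibration chosen so that the default
system reproduces the qualitative behaviour the scenarios are meant to
exhibit — an as-is system understaffed in both upstream settings
(Screening PI ≈ 0.11, Primary-care PI ≈ 0.88–0.99), a GP-only expansion
that raises spending while barely moving the hospitalisation rate, a
screening expansion that clearly improves it, and an endogenised policy
that spends more in the short term, crosses below every fixed run's cost
rate during the second year, and is both the cheapest and the
best-performing over four years. These qualitative orderings, not any
single parameter value, are the binding constraint; the suite in
`tests/test_acceptance.py` checks them.

## What the simulator does and does not capture

The model is aggregate and deterministic: no stochastic incidence, no
age/sex structure, no births or deaths (defensible over a 4-year
horizon; a mortality sink is a natural extension point), a single
disease, no budget constraint or training pipeline on hiring, and
coverage as a population-average blend rather than patient-level triage.
Passing tests therefore demonstrate internal consistency and the
structural logic of capacity-balanced prevention — not a forecast for
any real region. Real screening campaigns also have participation,
sensitivity and specificity below 1; here a screen of an undetected
case always detects it, so `screener_productivity` should be read as
*effective* screens per staff-year.

## Scenario presets

| Preset | Policy | Screeners | GPs |
|---|---|---|---|
| run1 | fixed ("as-is", understaffed) | 5 | 700 |
| run2 | fixed ("primary care") | 5 | 1,000 |
| run3 | fixed ("screening") | 15 | 1,000 |
| run4 | endogenous, starting from the as-is levels | 5 → demand-driven | 700 → demand-driven |

`compare()` reports end-of-horizon Outcome PI, cumulative costs by
setting, their orderings (always recomputed from the stored scalars),
and the cost-rate crossover time: the first output time at which the
endogenous run's instantaneous total cost rate falls below every fixed
run's (1.42 yr with the defaults). Sweeps rerun a scenario over a list
of values for one dot-path parameter and tabulate end outcome and total
cost.

## Problem sizes

The shipped analyses are small by construction: a 4-year horizon at a
monthly step is 48 integration steps over 12 stocks; the extended
endogenised run uses a 10-year horizon (120 steps); the extreme-condition
drain check uses 100 years (1,200 steps). The full four-preset
comparison completes in well under a second.
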