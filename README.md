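# chronicsim

A system-dynamics simulator of a chronic-care prevention pathway for
health-policy "what-if" analysis: screening → primary-care
take-in-charge → slowed disease progression → fewer hospitalisations,
with full cost accounting and demand-driven staffing policies.

It is aimed at health-services researchers and planners who want to
reason about how resources split between *prevention* (screening
campaigns) and *primary care* (GP capacity) shape a population outcome —
the hospitalisation rate — that responds only with long delays, making
real-world experimentation impossible.

## The model in brief

A closed population of N persons flows through compartments

```
Reference ──incidence──▶ Phase 1 ──progression──▶ Phase 2 ──admission──▶ Inpatient
    ▲                                                                        │
    └────────────────────────────── discharge ───────────────────────────────┘
```

with each chronic phase split into *undetected* and *in-care* pools.
Screening (capacity `staff × productivity` screens/yr, sampling the
community at prevalence) moves patients into care; GP coverage
`c = min(1, gp_staff × panel / in-care)` slows the cared disease course
as a population-average blend, e.g. phase-1 progression
`c·p1_c + (1−c)·p1_u`. Integration is explicit Euler (dt = 1/12 yr)
with donor-limited flows, so the model is deterministic, conservative
and nonnegative by construction. Three indicators are tracked:

* **Outcome PI** = inpatients / total population (hospitalisation rate),
* **Screening PI** = screening capacity / screening demand (target 1),
* **Primary-care PI** = GP capacity / in-care caseload (target 1),

where capacity = demand is precisely the fixed point of the endogenous
staffing policy (first-order adjustment of head counts toward
demand-implied need). See `docs/methods.md` for the full model account.

## Worked example

Compare the four shipped scenarios — as-is (5 screeners / 700 GPs), more
GPs (5/1,000), more screening (15/1,000), and endogenised demand-driven
staffing — over four years:

```bash
chronicsim compare --scenarios run1,run2,run3,run4 --out results/
```

prints

```
Scenario comparison over 4 years

scenario     end outcome PI   total cost (EUR)
run1            0.000651048        282,643,696
run2             0.00064946        286,701,309
run3            0.000610101        280,656,842
run4            0.000566901        275,937,303

outcome ordering (best first): run4 < run3 < run2 < run1
cost ordering (cheapest first): run4 < run3 < run1 < run2
cost-rate crossover of the endogenous run: 1.417 years
```

Reading: adding 300 GPs alone (run2) raises four-year spending by €4.1M
while cutting the hospitalisation rate by only 0.2% — the extra capacity
has almost nobody new to care for, because the screening stage (capacity
20,000 screens/yr against a demand near 180,000) is the binding
bottleneck. Tripling screening staff (run3) improves the outcome by 6%
*and* costs less than the as-is system, because averted admissions repay
the salaries. Letting both staffing levels follow demand (run4) spends
more in the first months (recruitment), drops below every fixed
scenario's spending rate during the second year, and ends both cheapest
and best. The same library calls are available in Python:

```python
from chronicsim import preset, run_scenario, compare

report = compare([preset(n) for n in ("run1", "run2", "run3", "run4")])
print(report.outcome_ordering)       # ['run4', 'run3', 'run2', 'run1']

res = run_scenario(preset("run4"), horizon=10.0)
print(res.kpis[["screening_pi", "primary_care_pi"]].iloc[-1])
# screening_pi       1.000579
# primary_care_pi    0.963832
```

Other subcommands: `chronicsim run` (one scenario → trajectory/KPI CSVs,
config snapshot, summary JSON), `chronicsim sweep` (one parameter over a
value list), `chronicsim benchmark` (observed KPI CSV vs a reference).
All parameters live in a YAML ledger (see `examples/default_config.yaml`);
any subset may be overridden, unknown keys are rejected, and a saved
config snapshot replays its run byte-identically.

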