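"""The chronic-care prevention pathway as a stock-and-flow model.

The population moves horizontally through disease phases::

    reference_population --incidence--> phase 1 --progression--> phase 2
        --hospitalisation--> inpatient --discharge--> phase 2 (in care)

Each chronic phase is split into an *undetected* pool and an *in-care*
pool.  A screening campaign, capacity-limited by the screening staff,
moves people from the undetected pools into care; general practitioners,
capacity-limited by their number and panel size, then slow progression
and hospitalisation for the fraction of the in-care caseload they can
actually take in charge (the *coverage*).  Under-capacity care is a
population-average blend of the cared and natural rates, not a triage of
specific individuals.

The population is closed: no births, deaths, or recovery, so the six
population stocks sum to a constant.  Phase-1 patients are never admitted
directly; admission happens only from phase 2, and a discharged inpatient
returns to the phase-2 in-care pool (hospitalisation entails diagnosis).

Three cost streams accrue alongside: screening salaries, the GPs'
chronic-care remuneration, and admissions at the DRG tariff.
"""

from __future__ import annotations

from typing import Mapping

from .engine import EXOGENOUS, Auxiliary, Flow, ModelSpec, Stock
from .params import CapacityParams, CostParams, DiseaseParams, InitialStocks
from .staffing import StaffingPolicy, staffing_rates

__all__ = [
    "POPULATION_STOCKS",
    "incidence_flow",
    "screening_detection_flows",
    "care_coverage",
    "progression_flows",
    "hospitalisation_flows",
    "discharge_flow",
    "cost_rates",
    "build_chronic_model",
]

#: The six stocks forming the closed population.
POPULATION_STOCKS = (
    "reference_population",
    "phase1_undetected",
    "phase1_in_care",
    "phase2_undetected",
    "phase2_in_care",
    "inpatient",
)


def incidence_flow(state: Mapping[str, float], disease: DiseaseParams) -> float:
    """Disease onset rate (persons/year), reference -> phase1 undetected."""
    return disease.incidence_rate * state["reference_population"]


def screening_detection_flows(
    state: Mapping[str, float], capacity: CapacityParams
) -> tuple[float, float]:
    """Detection rates (persons/year) into phase-1 and phase-2 care.

    The campaign screens the whole undiagnosed community at prevalence:
    capacity = staff x productivity screens/year, and detections in each
    phase are the throughput times that phase's share of the community.
    Both are zero when the community is empty.
    """
    community = (
        state["reference_population"]
        + state["phase1_undetected"]
        + state["phase2_undetected"]
    )
    if community <= 0:
        return 0.0, 0.0
    throughput = state["screener_staff"] * capacity.screener_productivity
    d1 = throughput * state["phase1_undetected"] / community
    d2 = throughput * state["phase2_undetected"] / community
    return d1, d2


def care_coverage(state: Mapping[str, float], capacity: CapacityParams) -> float:
    """Fraction of the in-care caseload the GPs can actually manage, in [0,1]."""
    in_care = state["phase1_in_care"] + state["phase2_in_care"]
    if in_care <= 0:
        return 1.0
    gp_capacity = state["gp_staff"] * capacity.gp_panel
    return min(1.0, gp_capacity / in_care)


def _blend(coverage: float, cared: float, natural: float) -> float:
    # population-average rate: covered share progresses at the cared rate,
    # the uncovered remainder at the natural rate
    return coverage * cared + (1.0 - coverage) * natural


def progression_flows(
    state: Mapping[str, float], disease: DiseaseParams, coverage: float
) -> tuple[float, float]:
    """Phase1 -> Phase2 rates (persons/year): (undetected, in-care)."""
    up = disease.p1_u * state["phase1_undetected"]
    cp = _blend(coverage, disease.p1_c, disease.p1_u) * state["phase1_in_care"]
    return up, cp


def hospitalisation_flows(
    state: Mapping[str, float], disease: DiseaseParams, coverage: float
) -> tuple[float, float]:
    """Phase2 -> Inpatient admission rates (persons/year): (undetected, in-care)."""
    uh = disease.h2_u * state["phase2_undetected"]
    ch = _blend(coverage, disease.h2_c, disease.h2_u) * state["phase2_in_care"]
    return uh, ch


def discharge_flow(state: Mapping[str, float], disease: DiseaseParams) -> float:
    """Inpatient -> Phase2-in-care rate (persons/year)."""
    return disease.discharge_rate * state["inpatient"]


def cost_rates(
    state: Mapping[str, float],
    capacity: CapacityParams,
    cost: CostParams,
    admission_rate: float,
) -> tuple[float, float, float]:
    """EUR/year spent on (screening staff, GPs, hospital admissions)."""
    if admission_rate < 0:
        raise ValueError(f"admission_rate must be >= 0, got {admission_rate}")
    return (
        state["screener_staff"] * cost.screener_salary,
        state["gp_staff"] * cost.gp_cost,
        admission_rate * cost.drg_tariff,
    )


def build_chronic_model(
    disease: DiseaseParams,
    capacity: CapacityParams,
    cost: CostParams,
    policy: StaffingPolicy,
    initial: InitialStocks | None = None,
) -> ModelSpec:
    """Wire the full pathway into a simulateable :class:`ModelSpec`.

    With a fixed policy the staffing stocks start at the fixed levels and
    have zero net flow; with the endogenous policy the hiring flows are
    active (signed, donor-limited so head counts never go negative).
    """
    initial = initial or InitialStocks()
    if policy.kind == "fixed":
        screeners0, gps0 = policy.fixed_screeners, policy.fixed_gps
    else:
        # endogenisation starts from the as-is staffing levels
        screeners0, gps0 = policy.fixed_screeners, policy.fixed_gps

    stocks = [
        Stock("reference_population", initial.reference_population, "persons"),
        Stock("phase1_undetected", initial.phase1_undetected, "persons"),
        Stock("phase1_in_care", initial.phase1_in_care, "persons"),
        Stock("phase2_undetected", initial.phase2_undetected, "persons"),
        Stock("phase2_in_care", initial.phase2_in_care, "persons"),
        Stock("inpatient", initial.inpatient, "persons"),
        Stock("screener_staff", screeners0, "staff"),
        Stock("gp_staff", gps0, "staff"),
        Stock("cumulative_admissions", 0.0, "admissions"),
        Stock("cumulative_cost_screening", 0.0, "EUR"),
        Stock("cumulative_cost_gp", 0.0, "EUR"),
        Stock("cumulative_cost_hospital", 0.0, "EUR"),
    ]

    aux = [
        Auxiliary(
            "coverage", lambda s, t, p, a: care_coverage(s, capacity), unit=""
        ),
        Auxiliary(
            "admission_rate",
            lambda s, t, p, a: sum(hospitalisation_flows(s, disease, a["coverage"])),
            unit="admissions/year",
        ),
        Auxiliary(
            "cost_rate_screening",
            lambda s, t, p, a: cost_rates(s, capacity, cost, a["admission_rate"])[0],
            unit="EUR/year",
        ),
        Auxiliary(
            "cost_rate_gp",
            lambda s, t, p, a: cost_rates(s, capacity, cost, a["admission_rate"])[1],
            unit="EUR/year",
        ),
        Auxiliary(
            "cost_rate_hospital",
            lambda s, t, p, a: cost_rates(s, capacity, cost, a["admission_rate"])[2],
            unit="EUR/year",
        ),
        Auxiliary(
            "cost_rate_total",
            lambda s, t, p, a: a["cost_rate_screening"] + a["cost_rate_gp"] + a["cost_rate_hospital"],
            unit="EUR/year",
        ),
    ]

    flows = [
        Flow(
            "incidence",
            "reference_population",
            "phase1_undetected",
            lambda s, t, p, a: incidence_flow(s, disease),
        ),
        Flow(
            "detect_phase1",
            "phase1_undetected",
            "phase1_in_care",
            lambda s, t, p, a: screening_detection_flows(s, capacity)[0],
        ),
        Flow(
            "detect_phase2",
            "phase2_undetected",
            "phase2_in_care",
            lambda s, t, p, a: screening_detection_flows(s, capacity)[1],
        ),
        Flow(
            "progress_undetected",
            "phase1_undetected",
            "phase2_undetected",
            lambda s, t, p, a: progression_flows(s, disease, a["coverage"])[0],
        ),
        Flow(
            "progress_in_care",
            "phase1_in_care",
            "phase2_in_care",
            lambda s, t, p, a: progression_flows(s, disease, a["coverage"])[1],
        ),
        Flow(
            "admit_undetected",
            "phase2_undetected",
            "inpatient",
            lambda s, t, p, a: hospitalisation_flows(s, disease, a["coverage"])[0],
        ),
        Flow(
            "admit_in_care",
            "phase2_in_care",
            "inpatient",
            lambda s, t, p, a: hospitalisation_flows(s, disease, a["coverage"])[1],
        ),
        Flow(
            "discharge",
            "inpatient",
            disease.discharge_destination,
            lambda s, t, p, a: discharge_flow(s, disease),
        ),
        Flow(
            "admissions_accrual",
            EXOGENOUS,
            "cumulative_admissions",
            lambda s, t, p, a: a["admission_rate"],
            unit="admissions/year",
        ),
        Flow(
            "cost_screening_accrual",
            EXOGENOUS,
            "cumulative_cost_screening",
            lambda s, t, p, a: a["cost_rate_screening"],
            unit="EUR/year",
        ),
        Flow(
            "cost_gp_accrual",
            EXOGENOUS,
            "cumulative_cost_gp",
            lambda s, t, p, a: a["cost_rate_gp"],
            unit="EUR/year",
        ),
        Flow(
            "cost_hospital_accrual",
            EXOGENOUS,
            "cumulative_cost_hospital",
            lambda s, t, p, a: a["cost_rate_hospital"],
            unit="EUR/year",
        ),
        Flow(
            "hire_screeners",
            EXOGENOUS,
            "screener_staff",
            lambda s, t, p, a: staffing_rates(s, capacity, policy)[0],
            unit="staff/year",
            bidirectional=True,
        ),
        Flow(
            "hire_gps",
            EXOGENOUS,
            "gp_staff",
            lambda s, t, p, a: staffing_rates(s, capacity, policy)[1],
            unit="staff/year",
            bidirectional=True,
        ),
    ]

    parameters: dict[str, float] = {}
    units: dict[str, str] = {}
    for section, obj in (
        ("disease", disease),
        ("capacity", capacity),
        ("cost", cost),
        ("policy", policy),
    ):
        for k, v in obj.model_dump().items():
            if isinstance(v, (int, float)) and not isinstance(v, bool):
                parameters[f"{section}.{k}"] = float(v)

    return ModelSpec(stocks=stocks, flows=flows, auxiliaries=aux, parameters=parameters, parameter_units=units)
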