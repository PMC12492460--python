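"""Parameter ledger for the chronic-care pathway model.

Every quantity carries its unit in the field description.  The defaults
below form the shipped ledger: staffing counts (5/15 screeners, 700/1,000
GPs) and the 4-year horizon are the scenario-defining values; the
epidemiological and cost defaults are a documented, tunable calibration
whose binding constraint is the qualitative scenario behaviour (see
docs/methods.md).
"""

from __future__ import annotations

from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["DiseaseParams", "CapacityParams", "CostParams", "InitialStocks"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class DiseaseParams(_Strict):
    """Incidence, progression and hospitalisation rates.

    Progression and hospitalisation each have an *undetected* rate (the
    natural course) and an *in-care* rate (the slowed course under proper
    primary care); care can only slow the disease, so the in-care rate
    may not exceed the natural one.
    """

    incidence_rate: float = Field(
        0.01, ge=0, description="fraction of the reference population per year developing Phase 1"
    )
    p1_u: float = Field(0.15, ge=0, description="Phase1->Phase2 progression per year, undetected")
    p1_c: float = Field(0.05, ge=0, description="Phase1->Phase2 progression per year, properly cared")
    h2_u: float = Field(0.35, ge=0, description="Phase2->Inpatient admissions per year, undetected")
    h2_c: float = Field(0.10, ge=0, description="Phase2->Inpatient admissions per year, properly cared")
    discharge_rate: float = Field(
        36.5, ge=0, description="discharges per year = 1 / average length of stay (default LOS 10 days)"
    )
    discharge_destination: Literal["reference_population", "phase2_in_care"] = Field(
        "reference_population",
        description=(
            "where discharged inpatients go: back to the community once the acute "
            "episode resolves (default; keeps the diseased pool non-absorbing), or "
            "into structured phase-2 care (hospitalisation entails diagnosis)"
        ),
    )

    @model_validator(mode="after")
    def _care_slows_disease(self) -> "DiseaseParams":
        if self.p1_c > self.p1_u:
            raise ValueError(f"disease.p1_c ({self.p1_c}) must be <= p1_u ({self.p1_u})")
        if self.h2_c > self.h2_u:
            raise ValueError(f"disease.h2_c ({self.h2_c}) must be <= h2_u ({self.h2_u})")
        return self


class CapacityParams(_Strict):
    """Productivity of the two upstream care settings."""

    screener_productivity: float = Field(
        4000.0, gt=0, description="screens per screening staff member per year"
    )
    screening_interval: float = Field(
        5.0, gt=0, description="target years between screens of the eligible community (sets demand)"
    )
    gp_panel: float = Field(
        100.0, gt=0, description="chronic patients effectively taken in charge per GP"
    )


class CostParams(_Strict):
    """Unit costs of the three settings (EUR)."""

    screener_salary: float = Field(35_000.0, ge=0, description="EUR per screening staff member per year")
    gp_cost: float = Field(
        15_000.0, ge=0, description="EUR per GP per year (chronic-care remuneration share)"
    )
    drg_tariff: float = Field(8_000.0, ge=0, description="EUR per hospital admission (DRG tariff)")


class InitialStocks(_Strict):
    """Initial population distribution (persons) and inpatients."""

    reference_population: float = Field(859_000.0, ge=0)
    phase1_undetected: float = Field(30_000.0, ge=0)
    phase1_in_care: float = Field(50_000.0, ge=0)
    phase2_undetected: float = Field(10_000.0, ge=0)
    phase2_in_care: float = Field(30_000.0, ge=0)
    inpatient: float = Field(1_000.0, ge=0)

    @property
    def total_population(self) -> float:
        return (
            self.reference_population
            + self.phase1_undetected
            + self.phase1_in_care
            + self.phase2_undetected
            + self.phase2_in_care
            + self.inpatient
        )
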