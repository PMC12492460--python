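"""Staffing rules: exogenous fixed levels vs endogenised feedback hiring.

Under the *fixed* policy the screener and GP head counts are exogenous
constants (the stage-1 scenarios).  Under the *endogenous* policy the
desired head counts are computed from the system's own state — service
demand over productivity — and actual staffing adjusts toward them with a
first-order delay (the stage-2 "endogenisation"): recruitment is driven
by actual need rather than by a fixed budget line.
"""

from __future__ import annotations

from typing import Literal, Mapping

from pydantic import BaseModel, ConfigDict, Field

from .engine import first_order_adjust
from .params import CapacityParams

__all__ = [
    "StaffingPolicy",
    "screening_demand",
    "desired_screeners",
    "desired_gps",
    "staffing_rates",
]


class StaffingPolicy(BaseModel):
    """Either FIXED head counts or ENDOGENOUS demand-driven adjustment.

    Staff counts are continuous (aggregate SD semantics); fractional staff
    are rounded only in output formatting, never in the dynamics.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    kind: Literal["fixed", "endogenous"] = "fixed"
    fixed_screeners: float = Field(5.0, ge=0, description="persons (fixed policy)")
    fixed_gps: float = Field(700.0, ge=0, description="persons (fixed policy)")
    adjustment_time: float = Field(
        0.25,
        gt=0,
        description="years; first-order adjustment time for screening staff (short-contract hires)",
    )
    adjustment_time_gps: float = Field(
        1.75,
        gt=0,
        description="years; first-order adjustment time for GP capacity (convention negotiation)",
    )
    allow_downsizing: bool = Field(
        True, description="if false, negative adjustment rates are clamped to zero"
    )


def screening_demand(state: Mapping[str, float], capacity: CapacityParams) -> float:
    """Screens per year needed to cover the undiagnosed community.

    The eligible community — reference population plus the undetected
    phase-1/phase-2 pools — should be screened once every
    ``screening_interval`` years, so demand = community / interval.
    """
    community = (
        state["reference_population"]
        + state["phase1_undetected"]
        + state["phase2_undetected"]
    )
    return community / capacity.screening_interval


def desired_screeners(demand: float, productivity: float) -> float:
    """Head count whose capacity exactly meets the screening demand."""
    if productivity <= 0:
        raise ValueError(f"productivity must be > 0, got {productivity}")
    return demand / productivity


def desired_gps(in_care: float, panel: float) -> float:
    """Head count whose panel capacity exactly covers the in-care caseload."""
    if panel <= 0:
        raise ValueError(f"gp_panel must be > 0, got {panel}")
    return in_care / panel


def staffing_rates(
    state: Mapping[str, float], capacity: CapacityParams, policy: StaffingPolicy
) -> tuple[float, float]:
    """Net hiring rates (screeners/year, GPs/year) for the current state.

    FIXED: both zero — the staffing stocks are initialised at the fixed
    levels and never move.  ENDOGENOUS: first-order adjustment toward the
    demand-implied desired levels; downsizing (negative rate) is allowed
    unless the policy forbids it.
    """
    if policy.kind == "fixed":
        return 0.0, 0.0
    demand = screening_demand(state, capacity)
    want_screeners = desired_screeners(demand, capacity.screener_productivity)
    in_care = state["phase1_in_care"] + state["phase2_in_care"]
    want_gps = desired_gps(in_care, capacity.gp_panel)
    r_s = first_order_adjust(state["screener_staff"], want_screeners, policy.adjustment_time)
    r_g = first_order_adjust(state["gp_staff"], want_gps, policy.adjustment_time_gps)
    if not policy.allow_downsizing:
        r_s = max(r_s, 0.0)
        r_g = max(r_g, 0.0)
    return r_s, r_g
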