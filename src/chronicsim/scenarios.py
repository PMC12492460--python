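"""Scenario presets, batch comparison and what-if parameter sweeps.

The four shipped presets reproduce the staged what-if analysis:

* **run1** — "as-is": understaffed screening (5) and primary care (700 GPs);
* **run2** — "primary care": GPs increased from 700 to 1,000;
* **run3** — "screening": screening staff increased from 5 to 15, GPs kept
  at 1,000;
* **run4** — "endogenisation": staffing of both settings adjusts toward
  demand-implied need, starting from the as-is levels (5, 700).

All runs use a 4-year horizon at a monthly step by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .engine import SimConfig, Trajectory, integrate
from .kpi import kpi_series
from .model import build_chronic_model
from .params import CapacityParams, CostParams, DiseaseParams, InitialStocks
from .staffing import StaffingPolicy

__all__ = [
    "Ledger",
    "SimSettings",
    "ScenarioSpec",
    "ScenarioResult",
    "ComparisonReport",
    "PRESET_NAMES",
    "preset",
    "run_scenario",
    "compare",
    "sweep",
]


class SimSettings(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    horizon: float = Field(4.0, gt=0, description="years")
    dt: float = Field(1.0 / 12.0, gt=0, description="years")
    stride: int = Field(1, ge=1)


class Ledger(BaseModel):
    """The full parameter ledger: one section per parameter group."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    disease: DiseaseParams = DiseaseParams()
    capacity: CapacityParams = CapacityParams()
    cost: CostParams = CostParams()
    policy: StaffingPolicy = StaffingPolicy()
    initial_stocks: InitialStocks = InitialStocks()
    sim: SimSettings = SimSettings()

    def with_overrides(self, overrides: dict[str, Any]) -> "Ledger":
        """Return a new ledger with dot-path overrides applied and revalidated."""
        data = self.model_dump()
        for path, value in overrides.items():
            parts = path.split(".")
            node = data
            for p in parts[:-1]:
                if not isinstance(node, dict) or p not in node:
                    raise KeyError(f"override path {path!r}: unknown section {p!r}")
                node = node[p]
            if parts[-1] not in node:
                raise KeyError(f"override path {path!r}: unknown key {parts[-1]!r}")
            node[parts[-1]] = value
        return Ledger.model_validate(data)


@dataclass(frozen=True)
class ScenarioSpec:
    """A named run: base ledger + dot-path overrides + simulation window."""

    name: str
    ledger: Ledger = field(default_factory=Ledger)
    overrides: dict[str, Any] = field(default_factory=dict)

    def resolved(self) -> Ledger:
        return self.ledger.with_overrides(self.overrides) if self.overrides else self.ledger


PRESET_NAMES = ("run1", "run2", "run3", "run4")

_PRESET_OVERRIDES: dict[str, dict[str, Any]] = {
    # staffing counts are the values printed for the staged scenarios
    "run1": {"policy.kind": "fixed", "policy.fixed_screeners": 5, "policy.fixed_gps": 700},
    "run2": {"policy.kind": "fixed", "policy.fixed_screeners": 5, "policy.fixed_gps": 1000},
    "run3": {"policy.kind": "fixed", "policy.fixed_screeners": 15, "policy.fixed_gps": 1000},
    # endogenisation starts from the as-is staffing
    "run4": {"policy.kind": "endogenous", "policy.fixed_screeners": 5, "policy.fixed_gps": 700},
}


def preset(name: str, ledger: Ledger | None = None) -> ScenarioSpec:
    """Return one of the four shipped scenario presets."""
    key = name.lower().replace(" ", "").replace("_", "")
    if key not in _PRESET_OVERRIDES:
        raise KeyError(f"unknown scenario {name!r}; presets are {', '.join(PRESET_NAMES)}")
    return ScenarioSpec(name=key, ledger=ledger or Ledger(), overrides=dict(_PRESET_OVERRIDES[key]))


@dataclass
class ScenarioResult:
    """Trajectory + KPI series + cost summary for one scenario run."""

    spec: ScenarioSpec
    trajectory: Trajectory
    kpis: pd.DataFrame
    cost_summary: dict[str, float]

    @property
    def end_outcome_pi(self) -> float:
        return float(self.kpis["outcome_pi"].iloc[-1])

    @property
    def total_cost(self) -> float:
        return self.cost_summary["total"]


def run_scenario(spec: ScenarioSpec, horizon: float | None = None, dt: float | None = None) -> ScenarioResult:
    """Build, integrate and post-process one scenario (deterministic)."""
    ledger = spec.resolved()
    sim = ledger.sim
    config = SimConfig(
        horizon=horizon if horizon is not None else sim.horizon,
        dt=dt if dt is not None else sim.dt,
        stride=sim.stride,
    )
    model = build_chronic_model(
        ledger.disease, ledger.capacity, ledger.cost, ledger.policy, ledger.initial_stocks
    )
    traj = integrate(model, config, scenario=spec.name)
    kpis = kpi_series(traj, ledger.capacity)
    final = traj.final_state
    cost_summary = {
        "screening": final["cumulative_cost_screening"],
        "gp": final["cumulative_cost_gp"],
        "hospital": final["cumulative_cost_hospital"],
        "total": (
            final["cumulative_cost_screening"]
            + final["cumulative_cost_gp"]
            + final["cumulative_cost_hospital"]
        ),
    }
    return ScenarioResult(spec=spec, trajectory=traj, kpis=kpis, cost_summary=cost_summary)


@dataclass
class ComparisonReport:
    """End-of-horizon outcomes, cumulative costs and cost-crossover time.

    ``crossover_time`` is the first output time (> 0) at which the
    endogenous run's instantaneous total cost rate falls below the rates
    of *every* fixed-staffing run in the batch, or ``None`` if that never
    happens (or the batch has no endogenous run).
    """

    end_outcome_pi: dict[str, float]
    total_cost: dict[str, float]
    cost_breakdown: dict[str, dict[str, float]]
    crossover_time: float | None
    horizon: float

    @property
    def outcome_ordering(self) -> list[str]:
        """Scenario names from best (lowest hospitalisation rate) to worst."""
        return sorted(self.end_outcome_pi, key=self.end_outcome_pi.__getitem__)

    @property
    def cost_ordering(self) -> list[str]:
        """Scenario names from cheapest to most expensive over the horizon."""
        return sorted(self.total_cost, key=self.total_cost.__getitem__)

    def to_dict(self) -> dict[str, Any]:
        return {
            "horizon_years": self.horizon,
            "end_outcome_pi": dict(sorted(self.end_outcome_pi.items())),
            "total_cost_eur": dict(sorted(self.total_cost.items())),
            "cost_breakdown_eur": {k: dict(v) for k, v in sorted(self.cost_breakdown.items())},
            "outcome_ordering_best_first": self.outcome_ordering,
            "cost_ordering_cheapest_first": self.cost_ordering,
            "cost_crossover_time_years": self.crossover_time,
        }


def compare(batch: list[ScenarioSpec]) -> ComparisonReport:
    """Run a batch of scenarios and compare outcomes, costs and crossover."""
    if len(batch) < 2:
        raise ValueError("compare() needs at least two scenarios")
    names = [s.name for s in batch]
    if len(set(names)) != len(names):
        raise ValueError(f"scenario names must be unique within a batch: {names}")
    horizons = {s.resolved().sim.horizon for s in batch}
    if len(horizons) != 1:
        raise ValueError(f"scenarios have mismatched horizons: {sorted(horizons)}")
    results = {s.name: run_scenario(s) for s in batch}

    endo = [s.name for s in batch if s.resolved().policy.kind == "endogenous"]
    fixed = [s.name for s in batch if s.resolved().policy.kind == "fixed"]
    crossover: float | None = None
    if len(endo) == 1 and fixed:
        endo_rate = results[endo[0]].trajectory.aux["cost_rate_total"]
        fixed_rates = pd.concat(
            [results[n].trajectory.aux["cost_rate_total"] for n in fixed], axis=1
        ).min(axis=1)
        below = (endo_rate < fixed_rates) & (endo_rate.index > 0)
        if below.any():
            crossover = float(below.idxmax())

    return ComparisonReport(
        end_outcome_pi={n: r.end_outcome_pi for n, r in results.items()},
        total_cost={n: r.total_cost for n, r in results.items()},
        cost_breakdown={n: dict(r.cost_summary) for n, r in results.items()},
        crossover_time=crossover,
        horizon=horizons.pop(),
    )


def sweep(base: ScenarioSpec, parameter_path: str, values: list[Any]) -> pd.DataFrame:
    """Independent runs of ``base`` with one parameter swept over ``values``.

    Returns a DataFrame with one row per value (ordered by input value):
    the swept value, end-of-horizon outcome PI and cumulative total cost.
    """
    if len(values) < 2:
        raise ValueError("sweep() needs at least two values")
    base.resolved().with_overrides({parameter_path: values[0]})  # fail fast on bad path
    rows = []
    for v in sorted(values):
        spec = ScenarioSpec(
            name=f"{base.name}[{parameter_path}={v}]",
            ledger=base.ledger,
            overrides={**base.overrides, parameter_path: v},
        )
        res = run_scenario(spec)
        rows.append({"value": v, "end_outcome_pi": res.end_outcome_pi, "total_cost": res.total_cost})
    return pd.DataFrame(rows)
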