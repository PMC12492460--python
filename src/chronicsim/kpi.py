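"""The three system performance indicators and outcome benchmarking.

* **Outcome PI** — hospitalisation rate: inpatients over the total
  population.  Its target is not a scalar but a reference trajectory (the
  endogenised-policy run), so benchmarking compares an observed series
  against a stored benchmark series.
* **Screening PI** — screening capacity (staff x productivity) over
  screening demand (community / re-screening interval).
* **Primary-care PI** — GP capacity (staff x panel) over the in-care
  chronic population.

The two capacity indicators should aim for a value of 1: capacity
matching demand is exactly the fixed point of the endogenous staffing
policy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .engine import Trajectory
from .model import POPULATION_STOCKS
from .params import CapacityParams
from .staffing import screening_demand

__all__ = [
    "outcome_pi",
    "screening_pi",
    "primary_care_pi",
    "kpi_series",
    "BenchmarkReport",
    "benchmark_compare",
]

KPI_COLUMNS = ["outcome_pi", "screening_pi", "primary_care_pi", "admissions_per_1000_py"]


def _total_population(state: Mapping[str, float]) -> float:
    return sum(state[k] for k in POPULATION_STOCKS)


def outcome_pi(state: Mapping[str, float]) -> float:
    """Hospitalisation rate: inpatients / total population."""
    total = _total_population(state)
    if total <= 0:
        raise ValueError("total population is zero; outcome PI undefined")
    return state["inpatient"] / total


def screening_pi(state: Mapping[str, float], capacity: CapacityParams) -> float:
    """Screening capacity over screening demand (1 = capacity meets demand).

    With an empty community there is nothing left to screen and the
    indicator is reported saturated at 1.
    """
    demand = screening_demand(state, capacity)
    if demand <= 0:
        return 1.0
    return state["screener_staff"] * capacity.screener_productivity / demand


def primary_care_pi(state: Mapping[str, float], capacity: CapacityParams) -> float:
    """GP capacity over the in-care population (1 = caseload fully covered)."""
    in_care = state["phase1_in_care"] + state["phase2_in_care"]
    if in_care <= 0:
        return 1.0
    return state["gp_staff"] * capacity.gp_panel / in_care


def kpi_series(trajectory: Trajectory, capacity: CapacityParams) -> pd.DataFrame:
    """Evaluate all indicators at every output time of a trajectory.

    Returns a DataFrame indexed by time with columns ``outcome_pi``,
    ``screening_pi``, ``primary_care_pi`` and the secondary column
    ``admissions_per_1000_py`` (instantaneous annualised admissions per
    1,000 population).
    """
    rows = []
    admit = trajectory.aux["admission_rate"]
    for t, state in trajectory.stocks.iterrows():
        s = state.to_dict()
        total = _total_population(s)
        rows.append(
            {
                "outcome_pi": outcome_pi(s),
                "screening_pi": screening_pi(s, capacity),
                "primary_care_pi": primary_care_pi(s, capacity),
                "admissions_per_1000_py": admit.loc[t] / total * 1000.0,
            }
        )
    return pd.DataFrame(rows, index=trajectory.stocks.index)


@dataclass
class BenchmarkReport:
    """Signed relative deviation of an observed outcome-PI series from a benchmark."""

    deviations: pd.Series  # (observed - benchmark) / benchmark, per time
    flags: pd.Series  # True where observed exceeds benchmark beyond tolerance
    tolerance: float
    mean_deviation: float
    max_deviation: float

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


def benchmark_compare(
    observed: pd.DataFrame, benchmark: pd.DataFrame, tolerance: float = 0.10
) -> BenchmarkReport:
    """Compare an observed outcome-PI series against a benchmark series.

    Both inputs are KPI frames indexed by time (as from
    :func:`kpi_series` or a benchmark CSV).  If the time grids differ the
    benchmark is linearly interpolated onto the observed grid; disjoint
    time ranges are an error.  Times where the observed hospitalisation
    rate exceeds the benchmark by more than ``tolerance`` (relative) are
    flagged.
    """
    obs = observed["outcome_pi"]
    ref = benchmark["outcome_pi"]
    t_obs = np.asarray(obs.index, dtype=float)
    t_ref = np.asarray(ref.index, dtype=float)
    if t_obs.min() > t_ref.max() or t_obs.max() < t_ref.min():
        raise ValueError(
            f"observed time range [{t_obs.min()}, {t_obs.max()}] does not overlap "
            f"benchmark range [{t_ref.min()}, {t_ref.max()}]"
        )
    if len(t_obs) == len(t_ref) and np.allclose(t_obs, t_ref):
        ref_on_obs = ref.to_numpy()
    else:
        keep = (t_obs >= t_ref.min()) & (t_obs <= t_ref.max())
        t_obs = t_obs[keep]
        obs = obs.iloc[keep]
        ref_on_obs = np.interp(t_obs, t_ref, ref.to_numpy())
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = np.where(ref_on_obs > 0, (obs.to_numpy() - ref_on_obs) / ref_on_obs, 0.0)
    deviations = pd.Series(dev, index=obs.index, name="relative_deviation")
    flags = deviations > tolerance
    return BenchmarkReport(
        deviations=deviations,
        flags=flags,
        tolerance=tolerance,
        mean_deviation=float(deviations.mean()),
        max_deviation=float(deviations.max()),
    )
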