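"""Minimal deterministic stock-and-flow integration engine.

Implements the classical system-dynamics simulation loop: stocks change
only through flows, flows are evaluated synchronously on the state at the
start of each step, and the state is advanced with explicit Euler
integration.  Two guard rails replace what a visual SD environment gives
its users for free:

* **donor limiting** — an outflow can never drain more material from its
  source stock than the stock holds, so population stocks stay
  non-negative for any step size;
* **unit checking** — every stock carries a unit string and every flow
  must declare ``<stock unit>/year``; the builder rejects mismatches.

The engine uses no random numbers: identical inputs give bit-identical
trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EXOGENOUS",
    "SINK",
    "Stock",
    "Flow",
    "Auxiliary",
    "ModelSpec",
    "SimConfig",
    "Trajectory",
    "ModelValidationError",
    "SimulationError",
    "euler_step",
    "donor_limited_rate",
    "first_order_adjust",
    "integrate",
]

#: Source marker for flows entering the model across its boundary.
EXOGENOUS = "EXOGENOUS"
#: Sink marker for flows leaving the model across its boundary.
SINK = "SINK"

RateFn = Callable[[Mapping[str, float], float, Mapping[str, float], Mapping[str, float]], float]


class ModelValidationError(ValueError):
    """A model specification violates a structural invariant."""


class SimulationError(RuntimeError):
    """A numerical failure (NaN/Inf/negative rate) during integration."""


@dataclass(frozen=True)
class Stock:
    """An accumulating state variable, changed only by flows."""

    name: str
    initial: float
    unit: str = "persons"


@dataclass(frozen=True)
class Flow:
    """A per-year transfer between stocks or across the model boundary.

    ``rate`` is called as ``rate(state, t, params, aux)`` and must return
    a finite value in ``<stock unit>/year``.  Ordinary flows are
    unidirectional: a negative requested rate aborts the run.  Flows
    marked ``bidirectional`` carry a signed net rate (used for staffing
    adjustment, where downsizing is a legitimate negative rate); their
    negative side is donor-limited against the *sink* stock instead.
    """

    name: str
    source: str
    sink: str
    rate: RateFn
    unit: str = "persons/year"
    bidirectional: bool = False


@dataclass(frozen=True)
class Auxiliary:
    """A named derived quantity evaluated each step before the flows.

    Auxiliaries are evaluated in declaration order and each one receives
    the values of those declared before it, so the declaration order must
    be a topological order of the dependency graph (no algebraic loops).
    """

    name: str
    func: RateFn
    unit: str = ""


@dataclass
class ModelSpec:
    """Declarative graph of stocks, flows, auxiliaries and parameters."""

    stocks: list[Stock]
    flows: list[Flow]
    auxiliaries: list[Auxiliary] = field(default_factory=list)
    parameters: dict[str, float] = field(default_factory=dict)
    parameter_units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        names = [s.name for s in self.stocks]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ModelValidationError(f"duplicate stock names: {dupes}")
        stock_by_name = {s.name: s for s in self.stocks}
        for s in self.stocks:
            if not math.isfinite(s.initial) or s.initial < 0:
                raise ModelValidationError(
                    f"stock {s.name!r}: initial value {s.initial} must be finite and >= 0"
                )
        seen_aux: set[str] = set()
        for a in self.auxiliaries:
            if a.name in seen_aux or a.name in stock_by_name:
                raise ModelValidationError(f"auxiliary name {a.name!r} duplicated or shadows a stock")
            seen_aux.add(a.name)
        for f in self.flows:
            for end, label in ((f.source, "source"), (f.sink, "sink")):
                if end not in (EXOGENOUS, SINK) and end not in stock_by_name:
                    raise ModelValidationError(
                        f"flow {f.name!r}: {label} {end!r} is not a stock, EXOGENOUS or SINK"
                    )
            if f.source == EXOGENOUS and f.sink == SINK:
                raise ModelValidationError(f"flow {f.name!r} connects EXOGENOUS to SINK")
            # unit check: declared flow unit must be <stock unit>/year at both stock ends
            for end in (f.source, f.sink):
                if end in stock_by_name:
                    expected = f"{stock_by_name[end].unit}/year"
                    if f.unit != expected:
                        raise ModelValidationError(
                            f"flow {f.name!r}: declared unit {f.unit!r} != {expected!r} "
                            f"required by stock {end!r}"
                        )

    @property
    def stock_names(self) -> list[str]:
        return [s.name for s in self.stocks]


@dataclass(frozen=True)
class SimConfig:
    """Integration window: start time, horizon and step, all in years."""

    horizon: float
    dt: float = 1.0 / 12.0
    start: float = 0.0
    stride: int = 1

    def __post_init__(self) -> None:
        if not self.horizon > 0:
            raise ModelValidationError(f"horizon must be > 0, got {self.horizon}")
        if not 0 < self.dt <= self.horizon:
            raise ModelValidationError(f"dt must satisfy 0 < dt <= horizon, got {self.dt}")
        n = self.horizon / self.dt
        if abs(n - round(n)) > 1e-6 * max(1.0, n):
            raise ModelValidationError(
                f"horizon/dt = {n} is not an integer number of steps"
            )
        if self.stride < 1 or self.stride != int(self.stride):
            raise ModelValidationError(f"stride must be an integer >= 1, got {self.stride}")

    @property
    def n_steps(self) -> int:
        return round(self.horizon / self.dt)


@dataclass
class Trajectory:
    """Time-indexed record of stocks, flow rates and auxiliaries for one run.

    All three frames share the same index (time in years, uniformly spaced
    ``dt * stride`` apart).  Flow and auxiliary rows hold the values
    evaluated *at* that time on the recorded state.
    """

    times: np.ndarray
    stocks: pd.DataFrame
    flows: pd.DataFrame
    aux: pd.DataFrame
    parameters: dict[str, float]
    scenario: str = ""

    def to_frame(self) -> pd.DataFrame:
        """Single wide DataFrame: time index, stock + flow + aux columns."""
        out = pd.concat([self.stocks, self.flows, self.aux], axis=1)
        out.index.name = "time"
        return out

    @property
    def final_state(self) -> dict[str, float]:
        return self.stocks.iloc[-1].to_dict()


def euler_step(
    state: np.ndarray | Sequence[float], net_rates: np.ndarray | Sequence[float], dt: float
) -> np.ndarray:
    """Advance stock values by one explicit-Euler step.

    ``stock' = stock + rate * dt``.  With donor limiting applied upstream
    no stock can go negative; as a belt-and-braces guard, values within
    rounding error below zero are clamped to exactly zero.
    """
    if dt <= 0:
        raise SimulationError(f"dt must be > 0, got {dt}")
    state = np.asarray(state, dtype=float)
    rates = np.asarray(net_rates, dtype=float)
    if not np.all(np.isfinite(rates)):
        bad = int(np.flatnonzero(~np.isfinite(rates))[0])
        raise SimulationError(f"non-finite net rate at stock index {bad}")
    new = state + rates * dt
    tiny = -1e-9 * np.maximum(1.0, np.abs(state))
    new = np.where((new < 0) & (new > tiny), 0.0, new)
    return new


def donor_limited_rate(requested: float, donor: float, dt: float) -> float:
    """Cap an outflow so one Euler step cannot overdraw the donor stock.

    Returns ``min(requested, donor / dt)``; flows are unidirectional, so a
    negative request is a modelling error and aborts.
    """
    if requested < 0:
        raise SimulationError(f"negative requested flow rate {requested}; flows are unidirectional")
    if dt <= 0:
        raise SimulationError(f"dt must be > 0, got {dt}")
    if donor < 0:
        raise SimulationError(f"donor stock is negative ({donor})")
    return min(requested, donor / dt)


def first_order_adjust(current: float, desired: float, adjustment_time: float) -> float:
    """First-order exponential adjustment rate toward a desired level.

    The canonical SD SMOOTH construct: ``(desired - current) / tau``.  The
    sign may be negative (downsizing); callers that forbid it clamp at 0.
    """
    if adjustment_time <= 0:
        raise SimulationError(f"adjustment_time must be > 0, got {adjustment_time}")
    return (desired - current) / adjustment_time


def _eval_aux(
    spec: ModelSpec, state: Mapping[str, float], t: float
) -> dict[str, float]:
    aux: dict[str, float] = {}
    for a in spec.auxiliaries:
        v = a.func(state, t, spec.parameters, aux)
        if not math.isfinite(v):
            raise SimulationError(f"auxiliary {a.name!r} is non-finite ({v}) at t={t:.6g}")
        aux[a.name] = v
    return aux


def _eval_rates(
    spec: ModelSpec, state: Mapping[str, float], t: float, aux: Mapping[str, float], dt: float
) -> dict[str, float]:
    """Evaluate all flow rates on one state, applying donor limiting.

    When several unidirectional flows drain the same stock and together
    request more than the stock holds, all of them are scaled down
    proportionally so the stock empties exactly instead of going negative.
    """
    raw: dict[str, float] = {}
    for f in spec.flows:
        r = f.rate(state, t, spec.parameters, aux)
        if not math.isfinite(r):
            raise SimulationError(f"flow {f.name!r} returned non-finite rate {r} at t={t:.6g}")
        if r < 0 and not f.bidirectional:
            raise SimulationError(
                f"flow {f.name!r} returned negative rate {r} at t={t:.6g}; flows are unidirectional"
            )
        raw[f.name] = r

    # group outflow demands per donor stock (negative bidirectional flows
    # drain their sink)
    demand: dict[str, float] = {}
    for f in spec.flows:
        r = raw[f.name]
        if r > 0 and f.source not in (EXOGENOUS,):
            demand[f.source] = demand.get(f.source, 0.0) + r
        elif r < 0 and f.bidirectional and f.sink not in (SINK,):
            demand[f.sink] = demand.get(f.sink, 0.0) - r

    scale: dict[str, float] = {}
    for name, total in demand.items():
        avail = state[name] / dt
        scale[name] = 1.0 if total <= avail else (avail / total if total > 0 else 1.0)

    limited: dict[str, float] = {}
    for f in spec.flows:
        r = raw[f.name]
        if r > 0 and f.source in scale:
            r *= scale[f.source]
        elif r < 0 and f.bidirectional and f.sink in scale:
            r *= scale[f.sink]
        limited[f.name] = r
    return limited


def integrate(spec: ModelSpec, config: SimConfig, scenario: str = "") -> Trajectory:
    """Run the model forward with synchronous explicit-Euler updates.

    All flow rates are evaluated on the state at the start of each step,
    donor-limited, then applied at once.  Deterministic; aborts with a
    diagnostic naming the offending flow on any NaN/Inf.
    """
    spec.validate()
    names = spec.stock_names
    state = {s.name: float(s.initial) for s in spec.stocks}
    dt = config.dt

    rec_times: list[float] = []
    rec_stocks: list[list[float]] = []
    rec_flows: list[dict[str, float]] = []
    rec_aux: list[dict[str, float]] = []

    def record(t: float) -> None:
        aux = _eval_aux(spec, state, t)
        rates = _eval_rates(spec, state, t, aux, dt)
        rec_times.append(t)
        rec_stocks.append([state[n] for n in names])
        rec_flows.append(rates)
        rec_aux.append(aux)

    t = config.start
    record(t)
    for step in range(config.n_steps):
        aux = _eval_aux(spec, state, t)
        rates = _eval_rates(spec, state, t, aux, dt)
        net = {n: 0.0 for n in names}
        for f in spec.flows:
            r = rates[f.name]
            if f.source in net:
                net[f.source] -= r
            if f.sink in net:
                net[f.sink] += r
        try:
            new_vals = euler_step([state[n] for n in names], [net[n] for n in names], dt)
        except SimulationError as exc:
            raise SimulationError(f"step {step} (t={t:.6g}): {exc}") from exc
        state = dict(zip(names, (float(v) for v in new_vals)))
        for n, v in state.items():
            if v < 0:
                raise SimulationError(
                    f"step {step}: stock {n!r} went negative ({v}); a flow bypassed donor limiting"
                )
        t = config.start + (step + 1) * dt
        if (step + 1) % config.stride == 0:
            record(t)

    times = np.array(rec_times)
    idx = pd.Index(times, name="time")
    return Trajectory(
        times=times,
        stocks=pd.DataFrame(rec_stocks, columns=names, index=idx),
        flows=pd.DataFrame(rec_flows, index=idx),
        aux=pd.DataFrame(rec_aux, index=idx),
        parameters=dict(spec.parameters),
        scenario=scenario,
    )
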