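"""Configuration loading and result serialisation.

Configs are YAML with one section per ledger group (``disease``,
``capacity``, ``cost``, ``policy``, ``initial_stocks``, ``sim``); missing
keys fall back to the shipped defaults (with a logged notice), unknown
keys are rejected with the offending key path.  Trajectories and KPI
series are written as plain CSV (``.`` decimal, ``,`` separator, UTF-8,
LF) at 12 significant digits; summaries as JSON with stable key order.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
import yaml
from pydantic import ValidationError

from .engine import Trajectory
from .scenarios import ComparisonReport, Ledger

__all__ = [
    "ConfigError",
    "load_config",
    "dump_config",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_kpi_csv",
    "read_kpi_csv",
    "write_summary_json",
]

SCHEMA_VERSION = "1.0"
logger = logging.getLogger("chronicsim")


class ConfigError(ValueError):
    """A configuration file failed to parse or validate."""


def _flatten(d: dict, prefix: str = "") -> list[str]:
    out = []
    for k, v in d.items():
        path = f"{prefix}{k}"
        if isinstance(v, dict):
            out.extend(_flatten(v, path + "."))
        else:
            out.append(path)
    return out


def load_config(path: str | Path | None) -> Ledger:
    """Load a YAML parameter ledger, filling gaps from the shipped defaults.

    ``None`` or an empty file yields the full default ledger.  Validation
    failures (unknown keys, negative rates, care rates above natural
    rates, ...) raise :class:`ConfigError` naming the key path.
    """
    if path is None:
        return Ledger()
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: YAML parse error: {exc}") from exc
    if raw is None:
        logger.info("%s is empty; using the full default ledger", path)
        return Ledger()
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping of sections")
    try:
        ledger = Ledger.model_validate(raw)
    except ValidationError as exc:
        details = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"] for err in exc.errors()
        )
        raise ConfigError(f"{path}: invalid configuration: {details}") from exc
    given = set(_flatten(raw))
    defaults = set(_flatten(Ledger().model_dump())) - given
    if defaults:
        logger.info("%s: %d keys filled from defaults", path, len(defaults))
    return ledger


def dump_config(ledger: Ledger, path: str | Path) -> Path:
    """Write a ledger snapshot that replays the run bit-identically."""
    path = Path(path)
    path.write_text(yaml.safe_dump(ledger.model_dump(), sort_keys=True), encoding="utf-8")
    return path


def write_trajectory_csv(trajectory: Trajectory, path: str | Path) -> Path:
    """Write time, stocks, flow rates and auxiliaries to one wide CSV.

    Values are written with 12 significant digits so a read-back matches
    the in-memory trajectory to better than 1e-9 relative.
    """
    path = Path(path)
    frame = trajectory.to_frame()
    frame.to_csv(path, float_format="%.12g", lineterminator="\n")
    return path


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    """Read a trajectory CSV back as a time-indexed DataFrame."""
    return pd.read_csv(path, index_col="time")


def write_kpi_csv(kpis: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    kpis.rename_axis("time").to_csv(path, float_format="%.12g", lineterminator="\n")
    return path


def read_kpi_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="time")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def write_summary_json(summary: ComparisonReport | dict[str, Any], path: str | Path) -> Path:
    """Write a comparison report or run summary as stable, full-precision JSON."""
    path = Path(path)
    payload = summary.to_dict() if isinstance(summary, ComparisonReport) else dict(summary)
    payload = {"schema_version": SCHEMA_VERSION, **_jsonable(payload)}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path
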