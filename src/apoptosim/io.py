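"""Serialization and scenario-running glue.

Parameters and cell-line specs round-trip through YAML/JSON; time courses
and trajectories through tidy CSV.  ``run_scenario`` drives a named
treatment arm end-to-end and writes its trajectory, endpoint summary and a
conservation audit, logging everything needed to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bik import BikParams, DecayTimecourse
from .network import (
    SPECIES,
    ApoptosisParams,
    CellLineSpec,
    PARENTAL_CELL,
    SRC_CELL,
    SimulationResult,
)
from .treatments import SCENARIOS, TreatmentSpec, simulate_treated

__all__ = [
    "RunConfig",
    "save_params",
    "load_params",
    "save_cell_specs",
    "load_cell_specs",
    "save_timecourses",
    "load_timecourses",
    "trajectory_frame",
    "run_scenario",
]

_TYPES = {
    "bik_params": BikParams,
    "network_params": ApoptosisParams,
    "cell_spec": CellLineSpec,
    "treatment": TreatmentSpec,
}


def _as_payload(obj) -> dict:
    kind = next(k for k, t in _TYPES.items() if isinstance(obj, t))
    return {"kind": kind, "fields": dataclasses.asdict(obj)}


def _from_payload(payload: dict):
    try:
        cls = _TYPES[payload["kind"]]
        return cls(**payload["fields"])
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed parameter payload: {exc}") from exc


def save_params(objs: dict, path: str | Path) -> None:
    """Write a name->dataclass mapping as YAML (or JSON by extension)."""
    path = Path(path)
    payload = {name: _as_payload(obj) for name, obj in objs.items()}
    text = (json.dumps(payload, indent=2) if path.suffix == ".json"
            else yaml.safe_dump(payload, sort_keys=True))
    path.write_text(text)


def load_params(path: str | Path) -> dict:
    path = Path(path)
    raw = (json.loads(path.read_text()) if path.suffix == ".json"
           else yaml.safe_load(path.read_text()))
    return {name: _from_payload(p) for name, p in raw.items()}


def save_cell_specs(specs, path: str | Path) -> None:
    save_params({s.label: s for s in specs}, path)


def load_cell_specs(path: str | Path) -> list[CellLineSpec]:
    return list(load_params(path).values())


def save_timecourses(courses, path: str | Path) -> None:
    """Tidy CSV with columns time_min, rel_level, cell_line, treatment."""
    rows = []
    for c in courses:
        for t, v in zip(c.times, c.values):
            rows.append({"time_min": t, "rel_level": v,
                         "cell_line": c.cell_line, "treatment": c.treatment})
    pd.DataFrame(rows).to_csv(path, index=False)


def load_timecourses(path: str | Path) -> list[DecayTimecourse]:
    df = pd.read_csv(path)
    required = {"time_min", "rel_level", "cell_line", "treatment"}
    if missing := required - set(df.columns):
        raise ValueError(f"timecourse CSV missing columns: {sorted(missing)}")
    out = []
    for (line, rx), grp in df.groupby(["cell_line", "treatment"], sort=True):
        grp = grp.sort_values("time_min")
        if grp["time_min"].duplicated().any():
            raise ValueError(f"non-monotone time column for {line}/{rx}")
        out.append(DecayTimecourse(
            times=tuple(grp["time_min"].astype(float)),
            values=tuple(grp["rel_level"].astype(float)),
            cell_line=str(line), treatment=str(rx),
        ))
    return out


def trajectory_frame(result: SimulationResult) -> pd.DataFrame:
    """Long-format trajectory: time, species, value, cell_line, treatment."""
    frames = []
    for i, sp in enumerate(SPECIES):
        frames.append(pd.DataFrame({
            "time_min": result.times, "species": sp, "value": result.states[:, i],
        }))
    frames.append(pd.DataFrame({
        "time_min": result.times, "species": "surviving_pct", "value": result.n,
    }))
    df = pd.concat(frames, ignore_index=True)
    df["cell_line"] = result.cell_line
    df["treatment"] = result.treatment_label
    return df


@dataclasses.dataclass
class RunConfig:
    """One reproducible scenario run: cells, parameters, arms, solver knobs."""

    cells: tuple[CellLineSpec, ...] = (PARENTAL_CELL, SRC_CELL)
    network_params: ApoptosisParams | None = None
    scenarios: dict = dataclasses.field(default_factory=lambda: dict(SCENARIOS))
    t_end: float = 480.0
    rtol: float = 1e-8
    atol: float = 1e-10
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("solver tolerances must be > 0")
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")

    def config_hash(self) -> str:
        net = self.network_params
        payload = {
            "cells": [dataclasses.asdict(c) for c in self.cells],
            "network_params": dataclasses.asdict(net) if net else None,
            "scenarios": {k: dataclasses.asdict(v) for k, v in self.scenarios.items()},
            "t_end": self.t_end, "rtol": self.rtol, "atol": self.atol,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_scenario(config: RunConfig, scenario: str) -> dict:
    """Simulate one named arm for every cell line in the config.

    Writes per-line trajectory CSVs, an endpoint summary CSV and a JSON run
    log (seed, config hash, tolerances, package version, conservation
    audit).  Raises on contract violations (conservation drift, negative
    concentrations) so callers can fail loudly.
    """
    if scenario not in config.scenarios:
        raise KeyError(f"unknown scenario {scenario!r}; have {sorted(config.scenarios)}")
    rx = config.scenarios[scenario]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary, audit = [], {}
    for cell in config.cells:
        res = simulate_treated(cell, rx, net=config.network_params,
                               t_end=config.t_end, rtol=config.rtol,
                               atol=config.atol)
        drift = res.conservation_drift
        if drift > 1e-6:
            raise RuntimeError(f"conservation drift {drift:.2e} exceeds 1e-6")
        if float(res.states.min()) < -1e-9:
            raise RuntimeError("negative concentration in trajectory")
        traj_path = out / f"trajectory_{scenario}_{cell.label}.csv"
        trajectory_frame(res).to_csv(traj_path, index=False)
        summary.append({"cell_line": cell.label, "treatment": rx.describe(),
                        "apoptotic_pct": res.apoptotic_pct,
                        "threshold_crossing_min": res.threshold_crossing_min})
        audit[cell.label] = {"conservation_drift": drift,
                             "min_concentration": float(res.states.min())}
    summary_df = pd.DataFrame(summary)
    summary_df.to_csv(out / f"summary_{scenario}.csv", index=False)
    log = {
        "scenario": scenario, "seed": config.seed,
        "config_hash": config.config_hash(),
        "rtol": config.rtol, "atol": config.atol,
        "package_version": __version__, "audit": audit,
    }
    (out / f"runlog_{scenario}.json").write_text(json.dumps(log, indent=2))
    return {"summary": summary_df, "log": log}
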