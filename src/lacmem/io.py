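"""CSV/JSON readers and writers for trajectories, traces and fit records.

CSV carries the data; a JSON sidecar (same stem, ``.json``) carries the
metadata needed to reproduce the run: parameters, variant, schedule,
integrator settings and package version.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .environment import EnvironmentSchedule
from .expression import FluorescenceTrace
from .growth import GrowthTrace
from .model import Trajectory, VariantConfig
from .params import ModelParameters


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n")


def fit_to_json(fit, path: str | Path) -> None:
    """Serialize any fit/result dataclass to a JSON record."""
    write_json(fit, path)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trajectory(
    traj: Trajectory,
    path: str | Path,
    params: ModelParameters | None = None,
    variant: VariantConfig | None = None,
    schedule: EnvironmentSchedule | None = None,
    integrator: dict | None = None,
) -> None:
    """Tidy CSV (time_min, env, L_nM, A_nM, M_nM, B_nM, hydrolyzed_nM) plus a
    JSON sidecar with the run configuration."""
    path = Path(path)
    traj.to_frame().to_csv(path, index=False)
    meta = {
        "lacmem_version": __version__,
        "parameters": params,
        "variant": variant,
        "schedule": None
        if schedule is None
        else {
            "starts": schedule.starts,
            "ends": schedule.ends,
            "labels": schedule.labels,
        },
        "integrator": integrator or {},
    }
    write_json(meta, _sidecar(path))


def read_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(
        times=df["time_min"].to_numpy(float),
        states=df[["L_nM", "A_nM", "M_nM", "B_nM"]].to_numpy(float),
        environment_labels=df["env"].to_numpy(object),
        hydrolysis=df["hydrolyzed_nM"].to_numpy(float)
        if "hydrolyzed_nM" in df
        else np.zeros(len(df)),
    )


def write_growth_trace(trace: GrowthTrace, path: str | Path) -> None:
    trace.to_frame().to_csv(Path(path), index=False)


def read_growth_trace(path: str | Path) -> GrowthTrace:
    return GrowthTrace.from_frame(pd.read_csv(path))


def write_fluorescence_trace(trace: FluorescenceTrace, path: str | Path) -> None:
    trace.to_frame().to_csv(Path(path), index=False)


def read_fluorescence_trace(path: str | Path) -> FluorescenceTrace:
    df = pd.read_csv(path)
    return FluorescenceTrace(
        times=df["time_min"].to_numpy(float),
        intensity=df["intensity_au"].to_numpy(float),
    )


def write_sweep(result, path: str | Path, params: ModelParameters | None = None):
    path = Path(path)
    result.to_frame().to_csv(path, index=False)
    write_json(
        {
            "lacmem_version": __version__,
            "parameters": params,
            "failures": result.failures,
            "max_excess_percent": result.max_excess_percent,
            "T_at_max_excess_min": result.T_at_max_excess,
        },
        _sidecar(path),
    )
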