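"""File formats: forcing and measurement CSV, trajectories, run manifests.

Schemas (CSV with a header row; units fixed by the schema):

* forcing: ``year`` (y), ``T`` (degC), ``Q1`` (W m^-2), ``Cg`` (ppm),
  optional ``Ra`` (dimensionless red:far-red ratio);
* measurements: ``age`` (y), ``height`` (m), optional ``radius`` (m),
  optional ``density`` (trees/ha).

Writers round-trip at full float precision.  Parameter configurations are
TOML/YAML/JSON (see :func:`meristree.params.load_parameters`).
"""

from __future__ import annotations

import json
import pathlib
from typing import Any

import numpy as np
import pandas as pd

from .calibrate import MeasurementSeries
from .core import ForcingSeries
from .integrate import Trajectory
from .params import ModelParameters

__all__ = [
    "ParseError",
    "read_forcing",
    "write_forcing",
    "read_measurements",
    "write_measurements",
    "write_trajectory",
    "read_trajectory_frame",
    "write_manifest",
]


class ParseError(ValueError):
    """Raised when an input table fails validation; the message names the
    offending file, column and row."""


def _read_csv(path: str | pathlib.Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = pathlib.Path(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path.name}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: missing required columns {missing}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path.name}: non-numeric value in column {col!r} at data row {row}"
            )
        df[col] = coerced
    return df


def read_forcing(path: str | pathlib.Path) -> ForcingSeries:
    """Read and validate an annual forcing series."""
    df = _read_csv(path, ("year", "T", "Q1", "Cg"))
    try:
        return ForcingSeries.from_dataframe(df)
    except ValueError as exc:
        raise ParseError(f"{pathlib.Path(path).name}: {exc}") from exc


def write_forcing(forcing: ForcingSeries, path: str | pathlib.Path) -> None:
    forcing.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def read_measurements(
    path: str | pathlib.Path, stand: str = "", site: str = ""
) -> MeasurementSeries:
    """Read and validate a stand measurement series."""
    df = _read_csv(path, ("age", "height"))
    try:
        return MeasurementSeries.from_dataframe(df, stand=stand, site=site)
    except ValueError as exc:
        raise ParseError(f"{pathlib.Path(path).name}: {exc}") from exc


def write_measurements(series: MeasurementSeries, path: str | pathlib.Path) -> None:
    series.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def write_trajectory(traj: Trajectory, path: str | pathlib.Path) -> None:
    """Write a trajectory as tidy CSV; solver metadata and parameters go
    to a JSON sidecar (``<name>.meta.json``) so a re-run can be
    reproduced bit-identically."""
    path = pathlib.Path(path)
    traj.to_dataframe().to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = {
        "params": traj.params.to_dict(),
        "meta": _jsonable(traj.meta),
    }
    sidecar.write_text(json.dumps(meta, indent=2))


def read_trajectory_frame(path: str | pathlib.Path) -> pd.DataFrame:
    """Read a trajectory CSV back as a DataFrame (values round-trip at
    full precision)."""
    return pd.read_csv(path, float_precision="round_trip")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_manifest(
    path: str | pathlib.Path,
    command: str,
    *,
    seed: int | None = None,
    params: ModelParameters | None = None,
    inputs: dict | None = None,
    solver: dict | None = None,
) -> None:
    """JSON run manifest: enough metadata to re-run bit-identically."""
    from . import __version__

    manifest = {
        "tool": "meristree",
        "version": __version__,
        "command": command,
        "seed": seed,
        "inputs": _jsonable(inputs or {}),
        "params": params.to_dict() if params is not None else None,
        "solver": _jsonable(solver or {}),
    }
    pathlib.Path(path).write_text(json.dumps(manifest, indent=2))
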