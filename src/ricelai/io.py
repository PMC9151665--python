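"""Flat-file schemas: strict CSV/JSON readers and writers.

All interchange is CSV (per-pixel series) and JSON (results and manifests).
Readers validate headers and date formats and fail with the offending
column or line; writers emit ISO-8601 dates so that write -> read is an
identity round trip.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .crop_model import LAITrajectory, validate_weather
from .exceptions import InvalidInputError
from .preprocessing import CompositeSeries

__all__ = [
    "read_weather_csv",
    "write_weather_csv",
    "read_composite_csv",
    "write_composite_csv",
    "read_feature_csv",
    "write_feature_csv",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_result_json",
    "write_result_json",
]

_ISO_DATE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


def _FLOAT_FMT(v):
    # shortest decimal string that parses back to the identical double
    return repr(float(v))

WEATHER_COLUMNS = ["date", "tmax", "tmin", "srad"]
COMPOSITE_COLUMNS = ["date", "ndvi", "qa"]
FEATURE_COLUMNS_FILE = ["pixel_id", "region", "year", "date", "cum_srad", "cum_tmax", "cum_tmin", "lai"]
TRAJECTORY_COLUMNS = ["date", "lai", "gdd"]


def _check_header(frame: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing column(s) {missing}; header is {list(frame.columns)}")


def _parse_dates(frame: pd.DataFrame, path) -> pd.DataFrame:
    bad = [
        (i + 2, v)  # +2: 1-based with header line
        for i, v in enumerate(frame["date"].astype(str))
        if not _ISO_DATE.match(v)
    ]
    if bad:
        line, value = bad[0]
        raise InvalidInputError(
            f"{path}: line {line}: date {value!r} is not ISO-8601 (expected YYYY-MM-DD)"
        )
    frame = frame.copy()
    frame["date"] = pd.to_datetime(frame["date"], format="%Y-%m-%d")
    return frame


def read_weather_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, float_precision="round_trip")
    _check_header(frame, WEATHER_COLUMNS, path)
    return validate_weather(_parse_dates(frame, path))


def write_weather_csv(weather: pd.DataFrame, path) -> None:
    out = validate_weather(weather).copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_composite_csv(path) -> CompositeSeries:
    frame = pd.read_csv(path, float_precision="round_trip")
    _check_header(frame, COMPOSITE_COLUMNS, path)
    frame = _parse_dates(frame, path)
    qa = frame["qa"].to_numpy()
    return CompositeSeries(
        dates=pd.DatetimeIndex(frame["date"]),
        ndvi=frame["ndvi"].to_numpy(dtype=float),
        qa_good=qa.astype(bool) if qa.dtype != bool else qa,
    )


def write_composite_csv(series: CompositeSeries, path) -> None:
    out = series.to_frame()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_feature_csv(path, *, require_target: bool = False) -> pd.DataFrame:
    frame = pd.read_csv(path, float_precision="round_trip")
    required = FEATURE_COLUMNS_FILE if require_target else FEATURE_COLUMNS_FILE[:-1]
    _check_header(frame, required, path)
    return _parse_dates(frame, path)


def write_feature_csv(table: pd.DataFrame, path) -> None:
    out = table.copy()
    for col in FEATURE_COLUMNS_FILE:
        if col not in out.columns and col != "lai":
            out[col] = "" if col in ("pixel_id", "region") else np.nan
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    cols = [c for c in FEATURE_COLUMNS_FILE if c in out.columns]
    out[cols].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory_csv(path) -> LAITrajectory:
    frame = pd.read_csv(path, float_precision="round_trip")
    _check_header(frame, TRAJECTORY_COLUMNS, path)
    frame = _parse_dates(frame, path)
    return LAITrajectory(
        dates=pd.DatetimeIndex(frame["date"]),
        lai=frame["lai"].to_numpy(dtype=float),
        gdd=frame["gdd"].to_numpy(dtype=float),
    )


def write_trajectory_csv(traj: LAITrajectory, path) -> None:
    out = traj.to_frame()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_result_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_result_json(result: dict, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(result, indent=2, default=_default) + "\n")
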