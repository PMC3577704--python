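"""CSV and JSON readers/writers for the pipeline's plain-text interchange formats.

All dates are ISO-8601 calendar dates, all coordinates decimal degrees
(WGS-84 implied).  Readers validate required columns and parse dates to
``datetime.date``; writers emit the same dialect so every table round-trips.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

DEPLOYMENT_COLUMNS = ["drifter_id", "site_id", "release_date", "release_lat", "release_lon"]
RECOVERY_COLUMNS = ["drifter_id", "recovery_date"]
CARCASS_COLUMNS = ["species", "date", "lat", "lon", "ccl_cm", "gear_marks", "site_id"]


def _require(df: pd.DataFrame, columns: list[str], what: str, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file {path} is missing columns {missing}")


def _parse_date(df: pd.DataFrame, column: str) -> None:
    df[column] = pd.to_datetime(df[column]).dt.date


def read_deployments(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"drifter_id": str, "site_id": str})
    _require(df, DEPLOYMENT_COLUMNS, "deployments", path)
    _parse_date(df, "release_date")
    return df


def read_recoveries(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"drifter_id": str})
    _require(df, RECOVERY_COLUMNS, "recoveries", path)
    _parse_date(df, "recovery_date")
    for col in ("recovery_lat", "recovery_lon"):
        if col not in df.columns:
            df[col] = pd.NA
    return df


def read_carcasses(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"species": str, "site_id": str})
    _require(df, ["species", "date", "site_id"], "carcasses", path)
    _parse_date(df, "date")
    if "gear_marks" in df.columns:
        df["gear_marks"] = df["gear_marks"].astype(bool)
    return df


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["N", "m"], "quadrat counts", path)
    return df


def write_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_json(obj: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=str)


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
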