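"""CSV contracts for every pipeline table.

All tables are plain CSV with ISO-8601 timestamps.  Readers validate the
required columns and name the offender on failure; extra columns pass
through untouched.  Closure traces live one file per closure under a
``traces/`` directory, with the scalar metadata in ``# key: value``
header comments.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .chamber import ClosureTrace
from .params import ChamberSpec

ENV_COLUMNS = ["timestamp", "par", "t_air", "rh", "es", "ea", "vpd", "p_amb",
               "precipitation", "soil_moisture", "ca", "delta13c_air",
               "is_daytime"]
GASEX_COLUMNS = ["timestamp", "a", "e", "gs", "t_leaf", "ci", "iwue_true",
                 "delta_cap_true", "delta13c_a_true"]
FLUX_COLUMNS = ["closure_id", "timestamp", "f12", "f13", "f_co2", "f_h2o",
                "delta13c_a_picarro", "t_chamber_c", "rh_chamber",
                "qc_co2_pass", "qc_h2o_pass"]
POOL_COLUMNS = ["date", "pool", "generation", "delta13c_permil"]
IWUE_COLUMNS = ["date", "iwue_gas", "iwue_iso_complex", "iwue_iso_simple",
                "source_pool"]
SURFACE_COLUMNS = ["n", "lam", "rho", "p", "significant"]

_TRACE_META = ["closure_id", "timestamp", "volume_dm3", "needle_area_m2",
               "sample_flow_dm3_min", "ca_ambient", "delta13c_air",
               "t_chamber_c", "rh_chamber", "p_amb_kpa"]


def _require(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required column(s) {missing}")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_table(path: str | Path, columns: list[str], what: str,
               parse_dates: list[str] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=list(parse_dates))
    _require(df, columns, what)
    return df


def read_env(path: str | Path) -> pd.DataFrame:
    return read_table(path, ENV_COLUMNS, "env.csv", parse_dates=["timestamp"])


def read_gasex(path: str | Path) -> pd.DataFrame:
    return read_table(path, GASEX_COLUMNS, "gasex.csv", parse_dates=["timestamp"])


def read_fluxes(path: str | Path) -> pd.DataFrame:
    return read_table(path, FLUX_COLUMNS, "fluxes.csv", parse_dates=["timestamp"])


def read_pools(path: str | Path) -> pd.DataFrame:
    return read_table(path, POOL_COLUMNS, "pools.csv", parse_dates=["date"])


def read_iwue(path: str | Path) -> pd.DataFrame:
    return read_table(path, IWUE_COLUMNS, "iwue.csv", parse_dates=["date"])


def read_surface(path: str | Path) -> pd.DataFrame:
    return read_table(path, SURFACE_COLUMNS, "surface.csv")


def write_trace(trace: ClosureTrace, directory: str | Path) -> Path:
    """Write one closure trace as ``closure_<id>.csv`` with metadata header."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"closure_{trace.closure_id}.csv"
    ch = trace.chamber
    meta = {
        "closure_id": trace.closure_id,
        "timestamp": pd.Timestamp(trace.timestamp).isoformat(),
        "volume_dm3": ch.volume_dm3,
        "needle_area_m2": ch.needle_area_m2,
        "sample_flow_dm3_min": ch.sample_flow_dm3_min,
        "ca_ambient": trace.ca_ambient,
        "delta13c_air": trace.delta13c_air,
        "t_chamber_c": trace.t_chamber_c,
        "rh_chamber": trace.rh_chamber,
        "p_amb_kpa": trace.p_amb_kpa,
    }
    t_fast = np.asarray(trace.t_fast, dtype=float)
    t_slow = np.asarray(trace.t_slow, dtype=float)
    df = pd.DataFrame({"t_s": t_fast,
                       "c12_ppm": trace.c12, "c13_ppm": trace.c13})
    slow = pd.DataFrame({"t_s": t_slow,
                         "co2_ppm": trace.co2, "h2o_ppm": trace.h2o})
    merged = df.merge(slow, on="t_s", how="outer").sort_values("t_s")
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        merged.to_csv(fh, index=False)
    return path


def read_trace(path: str | Path) -> ClosureTrace:
    """Read one closure trace written by :func:`write_trace`."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    missing = [k for k in _TRACE_META if k not in meta]
    if missing:
        raise ValueError(f"{path}: missing trace metadata {missing}")
    for col in ["t_s", "c12_ppm", "c13_ppm", "co2_ppm", "h2o_ppm"]:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column(s) ['{col}']")
    fast = df.dropna(subset=["c12_ppm"])
    slow = df.dropna(subset=["co2_ppm"])
    chamber = ChamberSpec(volume_dm3=float(meta["volume_dm3"]),
                          needle_area_m2=float(meta["needle_area_m2"]),
                          sample_flow_dm3_min=float(meta["sample_flow_dm3_min"]))
    return ClosureTrace(
        closure_id=meta["closure_id"],
        timestamp=pd.Timestamp(meta["timestamp"]),
        t_fast=fast["t_s"].to_numpy(), c12=fast["c12_ppm"].to_numpy(),
        c13=fast["c13_ppm"].to_numpy(),
        t_slow=slow["t_s"].to_numpy(), co2=slow["co2_ppm"].to_numpy(),
        h2o=slow["h2o_ppm"].to_numpy(),
        chamber=chamber,
        ca_ambient=float(meta["ca_ambient"]),
        delta13c_air=float(meta["delta13c_air"]),
        t_chamber_c=float(meta["t_chamber_c"]),
        rh_chamber=float(meta["rh_chamber"]),
        p_amb_kpa=float(meta["p_amb_kpa"]))


def read_traces(directory: str | Path) -> list[ClosureTrace]:
    paths = sorted(Path(directory).glob("closure_*.csv"))
    if not paths:
        raise ValueError(f"no closure_*.csv files under {directory}")
    return [read_trace(p) for p in paths]
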