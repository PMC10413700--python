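"""CSV and JSON writers/readers shared by the library and the CLI.

CSV dialect: comma-separated, '.' decimal, one mandatory header row,
preceded by a single '#'-prefixed comment line stating units.  The same
dialect is used by every writer and reader in the package.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import FitResult, ObservedT1Series
from .kinetics import ConcentrationCurves
from .relaxometry import PsirSeries, T1Series

__all__ = [
    "write_concentration_csv",
    "write_t1_csv",
    "write_psir_csv",
    "write_observations_csv",
    "read_observations_csv",
    "fit_result_to_dict",
    "write_fit_result",
]


def _write(df: pd.DataFrame, path: Path, units: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# units: {units}\n")
        df.to_csv(fh, index=False)


def write_concentration_csv(curves: ConcentrationCurves, path: str | Path) -> None:
    """Columns: time_min, C_p, C_e, C_b, then C_t_<tissue> (+ catenary pools)."""
    cols = {"time_min": curves.times, "C_p": curves.c_p, "C_e": curves.c_e,
            "C_b": curves.c_b}
    for name, tc in curves.tissues.items():
        cols[f"C_t_{name}"] = tc.c_t
        if tc.c_me2 is not None:
            cols[f"C_me1_{name}"] = tc.c_me
            cols[f"C_me2_{name}"] = tc.c_me2
    _write(pd.DataFrame(cols), Path(path),
           "time_min in minutes; concentrations in mmol/L")


def write_t1_csv(series: T1Series, path: str | Path) -> None:
    """Columns: time_min, then T1_ms_<channel>."""
    cols = {"time_min": series.times}
    for name, t1 in series.channels.items():
        cols[f"T1_ms_{name}"] = t1
    _write(pd.DataFrame(cols), Path(path), "time_min in minutes; T1 in ms")


def write_psir_csv(series: PsirSeries, path: str | Path) -> None:
    """Columns: time_min, TI_null_ms, then S_<channel> (dimensionless)."""
    cols = {"time_min": series.times, "TI_null_ms": series.ti_null}
    for name, s in series.signals.items():
        cols[f"S_{name}"] = s
    _write(pd.DataFrame(cols), Path(path),
           "time_min in minutes; TI in ms; S dimensionless in [-1, 1]")


def write_observations_csv(series: ObservedT1Series, path: str | Path) -> None:
    """Columns: time_min, T1_blood_ms, T1_<tissue>_ms, optional sd_<channel>_ms."""
    cols = {"time_min": series.times}
    for name, t1 in series.channels.items():
        key = "T1_blood_ms" if name == "blood" else f"T1_{name}_ms"
        cols[key] = t1
    for name, sd in series.sd.items():
        cols[f"sd_{name}_ms"] = sd
    _write(pd.DataFrame(cols), Path(path), "time_min in minutes; T1 and sd in ms")


def read_observations_csv(path: str | Path) -> ObservedT1Series:
    """Read an observation CSV (channel-wise missing cells allowed as NaN)."""
    df = pd.read_csv(path, comment="#")
    if df.empty or "time_min" not in df.columns:
        raise ValueError(f"{path}: no time_min column or no data rows")
    channels: dict[str, np.ndarray] = {}
    sd: dict[str, np.ndarray] = {}
    for col in df.columns:
        if col == "time_min":
            continue
        if col.startswith("sd_") and col.endswith("_ms"):
            sd[col[3:-3]] = df[col].to_numpy(float)
        elif col.startswith("T1_") and col.endswith("_ms"):
            channels[col[3:-3]] = df[col].to_numpy(float)
    if not channels:
        raise ValueError(f"{path}: no T1_<channel>_ms columns found")
    return ObservedT1Series(times=df["time_min"].to_numpy(float),
                            channels=channels, sd=sd)


def fit_result_to_dict(result: FitResult) -> dict:
    """JSON-serializable view of a fit result, stage ledger included."""
    return {
        "preset": result.preset.model_dump(),
        "rmse_ms": result.rmse,
        "stages": [dataclasses.asdict(s) for s in result.stages],
        "residuals_ms": {k: list(map(float, v))
                         for k, v in result.residuals.items()},
    }


def write_fit_result(result: FitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit_result_to_dict(result), indent=2))
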