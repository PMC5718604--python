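"""Delimited-text and JSON I/O for parameter tables, TACs and results.

All tabular formats are plain CSV with required headers:

* kinetic parameter table: ``region,K1,k2,k3,k4,Vb``
* TAC table: ``frame_start_min,frame_end_min`` then one column per region
  (kBq/mL)
* input-function table: ``time_min,plasma_parent_kBq_mL,whole_blood_kBq_mL``

Result sweeps are written as CSV plus a JSON sidecar carrying the cubic-fit
summary, the configuration hash and the seed, so every artifact is traceable
to the exact configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .kinetics import FrameSchedule, InputFunction, KineticParams, RegionalTAC
from .perturb import DeltaSUVRCurve

__all__ = [
    "read_params_table",
    "write_params_table",
    "read_tac_table",
    "write_tac_table",
    "read_input_function",
    "write_input_function",
    "write_sweep_results",
    "config_hash",
]

_PARAM_COLS = ["region", "K1", "k2", "k3", "k4", "Vb"]


def read_params_table(path: str | Path) -> dict[str, KineticParams]:
    """Read a regional kinetic-parameter table (CSV, header required)."""
    df = pd.read_csv(path)
    missing = [c for c in _PARAM_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"parameter table missing columns: {missing}")
    return {
        str(row.region): KineticParams(
            K1=float(row.K1), k2=float(row.k2), k3=float(row.k3),
            k4=float(row.k4), Vb=float(row.Vb),
        )
        for row in df.itertuples()
    }


def write_params_table(params: Mapping[str, KineticParams], path: str | Path) -> None:
    rows = [
        {"region": r, "K1": p.K1, "k2": p.k2, "k3": p.k3, "k4": p.k4, "Vb": p.Vb}
        for r, p in params.items()
    ]
    pd.DataFrame(rows, columns=_PARAM_COLS).to_csv(path, index=False)


def read_tac_table(path: str | Path) -> dict[str, RegionalTAC]:
    """Read frame-averaged TACs; one RegionalTAC per region column."""
    df = pd.read_csv(path)
    for col in ("frame_start_min", "frame_end_min"):
        if col not in df.columns:
            raise ValueError(f"TAC table missing column {col!r}")
    schedule = FrameSchedule(
        tuple(zip(df["frame_start_min"].astype(float), df["frame_end_min"].astype(float)))
    )
    regions = [c for c in df.columns if c not in ("frame_start_min", "frame_end_min")]
    if not regions:
        raise ValueError("TAC table has no region columns")
    return {
        r: RegionalTAC(region=r, schedule=schedule, values=df[r].to_numpy(float))
        for r in regions
    }


def write_tac_table(tacs: Iterable[RegionalTAC], path: str | Path) -> None:
    tacs = list(tacs)
    schedule = tacs[0].schedule
    if any(t.schedule != schedule for t in tacs):
        raise ValueError("all TACs must share one frame schedule")
    df = pd.DataFrame(
        {"frame_start_min": schedule.starts, "frame_end_min": schedule.ends}
    )
    for t in tacs:
        df[t.region] = t.values
    df.to_csv(path, index=False)


def read_input_function(path: str | Path) -> InputFunction:
    df = pd.read_csv(path)
    cols = ("time_min", "plasma_parent_kBq_mL", "whole_blood_kBq_mL")
    for col in cols:
        if col not in df.columns:
            raise ValueError(f"input-function table missing column {col!r}")
    return InputFunction(
        times=df["time_min"].to_numpy(float),
        plasma=df["plasma_parent_kBq_mL"].to_numpy(float),
        blood=df["whole_blood_kBq_mL"].to_numpy(float),
    )


def write_input_function(inp: InputFunction, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_min": inp.times,
            "plasma_parent_kBq_mL": inp.plasma,
            "whole_blood_kBq_mL": inp.blood,
        }
    ).to_csv(path, index=False)


def config_hash(obj) -> str:
    """Stable short hash of any YAML-serialisable configuration object."""
    canon = yaml.safe_dump(obj, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_sweep_results(
    curves: Iterable[DeltaSUVRCurve],
    out_csv: str | Path,
    sidecar_json: str | Path | None = None,
    config: Mapping | None = None,
    seed: int | None = None,
) -> None:
    """Write sweep curves as tidy CSV plus a JSON sidecar with fit summaries."""
    rows = []
    side = {"curves": [], "seed": seed}
    if config is not None:
        side["config_hash"] = config_hash(dict(config))
    for c in curves:
        label = f"{c.mode}:{c.target}/{c.reference}"
        for g, d in zip(c.grid_pct, c.delta_suvr_pct):
            rows.append(
                {
                    "mode": c.mode,
                    "target": c.target,
                    "reference": c.reference,
                    "dk1_pct": g,
                    "suvr": c.baseline_suvr * (1 + d / 100.0),
                    "delta_suvr_pct": d,
                }
            )
        side["curves"].append(
            {
                "label": label,
                "baseline_suvr": c.baseline_suvr,
                "cubic_coeffs_desc": None
                if c.cubic_coeffs is None
                else [float(v) for v in c.cubic_coeffs],
                "r_squared": None if c.r_squared is None else float(c.r_squared),
            }
        )
    pd.DataFrame(rows).to_csv(out_csv, index=False)
    if sidecar_json is not None:
        Path(sidecar_json).write_text(json.dumps(side, indent=2))
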