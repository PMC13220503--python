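"""Delimited-text readers and writers for the evidence formats.

Survival datasets travel as CSV with columns id, time, event, arm, endpoint
(time in years); digitized curves as two CSVs (step coordinates; risk table).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .datatypes import DigitizedCurve, SurvivalDataset

IPD_COLUMNS = ["id", "time", "event", "arm", "endpoint"]


def write_ipd(datasets, path) -> None:
    """Write one or many SurvivalDatasets to a single delimited file."""
    if isinstance(datasets, SurvivalDataset):
        datasets = [datasets]
    elif isinstance(datasets, dict):
        datasets = list(datasets.values())
    frames = [d.to_frame() for d in datasets]
    pd.concat(frames, ignore_index=True)[IPD_COLUMNS].to_csv(path, index=False)


def read_ipd(path) -> Dict[Tuple[str, str], SurvivalDataset]:
    """Read a delimited IPD file into {(arm, endpoint): SurvivalDataset}."""
    df = pd.read_csv(path)
    missing = [c for c in ("time", "event", "arm", "endpoint")
               if c not in df.columns]
    if missing:
        raise ValueError(f"IPD file {path} missing columns {missing}")
    out = {}
    for (arm, ep), sub in df.groupby(["arm", "endpoint"]):
        out[(str(arm), str(ep))] = SurvivalDataset(
            sub["time"].to_numpy(float), sub["event"].to_numpy(int),
            arm=str(arm), endpoint=str(ep))
    return out


def write_curve(curve: DigitizedCurve, coords_path, risk_path) -> None:
    curve.coords_frame().to_csv(coords_path, index=False)
    curve.risk_frame().to_csv(risk_path, index=False)


def read_curve(coords_path, risk_path, total_events: Optional[int] = None,
               arm: str = "arm", endpoint: str = "OS") -> DigitizedCurve:
    coords = pd.read_csv(coords_path)
    risk = pd.read_csv(risk_path)
    return DigitizedCurve(
        coords["time"].to_numpy(float), coords["survival"].to_numpy(float),
        risk["time"].to_numpy(float), risk["n_at_risk"].to_numpy(int),
        total_events=total_events, arm=arm, endpoint=endpoint)
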