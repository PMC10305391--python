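"""Plain-CSV input/output for waveforms and interval series."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import NNISeries, PPGRecording

__all__ = [
    "read_ppg_csv",
    "write_ppg_csv",
    "read_nni_csv",
    "write_nni_csv",
    "write_manifest",
]


def read_ppg_csv(path: str | Path, fs: float, subject_id: str = "", state: str = "") -> PPGRecording:
    """Read a waveform CSV with columns ``t_s, amplitude`` (or one amplitude column)."""
    df = pd.read_csv(path)
    if "amplitude" in df.columns:
        samples = df["amplitude"].to_numpy(dtype=float)
    else:
        samples = df.iloc[:, -1].to_numpy(dtype=float)
    t0 = float(df["t_s"].iloc[0]) if "t_s" in df.columns else 0.0
    return PPGRecording(samples=samples, fs=fs, subject_id=subject_id, state=state, t0=t0)


def write_ppg_csv(rec: PPGRecording, path: str | Path) -> None:
    pd.DataFrame({"t_s": rec.times, "amplitude": rec.samples}).to_csv(path, index=False)


def read_nni_csv(path: str | Path) -> NNISeries:
    """Read an NNI CSV: column ``nn_ms`` plus optional ``replaced`` flags."""
    df = pd.read_csv(path)
    col = "nn_ms" if "nn_ms" in df.columns else df.columns[0]
    intervals = df[col].to_numpy(dtype=float)
    replaced = (
        df["replaced"].to_numpy(dtype=bool)
        if "replaced" in df.columns
        else np.zeros(intervals.size, dtype=bool)
    )
    return NNISeries(intervals=intervals, replaced=replaced)


def write_nni_csv(nni: NNISeries, path: str | Path) -> None:
    pd.DataFrame({"nn_ms": nni.intervals, "replaced": nni.replaced.astype(int)}).to_csv(
        path, index=False
    )


def write_manifest(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
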