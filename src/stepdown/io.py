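"""Delimited-text readers and writers for all pipeline artefacts.

All files are UTF-8, tab-delimited with a mandatory header row and '.'
decimal separator.  Formats:

* trials:  participant_id, condition, block_index, trial_index,
           step_height_m, strategy
* markers: time_s, segment, marker, x_m, y_m, z_m  (long format)
* EDA:     time_s, eda_uS
* fear:    participant_id, condition, block_index, rating
* fits:    participant_id, condition, h_crit_m, slope_per_m, status,
           loglik, n_trials
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .cohort import EDATrace
from .markers import MarkerTrial
from .protocol import TrialRecord
from .psychometric import PsychometricFit

__all__ = [
    "write_trials", "read_trials", "write_markers", "read_markers",
    "write_eda", "read_eda", "write_fear", "read_fear", "write_fits",
    "read_fits",
]

_SEP = "\t"


def write_trials(records: Iterable[TrialRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "condition": r.condition,
                "block_index": r.block_index,
                "trial_index": r.trial_index,
                "step_height_m": r.step_height_m,
                "strategy": r.strategy,
            }
            for r in records
        ]
    )
    df.to_csv(path, sep=_SEP, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_SEP)
    required = {"participant_id", "condition", "block_index", "trial_index",
                "step_height_m", "strategy"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trials file missing columns: {sorted(missing)}")
    return df


def write_markers(trial: MarkerTrial, path: str | Path) -> None:
    frames = []
    for seg, arr in trial.markers.items():
        T, M, _ = arr.shape
        idx = np.arange(T * M)
        frames.append(
            pd.DataFrame(
                {
                    "time_s": trial.time_s[idx // M],
                    "segment": seg,
                    "marker": (idx % M).astype(int),
                    "x_m": arr.reshape(-1, 3)[:, 0],
                    "y_m": arr.reshape(-1, 3)[:, 1],
                    "z_m": arr.reshape(-1, 3)[:, 2],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep=_SEP, index=False)


def read_markers(path: str | Path) -> tuple[dict, np.ndarray, float]:
    """Long-format marker file -> (segment -> (T, M, 3) dict, time, fs)."""
    df = pd.read_csv(path, sep=_SEP)
    times = np.sort(df["time_s"].unique())
    if times.size < 2:
        raise ValueError("marker file holds fewer than two frames")
    fs = 1.0 / float(np.median(np.diff(times)))
    out = {}
    for seg, sub in df.groupby("segment"):
        markers = np.sort(sub["marker"].unique())
        arr = np.full((times.size, markers.size, 3), np.nan)
        t_idx = np.searchsorted(times, sub["time_s"].to_numpy())
        m_idx = np.searchsorted(markers, sub["marker"].to_numpy())
        arr[t_idx, m_idx] = sub[["x_m", "y_m", "z_m"]].to_numpy()
        out[seg] = arr
    return out, times, fs


def write_eda(trace: EDATrace, path: str | Path) -> None:
    t = np.arange(trace.signal.size) / trace.fs
    pd.DataFrame({"time_s": t, "eda_uS": trace.signal}).to_csv(
        path, sep=_SEP, index=False
    )


def read_eda(path: str | Path, condition: str = "unknown") -> EDATrace:
    df = pd.read_csv(path, sep=_SEP)
    t = df["time_s"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 1.0
    return EDATrace(fs, df["eda_uS"].to_numpy(), condition)


def write_fear(rows: Iterable[tuple[str, str, int, float]], path: str | Path) -> None:
    """Rows of (participant_id, condition, block_index, rating)."""
    pd.DataFrame(
        rows, columns=["participant_id", "condition", "block_index", "rating"]
    ).to_csv(path, sep=_SEP, index=False)


def read_fear(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_SEP)


def write_fits(
    fits: Iterable[tuple[str, str, PsychometricFit]], path: str | Path
) -> None:
    """Rows of (participant_id, condition, fit)."""
    pd.DataFrame(
        [
            {
                "participant_id": pid,
                "condition": cond,
                "h_crit_m": f.h_crit,
                "slope_per_m": f.slope,
                "status": f.status,
                "loglik": f.log_likelihood,
                "n_trials": f.n_trials,
            }
            for pid, cond, f in fits
        ]
    ).to_csv(path, sep=_SEP, index=False)


def read_fits(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_SEP)
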