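"""Clinical motor-score representations: FMA and WMFT summaries.

The Wolf Motor Function Test (WMFT) times 15 upper-limb tasks; a task
not completed within the 120 s limit is assigned the cap.  Two summary
statistics are supported:

* mean performance rate — the mean over tasks of 60 / time (per minute),
  with rate 0 for tasks not completed within 120 s;
* log performance time (lpt) — the natural log of the mean capped task
  time, bounded above by ln(120).

The Fugl-Meyer assessment (FMA) upper-limb motor total is carried as an
opaque 0-66 integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NOT_COMPLETED",
    "N_TASKS",
    "TIME_CAP",
    "WmftRecord",
    "MotorScores",
    "cap_time",
    "task_rate",
    "wmft_mean_rate",
    "wmft_lpt",
    "scores_from_record",
    "read_scores_csv",
    "write_scores_csv",
]

N_TASKS = 15
TIME_CAP = 120.0
#: CSV sentinel for a task the subject could not complete
NOT_COMPLETED = "NC"

_TASK_COLUMNS = [f"task_{k:02d}" for k in range(1, N_TASKS + 1)]


def _is_not_completed(raw) -> bool:
    if raw is None or raw is NOT_COMPLETED:
        return True
    if isinstance(raw, str):
        return raw.strip().upper() == NOT_COMPLETED
    return isinstance(raw, float) and math.isnan(raw)


def cap_time(raw_time) -> float:
    """Capped task time: min(time, 120); a not-completed task scores 120."""
    if _is_not_completed(raw_time):
        return TIME_CAP
    t = float(raw_time)
    if t <= 0:
        raise ValueError(f"task time must be positive (got {t})")
    return min(t, TIME_CAP)


def task_rate(raw_time) -> float:
    """Per-minute performance rate 60/time; 0 beyond the 120 s limit.

    A task finished in exactly 120 s counts as completed (rate 0.5);
    slower or not-completed tasks earn rate 0.
    """
    if _is_not_completed(raw_time):
        return 0.0
    t = float(raw_time)
    if t <= 0:
        raise ValueError(f"task time must be positive (got {t})")
    return 60.0 / t if t <= TIME_CAP else 0.0


@dataclass(frozen=True)
class WmftRecord:
    """One subject's 15 WMFT task times (seconds) at one timepoint.

    Not-completed tasks are stored as NaN.
    """

    subject: str
    timepoint: str
    times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(
            [np.nan if _is_not_completed(t) else float(t) for t in np.ravel(self.times)]
        )
        if times.shape != (N_TASKS,):
            raise ValueError(f"a WMFT record needs exactly {N_TASKS} task times")
        if np.any(times[~np.isnan(times)] <= 0):
            raise ValueError("task times must be positive")
        object.__setattr__(self, "times", times)


def wmft_mean_rate(record: WmftRecord) -> float:
    """Mean of the 15 per-task performance rates, per minute."""
    return float(np.mean([task_rate(t) for t in record.times]))


def wmft_lpt(record: WmftRecord, per_task_log: bool = False) -> float:
    """WMFT log performance time.

    Default: ln of the mean capped task time (bounded by ln 120).  With
    ``per_task_log`` the alternative reading — the mean of the per-task
    log times — is returned instead, for sensitivity analyses.
    """
    capped = np.array([cap_time(t) for t in record.times])
    if per_task_log:
        return float(np.mean(np.log(capped)))
    return float(np.log(capped.mean()))


@dataclass(frozen=True)
class MotorScores:
    """Summary motor scores for one subject at one timepoint."""

    subject: str
    timepoint: str
    fma_total: int
    wmft_rate: float
    wmft_lpt: float

    def __post_init__(self) -> None:
        if not 0 <= self.fma_total <= 66:
            raise ValueError("FMA total must lie in [0, 66]")
        if self.wmft_rate < 0:
            raise ValueError("WMFT rate must be nonnegative")
        if self.wmft_lpt > math.log(TIME_CAP) + 1e-12:
            raise ValueError("WMFT-lpt cannot exceed ln(120)")


def scores_from_record(record: WmftRecord, fma_total: int, per_task_log: bool = False) -> MotorScores:
    return MotorScores(
        subject=record.subject,
        timepoint=record.timepoint,
        fma_total=int(fma_total),
        wmft_rate=wmft_mean_rate(record),
        wmft_lpt=wmft_lpt(record, per_task_log=per_task_log),
    )


def read_scores_csv(path) -> pd.DataFrame:
    """Read a clinical score table (one row per subject x timepoint).

    Expected columns: ``subject, timepoint, fma_total, task_01 ..
    task_15``; task entries are seconds or the sentinel ``NC`` (read as
    NaN).  Missing columns raise, naming the first absent one.
    """
    df = pd.read_csv(path, na_values=[NOT_COMPLETED])
    for col in ["subject", "timepoint", "fma_total", *_TASK_COLUMNS]:
        if col not in df.columns:
            raise ValueError(f"score table is missing column {col!r}")
    return df


def write_scores_csv(df: pd.DataFrame, path) -> None:
    """Write a score table, encoding not-completed tasks as ``NC``."""
    out = df.copy()
    for col in _TASK_COLUMNS:
        out[col] = out[col].map(lambda v: NOT_COMPLETED if pd.isna(v) else repr(float(v)))
    out.to_csv(Path(path), index=False)


def records_from_frame(df: pd.DataFrame):
    """Iterate (WmftRecord, fma_total) over a score table's rows."""
    for _, row in df.iterrows():
        yield (
            WmftRecord(
                subject=str(row["subject"]),
                timepoint=str(row["timepoint"]),
                times=row[_TASK_COLUMNS].to_numpy(dtype=float),
            ),
            int(row["fma_total"]),
        )
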