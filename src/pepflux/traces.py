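"""Processing of dual-channel pyranine traces into the normalized ratio
readout and replicate summaries.

The assay's readout is F_R, the 460 nm-excitation signal divided by the
415 nm-excitation signal (emission 510 nm), normalized to 1 at the first
sample of each run.  Condition summaries are the replicate mean of F_R over
a readout window (55-65 s by default) with the standard error of the mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import TraceError, WindowError
from .simulate import FluorescenceTrace

__all__ = [
    "RatioTrace",
    "WindowStat",
    "compute_ratio",
    "normalize",
    "window_stats",
    "write_traces_csv",
    "read_traces_csv",
    "summarize_conditions",
    "DEFAULT_WINDOW",
]

#: Readout window in seconds: mean F_R is taken over this span.
DEFAULT_WINDOW = (55.0, 65.0)


@dataclass
class RatioTrace:
    """Fluorescence-ratio time series F_R(t) = f460/f415."""

    time: np.ndarray
    f_r: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.f_r = np.asarray(self.f_r, dtype=float)
        if len(self.time) != len(self.f_r):
            raise TraceError("time and f_r must have equal lengths")


@dataclass(frozen=True)
class WindowStat:
    """Across-replicate summary of F_R over a readout window."""

    window: tuple[float, float]
    mean_f_r: float
    sem: float
    n_replicates: int


def compute_ratio(trace: FluorescenceTrace) -> RatioTrace:
    """Elementwise 460/415 excitation ratio; not yet normalized."""
    if len(trace.time) == 0:
        raise TraceError("empty trace")
    if np.any(trace.f415 <= 0):
        raise TraceError("f415 contains zero or negative values")
    return RatioTrace(trace.time.copy(), trace.f460 / trace.f415, normalized=False)


def normalize(trace: RatioTrace) -> RatioTrace:
    """Scale the ratio to 1 at the first reading.

    Idempotent and invariant to multiplying the whole trace by a constant.
    """
    if len(trace.f_r) == 0:
        raise TraceError("cannot normalize an empty trace")
    first = trace.f_r[0]
    if first <= 0:
        raise TraceError("first ratio value must be positive")
    return RatioTrace(trace.time.copy(), trace.f_r / first, normalized=True)


def window_stats(
    replicates: Sequence[RatioTrace],
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> WindowStat:
    """Replicate mean and SEM of F_R over a time window.

    Each replicate contributes the mean of its samples with t in
    [t_start, t_end] (both endpoints included); the across-replicate mean
    and SEM (sample SD with n-1 denominator over sqrt(n)) summarize the
    condition.  A single replicate yields sem = 0 with a warning.
    """
    t0, t1 = window
    if not t0 < t1:
        raise WindowError(f"window start {t0} must precede end {t1}")
    if len(replicates) == 0:
        raise WindowError("no replicates supplied")
    means = []
    for rep in replicates:
        if len(rep.time) == 0 or rep.time[0] > t0 or rep.time[-1] < t1:
            raise WindowError(
                f"replicate span does not cover window [{t0}, {t1}] s"
            )
        mask = (rep.time >= t0) & (rep.time <= t1)
        if not mask.any():
            raise WindowError(f"no samples inside window [{t0}, {t1}] s")
        means.append(float(np.mean(rep.f_r[mask])))
    n = len(means)
    mean = float(np.mean(means))
    if n == 1:
        warnings.warn("single replicate: SEM reported as 0", stacklevel=2)
        sem = 0.0
    else:
        sem = float(np.std(means, ddof=1) / np.sqrt(n))
    return WindowStat(window=(t0, t1), mean_f_r=mean, sem=sem, n_replicates=n)


# ---------------------------------------------------------------------------
# Tabular I/O: long-form trace CSV (replicate, time_s, f460, f415)
# ---------------------------------------------------------------------------

def write_traces_csv(traces: Sequence[FluorescenceTrace], path) -> None:
    """Write replicates as long-form CSV with columns
    replicate, time_s, f460, f415."""
    frames = []
    for i, tr in enumerate(traces):
        frames.append(
            pd.DataFrame(
                {
                    "replicate": i,
                    "time_s": tr.time,
                    "f460": tr.f460,
                    "f415": tr.f415,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path) -> list[FluorescenceTrace]:
    """Read a long-form trace CSV back into per-replicate traces."""
    df = pd.read_csv(path)
    required = {"replicate", "time_s", "f460", "f415"}
    missing = required - set(df.columns)
    if missing:
        raise TraceError(f"trace CSV missing columns: {sorted(missing)}")
    traces = []
    for _, grp in df.groupby("replicate", sort=True):
        traces.append(
            FluorescenceTrace(
                grp["time_s"].to_numpy(),
                grp["f460"].to_numpy(),
                grp["f415"].to_numpy(),
            )
        )
    return traces


def summarize_conditions(
    condition_traces: dict[str, tuple[float, Sequence[FluorescenceTrace]]],
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Build the classification-ready summary table.

    ``condition_traces`` maps condition_id -> (voltage_mV, replicate traces).
    Returns a DataFrame with columns condition_id, voltage_mV, mean_f_r_60s,
    sem, n.
    """
    rows = []
    for cid, (voltage, traces) in condition_traces.items():
        ratios = [normalize(compute_ratio(tr)) for tr in traces]
        stat = window_stats(ratios, window)
        rows.append(
            {
                "condition_id": cid,
                "voltage_mV": voltage,
                "mean_f_r_60s": stat.mean_f_r,
                "sem": stat.sem,
                "n": stat.n_replicates,
            }
        )
    return pd.DataFrame(rows)
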