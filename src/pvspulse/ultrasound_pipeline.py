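"""Wall-motion and pulse-timing extraction from M-mode and Doppler traces.

Wall motion is the systolic−diastolic carotid diameter excursion, computed
per cardiac cycle as max−min of the diameter trace within the cycle window;
the pulse-timing measure is the interval between the R-wave and the peak
blood velocity.  Cycle windows are [R_i, R_{i+1}); a trailing partial cycle
is discarded.  Timepoint summaries (baseline vs post-injection periods) are
arithmetic means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .synth_cohort import DopplerTrace, MModeTrace

__all__ = [
    "WallMotionResult",
    "TimingResult",
    "extract_wall_motion",
    "extract_peak_velocity_interval",
    "summarize_timepoints",
]

MIN_CYCLES = 3


@dataclass(frozen=True)
class WallMotionResult:
    """Per-cycle diameter excursions (mm) and their mean."""

    excursions: np.ndarray
    mean_excursion: float
    n_cycles: int


@dataclass(frozen=True)
class TimingResult:
    """Per-cycle R-wave → peak-velocity intervals (ms) and their mean."""

    intervals: np.ndarray
    mean_interval: float


def _cycle_windows(times: np.ndarray, r_waves: np.ndarray) -> list[np.ndarray]:
    """Sample-index masks for each complete cycle [R_i, R_{i+1})."""
    if len(r_waves) < 2:
        raise ValueError("at least two R-wave events are required")
    windows = []
    for start, stop in zip(r_waves[:-1], r_waves[1:]):
        if stop > times[-1]:
            break  # partial trailing cycle
        idx = np.nonzero((times >= start) & (times < stop))[0]
        if idx.size:
            windows.append(idx)
    if len(windows) < MIN_CYCLES:
        raise ValueError(f"need at least {MIN_CYCLES} complete cardiac cycles")
    return windows


def extract_wall_motion(trace: MModeTrace) -> WallMotionResult:
    """Per-cycle max−min diameter and the across-cycle mean."""
    times = np.asarray(trace.times)
    diameters = np.asarray(trace.diameters)
    excursions = np.array([
        diameters[idx].max() - diameters[idx].min()
        for idx in _cycle_windows(times, np.asarray(trace.r_wave_times))])
    return WallMotionResult(excursions=excursions,
                            mean_excursion=float(excursions.mean()),
                            n_cycles=excursions.size)


def extract_peak_velocity_interval(trace: DopplerTrace) -> TimingResult:
    """Per-cycle argmax(velocity) − R-wave time and the across-cycle mean."""
    times = np.asarray(trace.times)
    velocities = np.asarray(trace.velocities)
    r_waves = np.asarray(trace.r_wave_times)
    intervals = []
    for idx, start in zip(_cycle_windows(times, r_waves), r_waves):
        intervals.append(times[idx[np.argmax(velocities[idx])]] - start)
    intervals = np.asarray(intervals)
    return TimingResult(intervals=intervals, mean_interval=float(intervals.mean()))


def summarize_timepoints(values: Sequence[float]) -> float:
    """Arithmetic mean across a period's repeated 5-minute timepoints."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("no timepoints in period")
    return float(values.mean())
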