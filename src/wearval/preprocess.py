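"""Epoch reintegration, vector magnitude, nonwear detection and valid days.

Research accelerometers export short epochs (10 s or 15 s here); all
classification happens on 60 s epochs, so series are first reintegrated by
summing counts within non-overlapping 60 s windows aligned to the series
start.  Nonwear time is then detected from sustained runs of zero activity
(vector magnitude for triaxial devices, the vertical axis otherwise), and a
day counts as valid only with at least 10 hours of detected wear.

Two zero-run rule sets are built in.  The intensity branch of the pipeline
uses the Hecht-style rule (90 min window); the energy-expenditure branch
uses the Troiano-style rule (60 min window), mirroring how commercial
analysis software pairs nonwear rules with its energy equations.  Both
allow a small number of interrupting "spike" minutes below a count ceiling.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MINUTES_PER_DAY, CountSeries


@dataclass(frozen=True)
class NonwearParams:
    """Zero-run nonwear rule: a minute is nonwear iff it lies in some
    interval that starts and ends on zero-activity minutes, spans at least
    ``window`` minutes, and contains at most ``spike_tolerance`` non-zero
    minutes, each below ``spike_ceiling`` CPM."""

    algorithm: str  # "hecht" | "troiano"
    window: int  # minutes
    spike_tolerance: int
    spike_ceiling: float  # CPM

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1 minute")
        if self.spike_tolerance < 0:
            raise ValueError("spike_tolerance must be >= 0")


def hecht_params(window: int = 90, spike_tolerance: int = 2,
                 spike_ceiling: float = 100.0) -> NonwearParams:
    """Hecht-style rule (intensity branch default): 90 min zero window."""
    return NonwearParams("hecht", window, spike_tolerance, spike_ceiling)


def troiano_params(window: int = 60, spike_tolerance: int = 2,
                   spike_ceiling: float = 100.0) -> NonwearParams:
    """Troiano-style rule (energy branch default): 60 min zero window."""
    return NonwearParams("troiano", window, spike_tolerance, spike_ceiling)


@dataclass
class WearMask:
    """Per-minute wear flags aligned to a 60 s CountSeries."""

    worn: np.ndarray  # bool, one entry per minute
    start_time: pd.Timestamp

    def __post_init__(self) -> None:
        self.worn = np.asarray(self.worn, dtype=bool)
        self.start_time = pd.Timestamp(self.start_time)

    @property
    def wear_minutes(self) -> int:
        return int(np.sum(self.worn))

    def to_csv(self, path) -> None:
        idx = pd.date_range(self.start_time, periods=len(self.worn), freq="60s")
        pd.DataFrame({"minute_start": idx, "worn": self.worn.astype(int)}).to_csv(
            Path(path), index=False
        )


def reintegrate(series: CountSeries, target_epoch: int = 60) -> CountSeries:
    """Sum counts (and steps) into non-overlapping ``target_epoch`` windows.

    Windows align to the series start time; a trailing partial window is
    dropped rather than padded, so no counts are fabricated.  Total counts
    over complete windows are conserved.
    """
    if target_epoch <= 0 or target_epoch % series.epoch_length != 0:
        raise ValueError(
            f"target epoch {target_epoch}s is not a positive multiple of the "
            f"source epoch {series.epoch_length}s"
        )
    k = target_epoch // series.epoch_length
    if k == 1:
        return series.replace()
    n_out = series.n_epochs // k

    def fold(arr):
        if arr is None:
            return None
        return arr[: n_out * k].reshape(n_out, k).sum(axis=1)

    return CountSeries(
        subject_id=series.subject_id,
        device=series.device,
        start_time=series.start_time,
        epoch_length=target_epoch,
        axis1=fold(series.axis1),
        axis2=fold(series.axis2),
        axis3=fold(series.axis3),
        steps=fold(series.steps),
    )


def vector_magnitude(series: CountSeries) -> np.ndarray:
    """Per-epoch vector magnitude sqrt(axis1² + axis2² + axis3²)."""
    if not series.is_triaxial:
        raise ValueError("vector magnitude requires a triaxial series")
    return np.sqrt(series.axis1 ** 2 + series.axis2 ** 2 + series.axis3 ** 2)


def _activity_metric(series: CountSeries) -> np.ndarray:
    return vector_magnitude(series) if series.is_triaxial else np.asarray(
        series.axis1, dtype=float
    )


def detect_nonwear(series: CountSeries, params: NonwearParams) -> WearMask:
    """Flag nonwear minutes of a 60 s series by the zero-run rule.

    A minute is nonwear iff it belongs to at least one interval that (a)
    starts and ends on zero-activity minutes, (b) spans ≥ ``params.window``
    minutes, (c) contains no minute at or above ``params.spike_ceiling``
    CPM, and (d) contains at most ``params.spike_tolerance`` non-zero
    minutes.  The worn mask is the complement of the union of all such
    intervals; runs may span midnight.
    """
    if series.epoch_length != 60:
        raise ValueError("detect_nonwear requires a series at 60 s epochs")
    a = _activity_metric(series)
    n = len(a)
    zero = a == 0
    under = a < params.spike_ceiling
    nonzero = (~zero).astype(int)

    nonwear = np.zeros(n, dtype=bool)
    mark = np.zeros(n + 1, dtype=int)  # difference array for interval union

    # Two-pointer scan: for each zero left endpoint, push the right endpoint
    # as far as the ceiling and spike budget allow, then trim back to the
    # last zero minute.  The farthest feasible right endpoint is
    # non-decreasing in the left endpoint, so the scan is linear.
    last_zero = np.full(n, -1)
    lz = -1
    for i in range(n):
        if zero[i]:
            lz = i
        last_zero[i] = lz

    j = -1
    spikes = 0
    for i in range(n):
        if not zero[i]:
            if i <= j:
                spikes -= 1  # minute i leaves the window
            continue
        if j < i:
            j = i - 1
            spikes = 0
        while j + 1 < n and under[j + 1] and spikes + nonzero[j + 1] <= params.spike_tolerance:
            j += 1
            spikes += nonzero[j]
        end = last_zero[j]
        if end >= i and end - i + 1 >= params.window:
            mark[i] += 1
            mark[end + 1] -= 1
    nonwear = np.cumsum(mark[:-1]) > 0
    return WearMask(worn=~nonwear, start_time=series.start_time)


def valid_days(mask: WearMask, min_hours: float = 10.0) -> np.ndarray:
    """Per-day validity: a day is valid iff worn ≥ ``min_hours`` × 60 minutes.

    The mask must cover whole days (length a multiple of 1440); a minute
    belongs to the day containing its start timestamp.
    """
    n = len(mask.worn)
    if n == 0 or n % MINUTES_PER_DAY != 0:
        raise ValueError("mask must cover whole days (multiple of 1440 minutes)")
    per_day = mask.worn.reshape(-1, MINUTES_PER_DAY).sum(axis=1)
    return per_day >= min_hours * 60
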