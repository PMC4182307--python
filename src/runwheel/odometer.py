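"""Reduction of wheel-rotation event streams to daily activity metrics.

A magnet-and-reed-switch odometer registers one event per wheel revolution.
This module turns one animal-day of revolution timestamps into the four
standard voluntary-running metrics:

* ``distance_km`` — revolutions x wheel circumference,
* ``time_h``     — summed span of running *bouts*, where a bout is a run of
  revolutions separated by gaps of at most 5 s,
* ``avg_speed_kmh`` — distance / time over the 24 h window,
* ``max_speed_kmh`` — peak smoothed instantaneous speed.

It also applies the day-level censoring rules used when hardware faults
(jammed wheel, unreset odometer, detached reed switch, water leak) invalidate
a recording.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

#: Default wheel circumference in metres (37.8 cm angled disc wheel).
DEFAULT_CIRCUMFERENCE_M = 0.378

#: Maximum inter-revolution gap (seconds) within a single bout. A gap of
#: exactly this value still counts as continuous running.
DEFAULT_MAX_GAP_S = 5.0

#: Window (number of consecutive within-bout revolution intervals) of the
#: rolling median used to smooth instantaneous speed before taking the
#: daily maximum.
MAX_SPEED_SMOOTHING_WINDOW = 5

SECONDS_PER_DAY = 86400.0

#: Valid reasons for censoring an animal-day of wheel data.
CENSOR_REASONS = (
    "jammed wheel",
    "odometer not reset",
    "detached switch",
    "water leak",
    "other",
)


@dataclass
class EventSeries:
    """Timestamps of individual wheel revolutions for one animal-day.

    Parameters
    ----------
    animal_id : str
        Animal identifier.
    age_day : int
        Age in days at the start of the 24 h recording window.
    timestamps : ndarray
        Strictly increasing revolution times in seconds within ``[0, 86400)``.
    circumference_m : float
        Wheel circumference in metres.
    """

    animal_id: str
    age_day: int
    timestamps: np.ndarray = field(default_factory=lambda: np.empty(0))
    circumference_m: float = DEFAULT_CIRCUMFERENCE_M

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.circumference_m <= 0:
            raise ValueError("circumference_m must be positive")
        t = self.timestamps
        if t.size:
            if t[0] < 0 or t[-1] >= SECONDS_PER_DAY:
                raise ValueError("timestamps must lie in [0, 86400) seconds")
            if np.any(np.diff(t) <= 0):
                raise ValueError("timestamps must be strictly increasing")

    @property
    def n_revolutions(self) -> int:
        return int(self.timestamps.size)


@dataclass
class DailyRecord:
    """One animal-day of derived wheel metrics plus censor status.

    Metric fields are ``nan`` when missing (censored day, or an undefined
    speed on a day with no measurable running time).
    """

    animal_id: str
    age_day: int
    distance_km: float = math.nan
    time_h: float = math.nan
    avg_speed_kmh: float = math.nan
    max_speed_kmh: float = math.nan
    censored: bool = False
    censor_reason: str = "none"


def segment_bouts(timestamps: np.ndarray, max_gap: float = DEFAULT_MAX_GAP_S) -> list[np.ndarray]:
    """Split revolution timestamps into bouts of continuous activity.

    Consecutive revolutions separated by at most ``max_gap`` seconds belong
    to the same bout; a larger gap starts a new bout. The union of the bouts
    is exactly the input.

    Parameters
    ----------
    timestamps : array-like
        Strictly increasing times in seconds.
    max_gap : float
        Largest inter-revolution gap (inclusive) treated as continuous.

    Returns
    -------
    list of ndarray
        One array of timestamps per bout, in chronological order.
    """
    t = np.asarray(timestamps, dtype=float)
    if t.size == 0:
        return []
    gaps = np.diff(t)
    if np.any(gaps <= 0):
        raise ValueError("timestamps must be strictly increasing")
    breaks = np.flatnonzero(gaps > max_gap) + 1
    return np.split(t, breaks)


def _max_smoothed_speed(
    timestamps: np.ndarray,
    circumference_m: float,
    max_gap: float,
    window: int = MAX_SPEED_SMOOTHING_WINDOW,
) -> float:
    """Daily maximum speed estimate (km/h).

    Instantaneous speed per revolution is circumference / inter-revolution
    interval; a rolling median over ``window`` consecutive intervals within a
    single bout guards against single-interval jitter. Returns ``nan`` when no
    bout contains ``window`` intervals.
    """
    if timestamps.size < window + 1:
        return math.nan
    intervals = np.diff(timestamps)
    # Intervals spanning a bout boundary are invalidated so that no smoothing
    # window mixes two bouts.
    intervals = np.where(intervals <= max_gap, intervals, np.nan)
    if intervals.size < window:
        return math.nan
    windows = np.lib.stride_tricks.sliding_window_view(intervals, window)
    med = np.median(windows, axis=1)  # windows containing nan -> nan
    valid = med[~np.isnan(med)]
    if valid.size == 0:
        return math.nan
    # m/s -> km/h
    return float(circumference_m / valid.min() * 3.6)


def daily_metrics(events: EventSeries, max_gap: float = DEFAULT_MAX_GAP_S) -> DailyRecord:
    """Compute the four daily metrics from one animal-day of revolutions.

    Distance is revolutions x circumference. Time is the sum of bout spans
    (last minus first timestamp per bout), so a single-revolution bout
    contributes no running time. Average speed is distance over time for the
    24 h window and is missing (nan) when no time accrued. Maximum speed is
    the peak rolling-median-smoothed instantaneous speed.
    """
    t = events.timestamps
    if t.size == 0:
        return DailyRecord(events.animal_id, events.age_day, 0.0, 0.0)
    bouts = segment_bouts(t, max_gap=max_gap)
    distance_km = t.size * events.circumference_m / 1000.0
    time_s = float(sum(b[-1] - b[0] for b in bouts))
    time_h = time_s / 3600.0
    avg = distance_km / time_h if time_h > 0 else math.nan
    vmax = _max_smoothed_speed(t, events.circumference_m, max_gap)
    if not math.isnan(avg) and not math.isnan(vmax):
        # the day's average is a hard lower bound for its maximum; the
        # median-smoothed estimate can dip ~1% below it on sparse days
        vmax = max(vmax, avg)
    return DailyRecord(events.animal_id, events.age_day, distance_km, time_h, avg, vmax)


def daily_table_from_events(events_frame, circumference_m: float = DEFAULT_CIRCUMFERENCE_M,
                            max_gap: float = DEFAULT_MAX_GAP_S):
    """Reduce a tidy events table (animal_id, age_day, timestamp_s) to daily records.

    Returns a DataFrame with one row per animal-day, in the daily-summary
    column order.
    """
    import pandas as pd

    rows = []
    for (animal, day), sub in events_frame.groupby(["animal_id", "age_day"], sort=True):
        series = EventSeries(str(animal), int(day),
                             sub["timestamp_s"].to_numpy(dtype=float), circumference_m)
        rows.append(vars(daily_metrics(series, max_gap=max_gap)))
    return pd.DataFrame(
        rows,
        columns=["animal_id", "age_day", "distance_km", "time_h",
                 "avg_speed_kmh", "max_speed_kmh", "censored", "censor_reason"],
    )


def apply_censoring(record: DailyRecord, reason: str) -> DailyRecord:
    """Return a censored copy of ``record`` with metric values cleared.

    ``reason`` must come from :data:`CENSOR_REASONS`. Downstream aggregations
    must skip censored records entirely.
    """
    if reason not in CENSOR_REASONS:
        raise ValueError(f"unknown censor reason {reason!r}; expected one of {CENSOR_REASONS}")
    return replace(
        record,
        distance_km=math.nan,
        time_h=math.nan,
        avg_speed_kmh=math.nan,
        max_speed_kmh=math.nan,
        censored=True,
        censor_reason=reason,
    )
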