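"""Per-animal onset detection: age at first sustained 20% decline.

The early readout of motor dysfunction used throughout this package is, per
animal and metric, the first age at which the daily value falls to at most
80% of that animal's baseline and stays there. The baseline for daily wheel
metrics is the running peak of a 7-day rolling mean over non-censored days;
weekly rotarod uses the animal's own post-training baseline with a single
confirmatory repeat. Clinical onset is the first age at which enhanced
tremor and defective hind-limb splay are both present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

WHEEL_METRICS = ("distance", "time", "avg_speed")

_METRIC_COLUMNS = {
    "distance": "distance_km",
    "time": "time_h",
    "avg_speed": "avg_speed_kmh",
}


@dataclass(frozen=True)
class OnsetResult:
    """Baseline and onset age for one animal and metric.

    ``onset_age`` is ``nan`` and ``censored`` is True when no sustained
    decline was observed within the series.
    """

    animal_id: str
    metric: str
    baseline_value: float
    baseline_day: float
    onset_age: float
    censored: bool
    threshold_fraction: float = 0.20


def rolling_baseline(
    days: np.ndarray,
    values: np.ndarray,
    censored: np.ndarray | None = None,
    window: int = 7,
    mode: str = "running-peak",
    reference: float | None = None,
) -> tuple[float, float]:
    """Baseline value and day for a daily series.

    In ``running-peak`` mode the baseline is the maximum of the
    ``window``-day rolling mean computed over non-censored days, reported at
    the centre day of the maximizing window. ``fixed-baseline`` mode returns
    the supplied ``reference`` anchored at the first day.
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if censored is None:
        censored = np.zeros(days.size, dtype=bool)
    keep = ~np.asarray(censored, dtype=bool) & ~np.isnan(values)
    d, v = days[keep], values[keep]
    if d.size == 0:
        raise ValueError("all days are censored; no baseline can be estimated")
    if mode == "fixed-baseline":
        if reference is None:
            raise ValueError("fixed-baseline mode requires a reference value")
        return float(reference), float(d[0])
    if mode != "running-peak":
        raise ValueError(f"unknown baseline mode {mode!r}")
    if d.size < window:
        raise ValueError(f"need at least {window} non-censored days, got {d.size}")
    means = pd.Series(v).rolling(window).mean().to_numpy()[window - 1:]
    centers = d[window // 2: window // 2 + means.size]
    i = int(np.argmax(means))
    return float(means[i]), float(centers[i])


def detect_decline_onset(
    days: np.ndarray,
    values: np.ndarray,
    baseline: float,
    baseline_day: float,
    censored: np.ndarray | None = None,
    threshold_fraction: float = 0.20,
    persistence: int = 3,
    animal_id: str = "",
    metric: str = "",
) -> OnsetResult:
    """First age of a sustained decline below ``(1 - threshold) * baseline``.

    The onset is the first day after ``baseline_day`` on which the value is
    at or below the cutoff and remains so on the next ``persistence - 1``
    evaluable (non-censored) days. Censored days are skipped, never
    interpolated. The crossing day itself is reported.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    if not (0 < threshold_fraction < 1):
        raise ValueError("threshold_fraction must be in (0, 1)")
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if censored is None:
        censored = np.zeros(days.size, dtype=bool)
    keep = ~np.asarray(censored, dtype=bool) & ~np.isnan(values) & (days > baseline_day)
    d, v = days[keep], values[keep]
    cutoff = (1.0 - threshold_fraction) * baseline
    below = v <= cutoff
    for i in range(below.size - persistence + 1):
        if below[i: i + persistence].all():
            return OnsetResult(animal_id, metric, baseline, baseline_day,
                               float(d[i]), False, threshold_fraction)
    return OnsetResult(animal_id, metric, baseline, baseline_day,
                       math.nan, True, threshold_fraction)


def rotarod_onset(
    test_ages: np.ndarray,
    latencies: np.ndarray,
    post_training_baseline: float | None = None,
    threshold_fraction: float = 0.20,
    animal_id: str = "",
) -> OnsetResult:
    """Onset age from weekly best-of-two rotarod latencies.

    The baseline defaults to the first post-training test. Onset is the
    first test age with latency at or below ``0.8 x baseline``, confirmed at
    the following test; an unconfirmed terminal crossing is censored. The
    5 s recording floor is an ordinary value, still comparable against the
    cutoff.
    """
    ages = np.asarray(test_ages, dtype=float)
    lat = np.asarray(latencies, dtype=float)
    if ages.size == 0:
        raise ValueError("empty rotarod latency series")
    baseline = float(lat[0]) if post_training_baseline is None else float(post_training_baseline)
    if baseline < 5.0:
        raise ValueError("rotarod baseline below the 5 s recording floor")
    cutoff = (1.0 - threshold_fraction) * baseline
    below = lat <= cutoff
    for i in range(below.size - 1):
        if below[i] and below[i + 1]:
            return OnsetResult(animal_id, "rotarod", baseline, float(ages[0]),
                               float(ages[i]), False, threshold_fraction)
    return OnsetResult(animal_id, "rotarod", baseline, float(ages[0]),
                       math.nan, True, threshold_fraction)


def clinical_milestones(
    ages: np.ndarray,
    tremor: np.ndarray,
    splay: np.ndarray,
    weights: np.ndarray,
) -> tuple[float, float]:
    """Clinical onset age and peak-weight age from weekly scores.

    Clinical onset is the first age at which enhanced tremor and defective
    hind-limb splay are both scored abnormal (nan if never). Peak-weight age
    is the age of maximum weight, ties broken to the earliest age.
    """
    ages = np.asarray(ages, dtype=float)
    tremor = np.asarray(tremor, dtype=bool)
    splay = np.asarray(splay, dtype=bool)
    weights = np.asarray(weights, dtype=float)
    if not (ages.size == tremor.size == splay.size == weights.size):
        raise ValueError("score and weight series must share one age grid")
    both = tremor & splay
    onset = float(ages[np.argmax(both)]) if both.any() else math.nan
    peak_age = float(ages[np.argmax(weights)])  # argmax returns the earliest max
    return onset, peak_age


def wheel_onsets_for_animal(
    daily: pd.DataFrame,
    metrics: tuple[str, ...] = WHEEL_METRICS,
    window: int = 7,
    threshold_fraction: float = 0.20,
    persistence: int = 3,
) -> list[OnsetResult]:
    """Run baseline estimation + decline detection for one animal's daily table."""
    animal_id = str(daily["animal_id"].iloc[0]) if len(daily) else ""
    days = daily["age_day"].to_numpy(dtype=float)
    cens = daily["censored"].to_numpy(dtype=bool)
    out = []
    for metric in metrics:
        values = daily[_METRIC_COLUMNS[metric]].to_numpy(dtype=float)
        base, base_day = rolling_baseline(days, values, cens, window=window)
        out.append(
            detect_decline_onset(
                days, values, base, base_day, cens,
                threshold_fraction=threshold_fraction, persistence=persistence,
                animal_id=animal_id, metric=metric,
            )
        )
    return out


def onsets_table(
    daily: pd.DataFrame,
    weekly: pd.DataFrame | None = None,
    window: int = 7,
    threshold_fraction: float = 0.20,
    persistence: int = 3,
) -> pd.DataFrame:
    """Per-animal onset results for a whole cohort, as a tidy table.

    Computes the three daily wheel metrics from ``daily`` and, when a
    ``weekly`` table is given, rotarod onset plus clinical and peak-weight
    milestones.
    """
    results: list[dict] = []
    if daily is not None and len(daily):
        for animal_id, sub in daily.groupby("animal_id", sort=True):
            for r in wheel_onsets_for_animal(
                sub.sort_values("age_day"), window=window,
                threshold_fraction=threshold_fraction, persistence=persistence,
            ):
                results.append(vars(r))
    if weekly is not None and len(weekly):
        for animal_id, sub in weekly.groupby("animal_id", sort=True):
            sub = sub.sort_values("age_day")
            ages = sub["age_day"].to_numpy(dtype=float)
            r = rotarod_onset(ages, sub["rotarod_s"].to_numpy(dtype=float),
                              threshold_fraction=threshold_fraction,
                              animal_id=str(animal_id))
            results.append(vars(r))
            clin, peak_w = clinical_milestones(
                ages, sub["tremor"].to_numpy(), sub["splay"].to_numpy(),
                sub["weight_g"].to_numpy(dtype=float),
            )
            results.append({
                "animal_id": str(animal_id), "metric": "clinical",
                "baseline_value": math.nan, "baseline_day": float(ages[0]),
                "onset_age": clin, "censored": math.isnan(clin),
                "threshold_fraction": math.nan,
            })
            results.append({
                "animal_id": str(animal_id), "metric": "peak_weight",
                "baseline_value": math.nan, "baseline_day": float(ages[0]),
                "onset_age": peak_w, "censored": False,
                "threshold_fraction": math.nan,
            })
    return pd.DataFrame(
        results,
        columns=["animal_id", "metric", "baseline_value", "baseline_day",
                 "onset_age", "censored", "threshold_fraction"],
    )
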