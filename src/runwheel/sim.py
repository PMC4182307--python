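"""Synthetic cohorts of home-cage wheel-running mice.

Generates rotation-event streams, weekly rotarod/weight/clinical series and
endpoint ages for cohorts of wild-type-like or SOD1-G93A-like animals, with
the longitudinal structure characteristic of voluntary running in this
disease model: a juvenile ramp to peak activity, a first decline to a
plateau, a late second decline and eventual cessation, with top running
speed preserved until late disease.

The event-level generative model is deliberately minimal: activity on a
night is a Poisson number of bouts placed in the 12 h dark phase, bout
durations are log-normal, and revolution intervals within a bout follow
circumference / speed with multiplicative jitter. Bout speeds are a mixture
of a "cruising" component, whose typical speed tracks the disease, and a
small "sprint" component whose speed is preserved until late disease —
this is what dissociates average speed (declines early) from maximum speed
(stable until ~120 d) in diseased animals.

Disease trajectories are piecewise log-linear between per-animal changepoints
drawn from truncated normal distributions, so a cohort is fully reproducible
from its master seed and each animal owns an independent substream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .odometer import (
    CENSOR_REASONS,
    DEFAULT_CIRCUMFERENCE_M,
    DailyRecord,
    EventSeries,
    apply_censoring,
    daily_metrics,
)

SECONDS_PER_HOUR = 3600.0
KMH_TO_M_PER_S = 1.0 / 3.6

ROTAROD_CEILING_S = 300.0
ROTAROD_FLOOR_S = 5.0


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectoryParams:
    """Shape of the activity-capacity curve over the life course.

    Capacity is a unitless multiplier (1 at peak health) with separate
    channels for bout count, cruising speed and sprint speed. All rates are
    per-day log-capacity slopes; ages are days of life.
    """

    ramp_rate: float                  # log-capacity growth/day during the juvenile ramp
    peak_day_mean: float              # age of peak activity (first decline starts here)
    peak_day_sd: float
    count_decline_rate: float = 0.0   # bout-count decline after the peak
    speed_decline_rate: float = 0.0   # cruising-speed decline after the peak
    plateau_offset_days: float = math.inf   # peak -> plateau duration (inf: no plateau stage)
    second_decline_day_mean: float = math.inf  # age the late decline begins
    second_decline_day_sd: float = 0.0
    cessation_day_mean: float = math.inf       # age activity reaches zero
    cessation_day_sd: float = 0.0
    slow_drift: float = 0.0           # per-day bout-count drift during the plateau (wild type)
    sprint_hold_day: float = math.inf  # top speed preserved until this age
    sprint_fade_rate: float = 0.05
    ramp_speed_fraction: float = 0.25  # speed ramps at this fraction of the count ramp
    terminal_fraction: float = 0.01    # capacity fraction (of plateau) reached at cessation

    def __post_init__(self) -> None:
        if self.ramp_rate < 0:
            raise ValueError("ramp_rate must be >= 0")
        if self.peak_day_sd < 0 or self.cessation_day_sd < 0:
            raise ValueError("SDs must be >= 0")

    @property
    def plateau_fraction(self) -> float:
        """Bout-count capacity retained at the end of the first decline."""
        if not math.isfinite(self.plateau_offset_days):
            return 1.0
        return math.exp(-self.count_decline_rate * self.plateau_offset_days)


@dataclass(frozen=True)
class BoutParams:
    """Event-level structure of nightly running.

    ``bouts_per_night`` is the expected bout count at capacity 1; durations
    are in seconds and speeds in km/h. The dark phase is the second half of
    the recording day (timestamps 43200-86400 s), matching a morning-aligned
    24 h window on a 12 h light/dark cycle.
    """

    bouts_per_night: float
    bout_duration_s: float            # mean cruising-bout duration
    bout_duration_cv: float = 0.6
    cruise_speed_kmh: float = 2.9     # mean cruising-bout speed at capacity 1
    cruise_speed_sigma: float = 0.10  # log-normal sigma of cruising speed
    sprint_fraction: float = 0.15     # share of bouts that are sprints
    sprint_speed_kmh: float = 3.3     # sprint speed at capacity 1
    sprint_speed_sd: float = 0.10
    sprint_duration_s: float = 90.0
    inter_rotation_jitter: float = 0.05  # log-normal sigma of revolution intervals
    dark_start_s: float = 43200.0
    dark_len_s: float = 43200.0

    def __post_init__(self) -> None:
        if self.bout_duration_s <= 0:
            raise ValueError("bout_duration_s must be positive")
        if not (0 < self.cruise_speed_kmh < 10):
            raise ValueError("cruise_speed_kmh must be in (0, 10) km/h")
        if self.dark_len_s != 43200.0:
            raise ValueError("dark phase must span 12 h (43200 s)")

    @property
    def mean_bout_time_s(self) -> float:
        """Expected running time contributed by one bout."""
        p = self.sprint_fraction
        return (1 - p) * self.bout_duration_s + p * self.sprint_duration_s

    @property
    def mean_bout_distance_km(self) -> float:
        """Expected distance contributed by one bout at capacity 1."""
        p = self.sprint_fraction
        return (
            (1 - p) * self.bout_duration_s * self.cruise_speed_kmh
            + p * self.sprint_duration_s * self.sprint_speed_kmh
        ) / SECONDS_PER_HOUR

    @property
    def nominal_distance_km(self) -> float:
        """Expected daily distance at capacity 1."""
        return self.bouts_per_night * self.mean_bout_distance_km

    @property
    def nominal_time_h(self) -> float:
        """Expected daily running time at capacity 1."""
        return self.bouts_per_night * self.mean_bout_time_s / SECONDS_PER_HOUR


@dataclass(frozen=True)
class RotarodParams:
    baseline_mean_s: float = 240.0
    baseline_sd_s: float = 25.0
    decline_start_mean: float = math.inf  # age the latency starts to fall
    decline_start_sd: float = 0.0
    decline_rate: float = 0.062           # log-latency slope/day after the start
    plateau_fraction: float = 0.55        # latency fraction held during mid-disease
    test_noise_sigma: float = 0.08        # log-normal per-trial noise
    first_test_age: float = 28.0
    interval_days: float = 7.0


@dataclass(frozen=True)
class WeightParams:
    peak_weight_mean_g: float = 15.9
    peak_weight_sd_g: float = 0.7
    peak_age_mean: float = 80.0
    peak_age_sd: float = 18.0
    curvature: float = 0.03   # g per day^1.3 away from the peak
    noise_sd_g: float = 0.12


@dataclass(frozen=True)
class ClinicalParams:
    tremor_onset_mean: float = math.inf
    tremor_onset_sd: float = 0.0
    splay_onset_mean: float = math.inf
    splay_onset_sd: float = 0.0


@dataclass(frozen=True)
class SurvivalParams:
    endpoint_mean: float = math.inf   # age of humane endpoint
    endpoint_sd: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulated cohort."""

    genotype: str                      # "wild-type" | "sod1-like"
    n_animals: int
    start_age: int
    end_age: int
    seed: int
    trajectory: TrajectoryParams
    bouts: BoutParams
    censor_rate: float = 0.23          # expected censored days per animal
    rotarod: RotarodParams = field(default_factory=RotarodParams)
    weight: WeightParams = field(default_factory=WeightParams)
    clinical: ClinicalParams = field(default_factory=ClinicalParams)
    survival: SurvivalParams = field(default_factory=SurvivalParams)
    animal_scale_cv: float = 0.12      # between-animal log-normal activity scale
    wheel_access: bool = True
    study_id: str = "study-1"
    group: str = "placebo"

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.start_age >= self.end_age:
            raise ValueError("start_age must be < end_age")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if self.genotype not in ("wild-type", "sod1-like"):
            raise ValueError("genotype must be 'wild-type' or 'sod1-like'")


@dataclass(frozen=True)
class AnimalDraws:
    """Per-animal realized changepoints and latent traits."""

    peak_day: float
    plateau_end_day: float
    second_decline_day: float
    cessation_day: float
    scale: float
    rotarod_baseline_s: float
    rotarod_decline_start: float
    peak_weight_g: float
    peak_weight_age: float
    tremor_onset: float
    splay_onset: float
    endpoint_age: float


@dataclass(frozen=True)
class Capacity:
    """Unitless activity multipliers at one age."""

    count: float
    speed: float
    sprint: float

    def scaled(self, alpha: float) -> "Capacity":
        return Capacity(self.count * alpha, self.speed, self.sprint)


@dataclass
class AnimalTrack:
    """One animal's full longitudinal dossier."""

    animal_id: str
    genotype: str
    group: str
    study_id: str
    draws: AnimalDraws
    daily: pd.DataFrame      # animal_id, age_day, distance_km, time_h, avg_speed_kmh, max_speed_kmh, censored, censor_reason
    weekly: pd.DataFrame     # animal_id, age_day, rotarod_s, weight_g, tremor, splay
    endpoint_age: float


# ---------------------------------------------------------------------------
# Capacity curve
# ---------------------------------------------------------------------------

def capacity_at_age(params: TrajectoryParams, age: float, draws: AnimalDraws) -> Capacity:
    """Activity-capacity multipliers at ``age`` for one animal's realized changepoints.

    Piecewise log-linear: ramp to the realized peak day, first decline to the
    plateau, flat plateau, second decline, and zero at/after cessation. The
    sprint channel stays at 1 until ``sprint_hold_day``. For wild-type-like
    parameters (no plateau stage) the post-peak phase is a slow drift of the
    bout-count channel with speeds stable.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    if age >= draws.cessation_day:
        return Capacity(0.0, 0.0, 0.0)
    peak = draws.peak_day
    if age < peak:
        d = peak - age
        return Capacity(
            math.exp(-params.ramp_rate * d),
            math.exp(-params.ramp_rate * params.ramp_speed_fraction * d),
            1.0,
        )
    plateau_end = draws.plateau_end_day
    second = draws.second_decline_day
    if age < plateau_end or not math.isfinite(plateau_end):
        d = age - peak
        count = math.exp(-(params.count_decline_rate + params.slow_drift) * d)
        speed = math.exp(-params.speed_decline_rate * d)
    elif age < second:
        dp = plateau_end - peak
        count = math.exp(-params.count_decline_rate * dp - params.slow_drift * (age - peak))
        speed = math.exp(-params.speed_decline_rate * dp)
    else:
        dp = plateau_end - peak
        count_p = math.exp(-params.count_decline_rate * dp - params.slow_drift * (second - peak))
        speed_p = math.exp(-params.speed_decline_rate * dp)
        span = max(draws.cessation_day - second, 1e-9)
        late = math.log(1.0 / params.terminal_fraction) / span
        f = math.exp(-late * (age - second))
        count = count_p * f
        speed = speed_p * f
    if age <= params.sprint_hold_day:
        sprint = 1.0
    else:
        sprint = math.exp(-params.sprint_fade_rate * (age - params.sprint_hold_day))
    return Capacity(count, speed, sprint)


# ---------------------------------------------------------------------------
# Event-level generator
# ---------------------------------------------------------------------------

def simulate_day_events(
    capacity: Capacity,
    bouts: BoutParams,
    rng: np.random.Generator,
    animal_id: str = "sim",
    age_day: int = 0,
    scale: float = 1.0,
    circumference_m: float = DEFAULT_CIRCUMFERENCE_M,
) -> EventSeries:
    """Generate one animal-day of revolution timestamps.

    The expected revolution count satisfies
    ``E[revolutions] * circumference ~= capacity.count * nominal distance``
    (with speed capacities at 1), all timestamps fall in the dark phase, and
    the sequence is strictly increasing. Zero capacity yields an empty series.
    """
    lam = bouts.bouts_per_night * capacity.count * scale
    n_bouts = int(rng.poisson(lam)) if lam > 0 else 0
    if n_bouts == 0:
        return EventSeries(animal_id, age_day, np.empty(0), circumference_m)

    is_sprint = rng.random(n_bouts) < bouts.sprint_fraction
    sigma_d = math.sqrt(math.log1p(bouts.bout_duration_cv ** 2))
    durations = np.where(
        is_sprint,
        bouts.sprint_duration_s,
        bouts.bout_duration_s,
    ) * rng.lognormal(-0.5 * sigma_d ** 2, sigma_d, n_bouts)
    durations = np.maximum(durations, 2.0)

    sig_v = bouts.cruise_speed_sigma
    speeds = bouts.cruise_speed_kmh * capacity.speed * rng.lognormal(
        -0.5 * sig_v ** 2, sig_v, n_bouts
    )
    sprint_speeds = rng.normal(
        bouts.sprint_speed_kmh * capacity.sprint, bouts.sprint_speed_sd, n_bouts
    )
    speeds = np.where(is_sprint, sprint_speeds, speeds)
    speeds = np.clip(speeds, 0.5, None)  # < ~0.5 km/h would break every bout on the 5 s rule

    # Place bouts sequentially in the dark phase; squeeze durations if the
    # draw exceeds the window.
    margin = 600.0
    window = bouts.dark_len_s - margin
    total = durations.sum()
    if total > 0.92 * window:
        durations *= 0.92 * window / total
        total = durations.sum()
    idle = window - total
    min_gap = 0.75
    free = max(idle - min_gap * (n_bouts + 1), 0.0)
    gaps = min_gap + free * rng.dirichlet(np.ones(n_bouts + 1))

    pieces = []
    t = bouts.dark_start_s
    for k in range(n_bouts):
        t += gaps[k]
        base = circumference_m * 3.6 / speeds[k]  # seconds per revolution
        n_rev = max(1, int(round(durations[k] / base)) + 1)
        jit = rng.lognormal(0.0, bouts.inter_rotation_jitter, n_rev - 1) if n_rev > 1 else np.empty(0)
        ts = t + np.concatenate(([0.0], np.cumsum(base * jit)))
        pieces.append(ts)
        t = ts[-1]
    stamps = np.concatenate(pieces)
    stamps = stamps[stamps < bouts.dark_start_s + bouts.dark_len_s - 1.0]
    return EventSeries(animal_id, age_day, stamps, circumference_m)


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    if not math.isfinite(mean):
        return math.inf
    if sd == 0:
        return min(max(mean, lo), hi)
    for _ in range(200):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return min(max(mean, lo), hi)


def draw_animal(config: SimConfig, trait_seq: np.random.SeedSequence) -> AnimalDraws:
    """Draw one animal's changepoints and latent traits.

    Each trait is sampled from its own substream of ``trait_seq``, so adding
    or reordering traits never perturbs the others.
    """
    tr = config.trajectory
    streams = [np.random.default_rng(s) for s in trait_seq.spawn(10)]
    (rng_peak, rng_end, rng_second, rng_cess, rng_scale,
     rng_ro, rng_wt, rng_clin, rng_extra, _) = streams
    peak = _trunc_normal(rng_peak, tr.peak_day_mean, tr.peak_day_sd,
                         config.start_age + 2, config.end_age)
    plateau_end = peak + tr.plateau_offset_days
    endpoint = _trunc_normal(
        rng_end, config.survival.endpoint_mean, config.survival.endpoint_sd,
        config.start_age + 5, math.inf,
    )
    second = _trunc_normal(
        rng_second, tr.second_decline_day_mean, tr.second_decline_day_sd,
        plateau_end + 2 if math.isfinite(plateau_end) else peak + 2, math.inf,
    )
    cess = _trunc_normal(
        rng_cess, tr.cessation_day_mean, tr.cessation_day_sd,
        second + 5 if math.isfinite(second) else peak + 5, math.inf,
    )
    if math.isfinite(cess) and math.isfinite(endpoint):
        cess = min(cess, endpoint)
    scale_sigma = math.sqrt(math.log1p(config.animal_scale_cv ** 2))
    scale = rng_scale.lognormal(-0.5 * scale_sigma ** 2, scale_sigma)
    ro = config.rotarod
    baseline = min(rng_ro.normal(ro.baseline_mean_s, ro.baseline_sd_s), ROTAROD_CEILING_S)
    ro_start = _trunc_normal(rng_ro, ro.decline_start_mean, ro.decline_start_sd,
                             config.start_age, math.inf)
    w = config.weight
    peak_w = rng_wt.normal(w.peak_weight_mean_g, w.peak_weight_sd_g)
    peak_w_age = _trunc_normal(rng_wt, w.peak_age_mean, w.peak_age_sd,
                               config.start_age + 7, math.inf)
    cl = config.clinical
    tremor = _trunc_normal(rng_clin, cl.tremor_onset_mean, cl.tremor_onset_sd,
                           config.start_age, math.inf)
    splay = _trunc_normal(rng_clin, cl.splay_onset_mean, cl.splay_onset_sd,
                          config.start_age, math.inf)
    return AnimalDraws(
        peak_day=peak, plateau_end_day=plateau_end, second_decline_day=second,
        cessation_day=cess, scale=scale, rotarod_baseline_s=baseline,
        rotarod_decline_start=ro_start, peak_weight_g=peak_w, peak_weight_age=peak_w_age,
        tremor_onset=tremor, splay_onset=splay, endpoint_age=endpoint,
    )


def _rotarod_capacity(ro: RotarodParams, age: float, start: float) -> float:
    if age < start or not math.isfinite(start):
        return 1.0
    f = math.exp(-ro.decline_rate * (age - start))
    return max(f, ro.plateau_fraction * math.exp(-0.01 * max(age - start - 40.0, 0.0)))


def _simulate_weekly(config: SimConfig, draws: AnimalDraws, animal_id: str,
                     rng: np.random.Generator) -> pd.DataFrame:
    ro = config.rotarod
    last = min(config.end_age, draws.endpoint_age)
    ages = np.arange(ro.first_test_age, last + 1e-9, ro.interval_days)
    rows = []
    for age in ages:
        cap = _rotarod_capacity(ro, age, draws.rotarod_decline_start)
        trials = draws.rotarod_baseline_s * cap * rng.lognormal(
            -0.5 * ro.test_noise_sigma ** 2, ro.test_noise_sigma, 2
        )
        latency = float(np.clip(trials.max(), ROTAROD_FLOOR_S, ROTAROD_CEILING_S))
        weight = draws.peak_weight_g - config.weight.curvature * abs(age - draws.peak_weight_age) ** 1.3
        weight += rng.normal(0.0, config.weight.noise_sd_g)
        rows.append({
            "animal_id": animal_id,
            "age_day": int(round(age)),
            "rotarod_s": round(latency, 1),
            "weight_g": round(float(weight), 2),
            "tremor": int(age >= draws.tremor_onset),
            "splay": int(age >= draws.splay_onset),
        })
    return pd.DataFrame(rows, columns=["animal_id", "age_day", "rotarod_s", "weight_g", "tremor", "splay"])


def simulate_animal(
    config: SimConfig,
    animal_id: str,
    seed_seq: np.random.SeedSequence,
    on_events=None,
) -> AnimalTrack:
    """Simulate one animal from its own random substream.

    ``on_events``, when given, receives each day's :class:`EventSeries`
    before reduction (event streams are otherwise discarded to bound
    memory).
    """
    trait_seq, day_seq = seed_seq.spawn(2)
    rng = np.random.default_rng(day_seq)
    draws = draw_animal(config, trait_seq)
    last_day = config.end_age if not math.isfinite(draws.endpoint_age) else int(
        min(config.end_age, math.floor(draws.endpoint_age)))
    days = np.arange(config.start_age, last_day + 1)
    p_censor = min(config.censor_rate / max(days.size, 1), 1.0)
    censor_flags = rng.random(days.size) < p_censor
    records: list[DailyRecord] = []
    if config.wheel_access:
        for day, flag in zip(days, censor_flags):
            cap = capacity_at_age(config.trajectory, float(day), draws)
            events = simulate_day_events(
                cap, config.bouts, rng, animal_id=animal_id, age_day=int(day), scale=draws.scale
            )
            if on_events is not None:
                on_events(events)
            rec = daily_metrics(events)
            if flag:
                rec = apply_censoring(rec, CENSOR_REASONS[int(rng.integers(len(CENSOR_REASONS)))])
            records.append(rec)
    daily = pd.DataFrame(
        [vars(r) for r in records],
        columns=["animal_id", "age_day", "distance_km", "time_h",
                 "avg_speed_kmh", "max_speed_kmh", "censored", "censor_reason"],
    )
    weekly = _simulate_weekly(config, draws, animal_id, rng)
    return AnimalTrack(
        animal_id=animal_id, genotype=config.genotype, group=config.group,
        study_id=config.study_id, draws=draws, daily=daily, weekly=weekly,
        endpoint_age=float(min(draws.endpoint_age, config.end_age)),
    )


def simulate_cohort(config: SimConfig, on_events=None) -> list[AnimalTrack]:
    """Simulate a full cohort; one independent substream per animal.

    The master seed spawns per-animal substreams, so enlarging a cohort never
    disturbs existing animals and identical configs are bit-reproducible.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_animals)
    return [
        simulate_animal(config, f"{config.study_id}-m{i + 1:02d}", child, on_events=on_events)
        for i, child in enumerate(children)
    ]


def write_events_csv(config: SimConfig, path) -> None:
    """Simulate a cohort and stream its rotation events to a CSV.

    Columns: ``animal_id,age_day,timestamp_s``. The same seed reproduces the
    same events as :func:`simulate_cohort`.
    """
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["animal_id", "age_day", "timestamp_s"])

        def sink(ev: EventSeries) -> None:
            w.writerows(
                (ev.animal_id, ev.age_day, f"{t:.3f}") for t in ev.timestamps
            )

        simulate_cohort(config, on_events=sink)


def cohort_daily_table(tracks: list[AnimalTrack]) -> pd.DataFrame:
    """Concatenate the per-animal daily records of a cohort."""
    return pd.concat([t.daily for t in tracks], ignore_index=True)


def cohort_weekly_table(tracks: list[AnimalTrack]) -> pd.DataFrame:
    return pd.concat([t.weekly for t in tracks], ignore_index=True)


def cohort_metadata(tracks: list[AnimalTrack]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "animal_id": t.animal_id, "genotype": t.genotype, "group": t.group,
            "study_id": t.study_id, "endpoint_age": t.endpoint_age,
        } for t in tracks]
    )
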