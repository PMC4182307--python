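import numpy as np
import pytest

from runwheel.presets import get_preset
from runwheel.sim import (
    BoutParams,
    SimConfig,
    TrajectoryParams,
    simulate_cohort,
)


def exact_sample(mean: float, sd: float, n: int, seed: int = 0) -> np.ndarray:
    """A sample of size n whose mean and sample SD (ddof=1) are exact."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


@pytest.fixture(scope="session")
def wt_cohort():
    """Default wild-type cohort: 15 animals, 130 days of daily recording."""
    return simulate_cohort(get_preset("wildtype", n_animals=15, seed=0))


@pytest.fixture(scope="session")
def sod1_cohort():
    """Default SOD1-like cohort with wheel access: 15 animals."""
    return simulate_cohort(get_preset("sod1", n_animals=15, seed=0))


@pytest.fixture(scope="session")
def sod1_norun_cohort():
    """Matched no-wheel SOD1-like control arm (weekly measures only)."""
    return simulate_cohort(get_preset("sod1-norun", n_animals=15, seed=0))


def light_config(n_animals: int = 3, seed: int = 0, **overrides) -> SimConfig:
    """A small, fast cohort configuration for structural tests."""
    kw = dict(
        genotype="wild-type",
        n_animals=n_animals,
        start_age=26,
        end_age=56,
        seed=seed,
        trajectory=TrajectoryParams(ramp_rate=0.1, peak_day_mean=31.0, peak_day_sd=1.0,
                                    slow_drift=0.002),
        bouts=BoutParams(bouts_per_night=8.0, bout_duration_s=60.0,
                         sprint_duration_s=30.0, cruise_speed_kmh=2.9),
        censor_rate=0.23,
        animal_scale_cv=0.1,
    )
    kw.update(overrides)
    return SimConfig(**kw)
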