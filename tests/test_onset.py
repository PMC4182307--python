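"""Baseline estimation and 20%-decline onset detection."""

import math

import numpy as np
import pytest

from runwheel.onset import (
    clinical_milestones,
    detect_decline_onset,
    onsets_table,
    rolling_baseline,
    rotarod_onset,
)
from runwheel.sim import cohort_weekly_table


class TestRollingBaseline:
    def test_constant_series(self):
        days = np.arange(10.0)
        val, _ = rolling_baseline(days, np.full(10, 3.5), window=7)
        assert val == pytest.approx(3.5)

    def test_window_one_returns_series_maximum(self):
        days = np.arange(6.0)
        vals = np.array([1, 9, 4, 2, 8, 3.0])
        val, day = rolling_baseline(days, vals, window=1)
        assert val == 9 and day == 1

    def test_peak_window_centered(self):
        # brute-force over all windows of 3: the 6,6,6 run wins, centre day 3
        days = np.arange(8.0)
        vals = np.array([2, 4, 6, 6, 6, 3, 2, 1.0])
        windows = [(vals[i:i + 3].mean(), days[i + 1]) for i in range(6)]
        expect = max(windows, key=lambda w: w[0])
        got = rolling_baseline(days, vals, window=3)
        assert got == pytest.approx(expect)
        assert got == (6.0, 3.0)

    def test_censored_days_are_skipped(self):
        days = np.arange(10.0)
        vals = np.array([5, 5, 50, 5, 5, 5, 5, 5, 5, 5.0])
        cens = days == 2
        val, _ = rolling_baseline(days, vals, cens, window=3)
        assert val == pytest.approx(5.0)

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="censored"):
            rolling_baseline(np.arange(5.0), np.ones(5), np.ones(5, dtype=bool))

    def test_fixed_mode_returns_reference(self):
        val, day = rolling_baseline(np.arange(5.0) + 10, np.ones(5),
                                    mode="fixed-baseline", reference=7.0)
        assert val == 7.0 and day == 10.0


class TestDetectDeclineOnset:
    def test_monotone_nondecreasing_is_censored(self):
        days = np.arange(40, 80.0)
        res = detect_decline_onset(days, np.linspace(5, 9, 40), 5.0, 40.0)
        assert res.censored and math.isnan(res.onset_age)

    def test_hand_traced_threshold_crossing(self):
        # baseline 10 at day 40; 10 through day 49, 7.9 (<= 8.0) from day 50
        days = np.arange(41, 70.0)
        vals = np.where(days < 50, 10.0, 7.9)
        res = detect_decline_onset(days, vals, 10.0, 40.0, persistence=3)
        assert not res.censored and res.onset_age == 50.0

    def test_crossing_day_reported_not_confirmation_day(self):
        days = np.arange(41, 60.0)
        vals = np.where(days < 45, 10.0, 7.0)
        res = detect_decline_onset(days, vals, 10.0, 40.0, persistence=3)
        assert res.onset_age == 45.0

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            detect_decline_onset(np.arange(5.0), np.ones(5), 0.0, 0.0)

    def test_deeper_threshold_never_earlier(self):
        rng = np.random.default_rng(8)
        days = np.arange(1, 101.0)
        for _ in range(50):
            vals = np.abs(10 * np.exp(-0.02 * days) + rng.normal(0, 0.8, 100)) + 0.01
            prev = -np.inf
            for th in (0.1, 0.2, 0.3, 0.4):
                r = detect_decline_onset(days, vals, 10.0, 0.0, threshold_fraction=th)
                age = math.inf if r.censored else r.onset_age
                assert age >= prev
                prev = age

    def test_inserting_censored_days_never_creates_onset(self):
        days = np.arange(1, 31.0)
        vals = np.full(30, 10.0)
        base = detect_decline_onset(days, vals, 10.0, 0.0)
        assert base.censored
        cens = np.zeros(30, dtype=bool)
        cens[5:9] = True
        vals2 = vals.copy()
        vals2[5:9] = 0.0  # censored values must be ignored no matter what they hold
        res = detect_decline_onset(days, vals2, 10.0, 0.0, censored=cens)
        assert res.censored

    def test_determinism(self):
        days = np.arange(41, 80.0)
        vals = np.where(days < 50, 10.0, 7.5)
        a = detect_decline_onset(days, vals, 10.0, 40.0, animal_id="m", metric="distance")
        b = detect_decline_onset(days, vals, 10.0, 40.0, animal_id="m", metric="distance")
        assert a == b

    def test_recovers_injected_changepoints_within_two_days(self):
        """Abrupt drop to 70% at a known age, 8% daily noise: median |error| <= 2 d."""
        rng = np.random.default_rng(123)
        errors = []
        days = np.arange(28, 120.0)
        for _ in range(200):
            tau = rng.uniform(45, 90)
            level = np.where(days < tau, 1.0, 0.7)
            vals = 10.0 * level * rng.lognormal(0, 0.08, days.size)
            base, base_day = rolling_baseline(days, vals, window=7)
            r = detect_decline_onset(days, vals, base, base_day)
            assert not r.censored
            errors.append(abs(r.onset_age - math.ceil(tau)))
        assert np.median(errors) <= 2.0


class TestRotarodOnset:
    def test_confirmed_crossing(self):
        ages = np.array([28, 35, 42, 49, 56.0])
        lat = np.array([300, 300, 235, 230, 200.0])
        r = rotarod_onset(ages, lat)
        assert not r.censored and r.onset_age == 42.0 and r.baseline_value == 300.0

    def test_flat_series_censored(self):
        r = rotarod_onset(np.array([28, 35, 42.0]), np.array([250, 250, 250.0]))
        assert r.censored

    def test_unconfirmed_terminal_crossing_censored(self):
        r = rotarod_onset(np.array([28, 35, 42.0]), np.array([300, 300, 200.0]))
        assert r.censored

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            rotarod_onset(np.empty(0), np.empty(0))

    def test_floor_value_still_comparable(self):
        ages = np.array([28, 35, 42.0])
        r = rotarod_onset(ages, np.array([200, 5, 5.0]))
        assert r.onset_age == 35.0

    def test_nonrunning_cohort_mean_onset_near_55_days(self, sod1_norun_cohort):
        """Simulated no-wheel disease cohort: mean rotarod onset ~55.1 d (2 SE)."""
        weekly = cohort_weekly_table(sod1_norun_cohort)
        ages = []
        for _, sub in weekly.groupby("animal_id"):
            sub = sub.sort_values("age_day")
            r = rotarod_onset(sub["age_day"].to_numpy(float), sub["rotarod_s"].to_numpy(float))
            if not r.censored:
                ages.append(r.onset_age)
        ages = np.array(ages)
        assert ages.size >= 12
        se = ages.std(ddof=1) / math.sqrt(ages.size)
        assert abs(ages.mean() - 55.1) < 2 * se


class TestClinicalMilestones:
    def test_conjunction_of_first_abnormal_ages(self):
        ages = np.arange(56, 100, 7.0)
        onset, _ = clinical_milestones(ages, ages >= 70, ages >= 77, np.ones(ages.size))
        assert onset == 77.0

    def test_never_abnormal_is_censored(self):
        ages = np.arange(56, 100, 7.0)
        onset, _ = clinical_milestones(ages, ages >= 70, np.zeros(ages.size, bool),
                                       np.ones(ages.size))
        assert math.isnan(onset)

    def test_peak_weight_earliest_tie(self):
        ages = np.array([60, 70, 80, 90.0])
        _, peak = clinical_milestones(ages, np.zeros(4, bool), np.zeros(4, bool),
                                      np.array([14.1, 15.9, 15.9, 15.0]))
        assert peak == 70.0

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="age grid"):
            clinical_milestones(np.arange(3.0), np.zeros(3, bool), np.zeros(2, bool),
                                np.ones(3))


def test_onsets_table_covers_all_metrics(sod1_cohort):
    from runwheel.sim import cohort_daily_table
    daily = cohort_daily_table(sod1_cohort)
    weekly = cohort_weekly_table(sod1_cohort)
    tbl = onsets_table(daily, weekly)
    assert set(tbl.metric.unique()) == {"distance", "time", "avg_speed",
                                        "rotarod", "clinical", "peak_weight"}
    assert (tbl.groupby("metric").size() == 15).all()
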