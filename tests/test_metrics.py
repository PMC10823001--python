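"""Analysis layer: thresholds, daily metrics, exclusions, summaries, profiles."""

import math
import warnings
from datetime import date, time

import numpy as np
import pandas as pd
import pytest

from wheelrun import metrics
from wheelrun.errors import DegenerateInputError
from wheelrun.metrics import AnalysisConfig

CIRC = math.pi * 0.127


def series_from_counts(counts, start="2024-03-04 10:20", session=None):
    """Minimal minute series from a rotation-count vector."""
    ts = pd.date_range(start, periods=len(counts), freq="min")
    session = session or ts[0].date()
    return pd.DataFrame(
        {
            "timestamp": ts,
            "session": [session] * len(counts),
            "minute": range(len(counts)),
            "open_events": 0,
            "close_events": counts,
            "open_dur_ms": 60_000,
            "closed_dur_ms": 0,
            "rotations": counts,
        }
    )


class TestActiveThreshold:
    def test_constant_distribution(self):
        assert metrics.derive_active_threshold([17, 17, 17, 17]) == 17

    def test_nearest_rank_q1(self):
        # brute-force nearest-rank Q1 of {10,20,30,40}: rank ceil(0.25*4)=1 -> 10
        assert metrics.derive_active_threshold([10, 20, 30, 40]) == 10

    def test_zeros_excluded_before_quartile(self):
        assert metrics.derive_active_threshold([0] * 100 + [10, 20, 30, 40]) == 10

    def test_all_zero_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            metrics.derive_active_threshold([0, 0, 0])

    def test_matches_brute_force_oracle_on_random_pools(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            pool = rng.integers(1, 200, size=rng.integers(1, 500)).tolist()
            got = metrics.derive_active_threshold(pool)
            srt = sorted(pool)
            oracle = srt[max(1, math.ceil(0.25 * len(srt))) - 1]
            assert got == round(oracle)

    @pytest.mark.parametrize(
        "rot,thr,strict,active",
        [
            (31, 30, True, True),
            (30, 30, True, False),   # strict boundary
            (30, 30, False, True),
            (18, 17, True, True),    # chronic threshold boundary
            (17, 17, True, False),
        ],
    )
    def test_classify_boundaries(self, rot, thr, strict, active):
        assert metrics.classify_active(rot, thr, strict) is active


class TestDailySummary:
    def test_distance_arithmetic(self):
        counts = np.zeros(1440, dtype=int)
        counts[:100] = 10  # 1000 rotations
        s = metrics.daily_summary(series_from_counts(counts), AnalysisConfig(), 30)
        assert s.distance_km == pytest.approx(1000 * CIRC / 1000, rel=1e-12)
        assert s.distance_km == pytest.approx(0.3990, abs=2e-4)

    def test_active_speed_single_minute(self):
        counts = np.zeros(1440, dtype=int)
        counts[0] = 60
        s = metrics.daily_summary(series_from_counts(counts), AnalysisConfig(), 30)
        assert s.active_min == 1
        assert s.active_speed_kmh == pytest.approx(1.436, abs=1e-3)

    def test_speed_uses_only_active_minutes(self):
        counts = np.zeros(1440, dtype=int)
        counts[0] = 60   # active
        counts[1] = 10   # below threshold: adds distance but not speed
        s = metrics.daily_summary(series_from_counts(counts), AnalysisConfig(), 30)
        assert s.active_speed_kmh == pytest.approx(60 * CIRC / 1000 * 60, rel=1e-12)
        assert s.distance_km == pytest.approx(70 * CIRC / 1000, rel=1e-12)

    def test_all_zero_day(self):
        s = metrics.daily_summary(
            series_from_counts(np.zeros(1440, dtype=int)), AnalysisConfig(), 30
        )
        assert s.distance_km == 0 and s.active_min == 0
        assert math.isnan(s.active_speed_kmh)

    def test_doubling_circumference_scales_distance_not_duration(self):
        counts = np.zeros(1440, dtype=int)
        counts[:50] = 40
        c1 = AnalysisConfig()
        c2 = AnalysisConfig(circumference_m=2 * c1.circ_m)
        s1 = metrics.daily_summary(series_from_counts(counts), c1, 30)
        s2 = metrics.daily_summary(series_from_counts(counts), c2, 30)
        assert s2.distance_km == pytest.approx(2 * s1.distance_km, rel=1e-12)
        assert s2.active_speed_kmh == pytest.approx(2 * s1.active_speed_kmh, rel=1e-12)
        assert s2.active_min == s1.active_min

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(25, size=1440)
        df = series_from_counts(counts)
        act = [
            metrics.daily_summary(df, AnalysisConfig(), thr).active_min
            for thr in (10, 20, 30, 40)
        ]
        assert act == sorted(act, reverse=True)


def _summaries(rows):
    return pd.DataFrame(
        rows,
        columns=["mouse_id", "day", "distance_km", "active_min",
                 "active_speed_kmh", "rotations", "excluded", "exclusion_reason"],
    )


class TestExclusions:
    def _row(self, day, active_min=100, speed=1.4, mouse="m1", rotations=5000):
        return ["%s" % mouse, day, 1.0, active_min, speed, rotations, False, "NONE"]

    def test_active_minute_boundary(self):
        df = _summaries([self._row(1, active_min=19), self._row(2, active_min=20)])
        out = metrics.apply_exclusions(df, AnalysisConfig())
        assert list(out["exclusion_reason"]) == ["TOO_FEW_ACTIVE_MIN", "NONE"]

    def test_offline_day_flagged(self):
        df = _summaries([self._row(1, active_min=0, speed=float("nan"), rotations=0)])
        out = metrics.apply_exclusions(df, AnalysisConfig())
        assert out["exclusion_reason"].iloc[0] == "OFFLINE"

    def test_speed_outlier_mad_rule(self):
        rows = [self._row(d, speed=1.4 + 0.01 * d) for d in range(8)]
        rows.append(self._row(9, speed=15.0))  # far above median + 5 MAD, below cap
        out = metrics.apply_exclusions(_summaries(rows), AnalysisConfig())
        assert out["exclusion_reason"].iloc[-1] == "SPEED_OUTLIER"
        assert (out["exclusion_reason"].iloc[:-1] == "NONE").all()

    def test_absolute_speed_cap(self):
        out = metrics.apply_exclusions(
            _summaries([self._row(1, speed=30.0)]), AnalysisConfig()
        )
        assert out["exclusion_reason"].iloc[0] == "SPEED_OUTLIER"

    def test_rows_are_kept_not_dropped(self):
        df = _summaries([self._row(1, active_min=5), self._row(2)])
        out = metrics.apply_exclusions(df, AnalysisConfig())
        assert len(out) == 2 and out["excluded"].tolist() == [True, False]


class TestWeeklyGroupSummary:
    def _manifest(self, ids, sex="F", genotype="A"):
        return pd.DataFrame(
            {"mouse_id": ids, "sex": sex, "genotype": genotype, "cohort": 1}
        )

    def test_two_animal_closed_form_sem(self):
        rows = []
        for mouse, dist in (("m1", 1.0), ("m2", 2.0)):
            for d in range(7):
                rows.append([mouse, d, dist, 100, 1.4, 1000, False, "NONE"])
        weekly = metrics.weekly_group_summary(_summaries(rows), self._manifest(["m1", "m2"]))
        dist = weekly[weekly["metric"] == "distance_km"].iloc[0]
        assert dist["mean"] == pytest.approx(1.5)
        assert dist["sem"] == pytest.approx(0.5)
        assert dist["n"] == 2

    def test_single_animal_sem_is_nan(self):
        rows = [["m1", d, 1.0, 100, 1.4, 1000, False, "NONE"] for d in range(7)]
        weekly = metrics.weekly_group_summary(_summaries(rows), self._manifest(["m1"]))
        dist = weekly[weekly["metric"] == "distance_km"].iloc[0]
        assert dist["n"] == 1 and math.isnan(dist["sem"])

    def test_excluded_days_leave_the_denominator(self):
        rows = [["m1", d, 1.0, 100, 1.4, 1000, False, "NONE"] for d in range(6)]
        rows.append(["m1", 6, 100.0, 100, 1.4, 1000, True, "SPEED_OUTLIER"])
        weekly = metrics.weekly_group_summary(_summaries(rows), self._manifest(["m1"]))
        dist = weekly[weekly["metric"] == "distance_km"].iloc[0]
        assert dist["mean"] == pytest.approx(1.0)

    def test_weeks_partition_sessions_in_blocks_of_seven(self):
        rows = [["m1", d, float(d), 100, 1.4, 1000, False, "NONE"] for d in range(13)]
        weekly = metrics.weekly_group_summary(_summaries(rows), self._manifest(["m1"]))
        w = weekly[weekly["metric"] == "distance_km"].set_index("week")["mean"]
        assert w[1] == pytest.approx(np.mean(range(7)))
        assert w[2] == pytest.approx(np.mean(range(7, 13)))  # short final week kept


class TestHourlyProfile:
    def test_flat_running_gives_flat_profile(self):
        counts = np.full(1440, 10)
        series = {"m1": series_from_counts(counts, start="2024-03-04 00:00")}
        prof = metrics.hourly_profile(series, AnalysisConfig())
        daily_km = 1440 * 10 * CIRC / 1000
        assert np.allclose(prof["km_per_h"], daily_km / 24)

    def test_lights_off_shift_relabels_but_preserves_values(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(5, size=1440)
        series = {"m1": series_from_counts(counts, start="2024-03-04 00:00")}
        p1 = metrics.hourly_profile(series, AnalysisConfig(lights_off=time(10, 0)))
        p2 = metrics.hourly_profile(series, AnalysisConfig(lights_off=time(12, 0)))
        assert np.array_equal(p1["km_per_h"], p2["km_per_h"])  # same clock bins
        assert not np.array_equal(p1["zt_hour"], p2["zt_hour"])  # relabelled

    def test_zt_anchor_puts_dark_in_bins_12_to_23(self):
        counts = np.zeros(1440, dtype=int)
        counts[:720] = 20  # first 12 h of a session starting at lights-off
        series = {"m1": series_from_counts(counts, start="2024-03-04 10:20")}
        cfg = AnalysisConfig(lights_off=time(10, 20))
        prof = metrics.hourly_profile(series, cfg, anchor="zt")
        dark = prof[prof["zt_hour"] >= 12]["km_per_h"]
        light = prof[prof["zt_hour"] < 12]["km_per_h"]
        assert (dark > 0).all() and (light == 0).all()

    def test_estimate_dark_fraction_degenerate_case(self):
        counts = np.zeros(1440, dtype=int)
        counts[:720] = 20
        series = {"m1": series_from_counts(counts, start="2024-03-04 10:20")}
        cfg = AnalysisConfig(lights_off=time(10, 20))
        assert metrics.estimate_dark_fraction(series, cfg) == 1.0


class TestQuartilePartition:
    def test_eight_distinct_totals(self):
        totals = pd.Series([8.0, 3.0, 5.0, 1.0, 7.0, 2.0, 6.0, 4.0],
                           index=[f"m{i}" for i in range(8)])
        labels = metrics.quartile_partition(totals)
        assert (labels == "High").sum() == 2
        assert (labels == "Low").sum() == 2
        assert (labels == "Average").sum() == 4
        assert labels["m0"] == "High" and labels["m3"] == "Low"

    def test_all_equal_breaks_ties_by_stable_order(self):
        totals = pd.Series([5.0] * 8, index=[f"m{i}" for i in range(8)])
        labels = metrics.quartile_partition(totals)
        assert list(labels[:2]) == ["Low", "Low"]
        assert list(labels[-2:]) == ["High", "High"]

    def test_fewer_than_four_is_degenerate(self):
        totals = pd.Series([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="degenerate"):
            labels = metrics.quartile_partition(totals)
        assert (labels == "Average").all()


class TestDensityAndZeroFraction:
    def test_zero_exclusion_arithmetic(self):
        d = metrics.density_data([0, 0, 5, 10])
        assert list(d.values) == [5, 10]
        assert d.mean == 7.5 and d.median == 7.5

    def test_zeros_included_on_request(self):
        d = metrics.density_data([0, 0, 5, 10], exclude_zeros=False)
        assert d.mean == 3.75

    def test_all_zero_gives_empty_distribution(self):
        d = metrics.density_data([0, 0, 0])
        assert d.values.size == 0 and math.isnan(d.mean) and math.isnan(d.median)

    def test_zero_minute_fraction_alternating(self):
        counts = np.tile([1, 0], 720)
        series = {"m1": series_from_counts(counts)}
        assert metrics.zero_minute_fraction(series) == 0.5

    def test_zero_minute_fraction_all_zero(self):
        series = {"m1": series_from_counts(np.zeros(100, dtype=int))}
        assert metrics.zero_minute_fraction(series) == 1.0


class TestQuartileModePipeline:
    def test_quartile_threshold_flows_through_summaries(self):
        counts1 = np.zeros(1440, dtype=int)
        counts1[:4] = [10, 20, 30, 40]
        series = {"m1": series_from_counts(counts1)}
        cfg = AnalysisConfig(active_threshold="quartile")
        daily = metrics.summarize_days(series, cfg)
        # derived threshold = Q1 of {10,20,30,40} = 10; strict > 10 leaves 3 active
        assert daily["active_min"].iloc[0] == 3

    def test_acute_and_chronic_modes_agree_at_equal_threshold(self):
        rng = np.random.default_rng(21)
        counts = rng.poisson(20, size=1440)
        series = {"m1": series_from_counts(counts)}
        fixed = metrics.summarize_days(series, AnalysisConfig(active_threshold=17))
        thr = metrics.resolve_threshold(
            AnalysisConfig(active_threshold="quartile"), counts
        )
        derived = metrics.summarize_days(
            series, AnalysisConfig(active_threshold="quartile")
        )
        if thr == 17:
            pd.testing.assert_frame_equal(fixed, derived)
        else:
            fixed2 = metrics.summarize_days(series, AnalysisConfig(active_threshold=thr))
            pd.testing.assert_frame_equal(fixed2, derived)
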