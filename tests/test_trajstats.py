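"""15-day period statistics, bearings and circular summaries."""
import math

import numpy as np
import pytest

from fledgemove.geo import GeoPoint, destination_point
from fledgemove.trajstats import (bearing_at_month, circular_summary,
                                  daily_distance, departure_bearing,
                                  mean_latitude, partition_periods,
                                  period_stats_table, sinuosity)

from conftest import COLONY


class TestPartitionPeriods:
    def test_90_day_daily_track(self, straight_track):
        tr = straight_track(speed_kmday=100, duration_days=90, fixes_per_day=1)
        segs = partition_periods(tr)
        assert len(segs) == 6
        assert all(s is not None for s in segs)
        assert sum(s.n_fixes for s in segs) <= tr.n_fixes
        # fixes assigned uniquely to half-open windows
        rel = tr.days_since_departure()
        for k, s in enumerate(segs):
            r = s.days_since(tr.times[tr.departure_index()])
            assert np.all((r >= 15 * k) & (r < 15 * (k + 1)))

    def test_short_track_partial_periods(self, straight_track):
        tr = straight_track(speed_kmday=100, duration_days=20, fixes_per_day=1)
        segs = partition_periods(tr)
        assert segs[0] is not None and segs[1] is not None
        assert all(s is None for s in segs[2:])

    def test_duty_cycle_gap_flags_empty_window(self, make_track):
        hours = np.concatenate([np.arange(0, 240, 12), np.arange(1080, 1440, 12)])
        lon = 53.0 + 0.05 * np.arange(len(hours))
        tr = make_track(lon, [-46.0] * len(hours), hours=hours)
        segs = partition_periods(tr)
        assert segs[0] is not None
        assert segs[1] is None and segs[2] is None  # days 15-45 unsampled


class TestSinuosity:
    def test_straight_path_zero(self, straight_track):
        tr = straight_track(bearing_rad=0.7, speed_kmday=200, duration_days=10)
        assert sinuosity(tr) == pytest.approx(0.0, abs=1e-6)

    def test_closed_loop_one(self, make_track):
        th = np.linspace(0, 2 * math.pi, 25)
        lon = 55.0 + 2.0 * np.cos(th)
        lat = -46.0 + 2.0 * np.sin(th)
        lon[-1], lat[-1] = lon[0], lat[0]
        tr = make_track(lon, lat)
        assert sinuosity(tr) == pytest.approx(1.0, abs=1e-9)

    def test_right_angle_two_legs(self, make_track):
        # two equal 10-km legs, east then north: S = 1 - 1/sqrt(2)
        # (short legs keep spherical convergence below the tolerance)
        a = COLONY
        b = destination_point(a, math.pi / 2, 10.0)
        c = destination_point(b, 0.0, 10.0)
        tr = make_track([a.lon, b.lon, c.lon], [a.lat, b.lat, c.lat])
        assert sinuosity(tr) == pytest.approx(1 - 1 / math.sqrt(2), abs=1e-3)

    def test_undefined_below_three_fixes(self, make_track):
        tr = make_track([50.0, 50.1], [-46.0, -46.0])
        assert sinuosity(tr) is None

    def test_invariant_under_subsampling_of_straight_path(self, straight_track):
        tr = straight_track(bearing_rad=1.0, speed_kmday=300, duration_days=12)
        sub = tr.subset(np.arange(0, tr.n_fixes, 7))
        assert sinuosity(sub) == pytest.approx(0.0, abs=1e-6)

    def test_monotone_in_positional_noise(self, straight_track):
        from fledgemove.simulate import add_positional_noise
        tr = straight_track(bearing_rad=1.0, speed_kmday=300, duration_days=15,
                            fixes_per_day=4)
        values = [sinuosity(add_positional_noise(tr, sd, seed=42))
                  for sd in (0.0, 15.0, 60.0)]
        assert values[0] < values[1] < values[2]


class TestDailyDistance:
    def test_constant_speed_hourly(self, straight_track):
        tr = straight_track(bearing_rad=0.0, speed_kmday=240, duration_days=10)
        assert daily_distance(tr) == pytest.approx(240.0, rel=1e-3)

    def test_transmitter_off_gap_excluded(self, straight_track):
        tr = straight_track(bearing_rad=0.0, speed_kmday=240, duration_days=10)
        rel = tr.days_since(tr.times[0]) * 24.0
        keep = (rel < 48.0) | (rel >= 108.0)  # cut a 60-h hole
        gappy = tr.subset(np.nonzero(keep)[0])
        assert daily_distance(gappy) == pytest.approx(240.0, rel=1e-3)

    def test_no_short_steps_undefined(self, make_track):
        tr = make_track([50.0, 51.0, 52.0], [-46.0] * 3, hours=[0.0, 48.0, 96.0])
        assert daily_distance(tr) is None

    def test_duty_cycled_nomad_recovers_nominal_speed(self):
        from fledgemove.simulate import SimConfig, simulate_track, DUTY_CYCLES
        errs = []
        for j in range(1, 51):
            tr, _ = simulate_track(SimConfig(mode="nomad", seed=j,
                                             duty_cycle=DUTY_CYCLES[(j - 1) % 3]))
            ddt = daily_distance(tr)
            errs.append(abs(ddt - 350.0) / 350.0)
        assert np.median(errs) < 0.15


class TestBearings:
    def test_departure_due_north(self, straight_track):
        tr = straight_track(bearing_rad=0.0, speed_kmday=200, duration_days=5)
        assert departure_bearing(tr) == pytest.approx(0.0, abs=1e-6)

    def test_departure_due_east(self, straight_track):
        tr = straight_track(bearing_rad=math.pi / 2, speed_kmday=200, duration_days=5)
        assert departure_bearing(tr) == pytest.approx(math.pi / 2, abs=0.02)

    def test_never_beyond_radius_undefined(self, make_track):
        tr = make_track([52.4, 52.5, 52.6], [-46.2, -46.25, -46.3])
        assert departure_bearing(tr) is None

    def test_cohort_departure_circular_mean(self):
        from fledgemove.simulate import SimConfig, simulate_track
        angles = []
        for j in range(1, 31):
            tr, _ = simulate_track(SimConfig(mode="half_migration", seed=j,
                                             heading_mean_rad=math.pi / 2,
                                             heading_kappa=20.0))
            angles.append(departure_bearing(tr))
        cs = circular_summary(angles)
        assert cs.mean_direction == pytest.approx(math.pi / 2, abs=0.1)

    def test_bearing_at_month_due_east(self, make_track):
        # bird due east of the colony (same latitude) at day 60
        hours = np.arange(0, 65 * 24, 24.0)
        lon = COLONY.lon + 0.3 * hours / 24.0
        tr = make_track(lon, [COLONY.lat] * len(hours), hours=hours)
        assert bearing_at_month(tr, month=2) == pytest.approx(math.pi / 2, abs=1e-6)

    def test_bearing_at_month_track_too_short(self, straight_track):
        tr = straight_track(speed_kmday=100, duration_days=40)
        assert bearing_at_month(tr, month=3) is None

    def test_settlement_orientation_consistency(self):
        # a settled half-migrant points the same way at months 2 and 3
        from fledgemove.simulate import SimConfig, simulate_track
        for j in (1, 2, 3, 4, 5):
            tr, _ = simulate_track(SimConfig(mode="half_migration", seed=j))
            b2, b3 = bearing_at_month(tr, month=2), bearing_at_month(tr, month=3)
            diff = abs((b2 - b3 + math.pi) % (2 * math.pi) - math.pi)
            assert diff < 0.2


class TestCircularSummary:
    def test_identical_angles_maximal_concentration(self):
        cs = circular_summary([1.0] * 10)
        assert cs.resultant_length == pytest.approx(1.0)
        assert cs.rayleigh_p < 0.001
        assert cs.angular_range == pytest.approx(0.0, abs=1e-9)

    def test_equally_spaced_uniform(self):
        cs = circular_summary(np.linspace(0, 2 * math.pi, 9)[:-1])
        assert cs.resultant_length == pytest.approx(0.0, abs=1e-12)
        assert cs.rayleigh_p > 0.95

    def test_against_independent_circular_package(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        for kappa in (0.3, 1.0, 2.0):
            a = rng.vonmises(1.0, kappa, size=30)
            cs = circular_summary(a)
            z, p = pingouin.circ_rayleigh(a)
            assert cs.rayleigh_z == pytest.approx(z, rel=1e-9)
            # the reference package uses a different classical approximation
            # of the p-value; the two agree to ~1e-4
            assert cs.rayleigh_p == pytest.approx(p, abs=5e-4)

    def test_quarter_circle_angular_range(self):
        cs = circular_summary(np.linspace(0, math.pi / 2, 12))
        assert cs.angular_range <= math.pi / 2 + 1e-9

    def test_p_monotone_decreasing_in_R(self):
        n = 20
        ps = []
        for R_target in (0.1, 0.3, 0.5, 0.7):
            # two-point construction with prescribed resultant length
            a = np.full(n, 0.0)
            a[: n // 2] = math.acos(R_target)
            a[n // 2:] = -math.acos(R_target)
            ps.append(circular_summary(a).rayleigh_p)
        assert all(x > y for x, y in zip(ps, ps[1:]))

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(99)
        n, reps = 20, 2000
        angles = rng.uniform(0, 2 * math.pi, size=(reps, n))
        C = np.cos(angles).mean(axis=1)
        S = np.sin(angles).mean(axis=1)
        Z = n * (C**2 + S**2)
        p = np.exp(-Z) * (1 + (2 * Z - Z**2) / (4 * n)
                          - (24 * Z - 132 * Z**2 + 76 * Z**3 - 9 * Z**4) / (288 * n**2))
        rate = np.mean(np.clip(p, 0, 1) < 0.05)
        assert 0.04 <= rate <= 0.06

    def test_too_few_angles(self):
        with pytest.raises(ValueError):
            circular_summary([1.0])


class TestMeanLatitude:
    def test_constant_latitude(self, make_track):
        hours = np.arange(0, 95 * 24, 24.0)
        lon = 53.0 + 0.9 * hours / 24.0
        tr = make_track(lon, [-48.0] * len(hours), hours=hours)
        for m in (1, 2, 3):
            assert mean_latitude(tr, month=m) == pytest.approx(-48.0, abs=1e-9)

    def test_empty_month_missing(self, straight_track):
        tr = straight_track(speed_kmday=100, duration_days=40)
        assert mean_latitude(tr, month=3) is None

    def test_southward_drift(self, make_track):
        # 0.1 deg/day southward from -46: month-3 mean is the mean of the
        # schedule's latitudes over days [60, 90)
        hours = np.arange(0, 95 * 24, 24.0)
        lat = -46.0 - 0.1 * hours / 24.0
        lon = 53.0 + 0.05 * np.arange(len(hours))  # move east to depart
        tr = make_track(lon, lat, hours=hours)
        rel = tr.days_since_departure()
        expected = np.mean(lat[(rel >= 60) & (rel < 90)])
        assert mean_latitude(tr, month=3) == pytest.approx(expected, abs=1e-9)
        assert mean_latitude(tr, month=3) == pytest.approx(-53.5, abs=0.3)


class TestPeriodStatsTable:
    def test_rows_and_values(self, straight_track):
        tr = straight_track(bearing_rad=0.0, speed_kmday=240, duration_days=90,
                            fixes_per_day=4)
        df = period_stats_table([tr])
        assert len(df) == 6
        assert df["sinuosity"].iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert df["ddt_kmday"].iloc[0] == pytest.approx(240.0, rel=1e-2)
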