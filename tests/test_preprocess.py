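"""Interpolation, residence time, daylight and immersion classification."""

import numpy as np
import pandas as pd
import pytest

from misi import classify_immersion, classify_residence, interpolate_hourly, residence_time
from misi.preprocess import (
    ParameterError,
    daylight_mask,
    read_immersion,
    solar_elevation_deg,
)
from misi.track import Behaviour

from conftest import make_trip


def brute_force_residence(xy, seconds, radius, i, n_sub=4000):
    """Independent oracle: dense sub-sampling of every segment."""
    total = 0.0
    c = xy[i]
    for j in range(len(xy) - 1):
        s = (np.arange(n_sub) + 0.5) / n_sub
        p = xy[j][None, :] + s[:, None] * (xy[j + 1] - xy[j])[None, :]
        inside = np.hypot(p[:, 0] - c[0], p[:, 1] - c[1]) <= radius
        total += inside.mean() * (seconds[j + 1] - seconds[j])
    return total


class TestInterpolation:
    def test_linear_midpoint(self):
        trip = make_trip([[0, 0], [2000, 0]], interval_s=7200.0)
        out = interpolate_hourly(trip)
        assert len(out) == 3
        assert out.fixes.loc[1, "x"] == pytest.approx(1000.0)
        assert out.fixes.loc[1, "y"] == pytest.approx(0.0)

    def test_idempotent_on_hourly_fixes(self):
        xy = np.column_stack([np.arange(5) * 1000.0, np.arange(5) ** 2 * 10.0])
        trip = make_trip(xy)
        out = interpolate_hourly(trip)
        assert np.allclose(out.xy(), xy)
        assert (out.fixes["t"].to_numpy() == trip.fixes["t"].to_numpy()).all()

    def test_output_count_for_irregular_trip(self):
        # 10-h trip sampled at irregular ~1.3-h intervals -> 11 hourly fixes
        s = np.array([0.0, 1.4, 2.2, 3.9, 5.1, 6.0, 7.7, 8.6, 10.0]) * 3600.0
        xy = np.column_stack([s / 10.0, np.zeros_like(s)])
        trip = make_trip(xy, interval_s=1.0)
        trip.fixes["t"] = trip.fixes["t"].iloc[0] + pd.to_timedelta(s, unit="s")
        out = interpolate_hourly(trip)
        assert len(out) == int(np.floor(10.0)) + 1

    def test_endpoints_preserved_exactly(self):
        s = np.array([0.0, 5000.0, 9500.0])
        xy = np.array([[0.0, 0.0], [3000.0, 100.0], [5000.0, -40.0]])
        trip = make_trip(xy)
        trip.fixes["t"] = trip.fixes["t"].iloc[0] + pd.to_timedelta(s, unit="s")
        out = interpolate_hourly(trip)
        assert np.allclose(out.xy()[0], xy[0])
        # last hourly fix is at floor(9500/3600) h, not extrapolated past the end
        assert out.seconds()[-1] <= s[-1]

    def test_short_trip_returned_unchanged(self):
        trip = make_trip([[0, 0], [100, 0]], interval_s=600.0)
        with pytest.warns(UserWarning, match="shorter"):
            out = interpolate_hourly(trip)
        assert out is trip


class TestResidenceTime:
    def test_stationary_trip_full_duration(self):
        trip = make_trip(np.zeros((10, 2)))
        prof = residence_time(trip, radius_m=1000.0)
        assert np.allclose(prof.residence_s, 9 * 3600.0)

    def test_straight_line_at_glide_speed(self):
        # 45 km/h straight track, 45-km radius: interior fixes see a 90-km
        # chord through the centre -> 7200 s inside the circle
        xy = np.column_stack([np.arange(11) * 45_000.0, np.zeros(11)])
        trip = make_trip(xy)
        prof = residence_time(trip, radius_m=45_000.0)
        assert np.allclose(prof.residence_s[2:-2], 7200.0)

    def test_radius_larger_than_extent(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 1000, size=(8, 2))
        trip = make_trip(xy)
        prof = residence_time(trip, radius_m=1e7)
        assert np.allclose(prof.residence_s, trip.duration_s)

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        steps = rng.normal(0, 20_000, size=(15, 2)).cumsum(axis=0)
        trip = make_trip(steps)
        radius = 25_000.0
        prof = residence_time(trip, radius)
        xy, s = trip.xy(), trip.seconds()
        for i in range(len(xy)):
            assert prof.residence_s[i] == pytest.approx(
                brute_force_residence(xy, s, radius, i), abs=25.0
            )

    def test_monotone_in_radius(self):
        rng = np.random.default_rng(3)
        trip = make_trip(rng.normal(0, 30_000, size=(12, 2)).cumsum(axis=0))
        radii = [5_000, 20_000, 50_000, 120_000]
        profiles = [residence_time(trip, r).residence_s for r in radii]
        for a, b in zip(profiles, profiles[1:]):
            assert (b >= a - 1e-9).all()

    def test_invalid_radius(self):
        trip = make_trip([[0, 0], [1, 1]])
        with pytest.raises(ParameterError):
            residence_time(trip, -1.0)


class TestClassifyResidence:
    def test_threshold_boundary(self):
        trip = make_trip([[0, 0], [1, 0]])
        prof = residence_time(trip, 10.0)
        prof.residence_s = np.array([24_999.0, 25_000.0, 25_001.0])
        labels = classify_residence(prof, 25_000.0)
        assert labels.tolist() == [Behaviour.TRANSIT, Behaviour.FORAGING, Behaviour.FORAGING]

    def test_partition_transit_foraging(self):
        rng = np.random.default_rng(5)
        trip = make_trip(rng.normal(0, 10_000, size=(20, 2)).cumsum(axis=0))
        prof = residence_time(trip, 45_000.0)
        labels = classify_residence(prof, 20_000.0)
        assert set(labels) <= {Behaviour.TRANSIT, Behaviour.FORAGING}
        assert len(labels) == len(trip)

    def test_all_stationary_is_all_foraging(self):
        trip = make_trip(np.zeros((10, 2)))
        prof = residence_time(trip, 1000.0)
        labels = classify_residence(prof, 25_000.0)
        assert (labels == Behaviour.FORAGING).all()


def _fixes_at(times_lonlat):
    rows = []
    for t, lon, lat in times_lonlat:
        rows.append({"t": pd.Timestamp(t, tz="UTC"), "lon": lon, "lat": lat})
    return pd.DataFrame(rows)


class TestDaylight:
    def test_solar_noon_at_equator_equinox_kept(self):
        fx = _fixes_at([("2001-03-20T12:00:00", 0.0, 0.0)])
        assert daylight_mask(fx).all()

    def test_midnight_at_equator_equinox_dropped(self):
        fx = _fixes_at([("2001-03-20T00:00:00", 0.0, 0.0)])
        assert not daylight_mask(fx).any()

    def test_polar_day_keeps_everything(self):
        # 75°S in mid-December: continuous daylight (declination ~ -23°)
        fx = _fixes_at([(f"2001-12-15T{h:02d}:00:00", -38.0, -75.0) for h in range(24)])
        assert daylight_mask(fx).all()

    def test_polar_night_drops_everything(self):
        fx = _fixes_at([(f"2001-06-15T{h:02d}:00:00", -38.0, -80.0) for h in range(24)])
        assert not daylight_mask(fx).any()

    def test_elevation_sane_at_noon(self):
        fx = _fixes_at([("2001-03-20T12:00:00", 0.0, 0.0)])
        elev = solar_elevation_deg(fx["t"], fx["lon"].to_numpy(), fx["lat"].to_numpy())
        assert elev[0] > 85.0  # sun nearly overhead


class TestImmersion:
    def _bouts(self, tmp_path, rows):
        p = tmp_path / "imm.csv"
        p.write_text("timestamp,wet_seconds\n" + "\n".join(rows) + "\n")
        return read_immersion(p)

    def test_wet_bout_at_fix_time_is_foraging(self, tmp_path):
        bouts = self._bouts(tmp_path, ["2001-02-01T12:00:00Z,5"])
        fx = _fixes_at([("2001-02-01T12:00:00", -38.0, -54.0)])
        assert classify_immersion(bouts, fx)[0] == Behaviour.FORAGING

    def test_three_seconds_is_not_wet(self, tmp_path):
        # "wet" needs strictly more than 3 s on the water
        bouts = self._bouts(tmp_path, ["2001-02-01T12:00:00Z,3"])
        fx = _fixes_at([("2001-02-01T12:00:00", -38.0, -54.0)])
        assert bouts["is_wet"].tolist() == [False]
        assert classify_immersion(bouts, fx)[0] == Behaviour.TRANSIT

    def test_bout_outside_window_not_counted(self, tmp_path):
        bouts = self._bouts(tmp_path, ["2001-02-01T12:45:00Z,600", "2001-02-01T12:10:00Z,0"])
        fx = _fixes_at([("2001-02-01T12:00:00", -38.0, -54.0)])
        # wet bout 45 min after the fix is outside [t-30min, t+30min); the
        # dry bout inside the window leaves the fix non-foraging
        assert classify_immersion(bouts, fx)[0] == Behaviour.TRANSIT

    def test_no_bout_coverage_is_unclassified(self, tmp_path):
        bouts = self._bouts(tmp_path, ["2001-02-01T18:00:00Z,600"])
        fx = _fixes_at([("2001-02-01T12:00:00", -38.0, -54.0)])
        assert classify_immersion(bouts, fx)[0] == Behaviour.UNCLASSIFIED

    def test_wet_seconds_out_of_range_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            self._bouts(tmp_path, ["2001-02-01T12:00:00Z,700"])
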