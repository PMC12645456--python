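"""Seismic-energy chain: Richter energy, geodesics, slant distance, windows."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seismobiome import seismic
from seismobiome._geodesy import vincenty_km

B944 = seismic.B944_SITE


class TestMagnitudeToEnergy:
    @pytest.mark.parametrize(
        "mag, expected_J",
        [(0.0, 10**4.4), (3.6, 10**9.8), (1.0, 10**5.9)],
    )
    def test_richter_relation(self, mag, expected_J):
        assert seismic.magnitude_to_energy(mag) == pytest.approx(expected_J, rel=1e-12)

    def test_two_magnitude_units_are_a_thousandfold(self):
        assert seismic.magnitude_to_energy(2.3) / seismic.magnitude_to_energy(0.3) == pytest.approx(
            1000.0, rel=1e-12
        )

    @given(st.floats(min_value=-2, max_value=8, allow_nan=False))
    def test_strictly_increasing(self, m):
        assert seismic.magnitude_to_energy(m + 0.01) > seismic.magnitude_to_energy(m)

    @pytest.mark.parametrize("bad", [float("nan"), float("inf")])
    def test_nonfinite_rejected(self, bad):
        with pytest.raises(ValueError):
            seismic.magnitude_to_energy(bad)


class TestSurfaceDistance:
    # frozen from an independent WGS-84 geodesic implementation
    # (R geosphere::distVincentyEllipsoid)
    ORACLE = [
        ((0.0, 0.0, 1.0, 0.0), 110.574389),
        ((44.43, -110.34, B944.lat, B944.lon), 16.834364),
        ((44.8, -111.0, B944.lat, B944.lon), 58.237724),
        ((48.8584, 2.2945, 40.6892, -74.0445), 5853.103677),
    ]

    @pytest.mark.parametrize("coords, expected_km", ORACLE)
    def test_against_independent_geodesic(self, coords, expected_km):
        assert vincenty_km(*coords) == pytest.approx(expected_km, abs=1e-4)

    def test_identity_and_symmetry(self):
        assert vincenty_km(44.4, -110.5, 44.4, -110.5) == 0.0
        d1 = vincenty_km(10.0, 20.0, -5.0, 140.0)
        d2 = vincenty_km(-5.0, 140.0, 10.0, 20.0)
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_near_antipodal_falls_back_sanely(self):
        # Vincenty's iteration diverges here; the fallback must still give
        # roughly half the ellipsoid circumference.
        d = vincenty_km(0.0, 0.0, 0.5, 179.7)
        assert d == pytest.approx(19_900, rel=0.02)

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            vincenty_km(91.0, 0.0, 0.0, 0.0)


class TestSlantDistance:
    def test_3_4_5_triangle(self):
        # receiver sampled at sea level => dv equals event depth
        site = seismic.ReceiverSite(lat=0, lon=0, elevation=0, sampling_depth=0)
        assert seismic.slant_distance(3.0, 4.0, site) == pytest.approx(5.0)

    def test_vertical_only(self):
        site = seismic.ReceiverSite(lat=0, lon=0, elevation=0, sampling_depth=0)
        assert seismic.slant_distance(0.0, 7.5, site) == pytest.approx(7.5)

    def test_sampled_point_convention(self):
        # dv = depth + (elevation - sampling_depth)/1000
        dv = 5.0 + (2365.0 - 99.1) / 1000.0
        assert seismic.slant_distance(0.0, 5.0, B944) == pytest.approx(dv)

    @given(
        st.floats(min_value=0, max_value=500, allow_nan=False),
        st.floats(min_value=-2, max_value=20, allow_nan=False),
    )
    @settings(max_examples=50)
    def test_matches_hypot_and_dominates_legs(self, surf, depth):
        d = seismic.slant_distance(surf, depth, B944)
        dv = depth + B944.sampled_elevation_km
        assert d == pytest.approx(math.hypot(surf, dv), rel=1e-12)
        assert d >= max(surf, abs(dv)) - 1e-12


class TestAbsorbedEnergy:
    def test_inverse_square_exact(self):
        e1 = 100.0 / 1.0**2
        site = seismic.ReceiverSite(lat=0, lon=0, elevation=0, sampling_depth=0)
        ev_near = seismic.SeismicEvent(day=150, lat=0, lon=0, depth_bsl=1.0, magnitude=0.0)
        ev_far = seismic.SeismicEvent(day=150, lat=0, lon=0, depth_bsl=2.0, magnitude=0.0)
        near = seismic.absorbed_energy(ev_near, site)
        far = seismic.absorbed_energy(ev_far, site)
        assert near.absorbed / far.absorbed == pytest.approx(4.0, rel=1e-12)
        assert near.absorbed == pytest.approx(near.radiated_J / 1.0, rel=1e-12) or e1

    def test_event_at_receiver_rejected(self):
        site = seismic.ReceiverSite(lat=0, lon=0, elevation=0, sampling_depth=0)
        ev = seismic.SeismicEvent(day=150, lat=0, lon=0, depth_bsl=0.0, magnitude=1.0)
        with pytest.raises(ValueError):
            seismic.absorbed_energy(ev, site)

    def test_vectorized_matches_per_row_scalar(self, bundle):
        catalog = bundle["catalog"].head(200)
        df = seismic.catalog_energies(catalog, B944)
        for _, row in df.sample(20, random_state=1).iterrows():
            ev = seismic.SeismicEvent(
                day=row.day, lat=row.lat, lon=row.lon,
                depth_bsl=row.depth_km, magnitude=row.magnitude,
            )
            scalar = seismic.absorbed_energy(ev, B944)
            assert row.absorbed_J == pytest.approx(scalar.absorbed, rel=1e-10)
            assert row.distance_km == pytest.approx(scalar.distance_km, rel=1e-10)


class TestWindows:
    def test_study_schedule_mean_interval_and_first_window(self):
        sched = seismic.SamplingSchedule((147, 174, 237, 279, 307))
        assert sched.mean_interval == pytest.approx(40.0)
        windows = seismic.build_windows(sched)
        assert windows[0] == (107, 147)
        assert windows == [(107, 147), (147, 174), (174, 237), (237, 279), (279, 307)]

    def test_two_day_schedule(self):
        assert seismic.build_windows(seismic.SamplingSchedule((10, 20))) == [(0, 10), (10, 20)]

    @given(st.lists(st.integers(min_value=1, max_value=366), min_size=2, max_size=8, unique=True))
    def test_windows_disjoint_ordered(self, days):
        sched = seismic.SamplingSchedule(tuple(sorted(days)))
        windows = seismic.build_windows(sched)
        for (s1, e1), (s2, e2) in zip(windows, windows[1:]):
            assert e1 == s2 and s1 < e1 < e2

    @pytest.mark.parametrize("days", [(147,), (147, 147), (174, 147), (100, 400)])
    def test_invalid_schedules_rejected(self, days):
        with pytest.raises(ValueError):
            seismic.SamplingSchedule(days)


class TestAccumulate:
    WINDOWS = [(107, 147), (147, 174), (174, 237), (237, 279), (279, 307)]

    def test_empty_catalog(self):
        accs, diag = seismic.accumulate([], [], self.WINDOWS)
        assert all(a.total == 0 and a.n_events == 0 for a in accs)
        assert diag["n_outside"] == 0

    def test_one_event_per_window(self):
        days = [120, 150, 200, 250, 300]
        accs, _ = seismic.accumulate(days, [3.0] * 5, self.WINDOWS)
        assert [a.total for a in accs] == [3.0] * 5

    def test_boundary_day_belongs_to_ending_window(self):
        accs, _ = seismic.accumulate([147.0], [1.0], self.WINDOWS)
        assert accs[0].total == 1.0 and accs[1].total == 0.0

    def test_matches_groupby_oracle_and_tiles(self):
        rng = np.random.default_rng(42)
        days = rng.uniform(90, 320, 500)
        vals = rng.exponential(10.0, 500)
        accs, diag = seismic.accumulate(days, vals, self.WINDOWS)
        # independent oracle: pandas cut + groupby
        cut = pd.cut(days, [107, 147, 174, 237, 279, 307], right=True)
        oracle = pd.Series(vals).groupby(cut, observed=False).sum()
        assert np.allclose([a.total for a in accs], oracle.to_numpy())
        in_range = vals[(days > 107) & (days <= 307)].sum()
        assert sum(a.total for a in accs) == pytest.approx(in_range, rel=1e-12)
        assert diag["n_outside"] == int(((days <= 107) | (days > 307)).sum())

    def test_dropped_missing_magnitudes_counted(self):
        cat = pd.DataFrame(
            {"day": [150, 160], "lat": [44, 44], "lon": [-110, -110],
             "depth_km": [5, 5], "magnitude": [1.0, np.nan]}
        )
        df = seismic.catalog_energies(cat, B944)
        assert len(df) == 1 and df.attrs["n_dropped"] == 1
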