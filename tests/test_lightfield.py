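"""Sky geometry, surface illuminance, attenuation, and unit conversions."""

import math
from datetime import datetime, timezone

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moondvm import lightfield as lf

UTC = timezone.utc


class TestSolarPosition:
    def test_matches_independent_solar_calculator(self):
        # frozen oracle: NOAA spreadsheet algorithm, geometric altitude
        t = datetime(2022, 9, 13, 12, 0, tzinfo=UTC)
        assert lf.solar_altitude(t, 53.15, 13.03) == pytest.approx(39.206, abs=0.5)

    def test_antipodal_longitude_flips_sign(self):
        t = datetime(2022, 9, 13, 12, 0, tzinfo=UTC)
        a1 = lf.solar_altitude(t, 53.15, 13.03)
        a2 = lf.solar_altitude(t, 53.15, 13.03 - 180.0)
        assert a2 == pytest.approx(-31.94, abs=2.0)
        assert np.sign(a1) == -np.sign(a2)

    def test_equinox_noon_sun_near_zenith_at_equator(self):
        # at the instant of equinox the subsolar point sits on the equator,
        # so the maximum altitude over longitude at lat 0 is ~90 deg
        t = datetime(2022, 3, 20, 15, 33, tzinfo=UTC)
        alts = [lf.solar_altitude(t, 0.0, lon) for lon in np.arange(-180, 180, 0.5)]
        assert max(alts) == pytest.approx(90.0, abs=1.0)

    def test_range_and_errors(self):
        t = datetime(2000, 6, 1, 3, 0, tzinfo=UTC)
        assert -90 <= lf.solar_altitude(t, -45.0, 170.0) <= 90
        with pytest.raises(ValueError):
            lf.solar_altitude(t, 95.0, 0.0)
        with pytest.raises(TypeError):
            lf.solar_altitude("2000-06-01", 0.0, 0.0)


class TestTwilight:
    @pytest.mark.parametrize(
        "alt,phase",
        [
            (5.0, "day"),
            (0.0, "day"),
            (-4.0, "civil"),
            (-6.0, "nautical"),
            (-10.0, "nautical"),
            (-12.0, "astronomical"),
            (-17.9, "astronomical"),
            (-18.0, "night"),
            (-90.0, "night"),
            (90.0, "day"),
        ],
    )
    def test_boundaries_assigned_to_darker_phase(self, alt, phase):
        assert lf.classify_twilight(alt) == phase

    @given(st.floats(min_value=-90.0, max_value=90.0))
    @settings(max_examples=200, deadline=None)
    def test_partitions_altitude_range(self, alt):
        assert lf.classify_twilight(alt) in lf.TWILIGHT_PHASES

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lf.classify_twilight(-91.0)


class TestLunarState:
    def test_full_moon_date_illuminated_fraction(self):
        # second full-moon sampling night; reference almanac value 91.5%
        s = lf.lunar_state(datetime(2022, 9, 13, 0, 0, tzinfo=UTC), 53.15, 13.03)
        assert s.illuminated_fraction == pytest.approx(0.915, abs=0.02)

    def test_new_moon_date_nearly_dark(self):
        s = lf.lunar_state(datetime(2022, 8, 25, 0, 0, tzinfo=UTC), 53.15, 13.03)
        assert s.illuminated_fraction < 0.10

    def test_fraction_consistent_with_phase_angle(self):
        for day in (1, 7, 13, 19, 25):
            s = lf.lunar_state(datetime(2022, 9, day, 22, 0, tzinfo=UTC), 53.15, 13.03)
            expected = (1 + math.cos(math.radians(s.lunar_phase_angle))) / 2
            assert s.illuminated_fraction == pytest.approx(expected, abs=1e-9)
            assert 0.0 <= s.illuminated_fraction <= 1.0

    def test_distance_plausible(self):
        s = lf.lunar_state(datetime(2022, 9, 13, 0, 0, tzinfo=UTC), 53.15, 13.03)
        assert 356_000 < s.lunar_distance < 407_000

    def test_out_of_window_date_rejected(self):
        with pytest.raises(ValueError):
            lf.lunar_state(datetime(1850, 1, 1, tzinfo=UTC), 0.0, 0.0)

    def test_skystate_rejects_inconsistent_fraction(self):
        with pytest.raises(ValueError):
            lf.SkyState(
                time=datetime(2022, 9, 13, tzinfo=UTC), lat=0, lon=0,
                solar_altitude=0, lunar_altitude=0, lunar_phase_angle=0.0,
                illuminated_fraction=0.5, lunar_distance=385000.0,
            )


def _sky(solar_alt=-30.0, lunar_alt=-10.0, phase=0.0, dist=385000.56, okta=0):
    return lf.SkyState(
        time=datetime(2022, 9, 13, tzinfo=UTC), lat=53.15, lon=13.03,
        solar_altitude=solar_alt, lunar_altitude=lunar_alt,
        lunar_phase_angle=phase,
        illuminated_fraction=(1 + math.cos(math.radians(phase))) / 2,
        lunar_distance=dist, cloud_okta=okta,
    )


class TestSurfaceIlluminance:
    def test_moonless_astronomical_night_is_starlight_floor(self):
        assert lf.surface_illuminance(_sky(-25.0, -10.0, 180.0)) == pytest.approx(0.001)

    def test_full_moon_zenith_in_literature_band(self):
        e = lf.surface_illuminance(_sky(-30.0, 90.0, 0.0))
        assert 0.1 <= e <= 0.4

    def test_cloud_factor_is_multiplicative(self):
        p = lf.SkyModelParams()
        clear = lf.surface_illuminance(_sky(-20.0, 45.0, 30.0, okta=0), p)
        overcast = lf.surface_illuminance(_sky(-20.0, 45.0, 30.0, okta=8), p)
        assert overcast == pytest.approx(p.okta_transmission[8] * clear, rel=1e-12)

    def test_nonnegative_and_monotone_in_okta(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            sky = _sky(
                rng.uniform(-90, 90), rng.uniform(-90, 90),
                rng.uniform(0, 180), rng.uniform(360000, 406000),
            )
            values = [
                lf.surface_illuminance(_sky(sky.solar_altitude, sky.lunar_altitude,
                                            sky.lunar_phase_angle, sky.lunar_distance, okta))
                for okta in range(9)
            ]
            assert all(v >= 0 for v in values)
            assert all(b <= a + 1e-12 for a, b in zip(values, values[1:]))

    def test_daylight_dwarfs_moonlight(self):
        assert lf.surface_illuminance(_sky(40.0, -10.0, 180.0)) > 1e4

    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            lf.SkyModelParams(extinction_mag_per_airmass=-1.0)
        with pytest.raises(ValueError):
            lf.SkyModelParams(okta_transmission=(1.0, 1.1, 1, 1, 1, 1, 1, 1, 1))


class TestAttenuation:
    def test_closed_form_decay(self):
        # 1 lx through 10 m at Kd=0.3: e^-3 = 0.0498
        edges = np.array([9.95, 10.05])
        prof = lf.attenuate_profile(1.0, 0.3, edges, floor_lx=0.0)
        assert prof.illuminance_lx[0] == pytest.approx(math.exp(-3.0), rel=1e-9)

    def test_floor_zeroes_dim_bins(self):
        edges = lf.make_bin_edges(16.7)
        prof = lf.attenuate_profile(0.05, 0.5, edges)
        lx = prof.illuminance_lx
        assert np.all((lx == 0) | (lx >= 0.001))
        # analytically, 0.05*exp(-0.5 z) < 0.001 below z = 2 ln(50) ~ 7.8 m
        assert lx[int(8.0 / 0.1)] == 0.0
        assert lx[0] > 0.001

    def test_zero_kd_keeps_surface_value(self):
        edges = lf.make_bin_edges(2.0)
        prof = lf.attenuate_profile(0.5, 0.0, edges)
        assert np.all(prof.illuminance_lx == 0.5)

    def test_monotone_before_flooring_and_flooring_never_raises(self):
        edges = lf.make_bin_edges(16.7)
        raw = lf.attenuate_profile(3.0, 0.4, edges, floor_lx=0.0).illuminance_lx
        floored = lf.attenuate_profile(3.0, 0.4, edges, floor_lx=0.001).illuminance_lx
        assert np.all(np.diff(raw) <= 0)
        assert np.all(floored <= raw)

    def test_bin_count_and_errors(self):
        assert lf.attenuate_profile(1, 0.2, lf.make_bin_edges(16.7)).n_bins == 167
        with pytest.raises(ValueError):
            lf.attenuate_profile(1.0, -0.1, lf.make_bin_edges(1.0))
        with pytest.raises(ValueError):
            lf.attenuate_profile(-1.0, 0.1, lf.make_bin_edges(1.0))


class TestRadiometricConversions:
    def test_night_illuminance_reference_values(self):
        # blue-green monochromatic approximation at 500 nm
        assert lf.lux_to_irradiance(0.06, 500) == pytest.approx(2.72e-4, rel=0.01)
        assert lf.lux_to_photon_flux(0.06, 500) == pytest.approx(1.14e-3, rel=0.01)

    def test_visual_floor_at_520nm(self):
        assert lf.lux_to_irradiance(0.001, 520) == pytest.approx(2.1e-6, rel=0.02)

    def test_photon_flux_closed_form(self):
        # lambda/(h c N_A): 1 W at 520 nm = 4.347 umol photons
        assert lf.irradiance_to_photon_flux(1.0, 520) == pytest.approx(4.347, rel=1e-3)

    def test_zero_maps_to_zero(self):
        assert lf.lux_to_irradiance(0.0, 500) == 0.0
        assert lf.irradiance_to_photon_flux(0.0, 480) == 0.0

    @given(st.floats(min_value=1e-6, max_value=1e6),
           st.floats(min_value=420.0, max_value=680.0))
    @settings(max_examples=100, deadline=None)
    def test_lux_irradiance_round_trip(self, lux, wavelength):
        w = lf.lux_to_irradiance(lux, wavelength)
        assert lf.irradiance_to_lux(w, wavelength) == pytest.approx(lux, rel=1e-12)

    def test_wavelength_outside_table_rejected(self):
        with pytest.raises(ValueError):
            lf.lux_to_irradiance(1.0, 900)
        with pytest.raises(ValueError):
            lf.photopic_sensitivity(200)

    def test_vectorized_conversion(self):
        lx = np.array([0.0, 0.001, 0.06])
        w = lf.lux_to_irradiance(lx, 500)
        assert w.shape == lx.shape and w[0] == 0.0
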