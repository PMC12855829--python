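"""Generator invariants: environment structure, gamma densities, placement,
schedules, and rendering determinism."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from moondvm import synthetic as syn
from moondvm.assembly import SIZE_CLASS_RANGES


class TestEnvironment:
    def test_structure_holds_across_seeds(self):
        for seed in range(100):
            env = syn.make_environment(seed=seed)
            assert np.all(np.diff(env.temperature) <= 1e-9), f"seed {seed}"
            assert np.all(env.oxygen >= 3.0), f"seed {seed}"
            chl_peak = env.depth_grid[np.argmax(env.chl_a)]
            pe_peak = env.depth_grid[np.argmax(env.phycoerythrin)]
            assert chl_peak < pe_peak, f"seed {seed}"

    def test_deep_chlorophyll_maximum_below_5m(self):
        env = syn.make_environment(seed=0)
        assert 5.0 < env.depth_grid[np.argmax(env.chl_a)] < env.depth_grid[np.argmax(env.phycoerythrin)]

    def test_surface_warmer_than_bottom(self):
        env = syn.make_environment(seed=1)
        assert env.temperature[0] > env.temperature[-1]

    def test_zero_jitter_reproduces_closed_forms(self):
        cfg = syn.EnvironmentConfig(parameter_jitter=0.0)
        env = syn.make_environment(cfg, seed=3)
        z = cfg.depth_grid()
        expected_t = cfg.bottom_temp_C + (cfg.surface_temp_C - cfg.bottom_temp_C) / (
            1 + np.exp((z - cfg.thermocline_depth_m) / cfg.thermocline_width_m)
        )
        np.testing.assert_allclose(env.temperature, expected_t, rtol=1e-12)

    def test_thermocline_outside_column_rejected(self):
        cfg = syn.EnvironmentConfig(thermocline_depth_m=30.0, parameter_jitter=0.0)
        with pytest.raises(ValueError):
            syn.make_environment(cfg, seed=0)


class TestSimulateBinDensities:
    @staticmethod
    def _design(n=4000, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "date": "d0",
                "profile_id": "p0",
                "size_class": rng.choice(["small", "medium", "large"], n),
                "illuminance_lx": rng.uniform(0, 0.06, n),
                "temperature_C": rng.uniform(8, 20, n),
                "chl_a_ugL": rng.uniform(2, 6, n),
            }
        )

    def test_intercept_only_mean_matches_gamma_mean(self):
        design = self._design()
        beta = {t: 0.0 for t in syn.NIGHT_COEFFICIENTS["cladoceran"]}
        beta["intercept"] = 1.3
        out = syn.simulate_bin_densities(design, beta, 0.0, 0.0, 2.0, seed=1)
        mc_se = out["density"].std() / np.sqrt(len(out))
        assert out["density"].mean() == pytest.approx(np.exp(1.3), abs=3 * mc_se)

    def test_huge_shape_collapses_to_conditional_mean(self):
        design = self._design(n=600)
        beta = syn.NIGHT_COEFFICIENTS["cladoceran"]
        out = syn.simulate_bin_densities(design, beta, 0.0, 0.0, 1e6, seed=2)
        from moondvm import glmm

        X, _ = glmm.design_matrix(design, glmm.GlmmSpec(design="night"))
        eta = X @ pd.Series(beta).reindex(list(glmm.NIGHT_TERMS)).to_numpy()
        np.testing.assert_allclose(out["density"], np.exp(eta), rtol=0.01)

    def test_densities_strictly_positive(self):
        out = syn.simulate_bin_densities(
            self._design(n=500), syn.NIGHT_COEFFICIENTS["copepod"], 0.2, 0.14, 2.0, seed=3
        )
        assert (out["density"] > 0).all()

    def test_missing_beta_term_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            syn.simulate_bin_densities(self._design(n=10), {"intercept": 1.0}, 0, 0, 2.0, seed=0)


class TestPlaceIndividuals:
    @staticmethod
    def _bins(density, n_bins=10, taxon="cladoceran", cls="medium"):
        return pd.DataFrame(
            {
                "profile_id": "p0",
                "taxon": taxon,
                "size_class": cls,
                "bin_index": np.arange(n_bins),
                "density": density,
            }
        )

    def test_zero_density_places_nothing(self):
        assert len(syn.place_individuals(self._bins(0.0), seed=0)) == 0

    def test_expected_count_is_density_times_bin_volume(self):
        # density 1 ind/L in one fully covered bin: 0.52 L expected
        bins = self._bins(1.0, n_bins=1)
        counts = [len(syn.place_individuals(bins, seed=s)) for s in range(400)]
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        assert mean == pytest.approx(0.52, abs=3 * se + 1e-9)

    def test_count_conservation_in_expectation(self):
        rng = np.random.default_rng(7)
        density = rng.uniform(0, 5, 30)
        bins = self._bins(density, n_bins=30)
        expected = density.sum() * 0.52
        ok = 0
        for s in range(40):
            n = len(syn.place_individuals(bins, seed=s))
            if abs(n - expected) <= 3 * np.sqrt(expected):
                ok += 1
        assert ok >= 0.95 * 40 - 2  # binomial slack on the 3-sigma rule

    def test_attributes_within_generating_ranges(self):
        ind = syn.place_individuals(self._bins(5.0, taxon="copepod", cls="large"), seed=1)
        lo, hi = SIZE_CLASS_RANGES["copepod"]["large"]
        assert ind["esd_true_mm"].between(lo, hi).all()
        assert ind["depth_m"].between(0.0, 1.0).all()
        assert (ind["axis_ratio"] >= 2.0).all() and ind["antenna"].all()


class TestSchedule:
    def test_new_moon_night_is_one_day_plus_twelve(self):
        sched = syn.schedule_profiles([date(2022, 8, 25)])[0]
        assert sched.labels.count("day") == 1
        assert len(sched.profile_times) == 13  # sunset-30min .. +5h half-hourly

    def test_times_strictly_increasing(self):
        for sched in syn.schedule_profiles(list(syn.SAMPLING_DATES)):
            t = sched.profile_times
            assert all(b > a for a, b in zip(t, t[1:]))

    def test_full_moon_series_respects_altitude_stop(self):
        from moondvm.lightfield import lunar_state

        sched = syn.schedule_profiles([date(2022, 10, 12)])[0]
        assert sched.moon_condition == "full"
        night = sched.profile_times[1:]
        if sched.warning is None:
            # every retained profile precedes the moon's 50-degree crossing
            for t in night:
                assert lunar_state(t, syn.STUDY_LAT, syn.STUDY_LON).lunar_altitude < 50.0
        else:
            assert len(night) <= 13  # capped at 5.5 h past sunset


class TestTruncatedNormalCalibration:
    def test_calibrated_moments(self):
        loc, scale = syn.truncated_normal_params(9.13, 4.24, 0.0, 16.7)
        from scipy import stats

        a, b = (0 - loc) / scale, (16.7 - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        assert float(m) == pytest.approx(9.13, abs=1e-6)
        assert float(np.sqrt(v)) == pytest.approx(4.24, abs=1e-6)

    def test_calibrated_individuals_sample_moments(self):
        ind = syn.make_calibrated_individuals(
            [f"p{i}" for i in range(6)], 9.13, 4.24, expected_per_profile=500, seed=11
        )
        se = 4.24 / np.sqrt(len(ind))
        assert ind["depth_m"].mean() == pytest.approx(9.13, abs=4 * se)
        assert ind["depth_m"].between(0, 16.7).all()


class TestRendering:
    def test_descent_and_overlap_constants(self):
        o = syn.Optics()
        assert o.descent_per_frame_m * 1000 == pytest.approx(34.72, abs=0.01)
        assert o.frame_height_mm - o.descent_per_frame_m * 1000 == pytest.approx(8.28, abs=0.01)

    def test_empty_water_noise_off_equals_illumination_field(self):
        frames = syn.render_profile_frames(
            pd.DataFrame(columns=list(syn.INDIVIDUAL_COLUMNS)),
            lake_depth_m=0.1,
            scale_factor=8,
            illumination_gradient=0.0,
            noise_sd=0.0,
            background_level=200.0,
            seed=0,
        )
        for f in frames:
            assert np.all(f.pixels == 200)

    def test_rendering_is_deterministic(self):
        ind = syn.make_calibrated_individuals(["p0"], 0.2, 0.1, expected_per_profile=20,
                                              lake_depth_m=0.4, seed=3)
        ind["depth_m"] = ind["depth_m"].clip(0, 0.39)
        f1 = syn.render_profile_frames(ind, lake_depth_m=0.4, scale_factor=4, seed=9)
        f2 = syn.render_profile_frames(ind, lake_depth_m=0.4, scale_factor=4, seed=9)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_individual_below_bottom_rejected(self):
        ind = pd.DataFrame(
            [{"profile_id": "p", "taxon": "cladoceran", "depth_m": 1.5,
              "esd_true_mm": 0.5, "lateral_mm": 20.0, "axis_ratio": 1.5,
              "antenna": False, "size_class": "medium"}]
        )
        with pytest.raises(ValueError, match="deeper"):
            syn.render_profile_frames(ind, lake_depth_m=1.0, scale_factor=8, seed=0)

    def test_frame_sequence_covers_water_column(self):
        frames = syn.render_profile_frames(
            pd.DataFrame(columns=list(syn.INDIVIDUAL_COLUMNS)),
            lake_depth_m=1.0, scale_factor=8, noise_sd=0.0, seed=0,
        )
        assert frames[0].top_depth_m == 0.0
        assert frames[-1].bottom_depth_m >= 1.0
        tops = [f.top_depth_m for f in frames]
        assert np.allclose(np.diff(tops), syn.Optics().descent_per_frame_m)

    def test_silhouette_centroid_depth_matches_truth(self, silhouette_sweep):
        truth, matched = silhouette_sweep
        whole = matched[~matched["edge_clipped"]]
        clads = whole[whole["true_taxon"] == "cladoceran"]
        # centroid depth within half a pixel pitch of the generating depth
        err = (clads["depth_m"] - clads["true_depth_m"]).abs()
        assert err.max() <= 0.5 * 0.021 / 1000.0
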