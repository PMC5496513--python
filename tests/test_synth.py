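import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from kelpscape import synth
from kelpscape.errors import ConfigError


class TestTrack:
    def test_straight_zero_sd_is_exactly_collinear(self):
        cfg = synth.SiteConfig("A", 5, spacing_mean=3.8, spacing_sd=0, track_style="straight")
        t = synth.generate_track(cfg, 1)
        np.testing.assert_allclose(t["x"], [0, 3.8, 7.6, 11.4, 15.2])
        np.testing.assert_allclose(t["y"], 0, atol=1e-12)

    def test_seeded_determinism(self):
        cfg = synth.SiteConfig("A", 50)
        pd.testing.assert_frame_equal(
            synth.generate_track(cfg, 7), synth.generate_track(cfg, 7)
        )

    def test_mean_spacing_close_to_configured(self):
        cfg = synth.SiteConfig("A", 500, spacing_mean=3.8, spacing_sd=1.0)
        t = synth.generate_track(cfg, 2)
        spacing = np.hypot(np.diff(t["x"]), np.diff(t["y"]))
        assert spacing.mean() == pytest.approx(3.8, rel=0.05)
        assert (spacing > 0).all()

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ConfigError):
            synth.SiteConfig("A", 10, spacing_mean=0.0)


class TestLatentField:
    def test_zero_variance_field_is_zero(self):
        z = synth.generate_latent_field(np.arange(5.0), np.zeros(5), 10.0, 0.0, 0.0, 1)
        np.testing.assert_array_equal(z, 0.0)

    def test_two_point_correlation_matches_exponential_covariance(self):
        # points at h = range_m apart: corr = exp(-1) ~ 0.368
        rng_pairs = [
            synth.generate_latent_field(
                np.array([0.0, 20.0]), np.zeros(2), 20.0, 1.0, 0.0, seed
            )
            for seed in range(2000)
        ]
        z = np.array(rng_pairs)
        corr = np.corrcoef(z[:, 0], z[:, 1])[0, 1]
        assert corr == pytest.approx(np.exp(-1), abs=0.05)

    def test_pure_nugget_has_no_lag_correlation(self):
        # neighboring positions on a line: correlation ~ 0
        x = np.arange(50.0) * 3.8
        z = np.array(
            [synth.generate_latent_field(x, np.zeros(50), 0.0, 0.0, 1.0, s) for s in range(200)]
        )
        corr = np.corrcoef(z[:, :-1].ravel(), z[:, 1:].ravel())[0, 1]
        assert abs(corr) < 0.03

    def test_variance_matches_sill_plus_nugget(self):
        x = np.arange(40.0) * 3.8
        z = np.array(
            [synth.generate_latent_field(x, np.zeros(40), 15.0, 0.8, 0.2, s) for s in range(300)]
        )
        assert z.var() == pytest.approx(1.0, rel=0.1)


class TestCoverAndCounts:
    def test_neutral_logit_gives_half(self):
        p = synth.cover_probabilities(np.zeros(3), np.zeros(3), 0.0, 0.0)
        np.testing.assert_allclose(p, 0.5)

    def test_low_cover_site_intercept(self):
        p = synth.cover_probabilities(np.zeros(1), np.zeros(1), -3.89, 0.0)
        assert p[0] == pytest.approx(0.02, abs=0.001)

    def test_depth_effect_is_monotone(self):
        alpha = logit(0.38)
        shallow = synth.cover_probabilities(np.zeros(1), np.array([0.0]), alpha, -0.5)
        deep = synth.cover_probabilities(np.zeros(1), np.array([10.0]), alpha, -0.5)
        assert deep[0] < shallow[0]
        assert shallow[0] == pytest.approx(0.38, abs=1e-12)

    def test_certain_cover_no_error_fills_all_points(self):
        k = synth.sample_counts(np.ones(10), 25, 0.0, 1)
        np.testing.assert_array_equal(k, 25)

    def test_label_error_expectation_closed_form(self):
        # E[k/m] = p(1-e) + (1-p)e = 0.2*0.93 + 0.8*0.07 = 0.242
        k = synth.sample_counts(np.full(10_000, 0.2), 25, 0.07, 3)
        assert (k / 25).mean() == pytest.approx(0.242, abs=0.005)

    def test_symmetric_cover_immune_to_label_error(self):
        assert synth.observed_probability(0.5, 0.3) == 0.5

    def test_binomial_variance_without_latent_structure(self):
        p = 0.3
        k = synth.sample_counts(np.full(20_000, p), 25, 0.0, 4)
        assert (k / 25).var() == pytest.approx(p * (1 - p) / 25, rel=0.05)

    def test_invalid_label_error_rejected(self):
        with pytest.raises(ConfigError):
            synth.sample_counts(np.array([0.5]), 25, 0.6, 1)


class TestEnvironment:
    @pytest.fixture(scope="class")
    def small_env(self):
        cfg = synth.SiteConfig("A", 100)
        t = synth.generate_track(cfg, 3)
        return t, synth.generate_environment({"A": t}, seed=3)

    def test_depth_increases_offshore(self, small_env):
        _, env = small_env
        col = env.bathymetry.data[:, env.bathymetry.ncols // 2]
        # northern (shoreline) edge is row 0: southern cells are deeper
        assert col[-1] > col[0]

    def test_all_quadrats_on_reef(self, small_env):
        t, env = small_env
        assert (env.reef_mask.sample(t["x"], t["y"]) > 0.5).all()

    def test_bathymetry_positive_on_reef(self, small_env):
        _, env = small_env
        assert (env.bathymetry.data[env.reef_bool()] > 0).all()

    def test_seeded_determinism(self, small_env):
        t, env = small_env
        env2 = synth.generate_environment({"A": t}, seed=3)
        np.testing.assert_array_equal(env.bathymetry.data, env2.bathymetry.data)
        np.testing.assert_array_equal(env.reef_mask.data, env2.reef_mask.data)


class TestStudy:
    @pytest.fixture(scope="class")
    def mini_study(self):
        configs = [
            synth.SiteConfig("A", 150, target_cover=0.05, range_m=2.0, sill=0.4, nugget=0.3),
            synth.SiteConfig("B", 150, target_cover=0.30, range_m=20.0, sill=1.0, nugget=0.2),
        ]
        return synth.generate_study(configs, seed=11)

    def test_records_schema_and_truth_alignment(self, mini_study):
        records, env, truth = mini_study
        assert len(records) == 300
        assert set(records["site_id"]) == {"A", "B"}
        assert list(truth.quadrats["quadrat_id"]) == list(records["quadrat_id"])
        assert ((records["k"] >= 0) & (records["k"] <= records["m"])).all()

    def test_calibrated_sites_hit_target_mean_cover(self, mini_study):
        _, _, truth = mini_study
        for _, row in truth.sites.iterrows():
            assert row["mean_p_true"] == pytest.approx(row["target_cover"], abs=1e-6)

    def test_depth_consistent_with_raster(self, mini_study):
        records, env, _ = mini_study
        sampled = env.bathymetry.sample(records["x"], records["y"])
        np.testing.assert_allclose(records["depth_m"], sampled)

    def test_truth_roundtrip(self, mini_study, tmp_path):
        _, _, truth = mini_study
        truth.write(tmp_path)
        back = synth.StudyTruth.read(tmp_path)
        assert list(back.quadrats["quadrat_id"]) == list(truth.quadrats["quadrat_id"])
        np.testing.assert_allclose(back.quadrats["p_true"], truth.quadrats["p_true"], rtol=1e-8)

    def test_duplicate_site_id_rejected(self):
        cfgs = [synth.SiteConfig("A", 10), synth.SiteConfig("A", 10)]
        with pytest.raises(ConfigError):
            synth.generate_study(cfgs, seed=1)

    def test_mean_cover_monotone_in_alpha(self):
        covers = []
        for alpha in (-3.0, -1.0, 1.0):
            cfg = synth.SiteConfig("A", 200, alpha=alpha, range_m=5.0, sill=0.5, nugget=0.2)
            records, _, truth = synth.generate_study([cfg], seed=5)
            covers.append(truth.sites["mean_p_true"][0])
        assert covers[0] < covers[1] < covers[2]

    def test_paperlike_preset_contract(self):
        configs = synth.paperlike_configs()
        assert len(configs) == 8
        assert all(400 <= c.n_quadrats <= 1000 for c in configs)
        targets = [c.target_cover for c in configs]
        assert min(targets) == pytest.approx(0.02) and max(targets) == pytest.approx(0.38)
        n_random = sum(c.range_m <= 2 for c in configs)
        n_patchy = sum(15 <= c.range_m <= 40 for c in configs)
        assert n_random == 2 and n_patchy == 6

    def test_config_file_roundtrip(self, tmp_path):
        configs = synth.paperlike_configs()[:2]
        path = tmp_path / "sites.cfg"
        synth.configs_to_file(configs, path)
        back = synth.configs_from_file(path)
        assert back == configs


class TestAlphaCalibration:
    def test_no_offsets_reduces_to_logit(self):
        a = synth.calibrate_alpha(0.38, np.zeros(1))
        assert a == pytest.approx(logit(0.38), abs=1e-8)

    def test_marginal_calibration_compensates_jensen(self):
        # with latent variance, E[invlogit(a+Z)] at a=logit(.02) overshoots;
        # the calibrated alpha is smaller
        a = synth.calibrate_alpha(0.02, np.zeros(1), latent_sd=1.0)
        assert a < logit(0.02)
        assert synth.expected_cover(a, np.zeros(1), 1.0) == pytest.approx(0.02, abs=1e-8)
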