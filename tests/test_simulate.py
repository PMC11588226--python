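import numpy as np
import pytest
from scipy.stats import norm

from faaknn.simulate import (
    GP_VARIANCE,
    OUTLIER_TYPES,
    LabeledSample,
    ScenarioConfig,
    build_scenario,
    build_toy_multicluster,
    exp_cov_matrix,
    group_mean_curves,
    mean_cluster1,
    mean_shape_cluster2,
    mean_shape_outlier,
    normal_bump,
    sample_gp_noise,
)


class TestGpNoise:
    def test_covariance_diagonal_is_pointwise_variance(self):
        grid = np.linspace(0.0, 1.0, 25)
        C = exp_cov_matrix(grid)
        assert np.allclose(np.diag(C), 0.3)

    def test_covariance_decay_at_lag_03(self):
        C = exp_cov_matrix(np.array([0.0, 0.3]))
        assert C[0, 1] == pytest.approx(0.3 * np.exp(-1.0), rel=1e-12)

    def test_empirical_variance_matches(self):
        grid = np.linspace(0.0, 1.0, 25)
        draws = sample_gp_noise(20_000, grid, seed=123)
        var = draws.var(axis=0)
        # sampling error of a variance estimate: sd ~ var * sqrt(2/n)
        se = GP_VARIANCE * np.sqrt(2.0 / 20_000)
        assert np.abs(var - GP_VARIANCE).max() < 3.0 * se

    def test_empirical_covariance_on_subgrid(self):
        grid = np.linspace(0.0, 1.0, 5)
        draws = sample_gp_noise(50_000, grid, seed=9)
        emp = np.cov(draws.T)
        se = GP_VARIANCE * np.sqrt(2.0 / 50_000)
        assert np.abs(emp - exp_cov_matrix(grid)).max() < 3.0 * se

    def test_deterministic_given_seed(self):
        grid = np.linspace(0.0, 1.0, 10)
        assert np.array_equal(
            sample_gp_noise(3, grid, seed=5), sample_gp_noise(3, grid, seed=5)
        )

    def test_rejects_unsorted_grid(self):
        with pytest.raises(ValueError, match="increasing"):
            sample_gp_noise(1, np.array([0.0, 0.5, 0.2]), seed=0)


class TestMeanFunctions:
    @pytest.mark.parametrize("t, expected", [(0.0, 0.0), (1.0, 0.0), (1.1, 0.0)])
    def test_cluster1_mean_boundary_and_clamp(self, t, expected):
        assert mean_cluster1(t) == pytest.approx(expected)

    def test_cluster1_mean_midpoint(self):
        # 30 * 0.5 * 0.5^1.5
        assert mean_cluster1(0.5) == pytest.approx(15.0 * 0.5**1.5)

    def test_shape_means_vanish_at_domain_ends(self):
        for f in (mean_shape_outlier, mean_shape_cluster2):
            assert f(0.0) == pytest.approx(0.0)
            assert f(1.0) == pytest.approx(0.0)


class TestNormalBump:
    def test_peak_is_standard_normal_density_at_zero(self):
        bump = normal_bump(6)
        assert bump[5] == pytest.approx(norm.pdf(0.0))

    def test_support_is_the_11_point_window(self):
        bump = normal_bump(6)
        assert np.all(bump[:11] > 0)
        assert np.allclose(bump[11:], 0.0)

    def test_symmetric_about_center(self):
        bump = normal_bump(6)
        assert np.allclose(bump[:11], bump[:11][::-1])

    def test_late_window_bump(self):
        bump = normal_bump(20)
        assert np.allclose(bump[:14], 0.0)
        assert bump[19] == pytest.approx(norm.pdf(0.0))

    def test_window_out_of_range(self):
        with pytest.raises(ValueError, match="window"):
            normal_bump(3)


class TestBuildScenario:
    @pytest.mark.parametrize("kind", OUTLIER_TYPES)
    def test_one_cluster_composition(self, kind):
        data = build_scenario(ScenarioConfig("one_cluster", kind, seed=1))
        assert data.sample.n == 100
        assert data.labels.sum() == 5
        assert (data.cluster_ids == 1).sum() == 95
        assert np.isfinite(data.sample.coefficients).all()

    def test_two_cluster_composition(self):
        data = build_scenario(ScenarioConfig("two_cluster", "shape", seed=1))
        assert (data.cluster_ids == 1).sum() == 70
        assert (data.cluster_ids == 2).sum() == 25
        assert data.labels.sum() == 5

    def test_v_shift_group_means_differ_by_constants(self):
        cfg = ScenarioConfig("two_cluster", "v_shift", seed=0)
        means = group_mean_curves(cfg)
        assert np.allclose(means["outlier"] - means["cluster1"], 3.0)
        assert np.allclose(means["cluster2"] - means["cluster1"], 6.0)

    def test_amplitude_group_means_at_midpoint(self):
        cfg = ScenarioConfig("two_cluster", "amplitude", seed=0)
        means = group_mean_curves(cfg)
        grid = np.linspace(0.0, 1.0, 25)
        i = np.argmin(np.abs(grid - 0.5))
        assert means["cluster1"][i] == pytest.approx(5.3033, abs=1e-4)
        assert means["outlier"][i] == pytest.approx(15.9099, abs=1e-4)
        assert means["cluster2"][i] == pytest.approx(31.8198, abs=1e-4)

    def test_amplitude_and_v_shift_share_noise_realization(self):
        """The outlier families of one seed transform the same underlying
        noise draw, so the implied noise vectors agree bit for bit."""
        amp = build_scenario(ScenarioConfig("one_cluster", "amplitude", seed=7))
        vsh = build_scenario(ScenarioConfig("one_cluster", "v_shift", seed=7))
        mu1 = mean_cluster1(np.linspace(0.0, 1.0, 25))
        noise_amp = amp.sample.coefficients[amp.labels] - 3.0 * mu1
        noise_vsh = vsh.sample.coefficients[vsh.labels] - 3.0 - mu1
        # the recovered noise differs only by the rounding of the two
        # transform arithmetics, not by the draw
        assert np.allclose(noise_amp, noise_vsh, atol=1e-12, rtol=0.0)

    def test_h_shift_uses_shifted_clamped_mean(self):
        cfg = ScenarioConfig("two_cluster", "h_shift", seed=0)
        means = group_mean_curves(cfg)
        grid = np.linspace(0.0, 1.0, 25)
        assert np.allclose(means["outlier"], mean_cluster1(grid + 0.15))
        # the shifted mean vanishes where t + 0.3 > 1
        assert np.allclose(means["cluster2"][grid > 0.7], 0.0)

    def test_isolated_bump_positions(self):
        cfg = ScenarioConfig("two_cluster", "isolated", seed=0)
        means = group_mean_curves(cfg)
        diff_out = means["outlier"] - means["cluster1"]
        diff_c2 = means["cluster2"] - means["cluster1"]
        assert diff_out.argmax() == 5  # 6th observation
        assert diff_c2.argmax() == 19  # 20th observation
        assert diff_out.max() == pytest.approx(15.0 * norm.pdf(0.0))

    def test_label_cluster_consistency_enforced(self):
        data = build_scenario(ScenarioConfig("one_cluster", "shape", seed=2))
        with pytest.raises(ValueError, match="labels"):
            LabeledSample(data.sample, ~data.labels, data.cluster_ids)

    def test_bad_cluster_sizes_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            ScenarioConfig(
                "two_cluster", "shape", n_total=100, cluster_sizes=(60, 20)
            )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_reproducible_and_seed_sensitive(self, seed):
        a = build_scenario(ScenarioConfig("one_cluster", "isolated", seed=seed))
        b = build_scenario(ScenarioConfig("one_cluster", "isolated", seed=seed))
        c = build_scenario(ScenarioConfig("one_cluster", "isolated", seed=seed + 50))
        assert np.array_equal(a.sample.coefficients, b.sample.coefficients)
        assert not np.allclose(a.sample.coefficients, c.sample.coefficients)


class TestToyMulticluster:
    def test_composition(self):
        toy = build_toy_multicluster()
        assert toy.sample.n == 66
        assert toy.labels.sum() == 1
        assert (toy.cluster_ids == 4).sum() == 5
        for cid in (1, 2, 3):
            assert (toy.cluster_ids == cid).sum() == 20
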