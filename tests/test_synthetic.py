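"""Generative model: latent stimulus, subject synthesis, closed-form oracle."""

import numpy as np
import pytest

from isfcpipe.synthetic import (
    GROUPS,
    ConfigurationError,
    SyntheticConfig,
    build_dataset,
    default_two_group_config,
    expected_pairwise_isfc,
    null_config,
    sample_latent_stimulus,
    sample_motion_confounds,
    synthesize_subject,
)


def _config(r=4, t=1000, sigma=None, weights=None, noise_sd=1.0, **kw):
    sigma = np.eye(r) if sigma is None else sigma
    w = np.full(r, 0.8) if weights is None else np.asarray(weights, float)
    return SyntheticConfig(
        n_regions=r,
        n_timepoints=t,
        group_sizes=(3, 3),
        stimulus_correlation=sigma,
        weights_by_group={"NT": w, "AUT": w},
        noise_sd=noise_sd,
        **kw,
    )


class TestLatentStimulus:
    def test_independent_regions_have_null_cross_correlation(self, rng):
        cfg = _config(r=5, t=10_000)
        u = sample_latent_stimulus(cfg, rng)
        c = np.corrcoef(u.T)
        off = c[np.triu_indices(5, k=1)]
        assert np.abs(off).max() < 0.05

    def test_same_seed_is_bit_identical(self):
        cfg = _config(t=500)
        a = sample_latent_stimulus(cfg, np.random.default_rng(3))
        b = sample_latent_stimulus(cfg, np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_prescribed_cross_correlation_is_recovered(self, rng):
        sigma = np.eye(4)
        sigma[1, 2] = sigma[2, 1] = 0.5
        cfg = _config(r=4, t=20_000, sigma=sigma)
        u = sample_latent_stimulus(cfg, rng)
        r12 = np.corrcoef(u[:, 1], u[:, 2])[0, 1]
        assert r12 == pytest.approx(0.5, abs=0.03)

    def test_ar1_coloring_preserves_cross_correlation(self, rng):
        sigma = np.eye(3)
        sigma[0, 1] = sigma[1, 0] = 0.6
        cfg = _config(r=3, t=20_000, sigma=sigma, smoothness=3.0)
        u = sample_latent_stimulus(cfg, rng)
        assert np.corrcoef(u[:, 0], u[:, 1])[0, 1] == pytest.approx(0.6, abs=0.05)
        # lag-1 autocorrelation should match exp(-1/smoothness)
        ac = np.corrcoef(u[:-1, 2], u[1:, 2])[0, 1]
        assert ac == pytest.approx(np.exp(-1 / 3.0), abs=0.05)

    def test_non_psd_matrix_is_rejected_naming_eigenvalue(self):
        sigma = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        with pytest.raises(ConfigurationError, match="eigenvalue"):
            _config(r=3, sigma=sigma)


class TestSynthesizeSubject:
    def test_zero_weights_give_pure_noise(self, rng):
        cfg = _config(r=3, t=5000)
        latent = sample_latent_stimulus(cfg, rng)
        x = synthesize_subject(latent, np.zeros(3), 1.0, rng)
        for r in range(3):
            assert abs(np.corrcoef(x[:, r], latent[:, r])[0, 1]) < 0.05

    def test_noise_free_limit_reproduces_latent(self, rng):
        cfg = _config(r=3, t=100)
        latent = sample_latent_stimulus(cfg, rng)
        x = synthesize_subject(latent, np.ones(3), 1e-8, rng)
        assert np.allclose(x, latent, atol=1e-6)

    def test_attenuation_matches_formula(self, rng):
        # corr(x, u) = w / sqrt(w^2 + sigma^2) = 0.8 / sqrt(0.64 + 0.36)
        cfg = _config(r=2, t=20_000)
        latent = sample_latent_stimulus(cfg, rng)
        x = synthesize_subject(latent, np.full(2, 0.8), 0.6, rng)
        r0 = np.corrcoef(x[:, 0], latent[:, 0])[0, 1]
        assert r0 == pytest.approx(0.8, abs=0.03)

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ConfigurationError):
            synthesize_subject(rng.standard_normal((10, 3)), np.ones(4), 1.0, rng)


class TestExpectedPairwiseIsfc:
    def test_noise_free_limit_equals_stimulus_correlation(self):
        sigma = np.eye(3)
        sigma[0, 2] = sigma[2, 0] = 0.4
        cfg = _config(r=3, sigma=sigma, weights=np.ones(3), noise_sd=1e-9)
        assert np.allclose(expected_pairwise_isfc(cfg, "NT"), sigma, atol=1e-12)

    def test_silent_region_zeroes_its_row_and_column(self):
        sigma = np.full((3, 3), 0.5)
        np.fill_diagonal(sigma, 1.0)
        cfg = _config(r=3, sigma=sigma, weights=[0.0, 0.8, 0.8])
        rho = expected_pairwise_isfc(cfg, "NT")
        assert np.all(rho[0, :] == 0) and np.all(rho[:, 0] == 0)

    def test_hand_case(self):
        sigma = np.eye(2)
        sigma[0, 1] = sigma[1, 0] = 0.5
        cfg = _config(r=2, sigma=sigma, weights=[0.8, 0.8], noise_sd=0.6)
        rho = expected_pairwise_isfc(cfg, "NT")
        # 0.64 * 0.5 / sqrt((0.64+0.36)(0.64+0.36)) = 0.32
        assert rho[0, 1] == pytest.approx(0.32, abs=1e-12)
        assert np.allclose(rho, rho.T)


class TestBuildDataset:
    def test_equal_weights_plant_nothing(self):
        ds = build_dataset(null_config(n_timepoints=50, group_sizes=(3, 3)))
        assert ds.planted_pairs == []

    def test_planted_pairs_enumerate_differing_cells(self):
        cfg = default_two_group_config(
            n_regions=15, n_timepoints=50, group_sizes=(3, 3),
            effect_regions=5, seed=1,
        )
        ds = build_dataset(cfg)
        # only pairs inside the coupled effect block differ between groups
        expected = {(i, j) for i in range(5) for j in range(i + 1, 5)}
        assert {(i, j) for i, j, _ in ds.planted_pairs} == expected
        assert all(s == 1 for _, _, s in ds.planted_pairs)

    def test_group_sizes_and_labels(self):
        cfg = default_two_group_config(
            n_timepoints=50, group_sizes=(10, 9), seed=2
        )
        ds = build_dataset(cfg)
        assert len(ds.subjects) == 19
        assert sum(s.group == "NT" for s in ds.subjects) == 10
        assert sum(s.group == "AUT" for s in ds.subjects) == 9

    def test_same_seed_gives_identical_dataset(self):
        cfg = default_two_group_config(n_timepoints=80, group_sizes=(3, 3), seed=11)
        a, b = build_dataset(cfg), build_dataset(cfg)
        for sa, sb in zip(a.subjects, b.subjects):
            assert sa.subject_id == sb.subject_id
            assert np.array_equal(sa.data, sb.data)
        for sid in a.confounds:
            assert np.array_equal(a.confounds[sid].motion, b.confounds[sid].motion)

    def test_truth_matrices_are_symmetric_and_bounded(self, small_config):
        ds = build_dataset(small_config)
        for g in GROUPS:
            m = ds.truth_expected_isfc[g]
            assert np.allclose(m, m.T)
            assert np.abs(m).max() <= 1.0


class TestMotionConfounds:
    def test_no_high_movers_when_fraction_zero(self, rng):
        cfg = _config(t=300)
        tables = sample_motion_confounds(cfg, rng)
        assert all(c.mean_fd <= 0.5 for c in tables.values())

    def test_exact_high_mover_count(self, rng):
        cfg = SyntheticConfig(
            n_regions=3, n_timepoints=300, group_sizes=(5, 5),
            stimulus_correlation=np.eye(3),
            weights_by_group={g: np.full(3, 0.5) for g in GROUPS},
            high_mover_fraction=0.2, seed=0,
        )
        tables = sample_motion_confounds(cfg, rng)
        assert sum(c.mean_fd > 0.5 for c in tables.values()) == 2

    def test_mean_fd_calibration(self, rng):
        cfg = _config(t=400)
        cfg.motion_mean_fd_by_group = {"NT": 0.25, "AUT": 0.1}
        tables = sample_motion_confounds(cfg, rng)
        for sid, c in tables.items():
            target = 0.25 if "NT" in sid else 0.1
            assert c.mean_fd == pytest.approx(target, rel=0.05)

    def test_fd_series_independent_across_subjects(self, rng):
        t = 2000
        cfg = _config(t=t)
        tables = sample_motion_confounds(cfg, rng)
        fds = [c.fd[1:] for c in tables.values()]
        r01 = np.corrcoef(fds[0], fds[1])[0, 1]
        assert abs(r01) < 3 / np.sqrt(t)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "patch,msg",
        [
            (dict(noise_sd=0.0), "noise_sd"),
            (dict(group_sizes=(1, 5)), "group_sizes"),
            (dict(high_mover_fraction=1.5), "high_mover_fraction"),
        ],
    )
    def test_invalid_parameters_rejected(self, patch, msg):
        kw = dict(
            n_regions=3, n_timepoints=50, group_sizes=(3, 3),
            stimulus_correlation=np.eye(3),
            weights_by_group={g: np.full(3, 0.5) for g in GROUPS},
        )
        kw.update(patch)
        with pytest.raises(ConfigurationError, match=msg):
            SyntheticConfig(**kw)

    def test_weights_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigurationError, match="weights"):
            _config(r=2, weights=[1.2, 0.5])
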