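"""Synthetic cohort generator tests: correlation templates, latent mixing,
time-series sampling, nuisance, satisfaction planting and full cohorts."""

import numpy as np
import pytest

from conftest import small_config
from dyadsat.similarity import build_similarity_matrix, dyad_similarity
from dyadsat.synthetic import (
    SyntheticConfig,
    apply_nuisance_leak,
    dyadic_variability_dials,
    generate_cohort,
    generate_template,
    make_signal_weights,
    plant_satisfaction,
    sample_nuisance,
    sample_timeseries,
    select_signal_regions,
    subject_latent_corr,
)


class TestGenerateTemplate:
    def test_zero_factors_gives_identity(self):
        np.testing.assert_array_equal(generate_template(6, 0, 0), np.eye(6))

    def test_valid_correlation_matrix_and_psd(self):
        c = generate_template(30, 5, 1)
        np.testing.assert_array_equal(np.diag(c), 1.0)
        np.testing.assert_allclose(c, c.T, atol=1e-15)
        assert np.linalg.eigvalsh(c).min() >= -1e-10

    def test_deterministic_given_seed(self):
        np.testing.assert_array_equal(
            generate_template(10, 3, 7), generate_template(10, 3, 7)
        )

    @pytest.mark.parametrize("n,k", [(0, 0), (5, 5), (5, -1)])
    def test_bad_dimensions_rejected(self, n, k):
        with pytest.raises(ValueError):
            generate_template(n, k, 0)


class TestSubjectLatentCorr:
    def test_zero_weights_return_template_exactly(self):
        template = generate_template(8, 3, 0)
        out = subject_latent_corr(template, generate_template(8, 3, 1), 0.0, 0.0, 2)
        np.testing.assert_array_equal(out, template)

    def test_output_is_correlation_matrix(self):
        template = generate_template(12, 3, 0)
        pair = generate_template(12, 3, 1)
        out = subject_latent_corr(template, pair, 0.5, 0.3, 3)
        np.testing.assert_array_equal(np.diag(out), 1.0)
        np.testing.assert_allclose(out, out.T, atol=1e-12)
        assert np.linalg.eigvalsh(out).min() >= -1e-10

    def test_invalid_weights_rejected(self):
        t = generate_template(5, 2, 0)
        with pytest.raises(ValueError):
            subject_latent_corr(t, t, 0.7, 0.5, 0)
        with pytest.raises(ValueError):
            subject_latent_corr(t, t, -0.1, 0.2, 0)

    def test_indiv_scale_validated(self):
        t = generate_template(5, 2, 0)
        with pytest.raises(ValueError, match="indiv_scale"):
            subject_latent_corr(t, t, 0.4, 0.4, 0, indiv_scale=np.full(4, 1.0))

    def test_within_pair_similarity_exceeds_cross_pair(self):
        """Monte-Carlo: pair-shared structure raises dyad similarity."""
        n, nf = 30, 3
        template = generate_template(n, nf, 0)
        rng_seed = 0
        within, cross = [], []
        prev = None
        for p in range(200):
            pair = generate_template(n, nf, 1000 + p)
            a = subject_latent_corr(template, pair, 0.5, 0.1, 2 * p)
            b = subject_latent_corr(template, pair, 0.5, 0.1, 2 * p + 1)
            within.append(dyad_similarity(a, b).mean())
            if prev is not None:
                cross.append(dyad_similarity(prev, a).mean())
            prev = b
        assert np.mean(within) > np.mean(cross)


class TestSampleTimeseries:
    def test_empirical_correlation_converges_to_latent(self):
        latent = generate_template(5, 2, 3)
        ts = sample_timeseries(latent, 20000, 0.0, 4)
        emp = np.corrcoef(ts, rowvar=False)
        assert np.abs(emp - latent).max() < 0.05

    def test_identity_latent_gives_independent_series(self):
        ts = sample_timeseries(np.eye(5), 20000, 0.0, 5)
        emp = np.corrcoef(ts, rowvar=False)
        off = emp[~np.eye(5, dtype=bool)]
        assert np.abs(off).mean() < 0.05

    def test_ar_coefficient_shapes_autocorrelation(self):
        ts = sample_timeseries(np.eye(3), 20000, 0.6, 6)
        lag1 = np.corrcoef(ts[:-1, 0], ts[1:, 0])[0, 1]
        assert abs(lag1 - 0.6) < 0.05

    def test_deterministic_given_seed(self):
        latent = generate_template(4, 2, 0)
        np.testing.assert_array_equal(
            sample_timeseries(latent, 50, 0.3, 9),
            sample_timeseries(latent, 50, 0.3, 9),
        )

    def test_explosive_ar_rejected(self):
        with pytest.raises(ValueError):
            sample_timeseries(np.eye(3), 10, 1.0, 0)


class TestNuisance:
    def test_shapes(self):
        motion, wm, csf = sample_nuisance(60, 0)
        assert motion.shape == (60, 6)
        assert wm.shape == (60,) and csf.shape == (60,)

    def test_deterministic_given_seed(self):
        a = sample_nuisance(40, 3)
        b = sample_nuisance(40, 3)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sample_nuisance(1, 0)

    def test_zero_leak_returns_series_unchanged(self):
        ts = np.random.default_rng(0).normal(size=(30, 4))
        motion, wm, csf = sample_nuisance(30, 1)
        out = apply_nuisance_leak(ts, motion, wm, csf, 0.0, 2)
        np.testing.assert_array_equal(out, ts)

    def test_nonzero_leak_changes_series(self):
        ts = np.random.default_rng(0).normal(size=(30, 4))
        motion, wm, csf = sample_nuisance(30, 1)
        out = apply_nuisance_leak(ts, motion, wm, csf, 0.5, 2)
        assert np.abs(out - ts).max() > 0


class TestPlantSatisfaction:
    def test_zero_signal_zero_noise_gives_intercept(self):
        s = np.random.default_rng(0).normal(size=(7, 5))
        y, items_a, items_b = plant_satisfaction(
            s, np.zeros(5), 6.5, 0.0, 0,
            subject_jitter_sd=0.0, item_noise_sd=0.0,
        )
        np.testing.assert_array_equal(y, 6.5)
        assert items_a.shape == (7, 18)

    def test_all_outputs_clipped_to_scale(self):
        s = np.random.default_rng(1).normal(size=(10, 4))
        y, items_a, items_b = plant_satisfaction(
            s, np.full(4, 50.0), 6.0, 2.0, 1
        )
        for arr in (y, items_a, items_b):
            assert arr.min() >= 1 and arr.max() <= 8

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            plant_satisfaction(np.zeros((3, 2)), np.zeros(2), 6.0, -1.0, 0)

    def test_pair_mean_of_items_tracks_target(self):
        s = np.random.default_rng(2).normal(size=(20, 3))
        y, items_a, items_b = plant_satisfaction(
            s, np.array([1.0, -1.0, 0.5]), 5.5, 0.3, 3
        )
        realized = (items_a.mean(axis=1) + items_b.mean(axis=1)) / 2
        assert np.abs(realized - y).mean() < 0.3


class TestSignalConstruction:
    def test_make_signal_weights_pattern(self):
        w = make_signal_weights(50, 0)
        assert np.sum(w > 0) == 3 and np.sum(w < 0) == 4

    def test_select_signal_regions_prefers_high_variance(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=(20, 30)) * 0.01
        s[:, [3, 11, 25]] += rng.normal(size=(20, 3))  # high-variance columns
        chosen = select_signal_regions(s, n_signal=3, pool=5)
        assert set(chosen) >= {3, 11, 25} or len(set(chosen) & {3, 11, 25}) >= 2

    def test_select_signal_regions_deterministic(self):
        s = np.random.default_rng(5).normal(size=(15, 20))
        np.testing.assert_array_equal(
            select_signal_regions(s, 3), select_signal_regions(s, 3)
        )


class TestDials:
    def test_shape_and_range(self):
        d = dyadic_variability_dials(29, 120, 0, scale=1.5, pair_frac=0.35)
        assert d.shape == (29, 120)
        assert d.min() >= 0 and d.max() <= 1.5 * 1.4

    def test_stratified_columns_cover_the_range(self):
        d = dyadic_variability_dials(
            29, 10, 1, scale=1.0, pair_frac=0.0, region_amp=(1.0, 1.0)
        )
        # flat amplitude, no pair component: each column is a shuffled grid
        for j in range(10):
            np.testing.assert_allclose(
                np.sort(d[:, j]), (np.arange(29) + 0.5) / 29
            )


class TestGenerateCohort:
    def test_default_cohort_has_study_dimensions(self):
        cohort = generate_cohort(SyntheticConfig(seed=0))
        assert len(cohort.subjects) == 58
        assert len(cohort.pairs) == 29
        ts = cohort.timeseries[cohort.subjects[0]]
        assert ts.shape == (180, 120)
        assert cohort.latent_similarity.shape == (29, 120)
        assert sorted(cohort.pair_sex) == ["F"] * 14 + ["M"] * 15

    def test_every_subject_in_exactly_one_pair(self, small_cohort):
        seen = [s for pair in small_cohort.pairs for s in pair]
        assert sorted(seen) == sorted(small_cohort.subjects)

    def test_items_within_scale(self, small_cohort):
        for items in small_cohort.satisfaction_items.values():
            assert items.min() >= 1 and items.max() <= 8

    def test_deterministic_given_seed(self):
        a = generate_cohort(small_config(seed=5))
        b = generate_cohort(small_config(seed=5))
        np.testing.assert_array_equal(a.pair_targets, b.pair_targets)
        np.testing.assert_array_equal(
            a.timeseries[a.subjects[3]], b.timeseries[b.subjects[3]]
        )

    def test_different_seeds_differ(self):
        a = generate_cohort(small_config(seed=1))
        b = generate_cohort(small_config(seed=2))
        assert not np.array_equal(a.pair_targets, b.pair_targets)

    def test_strong_preset_plants_mixed_sign_support(self):
        cohort = generate_cohort(
            SyntheticConfig.strong_signal(
                0, n_pairs=8, n_subjects=16, n_regions=24,
                n_timepoints=80, signal_pool=10,
            )
        )
        w = cohort.signal_weights[cohort.signal_support]
        assert len(cohort.signal_support) == 3
        assert np.sum(w > 0) == 2 and np.sum(w < 0) == 1

    def test_mismatched_subject_count_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_subjects=57)

    def test_invalid_mixture_weights_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(lambda_pair=0.7, lambda_indiv=0.5)


def test_latent_similarity_matches_similarity_module(small_cohort):
    """The stored ground-truth features come from the similarity operation."""
    cfg = small_cohort.config
    # regenerate one pair's latents through the public path and compare row 0
    cohort2 = generate_cohort(cfg)
    np.testing.assert_array_equal(
        small_cohort.latent_similarity, cohort2.latent_similarity
    )
    assert small_cohort.latent_similarity.shape == (cfg.n_pairs, cfg.n_regions)
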