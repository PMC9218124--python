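"""Voxelwise GLM, paired contrasts, class contrasts, and cluster inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from painpsych.mass_univariate import (
    class_contrasts,
    cluster_inference,
    find_clusters,
    fit_covariate_glm,
    paired_contrast,
    t_to_z,
)
from painpsych.synthetic import BetaMapSet, ellipsoid_mask, generate_beta_maps


def _flat_maps(data, mask=None, condition=""):
    if mask is None:
        mask = np.ones((4, 4, 4), dtype=bool)
        mask = mask & True
    ids = [f"S{i}" for i in range(data.shape[0])]
    return BetaMapSet(data=data, mask=mask, subject_ids=ids, condition=condition)


class TestCovariateGLM:
    def test_noiseless_slope_recovered_exactly(self):
        rng = np.random.default_rng(0)
        ratings = rng.uniform(0, 10, 20)
        data = 2.0 * ratings[:, None] + np.linspace(0, 1, 64)[None, :]
        res = fit_covariate_glm(_flat_maps(data), ratings, n_perm=100, seed=0)
        assert np.allclose(res.slopes, 2.0, atol=1e-10)

    def test_covariate_is_mean_centered(self):
        rng = np.random.default_rng(1)
        ratings = rng.uniform(2, 8, 15)
        data = rng.normal(0, 1, (15, 64))
        res = fit_covariate_glm(_flat_maps(data), ratings, n_perm=100, seed=0)
        assert abs(res.covariate.mean()) < 1e-12

    def test_slope_invariant_to_rating_offset(self):
        rng = np.random.default_rng(2)
        ratings = rng.uniform(0, 10, 18)
        data = rng.normal(0, 1, (18, 64)) + ratings[:, None]
        r1 = fit_covariate_glm(_flat_maps(data), ratings, n_perm=100, seed=0)
        r2 = fit_covariate_glm(_flat_maps(data), ratings + 100.0, n_perm=100, seed=0)
        assert np.allclose(r1.slopes, r2.slopes, atol=1e-10)
        assert np.allclose(r1.z, r2.z, atol=1e-10)

    def test_zero_variance_ratings_rejected(self):
        data = np.random.default_rng(0).normal(0, 1, (10, 64))
        with pytest.raises(ValueError, match="identical"):
            fit_covariate_glm(_flat_maps(data), np.full(10, 5.0), n_perm=100)

    def test_coupled_regime_detected(self, small_cohort):
        _, _, truth = small_cohort
        maps = generate_beta_maps(truth, "coupled", seed=3)
        ratings = truth.clean_rating_vector("heat", "high")
        res = fit_covariate_glm(maps["high"], ratings, n_perm=300, seed=1)
        assert res.n_significant_clusters >= 1


class TestPairedContrast:
    def test_identical_conditions_zero_t(self):
        data = np.random.default_rng(0).normal(0, 1, (12, 64))
        res = paired_contrast(_flat_maps(data), _flat_maps(data.copy()), n_perm=100, seed=0)
        assert np.allclose(res.t, 0.0)
        assert res.cluster_table.empty

    def test_df_is_n_minus_one(self):
        rng = np.random.default_rng(1)
        res = paired_contrast(
            _flat_maps(rng.normal(1, 1, (14, 64))),
            _flat_maps(rng.normal(0, 1, (14, 64))),
            n_perm=100, seed=0,
        )
        assert res.df == 13

    def test_equals_one_sample_t_on_differences(self):
        rng = np.random.default_rng(2)
        high = rng.normal(0.5, 1, (16, 64))
        low = rng.normal(0.0, 1, (16, 64))
        res = paired_contrast(_flat_maps(high), _flat_maps(low), n_perm=100, seed=0)
        ref = stats.ttest_1samp(high - low, 0.0, axis=0)
        assert np.allclose(res.t, ref.statistic, atol=1e-10)

    def test_mean_t_matches_analytic_expectation(self):
        # planted difference d = sigma at n=25 gives E[t] ~ d sqrt(n)/sigma = 5
        rng = np.random.default_rng(3)
        n, d, sigma = 25, 1.0, 1.0
        ts = []
        for _ in range(40):
            high = rng.normal(d, sigma, (n, 32))
            low = rng.normal(0.0, sigma, (n, 32))
            diff = high - low
            ts.append((diff.mean(axis=0) / (diff.std(axis=0, ddof=1) / np.sqrt(n))).mean())
        assert np.mean(ts) == pytest.approx(d * np.sqrt(n) / (sigma * np.sqrt(2)), rel=0.1)

    def test_subject_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        a = _flat_maps(rng.normal(0, 1, (10, 64)))
        b = _flat_maps(rng.normal(0, 1, (10, 64)))
        b.subject_ids = list(reversed(b.subject_ids))
        with pytest.raises(ValueError, match="subjects"):
            paired_contrast(a, b, n_perm=100)


class TestClusterInference:
    def test_zero_map_empty_table(self):
        mask = ellipsoid_mask((10, 10, 10))
        null = np.random.default_rng(0).normal(0, 1, (100, int(mask.sum())))
        table = cluster_inference(np.zeros(int(mask.sum())), mask, null)
        assert table.empty

    def test_planted_blob_found_with_exact_size(self):
        mask = np.ones((10, 10, 10), dtype=bool)
        zvol = np.zeros((10, 10, 10))
        zvol[2:4, 3:8, 4] = 5.0  # 10 contiguous voxels
        clusters = find_clusters(zvol, mask, z_thresh=3.1)
        assert len(clusters) == 1
        assert clusters[0]["size"] == 10
        assert clusters[0]["sign"] == 1

    def test_positive_and_negative_clusters_separated(self):
        mask = np.ones((8, 8, 8), dtype=bool)
        zvol = np.zeros((8, 8, 8))
        zvol[1:3, 1, 1] = 5.0
        zvol[3:5, 1, 1] = -5.0  # adjacent but opposite sign
        clusters = find_clusters(zvol, mask, z_thresh=3.1)
        assert sorted(c["sign"] for c in clusters) == [-1, 1]

    def test_six_connectivity_not_diagonal(self):
        mask = np.ones((6, 6, 6), dtype=bool)
        zvol = np.zeros((6, 6, 6))
        zvol[1, 1, 1] = 5.0
        zvol[2, 2, 2] = 5.0  # touches only diagonally
        clusters = find_clusters(zvol, mask, z_thresh=3.1)
        assert len(clusters) == 2

    def test_small_n_perm_rejected(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        with pytest.raises(ValueError, match="n_perm"):
            cluster_inference(np.zeros(64), mask, np.zeros((50, 64)))

    def test_t_to_z_preserves_tail_probability(self):
        t = np.array([-3.0, 0.0, 2.0, 30.0])
        z = t_to_z(t, df=20)
        assert z[1] == 0.0
        assert np.isfinite(z).all()
        assert stats.norm.sf(z[2]) == pytest.approx(stats.t.sf(2.0, 20), rel=1e-9)


class TestClassContrasts:
    def _maps_and_labels(self, seed=0, offset=0.0, n_per=8):
        rng = np.random.default_rng(seed)
        mask = np.ones((6, 6, 6), dtype=bool)
        data = rng.normal(0, 1, (3 * n_per, mask.sum()))
        ids = [f"S{i}" for i in range(3 * n_per)]
        labels = {pid: ["Low", "Moderate", "High"][i // n_per] for i, pid in enumerate(ids)}
        if offset:
            data[:n_per] += offset  # plant an offset into the "Low" class
        return BetaMapSet(data=data, mask=mask, subject_ids=ids), labels

    def test_null_classes_rarely_significant(self):
        maps, labels = self._maps_and_labels(seed=1)
        res = class_contrasts(maps, labels, n_perm=200, seed=0)
        n_sig = int(res.f_cluster_table["significant"].sum()) if not res.f_cluster_table.empty else 0
        assert n_sig == 0

    def test_planted_offset_detected(self):
        maps, labels = self._maps_and_labels(seed=2, offset=3.0)
        res = class_contrasts(maps, labels, n_perm=200, seed=0)
        assert int(res.f_cluster_table["significant"].sum()) >= 1

    def test_zero_noise_equal_means_f_zero(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        data = np.tile(np.linspace(0, 1, 64), (12, 1))  # identical subjects
        ids = [f"S{i}" for i in range(12)]
        labels = {pid: ["A", "B", "C"][i // 4] for i, pid in enumerate(ids)}
        res = class_contrasts(BetaMapSet(data=data, mask=mask, subject_ids=ids),
                              labels, n_perm=100, seed=0)
        assert np.all(res.f == 0.0)

    def test_directed_pairs_are_mirrors(self):
        maps, labels = self._maps_and_labels(seed=3, offset=2.0)
        res = class_contrasts(maps, labels, n_perm=100, seed=0)
        assert set(res.pairwise) == {
            "High>Low", "Low>High", "High>Moderate",
            "Moderate>High", "Low>Moderate", "Moderate>Low",
        }
        np.testing.assert_allclose(res.pairwise_z["High>Low"], -res.pairwise_z["Low>High"])

    def test_singleton_class_rejected(self):
        maps, labels = self._maps_and_labels(seed=4)
        labels[maps.subject_ids[0]] = "Oddball"
        with pytest.raises(ValueError, match="fewer than two"):
            class_contrasts(maps, labels, n_perm=100)
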