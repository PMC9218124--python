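"""Signature expression and LASSO-PCR: linearity, df conventions, leakage-free
cross-validation, signal recovery, and bootstrap ranking."""

import numpy as np
import pytest

from painpsych.multivariate_brain import (
    SignatureWeights,
    bootstrap_weights,
    expression_tests,
    lasso_pcr_fit,
    signature_expression,
    signature_from_planted,
)
from painpsych.synthetic import BetaMapSet, generate_beta_maps


def _maps(data, mask_shape=(4, 4, 4)):
    mask = np.ones(mask_shape, dtype=bool)
    return BetaMapSet(data=data, mask=mask,
                      subject_ids=[f"S{i}" for i in range(data.shape[0])])


class TestSignatureExpression:
    def test_indicator_weight_selects_voxel(self):
        weights = np.zeros(64)
        weights[7] = 1.0
        sig = SignatureWeights(weights=weights, signature_mask=weights > 0)
        beta = np.arange(64.0)
        assert signature_expression(beta, sig) == 7.0

    def test_orthogonal_map_zero(self):
        weights = np.zeros(64)
        weights[:32] = 1.0
        sig = SignatureWeights(weights=weights, signature_mask=np.ones(64, bool))
        beta = np.zeros(64)
        beta[32:] = 5.0
        assert signature_expression(beta, sig) == 0.0

    def test_linearity_machine_precision(self):
        rng = np.random.default_rng(0)
        w = rng.normal(0, 1, 64)
        sig = SignatureWeights(weights=w, signature_mask=rng.random(64) > 0.3)
        m1, m2 = rng.normal(0, 1, 64), rng.normal(0, 1, 64)
        a = 3.7
        lhs = signature_expression(a * m1 + m2, sig)
        rhs = a * signature_expression(m1, sig) + signature_expression(m2, sig)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_voxels_outside_signature_mask_ignored(self):
        w = np.ones(64)
        sig = SignatureWeights(weights=w, signature_mask=np.arange(64) < 8)
        beta = np.ones(64)
        assert signature_expression(beta, sig) == 8.0

    def test_grid_mismatch_rejected(self):
        sig = SignatureWeights(weights=np.ones(10), signature_mask=np.ones(10, bool))
        with pytest.raises(ValueError, match="mismatch"):
            signature_expression(np.ones(12), sig)

    def test_aligned_planting_gives_all_positive(self, small_cohort):
        _, _, truth = small_cohort
        maps = generate_beta_maps(truth, "coupled", seed=8)
        sig = signature_from_planted(truth, maps["high"])
        expr = signature_expression(maps["high"], sig)
        assert np.all(expr > 0)


class TestExpressionTests:
    def test_equal_expressions_zero_t(self):
        rng = np.random.default_rng(1)
        e = rng.normal(5, 1, 20)
        r = rng.normal(5, 1, 20)
        out = expression_tests(e, e.copy(), r)
        assert out["paired_t"]["t"] == 0.0

    def test_df_conventions_at_n_101(self):
        rng = np.random.default_rng(2)
        high = rng.normal(6, 1, 101)
        low = rng.normal(5, 1, 101)
        ratings = rng.normal(4, 2, 101)
        out = expression_tests(high, low, ratings)
        assert out["paired_t"]["df"] == 100
        assert out["correlation"]["df"] == 99

    def test_dissociated_regime_low_correlation(self, small_cohort):
        _, _, truth = small_cohort
        count = 0
        for seed in range(20):
            maps = generate_beta_maps(truth, "dissociated", seed=seed)
            sig = signature_from_planted(truth, maps["high"])
            out = expression_tests(
                signature_expression(maps["high"], sig),
                signature_expression(maps["low"], sig),
                truth.clean_rating_vector("heat", "high"),
            )
            if abs(out["correlation"]["r"]) < 0.4:
                count += 1
        assert count >= 18  # expression carries no rating signal

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            expression_tests(np.ones(5), np.ones(5), np.ones(4))


class TestLassoPcr:
    def test_recoverable_signal_high_r(self):
        rng = np.random.default_rng(3)
        n, v = 60, 200
        component = rng.normal(0, 1, v)
        scores = rng.normal(0, 2, n)
        data = scores[:, None] * component[None, :] + rng.normal(0, 0.01, (n, v))
        ratings = 3.0 * scores + 5.0
        mask = np.ones((10, 5, 4), dtype=bool)
        maps = BetaMapSet(data=data, mask=mask,
                          subject_ids=[f"S{i}" for i in range(n)])
        model = lasso_pcr_fit(maps, ratings, n_repeats=2, seed=0)
        assert model.pred_r > 0.99

    def test_permuted_ratings_no_skill(self):
        rng = np.random.default_rng(4)
        n, v = 50, 150
        data = rng.normal(0, 1, (n, v))
        ratings = rng.normal(5, 2, n)
        maps = _maps(data, (10, 5, 3))
        rs = []
        for seed in range(8):
            perm = rng.permutation(ratings)
            model = lasso_pcr_fit(maps, perm, n_repeats=1, seed=seed)
            rs.append(model.pred_r)
        assert abs(np.mean(rs)) < 0.2

    def test_same_seed_identical_predictions(self):
        rng = np.random.default_rng(5)
        data = rng.normal(0, 1, (30, 100))
        ratings = rng.normal(5, 2, 30)
        maps = _maps(data, (10, 5, 2))
        m1 = lasso_pcr_fit(maps, ratings, n_repeats=2, seed=7)
        m2 = lasso_pcr_fit(maps, ratings, n_repeats=2, seed=7)
        assert np.array_equal(m1.predictions, m2.predictions)
        assert np.array_equal(m1.fold_assignments, m2.fold_assignments)

    def test_every_subject_tested_once_per_repeat(self):
        rng = np.random.default_rng(6)
        maps = _maps(rng.normal(0, 1, (25, 64)))
        model = lasso_pcr_fit(maps, rng.normal(5, 2, 25), n_repeats=3, seed=1)
        for rep in range(3):
            assert np.bincount(model.fold_assignments[rep], minlength=5).sum() == 25

    def test_shuffled_test_ratings_do_not_change_lambda(self):
        """No-leakage audit: the penalty path depends only on training folds."""
        rng = np.random.default_rng(7)
        data = rng.normal(0, 1, (30, 80))
        ratings = 2.0 * data[:, 0] + rng.normal(0, 0.5, 30)
        maps = _maps(data, (4, 4, 5))
        m1 = lasso_pcr_fit(maps, ratings, n_repeats=1, seed=3)
        # perturb only the ratings of the first outer test fold
        test0 = np.flatnonzero(m1.fold_assignments[0] == 0)
        ratings2 = ratings.copy()
        ratings2[test0] = rng.permutation(ratings2[test0])
        m2 = lasso_pcr_fit(maps, ratings2, n_repeats=1, seed=3)
        # fold 0 is the first fold fitted, so its selected lambda must match
        assert m1.selected_alphas[0] == pytest.approx(m2.selected_alphas[0], rel=1e-12)

    def test_planted_weights_recovered_in_coupled_regime(self, small_cohort):
        _, _, truth = small_cohort
        maps = generate_beta_maps(truth, "coupled", noise_sd=0.5, seed=10)
        ratings = truth.clean_rating_vector("heat", "high")
        model = lasso_pcr_fit(maps["high"], ratings, n_repeats=2, seed=0)
        planted = np.zeros(maps["high"].n_voxels)
        planted[truth.planted["heat"].effect_voxels] = 1.0
        corr = np.corrcoef(model.voxel_weights, planted)[0, 1]
        assert corr > 0.8

    def test_constant_maps_rejected(self):
        maps = _maps(np.ones((10, 64)))
        with pytest.raises(ValueError, match="zero variance|constant"):
            lasso_pcr_fit(maps, np.arange(10.0))

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(8)
        maps = _maps(rng.normal(0, 1, (3, 64)))
        with pytest.raises(ValueError, match="k_folds"):
            lasso_pcr_fit(maps, np.arange(3.0), k_folds=5)


class TestBootstrapWeights:
    def test_planted_voxels_outrank_noise(self, small_cohort):
        _, _, truth = small_cohort
        maps = generate_beta_maps(truth, "coupled", noise_sd=0.5,
                                  shape=(8, 8, 8), effect_side=3, seed=11)
        ratings = truth.clean_rating_vector("heat", "high")
        model = lasso_pcr_fit(maps["high"], ratings, n_repeats=1, seed=0)
        boot = bootstrap_weights(maps["high"], ratings, model, n_boot=120, seed=1)
        effect = truth.planted["heat"].effect_voxels
        noise = np.setdiff1d(np.arange(maps["high"].n_voxels), effect)
        assert np.median(np.abs(boot.z[effect])) > np.median(np.abs(boot.z[noise]))

    def test_all_zero_weight_voxel_has_zero_z(self):
        rng = np.random.default_rng(9)
        data = rng.normal(0, 1, (20, 64))
        data[:, 10] = 0.0  # dead voxel: zero variance, never selected
        maps = _maps(data)
        ratings = rng.normal(5, 2, 20)
        model = lasso_pcr_fit(maps, ratings, n_repeats=1, seed=0)
        boot = bootstrap_weights(maps, ratings, model, n_boot=100, seed=2)
        assert boot.z[10] == 0.0

    def test_small_n_boot_rejected(self, small_cohort):
        _, _, truth = small_cohort
        maps = generate_beta_maps(truth, "coupled", shape=(6, 6, 6), effect_side=2, seed=12)
        ratings = truth.clean_rating_vector("heat", "high")
        model = lasso_pcr_fit(maps["high"], ratings, n_repeats=1, seed=0)
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_weights(maps["high"], ratings, model, n_boot=50)
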