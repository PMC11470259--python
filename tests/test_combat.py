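import numpy as np
import pytest

from histoharm.combat import (apply_reference, drop_degenerate_features,
                              eb_shrink_nonparametric, eb_shrink_parametric,
                              fit_transform, harmonize_cohort,
                              moments_hyperpriors, standardize)
from histoharm.synthetic import SimulationConfig, simulate_cohort
from oracles import combat_brute_force, nonparametric_shrink_brute_force

from conftest import make_bag, make_cohort


class TestDropDegenerateFeatures:
    def test_constant_feature_in_one_slide_dropped_everywhere(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(5, 4))
        A[:, 3] = 2.0  # constant within slide A only
        B = rng.normal(size=(5, 4))
        cohort = make_cohort([make_bag("a", "s1", A), make_bag("b", "s2", B)])
        mask, masked = drop_degenerate_features(cohort)
        np.testing.assert_array_equal(mask, [True, True, True, False])
        assert masked.n_features == 3

    def test_identity_mask_when_no_constants(self):
        rng = np.random.default_rng(1)
        cohort = make_cohort([make_bag("a", "s1", rng.normal(size=(5, 4))),
                              make_bag("b", "s2", rng.normal(size=(5, 4)))])
        mask, masked = drop_degenerate_features(cohort)
        assert mask.all()
        np.testing.assert_array_equal(masked.bags[0].features,
                                      cohort.bags[0].features)

    def test_enumerated_per_slide_variances(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(4, 3))
        A[:, 0] = 1.0  # constant in slide A
        B = rng.normal(size=(4, 3))
        B[:, 1] = -2.0  # constant in slide B
        cohort = make_cohort([make_bag("a", "s1", A), make_bag("b", "s2", B)])
        mask, masked = drop_degenerate_features(cohort)
        np.testing.assert_array_equal(mask, [False, False, True])
        assert masked.n_features == 1

    def test_all_degenerate_raises(self):
        cohort = make_cohort([make_bag("a", "s1", np.ones((3, 2)))])
        with pytest.raises(ValueError, match="degenerate"):
            drop_degenerate_features(cohort)


class TestStandardize:
    def test_hand_example(self):
        X = np.array([[1.0], [3.0], [5.0], [7.0]])
        batches = np.array(["A", "A", "B", "B"], dtype=object)
        Z, alpha, sigma = standardize(X, batches)
        assert alpha[0] == pytest.approx(4.0)
        assert sigma[0] ** 2 == pytest.approx(1.0)
        np.testing.assert_allclose(Z.ravel(), [-3.0, -1.0, 1.0, 3.0])

    def test_degenerate_pooled_variance_raises(self):
        X = np.array([[0.0], [0.0], [2.0], [2.0]])
        batches = np.array(["A", "A", "B", "B"], dtype=object)
        with pytest.raises(ValueError, match="pooled variance"):
            standardize(X, batches)

    def test_single_batch_reduction(self):
        rng = np.random.default_rng(3)
        X = rng.normal(5, 2, size=(30, 4))
        Z, alpha, sigma = standardize(X, np.array(["A"] * 30, dtype=object))
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(sigma, X.std(axis=0))  # N denominator
        np.testing.assert_allclose(alpha, X.mean(axis=0))

    def test_singleton_batch_raises(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError, match="fewer than 2"):
            standardize(X, np.array(["A", "A", "B"], dtype=object))

    def test_nan_rejected(self):
        X = np.full((4, 2), np.nan)
        with pytest.raises(ValueError, match="NaN"):
            standardize(X, np.array(["A", "A", "B", "B"], dtype=object))


class TestMomentsHyperpriors:
    def test_flat_fallback_when_no_spread(self):
        gbar, tau2, lam, theta = moments_hyperpriors(
            np.array([0.1, 0.2, 0.3]), np.array([1.0, 1.0, 1.0]))
        assert (lam, theta) == (1.0, 0.0)

    def test_inverse_gamma_moment_equations(self):
        d2 = np.array([0.5, 1.0, 1.5])
        _, _, lam, theta = moments_hyperpriors(np.zeros(3), d2)
        V, S2 = d2.mean(), d2.var(ddof=1)
        assert lam == pytest.approx((V * V + 2 * S2) / S2)
        assert theta == pytest.approx((V ** 3 + V * S2) / S2)
        # the recovered prior reproduces the observed mean and variance
        assert theta / (lam - 1) == pytest.approx(V)
        assert theta ** 2 / ((lam - 1) ** 2 * (lam - 2)) == pytest.approx(S2)

    def test_gamma_moments(self):
        gbar, tau2, _, _ = moments_hyperpriors(
            np.array([-1.0, 0.0, 1.0]), np.array([0.5, 1.0, 1.5]))
        assert gbar == pytest.approx(0.0)
        assert tau2 == pytest.approx(1.0)  # sample-variance convention

    def test_needs_three_features(self):
        with pytest.raises(ValueError):
            moments_hyperpriors(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestEBParametric:
    def test_no_shrinkage_limit(self):
        rng = np.random.default_rng(4)
        Z = rng.normal(size=(6, 4))
        g_hat = Z.mean(axis=0)
        d2_hat = Z.var(axis=0, ddof=1)
        g_st, _, _ = eb_shrink_parametric(Z, g_hat, d2_hat,
                                          (0.0, 1e12, 3.0, 2.0))
        np.testing.assert_allclose(g_st, g_hat, rtol=1e-6)

    def test_full_shrinkage(self):
        rng = np.random.default_rng(5)
        Z = rng.normal(size=(6, 4))
        g_hat = Z.mean(axis=0)
        d2_hat = Z.var(axis=0, ddof=1)
        g_st, _, _ = eb_shrink_parametric(Z, g_hat, d2_hat,
                                          (0.7, 0.0, 3.0, 2.0))
        np.testing.assert_allclose(g_st, 0.7, rtol=1e-10)

    def test_matches_independent_fixed_point(self):
        # 2 features, n=4: brute-force iterate coded inline to 1e-12
        Z = np.array([[0.3, -1.0], [1.1, 0.4], [-0.2, 0.9], [0.6, -0.5]])
        g_hat = Z.mean(axis=0)
        d2_hat = Z.var(axis=0, ddof=1)
        hyper = (0.2, 0.5, 4.0, 3.0)
        g_st, d2_st, conv = eb_shrink_parametric(Z, g_hat, d2_hat, hyper,
                                                 tol=1e-13, max_iter=10000)
        assert conv
        gbar, tau2, lam, theta = hyper
        n = 4
        g, d2 = g_hat.copy(), d2_hat.copy()
        for _ in range(10000):
            g_new = (n * tau2 * g_hat + d2 * gbar) / (n * tau2 + d2)
            d2_new = (theta + 0.5 * ((Z - g_new) ** 2).sum(axis=0)) / (n / 2 + lam - 1)
            if np.max(np.abs(d2_new - d2)) < 1e-14 and np.max(np.abs(g_new - g)) < 1e-14:
                g, d2 = g_new, d2_new
                break
            g, d2 = g_new, d2_new
        np.testing.assert_allclose(g_st, g, atol=1e-10)
        np.testing.assert_allclose(d2_st, d2, atol=1e-10)


class TestEBNonparametric:
    def test_two_identical_columns_forced_swap(self):
        rng = np.random.default_rng(6)
        col = rng.normal(size=5)
        Z = np.column_stack([col, col])
        g_hat = np.array([0.3, 0.8])
        d2_hat = np.array([1.0, 2.0])
        g_st, d2_st = eb_shrink_nonparametric(Z, g_hat, d2_hat)
        # leave-one-out with D=2 leaves a single candidate: the other column
        np.testing.assert_allclose(g_st, [0.8, 0.3])
        np.testing.assert_allclose(d2_st, [2.0, 1.0])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        Z = rng.normal(size=(8, 3))
        g_hat = Z.mean(axis=0)
        d2_hat = Z.var(axis=0, ddof=1)
        g_st, d2_st = eb_shrink_nonparametric(Z, g_hat, d2_hat)
        g_bf, d2_bf = nonparametric_shrink_brute_force(Z, g_hat, d2_hat)
        np.testing.assert_allclose(g_st, g_bf, atol=1e-10)
        np.testing.assert_allclose(d2_st, d2_bf, atol=1e-10)

    def test_feature_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        Z = rng.normal(size=(6, 4))
        g_hat = Z.mean(axis=0)
        d2_hat = Z.var(axis=0, ddof=1)
        perm = np.array([2, 0, 3, 1])
        g_a, d2_a = eb_shrink_nonparametric(Z, g_hat, d2_hat)
        g_b, d2_b = eb_shrink_nonparametric(Z[:, perm], g_hat[perm], d2_hat[perm])
        np.testing.assert_allclose(g_b, g_a[perm], atol=1e-12)
        np.testing.assert_allclose(d2_b, d2_a[perm], atol=1e-12)


class TestFitTransform:
    def test_one_batch_identity(self):
        rng = np.random.default_rng(9)
        X = rng.normal(3, 2, size=(25, 5))
        model, Xs = fit_transform(X, np.array(["A"] * 25, dtype=object),
                                  allow_single_batch=True)
        np.testing.assert_allclose(Xs, X, rtol=1e-6)

    def test_requires_two_batches_by_default(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        with pytest.raises(ValueError, match="2 batches"):
            fit_transform(X, np.array(["A"] * 10, dtype=object))

    def test_constant_offset_removed(self):
        rng = np.random.default_rng(10)
        base = rng.normal(size=(2000, 6))
        offset = np.array([1.0, -2.0, 0.5, 3.0, -1.0, 2.0])
        X = np.vstack([base[:1000], base[1000:] + offset])
        batches = np.array(["A"] * 1000 + ["B"] * 1000, dtype=object)
        _, Xs = fit_transform(X, batches)
        gap_pre = np.abs(X[:1000].mean(0) - X[1000:].mean(0))
        gap_post = np.abs(Xs[:1000].mean(0) - Xs[1000:].mean(0))
        assert np.all(gap_post <= 0.01 * gap_pre)

    def test_additive_only_keeps_variance_ratio(self):
        rng = np.random.default_rng(11)
        A = rng.normal(0, 1, size=(500, 4))
        B = rng.normal(2, 2, size=(500, 4))
        X = np.vstack([A, B])
        batches = np.array(["A"] * 500 + ["B"] * 500, dtype=object)
        model, Xs = fit_transform(X, batches, correction_mode="additive_only")
        gap_post = np.abs(Xs[:500].mean(0) - Xs[500:].mean(0))
        gap_pre = np.abs(A.mean(0) - B.mean(0))
        assert np.all(gap_post < 0.05 * gap_pre)
        ratio_pre = B.var(0) / A.var(0)
        ratio_post = Xs[500:].var(0) / Xs[:500].var(0)
        np.testing.assert_allclose(ratio_post, ratio_pre, rtol=0.05)
        assert np.all(model.delta_star2 > 0)

    def test_multiplicative_only_keeps_mean_gap(self):
        rng = np.random.default_rng(12)
        A = rng.normal(0, 1, size=(500, 4))
        B = rng.normal(2, 2, size=(500, 4))
        X = np.vstack([A, B])
        batches = np.array(["A"] * 500 + ["B"] * 500, dtype=object)
        _, Xs = fit_transform(X, batches, correction_mode="multiplicative_only")
        ratio_post = Xs[500:].var(0) / Xs[:500].var(0)
        assert np.all(np.abs(ratio_post - 1.0) < 0.15)

    def test_shape_and_finiteness(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(40, 5))
        batches = np.array(["A"] * 15 + ["B"] * 25, dtype=object)
        model, Xs = fit_transform(X, batches)
        assert Xs.shape == X.shape
        assert np.all(np.isfinite(Xs))
        assert np.all(model.delta_star2 > 0)
        assert model.batch_levels == ["A", "B"]
        assert model.n_per_batch == {"A": 15, "B": 25}

    def test_nan_rejected(self):
        X = np.zeros((6, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            fit_transform(X, np.array(["A"] * 3 + ["B"] * 3, dtype=object))

    def test_unknown_prior_mode(self):
        with pytest.raises(ValueError, match="prior_mode"):
            fit_transform(np.zeros((4, 3)),
                          np.array(["A", "A", "B", "B"], dtype=object),
                          prior_mode="banana")

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence(self, seed):
        rng = np.random.default_rng(100 + seed)
        n_a = int(rng.integers(5, 21))
        n_b = int(rng.integers(5, 21))
        D = int(rng.integers(3, 7))
        X = np.vstack([rng.normal(0, 1, size=(n_a, D)),
                       rng.normal(rng.normal(size=D), 1.5, size=(n_b, D))])
        batches = np.array(["A"] * n_a + ["B"] * n_b, dtype=object)
        _, Xs = fit_transform(X, batches, tol=1e-13, max_iter=100000)
        Xo = combat_brute_force(X, batches)
        assert np.max(np.abs(Xs - Xo)) < 1e-8

    @pytest.mark.parametrize("mode", ["additive_only", "multiplicative_only"])
    def test_oracle_equivalence_modes(self, mode):
        rng = np.random.default_rng(42)
        X = np.vstack([rng.normal(0, 1, size=(12, 4)),
                       rng.normal(1, 2, size=(15, 4))])
        batches = np.array(["A"] * 12 + ["B"] * 15, dtype=object)
        _, Xs = fit_transform(X, batches, correction_mode=mode,
                              tol=1e-13, max_iter=100000)
        Xo = combat_brute_force(X, batches, correction_mode=mode)
        assert np.max(np.abs(Xs - Xo)) < 1e-8


class TestApplyReference:
    def _corrected_train(self, seed=14, n=200, D=5):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 1, size=(n // 2, D)),
                       rng.normal(1, 1.5, size=(n // 2, D))])
        batches = np.array(["A"] * (n // 2) + ["B"] * (n // 2), dtype=object)
        model, Xs = fit_transform(X, batches)
        return model, Xs

    def test_self_reference_identity(self):
        model, Xs = self._corrected_train()
        out = apply_reference(model, Xs, Xs)
        np.testing.assert_allclose(out, Xs, atol=1e-6)

    def test_reference_rows_unchanged(self):
        model, Xs = self._corrected_train()
        rng = np.random.default_rng(15)
        X_ext = rng.normal(0.5, 1.2, size=(80, 5))
        from histoharm.combat import fit_transform as ft
        X = np.vstack([Xs, X_ext])
        batches = np.array(["__reference__"] * len(Xs) + ["ext"] * 80, dtype=object)
        _, X_star = ft(X, batches, reference_batch="__reference__")
        np.testing.assert_allclose(X_star[:len(Xs)], Xs, rtol=1e-6, atol=1e-9)

    def test_matched_external_barely_shifted(self):
        model, Xs = self._corrected_train()
        rng = np.random.default_rng(16)
        # draw external data from the corrected reference distribution
        idx = rng.integers(0, len(Xs), size=150)
        X_ext = Xs[idx] + rng.normal(0, 0.01, size=(150, 5))
        out = apply_reference(model, Xs, X_ext)
        shift = np.abs(out.mean(axis=0) - X_ext.mean(axis=0))
        se = Xs.std(axis=0) / np.sqrt(150)
        assert np.all(shift < 3 * se)

    def test_known_offset_removed(self):
        model, Xs = self._corrected_train()
        rng = np.random.default_rng(17)
        idx = rng.integers(0, len(Xs), size=200)
        c = 2.5
        X_ext = Xs[idx] + c
        out = apply_reference(model, Xs, X_ext)
        residual = np.abs(out.mean(axis=0) - Xs[idx].mean(axis=0))
        se = Xs.std(axis=0) / np.sqrt(200)
        assert np.all(residual < 4 * se)

    def test_small_external_rejected(self):
        model, Xs = self._corrected_train()
        with pytest.raises(ValueError, match=">= 2"):
            apply_reference(model, Xs, Xs[:1])

    def test_misaligned_features_rejected(self):
        model, Xs = self._corrected_train()
        with pytest.raises(ValueError, match="feature"):
            apply_reference(model, Xs, Xs[:, :3])


class TestHarmonizeCohort:
    def test_parameter_recovery_and_moment_repair(self):
        cfg = SimulationConfig(
            n_sites=4, slides_per_site=10, patches_per_slide=200, n_features=32,
            additive_prior=[(-2.0, 1.0), (-1.0, 1.0), (1.0, 1.0), (2.0, 1.0)],
            multiplicative_prior=(4.0, 3.0), seed=3,
        )
        cohort, truth = simulate_cohort(cfg)
        model, corrected = harmonize_cohort(cohort)
        # the grand mean absorbs the weighted per-feature average of the true
        # gammas, so the identifiable quantity is the centered effect
        g_units = model.sigma_hat * model.gamma_star
        centered = truth.gamma_true - truth.gamma_true.mean(axis=0)
        for i in range(4):
            r = np.corrcoef(g_units[i], centered[i])[0, 1]
            assert r > 0.9
        X, site, _ = cohort.stacked()
        Xc, _, _ = corrected.stacked()
        levels = model.batch_levels
        def spread(M):
            means = np.array([M[site == lv].mean(axis=0) for lv in levels])
            return (means.max(axis=0) - means.min(axis=0)).mean()
        def var_ratio(M):
            v = np.array([M[site == lv].var(axis=0) for lv in levels])
            return (v.max(axis=0) / v.min(axis=0)).mean()
        assert spread(Xc) < 0.1 * spread(X)
        assert var_ratio(Xc) < var_ratio(X)

    def test_nonparametric_prior_also_repairs_moments(self, small_cohort):
        _, cohort, _ = small_cohort
        model, corrected = harmonize_cohort(cohort, prior_mode="nonparametric")
        X, site, _ = cohort.stacked()
        Xc, _, _ = corrected.stacked()
        lv = model.batch_levels
        gap_pre = np.abs(X[site == lv[0]].mean(0) - X[site == lv[1]].mean(0)).mean()
        # with only 8 features the leave-one-out prior is coarse; require a
        # substantial (not near-total) reduction of the mean gap
        gap_post = np.abs(Xc[site == lv[0]].mean(0) - Xc[site == lv[1]].mean(0)).mean()
        assert gap_post < 0.5 * gap_pre

    def test_additive_vs_multiplicative_division_of_labor(self, small_cohort):
        _, cohort, _ = small_cohort
        X, site, _ = cohort.stacked()
        lv = sorted(set(site))
        def gaps(c):
            M = c.stacked()[0]
            mean_gap = np.abs(M[site == lv[0]].mean(0) - M[site == lv[1]].mean(0)).mean()
            v = np.array([M[site == l].var(0) for l in lv])
            ratio = (v.max(0) / v.min(0)).mean()
            return mean_gap, ratio
        _, add = harmonize_cohort(cohort, correction_mode="additive_only")
        _, mult = harmonize_cohort(cohort, correction_mode="multiplicative_only")
        add_gap, add_ratio = gaps(add)
        mult_gap, mult_ratio = gaps(mult)
        assert add_gap <= mult_gap          # additive wins on means
        assert mult_ratio <= add_ratio      # multiplicative wins on variances
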