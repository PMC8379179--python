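import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats
from sklearn.decomposition import PCA as SkPCA

from delfi.classifier import (
    CVConfig,
    DelfiModel,
    FeatureMatrix,
    augment_multimodal,
    choose_cutoff,
    classify,
    cross_validated_scores,
    fit_pca,
    fit_penalized_logistic,
    jeffreys_interval,
    project,
    roc_auc,
)


def gaussian_cohort(n_per_class=40, n_bins=60, n_arms=6, shift=0.0, z_shift=0.0, seed=0):
    """Direct feature-level cohort: optional mean shift on a few columns."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.normal(size=(n, n_bins))
    Z = rng.normal(size=(n, n_arms))
    y = np.repeat([0, 1], n_per_class)
    X[y == 1, :5] += shift
    Z[y == 1, :2] += z_shift
    ids = tuple(f"s{i}" for i in range(n))
    return FeatureMatrix(X=X, Z=Z, labels=y, sample_ids=ids)


class TestPCA:
    def test_rank_two_data_needs_two_components(self):
        rng = np.random.default_rng(1)
        basis = rng.normal(size=(2, 30))
        coords = rng.normal(size=(100, 2)) * [1.0, 0.8]  # neither direction reaches 90%
        X = coords @ basis
        L = fit_pca(X, variance_target=0.90)
        assert L.n_components == 2
        assert L.explained_variance_ratio.sum() >= 0.90

    def test_component_count_matches_eigen_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 10))
        L = fit_pca(X, variance_target=0.90)
        evals = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1]
        cum = np.cumsum(evals) / evals.sum()
        oracle_k = int(np.argmax(cum >= 0.90) + 1)
        assert L.n_components == oracle_k  # ~9 for isotropic 10-dim noise
        assert 8 <= L.n_components <= 10

    def test_loadings_orthonormal(self):
        X = np.random.default_rng(3).normal(size=(50, 20))
        L = fit_pca(X)
        gram = L.loadings.T @ L.loadings
        np.testing.assert_allclose(gram, np.eye(L.n_components), atol=1e-8)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_pca(np.ones((10, 5)))

    def test_training_scores_match_sklearn(self):
        X = np.random.default_rng(4).normal(size=(80, 25))
        L = fit_pca(X, variance_target=0.90)
        ours = project(X, L)
        sk = SkPCA(n_components=L.n_components).fit(X)
        theirs = sk.transform(X)
        # PCA scores agree up to per-component sign
        for k in range(L.n_components):
            col = ours[:, k]
            assert np.allclose(col, theirs[:, k], atol=1e-6) or np.allclose(
                col, -theirs[:, k], atol=1e-6
            )


class TestProject:
    def test_identity_loadings_select_coordinates(self):
        from delfi.classifier import PCALoadings

        L = PCALoadings(
            loadings=np.eye(4)[:, :2], means=np.zeros(4),
            explained_variance_ratio=np.array([0.6, 0.4]), variance_target=0.9,
        )
        x = np.array([3.0, -1.0, 2.0, 5.0])
        np.testing.assert_allclose(project(x, L), [3.0, -1.0])

    def test_matches_double_loop_oracle(self):
        from delfi.classifier import PCALoadings

        rng = np.random.default_rng(5)
        loadings = rng.normal(size=(4, 2))
        means = rng.normal(size=4)
        L = PCALoadings(loadings, means, np.array([0.5, 0.4]), 0.9)
        x = rng.normal(size=4)
        oracle = [sum(loadings[i, k] * (x[i] - means[i]) for i in range(4)) for k in range(2)]
        np.testing.assert_allclose(project(x, L), oracle, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        L = fit_pca(np.random.default_rng(0).normal(size=(10, 6)))
        with pytest.raises(ValueError, match="length"):
            project(np.zeros(5), L)


class TestPenalizedLogistic:
    def test_separable_feature_reaches_training_auc_one(self):
        x = np.linspace(-2, 2, 40).reshape(-1, 1)
        y = (x[:, 0] > 0).astype(int)
        model, _ = fit_penalized_logistic(x, y, lam=1e-4)
        auc, _ = roc_auc(model.predict_proba(x)[:, 1], y, n_boot=10)
        assert auc == 1.0

    def test_extreme_penalty_shrinks_to_prevalence(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(100, 5))
        y = (rng.random(100) < 0.3).astype(int)
        model, _ = fit_penalized_logistic(X, y, lam=1e4)
        assert np.count_nonzero(model.coef_) == 0
        p = model.predict_proba(X)[:, 1]
        assert np.allclose(p, y.mean(), atol=0.02)

    def test_null_features_zeroed_informative_signs_recovered(self):
        rng = np.random.default_rng(7)
        n, k_inf, k_null = 500, 5, 20
        X = rng.normal(size=(n, k_inf + k_null))
        beta = np.concatenate([[1.5, -1.5, 1.0, -1.0, 0.8], np.zeros(k_null)])
        y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta)))).astype(int)
        model, _ = fit_penalized_logistic(X, y, lam=0.05)
        coef = model.coef_[0]
        assert np.all(coef[k_inf:] == 0.0)
        assert np.all(np.sign(coef[:k_inf]) == np.sign(beta[:k_inf]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            fit_penalized_logistic(np.zeros((10, 2)), np.zeros(10, int))

    def test_grid_selection_prefers_moderate_penalty(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(200, 10))
        y = (rng.random(200) < 1 / (1 + np.exp(-X[:, 0] * 2))).astype(int)
        _, lam = fit_penalized_logistic(X, y, lam_grid=np.array([1e-4, 0.01, 10.0]), seed=0)
        assert lam in (1e-4, 0.01)


class TestCrossValidation:
    def test_no_signal_scores_near_prevalence(self):
        fm = gaussian_cohort(shift=0.0, seed=10)
        fm = FeatureMatrix(
            X=np.tile(fm.X[:1], (len(fm.labels), 1)),
            Z=np.tile(fm.Z[:1], (len(fm.labels), 1)),
            labels=fm.labels, sample_ids=fm.sample_ids,
        )
        # constant X would break PCA; add microscopic jitter
        fm.X += np.random.default_rng(0).normal(scale=1e-9, size=fm.X.shape)
        scores, _ = cross_validated_scores(fm, CVConfig(repeats=2, seed=1, lam=0.05))
        assert np.allclose(scores, fm.labels.mean(), atol=0.08)

    def test_strong_signal_reaches_high_auc(self):
        fm = gaussian_cohort(shift=1.2, z_shift=2.0, seed=11)
        scores, coefs = cross_validated_scores(fm, CVConfig(repeats=3, seed=2))
        auc, _ = roc_auc(scores, fm.labels, n_boot=10)
        assert auc >= 0.95
        assert {"repeat", "fold", "lambda", "n_components"} <= set(coefs.columns)
        assert len(coefs) == 3 * 5

    def test_scores_bounded_and_deterministic(self):
        fm = gaussian_cohort(shift=0.5, seed=12)
        cfg = CVConfig(repeats=2, seed=3)
        s1, _ = cross_validated_scores(fm, cfg)
        s2, _ = cross_validated_scores(fm, cfg)
        assert np.array_equal(s1, s2)
        assert (s1 >= 0).all() and (s1 <= 1).all()

    def test_permuted_labels_give_null_auc(self):
        fm = gaussian_cohort(shift=1.2, z_shift=2.0, n_per_class=50, seed=13)
        rng = np.random.default_rng(99)
        perm = rng.permutation(fm.labels)
        fm_null = FeatureMatrix(fm.X, fm.Z, perm, fm.sample_ids)
        scores, _ = cross_validated_scores(fm_null, CVConfig(repeats=3, seed=4))
        auc, _ = roc_auc(scores, perm, n_boot=10)
        assert abs(auc - 0.5) <= 0.08


class TestCutoffAndClassify:
    def test_enumeration_oracle_example(self):
        scores = np.array([0.1, 0.2, 0.3, 0.9, 0.5, 0.8])
        labels = np.array([0, 0, 0, 0, 1, 1])
        assert choose_cutoff(scores, labels, 0.75) == pytest.approx(0.3)

    def test_zero_target_puts_cutoff_below_minimum(self):
        scores = np.array([0.2, 0.4])
        labels = np.array([0, 1])
        theta = choose_cutoff(scores, labels, 0.0)
        assert theta < 0.2
        assert classify(scores, theta).all()

    def test_unattainable_specificity_raises(self):
        with pytest.raises(ValueError, match="no non-cancer"):
            choose_cutoff(np.array([0.5]), np.array([1]), 0.9)

    def test_boundary_score_is_negative(self):
        assert classify(0.34, 0.34) is False
        assert classify(1.0, 0.99) is True
        np.testing.assert_array_equal(
            classify(np.array([0.1, 0.34, 0.5]), 0.34), [False, False, True]
        )


class TestMultimodal:
    def _cov(self, n, rng=None, cea=None):
        rng = rng or np.random.default_rng(0)
        return pd.DataFrame(
            {
                "age": np.full(n, 60.0),
                "pack_years": np.zeros(n),
                "copd": np.zeros(n),
                "cea": np.zeros(n) if cea is None else cea,
            },
            index=[f"s{i}" for i in range(n)],
        )

    def test_zero_covariates_append_zero_columns_except_age(self):
        out = augment_multimodal(np.zeros((3, 2)), self._cov(3))
        np.testing.assert_allclose(out[:, 2], 60.0)
        np.testing.assert_allclose(out[:, 3:], 0.0)  # log1p(0) = 0

    def test_cea_enters_log1p(self):
        out = augment_multimodal(np.zeros((1, 1)), self._cov(1, cea=np.array([7.5])))
        assert out[0, -1] == pytest.approx(np.log(8.5))

    def test_missing_covariate_names_sample(self):
        cov = self._cov(2)
        cov.loc["s1", "cea"] = np.nan
        with pytest.raises(ValueError, match="s1"):
            augment_multimodal(np.zeros((2, 1)), cov)

    def test_cea_only_signal_lifts_auc(self):
        rng = np.random.default_rng(14)
        fm = gaussian_cohort(shift=0.0, seed=15)
        y = fm.labels
        cea = np.where(y == 1, rng.lognormal(2.0, 0.5, len(y)), rng.lognormal(0.2, 0.5, len(y)))
        cov = self._cov(len(y), cea=cea)
        base = np.hstack([fm.X, fm.Z])
        multi = augment_multimodal(base, cov)
        m0, _ = fit_penalized_logistic(base, y, lam=0.01)
        m1, _ = fit_penalized_logistic(multi, y, lam=0.01)
        auc0, _ = roc_auc(m0.predict_proba(base)[:, 1], y, n_boot=10)
        auc1, _ = roc_auc(m1.predict_proba(multi)[:, 1], y, n_boot=10)
        assert auc1 > auc0


class TestJeffreys:
    def test_published_rounding_examples(self):
        lo, hi = jeffreys_interval(10, 11)
        assert round(lo * 100) == 65 and round(hi * 100) == 99
        lo10, hi10 = jeffreys_interval(10, 10)
        assert round(lo10 * 100) == 78 and round(hi10 * 100) == 100

    def test_full_level_spans_unit_interval(self):
        lo, hi = jeffreys_interval(3, 7, level=1.0)
        assert lo == 0.0 and hi == 1.0

    def test_matches_posterior_density_integration(self):
        for k, n in [(10, 11), (3, 20), (0, 5), (7, 7)]:
            lo, hi = jeffreys_interval(k, n)
            pdf = stats.beta(k + 0.5, n - k + 0.5).pdf
            mass_lo, _ = integrate.quad(pdf, 0, lo)
            mass_hi, _ = integrate.quad(pdf, hi, 1)
            assert mass_lo == pytest.approx(0.025, abs=1e-6)
            assert mass_hi == pytest.approx(0.025, abs=1e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            jeffreys_interval(5, 4)
        with pytest.raises(ValueError):
            jeffreys_interval(-1, 4)


class TestAUC:
    def test_perfect_ordering(self):
        auc, _ = roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]), n_boot=10)
        assert auc == 1.0

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(16)
        scores = rng.random(30)
        labels = (rng.random(30) < 0.4).astype(int)
        auc, _ = roc_auc(scores, labels, n_boot=10)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(17)
        scores = rng.random(2000)
        labels = (rng.random(2000) < 0.5).astype(int)
        auc, (lo, hi) = roc_auc(scores, labels, n_boot=200)
        assert abs(auc - 0.5) < 0.05
        assert lo < auc < hi


class TestDelfiModel:
    def test_fit_save_load_score_roundtrip(self, tmp_path):
        fm = gaussian_cohort(shift=1.0, z_shift=1.5, seed=18)
        model = DelfiModel.fit(
            fm, target_specificity=0.80, cv=CVConfig(repeats=2, seed=5), seed=5
        )
        assert model.theta is not None and 0 <= model.theta <= 1
        s1 = model.score(fm.X, fm.Z)
        model.save(tmp_path / "model")
        loaded = DelfiModel.load(tmp_path / "model")
        s2 = loaded.score(fm.X, fm.Z)
        np.testing.assert_allclose(s1, s2, atol=1e-10)
        assert loaded.theta == pytest.approx(model.theta)

    def test_external_projection_uses_training_means(self):
        fm = gaussian_cohort(shift=1.0, seed=19)
        model = DelfiModel.fit(fm, seed=6)
        shifted = fm.X + 5.0  # external cohort with a global batch shift
        s_train = model.score(fm.X, fm.Z)
        s_shift = model.score(shifted, fm.Z)
        # frozen centering means: projection changes, so this documents that
        # centering is frozen at training rather than recomputed per cohort
        assert not np.allclose(s_train, s_shift)
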