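"""PCA engine: closed-form eigenvalues, oracles, invariants, projection."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from pcaudit.colors import Dataset
from pcaudit.pca import PCA, PCAResults
from tests.conftest import random_dataset


def brute_force_eigen(X):
    """Independent oracle: eigen-decomposition of the sample covariance."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    return w[order], V[:, order]


class TestFit:
    def test_noiseless_simplex_eigenvalues_closed_form(self, noiseless_simplex):
        res = PCA(noiseless_simplex).fit()
        assert np.allclose(res.eigenvalues, [1 / 3, 1 / 3, 1 / 12], atol=1e-12)
        # cross-check against the brute-force covariance oracle
        w, _ = brute_force_eigen(noiseless_simplex.values)
        assert np.allclose(res.eigenvalues, w, atol=1e-12)

    def test_identical_rows_give_zero_eigenvalues(self):
        X = np.tile([0.3, 0.7, 0.1], (5, 1))
        res = PCA(X).fit()
        assert np.allclose(res.eigenvalues, 0, atol=1e-14)

    def test_loadings_orthonormal_and_explained_sums_to_one(self):
        rng = np.random.default_rng(0)
        res = PCA(rng.normal(size=(20, 5))).fit()
        assert np.allclose(res.loadings.T @ res.loadings, np.eye(res.r), atol=1e-10)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert res.explained_fraction.sum() == pytest.approx(1.0, abs=1e-10)

    def test_scores_definition(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 4))
        res = PCA(X).fit()
        assert np.allclose(res.scores, (X - res.center) @ res.loadings, atol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(6, 4))
        res = PCA(X).fit()
        w, V = brute_force_eigen(X)
        assert np.allclose(res.eigenvalues, w[: res.r], atol=1e-8)
        for j in range(res.r):
            if w[j] > 1e-10:
                dot = abs(V[:, j] @ res.loadings[:, j])
                assert dot == pytest.approx(1.0, abs=1e-8)

    def test_agrees_with_sklearn(self):
        from sklearn.decomposition import PCA as SkPCA

        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 6))
        res = PCA(X).fit()
        sk = SkPCA().fit(X)
        assert np.allclose(res.eigenvalues, sk.explained_variance_, atol=1e-8)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(2)
        res = PCA(rng.normal(size=(15, 4))).fit()
        for j in range(res.r):
            assert res.loadings[np.argmax(np.abs(res.loadings[:, j])), j] > 0

    def test_missing_entries_rejected_with_guidance(self):
        ds = Dataset(
            values=np.zeros((3, 2)),
            sample_labels=np.array(list("abc"), dtype=object),
            feature_ids=["x", "y"],
            feature_class=["color-component"] * 2,
            missing_mask=np.array([[True, False], [False, False], [False, False]]),
        )
        with pytest.raises(ValueError, match="collapse_windows"):
            PCA(ds)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            PCA(np.zeros((1, 3)))


class TestExplainedVariance:
    def test_noiseless_simplex_top2_is_eight_ninths(self, noiseless_simplex):
        res = PCA(noiseless_simplex).fit()
        assert res.explained_variance(2) == pytest.approx(8 / 9, abs=1e-12)
        assert res.explained_percent(2) == 89.0  # 88.9 rounds half away from zero

    def test_full_rank_is_one(self, noiseless_simplex):
        res = PCA(noiseless_simplex).fit()
        assert res.explained_variance(res.r) == pytest.approx(1.0)

    def test_k_out_of_range(self, noiseless_simplex):
        res = PCA(noiseless_simplex).fit()
        with pytest.raises(ValueError):
            res.explained_variance(0)
        with pytest.raises(ValueError):
            res.explained_variance(res.r + 1)


class TestTransform:
    def test_training_data_reproduces_scores(self, noisy_simplex):
        res = PCA(noisy_simplex).fit()
        assert np.allclose(res.transform(noisy_simplex, k=2), res.scores[:, :2], atol=1e-10)

    def test_center_row_maps_to_origin(self, noisy_simplex):
        res = PCA(noisy_simplex).fit()
        assert np.allclose(res.transform(res.center[None, :], k=2), 0, atol=1e-12)

    def test_black_squared_distance_to_primaries_in_plane(self, noiseless_simplex):
        # projecting the simplex on the top-2 plane (orthogonal to (1,1,1))
        # puts Black at squared distance 2/3 from each primary
        res = PCA(noiseless_simplex).fit()
        s = res.scores[:, :2]
        for i in range(3):
            assert np.sum((s[i] - s[3]) ** 2) == pytest.approx(2 / 3, abs=1e-10)

    def test_feature_mismatch_rejected(self, noisy_simplex):
        res = PCA(noisy_simplex).fit()
        with pytest.raises(ValueError, match="mismatch"):
            res.transform(np.zeros((2, 5)))


class TestInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_rotation_invariance_full_rank(self, seed):
        rng = np.random.default_rng(seed)
        ds = random_dataset(rng, 15, 4)
        res = PCA(ds).fit()
        assert np.allclose(pdist(res.scores), pdist(ds.values), atol=1e-8)

    def test_reconstruction_error_nonincreasing_and_exact_at_full_rank(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 5))
        res = PCA(X).fit()
        errs = [np.linalg.norm(X - res.reconstruct(k)) for k in range(1, res.r + 1)]
        assert all(a >= b - 1e-10 for a, b in zip(errs, errs[1:]))
        assert errs[-1] == pytest.approx(0.0, abs=1e-8)


class TestProjection:
    def test_fully_observed_equals_transform(self, noisy_simplex):
        res = PCA(noisy_simplex).fit()
        x = noisy_simplex.values[0]
        proj = res.project_with_missing(x, np.zeros(3, bool), k=2)
        assert np.allclose(proj, res.transform(x[None, :], k=2)[0], atol=1e-12)

    def test_partial_observation_closed_form(self):
        # two-feature toy: verify restriction + p/p_obs rescaling by hand
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 2))
        res = PCA(X).fit()
        x = np.array([0.7, np.nan])
        proj = res.project_with_missing(x, np.array([False, True]), k=1)
        expected = (0.7 - res.center[0]) * res.loadings[0, 0] * (2 / 1)
        assert proj[0] == pytest.approx(expected, abs=1e-12)
        unscaled = res.project_with_missing(x, np.array([False, True]), k=1, rescale=False)
        assert unscaled[0] == pytest.approx(expected / 2, abs=1e-12)

    def test_too_few_observed_features(self, noisy_simplex):
        res = PCA(noisy_simplex).fit()
        with pytest.raises(ValueError, match="observes"):
            res.project_with_missing(
                noisy_simplex.values[0], np.array([False, True, True]), k=2
            )

    def test_identical_populations_overlap(self):
        # base and projected cohorts drawn from the same ColorSpecs must
        # land on top of each other (within sampling error of centroids)
        from pcaudit.colors import generate_cohort
        from tests.conftest import simplex_cohort

        n = 200
        base = generate_cohort(simplex_cohort(n, 0.01, seed=0))
        held = generate_cohort(simplex_cohort(n, 0.01, seed=99))
        res = PCA(base).fit()
        proj = res.project_dataset(held, k=2)
        for lab in base.labels_in_order():
            b = res.scores[np.asarray(base.sample_labels == lab), :2].mean(axis=0)
            h = proj[np.asarray(held.sample_labels == lab)].mean(axis=0)
            se = 0.01 * np.sqrt(2 / n)
            assert np.all(np.abs(b - h) < 4 * se)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, noisy_simplex):
        res = PCA(noisy_simplex).fit()
        path = tmp_path / "model.json"
        res.save(path)
        back = PCAResults.load(path)
        assert np.allclose(back.center, res.center)
        assert np.allclose(back.loadings, res.loadings)
        assert np.allclose(back.eigenvalues, res.eigenvalues)
        x = noisy_simplex.values[2]
        assert np.allclose(
            back.project_with_missing(x, np.zeros(3, bool), k=2),
            res.project_with_missing(x, np.zeros(3, bool), k=2),
        )

    def test_summary_mentions_components(self, noisy_simplex):
        res = PCA(noisy_simplex).fit()
        text = res.summary()
        assert "PC1" in text and "eigenvalue" in text
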