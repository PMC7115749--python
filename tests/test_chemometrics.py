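import numpy as np
import pandas as pd
import pytest

from ramanphen.chemometrics import contributions, fit_dapc, fit_pca, predict
from ramanphen.spectra_io import Spectrum, SpectrumSet


def _set_from_matrix(X, grid=None, ids=None):
    n, p = X.shape
    grid = grid if grid is not None else np.arange(400.0, 400.0 + p, 1.0)
    ids = ids or [f"s{i}" for i in range(n)]
    return SpectrumSet([Spectrum(grid, row, sample_id=i) for row, i in zip(X, ids)])


def _two_class_set(rng, n_per=6, p=60, sep=10.0, band=30):
    """Two classes split along one band by `sep` within-class SDs."""
    X = rng.normal(0.0, 1.0, size=(2 * n_per, p))
    X[n_per:, band] += sep
    labels = ["lo"] * n_per + ["hi"] * n_per
    return _set_from_matrix(X), np.asarray(labels, dtype=object)


class TestPCA:
    def test_rank_one_data_concentrates_variance(self, rng):
        shape = rng.normal(size=50)
        coeffs = rng.normal(size=8)
        X = 3.0 + np.outer(coeffs, shape)
        pca = fit_pca(_set_from_matrix(X))
        assert pca.explained_variance_ratio[0] > 0.999

    def test_eigenvalues_match_dense_covariance_oracle(self, rng):
        """SVD route vs brute-force eigendecomposition of the covariance."""
        X = rng.normal(size=(12, 40))
        pca = fit_pca(_set_from_matrix(X))
        Xc = X - X.mean(axis=0)
        evals = np.linalg.eigvalsh(Xc.T @ Xc)[::-1][: pca.n_components]
        ratios = evals / evals.sum()
        np.testing.assert_allclose(pca.explained_variance_ratio, ratios, atol=1e-8)

    def test_two_spectra_give_one_component(self, rng):
        X = rng.normal(size=(2, 30))
        pca = fit_pca(_set_from_matrix(X))
        assert pca.n_components == 1

    def test_reconstruction_with_all_components(self, rng):
        X = rng.normal(size=(9, 25))
        pca = fit_pca(_set_from_matrix(X))
        recon = pca.scores @ pca.loadings + pca.mean_spectrum
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_loadings_orthonormal(self, rng):
        X = rng.normal(size=(10, 30))
        pca = fit_pca(_set_from_matrix(X))
        G = pca.loadings @ pca.loadings.T
        np.testing.assert_allclose(G, np.eye(pca.n_components), atol=1e-10)

    def test_sign_convention_deterministic(self, rng):
        X = rng.normal(size=(8, 20))
        pca = fit_pca(_set_from_matrix(X))
        for row in pca.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_single_spectrum_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            fit_pca(_set_from_matrix(rng.normal(size=(1, 10))))


class TestDAPC:
    def test_separated_classes_have_distant_centroids(self, rng):
        sset, labels = _two_class_set(rng, sep=10.0)
        pca = fit_pca(sset)
        dapc = fit_dapc(pca, labels, n_pcs=5)
        sep = np.linalg.norm(dapc.group_centroids[0] - dapc.group_centroids[1])
        # canonical axes are scaled to unit pooled within-class variance
        assert sep > 5.0

    def test_single_class_rejected(self, rng):
        sset, _ = _two_class_set(rng)
        pca = fit_pca(sset)
        with pytest.raises(ValueError, match="2 classes"):
            fit_dapc(pca, ["same"] * len(sset), 3)

    def test_one_pc_two_classes_one_axis(self, rng):
        sset, labels = _two_class_set(rng)
        dapc = fit_dapc(fit_pca(sset), labels, n_pcs=1)
        assert dapc.n_axes == 1

    def test_axis_count_bounded_by_classes(self, rng):
        X = rng.normal(size=(12, 30))
        X[4:8, 5] += 8.0
        X[8:, 11] += 8.0
        labels = np.repeat(["a", "b", "c"], 4)
        dapc = fit_dapc(fit_pca(_set_from_matrix(X)), labels, n_pcs=6)
        assert dapc.n_axes == 2

    def test_small_class_rejected(self, rng):
        sset, labels = _two_class_set(rng, n_per=4)
        labels = labels.copy()
        labels[0] = "tiny"
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_dapc(fit_pca(sset), labels, 3)

    def test_rotation_invariance_of_canonical_scores(self, rng):
        """Jointly rotating retained PC scores leaves canonical scores
        unchanged up to sign."""
        sset, labels = _two_class_set(rng, n_per=8)
        pca = fit_pca(sset)
        k = 5
        dapc = fit_dapc(pca, labels, n_pcs=k)
        # rotate the retained score block with a random orthogonal matrix
        Q = np.linalg.qr(rng.normal(size=(k, k)))[0]
        import dataclasses

        rotated = dataclasses.replace(pca, scores=pca.scores.copy())
        rotated.scores[:, :k] = pca.scores[:, :k] @ Q
        dapc_rot = fit_dapc(rotated, labels, n_pcs=k)
        a = dapc.canonical_scores[:, 0]
        b = dapc_rot.canonical_scores[:, 0]
        assert min(np.max(np.abs(a - b)), np.max(np.abs(a + b))) < 1e-6

    def test_agrees_with_sklearn_lda_direction(self, rng):
        """Independent cross-check: canonical axis spans the same direction
        as scikit-learn's LDA on the retained scores."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        sset, labels = _two_class_set(rng, n_per=8)
        pca = fit_pca(sset)
        dapc = fit_dapc(pca, labels, n_pcs=5)
        lda = LinearDiscriminantAnalysis(solver="eigen").fit(pca.scores[:, :5], labels)
        v1 = dapc.canonical_axes[0] / np.linalg.norm(dapc.canonical_axes[0])
        v2 = lda.scalings_[:, 0] / np.linalg.norm(lda.scalings_[:, 0])
        assert abs(abs(v1 @ v2) - 1.0) < 1e-6


class TestPredict:
    def test_class_centroid_preimage_maps_to_class(self, rng):
        sset, labels = _two_class_set(rng, n_per=6)
        pca = fit_pca(sset)
        dapc = fit_dapc(pca, labels, n_pcs=5)
        grid, X, _ = sset.to_matrix()
        class_mean = X[np.asarray(labels) == "hi"].mean(axis=0)
        s = Spectrum(grid, class_mean, sample_id="probe")
        assert predict(dapc, pca, s) == "hi"

    def test_tie_breaks_to_first_listed_class(self, rng):
        sset, labels = _two_class_set(rng, n_per=6)
        pca = fit_pca(sset)
        dapc = fit_dapc(pca, labels, n_pcs=5)
        # symmetrise: a point exactly between the two centroids
        mid = dapc.group_centroids.mean(axis=0)
        dapc.group_centroids[0] = mid + 1.0
        dapc.group_centroids[1] = mid - 1.0
        grid, X, _ = sset.to_matrix()
        # construct a spectrum whose canonical score is exactly mid
        s = Spectrum(grid, X.mean(axis=0), sample_id="probe")
        canon = dapc.transform(pca.transform(s.intensities))
        d = np.linalg.norm(dapc.group_centroids - canon, axis=1)
        if abs(d[0] - d[1]) < 1e-9:
            assert predict(dapc, pca, s) == dapc.class_labels[0]

    def test_held_out_member_of_separated_class(self, rng):
        sset, labels = _two_class_set(rng, n_per=7, sep=10.0)
        keep = list(range(1, len(sset)))
        pca = fit_pca(sset.subset(keep))
        dapc = fit_dapc(pca, labels[1:], n_pcs=5)
        assert predict(dapc, pca, sset.spectra[0]) == labels[0]

    def test_grid_mismatch_rejected(self, rng):
        sset, labels = _two_class_set(rng)
        pca = fit_pca(sset)
        dapc = fit_dapc(pca, labels, n_pcs=3)
        bad = Spectrum(np.arange(500.0, 560.0), np.ones(60), sample_id="bad")
        with pytest.raises(ValueError, match="grid"):
            predict(dapc, pca, bad)


class TestContributions:
    def test_single_band_difference_ranks_first(self, rng):
        grid = np.arange(400.0, 1801.0, 1.0)
        profile = np.exp(-0.5 * ((grid - 1520.0) / 6.0) ** 2)
        X = rng.normal(0.0, 0.01, size=(12, grid.size))
        X[:6] += 1.0 * profile
        X[6:] += 3.0 * profile
        sset = _set_from_matrix(X, grid=grid)
        labels = np.repeat(["lo", "hi"], 6)
        pca = fit_pca(sset)
        table = contributions(pca, top_k=5)
        assert abs(table.iloc[0]["shift"] - 1520.0) <= 2.0
        dapc = fit_dapc(pca, labels, n_pcs=5)
        table_d = contributions(dapc, top_k=5, pca=pca)
        assert abs(table_d.iloc[0]["shift"] - 1520.0) <= 2.0
        assert table_d.iloc[0]["assignment"] == "carotenoids"

    def test_full_table_when_top_k_is_grid_length(self, rng):
        X = rng.normal(size=(6, 40))
        pca = fit_pca(_set_from_matrix(X))
        table = contributions(pca, top_k=40)
        assert len(table) == 40
        assert list(table["rank"]) == list(range(1, 41))
        w = table["weight"].abs().to_numpy()
        assert np.all(np.diff(w) <= 1e-15)

    def test_white_noise_null_has_no_dominant_band(self, rng):
        """Null construction: loadings of pure-noise data behave like a
        random unit vector, whose largest |entry| obeys the Gaussian
        order-statistic bound ~ sqrt(2 log p + 10)/sqrt(p)."""
        p = 1401
        X = rng.normal(size=(12, p))
        pca = fit_pca(_set_from_matrix(X, grid=np.arange(400.0, 400.0 + p)))
        w = np.abs(pca.loadings[0])
        bound = np.sqrt((2.0 * np.log(p) + 10.0) / p)
        assert w.max() < bound

    def test_top_k_must_be_positive(self, rng):
        pca = fit_pca(_set_from_matrix(rng.normal(size=(4, 10))))
        with pytest.raises(ValueError, match="top_k"):
            contributions(pca, top_k=0)
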