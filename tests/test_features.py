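"""PCA basis properties, SMOTE geometry and t-SNE diagnostics."""

import numpy as np
import pytest
from sklearn.metrics import silhouette_score

from metaldecoder.core_io import SampleMeta, SpectralDataset, Spectrum
from metaldecoder.features import (
    FeatureMatrix,
    downsample_class,
    fit_pca,
    project,
    reconstruct,
    smote_oversample,
    tsne_embed,
)

from .oracles import pca_eig


def _dataset_from_matrix(X, class_index=None):
    grid = 400.0 + np.arange(X.shape[1])
    metas = class_index or [0] * X.shape[0]
    spectra = []
    for row, ci in zip(X, metas):
        meta = SampleMeta(concentration_molar=float(ci) * 1e-9, class_index=ci) \
            if ci else SampleMeta()
        spectra.append(Spectrum(grid, row, meta))
    return SpectralDataset(spectra)


class TestFitPca:
    def test_collinear_points_single_component(self, rng):
        t = rng.normal(size=30)
        X = 2.0 + np.outer(t, rng.normal(size=8))
        basis = fit_pca(_dataset_from_matrix(X), n_components=3)
        assert basis.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("n,p,k", [(6, 4, 2), (20, 10, 5), (15, 7, 7)])
    def test_matches_eigendecomposition_oracle(self, n, p, k, rng):
        X = rng.normal(size=(n, p))
        basis = fit_pca(_dataset_from_matrix(X), n_components=k)
        mean, comps, evr = pca_eig(X, k)
        np.testing.assert_allclose(basis.mean_spectrum, mean, atol=1e-10)
        np.testing.assert_allclose(np.abs(basis.components), np.abs(comps), atol=1e-8)
        np.testing.assert_allclose(basis.components, comps, atol=1e-8)
        np.testing.assert_allclose(basis.explained_variance_ratio, evr[:k], atol=1e-10)

    def test_components_orthonormal(self, cr_features):
        comps = cr_features[0].basis.components
        gram = comps @ comps.T
        np.testing.assert_allclose(gram, np.eye(comps.shape[0]), atol=1e-8)

    def test_evr_nonincreasing_and_bounded(self, cr_features):
        evr = cr_features[0].basis.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert 0 < evr.sum() <= 1 + 1e-9

    def test_default_component_count_is_22(self, cr_features):
        assert cr_features[0].basis.n_components == 22
        assert cr_features[0].scores.shape[1] == 22

    def test_too_few_samples_rejected(self, rng):
        X = rng.normal(size=(5, 4))
        with pytest.raises(ValueError):
            fit_pca(_dataset_from_matrix(X), n_components=5)


class TestProject:
    def test_mean_spectrum_projects_to_zero(self, rng):
        X = rng.normal(size=(12, 6))
        ds = _dataset_from_matrix(X)
        basis = fit_pca(ds, n_components=3)
        fm = project(Spectrum(ds.grid, basis.mean_spectrum), basis)
        np.testing.assert_allclose(fm.scores, 0.0, atol=1e-10)

    def test_component_plus_mean_projects_to_unit_vector(self, rng):
        X = rng.normal(size=(12, 6))
        ds = _dataset_from_matrix(X)
        basis = fit_pca(ds, n_components=3)
        fm = project(Spectrum(ds.grid, basis.mean_spectrum + basis.components[0]), basis)
        np.testing.assert_allclose(fm.scores.ravel(), [1.0, 0.0, 0.0], atol=1e-10)

    def test_reconstruction_error_monotone_in_components(self, rng):
        X = rng.normal(size=(25, 10))
        ds = _dataset_from_matrix(X)
        basis = fit_pca(ds, n_components=8)
        fm = project(ds, basis)
        errs = [
            np.linalg.norm(X - reconstruct(fm, k)) for k in range(1, 9)
        ]
        assert np.all(np.diff(errs) <= 1e-9)

    def test_grid_mismatch_rejected(self, rng):
        X = rng.normal(size=(12, 6))
        basis = fit_pca(_dataset_from_matrix(X), n_components=2)
        other = _dataset_from_matrix(X)
        for s in other.spectra:
            s.wavenumbers = s.wavenumbers + 5.0
        with pytest.raises(ValueError):
            project(other, basis)


class TestSmote:
    def _fm(self, rng, n_minority=60, n_majority=200):
        scores = np.vstack([
            rng.normal(0, 1, size=(n_majority, 5)),
            rng.normal(4, 1, size=(n_minority, 5)),
        ])
        labels = np.array([0] * n_majority + [1] * n_minority)
        return FeatureMatrix(scores, labels)

    def test_exact_synthetic_count(self, rng):
        fm = self._fm(rng)
        out = smote_oversample(fm, {1: 100}, rng=rng)
        assert out.class_counts[1] == 100
        assert int(out.synthetic.sum()) == 40
        assert not out.synthetic[: len(fm)].any()

    def test_balanced_input_untouched(self, rng):
        fm = self._fm(rng)
        out = smote_oversample(fm, {0: 200, 1: 60}, rng=rng)
        assert len(out) == len(fm)
        np.testing.assert_array_equal(out.scores, fm.scores)

    def test_synthetic_rows_on_segments(self, rng):
        """Each synthetic row is collinear with two real same-class rows."""
        fm = self._fm(rng, n_minority=25)
        out = smote_oversample(fm, {1: 60}, k=5, rng=rng)
        real = fm.scores[fm.labels == 1]
        for x in out.scores[out.synthetic]:
            d = x - real  # (n_real, 5)
            # residual of x from the best segment through any pair
            best = np.inf
            for i in range(len(real)):
                for j in range(len(real)):
                    if i == j:
                        continue
                    seg = real[j] - real[i]
                    t = np.dot(x - real[i], seg) / np.dot(seg, seg)
                    if -1e-9 <= t <= 1 + 1e-9:
                        best = min(best, np.linalg.norm(real[i] + t * seg - x))
            assert best <= 1e-9

    def test_synthetic_rows_inside_class_bounding_box(self, rng):
        fm = self._fm(rng)
        out = smote_oversample(fm, {1: 120}, rng=rng)
        real = fm.scores[fm.labels == 1]
        synth = out.scores[out.synthetic]
        assert np.all(synth >= real.min(axis=0) - 1e-9)
        assert np.all(synth <= real.max(axis=0) + 1e-9)

    def test_target_below_count_rejected(self, rng):
        with pytest.raises(ValueError, match="down-sample"):
            smote_oversample(self._fm(rng), {1: 10}, rng=rng)

    def test_seeded_determinism(self, rng):
        fm = self._fm(rng)
        a = smote_oversample(fm, {1: 90}, rng=42)
        b = smote_oversample(fm, {1: 90}, rng=42)
        np.testing.assert_array_equal(a.scores, b.scores)


class TestDownsample:
    def test_uniform_without_replacement(self, rng):
        fm = FeatureMatrix(rng.normal(size=(100, 3)),
                           np.repeat([0, 1], 50))
        out = downsample_class(fm, 0, 20, rng=0)
        assert out.class_counts == {0: 20, 1: 50}
        a = downsample_class(fm, 0, 20, rng=0)
        np.testing.assert_array_equal(a.scores, out.scores)

    def test_target_above_count_rejected(self, rng):
        fm = FeatureMatrix(rng.normal(size=(10, 2)), np.zeros(10, int))
        with pytest.raises(ValueError):
            downsample_class(fm, 0, 20, rng=0)


class TestTsne:
    def test_embedding_shape_and_determinism(self, rng):
        fm = FeatureMatrix(rng.normal(size=(80, 5)), np.zeros(80, int))
        emb1 = tsne_embed(fm, perplexity=10, rng=0)
        emb2 = tsne_embed(fm, perplexity=10, rng=0)
        assert emb1.shape == (80, 2)
        np.testing.assert_array_equal(emb1, emb2)

    @pytest.mark.parametrize("seed", range(5))
    def test_separated_clusters_positive_silhouette(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.vstack([
            rng.normal(0, 0.5, size=(60, 5)),
            rng.normal(10, 0.5, size=(60, 5)),
        ])
        labels = np.repeat([0, 1], 60)
        emb = tsne_embed(FeatureMatrix(scores, labels), perplexity=15, rng=seed)
        assert silhouette_score(emb, labels) > 0

    def test_too_small_for_perplexity_rejected(self, rng):
        fm = FeatureMatrix(rng.normal(size=(20, 3)), np.zeros(20, int))
        with pytest.raises(ValueError):
            tsne_embed(fm, perplexity=10)

    def test_degenerate_duplicates_rejected(self):
        fm = FeatureMatrix(np.ones((200, 3)), np.zeros(200, int))
        with pytest.raises(ValueError):
            tsne_embed(fm, perplexity=5)
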