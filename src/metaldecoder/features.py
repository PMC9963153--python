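"""Dimensionality reduction and class balancing for preprocessed spectra.

PCA compresses each spectrum to 22 scores (the representation every model in
this package consumes); t-SNE gives a diagnostic 2-D view; SMOTE synthesises
minority-class rows by interpolating toward same-class nearest neighbours so
the heavily over-represented control class can be balanced against without
discarding data.  SMOTE must only ever be applied to training partitions —
synthetic rows carry a provenance flag so leakage is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .core_io import Spectrum, SpectralDataset

__all__ = [
    "PcaBasis",
    "FeatureMatrix",
    "fit_pca",
    "project",
    "smote_oversample",
    "downsample_class",
    "tsne_embed",
]

N_COMPONENTS_DEFAULT = 22


@dataclass
class PcaBasis:
    """Fitted principal-component basis for a fixed wavenumber grid."""

    grid: np.ndarray
    mean_spectrum: np.ndarray
    components: np.ndarray  # (n_components, n_points), rows orthonormal
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


@dataclass
class FeatureMatrix:
    """PCA-score rows with class labels and SMOTE provenance flags."""

    scores: np.ndarray  # (n, n_components)
    labels: np.ndarray  # (n,) int class indices
    basis: PcaBasis | None = None
    synthetic: np.ndarray | None = None  # (n,) bool, True for SMOTE rows
    concentrations: np.ndarray | None = None  # (n,) mol/L, optional

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape[0] != self.labels.shape[0]:
            raise ValueError("scores and labels must have the same number of rows")
        if self.synthetic is None:
            self.synthetic = np.zeros(len(self.labels), dtype=bool)
        else:
            self.synthetic = np.asarray(self.synthetic, dtype=bool)

    def __len__(self) -> int:
        return self.scores.shape[0]

    @property
    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.scores[idx],
            self.labels[idx],
            basis=self.basis,
            synthetic=self.synthetic[idx],
            concentrations=None
            if self.concentrations is None
            else self.concentrations[idx],
        )


def fit_pca(ds: SpectralDataset, n_components: int = N_COMPONENTS_DEFAULT) -> PcaBasis:
    """Fit a mean-centred PCA basis on a dataset.

    Components are ordered by descending explained variance, with the sign
    convention that each loading vector's largest-magnitude entry is
    positive (removes the inherent sign ambiguity so bases are comparable
    across runs).
    """
    X = ds.intensity_matrix()
    if X.shape[0] <= n_components:
        raise ValueError(
            f"need more than {n_components} spectra to fit {n_components} components"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    components = pca.components_.copy()
    for row in components:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PcaBasis(
        grid=ds.grid.copy(),
        mean_spectrum=pca.mean_,
        components=components,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def project(data: SpectralDataset | Spectrum, basis: PcaBasis) -> FeatureMatrix:
    """Project spectra onto a fitted basis: ``scores = (x - mean) @ W^T``."""
    if isinstance(data, Spectrum):
        ds = SpectralDataset([data])
    else:
        ds = data
    if len(ds) and (
        ds.grid.shape != basis.grid.shape or not np.allclose(ds.grid, basis.grid)
    ):
        raise ValueError("dataset grid does not match the PCA basis grid")
    X = ds.intensity_matrix()
    scores = (X - basis.mean_spectrum) @ basis.components.T
    return FeatureMatrix(
        scores,
        ds.labels(),
        basis=basis,
        concentrations=ds.concentrations(),
    )


def reconstruct(fm: FeatureMatrix, n_components: int | None = None) -> np.ndarray:
    """Back-project scores to spectrum space using the leading components."""
    if fm.basis is None:
        raise ValueError("feature matrix has no basis attached")
    k = fm.basis.n_components if n_components is None else n_components
    return fm.scores[:, :k] @ fm.basis.components[:k] + fm.basis.mean_spectrum


def smote_oversample(
    fm: FeatureMatrix,
    target_count_per_class: Mapping[int, int],
    k: int = 5,
    rng: np.random.Generator | int | None = None,
) -> FeatureMatrix:
    """Oversample minority classes to the requested counts.

    Each synthetic row is ``x + u * (x_nn - x)`` with ``u ~ Uniform(0, 1)``
    and ``x_nn`` one of the ``k`` same-class Euclidean nearest neighbours of
    a randomly drawn parent row, so synthetic points lie on segments between
    real class members (and hence inside the class's convex hull).
    Synthetic rows are flagged in ``.synthetic``.  Targets below the current
    count are an error — this operation never discards rows.
    """
    rng = np.random.default_rng(rng)
    counts = fm.class_counts
    new_scores, new_labels = [fm.scores], [fm.labels]
    new_flags = [fm.synthetic]
    for cls, target in sorted(target_count_per_class.items()):
        have = counts.get(cls, 0)
        if target < have:
            raise ValueError(
                f"class {cls}: target {target} below current count {have} "
                "(SMOTE does not down-sample)"
            )
        n_new = target - have
        if n_new == 0:
            continue
        if have < 2:
            raise ValueError(f"class {cls}: need >= 2 samples to interpolate")
        X = fm.scores[fm.labels == cls]
        k_eff = min(k, have - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X)
        _, neigh = nn.kneighbors(X)  # column 0 is the point itself
        parents = rng.integers(0, have, size=n_new)
        picks = rng.integers(1, k_eff + 1, size=n_new)
        u = rng.uniform(0.0, 1.0, size=n_new)
        x = X[parents]
        x_nn = X[neigh[parents, picks]]
        new_scores.append(x + u[:, None] * (x_nn - x))
        new_labels.append(np.full(n_new, cls, dtype=int))
        new_flags.append(np.ones(n_new, dtype=bool))
    conc = None
    if fm.concentrations is not None:
        # synthetic rows inherit their class's concentration
        cls_conc = {
            c: fm.concentrations[fm.labels == c][0] for c in counts
        }
        conc = np.concatenate(
            [fm.concentrations]
            + [np.full(len(l), cls_conc[l[0]]) for l in new_labels[1:]]
        )
    return FeatureMatrix(
        np.concatenate(new_scores),
        np.concatenate(new_labels),
        basis=fm.basis,
        synthetic=np.concatenate(new_flags),
        concentrations=conc,
    )


def downsample_class(
    fm: FeatureMatrix,
    cls: int,
    target: int,
    rng: np.random.Generator | int | None = None,
) -> FeatureMatrix:
    """Uniformly down-sample one class without replacement (seeded)."""
    rng = np.random.default_rng(rng)
    idx_cls = np.flatnonzero(fm.labels == cls)
    if target > idx_cls.size:
        raise ValueError(f"target {target} exceeds class size {idx_cls.size}")
    keep_cls = rng.choice(idx_cls, size=target, replace=False)
    keep = np.sort(np.concatenate([np.flatnonzero(fm.labels != cls), keep_cls]))
    return fm.subset(keep)


def tsne_embed(
    fm: FeatureMatrix,
    perplexity: float = 30.0,
    rng: int | None = 0,
) -> np.ndarray:
    """Diagnostic 2-D t-SNE embedding of the score rows (seeded)."""
    n = len(fm)
    if n <= 3 * perplexity:
        raise ValueError(f"need n > 3*perplexity (= {3 * perplexity}), got {n}")
    if np.allclose(fm.scores, fm.scores[0]):
        raise ValueError("degenerate input: all score rows identical")
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=rng,
        init="pca",
    )
    return tsne.fit_transform(fm.scores)
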