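"""PCA and discriminant analysis of principal components (DAPC).

PCA reduces the processed spectra (hundreds of correlated intensity
channels) to a small number of orthogonal components; DAPC then runs a
linear discriminant analysis on the retained PC scores, producing
canonical axes that maximise between-class over within-class scatter.
Classification assigns a spectrum to the nearest class centroid in
canonical space.  Contribution tables map model axes back onto the Raman
shift grid to show which bands drive the separation.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .bands import assign_band
from .spectra_io import Spectrum, SpectrumSet

__all__ = ["PCAModel", "DAPCModel", "fit_pca", "fit_dapc", "predict", "contributions"]


def _orient_rows(M: np.ndarray) -> np.ndarray:
    """Flip each row so its largest-magnitude element is positive.

    Fixes the arbitrary sign of eigenvectors so outputs are reproducible
    across linear-algebra backends.
    """
    M = M.copy()
    for i, row in enumerate(M):
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            M[i] = -row
    return M


@dataclasses.dataclass
class PCAModel:
    """Mean-centred PCA of a spectrum matrix.

    ``loadings`` is (n_components, n_points) with orthonormal rows;
    ``scores`` is (n_spectra, n_components); score column *i* holds the
    per-spectrum value of PC *i* used by the principal-component distance.
    """

    loadings: np.ndarray
    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    mean_spectrum: np.ndarray
    grid: np.ndarray
    sample_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def transform(self, intensities: np.ndarray) -> np.ndarray:
        """Project one spectrum (or a matrix of them) into PC space."""
        X = np.atleast_2d(np.asarray(intensities, dtype=float))
        if X.shape[1] != self.mean_spectrum.size:
            raise ValueError("spectrum length does not match the model grid")
        scores = (X - self.mean_spectrum) @ self.loadings.T
        return scores[0] if np.asarray(intensities).ndim == 1 else scores


def fit_pca(sset: SpectrumSet) -> PCAModel:
    """Fit mean-centred PCA by singular value decomposition.

    Retains ``min(n_spectra - 1, n_points)`` components, which captures
    the full rank of the centred matrix; explained-variance ratios are
    singular values squared over the total variance.
    """
    grid, X, ids = sset.to_matrix()
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 spectra")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in spectra")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(X.shape[0] - 1, X.shape[1])
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # apply the deterministic sign convention to loadings, compensate scores
    flip = np.array([-1.0 if row[np.argmax(np.abs(row))] < 0 else 1.0 for row in Vt])
    Vt = Vt * flip[:, None]
    scores = U * s * flip[None, :]
    total_var = np.sum(Xc**2)
    evr = (s**2) / total_var if total_var > 0 else np.zeros_like(s)
    return PCAModel(
        loadings=Vt,
        scores=scores,
        explained_variance_ratio=evr,
        mean_spectrum=mean,
        grid=grid,
        sample_ids=list(ids),
    )


@dataclasses.dataclass
class DAPCModel:
    """Linear discriminant analysis on retained PC scores.

    ``canonical_axes`` is (n_axes, n_pcs); axes are scaled so the pooled
    within-class covariance of the canonical scores is the identity.
    ``canonical_scores`` column *i* holds the canonical value of axis *i*
    used by the canonical distance.
    """

    n_pcs: int
    canonical_axes: np.ndarray
    canonical_scores: np.ndarray
    group_centroids: np.ndarray
    class_labels: list
    labels: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.canonical_axes.shape[0]

    def transform(self, pc_scores: np.ndarray) -> np.ndarray:
        """Map PC scores (first ``n_pcs`` used) to canonical coordinates."""
        S = np.atleast_2d(np.asarray(pc_scores, dtype=float))
        if S.shape[1] < self.n_pcs:
            raise ValueError(f"need at least {self.n_pcs} PC scores")
        out = S[:, : self.n_pcs] @ self.canonical_axes.T
        return out[0] if np.asarray(pc_scores).ndim == 1 else out


def fit_dapc(pca: PCAModel, labels: Sequence, n_pcs: int) -> DAPCModel:
    """Fit DAPC: LDA on the top ``n_pcs`` PC scores.

    Solves the generalised eigenproblem ``S_b v = λ S_w v`` for the
    between- and pooled within-class scatter of the retained scores; the
    within-class scatter receives a small ridge (1e-8 x trace/dim) when
    singular.  At most ``min(n_pcs, n_classes - 1)`` canonical axes are
    returned, ordered by decreasing discriminating power.
    """
    labels = np.asarray(labels)
    if labels.size != pca.scores.shape[0]:
        raise ValueError("one label per spectrum required")
    if n_pcs < 1 or n_pcs > pca.n_components:
        raise ValueError(f"n_pcs must be in [1, {pca.n_components}]")
    classes = sorted(pd.unique(labels).tolist())
    if len(classes) < 2:
        raise ValueError("DAPC needs at least 2 classes")
    S = pca.scores[:, :n_pcs]
    n, d = S.shape
    overall = S.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for c in classes:
        idx = labels == c
        if idx.sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 members")
        Sc = S[idx]
        mu = Sc.mean(axis=0)
        dev = Sc - mu
        Sw += dev.T @ dev
        Sb += idx.sum() * np.outer(mu - overall, mu - overall)
    # ridge-regularise a singular within-class scatter
    eigvals_w = np.linalg.eigvalsh(Sw)
    if eigvals_w[0] <= 1e-10 * max(np.trace(Sw), 1.0) / d:
        Sw = Sw + (1e-8 * np.trace(Sw) / d + 1e-12) * np.eye(d)
    evals, evecs = scipy.linalg.eigh(Sb, Sw)
    order = np.argsort(evals)[::-1]
    n_axes = min(n_pcs, len(classes) - 1)
    axes = evecs[:, order[:n_axes]].T
    # scale so the pooled within-class variance along each axis is 1
    n_within = n - len(classes)
    if n_within > 0:
        w_var = np.einsum("ij,jk,ik->i", axes, Sw / n_within, axes)
        axes = axes / np.sqrt(np.maximum(w_var, 1e-300))[:, None]
    axes = _orient_rows(axes)
    canon = S @ axes.T
    centroids = np.vstack([canon[labels == c].mean(axis=0) for c in classes])
    return DAPCModel(
        n_pcs=n_pcs,
        canonical_axes=axes,
        canonical_scores=canon,
        group_centroids=centroids,
        class_labels=classes,
        labels=labels,
    )


def predict(dapc: DAPCModel, pca: PCAModel, s: Spectrum):
    """Classify a spectrum as the nearest group centroid in canonical space.

    The spectrum must be on the model grid and processed identically to
    the training spectra.  Exact ties go to the first label in
    ``class_labels`` order.
    """
    if s.shifts.size != pca.grid.size or not np.array_equal(s.shifts, pca.grid):
        raise ValueError("spectrum grid does not match the model grid")
    canon = dapc.transform(pca.transform(s.intensities))
    d = np.linalg.norm(dapc.group_centroids - canon, axis=1)
    # distances within a hair of the minimum count as a tie
    tied = np.flatnonzero(d <= d.min() + 1e-9 * (1.0 + d.min()))
    return dapc.class_labels[int(tied[0])]


def contributions(
    model: PCAModel | DAPCModel,
    top_k: int,
    *,
    component: int = 1,
    pca: PCAModel | None = None,
    annotate: bool = True,
) -> pd.DataFrame:
    """Per-shift contribution weights of one model axis, ranked by |weight|.

    For a PCA model the weights are the loading of PC ``component``; for
    a DAPC model, canonical axis ``component`` is back-projected through
    the PC loadings onto the shift grid (pass the ``pca`` the DAPC was
    built on).  Returns a table with columns shift, weight, rank and an
    optional band assignment.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if isinstance(model, PCAModel):
        if not 1 <= component <= model.n_components:
            raise ValueError(f"component must be in [1, {model.n_components}]")
        weights = model.loadings[component - 1]
        grid = model.grid
    elif isinstance(model, DAPCModel):
        if pca is None:
            raise ValueError("back-projecting DAPC contributions requires the parent PCA model")
        if not 1 <= component <= model.n_axes:
            raise ValueError(f"component must be in [1, {model.n_axes}]")
        weights = model.canonical_axes[component - 1] @ pca.loadings[: model.n_pcs]
        grid = pca.grid
    else:
        raise TypeError("model must be a PCAModel or DAPCModel")
    order = np.argsort(-np.abs(weights), kind="stable")[: min(top_k, weights.size)]
    rows = []
    for rank, i in enumerate(order, start=1):
        rows.append(
            {
                "shift": float(grid[i]),
                "weight": float(weights[i]),
                "rank": rank,
                "assignment": assign_band(grid[i]) if annotate else None,
            }
        )
    return pd.DataFrame(rows)
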