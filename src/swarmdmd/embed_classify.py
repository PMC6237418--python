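"""Embedding and outcome prediction from spectral-kernel matrices.

Classical multidimensional scaling places segments in a low-dimensional
space that preserves the kernel-induced distances; a Gaussian naive Bayes
classifier on kernel-similarity features predicts the binary segment
outcome, scored by the median error over stratified 5-fold
cross-validation, as is standard for small labelled collections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB

logger = logging.getLogger(__name__)

__all__ = ["EmbeddingResult", "ClassificationReport", "classical_mds", "nb_predict_cv"]


@dataclass
class EmbeddingResult:
    """MDS coordinates (centred), eigenvalue spectrum and stress."""

    coordinates: np.ndarray  # (m, dims)
    eigenvalues: np.ndarray  # full spectrum of the double-centred matrix
    stress: float  # rms distance distortion, relative


@dataclass
class ClassificationReport:
    """Cross-validated prediction summary."""

    fold_errors: np.ndarray
    median_error: float
    posteriors: np.ndarray  # (m,) posterior probability of class 1
    predictions: np.ndarray  # (m,)
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def confusion(self) -> tuple[int, int, int, int]:
        return self.tp, self.tn, self.fp, self.fn


def classical_mds(D: np.ndarray, dims: int = 2) -> EmbeddingResult:
    """Classical (Torgerson) multidimensional scaling.

    Double-centres ``-D**2 / 2`` and takes the top ``dims`` components with
    nonnegative eigenvalues; exact Euclidean distance matrices are
    reproduced up to rotation/reflection.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("D must be symmetric")
    m = D.shape[0]
    J = np.eye(m) - np.full((m, m), 1.0 / m)
    Bmat = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(Bmat)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    top = np.clip(evals[:dims], 0.0, None)
    coords = evecs[:, :dims] * np.sqrt(top)[None, :]
    emb = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    denom = np.linalg.norm(D)
    stress = float(np.linalg.norm(emb - D) / denom) if denom > 0 else 0.0
    return EmbeddingResult(coordinates=coords, eigenvalues=evals, stress=stress)


def nb_predict_cv(
    K: np.ndarray,
    labels: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    feature: str = "kernel",
    D: Optional[np.ndarray] = None,
) -> ClassificationReport:
    """Gaussian naive Bayes on kernel rows, stratified k-fold CV.

    The feature vector of a segment is its row of similarities to the
    training-fold segments (``feature="kernel"``) or of distances
    (``feature="distance"``, requires ``D``).  Class priors come from the
    training folds; the summary error is the median of the per-fold error
    rates, and the confusion counts are pooled over all folds.
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(labels, dtype=int)
    m = y.size
    if K.shape != (m, m):
        raise ValueError("K must be m x m matching labels")
    if m < folds:
        raise ValueError("need at least as many segments as folds")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need both outcome labels present")
    counts = np.bincount(y)
    if counts[counts > 0].min() < folds:
        raise ValueError("too few members of the rarer class for stratified folding")
    if feature == "distance":
        if D is None:
            raise ValueError("feature='distance' requires D")
        F = np.asarray(D, dtype=float)
    elif feature == "kernel":
        F = K
    else:
        raise ValueError("feature must be 'kernel' or 'distance'")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_errors = []
    posteriors = np.full(m, np.nan)
    predictions = np.full(m, -1)
    for train, test in skf.split(np.zeros(m), y):
        X_train = F[np.ix_(train, train)]
        X_test = F[np.ix_(test, train)]
        clf = GaussianNB(var_smoothing=1e-9)
        clf.fit(X_train, y[train])
        proba = clf.predict_proba(X_test)
        pred = clf.classes_[np.argmax(proba, axis=1)]
        fold_errors.append(float(np.mean(pred != y[test])))
        col1 = int(np.nonzero(clf.classes_ == 1)[0][0]) if 1 in clf.classes_ else None
        posteriors[test] = proba[:, col1] if col1 is not None else 0.0
        predictions[test] = pred
    fold_errors = np.asarray(fold_errors)
    tp = int(np.sum((predictions == 1) & (y == 1)))
    tn = int(np.sum((predictions == 0) & (y == 0)))
    fp = int(np.sum((predictions == 1) & (y == 0)))
    fn = int(np.sum((predictions == 0) & (y == 1)))
    return ClassificationReport(
        fold_errors=fold_errors,
        median_error=float(np.median(fold_errors)),
        posteriors=posteriors,
        predictions=predictions,
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
    )


def outcome_density(
    embedding: EmbeddingResult, labels: np.ndarray, grid_size: int = 50
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Success/failure density surfaces on the 2-D embedding (presentation).

    Kernel density estimates (Scott's rule) per outcome class over a common
    grid; returns (x_grid, y_grid, density_success, density_failure).
    """
    X = embedding.coordinates[:, :2]
    y = np.asarray(labels, dtype=int)
    pad = 0.1 * (X.max(axis=0) - X.min(axis=0) + 1e-12)
    lo, hi = X.min(axis=0) - pad, X.max(axis=0) + pad
    gx = np.linspace(lo[0], hi[0], grid_size)
    gy = np.linspace(lo[1], hi[1], grid_size)
    mesh = np.stack(np.meshgrid(gx, gy), axis=0).reshape(2, -1)
    out = []
    for cls in (1, 0):
        pts = X[y == cls].T
        if pts.shape[1] < 3:
            out.append(np.zeros(mesh.shape[1]).reshape(grid_size, grid_size))
            continue
        kde = gaussian_kde(pts)  # Scott's rule by default
        out.append(kde(mesh).reshape(grid_size, grid_size))
    return gx, gy, out[0], out[1]
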