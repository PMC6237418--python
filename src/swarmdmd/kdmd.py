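"""Dynamic mode decomposition with reproducing kernels.

Lifts the snapshots into the RKHS of a positive-definite kernel, performs
kernel PCA on the centred Gram matrix, and eigendecomposes the projection
of the Koopman operator onto the leading principal directions.  Everything
is expressed through Gram matrices, so the (possibly infinite-dimensional)
feature vectors never have to be materialised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .dmd import dmd_frequencies
from .features import SnapshotSequence

logger = logging.getLogger(__name__)

__all__ = [
    "KernelSpec",
    "KernelDMDResult",
    "median_bandwidth",
    "gram_matrices",
    "fit_kdmd",
]

_EIG_DROP = 1e-12  # relative threshold below which eigenpairs are dropped


@dataclass(frozen=True)
class KernelSpec:
    """A positive-definite kernel: gaussian, linear or polynomial.

    The gaussian kernel is ``exp(-||y - y'||^2 / (2 sigma^2))`` with
    ``sigma`` ("bandwidth") conventionally set to the median pairwise
    snapshot distance.  The polynomial kernel is ``(<y, y'> + offset)^degree``.
    """

    kind: str = "gaussian"
    bandwidth: Optional[float] = None
    degree: int = 2
    offset: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "linear", "polynomial"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.kind == "polynomial" and self.degree < 1:
            raise ValueError("polynomial degree must be >= 1")

    def with_bandwidth(self, sigma: float) -> "KernelSpec":
        return KernelSpec(self.kind, sigma, self.degree, self.offset)

    def __call__(self, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
        """Kernel matrix between snapshot columns of X (p x n) and Z (p x m)."""
        if self.kind == "linear":
            return X.T @ Z
        if self.kind == "polynomial":
            return (X.T @ Z + self.offset) ** self.degree
        if self.bandwidth is None:
            raise ValueError("gaussian kernel requires a bandwidth; see median_bandwidth")
        sq = cdist(X.T, Z.T, metric="sqeuclidean")
        return np.exp(-sq / (2.0 * self.bandwidth**2))


def median_bandwidth(seq: SnapshotSequence | np.ndarray) -> float:
    """Median pairwise Euclidean distance between distinct snapshots."""
    values = seq.values if isinstance(seq, SnapshotSequence) else np.asarray(seq)
    d = pdist(values.T)
    d = d[d > 0]
    if d.size == 0:
        raise ValueError("all snapshots identical: bandwidth would be zero")
    return float(np.median(d))


def _centering(n: int) -> np.ndarray:
    return np.eye(n) - np.full((n, n), 1.0 / n)


def gram_matrices(
    seq: SnapshotSequence, kernel: KernelSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(G_yy, G_yy', centred G_yy, centred G_yy') for a snapshot sequence.

    ``G_yy[i, j] = k(y_i, y_j)`` over the first tau-1 snapshots and
    ``G_yy'[i, j] = k(y_i, y_{j+1})``; both are centred as ``H G H`` with
    the (tau-1)-sized centring matrix ``H = I - 1/n``.
    """
    if seq.tau < 3:
        raise ValueError("need at least 3 snapshots")
    Y = seq.values[:, :-1]
    Yp = seq.values[:, 1:]
    kern = _resolve_bandwidth(kernel, seq)
    G_yy = kern(Y, Y)
    G_yyp = kern(Y, Yp)
    if not (np.all(np.isfinite(G_yy)) and np.all(np.isfinite(G_yyp))):
        raise ValueError("non-finite kernel values")
    H = _centering(G_yy.shape[0])
    return G_yy, G_yyp, H @ G_yy @ H, H @ G_yyp @ H


def _resolve_bandwidth(kernel: KernelSpec, seq: SnapshotSequence) -> KernelSpec:
    if kernel.kind == "gaussian" and kernel.bandwidth is None:
        return kernel.with_bandwidth(median_bandwidth(seq))
    return kernel


@dataclass
class KernelDMDResult:
    """Spectral decomposition of the kernel-projected Koopman operator.

    ``B`` (n x r) and ``S`` (r,) are the retained kernel-PCA eigenvectors and
    (positive) eigenvalues of the centred Gram matrix; ``F_hat`` is the r x r
    projected operator; ``eigenvalues`` its spectrum; ``eigenvectors`` the
    matrix of (unit-norm, phase-fixed) right eigenvectors.  The implicit
    feature-space mode j is ``U b_j`` with ``U = M1 H B S^{-1/2}`` and
    ``b_j`` the j-th eigenvector column.
    """

    kernel: KernelSpec
    G_yy: np.ndarray
    G_yyp: np.ndarray
    G_yy_centered: np.ndarray
    G_yyp_centered: np.ndarray
    B: np.ndarray
    S: np.ndarray
    F_hat: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    rank: int
    dt: float
    snapshots: np.ndarray  # retained reference to the source data (p x tau)

    @property
    def frequencies(self) -> np.ndarray:
        f, _ = dmd_frequencies(self.eigenvalues, self.dt)
        return f

    @property
    def growth_rates(self) -> np.ndarray:
        _, g = dmd_frequencies(self.eigenvalues, self.dt)
        return g


def _fix_phase(V: np.ndarray) -> np.ndarray:
    """Unit-normalise columns and rotate the first significant entry to be
    real-positive, making eigenvector scaling reproducible."""
    V = V / np.linalg.norm(V, axis=0, keepdims=True)
    out = V.copy()
    for j in range(V.shape[1]):
        col = V[:, j]
        idx = int(np.argmax(np.abs(col)))
        phase = col[idx] / abs(col[idx]) if col[idx] != 0 else 1.0
        out[:, j] = col / phase
    return out


def fit_kdmd(
    seq: SnapshotSequence,
    kernel: KernelSpec = KernelSpec(),
    rank: Optional[int] = None,
) -> KernelDMDResult:
    """Kernel-PCA-projected Koopman spectral decomposition.

    The centred Gram matrix is eigendecomposed with the symmetric solver;
    components with eigenvalue <= 1e-12 of the largest are dropped, and
    ``rank`` (if given) keeps at most that many leading components.  The
    projected operator ``F_hat = S^{-1/2} B* (H G_yy' H) B S^{-1/2}`` is then
    eigendecomposed; eigenvalues with magnitude <= 1e-12 of the largest are
    discarded as numerically fully decayed.
    """
    kernel = _resolve_bandwidth(kernel, seq)
    G_yy, G_yyp, Gc, Gpc = gram_matrices(seq, kernel)
    evals, evecs = np.linalg.eigh(Gc)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > _EIG_DROP * max(evals[0], 0.0)
    n_keep = int(keep.sum())
    if n_keep == 0:
        raise ValueError("centred Gram matrix is numerically zero")
    if rank is not None:
        if rank > n_keep:
            logger.warning("rank %d exceeds numerical rank %d; truncating", rank, n_keep)
        n_keep = min(rank, n_keep)
    B = evecs[:, :n_keep]
    S = evals[:n_keep]
    S_isqrt = 1.0 / np.sqrt(S)
    F_hat = (S_isqrt[:, None] * (B.T @ Gpc @ B)) * S_isqrt[None, :]
    lam, V = np.linalg.eig(F_hat)
    mags = np.abs(lam)
    keep_l = mags > _EIG_DROP * max(mags.max(), 1e-300)
    if not keep_l.all():
        logger.info("dropping %d numerically zero eigenvalue(s)", (~keep_l).sum())
    lam, V = lam[keep_l], V[:, keep_l]
    order = np.argsort(-np.abs(lam))
    lam, V = lam[order], V[:, order]
    V = _fix_phase(V)
    return KernelDMDResult(
        kernel=kernel,
        G_yy=G_yy,
        G_yyp=G_yyp,
        G_yy_centered=Gc,
        G_yyp_centered=Gpc,
        B=B,
        S=S,
        F_hat=F_hat,
        eigenvalues=lam,
        eigenvectors=V,
        rank=int(lam.size),
        dt=seq.dt,
        snapshots=seq.values,
    )


def one_step_prediction_error(result: KernelDMDResult) -> float:
    """Mean relative one-step spectral prediction error in feature space.

    The centred feature vector of each snapshot is expanded in the retained
    principal directions; the Koopman matrix advances the expansion one step
    and the result is compared with the expansion of the true next snapshot.
    Serves as a data-space-free consistency check of the fitted operator.
    """
    S_isqrt = 1.0 / np.sqrt(result.S)
    # coordinates of centred snapshots in the principal basis: S^{-1/2} B* Gc
    C = (S_isqrt[:, None] * (result.B.T @ result.G_yy_centered))
    C_next = (S_isqrt[:, None] * (result.B.T @ result.G_yyp_centered))
    pred = result.F_hat @ C
    num = np.linalg.norm(pred - C_next)
    den = max(np.linalg.norm(C_next), 1e-30)
    return float(num / den)
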