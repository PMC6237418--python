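"""Koopman spectral kernels between fitted dynamical systems.

Two kernel-DMD fits each span a subspace of the RKHS with their Koopman
modes.  The cosines of the principal angles between those subspaces arise
as generalized eigenvalues of a block problem built from the mode Gram
matrices, and define a similarity kernel (Binet-Cauchy style) between the
dynamical systems; the induced squared distance
``d(i, j) = k(i, i) + k(j, j) - 2 k(i, j)`` feeds embedding and
classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from .features import SegmentSet, SnapshotSequence
from .kdmd import KernelDMDResult, KernelSpec, fit_kdmd, median_bandwidth

logger = logging.getLogger(__name__)

__all__ = [
    "PrincipalAngleSpectrum",
    "KernelMatrix",
    "subspace_products",
    "principal_angle_kernel",
    "kernel_and_distance_matrix",
]


@dataclass
class PrincipalAngleSpectrum:
    """Cosines of the principal angles between two mode subspaces,
    descending, clipped to [0, 1]; length min(r_i, r_j)."""

    values: np.ndarray


@dataclass
class KernelMatrix:
    """Pairwise spectral kernel and induced distance over a segment set."""

    ids: list[str]
    K: np.ndarray
    D: np.ndarray
    labels: Optional[np.ndarray] = None


def _mode_basis(result: KernelDMDResult) -> np.ndarray:
    """Coefficients of the Koopman modes in the principal-direction basis.

    Mode j in feature space is ``U v_j``; since the principal directions U
    are orthonormal, all feature-space inner products between modes reduce
    to products of these coefficient matrices.
    """
    return result.eigenvectors


def _check_same_kernel(a: KernelSpec, b: KernelSpec) -> None:
    if a != b:
        raise ValueError(f"segments fitted with different kernels: {a} vs {b}")


def subspace_products(
    kdmd_i: KernelDMDResult, kdmd_j: KernelDMDResult
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gram blocks (A*A, B*B, A*B) of the two mode subspaces in the RKHS.

    The diagonal blocks are the mode Gram matrices of each system (order
    r_i and r_j).  The cross block routes through the centred Gram of the
    two snapshot series connected head to tail: the kernel matrix of the
    concatenation is centred with the full-length centring matrix and its
    upper-right n_i x n_j block replaces the within-segment Gram in the
    mode inner products.
    """
    _check_same_kernel(kdmd_i.kernel, kdmd_j.kernel)
    Vi, Vj = _mode_basis(kdmd_i), _mode_basis(kdmd_j)

    def _self_product(res: KernelDMDResult, V: np.ndarray) -> np.ndarray:
        S_isqrt = 1.0 / np.sqrt(res.S)
        M = (S_isqrt[:, None] * (res.B.T @ res.G_yy_centered @ res.B)) * S_isqrt[None, :]
        return V.conj().T @ M @ V

    AA = _self_product(kdmd_i, Vi)
    BB = _self_product(kdmd_j, Vj)

    Yi = kdmd_i.snapshots[:, :-1]
    Yj = kdmd_j.snapshots[:, :-1]
    ni, nj = Yi.shape[1], Yj.shape[1]
    joint = np.concatenate([Yi, Yj], axis=1)
    G_joint = kdmd_i.kernel(joint, joint)
    n = ni + nj
    H = np.eye(n) - np.full((n, n), 1.0 / n)
    G_centered = H @ G_joint @ H
    G_ij = G_centered[:ni, ni:]
    Si_isqrt = 1.0 / np.sqrt(kdmd_i.S)
    Sj_isqrt = 1.0 / np.sqrt(kdmd_j.S)
    cross = (Si_isqrt[:, None] * (kdmd_i.B.T @ G_ij @ kdmd_j.B)) * Sj_isqrt[None, :]
    AB = Vi.conj().T @ cross @ Vj
    return AA, BB, AB


def principal_angle_spectrum(
    AA: np.ndarray, BB: np.ndarray, AB: np.ndarray
) -> PrincipalAngleSpectrum:
    """Solve the block generalized eigenproblem for principal-angle cosines.

    The eigenvalues of ``[[0, AB], [AB*, 0]] v = lam [[AA, 0], [0, BB]] v``
    come in +/- pairs (plus zeros when the ranks differ); the magnitudes of
    the top min(r_i, r_j) pairs are the cosines.  An indefinite right-hand
    block is regularized by ``+ eps I`` with ``eps = 1e-10 trace``.
    """
    ri, rj = AA.shape[0], BB.shape[0]
    lhs = np.block(
        [
            [np.zeros((ri, ri), dtype=complex), AB],
            [AB.conj().T, np.zeros((rj, rj), dtype=complex)],
        ]
    )
    rhs = np.block(
        [
            [AA, np.zeros((ri, rj), dtype=complex)],
            [np.zeros((rj, ri), dtype=complex), BB],
        ]
    )
    lhs = 0.5 * (lhs + lhs.conj().T)
    rhs = 0.5 * (rhs + rhs.conj().T)
    eps = 1e-10 * max(np.trace(rhs).real, 1e-300)
    try:
        w = scipy.linalg.eigh(lhs, rhs + eps * np.eye(ri + rj), eigvals_only=True)
    except scipy.linalg.LinAlgError:
        logger.warning("indefinite subspace Gram; increasing regularization")
        eps = 1e-6 * max(np.trace(rhs).real, 1e-300)
        w = scipy.linalg.eigh(lhs, rhs + eps * np.eye(ri + rj), eigvals_only=True)
    mags = np.sort(np.abs(w))[::-1]
    r = min(ri, rj)
    cosines = mags[: 2 * r : 2]  # +/- pairs: take one of each
    return PrincipalAngleSpectrum(values=np.clip(cosines, 0.0, 1.0))


def principal_angle_kernel(
    AA: np.ndarray, BB: np.ndarray, AB: np.ndarray, aggregation: str = "product"
) -> float:
    """Scalar spectral kernel from the principal-angle cosines.

    ``product`` (default) is the Binet-Cauchy determinant form; ``sum``
    averages the cosines instead.
    """
    spec = principal_angle_spectrum(AA, BB, AB)
    if aggregation == "product":
        return float(np.prod(spec.values))
    if aggregation == "sum":
        return float(np.sum(spec.values))
    raise ValueError("aggregation must be 'product' or 'sum'")


def kernel_and_distance_matrix(
    segments: SegmentSet,
    kernel: KernelSpec = KernelSpec(),
    rank: Optional[int] = None,
    aggregation: str = "product",
    min_tau: int = 3,
) -> KernelMatrix:
    """Pairwise Koopman spectral kernels and distances over a segment set.

    Each segment is fitted once (cached).  For the gaussian kernel a single
    shared bandwidth — the median pairwise snapshot distance of the pooled
    (series-connected) segment data — keeps every fit in the same RKHS.
    Segments shorter than ``min_tau`` snapshots are excluded with a warning.
    The squared-distance formula can go infinitesimally negative from
    rounding; negatives are clipped to zero.
    """
    keep = [i for i, s in enumerate(segments.sequences) if s.tau >= min_tau]
    if len(keep) < len(segments.sequences):
        logger.warning("excluding %d too-short segment(s)", len(segments.sequences) - len(keep))
    if len(keep) < 2:
        raise ValueError("need at least 2 usable segments")
    seqs = [segments.sequences[i] for i in keep]
    ids = [segments.ids[i] for i in keep]
    labels = segments.labels[keep]

    if kernel.kind == "gaussian" and kernel.bandwidth is None:
        pooled = np.concatenate([s.values for s in seqs], axis=1)
        kernel = kernel.with_bandwidth(median_bandwidth(pooled))

    fits = [fit_kdmd(s, kernel, rank=rank) for s in seqs]
    m = len(fits)
    K = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            AA, BB, AB = subspace_products(fits[i], fits[j])
            K[i, j] = K[j, i] = principal_angle_kernel(AA, BB, AB, aggregation)
    diag = np.diag(K)
    D = diag[:, None] + diag[None, :] - 2.0 * K
    if (D < -1e-8).any():
        logger.warning("negative squared distances clipped to zero (min %.3g)", D.min())
    D = np.clip(D, 0.0, None)
    np.fill_diagonal(D, 0.0)
    return KernelMatrix(ids=ids, K=K, D=D, labels=labels)
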