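"""Projected (SVD-based) dynamic mode decomposition.

Fits the best linear one-step propagator to a snapshot sequence, projects it
onto the leading POD modes, and decomposes the dynamics into spatial modes
that each evolve as a single complex exponential.  Exact on data generated
by a linear system; on nonlinear data the modes approximate the dominant
Koopman spectral components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .features import SnapshotSequence

logger = logging.getLogger(__name__)

__all__ = [
    "DMDResult",
    "fit_dmd",
    "dmd_frequencies",
    "reconstruct",
    "temporal_spectrum",
    "spatial_mode_power",
]

#: Sentinel growth rate reported for fully decayed (lambda = 0) modes.
DECAYED = -np.inf


@dataclass
class DMDResult:
    """Eigenvalues, modes and coefficients of a fitted decomposition.

    ``eigenvalues`` are the discrete-time propagator eigenvalues lambda_j;
    ``omegas = ln(lambda)/dt`` are the continuous-time exponents whose real
    part is the growth rate (1/s) and imaginary part the angular frequency
    (rad/s); ``frequencies`` are Im(ln lambda)/(2 pi dt) in Hz.
    """

    eigenvalues: np.ndarray  # (r,) complex
    modes: np.ndarray  # (p, r) complex, columns phi_j
    amplitudes: np.ndarray  # (r,) complex psi
    rank: int
    dt: float
    U: np.ndarray
    singular_values: np.ndarray
    V: np.ndarray
    zero_modes: np.ndarray  # boolean flags for lambda = 0 columns

    @property
    def omegas(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.eigenvalues != 0, np.log(self.eigenvalues) / self.dt, DECAYED)

    @property
    def frequencies(self) -> np.ndarray:
        f, _ = dmd_frequencies(self.eigenvalues, self.dt)
        return f

    @property
    def growth_rates(self) -> np.ndarray:
        _, g = dmd_frequencies(self.eigenvalues, self.dt)
        return g


def _numerical_rank(s: np.ndarray, rtol: float = 1e-10) -> int:
    if s.size == 0 or s[0] == 0:
        return 0
    return int(np.sum(s > rtol * s[0]))


def fit_dmd(seq: SnapshotSequence, rank: Optional[int] = None, rank_rtol: float = 1e-10) -> DMDResult:
    """Fit the POD-projected decomposition to a snapshot sequence.

    The snapshot matrix is split into Y (columns 1..tau-1) and Y' (columns
    2..tau); the reduced SVD ``Y = U S V*`` projects the least-squares
    propagator to ``F_hat = U* Y' V S^-1``, whose eigenpairs give the
    eigenvalues and (after lifting by ``Y' V S^-1 W L^-1``) the modes.
    Mode coefficients solve ``Phi psi = y_1``.

    ``rank`` defaults to the numerical rank of the singular spectrum at
    relative threshold ``rank_rtol``.
    """
    if seq.tau < 3:
        raise ValueError("need at least 3 snapshots to fit dynamics")
    Y = seq.values[:, :-1]
    Yp = seq.values[:, 1:]
    U, s, Vh = np.linalg.svd(Y, full_matrices=False)
    nrank = _numerical_rank(s, rank_rtol)
    if rank is None:
        r = nrank
    else:
        if not 1 <= rank <= min(seq.p, seq.tau - 1):
            raise ValueError("rank must satisfy 1 <= r <= min(p, tau - 1)")
        if rank > nrank:
            logger.warning("requested rank %d exceeds numerical rank %d; truncating", rank, nrank)
        r = min(rank, nrank)
    if r == 0:
        raise ValueError("snapshot matrix is numerically zero")
    U, s, Vh = U[:, :r], s[:r], Vh[:r, :]
    V = Vh.conj().T
    B = Yp @ V / s  # Y' V S^-1
    F_hat = U.conj().T @ B
    lam, W = np.linalg.eig(F_hat)
    zero = np.abs(lam) < 1e-14 * max(1.0, np.abs(lam).max())
    if zero.any():
        logger.warning("%d zero eigenvalue(s): mode(s) kept without eigenvalue scaling", zero.sum())
    scale = np.where(zero, 1.0, lam)
    Phi = (B @ W) / scale
    psi, *_ = np.linalg.lstsq(Phi, Y[:, 0].astype(complex), rcond=None)
    return DMDResult(
        eigenvalues=lam,
        modes=Phi,
        amplitudes=psi,
        rank=r,
        dt=seq.dt,
        U=U,
        singular_values=s,
        V=V,
        zero_modes=zero,
    )


def dmd_frequencies(eigenvalues: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Temporal frequency (Hz) and growth rate (1/s) of propagator eigenvalues.

    The principal branch of the complex logarithm separates oscillation from
    growth: ``f = Im(ln lambda) / (2 pi dt)``, ``growth = Re(ln lambda)/dt``.
    Zero eigenvalues are fully decayed and report ``growth = -inf, f = 0``.
    """
    lam = np.asarray(eigenvalues, dtype=complex)
    f = np.zeros(lam.shape)
    growth = np.full(lam.shape, DECAYED)
    nz = lam != 0
    log_lam = np.log(lam[nz])
    f[nz] = log_lam.imag / (2.0 * np.pi * dt)
    growth[nz] = log_lam.real / dt
    return f, growth


def reconstruct(result: DMDResult, t: np.ndarray | float) -> np.ndarray:
    """Evaluate ``y(t) = sum_j phi_j exp(omega_j t) psi_j``.

    ``t`` is seconds measured from the first snapshot; values beyond the
    fitted window extrapolate the fitted exponentials.  Returns (p,) for a
    scalar ``t`` or (p, len(t)) for an array.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    steps = t_arr / result.dt
    lam = result.eigenvalues
    # lambda^(t/dt) on the principal branch, avoiding overflow warnings at 0
    powers = np.zeros((lam.size, t_arr.size), dtype=complex)
    nz = lam != 0
    powers[nz] = np.exp(np.outer(np.log(lam[nz]), steps))
    powers[~nz, :] = np.where(steps[None, :] == 0, 1.0, 0.0)
    out = result.modes @ (powers * result.amplitudes[:, None])
    return out[:, 0] if np.isscalar(t) or np.ndim(t) == 0 else out


def reconstruction_error(result: DMDResult, seq: SnapshotSequence) -> float:
    """Max relative error of the reconstruction over the fitted window."""
    times = result.dt * np.arange(seq.tau - 1)
    recon = reconstruct(result, times)
    ref = seq.values[:, : seq.tau - 1]
    scale = max(np.abs(ref).max(), 1e-30)
    return float(np.abs(recon - ref).max() / scale)


def temporal_spectrum(result: DMDResult, amplitude: str = "psi_mode") -> tuple[np.ndarray, np.ndarray]:
    """Frequency / amplitude pairs of the decomposition, conjugates merged.

    Real input data yields a conjugate-symmetric spectrum, so only modes
    with ``f >= 0`` are reported.  Amplitude is ``|psi_j| * ||phi_j||``
    (``amplitude="psi_mode"``, default) or plain ``|psi_j|``
    (``amplitude="psi"``).
    """
    if amplitude not in ("psi_mode", "psi"):
        raise ValueError("amplitude must be 'psi_mode' or 'psi'")
    f = result.frequencies
    amp = np.abs(result.amplitudes)
    if amplitude == "psi_mode":
        amp = amp * np.linalg.norm(result.modes, axis=0)
    keep = f >= 0
    order = np.argsort(f[keep])
    return f[keep][order], amp[keep][order]


def band_power(result: DMDResult, band: tuple[float, float], amplitude: str = "psi_mode") -> float:
    """Summed spectral amplitude of modes whose frequency lies in ``band`` (Hz)."""
    f, amp = temporal_spectrum(result, amplitude)
    lo, hi = band
    mask = (f >= lo) & (f <= hi)
    return float(amp[mask].sum())


def spatial_mode_power(
    result: DMDResult,
    band: tuple[float, float],
    layout: Optional[tuple[int, int]] = None,
    weight: str = "amplitude",
) -> np.ndarray:
    """Mean spatial power of the modes with frequency in ``band`` (Hz).

    Each mode's elementwise power |phi_j|^2 is scaled by |psi_j|^2 before
    averaging (``weight="amplitude"``, default), so the map measures the
    modes' actual contribution to the signal rather than their arbitrarily
    normalised shapes; ``weight="none"`` averages bare |phi_j|^2.
    ``layout`` reshapes the p-vector map, e.g. (N, N-1) for nearest-sorted
    distance features.  Raises if no mode falls inside the band.
    """
    if weight not in ("amplitude", "none"):
        raise ValueError("weight must be 'amplitude' or 'none'")
    lo, hi = band
    f = result.frequencies
    mask = (np.abs(f) >= lo) & (np.abs(f) <= hi)
    if not mask.any():
        nyquist = 0.5 / result.dt
        raise ValueError(
            f"no modes in band [{lo}, {hi}] Hz (Nyquist {nyquist:g} Hz)"
        )
    shapes = np.abs(result.modes[:, mask]) ** 2
    if weight == "amplitude":
        shapes = shapes * (np.abs(result.amplitudes[mask]) ** 2)[None, :]
    power = shapes.mean(axis=1)
    if layout is not None:
        power = power.reshape(layout)
    return power
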