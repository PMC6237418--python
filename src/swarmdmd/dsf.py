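"""Longitudinal and transverse dynamic structure factors.

The particle-current field of a swarm, Fourier-transformed in space and
time, separates compression-like (longitudinal, along the wavevector) and
shear-like (transverse) collective motion.  A linear ridge of spectral
peaks, ``omega_shift = c |q|``, indicates sound-like propagation at speed c
(a Brillouin-style dispersion relation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .schooling import TrajectoryEnsemble

logger = logging.getLogger(__name__)

__all__ = ["DSFResult", "current_modes", "dsf_spectrum", "dispersion_fit"]


@dataclass
class DSFResult:
    """S_L / S_T grids over (q, omega) with peak ridge and dispersion fit."""

    q: np.ndarray  # (nq,) 1/m
    omega: np.ndarray  # (nw,) rad/s, nonnegative half
    S_L: np.ndarray  # (nq, nw)
    S_T: np.ndarray  # (nq, nw)

    def peak_ridge(self, component: str = "L", positive_only: bool = True) -> np.ndarray:
        """omega of the maximal spectral weight per wavenumber.

        By default only strictly positive omega is searched (the Brillouin
        ridge); with ``positive_only=False`` the whole grid is searched and
        ties break towards the smallest |omega|, so a featureless spectrum
        reports a peak at zero.
        """
        S = self.S_L if component == "L" else self.S_T
        mask = self.omega > 0 if positive_only else np.ones_like(self.omega, dtype=bool)
        om = self.omega[mask]
        sub = S[:, mask]
        ridge = np.empty(sub.shape[0])
        edge = False
        for i, row in enumerate(sub):
            near_max = row >= row.max() - 1e-12 * max(row.max(), 1e-300)
            cand = om[near_max]
            ridge[i] = cand[np.argmin(np.abs(cand))]
            edge = edge or np.abs(ridge[i]) >= np.abs(om).max() - 1e-12
        if edge and ridge.any():
            logger.warning("spectral peak at the omega grid edge: possible aliasing")
        return ridge


def current_modes(
    positions: np.ndarray, velocities: np.ndarray, q: np.ndarray
) -> tuple[complex, complex]:
    """Longitudinal and transverse current amplitudes for one wavevector.

    ``j_L = sum_i (v_i . q_hat) exp(i q . r_i)`` and ``j_T`` likewise with
    the component of v_i perpendicular to q_hat; both are reported as the
    signed complex amplitude along the respective unit direction.
    """
    q = np.asarray(q, dtype=float)
    qn = np.linalg.norm(q)
    if qn == 0:
        raise ValueError("wavevector must be nonzero")
    q_hat = q / qn
    q_perp = np.array([-q_hat[1], q_hat[0]])
    phase = np.exp(1j * (positions @ q))
    jL = complex(((velocities @ q_hat) * phase).sum())
    jT = complex(((velocities @ q_perp) * phase).sum())
    return jL, jT


def _current_series(traj: TrajectoryEnsemble, q_vec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised j_L(t), j_T(t) over all frames for one wavevector."""
    qn = np.linalg.norm(q_vec)
    q_hat = q_vec / qn
    q_perp = np.array([-q_hat[1], q_hat[0]])
    phase = np.exp(1j * (traj.positions @ q_vec))  # (T, N)
    vL = traj.velocities @ q_hat
    vT = traj.velocities @ q_perp
    return (vL * phase).sum(axis=1), (vT * phase).sum(axis=1)


def dsf_spectrum(
    trajectories: TrajectoryEnsemble | Sequence[TrajectoryEnsemble],
    q_magnitudes: Sequence[float],
    n_angles: int = 16,
    window: Optional[str] = None,
) -> DSFResult:
    """Direction- and trial-averaged dynamic structure factors.

    For each |q| the current series is computed along ``n_angles`` equally
    spaced directions, Fourier-transformed in time, and normalised as
    ``S = |sum_t j(t) e^{i omega t}|^2 dt / (2 pi N T)`` with T the window
    duration; directions and trials are averaged arithmetically.  No taper
    is applied by default (peak positions are insensitive); ``window="hann"``
    applies a Hann taper.
    """
    trials = [trajectories] if isinstance(trajectories, TrajectoryEnsemble) else list(trajectories)
    if not trials:
        raise ValueError("no trajectories given")
    n_frames = trials[0].n_frames
    dt = trials[0].dt
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    for tr in trials:
        if tr.n_frames != n_frames or tr.dt != dt:
            raise ValueError("all trials must share the frame grid")
    q_magnitudes = np.asarray(q_magnitudes, dtype=float)
    if np.any(q_magnitudes <= 0):
        raise ValueError("q magnitudes must be positive")
    if window is None:
        taper = np.ones(n_frames)
    elif window == "hann":
        taper = np.hanning(n_frames)
    else:
        raise ValueError("window must be None or 'hann'")

    omega_full = 2.0 * np.pi * np.fft.fftfreq(n_frames, d=dt)
    order = np.argsort(omega_full)
    omega = omega_full[order]  # full grid, ascending (negative to positive)

    angles = np.arange(n_angles) * (2.0 * np.pi / n_angles)
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)

    S_L = np.zeros((q_magnitudes.size, omega.size))
    S_T = np.zeros_like(S_L)
    for tr in trials:
        N = tr.n_agents
        T_dur = n_frames * dt
        # |dt * sum_t j e^{i w t}|^2 / (2 pi N T): with this normalisation
        # sum_w S dw equals the time-averaged |j|^2 / N (discrete Parseval)
        norm = dt * dt / (2.0 * np.pi * N * T_dur)
        for iq, qmag in enumerate(q_magnitudes):
            for d in dirs:
                jL, jT = _current_series(tr, qmag * d)
                S_L[iq] += (np.abs(np.fft.fft(jL * taper)[order]) ** 2) * norm
                S_T[iq] += (np.abs(np.fft.fft(jT * taper)[order]) ** 2) * norm
    S_L /= len(trials) * n_angles
    S_T /= len(trials) * n_angles
    return DSFResult(q=q_magnitudes, omega=omega, S_L=S_L, S_T=S_T)


def dispersion_fit(result: DSFResult, component: str = "L") -> tuple[float, float]:
    """Least-squares slope of the peak ridge through the origin.

    Returns ``(c, residual)`` where c (m/s) solves
    ``min_c sum_q (omega_shift(q) - c q)^2`` and the residual is the rms
    misfit relative to the rms ridge frequency (0 for a perfect line).
    """
    if result.q.size < 2:
        raise ValueError("need at least 2 wavenumbers")
    ridge = result.peak_ridge(component)
    q = result.q
    c = float(np.dot(q, ridge) / np.dot(q, q))
    resid = float(np.linalg.norm(ridge - c * q) / max(np.linalg.norm(ridge), 1e-300))
    return c, resid
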