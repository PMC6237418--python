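"""Seed-deterministic fixture generators with known ground truth.

Every analysis stage has a generator here whose output it should recover
exactly or to a stated tolerance: linear systems for plain DMD, a
quadratically coupled system with an analytically known Koopman spectrum
for kernel DMD, ballistic swarms for the structure-factor dispersion, and
a two-class 5-on-5 game-segment generator whose outcome label is carried by
the dynamics of the four critical attacker-defender distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .features import AttackSegment, SnapshotSequence
from .schooling import TrajectoryEnsemble

__all__ = [
    "linear_fixture",
    "koopman_oscillator_fixture",
    "ballistic_fixture",
    "game_segment_generator",
]


def linear_fixture(
    A: np.ndarray,
    y0: Optional[np.ndarray] = None,
    tau: int = 200,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt: float = 1.0,
) -> tuple[SnapshotSequence, np.ndarray]:
    """Iterate ``y_{t+1} = A y_t + noise``; returns (sequence, eigenvalues).

    The returned eigenvalues of the generating matrix are the exact
    discrete-time spectrum a decomposition should recover at zero noise.
    """
    A = np.asarray(A, dtype=float)
    if tau < 3:
        raise ValueError("tau must be >= 3")
    p = A.shape[0]
    rng = np.random.default_rng(seed)
    y = np.empty((p, tau))
    y[:, 0] = rng.standard_normal(p) if y0 is None else np.asarray(y0, dtype=float)
    for t in range(tau - 1):
        y[:, t + 1] = A @ y[:, t]
        if noise_sd > 0:
            y[:, t + 1] += noise_sd * rng.standard_normal(p)
    seq = SnapshotSequence(values=y, dt=dt, feature_mode="raw", provenance="linear_fixture")
    return seq, np.linalg.eigvals(A)


def koopman_oscillator_fixture(
    lam: float = 0.95,
    mu: float = 0.5,
    c: float = 1.0,
    y0: Sequence[float] = (1.0, 0.3),
    tau: int = 100,
    dt: float = 1.0,
) -> tuple[SnapshotSequence, np.ndarray]:
    """Quadratically coupled pair with closed-form Koopman spectrum.

    ``x1 <- lam x1; x2 <- mu x2 + c x1^2``.  The observables x1, x2 and
    x1^2 evolve linearly with eigenvalues {lam, mu, lam^2}, so a kernel
    decomposition whose feature space contains quadratics recovers all
    three; returns (sequence, those eigenvalues).
    """
    if abs(lam) > 1 or abs(mu) > 1:
        raise ValueError("|lam| and |mu| must be <= 1 for a stable fixture")
    x = np.empty((2, tau))
    x[:, 0] = y0
    for t in range(tau - 1):
        x[0, t + 1] = lam * x[0, t]
        x[1, t + 1] = mu * x[1, t] + c * x[0, t] ** 2
    seq = SnapshotSequence(values=x, dt=dt, feature_mode="raw", provenance="koopman_oscillator")
    return seq, np.array([lam, mu, lam**2])


def ballistic_fixture(
    speed: float = 4.0,
    heading: Sequence[float] = (1.0, 0.0),
    n_agents: int = 64,
    duration: float = 10.0,
    dt: float = 0.01,
    box: float = 25.0,
    seed: int = 0,
) -> TrajectoryEnsemble:
    """Uniform translation: random initial positions, one shared velocity.

    The current field is then a superposition of plane waves at
    ``omega = q . v``, so the longitudinal dispersion slope equals the set
    speed — the analytic oracle for the structure-factor pipeline.  A zero
    speed gives the static fixture whose spectra peak at omega = 0.
    """
    if speed < 0:
        raise ValueError("speed must be nonnegative")
    heading = np.asarray(heading, dtype=float)
    nrm = np.linalg.norm(heading)
    if nrm == 0:
        raise ValueError("heading must be nonzero")
    heading = heading / nrm
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration / dt))
    r0 = rng.uniform(-box / 2, box / 2, size=(n_agents, 2))
    times = dt * np.arange(n_frames)
    v = speed * heading
    positions = r0[None, :, :] + times[:, None, None] * v[None, None, :]
    velocities = np.broadcast_to(v, (n_frames, n_agents, 2)).copy()
    return TrajectoryEnsemble(
        dt=dt, times=times, positions=positions, velocities=velocities, seed=seed
    )


def _smooth_noise(rng: np.random.Generator, n: int, sd: float, tau_frames: int = 12) -> np.ndarray:
    """Temporally smoothed Gaussian noise (moving average), sd preserved."""
    if sd == 0:
        return np.zeros(n)
    raw = rng.standard_normal(n + tau_frames)
    kernel = np.ones(tau_frames) / tau_frames
    sm = np.convolve(raw, kernel, mode="valid")[:n]
    return sd * sm / np.std(sm) if np.std(sm) > 0 else np.zeros(n)


def game_segment_generator(
    m: int = 40,
    class_effect: float = 1.0,
    seed: int = 0,
    frame_rate: float = 25.0,
    min_duration: float = 3.0,
    max_duration: float = 8.0,
) -> list[AttackSegment]:
    """Two-class synthetic 5-on-5 attack segments, labels balanced.

    Attackers drift slowly around a spread formation on a half court;
    each defender marks one attacker at a controlled distance.  The
    outcome label is written into the *dynamics* of those marking
    distances: "score" segments carry a slowly growing ~0.5 Hz
    oscillation of the ball-mark / pass-mark separations (defenders losing
    their marks), while "no-score" segments show only fast (~3 Hz)
    small-amplitude tracking jitter.  ``class_effect`` scales both class
    signatures; at 0 the two classes are statistically identical and any
    classifier sits at chance.
    """
    if m < 10:
        raise ValueError("need at least 10 segments")
    rng = np.random.default_rng(seed)
    labels = np.zeros(m, dtype=int)
    labels[: m // 2] = 1
    rng.shuffle(labels)
    segments: list[AttackSegment] = []
    court_center = np.array([7.0, 7.5])  # half court ~ 14 x 15 m
    for s in range(m):
        T = int(round(rng.uniform(min_duration, max_duration) * frame_rate))
        t = np.arange(T) / frame_rate
        label = int(labels[s])
        # attacker formation: pentagon of radius ~5 m plus slow smooth drift
        base_angles = 2 * np.pi * np.arange(5) / 5 + rng.uniform(0, 2 * np.pi)
        attackers = np.empty((T, 5, 2))
        for a in range(5):
            center = court_center + 5.0 * np.array(
                [np.cos(base_angles[a]), np.sin(base_angles[a])]
            )
            drift_f = rng.uniform(0.05, 0.15, size=2)
            drift_ph = rng.uniform(0, 2 * np.pi, size=2)
            drift_amp = rng.uniform(0.5, 1.5, size=2)
            attackers[:, a, 0] = center[0] + drift_amp[0] * np.sin(
                2 * np.pi * drift_f[0] * t + drift_ph[0]
            )
            attackers[:, a, 1] = center[1] + drift_amp[1] * np.sin(
                2 * np.pi * drift_f[1] * t + drift_ph[1]
            )
        # marking distances carry the class signal
        defenders = np.empty((T, 5, 2))
        for a in range(5):
            # marking distances are stereotyped across possessions; the
            # label-linked dynamics must dominate the baseline scatter
            base = 2.0 + 0.2 * rng.standard_normal()
            phase = rng.uniform(0, 2 * np.pi)
            common = _smooth_noise(rng, T, sd=0.05)
            if label == 1:
                sig = 0.5 * np.exp(0.1 * t) * np.sin(2 * np.pi * 0.5 * t + phase)
            else:
                sig = 0.15 * np.sin(2 * np.pi * 3.0 * t + phase)
            dist = np.clip(base + common + class_effect * sig, 0.3, None)
            ang0 = rng.uniform(0, 2 * np.pi)
            ang = ang0 + _smooth_noise(rng, T, sd=0.2, tau_frames=25).cumsum() / frame_rate
            u = np.stack([np.cos(ang), np.sin(ang)], axis=1)
            defenders[:, a] = attackers[:, a] + dist[:, None] * u
        # ball: held by one attacker at a time, switching every ~2 s
        ball_holder = np.empty(T, dtype=int)
        holder = int(rng.integers(5))
        nxt = 0
        for frame in range(T):
            if frame >= nxt:
                holder = int(rng.integers(5))
                nxt = frame + int(rng.uniform(1.0, 3.0) * frame_rate)
            ball_holder[frame] = holder
        ball = attackers[np.arange(T), ball_holder] + rng.uniform(-0.3, 0.3, size=(T, 2))
        segments.append(
            AttackSegment(
                attackers=attackers,
                defenders=defenders,
                ball=ball,
                ball_holder=ball_holder,
                label=label,
                segment_id=f"synth{s:03d}",
                frame_rate=frame_rate,
            )
        )
    return segments
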