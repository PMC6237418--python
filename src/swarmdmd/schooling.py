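"""Metric zonal schooling simulator.

Agents move at constant individual speed in 2-D and steer according to three
concentric interaction shells: repulsion (avoid collisions, highest priority),
orientation (align headings) and attraction (stay with the group).  Varying
the orientation radius ``r_o`` alone produces the three classic regimes:
swarm (disordered aggregate), torus (rotating mill) and parallel (aligned
translation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SchoolingParams",
    "SwarmState",
    "TrajectoryEnsemble",
    "init_state",
    "desired_direction",
    "limit_turn",
    "step",
    "simulate",
    "order_parameters",
]

_UNIT_TOL = 1e-9

#: Orientation radius and analysis-window start (s) for each named regime.
#: The torus is analysed right after its short transient; the swarm and
#: parallel states take longer to develop, so their windows start later.
REGIME_PROTOCOL: dict[str, tuple[float, float]] = {
    "swarm": (2.0, 30.0),
    "torus": (10.0, 10.0),
    "parallel": (13.0, 30.0),
}


def regime_params(regime: str, seed: int = 0, duration: float = 40.0) -> "SchoolingParams":
    """Parameters generating a named regime (swarm / torus / parallel)."""
    try:
        r_o, start = REGIME_PROTOCOL[regime]
    except KeyError:
        raise ValueError(f"unknown regime {regime!r}; expected one of {sorted(REGIME_PROTOCOL)}")
    return SchoolingParams(r_o=r_o, analysis_start=start, duration=duration, seed=seed)


@dataclass(frozen=True)
class SchoolingParams:
    """Configuration of the zonal schooling model.

    Parameters
    ----------
    n_agents
        Number of agents N.
    speed
        Nominal cruising speed in m/s; each agent's actual speed is
        ``speed * (1 + speed_noise_sd * z)`` with z standard normal, drawn
        once at initialisation and constant thereafter.
    speed_noise_sd
        Dimensionless standard deviation of the per-agent speed noise.
    r_r, r_o, r_a
        Radii (m) of the repulsion, orientation and attraction shells,
        with ``0 < r_r <= r_o <= r_a``.  The shells are concentric annuli:
        repulsion ``dist < r_r``, orientation ``r_r <= dist < r_o``,
        attraction ``r_o <= dist < r_a``.
    beta
        Maximum turning angle per time step (rad).
    dt
        Integration time step (s).
    boundary_radius
        Radius of the circular arena (m); ``None`` for unbounded motion.
    duration
        Simulated time (s).
    analysis_start
        Time (s) before which frames are considered transient.
    seed
        Seed for the run's random number generator.
    """

    n_agents: int = 64
    speed: float = 4.0
    speed_noise_sd: float = 0.05
    r_r: float = 2.0
    r_o: float = 10.0
    r_a: float = 20.0
    beta: float = 0.012
    dt: float = 0.01
    boundary_radius: Optional[float] = 25.0
    duration: float = 40.0
    analysis_start: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ValueError("n_agents must be >= 2")
        if not (0 < self.r_r <= self.r_o <= self.r_a):
            raise ValueError("zone radii must satisfy 0 < r_r <= r_o <= r_a")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0 < self.beta <= np.pi):
            raise ValueError("beta must lie in (0, pi]")
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.speed_noise_sd < 0:
            raise ValueError("speed_noise_sd must be nonnegative")
        if self.boundary_radius is not None and self.boundary_radius <= 0:
            raise ValueError("boundary_radius must be positive or None")


@dataclass
class SwarmState:
    """Instantaneous state of the swarm."""

    time: float
    positions: np.ndarray  # (N, 2) m
    directions: np.ndarray  # (N, 2) unit vectors
    speeds: np.ndarray  # (N,) m/s, fixed per run

    def validate(self) -> None:
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=_UNIT_TOL):
            raise ValueError("direction vectors must be unit norm")


@dataclass
class TrajectoryEnsemble:
    """A simulated (or recorded) multi-agent trajectory.

    ``velocities[t]`` holds the forward difference
    ``(positions[t+1] - positions[t]) / dt`` (the last frame repeats the
    previous value), so the stored velocities are exactly consistent with
    the stored positions.
    """

    dt: float
    times: np.ndarray  # (T,)
    positions: np.ndarray  # (T, N, 2)
    velocities: np.ndarray  # (T, N, 2)
    params: Optional[SchoolingParams] = None
    seed: Optional[int] = None

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_agents(self) -> int:
        return self.positions.shape[1]

    def window(self, t_start: float, t_stop: Optional[float] = None) -> "TrajectoryEnsemble":
        """Frames with ``t_start <= time < t_stop``."""
        mask = self.times >= t_start - 1e-12
        if t_stop is not None:
            mask &= self.times < t_stop - 1e-12
        return TrajectoryEnsemble(
            dt=self.dt,
            times=self.times[mask],
            positions=self.positions[mask],
            velocities=self.velocities[mask],
            params=self.params,
            seed=self.seed,
        )


def _normalize_rows(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    out = np.divide(v, n, out=np.zeros_like(v), where=n > 0)
    return out


def init_state(params: SchoolingParams, rng: np.random.Generator) -> SwarmState:
    """Place agents on a ring and start them on tangential headings.

    Initial radii are uniform in [6, 16] m with uniform angles; each initial
    heading is perpendicular to the position vector (counter-clockwise
    tangent), which seeds a coherent rotation from which all three regimes
    can emerge.  Per-agent speeds are drawn once here and never change.
    """
    n = params.n_agents
    radii = rng.uniform(6.0, 16.0, size=n)
    angles = rng.uniform(0.0, 2.0 * np.pi, size=n)
    positions = np.stack([radii * np.cos(angles), radii * np.sin(angles)], axis=1)
    radial = _normalize_rows(positions)
    directions = np.stack([-radial[:, 1], radial[:, 0]], axis=1)  # CCW tangent
    speeds = params.speed * (1.0 + params.speed_noise_sd * rng.standard_normal(n))
    state = SwarmState(time=0.0, positions=positions, directions=directions, speeds=speeds)
    state.validate()
    return state


def _zone_masks(positions: np.ndarray, params: SchoolingParams):
    """Pairwise distances and the three boolean shell masks (self excluded)."""
    diff = positions[None, :, :] - positions[:, None, :]  # diff[i, j] = r_j - r_i
    dist = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(dist, np.inf)
    rep = dist < params.r_r
    orient = (dist >= params.r_r) & (dist < params.r_o)
    attract = (dist >= params.r_o) & (dist < params.r_a)
    return diff, dist, rep, orient, attract


def _desired_directions(
    state: SwarmState, params: SchoolingParams, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Vectorised zonal steering for all agents at once."""
    pos, dirs = state.positions, state.directions
    diff, dist, rep, orient, attract = _zone_masks(pos, params)

    coincident = dist == 0.0
    unit = np.divide(diff, dist[..., None], out=np.zeros_like(diff), where=dist[..., None] > 0)

    desired = dirs.copy()
    has_rep = rep.any(axis=1)
    if has_rep.any():
        rep_sum = -(unit * rep[..., None]).sum(axis=1)
        if coincident.any():
            logger.warning("coincident agent positions treated as repulsion with random direction")
            gen = rng if rng is not None else np.random.default_rng(0)
            idx_i, _ = np.nonzero(coincident)
            for i in np.unique(idx_i):
                theta = gen.uniform(0.0, 2.0 * np.pi)
                rep_sum[i] += np.array([np.cos(theta), np.sin(theta)])
            has_rep = has_rep | coincident.any(axis=1)
        rep_dir = _normalize_rows(rep_sum)
        degenerate = np.linalg.norm(rep_sum, axis=1) == 0
        rep_dir[degenerate] = dirs[degenerate]
        desired[has_rep] = rep_dir[has_rep]

    free = ~has_rep
    if free.any():
        o_sum = (dirs[None, :, :] * orient[..., None]).sum(axis=1)
        a_sum = (unit * attract[..., None]).sum(axis=1)
        o_dir = _normalize_rows(o_sum)
        a_dir = _normalize_rows(a_sum)
        has_o = orient.any(axis=1) & (np.linalg.norm(o_sum, axis=1) > 0)
        has_a = attract.any(axis=1) & (np.linalg.norm(a_sum, axis=1) > 0)
        comb = np.where(
            (has_o & has_a)[:, None],
            0.5 * (o_dir + a_dir),
            np.where(has_o[:, None], o_dir, a_dir),
        )
        comb_dir = _normalize_rows(comb)
        ok = free & (has_o | has_a) & (np.linalg.norm(comb, axis=1) > 0)
        desired[ok] = comb_dir[ok]
    return desired


def desired_direction(
    agent_index: int,
    state: SwarmState,
    params: SchoolingParams,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Zonal steering rule for one agent.

    Repulsion has absolute priority: if any neighbour sits inside the
    repulsion shell the result is the normalised sum of unit vectors away
    from them, regardless of the other shells.  Otherwise the orientation
    term (neighbours' mean heading) and attraction term (mean unit vector
    towards attraction-shell neighbours) are each normalised and combined
    with weight 1/2; a single populated shell contributes alone; with all
    shells empty the agent keeps its current heading.
    """
    return _desired_directions(state, params, rng)[agent_index]


def limit_turn(d_current: np.ndarray, d_desired: np.ndarray, beta: float) -> np.ndarray:
    """Rotate ``d_current`` towards ``d_desired`` by at most ``beta`` rad."""
    dot = float(np.clip(np.dot(d_current, d_desired), -1.0, 1.0))
    cross = d_current[0] * d_desired[1] - d_current[1] * d_desired[0]
    theta = np.arctan2(cross, dot)
    if abs(theta) <= beta:
        return np.asarray(d_desired, dtype=float)
    phi = np.sign(theta) * beta if theta != 0 else beta
    c, s = np.cos(phi), np.sin(phi)
    return np.array([c * d_current[0] - s * d_current[1], s * d_current[0] + c * d_current[1]])


def _limit_turns(dirs: np.ndarray, desired: np.ndarray, beta: float) -> np.ndarray:
    dot = np.clip((dirs * desired).sum(axis=1), -1.0, 1.0)
    cross = dirs[:, 0] * desired[:, 1] - dirs[:, 1] * desired[:, 0]
    theta = np.arctan2(cross, dot)
    clipped = np.abs(theta) > beta
    phi = np.where(theta >= 0, beta, -beta)
    c, s = np.cos(phi), np.sin(phi)
    rotated = np.stack(
        [c * dirs[:, 0] - s * dirs[:, 1], s * dirs[:, 0] + c * dirs[:, 1]], axis=1
    )
    out = np.where(clipped[:, None], rotated, desired)
    # 180-degree conflicts have theta = pi and rotate by the full beta.
    return _normalize_rows(out)


def step(
    state: SwarmState, params: SchoolingParams, rng: Optional[np.random.Generator] = None
) -> SwarmState:
    """Advance the swarm by one time step.

    The desired direction of an agent whose provisional next position would
    leave the circular arena is replaced by the unit vector towards the
    origin before the turn limit is applied; positions are finally projected
    back onto the disc so containment holds exactly.
    """
    desired = _desired_directions(state, params, rng)
    steps = state.speeds[:, None] * params.dt
    if params.boundary_radius is not None:
        provisional = state.positions + steps * desired
        outside = np.linalg.norm(provisional, axis=1) > params.boundary_radius
        if outside.any():
            inward = _normalize_rows(-state.positions[outside])
            desired = desired.copy()
            desired[outside] = inward
    new_dirs = _limit_turns(state.directions, desired, params.beta)
    new_pos = state.positions + steps * new_dirs
    if params.boundary_radius is not None:
        norms = np.linalg.norm(new_pos, axis=1)
        over = norms > params.boundary_radius
        if over.any():
            new_pos[over] *= (params.boundary_radius / norms[over])[:, None]
    return SwarmState(
        time=state.time + params.dt,
        positions=new_pos,
        directions=new_dirs,
        speeds=state.speeds,
    )


def simulate(params: SchoolingParams) -> TrajectoryEnsemble:
    """Run the model for ``round(duration / dt)`` frames, seed-deterministic."""
    rng = np.random.default_rng(params.seed)
    n_frames = int(round(params.duration / params.dt))
    state = init_state(params, rng)
    positions = np.empty((n_frames, params.n_agents, 2))
    times = np.empty(n_frames)
    for t in range(n_frames):
        positions[t] = state.positions
        times[t] = state.time
        state = step(state, params, rng)
    velocities = np.empty_like(positions)
    velocities[:-1] = np.diff(positions, axis=0) / params.dt
    velocities[-1] = velocities[-2]
    return TrajectoryEnsemble(
        dt=params.dt,
        times=times,
        positions=positions,
        velocities=velocities,
        params=params,
        seed=params.seed,
    )


def order_parameters(directions: np.ndarray, positions: np.ndarray) -> tuple[float, float]:
    """Group polarization and angular momentum, each in [0, 1].

    Polarization is the norm of the mean heading.  Angular momentum is the
    norm of the mean 2-D cross product between the unit vector from the
    group centroid to each agent and that agent's heading; agents exactly
    at the centroid are skipped.
    """
    directions = np.asarray(directions, dtype=float)
    positions = np.asarray(positions, dtype=float)
    n = directions.shape[0]
    if n < 2:
        raise ValueError("need at least two agents")
    polarization = float(np.linalg.norm(directions.sum(axis=0)) / n)
    centroid = positions.mean(axis=0)
    rel = positions - centroid
    norms = np.linalg.norm(rel, axis=1)
    ok = norms > 0
    if not ok.all():
        logger.warning("agent(s) at the centroid skipped in angular momentum")
    u = rel[ok] / norms[ok, None]
    cross = u[:, 0] * directions[ok, 1] - u[:, 1] * directions[ok, 0]
    angular_momentum = float(abs(cross.sum()) / n)
    return polarization, angular_momentum


def order_parameter_series(traj: TrajectoryEnsemble) -> tuple[np.ndarray, np.ndarray]:
    """Polarization and angular momentum per frame, headings from velocities."""
    dirs = _normalize_rows(traj.velocities)
    pol = np.empty(traj.n_frames)
    mom = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        pol[t], mom[t] = order_parameters(dirs[t], traj.positions[t])
    return pol, mom
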