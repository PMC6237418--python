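"""Observable matrices for decomposition analysis.

Turns raw multi-agent trajectories into the snapshot matrices consumed by
dynamic mode decomposition: nearest-sorted inter-agent distance series for
swarms, and attacker-defender distance features for 5-on-5 game segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .schooling import TrajectoryEnsemble

logger = logging.getLogger(__name__)

__all__ = [
    "SnapshotSequence",
    "AttackSegment",
    "SegmentSet",
    "pairwise_distances",
    "sorted_distance_snapshot",
    "build_snapshot_sequence",
    "critical_distances",
    "game_distance_features",
    "extract_attack_segments",
]

FEATURE_MODES = (
    "sorted_distance",
    "fixed_distance",
    "cartesian",
    "critical_k",
    "game_matrix_k",
    "euclidean25",
)

FRAME_RATE = 25.0  # game tracking data, frames per second


@dataclass
class SnapshotSequence:
    """A p x tau matrix of observables; columns are time snapshots."""

    values: np.ndarray
    dt: float
    feature_mode: str = "raw"
    provenance: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (p x tau) array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("snapshot values must be finite")
        if self.values.shape[1] < 2:
            raise ValueError("need at least two snapshots")

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def tau(self) -> int:
        return self.values.shape[1]


@dataclass
class AttackSegment:
    """One 5-on-5 possession: attackers, defenders, ball, and outcome label."""

    attackers: np.ndarray  # (T, 5, 2) m
    defenders: np.ndarray  # (T, 5, 2) m
    ball: np.ndarray  # (T, 2) m
    ball_holder: np.ndarray  # (T,) attacker index in 0..4
    label: int  # 1 = score, 0 = no score
    segment_id: str = ""
    frame_rate: float = FRAME_RATE

    def __post_init__(self) -> None:
        self.attackers = np.asarray(self.attackers, dtype=float)
        self.defenders = np.asarray(self.defenders, dtype=float)
        self.ball = np.asarray(self.ball, dtype=float)
        self.ball_holder = np.asarray(self.ball_holder, dtype=int)
        if self.attackers.shape[1] != 5 or self.defenders.shape[1] != 5:
            raise ValueError("need exactly 5 attackers and 5 defenders")
        if self.attackers.shape[0] < 2:
            raise ValueError("segment must span at least 2 frames")
        if self.ball_holder.min() < 0 or self.ball_holder.max() > 4:
            raise ValueError("ball_holder indices must lie in 0..4")

    @property
    def n_frames(self) -> int:
        return self.attackers.shape[0]


@dataclass
class SegmentSet:
    """Labelled collection of snapshot sequences with a shared feature mode."""

    sequences: list[SnapshotSequence]
    labels: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.sequences) != len(self.labels) or len(self.sequences) != len(self.ids):
            raise ValueError("sequences, labels and ids must have equal length")
        modes = {s.feature_mode for s in self.sequences}
        if len(modes) > 1:
            raise ValueError(f"inconsistent feature modes in set: {modes}")

    def __len__(self) -> int:
        return len(self.sequences)


def pairwise_distances(positions: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix with zero diagonal."""
    positions = np.asarray(positions, dtype=float)
    if not np.all(np.isfinite(positions)):
        raise ValueError("positions must be finite")
    return squareform(pdist(positions))


def sorted_distance_snapshot(D: np.ndarray) -> np.ndarray:
    """Row-wise nearest-neighbour-sorted distances, self excluded.

    Row i holds agent i's distances to the other N-1 agents in ascending
    order; rows are concatenated row-major into one vector of length N(N-1).
    Within-row sorting removes neighbour identity, which keeps the series
    temporally much smoother than a fixed-order distance matrix; relabelling
    the agents only permutes whole rows (the multiset of rows is invariant).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    off_diag = D[~np.eye(n, dtype=bool)].reshape(n, n - 1)
    return np.sort(off_diag, axis=1).reshape(-1)


def build_snapshot_sequence(traj: TrajectoryEnsemble, feature_mode: str) -> SnapshotSequence:
    """Snapshot matrix from a swarm trajectory.

    Modes: ``sorted_distance`` (p = N(N-1) nearest-sorted distances),
    ``fixed_distance`` (p = N(N-1)/2 upper-triangle distances in fixed agent
    order) and ``cartesian`` (p = 2N stacked coordinates).
    """
    n = traj.n_agents
    T = traj.n_frames
    if feature_mode == "sorted_distance":
        cols = np.empty((n * (n - 1), T))
        for t in range(T):
            cols[:, t] = sorted_distance_snapshot(pairwise_distances(traj.positions[t]))
    elif feature_mode == "fixed_distance":
        iu = np.triu_indices(n, k=1)
        cols = np.empty((n * (n - 1) // 2, T))
        for t in range(T):
            cols[:, t] = pairwise_distances(traj.positions[t])[iu]
    elif feature_mode == "cartesian":
        cols = traj.positions.reshape(T, 2 * n).T
    else:
        raise ValueError(f"unknown feature mode {feature_mode!r}")
    return SnapshotSequence(values=cols, dt=traj.dt, feature_mode=feature_mode)


def critical_distances(segment: AttackSegment) -> np.ndarray:
    """The four critical attacker-defender distances per frame (T x 4).

    Columns: ball-mark (ball-handler's nearest-defender distance), ball-help
    (ball-handler's second-nearest), pass-mark (largest nearest-defender
    distance among off-ball attackers) and pass-help (second largest).
    """
    T = segment.n_frames
    out = np.empty((T, 4))
    for t in range(T):
        D = cdist(segment.attackers[t], segment.defenders[t])  # (5 attackers, 5 defenders)
        sorted_rows = np.sort(D, axis=1)
        holder = segment.ball_holder[t]
        out[t, 0] = sorted_rows[holder, 0]
        out[t, 1] = sorted_rows[holder, 1]
        others = np.delete(np.arange(5), holder)
        nearest = np.sort(sorted_rows[others, 0])[::-1]
        out[t, 2] = nearest[0]
        out[t, 3] = nearest[1]
    return out


def _sorted_game_matrix(segment: AttackSegment, t: int) -> np.ndarray:
    """The 5x5 sorted attacker-defender distance matrix for one frame.

    Column a holds one attacker's distances to the five defenders sorted
    nearest-first.  Attacker order: ball-handler first, then the remaining
    attackers by decreasing nearest-defender separation (ties broken by
    attacker index, so runs are reproducible).
    """
    D = cdist(segment.attackers[t], segment.defenders[t])
    sorted_rows = np.sort(D, axis=1)  # row a = attacker a's defender distances ascending
    holder = segment.ball_holder[t]
    others = np.delete(np.arange(5), holder)
    # decreasing nearest-defender separation; np.argsort is stable, so ties
    # fall back to attacker index
    order = others[np.argsort(-sorted_rows[others, 0], kind="stable")]
    attacker_order = np.concatenate([[holder], order])
    return sorted_rows[attacker_order].T  # column a = attacker attacker_order[a]


_VARIANT_P = {
    "i": 1, "ii": 2, "iii": 3, "iv": 4, "v": 9, "vi": 16, "vii": 25,
    "viii": 25, "ix": 20,
}


def game_distance_features(segment: AttackSegment, variant: str = "iv") -> SnapshotSequence:
    """The (i)-(ix) observable series of a game segment.

    (i)-(iv): the first one to four critical distances; (v)-(vii): the
    top-left 3x3 / 4x4 / full 5x5 block of the sorted attacker-defender
    distance matrix, flattened; (viii): the 25 unsorted Euclidean
    attacker-defender distances; (ix): the 20 Cartesian coordinates of all
    ten players.
    """
    if variant not in _VARIANT_P:
        raise ValueError(f"unknown variant {variant!r}; expected one of {sorted(_VARIANT_P)}")
    T = segment.n_frames
    dt = 1.0 / segment.frame_rate
    if variant in ("i", "ii", "iii", "iv"):
        k = _VARIANT_P[variant]
        vals = critical_distances(segment)[:, :k].T
        mode = "critical_k"
    elif variant in ("v", "vi", "vii"):
        k = {"v": 3, "vi": 4, "vii": 5}[variant]
        vals = np.empty((k * k, T))
        for t in range(T):
            vals[:, t] = _sorted_game_matrix(segment, t)[:k, :k].reshape(-1)
        mode = "game_matrix_k"
    elif variant == "viii":
        vals = np.empty((25, T))
        for t in range(T):
            vals[:, t] = cdist(segment.attackers[t], segment.defenders[t]).reshape(-1)
        mode = "euclidean25"
    else:  # ix
        vals = np.concatenate(
            [segment.attackers.reshape(T, 10), segment.defenders.reshape(T, 10)], axis=1
        ).T
        mode = "cartesian"
    return SnapshotSequence(values=vals, dt=dt, feature_mode=mode, provenance=segment.segment_id)


def segment_set(
    segments: Iterable[AttackSegment], variant: str = "iv"
) -> SegmentSet:
    """Feature sequences for a collection of segments under one variant."""
    seqs, labels, ids = [], [], []
    for seg in segments:
        seqs.append(game_distance_features(seg, variant))
        labels.append(seg.label)
        ids.append(seg.segment_id)
    return SegmentSet(sequences=seqs, labels=np.asarray(labels), ids=ids)


def extract_attack_segments(
    attackers: np.ndarray,
    defenders: np.ndarray,
    ball: np.ndarray,
    ball_holder: np.ndarray,
    shot_frames: Sequence[int],
    shot_outcomes: Sequence[int],
    half_line_x: float = 0.0,
    attack_direction: int = 1,
    frame_rate: float = FRAME_RATE,
) -> list[AttackSegment]:
    """Cut attack segments out of a full game trajectory.

    A segment begins at the first frame (after the previous shot) at which
    all five attackers are in the attacking half, and ends exactly one
    second (``frame_rate`` frames) before the shot.  Shots taken before all
    attackers have crossed are skipped with a warning.
    """
    if len(shot_frames) != len(shot_outcomes):
        raise ValueError("shot_frames and shot_outcomes must have equal length")
    segments: list[AttackSegment] = []
    prev_shot = 0
    lead = int(round(frame_rate))
    x = attackers[..., 0] * attack_direction
    all_in = np.all(x > half_line_x * attack_direction, axis=1)
    for k, (shot, outcome) in enumerate(zip(shot_frames, shot_outcomes)):
        end = shot - lead
        crossed = np.nonzero(all_in[prev_shot:shot])[0]
        if crossed.size == 0 or prev_shot + crossed[0] >= end - 1:
            logger.warning("shot at frame %d skipped: attackers never all crossed", shot)
            prev_shot = shot
            continue
        start = prev_shot + int(crossed[0])
        segments.append(
            AttackSegment(
                attackers=attackers[start:end],
                defenders=defenders[start:end],
                ball=ball[start:end],
                ball_holder=ball_holder[start:end],
                label=int(outcome),
                segment_id=f"seg{k:03d}",
                frame_rate=frame_rate,
            )
        )
        prev_shot = shot
    return segments
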