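"""Readers, writers and configuration for the pipeline artifacts.

All artifacts are plain CSV with JSON sidecars (``<file>.meta.json``)
carrying a schema version, the seed, and stage parameters.  Conventions:
times in seconds, positions in metres, 0-based agent indices, row-major
flattening.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from .features import AttackSegment, SegmentSet, SnapshotSequence
from .schooling import SchoolingParams, TrajectoryEnsemble
from .spectral_kernels import KernelMatrix

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_segment",
    "write_segment",
    "read_snapshot_sequence",
    "write_snapshot_sequence",
    "read_kernel_matrix",
    "write_kernel_matrix",
    "read_config",
    "write_config",
]


class ArtifactError(ValueError):
    """A file did not parse as the expected artifact."""


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def _write_meta(path: Path, kind: str, **fields: Any) -> None:
    meta = {"schema_version": SCHEMA_VERSION, "kind": kind, **fields}
    _sidecar(path).write_text(json.dumps(meta, indent=2, default=_json_default))


def _json_default(obj: Any):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def _read_meta(path: Path, kind: Optional[str] = None) -> dict:
    sc = _sidecar(path)
    if not sc.exists():
        return {}
    meta = json.loads(sc.read_text())
    version = meta.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ArtifactError(
            f"{sc}: schema version {version!r} incompatible with {SCHEMA_VERSION}"
        )
    if kind is not None and meta.get("kind") not in (None, kind):
        raise ArtifactError(f"{sc}: artifact kind {meta.get('kind')!r}, expected {kind!r}")
    return meta


def write_trajectory(traj: TrajectoryEnsemble, path: str | Path) -> Path:
    """Trajectory as CSV ``time,agent,x,y,vx,vy`` (SI units) + metadata."""
    path = Path(path)
    T, N = traj.n_frames, traj.n_agents
    times = np.repeat(traj.times, N)
    agents = np.tile(np.arange(N), T)
    flat_p = traj.positions.reshape(T * N, 2)
    flat_v = traj.velocities.reshape(T * N, 2)
    df = pd.DataFrame(
        {
            "time": times,
            "agent": agents,
            "x": flat_p[:, 0],
            "y": flat_p[:, 1],
            "vx": flat_v[:, 0],
            "vy": flat_v[:, 1],
        }
    )
    df.to_csv(path, index=False)
    _write_meta(
        path,
        "trajectory",
        dt=traj.dt,
        seed=traj.seed,
        params=traj.params,
    )
    return path


def read_trajectory(path: str | Path) -> TrajectoryEnsemble:
    """Read a trajectory CSV; velocities default to forward differences.

    Rows may arrive in any order (they are sorted by time then agent); the
    time grid must be regular to 1e-9 and every agent must appear in every
    frame.
    """
    path = Path(path)
    meta = _read_meta(path, "trajectory")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ArtifactError(f"{path}: failed to parse CSV: {exc}") from exc
    required = {"time", "agent", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ArtifactError(f"{path}: missing columns {sorted(missing)}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise ArtifactError(f"{path}: non-numeric value in column {col!r} near line {line}")
    df = df.sort_values(["time", "agent"], kind="stable").reset_index(drop=True)
    times = np.unique(df["time"].to_numpy())
    agents = np.unique(df["agent"].to_numpy())
    T, N = times.size, agents.size
    if len(df) != T * N:
        counts = df.groupby("time")["agent"].count()
        bad_t = counts.index[counts != N]
        raise ArtifactError(f"{path}: missing agents at time(s) {list(bad_t[:3])}")
    if T < 2:
        raise ArtifactError(f"{path}: need at least 2 frames")
    dts = np.diff(times)
    dt = float(np.median(dts))
    if np.max(np.abs(dts - dt)) >= 1e-9:
        k = int(np.argmax(np.abs(dts - dt)))
        raise ArtifactError(
            f"{path}: irregular sampling between t={times[k]} and t={times[k + 1]}"
        )
    positions = df[["x", "y"]].to_numpy().reshape(T, N, 2)
    if {"vx", "vy"} <= set(df.columns):
        velocities = df[["vx", "vy"]].to_numpy().reshape(T, N, 2)
    else:
        velocities = np.empty_like(positions)
        velocities[:-1] = np.diff(positions, axis=0) / dt
        velocities[-1] = velocities[-2]
    params = meta.get("params")
    return TrajectoryEnsemble(
        dt=dt,
        times=times,
        positions=positions,
        velocities=velocities,
        params=SchoolingParams(**params) if isinstance(params, dict) else None,
        seed=meta.get("seed"),
    )


def write_segment(segment: AttackSegment, path: str | Path) -> Path:
    """Game segment as CSV ``frame,entity,role,x,y`` + JSON sidecar."""
    path = Path(path)
    rows = []
    for t in range(segment.n_frames):
        for a in range(5):
            rows.append((t, a, "attacker", *segment.attackers[t, a]))
        for d in range(5):
            rows.append((t, d, "defender", *segment.defenders[t, d]))
        rows.append((t, 0, "ball", *segment.ball[t]))
    pd.DataFrame(rows, columns=["frame", "entity", "role", "x", "y"]).to_csv(path, index=False)
    _write_meta(
        path,
        "segment",
        segment_id=segment.segment_id,
        label=int(segment.label),
        ball_holder=segment.ball_holder,
        frame_rate=segment.frame_rate,
    )
    return path


def read_segment(path: str | Path) -> AttackSegment:
    path = Path(path)
    meta = _read_meta(path, "segment")
    if not meta:
        raise ArtifactError(f"{path}: segment sidecar {_sidecar(path)} is required")
    df = pd.read_csv(path)
    frames = np.unique(df["frame"].to_numpy())
    T = frames.size

    def _grid(role: str, n: int) -> np.ndarray:
        sub = df[df["role"] == role].sort_values(["frame", "entity"], kind="stable")
        if len(sub) != T * n:
            raise ArtifactError(f"{path}: expected {T * n} {role} rows, got {len(sub)}")
        return sub[["x", "y"]].to_numpy().reshape(T, n, 2)

    return AttackSegment(
        attackers=_grid("attacker", 5),
        defenders=_grid("defender", 5),
        ball=_grid("ball", 1)[:, 0, :],
        ball_holder=np.asarray(meta["ball_holder"], dtype=int),
        label=int(meta["label"]),
        segment_id=meta.get("segment_id", path.stem),
        frame_rate=float(meta.get("frame_rate", 25.0)),
    )


def write_snapshot_sequence(seq: SnapshotSequence, path: str | Path) -> Path:
    """Snapshot matrix as CSV (rows = features, columns = snapshots)."""
    path = Path(path)
    pd.DataFrame(seq.values).to_csv(path, index=False)
    _write_meta(path, "snapshots", dt=seq.dt, feature_mode=seq.feature_mode,
                provenance=seq.provenance)
    return path


def read_snapshot_sequence(path: str | Path) -> SnapshotSequence:
    path = Path(path)
    meta = _read_meta(path, "snapshots")
    df = pd.read_csv(path)
    dt = float(meta.get("dt", 1.0))
    return SnapshotSequence(
        values=df.to_numpy(dtype=float),
        dt=dt,
        feature_mode=meta.get("feature_mode", "raw"),
        provenance=meta.get("provenance"),
    )


def write_kernel_matrix(km: KernelMatrix, path: str | Path) -> Path:
    """Kernel and distance matrices as CSVs with segment-id headers."""
    path = Path(path)
    pd.DataFrame(km.K, index=km.ids, columns=km.ids).to_csv(path)
    dpath = path.with_name(path.stem + ".dist" + path.suffix)
    pd.DataFrame(km.D, index=km.ids, columns=km.ids).to_csv(dpath)
    _write_meta(
        path,
        "kernel_matrix",
        labels=None if km.labels is None else km.labels,
        distance_file=dpath.name,
    )
    return path


def read_kernel_matrix(path: str | Path) -> KernelMatrix:
    path = Path(path)
    meta = _read_meta(path, "kernel_matrix")
    K = pd.read_csv(path, index_col=0)
    dname = meta.get("distance_file", path.stem + ".dist" + path.suffix)
    dpath = path.with_name(dname)
    if dpath.exists():
        D = pd.read_csv(dpath, index_col=0).to_numpy(dtype=float)
    else:
        k = K.to_numpy(dtype=float)
        diag = np.diag(k)
        D = np.clip(diag[:, None] + diag[None, :] - 2 * k, 0.0, None)
    labels = meta.get("labels")
    return KernelMatrix(
        ids=[str(c) for c in K.columns],
        K=K.to_numpy(dtype=float),
        D=D,
        labels=None if labels is None else np.asarray(labels, dtype=int),
    )


def read_config(path: str | Path) -> dict:
    """YAML-style key: value mapping (``key=value`` lines also accepted)."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text)
    if isinstance(data, dict):
        return data
    # fall back to plain key=value lines
    out: dict = {}
    for i, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ArtifactError(f"{path}:{i}: expected 'key=value' or a YAML mapping")
        k, v = line.split("=", 1)
        out[k.strip()] = yaml.safe_load(v.strip())
    if not out:
        raise ArtifactError(f"{path}: empty config")
    return out


def write_config(config: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config, sort_keys=True))
    return path
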