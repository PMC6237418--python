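import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from swarmdmd.features import (
    AttackSegment,
    build_snapshot_sequence,
    critical_distances,
    extract_attack_segments,
    game_distance_features,
    pairwise_distances,
    sorted_distance_snapshot,
)
from swarmdmd.schooling import TrajectoryEnsemble


def make_traj(positions, dt=0.04):
    positions = np.asarray(positions, dtype=float)
    T = positions.shape[0]
    vel = np.empty_like(positions)
    vel[:-1] = np.diff(positions, axis=0) / dt
    vel[-1] = vel[-2] if T > 1 else 0.0
    return TrajectoryEnsemble(
        dt=dt, times=dt * np.arange(T), positions=positions, velocities=vel
    )


class TestDistances:
    def test_hand_case(self):
        D = pairwise_distances([(0, 0), (1, 0), (3, 0)])
        np.testing.assert_allclose(D, [[0, 1, 3], [1, 0, 2], [3, 2, 0]])

    def test_sorted_snapshot_hand_case(self):
        # per-agent ascending rows [1,3], [1,2], [2,3] in agent order
        D = pairwise_distances([(0, 0), (1, 0), (3, 0)])
        np.testing.assert_allclose(sorted_distance_snapshot(D), [1, 3, 1, 2, 2, 3])

    @given(
        pts=hnp.arrays(
            float,
            (5, 2),
            elements=st.floats(-50, 50, allow_nan=False),
        ),
        perm_seed=st.integers(0, 10_000),
    )
    @settings(deadline=None, max_examples=100)
    def test_sorted_snapshot_permutation_invariant(self, pts, perm_seed):
        # relabelling agents permutes whole rows; the row multiset and every
        # within-row ordering are invariant
        D = pairwise_distances(pts)
        perm = np.random.default_rng(perm_seed).permutation(5)
        Dp = D[np.ix_(perm, perm)]
        rows = sorted_distance_snapshot(D).reshape(5, 4)
        rows_p = sorted_distance_snapshot(Dp).reshape(5, 4)
        canon = lambda r: r[np.lexsort(r.T[::-1])]
        np.testing.assert_allclose(canon(rows), canon(rows_p), atol=1e-9)
        assert np.all(np.diff(rows, axis=1) >= 0)


class TestSnapshotSequences:
    def test_dimensions_per_mode(self):
        pos = np.random.default_rng(0).normal(size=(5, 6, 2))
        traj = make_traj(pos)
        assert build_snapshot_sequence(traj, "sorted_distance").p == 30
        assert build_snapshot_sequence(traj, "fixed_distance").p == 15
        assert build_snapshot_sequence(traj, "cartesian").p == 12
        with pytest.raises(ValueError):
            build_snapshot_sequence(traj, "nope")

    def test_fixed_matches_sorted_when_ranks_stable(self):
        # collinear agents drifting rigidly: neighbour ranking never changes
        base = np.array([(0.0, 0.0), (1.0, 0.0), (3.0, 0.0)])
        pos = base[None, :, :] + np.linspace(0, 1, 4)[:, None, None] * np.array([0.1, 0.0])
        traj = make_traj(pos)
        srt = build_snapshot_sequence(traj, "sorted_distance").values
        fix = build_snapshot_sequence(traj, "fixed_distance").values
        assert set(np.round(srt[:, 0], 9)) >= set(np.round(fix[:, 0], 9))
        # every fixed-order distance appears in the sorted snapshot
        for t in range(4):
            assert np.allclose(np.sort(np.unique(srt[:, t])), np.sort(np.unique(fix[:, t])))

    def test_sorting_smooths_torus_series(self, torus_window):
        srt = build_snapshot_sequence(torus_window, "sorted_distance").values
        fix = build_snapshot_sequence(torus_window, "fixed_distance").values
        rough_sorted = np.abs(np.diff(srt, axis=1)).mean()
        rough_fixed = np.abs(np.diff(fix, axis=1)).mean()
        assert rough_sorted <= rough_fixed


def make_segment(attackers, defenders, holder=0, label=1):
    attackers = np.asarray(attackers, dtype=float)[None, :, :].repeat(2, axis=0)
    defenders = np.asarray(defenders, dtype=float)[None, :, :].repeat(2, axis=0)
    ball = attackers[:, holder, :]
    return AttackSegment(
        attackers=attackers,
        defenders=defenders,
        ball=ball,
        ball_holder=np.full(2, holder),
        label=label,
    )


class TestGameFeatures:
    def test_glued_defenders_degenerate(self):
        # everyone within eps of one spot: all 25 pair distances ~ eps, so
        # every critical distance collapses to the eps scale
        eps = 0.01
        rng = np.random.default_rng(0)
        att = 5.0 + eps * rng.uniform(-0.5, 0.5, size=(5, 2))
        dfd = 5.0 + eps * rng.uniform(-0.5, 0.5, size=(5, 2))
        cd = critical_distances(make_segment(att, dfd))
        assert np.all(cd <= 2 * eps)

    def test_hand_placed_frame(self):
        # brute-force oracle over all attacker-defender pairs
        att = [(0.0, 0.0), (10.0, 0.0), (0.0, 10.0), (10.0, 10.0), (5.0, 5.0)]
        dfd = [(1.0, 0.0), (10.0, 3.0), (0.0, 14.0), (12.0, 10.0), (5.0, 5.5)]
        seg = make_segment(att, dfd, holder=0)
        from scipy.spatial.distance import cdist

        D = cdist(np.asarray(att, float), np.asarray(dfd, float))
        rows = np.sort(D, axis=1)
        expected = [
            rows[0, 0],
            rows[0, 1],
            np.sort(rows[1:, 0])[-1],
            np.sort(rows[1:, 0])[-2],
        ]
        np.testing.assert_allclose(critical_distances(seg)[0], expected, atol=1e-12)

    @pytest.mark.parametrize(
        "variant,p",
        [("i", 1), ("iv", 4), ("v", 9), ("vi", 16), ("vii", 25), ("viii", 25), ("ix", 20)],
    )
    def test_variant_dimensions(self, variant, p):
        att = [(0, 0), (5, 0), (10, 0), (0, 5), (5, 5)]
        dfd = [(1, 1), (6, 1), (11, 1), (1, 6), (6, 6)]
        seq = game_distance_features(make_segment(att, dfd), variant)
        assert seq.p == p

    def test_sorted_matrix_column_order(self):
        # ball-handler first, then attackers by decreasing nearest-defender gap
        att = [(0.0, 0.0), (10.0, 0.0), (0.0, 10.0), (10.0, 10.0), (5.0, 5.0)]
        dfd = [(1.0, 0.0), (10.0, 3.0), (0.0, 14.0), (12.0, 10.0), (5.0, 5.5)]
        seg = make_segment(att, dfd, holder=1)
        M = game_distance_features(seg, "vii").values[:, 0].reshape(5, 5)
        assert M[0, 0] == pytest.approx(3.0)  # holder's nearest defender
        gaps = M[0, 1:]
        assert np.all(np.diff(gaps) <= 1e-12)  # decreasing separation
        assert np.all(np.diff(M, axis=0) >= -1e-12)  # each column sorted ascending


class TestSegmentExtraction:
    def make_game(self, T=600, cross_frame=100):
        rng = np.random.default_rng(0)
        attackers = np.full((T, 5, 2), -5.0) + 0.1 * rng.normal(size=(T, 5, 2))
        attackers[cross_frame:, :, 0] = 5.0 + 0.1 * rng.normal(size=(T - cross_frame, 5))
        defenders = attackers + 1.0
        ball = attackers[:, 0, :]
        holder = np.zeros(T, dtype=int)
        return attackers, defenders, ball, holder

    def test_segment_ends_one_second_before_shot(self):
        att, dfd, ball, holder = self.make_game()
        segs = extract_attack_segments(att, dfd, ball, holder, [500], [1])
        assert len(segs) == 1
        assert segs[0].n_frames == 475 - 100
        assert segs[0].label == 1

    def test_multiple_shots_multiple_segments(self):
        att, dfd, ball, holder = self.make_game(T=1500)
        segs = extract_attack_segments(att, dfd, ball, holder, [400, 900, 1400], [1, 0, 1])
        assert len(segs) == 3
        assert [s.label for s in segs] == [1, 0, 1]

    def test_never_crossing_yields_no_segments(self, caplog):
        T = 300
        att = np.full((T, 5, 2), -5.0)
        segs = extract_attack_segments(
            att, att + 1.0, att[:, 0, :], np.zeros(T, dtype=int), [250], [1]
        )
        assert segs == []
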