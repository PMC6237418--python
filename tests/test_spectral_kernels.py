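import numpy as np
import pytest

from swarmdmd.features import SegmentSet, SnapshotSequence
from swarmdmd.kdmd import KernelSpec, fit_kdmd
from swarmdmd.spectral_kernels import (
    kernel_and_distance_matrix,
    principal_angle_kernel,
    principal_angle_spectrum,
    subspace_products,
)
from swarmdmd.synthetic import linear_fixture
from tests.conftest import rotation


def rotation_seq(theta, tau=40, seed=0, scale=0.95, dim_offset=0, p=4, jitter=0.05):
    """Snapshot sequence of a damped rotation embedded in p dims.

    All instances start near (1, 0) so that sequences sharing the same
    rotation speed trace nearly the same spiral.
    """
    rng = np.random.default_rng(seed)
    A2 = scale * rotation(theta)
    y = np.zeros((p, tau))
    x = np.array([1.0, 0.0]) + jitter * rng.normal(size=2)
    for t in range(tau):
        y[dim_offset : dim_offset + 2, t] = x
        x = A2 @ x
    return SnapshotSequence(y, dt=1.0)


class TestSubspaceProducts:
    def test_self_products_coincide(self):
        seq = rotation_seq(0.3)
        kd = fit_kdmd(seq, KernelSpec(kind="linear"))
        AA, BB, AB = subspace_products(kd, kd)
        np.testing.assert_allclose(AA, BB, atol=1e-10)
        np.testing.assert_allclose(AA, AB, atol=1e-10)

    def test_shapes(self):
        kd_i = fit_kdmd(rotation_seq(0.3), KernelSpec(kind="linear"))
        kd_j = fit_kdmd(rotation_seq(0.7, seed=1), KernelSpec(kind="linear"))
        AA, BB, AB = subspace_products(kd_i, kd_j)
        assert AA.shape == (kd_i.rank, kd_i.rank)
        assert BB.shape == (kd_j.rank, kd_j.rank)
        assert AB.shape == (kd_i.rank, kd_j.rank)

    def test_mismatched_kernels_rejected(self):
        kd_i = fit_kdmd(rotation_seq(0.3), KernelSpec(kind="linear"))
        kd_j = fit_kdmd(rotation_seq(0.3), KernelSpec(kind="polynomial"))
        with pytest.raises(ValueError, match="kernel"):
            subspace_products(kd_i, kd_j)

    def test_linear_kernel_matches_explicit_modes(self):
        """Cross-Gram route vs directly computed mode vectors in data space."""
        seq_i = rotation_seq(0.3, seed=0)
        seq_j = rotation_seq(0.5, seed=1)
        kd_i = fit_kdmd(seq_i, KernelSpec(kind="linear"))
        kd_j = fit_kdmd(seq_j, KernelSpec(kind="linear"))

        def explicit_modes(kd, seq):
            Y = seq.values[:, :-1]
            n = Y.shape[1]
            H = np.eye(n) - np.full((n, n), 1.0 / n)
            return (Y @ H @ kd.B / np.sqrt(kd.S)) @ kd.eigenvectors

        Mi = explicit_modes(kd_i, seq_i)
        Mj = explicit_modes(kd_j, seq_j)
        AA, BB, AB = subspace_products(kd_i, kd_j)
        np.testing.assert_allclose(AA, Mi.conj().T @ Mi, atol=1e-8)
        np.testing.assert_allclose(BB, Mj.conj().T @ Mj, atol=1e-8)
        k_ij = principal_angle_kernel(AA, BB, AB)
        k_ji = principal_angle_kernel(BB, AA, AB.conj().T)
        assert k_ij == pytest.approx(k_ji, abs=1e-8)


class TestPrincipalAngles:
    def test_identical_systems_kernel_one(self):
        kd = fit_kdmd(rotation_seq(0.4), KernelSpec(kind="linear"))
        AA, BB, AB = subspace_products(kd, kd)
        spec = principal_angle_spectrum(AA, BB, AB)
        np.testing.assert_allclose(spec.values, 1.0, atol=1e-6)
        assert principal_angle_kernel(AA, BB, AB) == pytest.approx(1.0, abs=1e-6)

    def test_orthogonal_subspaces_kernel_zero(self):
        # segments varying in disjoint coordinate blocks: orthogonal in the
        # linear feature space
        kd_i = fit_kdmd(rotation_seq(0.4, dim_offset=0), KernelSpec(kind="linear"))
        kd_j = fit_kdmd(rotation_seq(0.4, seed=1, dim_offset=2), KernelSpec(kind="linear"))
        AA, BB, AB = subspace_products(kd_i, kd_j)
        spec = principal_angle_spectrum(AA, BB, AB)
        np.testing.assert_allclose(spec.values, 0.0, atol=1e-6)
        assert principal_angle_kernel(AA, BB, AB) == pytest.approx(0.0, abs=1e-6)

    def test_cosines_in_unit_interval(self):
        shared = KernelSpec(bandwidth=1.0)
        kd_i = fit_kdmd(rotation_seq(0.4), shared)
        kd_j = fit_kdmd(rotation_seq(1.2, seed=3), shared)
        AA, BB, AB = subspace_products(kd_i, kd_j)
        spec = principal_angle_spectrum(AA, BB, AB)
        assert np.all(spec.values >= 0.0) and np.all(spec.values <= 1.0)
        assert spec.values.size == min(kd_i.rank, kd_j.rank)

    def test_svd_oracle_agreement(self):
        """Principal-angle cosines via the generalized eigenproblem must
        match the standard whitened-SVD computation."""
        rng = np.random.default_rng(7)
        A = rng.normal(size=(6, 3))
        B = rng.normal(size=(6, 3))
        AA, BB, AB = A.T @ A, B.T @ B, A.T @ B
        spec = principal_angle_spectrum(
            AA.astype(complex), BB.astype(complex), AB.astype(complex)
        )
        Qa, _ = np.linalg.qr(A)
        Qb, _ = np.linalg.qr(B)
        svals = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
        np.testing.assert_allclose(spec.values, np.sort(svals)[::-1], atol=1e-8)

    def test_time_shift_invariance_on_linear_fixture(self):
        A = 0.95 * rotation(0.3)
        seq, _ = linear_fixture(A, tau=60, seed=0)
        s1 = SnapshotSequence(seq.values[:, :40], dt=1.0)
        s2 = SnapshotSequence(seq.values[:, 10:50], dt=1.0)
        kd1 = fit_kdmd(s1, KernelSpec(kind="linear"))
        kd2 = fit_kdmd(s2, KernelSpec(kind="linear"))
        AA, BB, AB = subspace_products(kd1, kd2)
        np.testing.assert_allclose(
            principal_angle_spectrum(AA, BB, AB).values, 1.0, atol=1e-6
        )


class TestKernelMatrix:
    def make_set(self, thetas, seeds, dim_offsets=None, labels=None):
        dim_offsets = dim_offsets or [0] * len(thetas)
        seqs = [
            rotation_seq(t, seed=s, dim_offset=d)
            for t, s, d in zip(thetas, seeds, dim_offsets)
        ]
        labels = labels if labels is not None else np.zeros(len(seqs), dtype=int)
        # SegmentSet requires both labels for classification but not here
        return SegmentSet(
            sequences=seqs, labels=np.asarray(labels), ids=[f"s{i}" for i in range(len(seqs))]
        )

    def test_duplicate_segment_zero_distance(self):
        sset = self.make_set([0.3, 0.3, 1.1], [0, 0, 2])
        km = kernel_and_distance_matrix(sset, KernelSpec(kind="linear"))
        assert km.D[0, 1] == pytest.approx(0.0, abs=1e-8)
        assert km.K.shape == (3, 3) and km.D.shape == (3, 3)
        np.testing.assert_allclose(np.diag(km.D), 0.0, atol=1e-8)
        np.testing.assert_allclose(km.K, km.K.T, atol=1e-8)
        assert np.all(km.D >= 0)

    def test_two_dynamical_classes_separate(self):
        # fast vs slow rotations, a few noisy instances each
        thetas = [0.2, 0.25, 0.22, 1.2, 1.25, 1.22]
        sset = self.make_set(thetas, seeds=range(6))
        km = kernel_and_distance_matrix(sset, KernelSpec())
        labels = np.array([0, 0, 0, 1, 1, 1])
        same = km.D[np.ix_(labels == 0, labels == 0)]
        within = (same.sum() + km.D[np.ix_(labels == 1, labels == 1)].sum()) / 12
        between = km.D[np.ix_(labels == 0, labels == 1)].mean()
        assert within < between

    def test_short_segments_excluded(self):
        seqs = [rotation_seq(0.3), rotation_seq(0.5, seed=1)]
        seqs.append(SnapshotSequence(np.random.default_rng(0).normal(size=(4, 2)), dt=1.0))
        sset = SegmentSet(sequences=seqs, labels=np.zeros(3, dtype=int), ids=["a", "b", "c"])
        km = kernel_and_distance_matrix(sset, KernelSpec(kind="linear"))
        assert km.ids == ["a", "b"]
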