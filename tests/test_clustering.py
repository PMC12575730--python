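import numpy as np
import pytest

from ensemblefit.clustering import (
    ClusterResult,
    RigidTransform,
    align_ensemble,
    internal_distance_rmsd_matrix,
    kmeans_cluster,
    kmedoids_cluster,
    superpose,
)
from ensemblefit.structures import Ensemble, StructureModel, ca_coordinates
from ensemblefit.synth import make_helix

from conftest import random_rotation


def quaternion_superpose_rmsd(mobile, reference):
    """Independent oracle: Horn's closed-form quaternion superposition."""
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)
    Sxx = P.T @ Q
    K = np.empty((4, 4))
    K[0, 0] = Sxx[0, 0] + Sxx[1, 1] + Sxx[2, 2]
    K[0, 1] = K[1, 0] = Sxx[1, 2] - Sxx[2, 1]
    K[0, 2] = K[2, 0] = Sxx[2, 0] - Sxx[0, 2]
    K[0, 3] = K[3, 0] = Sxx[0, 1] - Sxx[1, 0]
    K[1, 1] = Sxx[0, 0] - Sxx[1, 1] - Sxx[2, 2]
    K[1, 2] = K[2, 1] = Sxx[0, 1] + Sxx[1, 0]
    K[1, 3] = K[3, 1] = Sxx[0, 2] + Sxx[2, 0]
    K[2, 2] = -Sxx[0, 0] + Sxx[1, 1] - Sxx[2, 2]
    K[2, 3] = K[3, 2] = Sxx[1, 2] + Sxx[2, 1]
    K[3, 3] = -Sxx[0, 0] - Sxx[1, 1] + Sxx[2, 2]
    lam = np.linalg.eigvalsh(K)[-1]
    msd = (np.sum(P ** 2) + np.sum(Q ** 2) - 2 * lam) / len(P)
    return float(np.sqrt(max(msd, 0.0)))


class TestSuperpose:
    def test_identity_on_equal_sets(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        tf, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(tf.translation, 0.0, atol=1e-9)

    def test_exact_rigid_case_recovered(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(12, 3)) * 5
        Rz = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])  # 90° about z
        mobile = ref @ Rz.T + [5.0, 0.0, 0.0]
        tf, rmsd = superpose(mobile, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(tf.apply(mobile), ref, atol=1e-9)

    def test_noisy_case_matches_quaternion_oracle(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(30, 3)) * 4
        mobile = ref + rng.normal(0, 0.1, ref.shape)
        R = random_rotation(rng)
        mobile = mobile @ R.T + [1.0, 2.0, 3.0]
        _, rmsd = superpose(mobile, ref)
        assert rmsd == pytest.approx(quaternion_superpose_rmsd(mobile, ref), abs=1e-6)

    def test_degenerate_geometry_rejected(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError):
            superpose(line, line + 1.0)
        with pytest.raises(ValueError):
            superpose(line[:2], line[:2])

    def test_rigid_transform_invariants_enforced(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestAlignEnsemble:
    def test_rigid_copies_collapse_onto_reference(self, helix20):
        rng = np.random.default_rng(3)
        models = []
        for _ in range(4):
            R = random_rotation(rng)
            t = rng.normal(0, 10, 3)
            models.append(helix20.with_positions(helix20.positions @ R.T + t))
        stack = align_ensemble(Ensemble(models=models), helix20)
        ref = ca_coordinates(helix20)
        for aligned in stack:
            np.testing.assert_allclose(aligned, ref, atol=1e-6)

    def test_single_model_stack(self, helix20):
        stack = align_ensemble(Ensemble(models=[helix20.copy()]), helix20)
        assert stack.shape == (1, 20, 3)

    def test_alignment_preserves_internal_distances(self, helix20):
        rng = np.random.default_rng(4)
        noisy = helix20.with_positions(helix20.positions + rng.normal(0, 0.5, (helix20.n_atoms, 3)))
        ens = Ensemble(models=[noisy])
        stack = align_ensemble(ens, helix20)
        from scipy.spatial.distance import pdist
        before = pdist(ca_coordinates(noisy))
        after = pdist(stack[0])
        np.testing.assert_allclose(after, before, atol=1e-9)


class TestKMeans:
    def _blob_stack(self, rng, n_per=50, sep=100.0, noise=0.1, n_res=10):
        centers = [np.zeros((n_res, 3)), np.full((n_res, 3), sep / np.sqrt(3))]
        stack, labels = [], []
        for c, center in enumerate(centers):
            for _ in range(n_per):
                stack.append(center + rng.normal(0, noise, (n_res, 3)))
                labels.append(c)
        return np.array(stack), np.array(labels)

    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(5)
        stack, truth = self._blob_stack(rng)
        result = kmeans_cluster(stack, k=2, seed=0)
        # oracle: nearest generating center; compare partitions via Rand index
        same = result.labels[:, None] == result.labels[None, :]
        same_truth = truth[:, None] == truth[None, :]
        rand = (same == same_truth).mean()
        assert rand == 1.0

    def test_k_one_representative_is_nearest_to_mean(self):
        rng = np.random.default_rng(6)
        stack = rng.normal(size=(20, 8, 3))
        result = kmeans_cluster(stack, k=1, seed=0)
        assert set(result.labels.tolist()) == {0}
        X = stack.reshape(20, -1)
        expected = int(np.argmin(np.linalg.norm(X - X.mean(axis=0), axis=1)))
        assert result.representative_indices == [expected]

    def test_k_equals_n(self):
        rng = np.random.default_rng(7)
        stack = rng.normal(size=(6, 5, 3)) * 10
        result = kmeans_cluster(stack, k=6, seed=0)
        assert sorted(result.representative_indices) == list(range(6))
        assert len(set(result.labels.tolist())) == 6

    def test_invalid_k_rejected(self):
        stack = np.zeros((4, 5, 3))
        with pytest.raises(ValueError):
            kmeans_cluster(stack, k=5, seed=0)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(8)
        stack, _ = self._blob_stack(rng, n_per=20)
        a = kmeans_cluster(stack, k=4, seed=3)
        b = kmeans_cluster(stack, k=4, seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.representative_indices == b.representative_indices

    def test_wcss_no_worse_than_generating_assignment(self):
        rng = np.random.default_rng(9)
        stack, truth = self._blob_stack(rng, n_per=30, sep=50.0, noise=0.5)
        X = stack.reshape(len(stack), -1)
        result = kmeans_cluster(stack, k=2, seed=0)
        wcss_gen = sum(
            np.sum((X[truth == c] - X[truth == c].mean(axis=0)) ** 2)
            for c in (0, 1)
        )
        assert result.inertia <= wcss_gen + 1e-6


class TestDrmsdMatrix:
    def test_identical_models_zero_matrix(self, helix20):
        ens = Ensemble(models=[helix20.copy() for _ in range(4)])
        D = internal_distance_rmsd_matrix(ens)
        np.testing.assert_allclose(D, 0.0, atol=1e-12)

    def test_rigid_transform_gives_zero_entry(self, helix20):
        rng = np.random.default_rng(10)
        R = random_rotation(rng)
        moved = helix20.with_positions(helix20.positions @ R.T + [4.0, 5.0, 6.0])
        D = internal_distance_rmsd_matrix(Ensemble(models=[helix20, moved]))
        assert D[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_three_residue_hand_computation(self):
        def toy(gaps):
            n = len(gaps) + 1
            x = np.concatenate([[0.0], np.cumsum(gaps)])
            return StructureModel(
                names=["CA"] * n, elements=["C"] * n,
                residue_indices=list(range(1, n + 1)),
                residue_names=["GLY"] * n, chain_ids=["A"] * n,
                positions=np.column_stack([x, np.zeros(n), np.zeros(n)]),
            )

        a = toy([3.8, 3.8])               # pair distances 3.8, 3.8, 7.6
        b = toy([3.8, 4.8])               # pair distances 3.8, 4.8, 8.6
        D = internal_distance_rmsd_matrix(Ensemble(models=[a, b]))
        assert D[0, 1] == pytest.approx(np.sqrt((0 + 1 + 1) / 3), abs=1e-9)

    def test_symmetry_and_zero_diagonal(self, small_system):
        ens = Ensemble(models=small_system.ensemble.models[:8])
        D = internal_distance_rmsd_matrix(ens)
        np.testing.assert_array_equal(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0.0, atol=1e-12)


class TestKMedoids:
    def _block_matrix(self, sizes, within=0.5, between=50.0, seed=0):
        n = sum(sizes)
        rng = np.random.default_rng(seed)
        labels = np.repeat(np.arange(len(sizes)), sizes)
        D = np.where(labels[:, None] == labels[None, :], within, between)
        D = D + rng.uniform(0, 0.01, (n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        return D, labels

    def test_two_blocks_recovered(self):
        D, truth = self._block_matrix([6, 6])
        result = kmedoids_cluster(D, k=2, seed=0)
        assert set(result.labels[:6].tolist()) != set(result.labels[6:].tolist())
        assert len(set(result.labels.tolist())) == 2

    def test_matches_exhaustive_oracle_small_n(self):
        from itertools import combinations

        D, _ = self._block_matrix([5, 5], within=2.0, between=9.0, seed=1)
        result = kmedoids_cluster(D, k=2, seed=0)
        cost = np.min(D[:, result.representative_indices], axis=1).sum()
        best = min(np.minimum(D[:, i], D[:, j]).sum()
                   for i, j in combinations(range(10), 2))
        assert cost == pytest.approx(best, abs=1e-9)

    def test_k_equals_n_zero_cost(self):
        D, _ = self._block_matrix([3, 3])
        result = kmedoids_cluster(D, k=6, seed=0)
        assert sorted(result.representative_indices) == list(range(6))

    def test_all_zero_matrix_single_medoid(self):
        D = np.zeros((5, 5))
        result = kmedoids_cluster(D, k=1, seed=0)
        assert len(result.representative_indices) == 1
        assert set(result.labels.tolist()) == {0}

    def test_invalid_matrices_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])  # asymmetric
        with pytest.raises(ValueError):
            kmedoids_cluster(D, k=1, seed=0)
        D = -np.ones((3, 3))
        with pytest.raises(ValueError):
            kmedoids_cluster(D, k=1, seed=0)


class TestClusterResult:
    def test_representative_must_belong_to_cluster(self):
        with pytest.raises(ValueError):
            ClusterResult(labels=np.array([0, 0, 1, 1]), k=2,
                          representative_indices=[0, 1], method="kmeans_cartesian",
                          seed=0)

    def test_every_cluster_nonempty(self):
        with pytest.raises(ValueError):
            ClusterResult(labels=np.array([0, 0, 0]), k=2,
                          representative_indices=[0, 0], method="kmeans_cartesian",
                          seed=0)
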