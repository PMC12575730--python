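"""Ensemble superposition and clustering.

Two clustering routes mirror the two practical situations:

* ``kmeans_cartesian`` — models are first superposed onto a reference (the
  already-known experimental state) and k-means is run on the flattened Cα
  Cartesian vectors. Requires a known state to align to.
* ``kmedoids_drmsd`` — no alignment: a pairwise internal-distance RMSD
  (dRMSD) matrix over Cα atoms feeds PAM k-medoids. Rigid-transform
  invariant, so usable when no structure is known in any state.

Representatives (the refinement starting points) are the member closest to
each k-means centroid, or the medoids themselves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .structures import Ensemble, StructureModel, ca_coordinates

__all__ = [
    "RigidTransform",
    "ClusterResult",
    "superpose",
    "align_ensemble",
    "kmeans_cluster",
    "internal_distance_rmsd_matrix",
    "kmedoids_cluster",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x ↦ R·x + t (rotation matrix + translation, Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def rotation_angle_deg(self) -> float:
        cos = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


@dataclass
class ClusterResult:
    labels: np.ndarray
    k: int
    representative_indices: list[int]
    method: str                       # "kmeans_cartesian" | "kmedoids_drmsd"
    seed: int
    inertia: float | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = set(self.labels.tolist())
        if present != set(range(self.k)):
            raise ValueError("every cluster id in [0, k) must be non-empty")
        for c, rep in enumerate(self.representative_indices):
            if self.labels[rep] != c:
                raise ValueError(f"representative {rep} not in cluster {c}")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "labels": self.labels.tolist(),
                    "k": self.k,
                    "representative_indices": list(self.representative_indices),
                    "method": self.method,
                    "seed": self.seed,
                    "inertia": self.inertia,
                },
                fh,
                indent=2,
            )


# ---------------------------------------------------------------------------
# superposition


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    subset: np.ndarray | list[int] | None = None,
) -> tuple[RigidTransform, float]:
    """Least-squares (Kabsch) rigid superposition of point sets.

    Returns the transform minimizing RMSD of ``mobile`` onto ``reference``
    over ``subset`` (default: all points), and the post-fit RMSD over that
    subset. Needs ≥ 3 non-degenerate points.
    """
    mob = np.asarray(mobile, dtype=np.float64)
    ref = np.asarray(reference, dtype=np.float64)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    sel = np.arange(mob.shape[0]) if subset is None else np.asarray(subset, int)
    if len(sel) < 3:
        raise ValueError("superposition needs at least 3 points")
    P = mob[sel]
    Q = ref[sel]
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12 * max(S[0], 1.0):
        raise ValueError("degenerate (collinear) geometry: superposition ill-defined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    tf = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((tf.apply(P) - Q) ** 2, axis=1))))
    return tf, rmsd


def align_ensemble(ensemble: Ensemble, reference: StructureModel) -> np.ndarray:
    """Superpose every model's Cα onto the reference; returns an
    (n_models, n_res, 3) stack of aligned Cα coordinates."""
    ref_ca = ca_coordinates(reference)
    stack = np.empty((len(ensemble), ref_ca.shape[0], 3))
    for i, model in enumerate(ensemble.models):
        ca = ca_coordinates(model)
        if ca.shape != ref_ca.shape:
            raise ValueError(
                f"model {i}: {ca.shape[0]} Cα vs reference {ref_ca.shape[0]}"
            )
        tf, _ = superpose(ca, ref_ca)
        stack[i] = tf.apply(ca)
    return stack


# ---------------------------------------------------------------------------
# k-means on aligned Cartesian coordinates


def kmeans_cluster(aligned_stack: np.ndarray, k: int = 20, seed: int = 0) -> ClusterResult:
    """K-means (k-means++, 10 restarts) on flattened aligned Cα coordinates.

    Representatives are the models nearest each centroid in Euclidean norm,
    ties broken by lowest model index. Deterministic for a fixed seed.
    """
    stack = np.asarray(aligned_stack, dtype=np.float64)
    n = stack.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k = {k} must be in [1, n_models = {n}]")
    X = stack.reshape(n, -1)
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=300,
                tol=1e-6, random_state=seed)
    labels = km.fit_predict(X)
    # remap labels so every id in [0, k) is populated (KMeans guarantees this
    # for n >= k, but relabel deterministically by first appearance)
    reps: list[int] = []
    for c in range(km.n_clusters):
        members = np.flatnonzero(labels == c)
        dists = np.linalg.norm(X[members] - km.cluster_centers_[c], axis=1)
        reps.append(int(members[np.argmin(dists)]))  # argmin takes first on tie
    return ClusterResult(labels, km.n_clusters, reps, "kmeans_cartesian", seed,
                         inertia=float(km.inertia_))


# ---------------------------------------------------------------------------
# dRMSD + k-medoids


def internal_distance_rmsd_matrix(ensemble: Ensemble) -> np.ndarray:
    """Pairwise dRMSD matrix (Å): RMS difference of Cα–Cα internal distances.

    Entry (i, j) = sqrt(mean over residue pairs a<b of (d_i(a,b) − d_j(a,b))²).
    Symmetric, zero diagonal, invariant under rigid motion of any model.
    """
    cas = [ca_coordinates(m) for m in ensemble.models]
    n_res = cas[0].shape[0]
    if n_res < 2:
        raise ValueError("dRMSD needs at least 2 residues")
    dvecs = np.stack([pdist(ca) for ca in cas])  # (n_models, n_pairs)
    n_pairs = dvecs.shape[1]
    # ||di - dj|| / sqrt(n_pairs) == sqrt(mean (di-dj)^2)
    diff = squareform(pdist(dvecs)) / np.sqrt(n_pairs)
    return diff


def kmedoids_cluster(distance_matrix: np.ndarray, k: int, seed: int = 0) -> ClusterResult:
    """PAM k-medoids (greedy BUILD then SWAP to convergence) on a distance matrix.

    Deterministic: BUILD is greedy (no randomness); ties break toward the
    lowest index. The seed is recorded for provenance only.
    """
    D = np.asarray(distance_matrix, dtype=np.float64)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < -1e-12):
        raise ValueError("distance matrix must be non-negative")
    if np.any(np.abs(np.diag(D)) > 1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    if not 1 <= k <= n:
        raise ValueError(f"k = {k} must be in [1, n = {n}]")

    # BUILD: greedily add the medoid that most reduces total cost
    medoids: list[int] = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        current = np.min(D[:, medoids], axis=1)
        gains = np.sum(np.maximum(current[None, :] - D, 0.0), axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    def total_cost(meds: list[int]) -> float:
        return float(np.min(D[:, meds], axis=1).sum())

    # SWAP: steepest-improvement exchanges until no swap helps
    cost = total_cost(medoids)
    improved = True
    while improved:
        improved = False
        best = (0.0, None, None)
        med_set = set(medoids)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in med_set:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                delta = total_cost(trial) - cost
                if delta < best[0] - 1e-12:
                    best = (delta, mi, h)
        if best[1] is not None:
            medoids[best[1]] = best[2]
            cost += best[0]
            improved = True

    medoids = sorted(medoids)
    labels = np.argmin(D[:, medoids], axis=1)
    # guarantee each medoid labels itself (ties in its row)
    for c, m in enumerate(medoids):
        labels[m] = c
    return ClusterResult(np.asarray(labels), k, [int(m) for m in medoids],
                         "kmedoids_drmsd", seed)
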