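"""Synthetic two-state test systems.

The generator emulates the statistical structure the pipeline assumes in
real use: a protein known experimentally in one conformation (state A, a
straight α-helix), a cryo-EM density solved in another (state B, the same
helix kinked partway along — the single-helix analogue of an activation-type
transition), and an ensemble of imperfect predicted models scattered around
both states with per-atom Gaussian coordinate noise, optionally salted with
coordinate-scrambled decoys for filter testing. Everything is deterministic
under a seed, so every pipeline stage is testable without downloads.

The toy protein is poly-alanine (backbone N, CA, C, O plus CB): large enough
to exercise clash and restraint logic, small enough for seconds-scale runs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .maps import DensityMap, SpreadConfig, gaussian_blur, simulate_map, write_map
from .structures import Ensemble, StructureModel, Trajectory, write_structure, write_trajectory

__all__ = [
    "ToySystemConfig",
    "SyntheticSystem",
    "make_helix",
    "make_kinked_helix",
    "sample_ensemble",
    "make_toy_system",
    "write_system",
]

# ideal backbone internal coordinates (lengths Å, angles deg)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O, _A_N_CA_CB = 120.8, 110.5
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0
_T_CB = -122.55  # improper C-N-CA-CB for L-amino acids


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position d with |cd| = bond, ∠(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(angle), np.sin(angle) * np.cos(torsion), np.sin(angle) * np.sin(torsion)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_helix(n_res: int = 40) -> StructureModel:
    """Ideal poly-ALA α-helix (φ = −57°, ψ = −47°): ~100°/residue twist,
    ~1.5 Å rise, Cα–Cα ≈ 3.8 Å."""
    if n_res < 2:
        raise ValueError("helix needs at least 2 residues")
    N, CA, C, O, CB = [], [], [], [], []
    N.append(np.zeros(3))
    CA.append(np.array([_B_N_CA, 0.0, 0.0]))
    ang = np.radians(_A_N_CA_C)
    C.append(CA[0] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0]))
    for i in range(1, n_res):
        N.append(_place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, _PSI))
        CA.append(_place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, _OMEGA))
        C.append(_place_atom(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, _PHI))
    for i in range(n_res):
        # carbonyl O anti to the next N (torsion ψ + 180 about CA–C)
        O.append(_place_atom(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, _PSI + 180.0))
        CB.append(_place_atom(C[i], N[i], CA[i], _B_CA_CB, _A_N_CA_CB, _T_CB))

    names, elements, ridx, rnames, chains, pos = [], [], [], [], [], []
    for i in range(n_res):
        for name, el, xyz in (("N", "N", N[i]), ("CA", "C", CA[i]),
                              ("C", "C", C[i]), ("O", "O", O[i]),
                              ("CB", "C", CB[i])):
            names.append(name)
            elements.append(el)
            ridx.append(i + 1)
            rnames.append("ALA")
            chains.append("A")
            pos.append(xyz)
    return StructureModel(names, elements, ridx, rnames, chains,
                          np.array(pos, dtype=np.float64))


def _helix_axis(model: StructureModel) -> np.ndarray:
    ca = model.positions[model.ca_mask]
    steps = np.diff(ca, axis=0)
    axis = steps.mean(axis=0)
    return axis / np.linalg.norm(axis)


def make_kinked_helix(
    n_res: int = 40, kink_residue: int = 20, kink_angle: float = 40.0
) -> StructureModel:
    """Helix bent by ``kink_angle`` degrees at ``kink_residue``.

    Residues beyond the kink rotate rigidly about an axis through the kink
    Cα perpendicular to the helix axis; the downstream segment is then
    translated along the crossing peptide bond so that bond's length is
    exactly preserved. Pre-kink residues are untouched.
    """
    helix = make_helix(n_res)
    if not 1 < kink_residue < n_res:
        raise ValueError("kink residue must be strictly inside the chain")
    if kink_angle == 0:
        return helix

    axis_h = _helix_axis(helix)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis_h)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    rot_axis = np.cross(axis_h, ref)
    rot_axis /= np.linalg.norm(rot_axis)

    theta = np.radians(kink_angle)
    K = np.array([[0, -rot_axis[2], rot_axis[1]],
                  [rot_axis[2], 0, -rot_axis[0]],
                  [-rot_axis[1], rot_axis[0], 0]])
    R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)

    pos = helix.positions.copy()
    downstream = helix.residue_indices > kink_residue
    kink_ca = None
    c_kink = None
    n_next = None
    for i in range(helix.n_atoms):
        if helix.residue_indices[i] == kink_residue and helix.names[i] == "CA":
            kink_ca = pos[i].copy()
        if helix.residue_indices[i] == kink_residue and helix.names[i] == "C":
            c_kink = i
        if helix.residue_indices[i] == kink_residue + 1 and helix.names[i] == "N":
            n_next = i
    bond0 = float(np.linalg.norm(pos[n_next] - pos[c_kink]))
    pos[downstream] = (pos[downstream] - kink_ca) @ R.T + kink_ca
    # restore the crossing peptide bond length exactly
    vec = pos[n_next] - pos[c_kink]
    L = float(np.linalg.norm(vec))
    pos[downstream] += (bond0 - L) * vec / L
    return helix.with_positions(pos)


# ---------------------------------------------------------------------------
# ensemble sampling


def sample_ensemble(
    states: list[StructureModel],
    weights: list[float],
    n: int,
    noise_sigma: float = 0.5,
    seed: int = 0,
    decoy_fraction: float = 0.0,
) -> tuple[Ensemble, list[str]]:
    """Sample an ensemble around the given states.

    Each model is a weighted-random state plus i.i.d. per-atom Gaussian
    noise (σ = ``noise_sigma`` Å). With probability ``decoy_fraction`` a
    model is instead a coordinate-scrambled decoy (atom positions permuted,
    destroying all bonded geometry) used to exercise the quality filter.
    Labels are the state index as a letter ('A', 'B', ...) or 'decoy'.
    """
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("state weights must sum to 1")
    if len(weights) != len(states):
        raise ValueError("one weight per state required")
    rng = np.random.default_rng(seed)
    models, labels = [], []
    for _ in range(n):
        if decoy_fraction > 0 and rng.random() < decoy_fraction:
            base = states[rng.integers(len(states))]
            perm = rng.permutation(base.n_atoms)
            noisy = base.positions[perm] + rng.normal(0, noise_sigma,
                                                      (base.n_atoms, 3))
            models.append(base.with_positions(noisy))
            labels.append("decoy")
            continue
        s = int(rng.choice(len(states), p=weights))
        base = states[s]
        noisy = base.positions + rng.normal(0, noise_sigma, (base.n_atoms, 3))
        models.append(base.with_positions(noisy))
        labels.append(chr(ord("A") + s))
    return Ensemble(models=models, source_labels=[f"model_{i:04d}" for i in range(n)]), labels


# ---------------------------------------------------------------------------
# whole-system assembly


@dataclass
class ToySystemConfig:
    n_res: int = 40
    kink_residue: int = 20
    kink_angle: float = 40.0          # degrees
    ensemble_size: int = 200
    state_b_fraction: float = 0.2     # fraction of models near the target state
    noise_sigma: float = 0.5          # Å per-atom coordinate noise
    decoy_fraction: float = 0.0
    map_voxel: float = 1.0            # Å
    map_sigma: float = 1.5            # Å atom spreading width
    blur_sigma: float = 1.0           # Å extra blur on the target map
    map_pad: float = 8.0              # Å grid padding around the model
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 < self.kink_residue < self.n_res:
            raise ValueError("kink_residue must be strictly inside the chain")
        for name in ("state_b_fraction", "decoy_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SyntheticSystem:
    known_model: StructureModel        # state A (the "already solved" state)
    target_model: StructureModel       # state B ground truth
    target_map: DensityMap             # simulated from B, blurred
    target_map_sharp: DensityMap       # simulated from B, pre-blur
    ensemble: Ensemble
    generating_labels: list[str]
    config: ToySystemConfig


def make_toy_system(config: ToySystemConfig | None = None) -> SyntheticSystem:
    """Assemble the full two-state system (models, map, ensemble); seeded."""
    cfg = config or ToySystemConfig()
    known = make_helix(cfg.n_res)
    target = make_kinked_helix(cfg.n_res, cfg.kink_residue, cfg.kink_angle)
    spread = SpreadConfig(sigma=cfg.map_sigma)
    sharp = simulate_map(target, voxel_size=cfg.map_voxel, spread=spread,
                         pad=cfg.map_pad)
    blurred = gaussian_blur(sharp, cfg.blur_sigma) if cfg.blur_sigma > 0 else sharp.copy()
    ensemble, labels = sample_ensemble(
        [known, target],
        [1.0 - cfg.state_b_fraction, cfg.state_b_fraction],
        cfg.ensemble_size,
        noise_sigma=cfg.noise_sigma,
        seed=cfg.seed,
        decoy_fraction=cfg.decoy_fraction,
    )
    return SyntheticSystem(known, target, blurred, sharp, ensemble, labels, cfg)


def write_system(system: SyntheticSystem, out_dir: str) -> None:
    """Write the system as plain files: known.pdb, target.pdb, target.mrc,
    target_blur.mrc, ensemble.pdb (multi-model), labels.csv, config.yaml."""
    os.makedirs(out_dir, exist_ok=True)
    write_structure(system.known_model, os.path.join(out_dir, "known.pdb"))
    write_structure(system.target_model, os.path.join(out_dir, "target.pdb"))
    write_map(system.target_map_sharp, os.path.join(out_dir, "target.mrc"))
    write_map(system.target_map, os.path.join(out_dir, "target_blur.mrc"))
    write_trajectory(Trajectory(frames=system.ensemble.models),
                     os.path.join(out_dir, "ensemble.pdb"))
    with open(os.path.join(out_dir, "labels.csv"), "w") as fh:
        fh.write("model_label,state\n")
        for lab, st in zip(system.ensemble.labels(), system.generating_labels):
            fh.write(f"{lab},{st}\n")
    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump(asdict(system.config), fh)
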