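"""Desk-scale density-guided refinement.

A full MD engine is out of scope here; what this module reproduces is the
*protocol logic* of density-guided simulation: stereochemical restraints
keep the model chemically sensible while a bias force proportional to the
local density gradient pulls atoms toward the target map, the bias strength
grows adaptively over the run, and the run terminates automatically once
per-step atomic displacements become too large for stable integration — the
observable consequence of "forces too large for the time step". The
integrator is damped steepest descent on harmonic bond/angle restraints
whose reference values are measured from the starting model. No
secondary-structure restraints are applied, so conformational transitions
remain possible. Externally produced trajectories (e.g. from a real MD
engine) can be imported via :func:`ensemblefit.structures.read_trajectory`
and scored with :func:`score_trajectory` exactly like internal ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._chem import bonded_pairs
from .maps import DensityMap, MapBoundaryError, SpreadConfig, pad_map, value_and_gradient
from .quality import FallbackScoreConfig, fallback_geometry_score
from .rigidfit import CCConfig, model_map_cc
from .selection import ScoreSeries
from .structures import StructureModel, Trajectory

__all__ = [
    "RefineConfig",
    "RestraintTopology",
    "build_restraints",
    "restraint_energy_forces",
    "density_bias_force",
    "refine_model",
    "score_trajectory",
]


@dataclass
class RefineConfig:
    """Parameters of the density-guided descent.

    ``k_density`` is the initial bias force factor (energy per unit density
    gradient); adaptive scaling multiplies it by ``adaptive_growth`` every
    ``growth_interval`` bias applications, so the pull strengthens steadily
    until the displacement limit trips the automatic termination.
    """

    k_density: float = 1000.0
    apply_every: int = 2                 # bias force applied every N steps
    adaptive_growth: float = 1.005       # multiplicative growth factor
    growth_interval: int = 10            # bias applications per growth step
    step_size: float = 1e-5              # Å per unit force (descent damping)
    max_steps: int = 8000
    frame_stride: int = 80               # store every n-th step as a frame
    displacement_limit: float = 0.5      # Å per step; exceeding it terminates
    k_bond: float = 10000.0              # energy/Å² harmonic bond constant
    k_angle: float = 2000.0              # energy/rad² harmonic angle constant
    relax_steps: int = 500               # restraint-only preparation steps
    seed: int = 0                        # recorded for provenance

    def __post_init__(self) -> None:
        if self.apply_every < 1:
            raise ValueError("apply_every must be >= 1")
        if self.adaptive_growth < 1.0:
            raise ValueError("adaptive_growth must be >= 1")
        if self.displacement_limit <= 0:
            raise ValueError("displacement_limit must be positive")


@dataclass
class RestraintTopology:
    """Harmonic restraint network derived once from the starting model."""

    bond_indices: np.ndarray      # (n_bonds, 2) atom indices
    bond_lengths: np.ndarray      # (n_bonds,) reference lengths, Å
    angle_indices: np.ndarray     # (n_angles, 3) atom indices, center second
    angle_values: np.ndarray      # (n_angles,) reference angles, rad

    def __post_init__(self) -> None:
        if len(self.bond_lengths) and not (
            np.all(self.bond_lengths > 0.8) and np.all(self.bond_lengths < 2.2)
        ):
            raise ValueError("bond reference lengths must lie in (0.8, 2.2) Å")


def build_restraints(model: StructureModel) -> RestraintTopology:
    """Bonds from standard connectivity (+ peptide bonds) and angles from
    bonded triples; reference values measured from the input coordinates."""
    bonds = bonded_pairs(model)
    bidx = np.array(bonds, dtype=int).reshape(-1, 2)
    pos = model.positions
    if len(bonds):
        blen = np.linalg.norm(pos[bidx[:, 0]] - pos[bidx[:, 1]], axis=1)
        # noisy input coordinates can measure a bond outside the chemically
        # plausible window; those references revert to the template ideal
        bad = (blen <= 0.8) | (blen >= 2.2)
        if bad.any():
            ideals = np.array([
                FallbackScoreConfig.ideal_length(model.names[i], model.names[j])
                for i, j in bidx[bad]
            ])
            blen = blen.copy()
            blen[bad] = ideals
    else:
        blen = np.empty(0)

    adj: dict[int, list[int]] = {}
    for i, j in bonds:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    triples = []
    for center, nbrs in sorted(adj.items()):
        nb = sorted(nbrs)
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                triples.append((nb[a], center, nb[b]))
    aidx = np.array(triples, dtype=int).reshape(-1, 3)
    if len(triples):
        u = pos[aidx[:, 0]] - pos[aidx[:, 1]]
        w = pos[aidx[:, 2]] - pos[aidx[:, 1]]
        cos = np.sum(u * w, axis=1) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(w, axis=1)
        )
        aval = np.arccos(np.clip(cos, -1.0, 1.0))
    else:
        aval = np.empty(0)
    return RestraintTopology(bidx, blen, aidx, aval)


def restraint_energy_forces(
    positions: np.ndarray, topo: RestraintTopology, k_bond: float, k_angle: float
) -> tuple[float, np.ndarray]:
    """Harmonic restraint energy and per-atom forces (−∂E/∂x)."""
    forces = np.zeros_like(positions)
    energy = 0.0

    if len(topo.bond_lengths):
        i, j = topo.bond_indices[:, 0], topo.bond_indices[:, 1]
        vec = positions[i] - positions[j]
        d = np.linalg.norm(vec, axis=1)
        dev = d - topo.bond_lengths
        energy += float(k_bond * np.sum(dev ** 2))
        f = (-2.0 * k_bond * dev / np.maximum(d, 1e-12))[:, None] * vec
        np.add.at(forces, i, f)
        np.add.at(forces, j, -f)

    if len(topo.angle_values):
        ai, aj, ak = (topo.angle_indices[:, c] for c in range(3))
        u = positions[ai] - positions[aj]
        w = positions[ak] - positions[aj]
        nu = np.linalg.norm(u, axis=1)
        nw = np.linalg.norm(w, axis=1)
        uh = u / nu[:, None]
        wh = w / nw[:, None]
        cos = np.clip(np.sum(uh * wh, axis=1), -1.0, 1.0)
        theta = np.arccos(cos)
        sin = np.sqrt(np.maximum(1.0 - cos ** 2, 1e-12))
        dev = theta - topo.angle_values
        energy += float(k_angle * np.sum(dev ** 2))
        dE = 2.0 * k_angle * dev
        gi = -(wh - cos[:, None] * uh) / (nu * sin)[:, None]
        gk = -(uh - cos[:, None] * wh) / (nw * sin)[:, None]
        fi = -dE[:, None] * gi
        fk = -dE[:, None] * gk
        np.add.at(forces, ai, fi)
        np.add.at(forces, ak, fk)
        np.add.at(forces, aj, -(fi + fk))

    return energy, forces


def density_bias_force(
    model: StructureModel, target: DensityMap, k: float
) -> np.ndarray:
    """Bias force pulling atoms up the density gradient: k·∇ρ at each atom.

    This is the uniform-weight point-sampling limit of the similarity
    gradient; it vanishes where the map is flat.
    """
    _, grad = value_and_gradient(target, model.positions)
    return k * grad


def refine_model(
    model: StructureModel,
    target: DensityMap,
    restraints: RestraintTopology | None = None,
    config: RefineConfig | None = None,
) -> Trajectory:
    """Run density-guided steepest descent; returns the stored trajectory.

    Frames are stored every ``frame_stride`` steps (plus the final state).
    The trajectory's metadata records the termination reason
    (``max_steps`` or ``displacement_limit``), the per-interval bias factor
    history, and the stored frame step indices. Fully deterministic.
    """
    config = config or RefineConfig()
    topo = restraints if restraints is not None else build_restraints(model)
    # pad the target so moving atoms stay interpolable, and normalize to
    # unit peak so k_density means the same thing for any map amplitude
    # (map similarity itself is amplitude-invariant)
    work_map = pad_map(target, pad=8.0)
    peak = float(np.abs(work_map.grid).max())
    if peak == 0:
        raise ValueError("target map is empty")
    work_map.grid = work_map.grid / peak

    pos = model.positions.copy()
    # preparation: restraint-only minimization with a trust-radius cap, so
    # strained input geometry (noisy models) is settled before dynamics
    for _ in range(config.relax_steps):
        _, forces = restraint_energy_forces(pos, topo, config.k_bond, config.k_angle)
        disp = config.step_size * forces
        max_disp = float(np.max(np.linalg.norm(disp, axis=1)))
        if max_disp > 0.1:
            disp *= 0.1 / max_disp
        pos = pos + disp

    k = config.k_density
    k_history = [k]
    frames = [model.with_positions(pos)]
    frame_steps = [0]
    bias_applications = 0
    termination = "max_steps"
    step = 0
    for step in range(1, config.max_steps + 1):
        _, forces = restraint_energy_forces(pos, topo, config.k_bond, config.k_angle)
        if step % config.apply_every == 0:
            try:
                forces = forces + density_bias_force(
                    model.with_positions(pos), work_map, k
                )
            except MapBoundaryError:
                termination = "left_map"
                break
            bias_applications += 1
            if bias_applications % config.growth_interval == 0:
                k *= config.adaptive_growth
                k_history.append(k)
        disp = config.step_size * forces
        max_disp = float(np.max(np.linalg.norm(disp, axis=1)))
        if max_disp > config.displacement_limit:
            if step == 1:
                raise ValueError(
                    f"displacement {max_disp:.2f} Å exceeds the limit at the "
                    "first step: reduce step_size or k_density"
                )
            termination = "displacement_limit"
            break
        pos = pos + disp
        if step % config.frame_stride == 0:
            frames.append(model.with_positions(pos))
            frame_steps.append(step)

    if frame_steps[-1] != step and termination != "displacement_limit":
        frames.append(model.with_positions(pos))
        frame_steps.append(step)

    return Trajectory(
        frames=frames,
        frame_interval=config.frame_stride,
        metadata={
            "termination_reason": termination,
            "k_history": k_history,
            "final_k": k,
            "n_steps": step,
            "frame_steps": frame_steps,
            "seed": config.seed,
        },
    )


def score_trajectory(
    traj: Trajectory,
    target: DensityMap,
    spread: SpreadConfig | None = None,
    geometry_scorer=None,
    trajectory_id: str = "traj",
    cc_config: CCConfig | None = None,
) -> ScoreSeries:
    """Per-frame map cross-correlation and scaled geometry score.

    ``geometry_scorer`` maps a StructureModel to a scaled score (more
    negative = better); the default is the internal fallback scorer.
    """
    if geometry_scorer is None:
        fallback_cfg = FallbackScoreConfig()

        def geometry_scorer(m: StructureModel) -> float:
            return fallback_geometry_score(m, fallback_cfg).scaled

    frame_idx = traj.metadata.get("frame_steps") or list(range(len(traj.frames)))
    cc = [model_map_cc(f, target, spread, cc_config) for f in traj.frames]
    geo = [float(geometry_scorer(f)) for f in traj.frames]
    return ScoreSeries(
        frame_indices=list(frame_idx),
        cc=cc,
        geometry_scaled=geo,
        trajectory_id=trajectory_id,
    )
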