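import numpy as np
import pytest

from ensemblefit.maps import SpreadConfig, gaussian_blur, pad_map, simulate_map, value_and_gradient
from ensemblefit.metrics import ca_rmsd
from ensemblefit.refine import (
    RefineConfig,
    RestraintTopology,
    build_restraints,
    density_bias_force,
    refine_model,
    restraint_energy_forces,
    score_trajectory,
)
from ensemblefit.rigidfit import model_map_cc
from ensemblefit.structures import StructureModel
from ensemblefit.synth import make_helix


def _two_ala():
    h = make_helix(2)
    return h


class TestBuildRestraints:
    def test_peptide_bond_appears_exactly_once(self):
        topo = build_restraints(_two_ala())
        model = _two_ala()
        peptide = [
            (i, j) for i, j in topo.bond_indices
            if {model.names[i], model.names[j]} == {"C", "N"}
            and model.residue_indices[i] != model.residue_indices[j]
        ]
        assert len(peptide) == 1

    def test_single_residue_has_no_inter_residue_bonds(self):
        gly = StructureModel(
            names=["N", "CA", "C", "O"], elements=["N", "C", "C", "O"],
            residue_indices=[1] * 4, residue_names=["GLY"] * 4,
            chain_ids=["A"] * 4,
            positions=np.array([[0.0, 0, 0], [1.458, 0, 0],
                                [2.0, 1.4, 0], [1.25, 2.39, 0]]),
        )
        topo = build_restraints(gly)
        assert len(topo.bond_lengths) == 3  # N-CA, CA-C, C-O

    def test_poly_ala_bond_count_matches_enumeration(self):
        # per residue: N-CA, CA-C, C-O, CA-CB = 4; plus 4 peptide bonds
        topo = build_restraints(make_helix(5))
        assert len(topo.bond_lengths) == 5 * 4 + 4

    def test_reference_lengths_within_chemical_window(self):
        topo = build_restraints(make_helix(8))
        assert np.all(topo.bond_lengths > 0.8)
        assert np.all(topo.bond_lengths < 2.2)
        with pytest.raises(ValueError):
            RestraintTopology(np.array([[0, 1]]), np.array([3.0]),
                              np.empty((0, 3), int), np.empty(0))

    def test_angles_come_from_bonded_triples(self):
        topo = build_restraints(_two_ala())
        for i, j, k in topo.angle_indices:
            bonds = {tuple(b) for b in topo.bond_indices.tolist()}
            assert (min(i, j), max(i, j)) in bonds
            assert (min(j, k), max(j, k)) in bonds


class TestRestraintForces:
    def test_forces_vanish_at_reference_geometry(self):
        model = make_helix(6)
        topo = build_restraints(model)
        energy, forces = restraint_energy_forces(model.positions, topo, 1e4, 2e3)
        assert energy == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_allclose(forces, 0.0, atol=1e-9)

    def test_forces_match_finite_difference(self):
        model = make_helix(4)
        topo = build_restraints(model)
        rng = np.random.default_rng(0)
        pos = model.positions + rng.normal(0, 0.1, model.positions.shape)
        _, forces = restraint_energy_forces(pos, topo, 100.0, 50.0)
        eps = 1e-6
        for idx in [(0, 0), (5, 1), (11, 2)]:
            a, c = idx
            dp = pos.copy(); dp[a, c] += eps
            dm = pos.copy(); dm[a, c] -= eps
            ep, _ = restraint_energy_forces(dp, topo, 100.0, 50.0)
            em, _ = restraint_energy_forces(dm, topo, 100.0, 50.0)
            assert forces[a, c] == pytest.approx(-(ep - em) / (2 * eps), rel=1e-4)

    def test_descent_reduces_energy(self):
        model = make_helix(6)
        topo = build_restraints(model)
        rng = np.random.default_rng(1)
        pos = model.positions + rng.normal(0, 0.2, model.positions.shape)
        energies = []
        for _ in range(200):
            e, f = restraint_energy_forces(pos, topo, 1e4, 2e3)
            energies.append(e)
            pos = pos + 1e-5 * f
        diffs = np.diff(energies)
        assert np.all(diffs <= 1e-9)


class TestDensityBiasForce:
    @pytest.fixture()
    def blob(self, spread15):
        atom = StructureModel(["CA"], ["C"], [1], ["ALA"], ["A"],
                              np.array([[0.0, 0.0, 0.0]]))
        return pad_map(simulate_map(atom, 0.5, spread15, pad=8.0), 2.0)

    def _probe(self, pos):
        return StructureModel(["CA"], ["C"], [1], ["ALA"], ["A"],
                              np.array([pos], float))

    def test_zero_force_at_peak(self, blob):
        F = density_bias_force(self._probe([0.0, 0.0, 0.0]), blob, k=100.0)
        assert np.linalg.norm(F) < 1e-6 * 100.0

    def test_flank_force_points_uphill(self, blob):
        F = density_bias_force(self._probe([2.0, 0.0, 0.0]), blob, k=100.0)
        assert F[0, 0] < 0  # pulled back toward the peak at x = 0

    def test_matches_finite_difference_of_interpolant(self, blob):
        k = 50.0
        p = np.array([1.3, -0.7, 0.9])
        F = density_bias_force(self._probe(p), blob, k)[0]
        eps = 1e-5
        for c in range(3):
            pp, pm = p.copy(), p.copy()
            pp[c] += eps
            pm[c] -= eps
            vp, _ = value_and_gradient(blob, pp)
            vm, _ = value_and_gradient(blob, pm)
            fd = k * (vp - vm) / (2 * eps)
            assert F[c] == pytest.approx(fd, rel=1e-4, abs=1e-10)


class TestRefineModel:
    def test_fixed_point_on_own_map(self, helix20, spread15):
        target = simulate_map(helix20, 1.0, spread15, pad=8.0)
        cfg = RefineConfig(max_steps=2000, frame_stride=200)
        traj = refine_model(helix20, target, config=cfg)
        final = traj.frames[-1]
        assert ca_rmsd(final, helix20, align=False) < 0.3
        assert model_map_cc(final, target, spread15) >= 0.99

    def test_two_state_best_compound_frame_improves(self, default_system, spread15):
        """Fit + refine + compound-score frame pick beats the starting model."""
        from ensemblefit.rigidfit import FitConfig, rigid_body_fit
        from ensemblefit.selection import compound_scores

        sys_ = default_system
        _, fitted, _ = rigid_body_fit(
            sys_.known_model, sys_.target_map,
            FitConfig(seed=0, spread=spread15),
        )
        traj = refine_model(fitted, sys_.target_map, config=RefineConfig())
        series = score_trajectory(traj, sys_.target_map, spread15)
        best = int(np.argmax(compound_scores(series)))
        best_frame = traj.frames[best]
        start_rmsd = ca_rmsd(sys_.known_model, sys_.target_model)
        assert ca_rmsd(best_frame, sys_.target_model) < start_rmsd
        assert (model_map_cc(best_frame, sys_.target_map, spread15)
                > model_map_cc(sys_.known_model, sys_.target_map, spread15))

    def test_no_bias_limit_is_pure_relaxation(self, helix20, spread15):
        target = simulate_map(helix20, 1.0, spread15, pad=8.0)
        cfg = RefineConfig(k_density=0.0, adaptive_growth=1.0,
                           max_steps=1500, frame_stride=500)
        traj = refine_model(helix20, target, config=cfg)
        final = traj.frames[-1]
        assert ca_rmsd(final, helix20, align=False) < 0.1
        cc0 = model_map_cc(helix20, target, spread15)
        cc1 = model_map_cc(final, target, spread15)
        assert abs(cc1 - cc0) < 0.01

    def test_determinism_bitwise(self, small_system):
        cfg = RefineConfig(max_steps=600, frame_stride=100)
        t1 = refine_model(small_system.known_model, small_system.target_map, config=cfg)
        t2 = refine_model(small_system.known_model, small_system.target_map, config=cfg)
        assert len(t1.frames) == len(t2.frames)
        for a, b in zip(t1.frames, t2.frames):
            np.testing.assert_array_equal(a.positions, b.positions)

    def test_bias_scale_nondecreasing_and_termination_recorded(self, small_system):
        cfg = RefineConfig(max_steps=1200, frame_stride=200, adaptive_growth=1.05)
        traj = refine_model(small_system.known_model, small_system.target_map, config=cfg)
        ks = traj.metadata["k_history"]
        assert all(b >= a for a, b in zip(ks, ks[1:]))
        assert traj.metadata["termination_reason"] in (
            "max_steps", "displacement_limit", "left_map"
        )

    def test_immediate_blowup_is_config_error(self, small_system):
        cfg = RefineConfig(step_size=10.0, relax_steps=0)
        noisy = small_system.ensemble.models[0]
        with pytest.raises(ValueError, match="step_size"):
            refine_model(noisy, small_system.target_map, config=cfg)


class TestScoreTrajectory:
    def test_single_frame_series(self, helix20, spread15):
        from ensemblefit.structures import Trajectory

        target = simulate_map(helix20, 1.0, spread15, pad=8.0)
        traj = Trajectory(frames=[helix20])
        series = score_trajectory(traj, target, spread15)
        assert len(series.cc) == 1
        assert series.cc[0] == pytest.approx(1.0, abs=1e-6)

    def test_identical_frames_constant_series(self, helix20, spread15):
        from ensemblefit.structures import Trajectory

        target = simulate_map(helix20, 1.0, spread15, pad=8.0)
        traj = Trajectory(frames=[helix20.copy() for _ in range(3)])
        series = score_trajectory(traj, target, spread15)
        assert len(set(np.round(series.cc, 12))) == 1
        assert len(set(np.round(series.geometry_scaled, 12))) == 1

    def test_values_equal_frame_by_frame_recomputation(self, small_system, spread15):
        from ensemblefit.quality import fallback_geometry_score

        traj = refine_model(small_system.known_model, small_system.target_map,
                            config=RefineConfig(max_steps=400, frame_stride=100))
        series = score_trajectory(traj, small_system.target_map, spread15)
        for frame, cc, geo in zip(traj.frames, series.cc, series.geometry_scaled):
            assert cc == pytest.approx(
                model_map_cc(frame, small_system.target_map, spread15), abs=1e-12
            )
            assert geo == pytest.approx(
                fallback_geometry_score(frame).scaled, abs=1e-12
            )
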