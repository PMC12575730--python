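# Methods

`ensemblefit` implements an ensemble-based protocol for building a protein
model into a cryo-EM density map that shows the protein in a conformation
different from any solved structure. This note records the models,
numerical choices and limitations behind each stage.

## The protocol

Given an ensemble of candidate models (in real use, predictions generated
with stochastically subsampled MSAs; here, imported from multi-model PDB or
synthesized), a known-state structure, and a target density map:

1. **Geometry filtering.** Each model gets a length-scaled geometry score
   (total score / number of residues with a Cα). Models scoring above the
   threshold (default −100, a round, deliberately arbitrary cutoff that in
   practice separates grossly misfolded models) are discarded; a model
   exactly at the threshold is kept.
2. **Clustering.** Either k-means on Cα Cartesian coordinates after
   superposing every model onto the known state, or k-medoids (PAM) on the
   pairwise internal-distance RMSD (dRMSD) matrix, which needs no reference
   state. Default k = 20. Representatives are the member nearest each
   k-means centroid, or the medoids.
3. **Rigid docking.** Each representative is rigid-body fitted into the
   (blurred) target map by maximizing model-to-map cross-correlation.
4. **Density-guided refinement.** Each docked representative is refined
   under stereochemical restraints plus a density bias force with adaptive
   force scaling; every stored frame is scored by map cross-correlation and
   geometry.
5. **Selection.** The trajectory with the highest mean cross-correlation is
   chosen; within it, the frame maximizing the compound score
   `minmax(cc) + minmax(|geometry|)` becomes the final model. RMSD to a
   ground-truth structure, when available, is reported for validation but
   never drives selection.

A single-model baseline (rigid fit + refinement of the known structure,
several replicates differing in fit seed, same selection rule) provides the
comparison that motivates the ensemble route.

## Density maps

Maps are voxel grids with an origin (Cartesian position of the center of
voxel (0,0,0)) and per-axis voxel size in Å, read and written as MRC/CCP4
mode 2 via gemmi with axis order normalized to (x, y, z). Simulated maps
spread each heavy atom as an isotropic Gaussian truncated at 4σ. Gaussians
are *unit-mass* normalized (peak `(2πσ²)^{-3/2}`), so blurring a map
simulated at σ₁ by σ₂ equals simulating at √(σ₁²+σ₂²); cross-correlation is
unaffected by this choice because it is scale-invariant. The default
spreading width is σ = 1.5 Å, appropriate for a ~3.5 Å-resolution map under
the FWHM ≈ resolution heuristic (σ = 0.425·resolution, available as
`sigma_from_resolution`). The "1 Å Gaussian blur" applied to target maps is
interpreted as a standard deviation; whether the original usage meant a
standard deviation or a Chimera-style width is not documented anywhere we
know of, so the interpretation is stated here and configurable.

Map values and gradients at atom positions come from trilinear
interpolation with the analytic gradient of the interpolant; at points
lying exactly on a cell face — where the trilinear derivative is
one-sided — the two adjacent cells' gradients are averaged, so the bias
force vanishes at the exact peak of a symmetric blob as it should.

## Cross-correlation and rigid fitting

Cross-correlation defaults to mean-subtracted Pearson over the full grid
(mask and unsubtracted variants available). It is invariant to scaling and
shifting of either map, which is why amplitude conventions elsewhere are
free choices.

Rigid fitting maximizes model-to-map CC over the 6-DOF pose with
multi-start Nelder–Mead (rotation vector about the model centroid +
translation; default 8 starts = identity + 7 seeded perturbations within
±25°/±5 Å). For speed, the inner objective is the equivalent overlap
`Σ_atoms (target ⊛ G_σ)(x_atom)`: this equals the inner product between the
target and the simulated model density, and since the simulated map's own
norm is pose-invariant, ranking poses by overlap matches ranking by
unnormalized CC. The exact Pearson CC is evaluated at each start's end pose
to pick the winner, and the identity start guarantees the returned pose
never scores below the input pose. There is no FFT-accelerated global
search: inputs are assumed roughly posed (representatives are aligned to a
known-state frame first), and pose recovery is verified for perturbations
up to 20° and 4 Å.

## The refiner

A full MD engine (thermostat, PME, solvent, force field) is deliberately
not part of this package; the refiner reproduces the *protocol logic* of
density-guided simulation at desk scale, and an import path
(`read_trajectory` + `score_trajectory`) accepts frames produced by a real
MD engine.

* **Restraints.** Harmonic bonds (k = 10⁴ energy/Å²) and angles
  (k = 2×10³ energy/rad²) derived once from the starting model's standard
  residue connectivity (backbone template + peptide bonds; side chains
  beyond Cβ and nonstandard residues fall back to a < 1.9 Å heavy-atom
  distance heuristic). Reference values are measured from the input
  coordinates, except bonds measured outside (0.8, 2.2) Å — broken input
  geometry — which revert to template ideal lengths. No dihedral or
  secondary-structure restraints: conformational transitions must remain
  possible.
* **Integration.** Damped steepest descent, displacement = step_size ×
  force with step_size = 10⁻⁵ Å per force unit, preceded by 500
  restraint-only preparation steps with a 0.1 Å/step trust radius (the
  analogue of energy minimization before dynamics).
* **Bias force.** `F = k · ∇ρ(x_atom)` every `apply_every = 2` steps — the
  uniform-weight point-sampling limit of the similarity gradient, not the
  full derivative of Pearson CC (exactness against a finite-difference
  oracle is asserted for what is implemented). The working map is
  normalized to unit peak so `k_density` (default 10³) has the same meaning
  for any map amplitude.
* **Adaptive force scaling.** k is multiplied by `adaptive_growth` every
  `growth_interval = 10` bias applications. The schedule of the original
  GROMACS mechanism is internal to that engine and undocumented; the
  default growth factor here is 1.005, chosen so that over a default-length
  run (max_steps = 8000) the bias grows ~50× slower than a factor that
  measurably tears the model's geometry before termination. Growth and
  interval are exposed in `RefineConfig`.
* **Termination.** The run stops at `max_steps` or as soon as any atom's
  per-step displacement exceeds `displacement_limit` (0.5 Å) — the
  observable consequence of "forces too large for the time step" that ends
  adaptive-force-scaled runs in a real engine. The reason is recorded in
  the trajectory metadata.
* Frames are stored every `frame_stride = 80` steps (101 frames per default
  run). Everything is deterministic; the seed is provenance metadata.

## Geometry quality

The protocol expects an orientation-dependent statistical potential (more
negative = better); `read_external_scores` imports such totals from a CSV
produced by an external program. So the pipeline also runs self-contained,
an **internal fallback score** is provided:

    scaled = −(150 − 0.02·clashscore − 25·⟨(d − d_ideal)²⟩)

with the clash score in clashes per 1000 heavy atoms and the bond term the
mean squared deviation of template-bonded distances from ideal lengths
(Å²). A strain-free model scores −150; the weights are calibrated on the
synthetic suite so that 0.5 Å per-atom coordinate noise keeps models near
−120 (below the −100 filter threshold) while coordinate-scrambled decoys —
whose bonded pairs end up several Å apart — score far above it. Scrambling
permutes a point cloud without changing its pairwise-distance multiset, so
clash density barely changes; bond strain is the real discriminator. The
fallback is labeled `internal_fallback` in all outputs and mixing it with
external scores in one filtering call is an error, because scores are only
comparable within one source.

The clash score approximates the MolProbity convention with heavy atoms
only: unordered non-bonded pairs closer than r₁+r₂−0.4 Å (standard element
radii: C 1.70, N 1.55, O 1.52, S 1.80 Å), excluding same-residue pairs and
1-2/1-3 bonded neighbours, per 1000 atoms. It counts genuine 1-4 contacts
(e.g. O(i)–Cα(i+1) in helices) that hydrogen-aware MolProbity would not,
so absolute values are not comparable with published clashscores — only
differences within one run are meaningful.

## Selection details

Min-max normalization maps a series onto [0, 1]; a constant series becomes
zeros with a warning. The compound score normalizes cc and |geometry score|
either within each trajectory (default) or over all trajectories of a
system pooled (`global`); per-trajectory normalization is the default
because pooling was observed (in the setting this protocol comes from) to
select equal or worse models. Normalizing |score| means better geometry
(more negative score, larger magnitude) increases the compound score —
that is the intended reading, and it is only monotone if all scores are
negative, hence the hard error on non-negative geometry scores. Ties break
toward the earliest frame and the lexicographically smallest trajectory
label, making the full selection invariant to input order.

## The synthetic system

`make_toy_system` builds the statistical structure the pipeline assumes:

* a 40-residue poly-alanine α-helix (state A, the "known" structure) built
  by NeRF chain extension at φ = −57°, ψ = −47°, ω = 180° with ideal bond
  geometry — big enough to exercise clash/restraint logic, small enough
  for seconds-scale refinements;
* state B: the same helix bent 40° at residue 20 (rigid rotation of the
  downstream half about an axis through the kink Cα perpendicular to the
  helix axis, then a rigid translation restoring the crossing peptide bond
  exactly), ~3.2 Å Cα RMSD from state A — a single-helix analogue of an
  activation-type transition;
* a target map simulated from state B at 1 Å voxels with σ = 1.5 Å spread,
  plus a 1 Å blur;
* an ensemble of 200 models: each a state drawn with weights (0.8 A /
  0.2 B) plus isotropic per-atom Gaussian noise, σ = 0.5 Å; optionally a
  fraction of coordinate-scrambled decoys for filter tests.

What it does **not** emulate: realistic map noise (CTF envelopes, solvent,
anisotropy), prediction-confidence structure (pLDDT, per-domain error),
internal-coordinate noise correlations, side chains beyond Cβ, oligomers,
ligands or membranes. Passing tests therefore demonstrate the protocol
logic — filtering, clustering, docking, biased refinement, selection —
under controlled conditions, not performance on experimental maps.

## Problem sizes and determinism

Default end-to-end runs use the 200-model ensemble, k = 20 representatives
and 8000-step refinements (~2 minutes for the pipeline plus ~30 s for the
5-replicate baseline on one CPU); unit tests use smaller instances of the
same generators. Every stage is deterministic under its seed: k-means uses
seeded k-means++ with 10 restarts, PAM k-medoids is greedy BUILD + steepest
SWAP with lowest-index tie-breaks, the refiner contains no randomness, and
rigid-fit starts are drawn from a seeded generator. Reports record all
seeds so a rerun reproduces every number bitwise.

## Known limitations

* The refiner is a gradient-descent caricature of MD: no inertia, no
  temperature, no barrier crossing; it converges to the nearest compatible
  conformation, which is exactly why ensemble starting points matter.
* The bias is per-atom local density ascent; atoms further than the
  spreading cutoff from any density feel no force, so large rigid-body
  mismatches must be resolved by the docking stage first.
* The fallback geometry score is not a statistical potential; it ranks
  models within this package's conventions but its absolute values have no
  meaning outside them.
* Single-chain protein models only; HETATM records are carried through but
  ignored by Cα operations, and oligomeric assemblies are out of scope.
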