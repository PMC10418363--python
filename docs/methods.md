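# Methods

This note records the models implemented in phosfold, the assumptions and
tunable parameters behind them, what the synthetic structures do and do not
emulate, and the numerical choices that make every stage deterministic and
testable.

## Structure representation

Structures are flat atom lists with author (1-based) residue numbering;
domain extraction uses inclusive residue ranges (extracting 815–1124 from a
chain numbered 1–1124 keeps 310 residues). Fixed-width PDB input is parsed
strictly: records shorter than the coordinate block, alternate-location
indicators and insertion codes are rejected with the offending line number
rather than silently resolved, because guessing among conformers corrupts
coordinates downstream. Coordinates are carried at the PDB precision of
0.001 Å; write→read round trips are exact for structures on that grid.
Parameterized structures are written as whitespace-separated PQR with the
charge column before the radius.

The shipped parameter table covers a reduced representation: a backbone CA
pseudo-atom, a lumped side-chain pseudo-atom (SC) carrying the residue's
dominant-protonation charge near neutral pH, explicit hydroxyl/phosphate
atoms for tyrosine and phosphotyrosine, plus single-atom ion species.
Hydrogens are optional throughout; nothing downstream requires them.
Full-atom force-field parameterization of arbitrary real PDB files is out
of scope — unknown residue/atom combinations raise a parameterization
error naming the culprit.

**Phosphotyrosine building.** The modification is purely geometric and
reproducible: the hydroxyl hydrogen (if present) is removed, phosphorus is
placed 1.63 Å beyond the hydroxyl oxygen on the C–OH bond axis, and three
terminal oxygens are placed 1.52 Å from P at tetrahedral angles in a
deterministic frame. The residue is renamed PTR; its partial charges sum
to −2 e at full deprotonation. The titration model carries the phosphate's
primary ionization as a fixed −1 e and titrates the secondary ionization
(model pKa 5.8), so both the −1 and −2 protonation states are represented
as a function of pH rather than fixed at build time.

## Titration and folding energetics

Net charge follows Henderson–Hasselbalch per site; the unfolded state uses
model-compound pKa values (no interactions — the standard null model), and
the folded state uses shifted values from a two-term empirical model:

* **Coulomb term.** For site *i*, Δ pKa_i = −(332.0637 / (RT ln10 · s)) ·
  Σ_j q_j / r_ij², using a distance-dependent dielectric ε(r) = s·r with
  slope s = 8 by default. The sum runs over the other titratable sites'
  fully ionized (reference) charges and over fixed background charges of
  non-titratable residues (ions, cofactors); charges belonging to
  titratable residues are represented by their site's reference charge
  only, never double-counted from the partial-charge table. A positive
  neighbouring charge favours deprotonation and lowers any site's pKa.
* **Burial term.** ±(max shift)·(burial fraction), raising acid and
  lowering base pKa values; the burial fraction is the Shrake–Rupley
  occluded fraction of the site's titration atom, counting occlusion by
  *other residues only* so that covalent geometry (a phosphate surrounding
  its own bridging oxygen) is not mistaken for desolvation. Default
  maximum shift: 3.0 pKa units at full burial — in the range empirical
  predictors assign to deeply buried groups — and configurable.

This model is intentionally simple: it is deterministic, linear in the
perturbing charges, and every number in it can be recomputed by hand, which
is what the test oracles do. It does not attempt coupled-site titration
(Tanford–Roxby/Monte-Carlo), temperature-dependent pKas, or agreement with
any particular pKa-prediction program.

ΔG(pH) = RT ln10 ∫₀^pH (Q_f − Q_u) dpH′ is evaluated by trapezoidal
quadrature on a pH grid from 0 to 14 (default step 0.1; the closed-form
single-site plateau RT ln10 ΔpKa is reproduced to better than 10⁻⁴
kcal/mol at step 0.01). The profile is referenced to pH 0 exactly
(ΔG(0) ≡ 0). R is fixed at 1.9872×10⁻³ kcal/(mol·K) and T defaults to
300 K.

**Stability windows.** The window is the widest contiguous interval where
|dΔG/dpH| (central differences; one-sided at the ends) stays within a
slope tolerance, equivalently where |Q_f − Q_u| ≤ tol/(RT ln10). The
tolerance is an analysis choice, reported with every output: 0.5
kcal/mol/pH is the general default; the designed phospho-pair toy is
analysed at 0.2 kcal/mol/pH because its shifts are deliberately mild (a
single 0.42-unit pKa perturbation on an otherwise clean background).
Windows may be empty; that is a result, not an error.

## Linearized Poisson–Boltzmann solver

With φ in kT/e, lengths in Å and charges in e, the equation solved is
∇·(ε∇φ) − ε_w κ² φ = −4π C Σ q_i δ(r−r_i), C = 332.0637/(RT). The
screening term κ² = 8π (C/ε_w) · 2 I N_A/10²⁷ acts on solvent nodes only;
at 300 K and 0.15 M this gives a Debye length of ≈ 8 Å. The kT/e scale is
evaluated at the configured temperature (default 300 K for consistency
with the titration stage, though many continuum tools default to ~298 K);
the choice is recorded in the grid metadata.

Discretization and solution:

* seven-point stencil; dielectric values live on half-grid links, assigned
  ε_in when the link midpoint falls inside any probe-inflated atom sphere
  (van der Waals + 1.4 Å probe — a solvent-excluded-surface approximation
  without triangulation; its bias is toward a slightly enlarged cavity);
* charges spread to the eight neighbouring nodes by trilinear weights;
* boundary nodes carry a sum of Debye–Hückel monopoles (exact for a
  spherically symmetric exterior, cheap and smooth otherwise);
* checkerboard successive over-relaxation, ω = 1.9, until the relative
  residual ‖Aφ−b‖/‖b‖ ≤ 10⁻⁶ (at most 10 000 sweeps; non-convergence
  raises with the residual attached). Red-black ordering makes the
  iteration order, and hence the result, machine-deterministic.

Accuracy on the analytic oracles at the default 0.5 Å spacing (65³ grid):
exterior Born-ion potential within ~2–4 % for r ≥ 4 Å; uniform-medium
Coulomb within ~0.5 % away from the source; charge negation is exactly
antisymmetric; the exterior error decreases monotonically under grid
refinement 1.0 → 0.5 → 0.25 Å. The linearized (not nonlinear) form was
chosen precisely because these closed-form oracles exist.

**Surfaces and field lines.** Molecular surfaces are sampled with a
deterministic golden-spiral point set (960 points/atom by default, floor
92) on probe-inflated spheres, keeping exterior points only; potentials are
interpolated trilinearly and labelled positive/negative at ±1 kT/e. Field
lines integrate dx/ds = −∇φ/|∇φ| with fixed-step RK2 (default 0.25 Å) from
each seed in both directions, terminating on a molecular surface, at the
grid boundary, or after the step budget; seeds in a numerically field-free
region (|∇φ| < 10⁻¹² kT/e/Å) are flagged individually as degenerate.

## Interface analysis

Per-atom accessible surface areas use the same Shrake–Rupley machinery
(isolated-sphere area exact by construction; two-sphere overlaps within
0.5 % of the spherical-cap closed form at 960 points). Buried interface
area is ASA(A) + ASA(B) − ASA(AB) and is symmetric in the two monomers.

**Docking stand-in.** The rigid-body search replaces an external docking
server with something reproducible at desk scale: a deterministic rotation
set (identity plus seeded uniform quaternions) applied to monomer B about
its centroid, each rotation slid along the inter-centroid axis to the first
clash-free contact (closed-form slide distance; clash floor 2.4 Å between
heavy atoms), scored by buried area. ASA(B) is recomputed on the rotated
coordinates so the stored score agrees exactly with an independent
re-scoring of the posed structure. Poses are returned sorted; selection
takes the largest buried area, ties broken by fewer clashes, then lower
rotation index. The search explores orientations of B along a fixed
approach axis — adequate for the toys it serves, and not intended to
reproduce any particular server's pose for a real protein.

**Open-book complementarity.** Surface patches are connected components
(points linked within twice the nominal sampling spacing) of same-sign
labels restricted to the buried interface, with components below 2 Å²
discarded as sampling speckle. Opposite-sign patches across the interface
are paired greedily by centroid distance within a 10 Å cutoff. For
presentation the monomers are rotated ±45° about the principal in-plane
axis of the interface point cloud and separated 15 Å along the interface
normal; for field-line tracing the separated (unrotated) two-monomer
system is re-solved on a coarser grid (default 1.0 Å spacing — the lines'
topology, not their fine geometry, is the point) and lines are launched
just off each positive patch of monomer A, recording whether they
terminate on the partner.

## Synthetic structures

The generators define the study conditions; all are bit-deterministic
under a fixed spec and seed and round-trip through the package's own I/O.

* **Born ion** — one charged sphere; pure solver oracle.
* **Ideal helix** — rise 1.5 Å, twist 100°/residue, CA at 2.3 Å radius,
  lumped side chains at 5.0 Å (hydroxyl at 6.8 Å). Residues sit far enough
  apart that single-site closed forms dominate; termini are non-titratable
  by default to keep those closed forms clean.
* **Phospho pair** — Asp, a fixed +2 cation and Tyr placed at 8.5 / 8.5 /
  12.02 Å so that (i) every pairwise separation exceeds mutual occlusion
  range (burial exactly zero), (ii) the cation's field at the Asp is
  exactly twice the magnitude of a −1 charge at the hydroxyl position, so
  the phosphotyrosine's −2 reference charge cancels it exactly, and
  (iii) the field of cation + Asp vanishes at the hydroxyl, so the
  tyrosine/phosphotyrosine site itself is unshifted in both variants. The
  phospho variant is literally `apply_phospho_tyrosine` applied to the
  other, so the two differ only at the modified residue.
* **Patch dimer** — two facing single-layer slabs of neutral 1.9 Å atoms
  (3 Å pitch, 3.5 Å gap), with n mirrored ±0.5 e patches at 12 Å spacing.
  Charge and spacing are chosen so each patch's ±1 kT/e footprint stays
  local: at ±0.5 e the labelled caps are ~20 Å² and disjoint, while ±1 e
  at 9 Å spacing merges them into one sheet. The five-patch layout is
  fourfold symmetric, so every interface-preserving docked orientation
  keeps the five pairings intact.

What the toys do **not** emulate: real side-chain rotamers and packing,
backbone solvation, correlated titration of clustered sites, conformational
change on phosphorylation, and realistic interface shapes. Passing tests
on them demonstrates that the machinery — equations, discretizations,
bookkeeping — is correct, not that predictions for any real kinase domain
are quantitatively right.

## Problem sizes and runtime choices

Defaults are sized for a laptop CPU: 65³ solver grids at 0.5 Å for
single-molecule oracles, ~120-atom slabs with 16–500 docking rotations,
960 surface points/atom, and a 1.0 Å tracing grid for the separated dimer.
The full test suite and the acceptance script each run in a few minutes.

## Known limitations

* The pKa model is uncoupled and pairwise; strongly interacting site
  clusters (where titration order matters) are outside its validity.
* The dielectric cavity is a union of inflated spheres, not a true
  solvent-excluded surface; narrow crevices are smoothed over.
* The docking search is orientational only (no lateral translation scan)
  and is a selection-criterion testbed, not a pose predictor.
* Linearized PB underestimates potentials near highly charged surfaces
  where the nonlinear response matters.
* Patch pairing is greedy nearest-centroid; pathological patch geometries
  could pair suboptimally, though the validity constraints (opposite sign,
  within cutoff) always hold.
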