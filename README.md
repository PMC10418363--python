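# phosfold

Computational-biophysics toolkit for asking how a single phosphotyrosine
changes a protein domain's behaviour: its pH-dependent folding stability,
its electrostatic surface, and its ability to form a charge-complementary
dimer interface. The motivating use case is tyrosine-kinase domains (for
example the C-terminal kinase domain of Janus kinases, where an
autophosphorylation site sits on the N-lobe surface), but every stage runs
and is verified on small synthetic structures, so no external models,
servers, or downloads are required.

Intended users are structural bioinformaticians and biophysics students who
want a desk-scale, fully inspectable version of the standard pipeline:
titration → folding energetics → continuum electrostatics → docking →
interface complementarity.

## What it computes

**pH-dependent folding energy.** For titratable sites with folded-state
pKa values `pKa_f,i` and unfolded (model-compound) values `pKa_u,i`, the
net charges

```
Q(pH) = Σ_bases 1/(1+10^(pH−pKa)) − Σ_acids 1/(1+10^(pKa−pH))
```

enter the proton-linkage (Tanford–Wyman) relation

```
ΔG(pH) = RT ln10 ∫₀^pH (Q_f − Q_u) dpH′ ,   R = 1.9872×10⁻³ kcal/(mol·K)
```

referenced to pH 0. Flat stretches of ΔG(pH) are pH-insensitive "stability
windows"; the window detector reports the widest interval where
|dΔG/dpH| stays below a slope tolerance. Folded-state pKa shifts come from
a documented empirical model (pairwise Coulomb term with a
distance-dependent dielectric, plus a burial desolvation penalty from
Shrake–Rupley exposure).

**Continuum electrostatics.** A finite-difference linearized
Poisson–Boltzmann solver (successive over-relaxation, checkerboard
ordering, Debye–Hückel boundary values) with the standard protein settings:
solute dielectric 2, water 80, 0.15 M salt, probe 1.4 Å, 2 grid points/Å,
protein filling ratio 0.70. Potentials are in kT/e; surfaces are sampled by
deterministic Shrake–Rupley points and labelled at ±1 kT/e; electric field
lines are RK2 streamlines of −∇φ.

**Dimer interfaces.** Accessible surface areas (Shrake–Rupley), a
deterministic rigid-body docking search scored by buried interface area
`ASA(A)+ASA(B)−ASA(AB)` with selection of the largest-interface pose, and
an "open-book" report: the two monomers are rotated 90° apart and separated
by 15 Å, same-sign surface patches on the buried interface are paired
across the gap by opposite sign, and field lines are traced between them.

## Worked example

The built-in phospho/non-phospho toy is a three-residue cluster (aspartate,
a fixed +2 cation, tyrosine) designed so the cation's field perturbs the
aspartate pKa while the phosphotyrosine's −2 charge cancels it exactly:

```python
import phosfold as pf
from phosfold.titration import (folding_energy_profile, predict_pkas,
                                stability_window, titration_curve)

non, pho = pf.make_phospho_pair()
for tag, ps in (("non-phospho", non), ("phospho", pho)):
    sites = predict_pkas(ps)
    profile = folding_energy_profile(titration_curve(sites))
    print(tag, [(s.residue_type, round(s.shifted_pka, 3)) for s in sites],
          "window:", stability_window(profile, slope_tol=0.2))
```

prints

```
non-phospho [('ASP', 3.381), ('TYR', 10.0)] window: (4.3, 14.0)
phospho [('ASP', 3.8), ('PTR', 5.8)] window: (0.0, 14.0)
```

i.e. the unmodified variant's aspartate is shifted 0.42 pH units below its
model pKa, which costs it the acidic flank of its stability window
(stable only above pH 4.3), while the phosphorylated variant titrates like
the free model compounds and is stable across the whole range — the
directional result that phosphorylation can decrease a domain's pH
sensitivity, reproduced on a toy whose every number is checkable by hand.

The same comparison runs from the shell, along with the dimer analysis of
the five-patch complementary toy interface:

```
phosfold stability --toy phospho_pair --slope-tol 0.2 --out report/
phosfold dimer --toy patch_dimer --n-rotations 16 --seed 1 --out report/
```

The dimer report finds five opposite-sign patch pairs across the docked
interface and five field lines connecting the separated monomers
(`"pair_count": 5`, `"field_lines_to_partner": 5`), with the posed PDB,
OpenDX potential grids, and field-line polylines written next to it.

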