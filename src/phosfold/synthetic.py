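"""Deterministic toy structures exercising every pipeline stage.

Four families, mirroring what each stage needs to be verifiable without any
external structure download:

* ``make_born_ion`` -- a single charged sphere, the analytic oracle for the
  finite-difference Poisson-Boltzmann solver;
* ``make_titratable_helix`` -- an ideal alpha-helix backbone (rise 1.5 Å,
  twist 100°/residue) with lumped single-pseudo-atom side chains carrying
  the titratable groups, including phosphotyrosine via lowercase ``y``;
* ``make_phospho_pair`` -- a designed three-residue cluster (Asp, a fixed
  divalent cation, Tyr) in which the cation's field shifts the aspartate
  pKa in the unmodified protein while the phosphotyrosine's charge cancels
  it exactly, so phosphorylation widens the pH-stability window;
* ``make_patch_dimer`` -- two facing neutral slabs decorated with mirrored
  positive/negative charge patches, the analogue of a charge-complementary
  dimer interface.

All generators are deterministic under a fixed spec and seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, ValidationError
from .parameters import (
    ParameterizedStructure,
    default_parameter_table,
    parameterize,
)
from .structure import Atom, Structure, apply_phospho_tyrosine

__all__ = [
    "ToySpec",
    "make_born_ion",
    "make_titratable_helix",
    "make_patch_dimer",
    "make_phospho_pair",
]

_AA_CODE = {
    "A": "ALA", "G": "GLY", "D": "ASP", "E": "GLU", "H": "HIS",
    "K": "LYS", "R": "ARG", "C": "CYS", "Y": "TYR",
}

HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = 100.0  # degrees per residue
_CA_RADIUS = 2.3  # Å, helical radius of the backbone trace
_SC_RADIUS = 5.0  # Å, radial offset of the lumped side-chain atom
_OH_RADIUS = 6.8  # Å, radial offset of the tyrosine hydroxyl


@dataclass(frozen=True)
class ToySpec:
    """Serializable description of a synthetic fixture."""

    kind: str  # born_ion | helix_peptide | patch_dimer | phospho_pair
    parameters: tuple[tuple[str, object], ...]
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {"kind": self.kind, "parameters": dict(self.parameters), "seed": self.seed},
            sort_keys=True,
        )


def make_born_ion(charge: float, radius: float) -> ParameterizedStructure:
    """One charged sphere at the origin; the solver's analytic test case."""
    if radius <= 0:
        raise ValidationError("Born ion radius must be positive")
    s = Structure(
        atoms=[
            Atom(
                serial=1, atom_name="ION", element="X", residue_name="ION",
                residue_number=1, chain="A", xyz=(0.0, 0.0, 0.0),
            )
        ],
        title="Born ion",
    )
    return ParameterizedStructure(
        structure=s,
        radii=np.array([radius]),
        charges=np.array([charge]),
        titratable_sites=[],
    )


def make_titratable_helix(sequence: str, seed: int = 0) -> ParameterizedStructure:
    """Ideal helix with single-pseudo-atom side chains.

    Uppercase letters select supported residue types; lowercase ``y`` builds
    a tyrosine and then phosphorylates it in place.  Termini are not
    titratable in this representation.
    """
    if not sequence:
        raise ValidationError("empty sequence")
    atoms: list[Atom] = []
    serial = 0
    phospho_positions: list[int] = []
    for i, letter in enumerate(sequence):
        resnum = i + 1
        if letter == "y":
            resname = "TYR"
            phospho_positions.append(resnum)
        elif letter in _AA_CODE:
            resname = _AA_CODE[letter]
        else:
            raise ValidationError(
                f"unsupported residue letter {letter!r} at position {resnum}"
            )
        theta = math.radians(HELIX_TWIST * i)
        z = HELIX_RISE * i
        c, s_ = math.cos(theta), math.sin(theta)
        placements = [("CA", "C", _CA_RADIUS), ("SC", "X", _SC_RADIUS)]
        if resname == "TYR":
            placements.append(("OH", "O", _OH_RADIUS))
        for name, element, rad in placements:
            serial += 1
            atoms.append(
                Atom(
                    serial=serial, atom_name=name, element=element,
                    residue_name=resname, residue_number=resnum, chain="A",
                    # quantized to the 0.001 Å PDB coordinate grid so the
                    # generated structure round-trips bit-identically
                    xyz=(round(rad * c, 3), round(rad * s_, 3), round(z, 3)),
                )
            )
    s = Structure(atoms=atoms, title=f"ideal helix {sequence}")
    for resnum in phospho_positions:
        s = apply_phospho_tyrosine(s, "A", resnum)
    return parameterize(s, default_parameter_table())


# Designed phospho/non-phospho cluster.  All heavy-atom separations exceed
# the mutual occlusion range of the inflated spheres, so burial is zero and
# the folded-state pKa shifts are purely Coulombic and exactly computable:
# the +2 cation at 8.5 Å from the Asp carboxylate lowers its pKa; the
# phosphotyrosine hydroxyl sits 8.5 Å from the Asp and 12.02 Å from the
# cation, where its -2 reference charge exactly cancels the cation's field
# at the Asp while its own shift vanishes by symmetry.
_PAIR_R_ASP_OH = 8.5
_PAIR_CAT = (8.5, 0.0, 0.0)
_PAIR_OH = (0.0, 8.5, 0.0)
_PAIR_SC_TYR = (2.5, 8.5, 0.0)  # C-OH axis perpendicular to the OH-Asp line


def make_phospho_pair(
    seed: int = 0,
) -> tuple[ParameterizedStructure, ParameterizedStructure]:
    """Non-phospho and phospho variants differing only at the tyrosine."""
    atoms = [
        Atom(1, "CA", "C", "ASP", 1, "A", (0.0, 0.0, 7.0)),
        Atom(2, "SC", "X", "ASP", 1, "A", (0.0, 0.0, 0.0)),
        Atom(3, "CAT", "X", "CAT", 2, "A", _PAIR_CAT),
        Atom(4, "CA", "C", "TYR", 3, "A", (2.5, 8.5, 7.0)),
        Atom(5, "SC", "X", "TYR", 3, "A", _PAIR_SC_TYR),
        Atom(6, "OH", "O", "TYR", 3, "A", _PAIR_OH),
    ]
    base = Structure(atoms=atoms, title="designed phospho-stabilized cluster")
    table = default_parameter_table()
    nonphospho = parameterize(base, table)
    phospho = parameterize(apply_phospho_tyrosine(base, "A", 3), table)
    return nonphospho, phospho


def _patch_layout(n: int, spacing: float) -> np.ndarray:
    """Deterministic centered layout: middle point, then ring offsets."""
    offsets = [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1),
               (1, 1), (-1, -1), (1, -1), (-1, 1), (2, 0), (-2, 0),
               (0, 2), (0, -2)]
    if n > len(offsets):
        raise ValidationError(f"at most {len(offsets)} patch pairs supported")
    return np.array(offsets[:n], dtype=float) * spacing


def make_patch_dimer(
    n_pairs: int,
    patch_charge: float = 0.5,
    spacing: float = 12.0,
    seed: int = 0,
    gap: float = 3.5,
    pitch: float = 3.0,
    atom_radius: float = 1.9,
    probe: float = 1.4,
) -> tuple[ParameterizedStructure, ParameterizedStructure]:
    """Two facing neutral slabs with mirrored charge patches.

    Monomer A (chain A) carries ``n_pairs`` patches of ``+patch_charge`` on
    a square slab of neutral atoms in the y-z plane; monomer B (chain B) is
    the mirror image across the gap plane with ``-patch_charge`` patches.
    """
    if n_pairs < 0:
        raise ValidationError("n_pairs must be >= 0")
    if n_pairs >= 2 and spacing < 2.0 * (atom_radius + probe):
        raise GeometryError(
            f"patches overlap: spacing {spacing} below {2 * (atom_radius + probe)} Å"
        )
    layout = _patch_layout(n_pairs, spacing) if n_pairs else np.empty((0, 2))
    half = max(2, int(np.ceil((abs(layout).max() if n_pairs else 0.0) / pitch)) + 2)
    ys = np.arange(-half, half + 1) * pitch
    zs = np.arange(-half, half + 1) * pitch

    def build(chain: str, x: float, sign: float) -> ParameterizedStructure:
        atoms: list[Atom] = []
        charges: list[float] = []
        serial = 0
        patch_set = {
            (int(round(p[0] / pitch)), int(round(p[1] / pitch))) for p in layout
        }
        for iy, y in enumerate(ys):
            for iz, z in enumerate(zs):
                serial += 1
                key = (iy - half, iz - half)
                q = sign * patch_charge if key in patch_set else 0.0
                atoms.append(
                    Atom(
                        serial=serial, atom_name="Q", element="X",
                        residue_name="SLB", residue_number=serial,
                        chain=chain, xyz=(x, float(y), float(z)),
                    )
                )
                charges.append(q)
        s = Structure(atoms=atoms, title=f"patch slab {chain}")
        return ParameterizedStructure(
            structure=s,
            radii=np.full(len(atoms), atom_radius),
            charges=np.array(charges),
            titratable_sites=[],
        )

    a = build("A", 0.0, +1.0)
    b = build("B", gap, -1.0)
    return a, b
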