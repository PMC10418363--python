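"""Radius/charge assignment and titratable-site enumeration.

The shipped table covers the package's reduced residue representation
(backbone CA pseudo-atom, lumped side-chain pseudo-atom, explicit hydroxyl
and phosphate atoms for tyrosine/phosphotyrosine) plus the single-ion and
slab species used by the synthetic generators.  Charges are the dominant
protonation state near neutral pH; pH dependence is handled by the titration
model, not by re-assigning partial charges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import ParameterizationError, ParseError, ValidationError
from .structure import Atom, Structure

__all__ = [
    "TitratableSite",
    "ResidueParameterTable",
    "ParameterizedStructure",
    "default_parameter_table",
    "parameterize",
    "write_pqr",
    "read_pqr",
]


@dataclass
class TitratableSite:
    """One ionizable group with its model-compound and folded-state pKa.

    ``fixed_charge`` is a pH-independent offset carried by the group in the
    modelled pH range (phosphotyrosine's primary phosphate ionization);
    ``ionized_charge`` is the charge added by the modelled (de)protonation.
    The unfolded-state pKa is by definition the model-compound value.
    """

    chain: str
    residue_number: int
    residue_type: str
    is_acid: bool
    model_pka: float
    shifted_pka: float
    ionized_charge: float
    fixed_charge: float = 0.0
    atom_name: str = "SC"
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def reference_charge(self) -> float:
        """Fully ionized charge, used for pairwise electrostatic coupling."""
        return self.fixed_charge + self.ionized_charge

    def __post_init__(self) -> None:
        for v in (self.model_pka, self.shifted_pka):
            if not -5.0 <= v <= 20.0:
                raise ValidationError(f"pKa {v} outside [-5, 20] for {self.residue_type}")


class ResidueParameterTable:
    """Per-residue-type atom radii, partial charges and titration constants."""

    def __init__(self, data: dict):
        self.version = data.get("version", "unversioned")
        self.residues = data["residues"]
        self.termini = data.get("termini", {"n_term_pka": 8.0, "c_term_pka": 3.2})
        for name, entry in self.residues.items():
            tit = entry.get("titratable")
            if tit is not None and not 0.0 <= tit["model_pka"] <= 14.0:
                raise ValidationError(f"model pKa of {name} outside [0, 14]")
        if "PTR" not in self.residues or "titratable" not in self.residues["PTR"]:
            raise ValidationError("table must include phosphotyrosine (PTR) ionization")

    @classmethod
    def from_json(cls, text: str) -> "ResidueParameterTable":
        return cls(json.loads(text))

    def atom_params(self, residue_name: str, atom_name: str) -> tuple[float, float]:
        """Return (radius, partial charge) for one atom."""
        entry = self.residues.get(residue_name)
        if entry is None:
            raise ParameterizationError(f"unknown residue type {residue_name!r}")
        atom = entry["atoms"].get(atom_name)
        if atom is None:
            raise ParameterizationError(
                f"atom {atom_name!r} not parameterized for residue {residue_name!r}"
            )
        return float(atom["radius"]), float(atom["charge"])


def default_parameter_table() -> ResidueParameterTable:
    text = resources.files("phosfold.data").joinpath("residue_params.json").read_text()
    return ResidueParameterTable.from_json(text)


@dataclass
class ParameterizedStructure:
    """A structure with per-atom radii/charges and its titratable sites."""

    structure: Structure
    radii: np.ndarray
    charges: np.ndarray
    titratable_sites: list[TitratableSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.structure)
        self.radii = np.asarray(self.radii, dtype=float).reshape(n)
        self.charges = np.asarray(self.charges, dtype=float).reshape(n)
        if np.any(self.radii <= 0):
            raise ValidationError("all atom radii must be positive")

    def coords(self) -> np.ndarray:
        return self.structure.coords()

    @property
    def net_fixed_charge(self) -> float:
        return float(self.charges.sum())


def parameterize(
    s: Structure,
    table: ResidueParameterTable | None = None,
    include_termini: bool = False,
) -> ParameterizedStructure:
    """Assign radii/partial charges and enumerate titratable sites.

    Per-residue partial charges are checked to sum to the residue's formal
    charge (at the table's reference protonation) within 1e-6 e.  Unknown
    residue types or atoms raise :class:`ParameterizationError`.
    """
    if table is None:
        table = default_parameter_table()
    n = len(s)
    radii = np.empty(n)
    charges = np.empty(n)
    for i, a in enumerate(s.atoms):
        radii[i], charges[i] = table.atom_params(a.residue_name, a.atom_name)

    sites: list[TitratableSite] = []
    for chain, resnum in s.residue_ids():
        res_atoms = s.residue_atoms(chain, resnum)
        resname = res_atoms[0].residue_name
        entry = table.residues[resname]
        present = {a.atom_name for a in res_atoms}
        if present == set(entry["atoms"]):
            actual = sum(
                charges[i]
                for i, a in enumerate(s.atoms)
                if a.chain == chain and a.residue_number == resnum
            )
            if abs(actual - float(entry["formal_charge"])) > 1e-6:
                raise ParameterizationError(
                    f"partial charges of {resname} {chain}{resnum} sum to "
                    f"{actual:.6f}, expected formal charge {entry['formal_charge']}"
                )
        tit = entry.get("titratable")
        if tit is not None:
            site_atom = next(
                (a for a in res_atoms if a.atom_name == tit["atom"]), res_atoms[0]
            )
            sites.append(
                TitratableSite(
                    chain=chain,
                    residue_number=resnum,
                    residue_type=resname,
                    is_acid=bool(tit["is_acid"]),
                    model_pka=float(tit["model_pka"]),
                    shifted_pka=float(tit["model_pka"]),
                    ionized_charge=float(tit["ionized_charge"]),
                    fixed_charge=float(tit.get("fixed_charge", 0.0)),
                    atom_name=site_atom.atom_name,
                    position=site_atom.xyz,
                )
            )
    if include_termini:
        for chain in dict.fromkeys(a.chain for a in s.atoms):
            chain_atoms = [a for a in s.atoms if a.chain == chain]
            first, last = chain_atoms[0], chain_atoms[-1]
            sites.append(
                TitratableSite(
                    chain=chain,
                    residue_number=first.residue_number,
                    residue_type="NTERM",
                    is_acid=False,
                    model_pka=float(table.termini["n_term_pka"]),
                    shifted_pka=float(table.termini["n_term_pka"]),
                    ionized_charge=1.0,
                    atom_name=first.atom_name,
                    position=first.xyz,
                )
            )
            sites.append(
                TitratableSite(
                    chain=chain,
                    residue_number=last.residue_number,
                    residue_type="CTERM",
                    is_acid=True,
                    model_pka=float(table.termini["c_term_pka"]),
                    shifted_pka=float(table.termini["c_term_pka"]),
                    ionized_charge=-1.0,
                    atom_name=last.atom_name,
                    position=last.xyz,
                )
            )
    return ParameterizedStructure(
        structure=s, radii=radii, charges=charges, titratable_sites=sites
    )


def write_pqr(ps: ParameterizedStructure) -> str:
    """Whitespace-separated PQR with charge before radius."""
    lines = []
    for i, a in enumerate(ps.structure.atoms):
        x, y, z = a.xyz
        lines.append(
            f"ATOM {a.serial} {a.atom_name} {a.residue_name} {a.chain} "
            f"{a.residue_number} {x:.3f} {y:.3f} {z:.3f} "
            f"{ps.charges[i]:.4f} {ps.radii[i]:.4f}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_pqr(text: str) -> ParameterizedStructure:
    """Read the PQR dialect written by :func:`write_pqr`.

    Titratable sites are not encoded in PQR; re-run :func:`parameterize` on
    the structure if sites are needed.
    """
    atoms: list[Atom] = []
    charges: list[float] = []
    radii: list[float] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        parts = line.split()
        if len(parts) != 11:
            raise ParseError(f"expected 11 whitespace fields, got {len(parts)}", lineno)
        try:
            atoms.append(
                Atom(
                    serial=int(parts[1]),
                    atom_name=parts[2],
                    element=parts[2][0].upper(),
                    residue_name=parts[3],
                    residue_number=int(parts[5]),
                    chain=parts[4],
                    xyz=(float(parts[6]), float(parts[7]), float(parts[8])),
                )
            )
            charges.append(float(parts[9]))
            radii.append(float(parts[10]))
        except ValueError as exc:
            raise ParseError(f"malformed numeric field: {exc}", lineno) from None
    if not atoms:
        raise ParseError("no atoms: input contains no ATOM/HETATM records")
    return ParameterizedStructure(
        structure=Structure(atoms=atoms),
        radii=np.array(radii),
        charges=np.array(charges),
    )
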