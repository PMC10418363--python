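"""Structure container and fixed-width PDB / whitespace PQR input-output.

The in-memory model is deliberately small: a flat list of atoms with author
(1-based) residue numbering, as used when carving a kinase domain out of a
full-length model by residue range.  Insertion codes and alternate locations
are rejected outright rather than guessed at, since silently picking one
conformer can corrupt downstream coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError, ParseError, ValidationError

__all__ = [
    "Atom",
    "Structure",
    "read_structure",
    "write_pdb",
    "extract_domain",
    "apply_phospho_tyrosine",
    "PHOSPHATE_P_OH_BOND",
    "PHOSPHATE_P_O_BOND",
]

# Ideal internal geometry used when building a phosphotyrosine in place:
# the phosphorus sits on the C-OH bond axis beyond the hydroxyl oxygen and
# carries three terminal oxygens in a tetrahedral arrangement.
PHOSPHATE_P_OH_BOND = 1.63  # Å, P to bridging (hydroxyl) oxygen
PHOSPHATE_P_O_BOND = 1.52  # Å, P to each terminal oxygen
_TETRAHEDRAL_DEG = 109.47122063449069


@dataclass(frozen=True)
class Atom:
    serial: int
    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    xyz: tuple[float, float, float]


@dataclass
class Structure:
    """A list of atoms plus a free-text title.

    Invariants (checked by :meth:`validate`): finite coordinates, unique
    (chain, residue_number, atom_name) triples, and residue numbers that do
    not decrease within a chain in file order.
    """

    atoms: list[Atom] = field(default_factory=list)
    title: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        last_resnum: dict[str, int] = {}
        for a in self.atoms:
            if not all(math.isfinite(c) for c in a.xyz):
                raise ValidationError(f"non-finite coordinate on atom serial {a.serial}")
            key = (a.chain, a.residue_number, a.atom_name)
            if key in seen:
                raise ValidationError(f"duplicate atom {key}")
            seen.add(key)
            prev = last_resnum.get(a.chain)
            if prev is not None and a.residue_number < prev:
                raise ValidationError(
                    f"residue numbers decrease in chain {a.chain!r} at residue "
                    f"{a.residue_number}"
                )
            last_resnum[a.chain] = a.residue_number

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float).reshape(-1, 3)

    def residue_ids(self) -> list[tuple[str, int]]:
        out: list[tuple[str, int]] = []
        for a in self.atoms:
            rid = (a.chain, a.residue_number)
            if not out or out[-1] != rid:
                out.append(rid)
        return out

    def residue_atoms(self, chain: str, residue_number: int) -> list[Atom]:
        return [
            a
            for a in self.atoms
            if a.chain == chain and a.residue_number == residue_number
        ]

    def __len__(self) -> int:
        return len(self.atoms)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Structure):
            return NotImplemented
        return self.atoms == other.atoms and self.title == other.title


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    if not stripped:
        return ""
    if stripped[0].isdigit() and len(stripped) > 1:
        return stripped[1].upper()
    return stripped[0].upper()


def read_structure(pdb_text: str) -> Structure:
    """Parse fixed-width ATOM/HETATM records into a :class:`Structure`.

    Coordinates are read at 0.001 Å precision.  Records carrying an
    insertion code or an alternate-location indicator raise :class:`ParseError`
    with the offending line number, as do records too short to hold the
    coordinate block.
    """
    atoms: list[Atom] = []
    title = ""
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        record = line[:6]
        if record.startswith("TITLE"):
            title = (title + " " + line[10:].strip()).strip()
            continue
        if record not in ("ATOM  ", "HETATM"):
            continue
        if len(line.rstrip("\n")) < 54:
            raise ParseError(
                f"ATOM/HETATM record shorter than 54 columns ({len(line.rstrip())})",
                lineno,
            )
        altloc = line[16]
        if altloc not in (" ", ""):
            raise ParseError(f"alternate location {altloc!r} not supported", lineno)
        icode = line[26]
        if icode not in (" ", ""):
            raise ParseError(f"insertion code {icode!r} not supported", lineno)
        try:
            serial = int(line[6:11])
            resnum = int(line[22:26])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise ParseError(f"malformed numeric field: {exc}", lineno) from None
        atom_name = line[12:16].strip()
        if not atom_name:
            raise ParseError("blank atom name", lineno)
        element = line[76:78].strip() if len(line) >= 78 else ""
        atoms.append(
            Atom(
                serial=serial,
                atom_name=atom_name,
                element=element or _guess_element(atom_name),
                residue_name=line[17:20].strip(),
                residue_number=resnum,
                chain=line[21].strip() or "A",
                xyz=(x, y, z),
            )
        )
    if not atoms:
        raise ParseError("no atoms: input contains no ATOM/HETATM records")
    return Structure(atoms=atoms, title=title)


def _format_atom_name(name: str) -> str:
    # PDB convention: 1-2 letter element names start in column 14.
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def write_pdb(s: Structure) -> str:
    lines = []
    if s.title:
        lines.append(f"TITLE     {s.title}")
    for a in s.atoms:
        x, y, z = a.xyz
        lines.append(
            f"ATOM  {a.serial:>5d} {_format_atom_name(a.atom_name)} "
            f"{a.residue_name:>3s} {a.chain:1s}{a.residue_number:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def extract_domain(s: Structure, chain: str, first: int, last: int) -> Structure:
    """Keep atoms with ``first <= residue_number <= last`` on ``chain``.

    Inclusive author numbering: extracting 815..1124 from a chain numbered
    1..1124 keeps exactly 310 residues.
    """
    if first > last:
        raise ValidationError(f"invalid range: first ({first}) > last ({last})")
    kept = [
        a
        for a in s.atoms
        if a.chain == chain and first <= a.residue_number <= last
    ]
    if not kept:
        raise ValidationError(
            f"empty selection: no residues of chain {chain!r} in [{first}, {last}]"
        )
    return Structure(atoms=kept, title=s.title)


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic pair of unit vectors perpendicular to ``axis``."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(float(np.dot(helper, axis))) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def apply_phospho_tyrosine(
    s: Structure,
    chain: str,
    residue_number: int,
    p_oh_bond: float = PHOSPHATE_P_OH_BOND,
    p_o_bond: float = PHOSPHATE_P_O_BOND,
) -> Structure:
    """Build a phosphotyrosine (PTR) in place of a tyrosine residue.

    The hydroxyl hydrogen, when present, is removed; a phosphate group
    (P, O1P, O2P, O3P) is placed on the C-OH bond axis with ideal tetrahedral
    internal geometry; the residue is renamed PTR.  Every other atom is
    returned bit-identical.
    """
    res = s.residue_atoms(chain, residue_number)
    if not res:
        raise ValidationError(
            f"no residue {residue_number} in chain {chain!r}"
        )
    if res[0].residue_name != "TYR":
        raise ValidationError(
            f"not a tyrosine: residue {residue_number} is {res[0].residue_name}"
        )
    oh = next((a for a in res if a.atom_name == "OH"), None)
    if oh is None:
        raise ValidationError("incomplete side chain: hydroxyl OH atom missing")

    heavy = [a for a in res if a.element != "H" and a.atom_name != "OH"]
    if not heavy:
        raise ValidationError("incomplete side chain: no carbon bonded to OH")
    oh_xyz = np.asarray(oh.xyz)
    dists = [float(np.linalg.norm(np.asarray(a.xyz) - oh_xyz)) for a in heavy]
    anchor = heavy[int(np.argmin(dists))]
    axis = oh_xyz - np.asarray(anchor.xyz)
    norm = float(np.linalg.norm(axis))
    if norm < 1e-9:
        raise GeometryError("degenerate C-OH bond: zero length")
    axis /= norm

    p_xyz = oh_xyz + p_oh_bond * axis
    e1, e2 = _orthonormal_frame(axis)
    half = math.radians(180.0 - _TETRAHEDRAL_DEG)
    new_xyz = [p_xyz]
    for k in range(3):
        phi = math.radians(120.0 * k)
        direction = (
            math.cos(half) * axis
            + math.sin(half) * (math.cos(phi) * e1 + math.sin(phi) * e2)
        )
        new_xyz.append(p_xyz + p_o_bond * direction)

    max_serial = max(a.serial for a in s.atoms)
    new_names = ["P", "O1P", "O2P", "O3P"]
    new_elements = ["P", "O", "O", "O"]
    out: list[Atom] = []
    for a in s.atoms:
        if a.chain == chain and a.residue_number == residue_number:
            if a.atom_name == "HH":  # hydroxyl hydrogen
                continue
            out.append(replace(a, residue_name="PTR"))
        else:
            out.append(a)
    insert_at = max(
        i for i, a in enumerate(out)
        if a.chain == chain and a.residue_number == residue_number
    ) + 1
    phosphate = [
        Atom(
            serial=max_serial + 1 + k,
            atom_name=new_names[k],
            element=new_elements[k],
            residue_name="PTR",
            residue_number=residue_number,
            chain=chain,
            xyz=tuple(float(c) for c in new_xyz[k]),
        )
        for k in range(4)
    ]
    out[insert_at:insert_at] = phosphate
    return Structure(atoms=out, title=s.title)
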