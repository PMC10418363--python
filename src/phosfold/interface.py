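"""Dimer interfaces: buried surface area, rigid docking, complementarity.

The docking search is a deterministic stand-in for an FFT docking server:
a seeded quasi-uniform set of rigid rotations of monomer B, each slid along
the inter-centroid axis to the first clash-free contact and scored by buried
accessible surface area, buried = ASA(A) + ASA(B) - ASA(AB).  The pose with
the largest buried area is selected, mirroring selection of the dimer with
the smallest remaining accessible area.

The open-book report rotates the two monomers apart around the interface
in-plane axis, separates them along the interface normal, collects
same-sign surface patches restricted to the buried region, pairs opposite
signs greedily by centroid distance, and traces electric field lines from
the positive patches of one monomer toward the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import ValidationError
from .parameters import ParameterizedStructure
from .sasa import shrake_rupley
from .electrostatics import (
    FieldLine,
    GridSpec,
    PotentialGrid,
    SurfaceMap,
    solve_linear_pb,
    surface_potential_map,
    trace_field_lines,
)

__all__ = [
    "DimerPose",
    "Patch",
    "ComplementarityReport",
    "accessible_surface_area",
    "buried_area",
    "transform_structure",
    "dock_rigid",
    "select_pose",
    "surface_patches",
    "open_book_complementarity",
]

CLASH_DISTANCE = 2.4  # Å, heavy-atom steric floor


@dataclass
class DimerPose:
    rotation: np.ndarray  # 3x3, applied to monomer B about its centroid
    translation: np.ndarray  # full translation so that B' = R (B - cB) + cB + t
    buried_asa: float
    clash_count: int
    rotation_index: int = 0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValidationError("rotation must be proper (det = +1)")
        if self.buried_asa < -1e-6:
            raise ValidationError("buried ASA must be non-negative")


@dataclass
class Patch:
    sign: int
    centroid: np.ndarray
    area: float
    point_indices: np.ndarray


@dataclass
class ComplementarityReport:
    pairs: list[dict]
    pair_count: int
    field_lines: list[FieldLine] = field(default_factory=list)
    patches_a: list[Patch] = field(default_factory=list)
    patches_b: list[Patch] = field(default_factory=list)
    opened_a: np.ndarray | None = None
    opened_b: np.ndarray | None = None
    separation: float = 15.0
    angle: float = 90.0


def accessible_surface_area(
    ps: ParameterizedStructure, probe: float = 1.4, points_per_atom: int = 960
) -> np.ndarray:
    """Per-atom Shrake-Rupley accessible surface areas in Å²."""
    return shrake_rupley(ps.coords(), ps.radii, probe, points_per_atom)


def _total_asa(
    coords: np.ndarray, radii: np.ndarray, probe: float, points_per_atom: int
) -> float:
    return float(shrake_rupley(coords, radii, probe, points_per_atom).sum())


def buried_area(
    a_coords: np.ndarray,
    a_radii: np.ndarray,
    b_coords: np.ndarray,
    b_radii: np.ndarray,
    probe: float = 1.4,
    points_per_atom: int = 960,
    asa_a: float | None = None,
    asa_b: float | None = None,
) -> float:
    """ASA(A) + ASA(B) - ASA(AB)."""
    if asa_a is None:
        asa_a = _total_asa(a_coords, a_radii, probe, points_per_atom)
    if asa_b is None:
        asa_b = _total_asa(b_coords, b_radii, probe, points_per_atom)
    combined = _total_asa(
        np.vstack([a_coords, b_coords]),
        np.concatenate([a_radii, b_radii]),
        probe,
        points_per_atom,
    )
    return asa_a + asa_b - combined


def transform_structure(
    ps: ParameterizedStructure, pose: DimerPose
) -> ParameterizedStructure:
    """Apply a pose to a copy of the structure (coordinates only)."""
    from dataclasses import replace as _replace

    c = ps.coords().mean(axis=0)
    new = (ps.coords() - c) @ pose.rotation.T + c + pose.translation
    atoms = [
        _replace(a, xyz=tuple(float(v) for v in new[i]))
        for i, a in enumerate(ps.structure.atoms)
    ]
    from .structure import Structure

    return ParameterizedStructure(
        structure=Structure(atoms=atoms, title=ps.structure.title),
        radii=ps.radii.copy(),
        charges=ps.charges.copy(),
        titratable_sites=list(ps.titratable_sites),
    )


def _rotation_set(n: int, seed: int) -> np.ndarray:
    """Deterministic quasi-uniform rotations: identity plus seeded uniform
    quaternions (Shoemake construction)."""
    rots = [np.eye(3)]
    if n > 1:
        rng = np.random.default_rng(seed)
        u = rng.random((n - 1, 3))
        q = np.column_stack(
            [
                np.sqrt(1 - u[:, 0]) * np.sin(2 * np.pi * u[:, 1]),
                np.sqrt(1 - u[:, 0]) * np.cos(2 * np.pi * u[:, 1]),
                np.sqrt(u[:, 0]) * np.sin(2 * np.pi * u[:, 2]),
                np.sqrt(u[:, 0]) * np.cos(2 * np.pi * u[:, 2]),
            ]
        )
        for x, y, z, w in q:
            rots.append(
                np.array(
                    [
                        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
                        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
                        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
                    ]
                )
            )
    return np.array(rots[:n])


def _first_contact_offset(
    a: np.ndarray, b: np.ndarray, axis: np.ndarray, contact: float
) -> float | None:
    """Slide of b along axis to the first clash-free contact with a.

    b approaches from far along -axis; the smallest admissible offset t
    (possibly negative, moving b closer than its initial placement) keeps
    every pair distance >= contact: |d + t u|^2 >= c^2 with d = b_j - a_i
    gives t >= -d.u + sqrt(c^2 - perp^2) whenever the perpendicular miss
    distance is below c.  Returns None when no pair ever comes within
    contact (the bodies slide past each other).
    """
    d = b[:, None, :] - a[None, :, :]
    along = d @ axis
    perp2 = (d * d).sum(axis=2) - along**2
    mask = perp2 < contact**2
    if not np.any(mask):
        return None
    t = -along[mask] + np.sqrt(contact**2 - perp2[mask])
    return float(t.max())


def dock_rigid(
    a: ParameterizedStructure,
    b: ParameterizedStructure,
    n_rotations: int = 500,
    seed: int = 0,
    probe: float = 1.4,
    points_per_atom: int = 960,
    clash_distance: float = CLASH_DISTANCE,
) -> list[DimerPose]:
    """Axial-approach rigid docking over a seeded rotation set.

    Returns every clash-free pose sorted by buried ASA, descending.
    """
    if n_rotations < 1:
        raise ValidationError("n_rotations must be >= 1")
    ca = a.coords().mean(axis=0)
    cb = b.coords().mean(axis=0)
    axis = cb - ca
    norm = float(np.linalg.norm(axis))
    axis = axis / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])

    asa_a = _total_asa(a.coords(), a.radii, probe, points_per_atom)
    acoords = a.coords()
    bcoords0 = b.coords()

    poses: list[DimerPose] = []
    for k, rot in enumerate(_rotation_set(n_rotations, seed)):
        brot = (bcoords0 - cb) @ rot.T + cb
        t = _first_contact_offset(acoords, brot, axis, clash_distance)
        if t is None:
            continue
        bposed = brot + t * axis
        dmin = np.linalg.norm(
            bposed[:, None, :] - acoords[None, :, :], axis=2
        )
        clash = int((dmin < clash_distance - 1e-9).sum())
        if clash:
            continue
        # ASA(B) is recomputed on the rotated coordinates: the sampled
        # point set is orientation-dependent, and the score must match an
        # independent re-scoring of the posed coordinates exactly
        buried = buried_area(
            acoords, a.radii, bposed, b.radii, probe, points_per_atom,
            asa_a=asa_a,
        )
        poses.append(
            DimerPose(
                rotation=rot,
                translation=t * axis,
                buried_asa=max(buried, 0.0),
                clash_count=clash,
                rotation_index=k,
            )
        )
    poses.sort(key=lambda p: (-p.buried_asa, p.clash_count, p.rotation_index))
    return poses


def select_pose(poses: list[DimerPose]) -> DimerPose:
    """Largest buried interface wins; ties by fewer clashes, then rotation index."""
    if not poses:
        raise ValidationError("no poses")
    return min(poses, key=lambda p: (-p.buried_asa, p.clash_count, p.rotation_index))


def surface_patches(
    smap: SurfaceMap,
    restrict: np.ndarray | None = None,
    min_area: float = 2.0,
) -> list[Patch]:
    """Connected components of same-sign labelled surface points.

    Adjacency: points within twice the nominal sampling spacing.  ``restrict``
    optionally masks the points considered (e.g. the buried interface);
    components below ``min_area`` Å² are discarded as sampling speckle.
    """
    labels = smap.sign_label
    keep = labels != 0
    if restrict is not None:
        keep &= restrict
    idx = np.flatnonzero(keep)
    if len(idx) == 0:
        return []
    pts = smap.points[idx]
    # nominal spacing from the per-point represented area
    spacing = 2.0 * np.sqrt(float(np.median(smap.weight[idx])))
    tree = cKDTree(pts)
    pairs = tree.query_pairs(spacing, output_type="ndarray")
    same = labels[idx[pairs[:, 0]]] == labels[idx[pairs[:, 1]]] if len(pairs) else np.empty(0, bool)
    pairs = pairs[same] if len(pairs) else pairs
    n = len(idx)
    if len(pairs):
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
    else:
        adj = coo_matrix((n, n))
    ncomp, comp = connected_components(adj, directed=False)
    patches = []
    for c in range(ncomp):
        members = idx[comp == c]
        area = float(smap.weight[members].sum())
        if area < min_area:
            continue
        patches.append(
            Patch(
                sign=int(labels[members[0]]),
                centroid=smap.points[members].mean(axis=0),
                area=area,
                point_indices=members,
            )
        )
    patches.sort(key=lambda p: -p.area)
    return patches


def _buried_mask(
    smap: SurfaceMap, other: ParameterizedStructure, probe: float
) -> np.ndarray:
    """Surface points of one monomer occluded by the partner's inflated spheres."""
    if len(smap.points) == 0:
        return np.zeros(0, dtype=bool)
    inflated = other.radii + probe
    tree = cKDTree(other.coords())
    rmax = float(inflated.max())
    mask = np.zeros(len(smap.points), dtype=bool)
    groups = tree.query_ball_point(smap.points, rmax)
    coords = other.coords()
    for i, g in enumerate(groups):
        if g:
            dd = np.linalg.norm(coords[g] - smap.points[i], axis=1)
            mask[i] = bool(np.any(dd <= inflated[g]))
    return mask


def _greedy_pairs(
    patches_a: list[Patch], patches_b: list[Patch], cutoff: float
) -> list[tuple[int, int, float]]:
    cands = []
    for i, pa in enumerate(patches_a):
        for j, pb in enumerate(patches_b):
            if pa.sign == -pb.sign:
                gap = float(np.linalg.norm(pa.centroid - pb.centroid))
                if gap <= cutoff:
                    cands.append((gap, i, j))
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    out = []
    for gap, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.append((i, j, gap))
    return out


def _rotation_about(axis: np.ndarray, degrees: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    t = np.radians(degrees)
    c, s = np.cos(t), np.sin(t)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) * c + s * K + (1 - c) * np.outer(axis, axis)


def open_book_complementarity(
    pose: DimerPose,
    a: ParameterizedStructure,
    b: ParameterizedStructure,
    grids: tuple[PotentialGrid, PotentialGrid],
    angle: float = 90.0,
    separation: float = 15.0,
    pairing_cutoff: float = 10.0,
    probe: float = 1.4,
    points_per_atom: int = 960,
    trace_spacing: float = 1.0,
    field_line_step: float = 0.25,
    solver_kwargs: dict | None = None,
) -> ComplementarityReport:
    """Interface charge-complementarity report for a posed dimer.

    ``b`` is placed by ``pose``; ``grids`` are the per-monomer potentials in
    the dimer frame (A grid, posed-B grid).  Patches are same-sign connected
    components of each monomer's surface labels restricted to the buried
    interface; opposite signs are paired greedily by centroid distance.
    For field-line tracing the two monomers are pulled ``separation`` Å apart
    along the interface normal and the potential of the separated pair is
    solved on a coarser grid; lines start just off the positive patches of
    monomer A.
    """
    bp = transform_structure(b, pose)
    grid_a, grid_b = grids
    smap_a = surface_potential_map(grid_a, a, probe, points_per_atom)
    smap_b = surface_potential_map(grid_b, bp, probe, points_per_atom)
    buried_a = _buried_mask(smap_a, bp, probe)
    buried_b = _buried_mask(smap_b, a, probe)
    patches_a = surface_patches(smap_a, restrict=buried_a)
    patches_b = surface_patches(smap_b, restrict=buried_b)

    ca = a.coords().mean(axis=0)
    cb = bp.coords().mean(axis=0)
    normal = cb - ca
    nn = float(np.linalg.norm(normal))
    normal = normal / nn if nn > 1e-9 else np.array([1.0, 0.0, 0.0])

    matches = _greedy_pairs(patches_a, patches_b, pairing_cutoff)
    pairs = [
        {
            "patch_A": {
                "sign": patches_a[i].sign,
                "centroid": [float(v) for v in patches_a[i].centroid],
                "area": patches_a[i].area,
            },
            "patch_B": {
                "sign": patches_b[j].sign,
                "centroid": [float(v) for v in patches_b[j].centroid],
                "area": patches_b[j].area,
            },
            "centroid_gap": gap,
        }
        for i, j, gap in matches
    ]

    # open-book coordinates: rotate each monomer +-angle/2 about the
    # principal in-plane axis of the interface point cloud, then separate
    contact_pts = []
    if buried_a.any():
        contact_pts.append(smap_a.points[buried_a])
    if buried_b.any():
        contact_pts.append(smap_b.points[buried_b])
    if contact_pts:
        cloud = np.vstack(contact_pts)
        center = cloud.mean(axis=0)
        centered = cloud - center
        inplane = centered - np.outer(centered @ normal, normal)
        cov = inplane.T @ inplane
        w, v = np.linalg.eigh(cov)
        book_axis = v[:, -1]
    else:
        center = (ca + cb) / 2.0
        book_axis = np.array([0.0, 0.0, 1.0])
        if abs(float(book_axis @ normal)) > 0.9:
            book_axis = np.array([0.0, 1.0, 0.0])
    rot_a = _rotation_about(book_axis, -angle / 2.0)
    rot_b = _rotation_about(book_axis, +angle / 2.0)
    opened_a = (a.coords() - center) @ rot_a.T + center - separation / 2.0 * normal
    opened_b = (bp.coords() - center) @ rot_b.T + center + separation / 2.0 * normal

    # separated (not rotated) configuration for field-line tracing
    field_lines: list[FieldLine] = []
    pos_patches = [p for p in patches_a if p.sign > 0]
    if pos_patches:
        shift_a = -separation / 2.0 * normal
        shift_b = +separation / 2.0 * normal
        sep_a = _shift(a, shift_a)
        sep_b = _shift(bp, shift_b)
        merged = _merge(sep_a, sep_b)
        spec = GridSpec.around(merged, spacing=trace_spacing,
                               fill_ratio=grid_a.spec.fill_ratio)
        kwargs = dict(
            eps_in=grid_a.eps_in, eps_out=grid_a.eps_out,
            ionic_strength=grid_a.ionic_strength,
            temperature=grid_a.temperature, probe=probe,
        )
        if solver_kwargs:
            kwargs.update(solver_kwargs)
        combined = solve_linear_pb(merged, spec, **kwargs)
        seeds = np.array(
            [p.centroid + shift_a + 1.5 * normal for p in pos_patches]
        )
        field_lines = trace_field_lines(
            combined, seeds, step=field_line_step,
            surfaces=[sep_a, sep_b], probe=probe,
        )

    return ComplementarityReport(
        pairs=pairs, pair_count=len(pairs), field_lines=field_lines,
        patches_a=patches_a, patches_b=patches_b,
        opened_a=opened_a, opened_b=opened_b,
        separation=separation, angle=angle,
    )


def _shift(ps: ParameterizedStructure, vec: np.ndarray) -> ParameterizedStructure:
    pose = DimerPose(rotation=np.eye(3), translation=vec, buried_asa=0.0, clash_count=0)
    return transform_structure(ps, pose)


def _merge(a: ParameterizedStructure, b: ParameterizedStructure) -> ParameterizedStructure:
    from dataclasses import replace as _replace
    from .structure import Structure

    atoms = list(a.structure.atoms)
    offset = max(x.serial for x in atoms)
    for at in b.structure.atoms:
        atoms.append(
            _replace(at, serial=at.serial + offset, chain="Z")
        )
    return ParameterizedStructure(
        structure=Structure(atoms=atoms),
        radii=np.concatenate([a.radii, b.radii]),
        charges=np.concatenate([a.charges, b.charges]),
    )
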