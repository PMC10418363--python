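"""Finite-difference linearized Poisson-Boltzmann electrostatics.

The potential phi is carried in kT/e units throughout.  With lengths in Å
and charges in elementary charges, the continuum problem is

    div( eps grad phi ) - eps_out * kappa^2 * phi = -4 pi C sum_i q_i delta(r - r_i)

where C = 332.0637 / (R T) Å kT/e^2 is the Coulomb constant expressed in
kT/e units at the configured temperature, and the screening term acts only
in the solvent region.  kappa^2 = 8 pi l_B n_ion with the Bjerrum length
l_B = C / eps_out and the ion number density of a 1:1 salt at the given
ionic strength; at 300 K and 0.15 M this gives a Debye length near 8 Å.

Discretization: seven-point stencil on a regular grid; dielectric values
live on the half-grid links (a link is low-dielectric when its midpoint is
inside any probe-inflated atom sphere); charges are spread to the eight
surrounding nodes by trilinear weighting; boundary nodes carry a sum of
Debye-Hückel monopoles.  The linear system is relaxed by checkerboard
(red-black) successive over-relaxation, which is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .errors import ConvergenceError, GeometryError, ValidationError
from .parameters import ParameterizedStructure
from .sasa import accessible_points
from .titration import COULOMB_KCAL, GAS_CONSTANT_KCAL

__all__ = [
    "GridSpec",
    "PotentialGrid",
    "SurfaceMap",
    "FieldLine",
    "coulomb_constant",
    "debye_kappa2",
    "solve_linear_pb",
    "surface_potential_map",
    "trace_field_lines",
    "write_dx",
]

AVOGADRO_PER_LITER_A3 = 6.02214076e-4  # (ions/Å^3) per mol/L


def coulomb_constant(temperature: float) -> float:
    """332.0637/(R T): Coulomb prefactor in Å kT/e^2."""
    return COULOMB_KCAL / (GAS_CONSTANT_KCAL * temperature)


def debye_kappa2(ionic_strength: float, eps_out: float, temperature: float) -> float:
    """Squared inverse Debye length (Å^-2) of a 1:1 salt."""
    bjerrum = coulomb_constant(temperature) / eps_out
    n = 2.0 * ionic_strength * AVOGADRO_PER_LITER_A3  # both ion species
    return 4.0 * np.pi * bjerrum * n


@dataclass(frozen=True)
class GridSpec:
    """Regular solver grid: origin corner, spacing (Å) and node counts."""

    origin: tuple[float, float, float]
    spacing: float = 0.5
    dims: tuple[int, int, int] = (65, 65, 65)
    fill_ratio: float = 0.70

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValidationError("grid spacing must be positive")
        if any(d < 17 for d in self.dims):
            raise ValidationError("grid needs at least 17 nodes per axis")

    @property
    def extent(self) -> np.ndarray:
        return (np.array(self.dims) - 1) * self.spacing

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        o = np.asarray(self.origin, dtype=float)
        return tuple(
            o[k] + self.spacing * np.arange(self.dims[k]) for k in range(3)
        )

    @classmethod
    def around(
        cls,
        ps: ParameterizedStructure,
        spacing: float = 0.5,
        fill_ratio: float = 0.70,
        min_dim: int = 17,
    ) -> "GridSpec":
        """Center the box on the structure, sized so the atom bounding box
        (inflated radii included) occupies at most ``fill_ratio`` per axis."""
        xyz = ps.coords()
        lo = (xyz - ps.radii[:, None]).min(axis=0)
        hi = (xyz + ps.radii[:, None]).max(axis=0)
        span = np.maximum(hi - lo, spacing)
        box = span / fill_ratio
        dims = np.maximum(np.ceil(box / spacing).astype(int) + 1, min_dim)
        dims += 1 - dims % 2  # odd node counts center the box on a node
        center = (lo + hi) / 2.0
        origin = center - (dims - 1) * spacing / 2.0
        return cls(origin=tuple(origin), spacing=spacing, dims=tuple(int(d) for d in dims),
                   fill_ratio=fill_ratio)


@dataclass
class PotentialGrid:
    """Solved potential (kT/e) with its grid and physical settings."""

    spec: GridSpec
    phi: np.ndarray
    eps_in: float = 2.0
    eps_out: float = 80.0
    ionic_strength: float = 0.15
    temperature: float = 300.0
    iterations: int = 0
    residual: float = 0.0
    metadata: dict = field(default_factory=dict)

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of phi at Cartesian points."""
        return self._sample(self.phi, points)

    def _sample(self, arr: np.ndarray, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        frac = (pts - np.asarray(self.spec.origin)) / self.spec.spacing
        if np.any(frac < -1e-9) or np.any(
            frac > np.asarray(self.spec.dims) - 1 + 1e-9
        ):
            raise GeometryError("interpolation point outside grid")
        return map_coordinates(arr, frac.T, order=1, mode="nearest")

    def gradient(self, points: np.ndarray) -> np.ndarray:
        """Central-difference grad(phi) interpolated at Cartesian points."""
        if "grad" not in self.metadata:
            self.metadata["grad"] = np.gradient(self.phi, self.spec.spacing)
        g = self.metadata["grad"]
        return np.column_stack([self._sample(gk, points) for gk in g])

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        pts = np.atleast_2d(points)
        o = np.asarray(self.spec.origin)
        top = o + self.spec.extent
        return np.all((pts >= o + margin) & (pts <= top - margin), axis=1)


@dataclass
class SurfaceMap:
    """Molecular-surface sample points with interpolated potential."""

    points: np.ndarray
    atom_index: np.ndarray
    potential: np.ndarray
    sign_label: np.ndarray  # +1 / -1 / 0 at the +-threshold kT/e cut
    weight: np.ndarray  # Å^2 represented by each point
    threshold: float = 1.0


@dataclass
class FieldLine:
    polyline: np.ndarray
    start_seed: np.ndarray
    termination_reason: str  # surface | boundary | max_steps | degenerate_seed
    terminal_body: int | None = None  # index of structure hit, if any


def _dielectric_links(
    spec: GridSpec,
    ps: ParameterizedStructure,
    eps_in: float,
    eps_out: float,
    probe: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Link dielectrics (x, y, z) and the solvent mask on nodes."""
    ax = spec.axes()
    coords = ps.coords()
    inflated = ps.radii + probe
    tree = cKDTree(coords)
    rmax = float(inflated.max())

    def inside(points: np.ndarray) -> np.ndarray:
        res = np.zeros(len(points), dtype=bool)
        groups = tree.query_ball_point(points, rmax)
        for i, g in enumerate(groups):
            if g:
                d = np.linalg.norm(coords[g] - points[i], axis=1)
                res[i] = bool(np.any(d <= inflated[g]))
        return res

    def eps_at(points: np.ndarray) -> np.ndarray:
        return np.where(inside(points), eps_in, eps_out)

    nx, ny, nz = spec.dims
    h = spec.spacing

    def grid_points(xa, ya, za):
        X, Y, Z = np.meshgrid(xa, ya, za, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    ex = eps_at(grid_points(ax[0][:-1] + h / 2, ax[1], ax[2])).reshape(nx - 1, ny, nz)
    ey = eps_at(grid_points(ax[0], ax[1][:-1] + h / 2, ax[2])).reshape(nx, ny - 1, nz)
    ez = eps_at(grid_points(ax[0], ax[1], ax[2][:-1] + h / 2)).reshape(nx, ny, nz - 1)
    solvent = ~inside(grid_points(ax[0], ax[1], ax[2])).reshape(nx, ny, nz)
    return ex, ey, ez, solvent


def _spread_charges(spec: GridSpec, ps: ParameterizedStructure) -> np.ndarray:
    """Trilinear distribution of point charges onto grid nodes."""
    rho = np.zeros(spec.dims)
    frac = (ps.coords() - np.asarray(spec.origin)) / spec.spacing
    base = np.floor(frac).astype(int)
    t = frac - base
    nx, ny, nz = spec.dims
    if np.any(base < 1) or np.any(base + 1 > np.array([nx, ny, nz]) - 2):
        raise GeometryError("atom outside grid interior")
    for (i, j, k), (tx, ty, tz), q in zip(base, t, ps.charges):
        for di in (0, 1):
            wi = tx if di else 1 - tx
            for dj in (0, 1):
                wj = ty if dj else 1 - ty
                for dk in (0, 1):
                    wk = tz if dk else 1 - tz
                    rho[i + di, j + dj, k + dk] += q * wi * wj * wk
    return rho


def _boundary_condition(
    spec: GridSpec,
    ps: ParameterizedStructure,
    eps_out: float,
    kappa2: float,
    temperature: float,
) -> np.ndarray:
    """Debye-Hückel monopole sum evaluated on the grid boundary nodes."""
    C = coulomb_constant(temperature)
    kappa = np.sqrt(max(kappa2, 0.0))
    phi = np.zeros(spec.dims)
    xs, ys, zs = spec.axes()
    coords = ps.coords()
    q = ps.charges

    def fill(points: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(points[:, None, :] - coords[None, :, :], axis=2)
        d = np.maximum(d, 1e-6)
        return (C / eps_out) * (q[None, :] * np.exp(-kappa * d) / d).sum(axis=1)

    faces = []
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    for axis, idx in ((0, 0), (0, -1), (1, 0), (1, -1), (2, 0), (2, -1)):
        sl = [slice(None)] * 3
        sl[axis] = idx
        sl = tuple(sl)
        pts = np.column_stack([X[sl].ravel(), Y[sl].ravel(), Z[sl].ravel()])
        phi[sl] = fill(pts).reshape(phi[sl].shape)
        faces.append(sl)
    return phi


def solve_linear_pb(
    ps: ParameterizedStructure,
    spec: GridSpec,
    eps_in: float = 2.0,
    eps_out: float = 80.0,
    ionic_strength: float = 0.15,
    temperature: float = 300.0,
    probe: float = 1.4,
    omega: float = 1.9,
    max_iterations: int = 10_000,
    tolerance: float = 1e-6,
) -> PotentialGrid:
    """Relax the linearized PB equation to a relative residual <= tolerance."""
    if eps_in <= 0 or eps_out <= 0:
        raise ValidationError("dielectric constants must be positive")
    h = spec.spacing
    C = coulomb_constant(temperature)
    kappa2 = debye_kappa2(ionic_strength, eps_out, temperature) if ionic_strength > 0 else 0.0

    ex, ey, ez, solvent = _dielectric_links(spec, ps, eps_in, eps_out, probe)
    rho = _spread_charges(spec, ps)
    b = 4.0 * np.pi * C * rho / h  # stencil scaled by h^2

    phi = _boundary_condition(spec, ps, eps_out, kappa2, temperature)
    if not np.any(ps.charges):
        return PotentialGrid(
            spec=spec, phi=np.zeros(spec.dims), eps_in=eps_in, eps_out=eps_out,
            ionic_strength=ionic_strength, temperature=temperature,
            metadata={"model": "linearized PB", "note": "zero source"},
        )

    # screening acts on solvent nodes only; scaled by h^2 like the stencil
    lam = np.where(solvent, eps_out * kappa2 * h * h, 0.0)

    interior = (slice(1, -1),) * 3
    diag = (
        ex[:-1, 1:-1, 1:-1] + ex[1:, 1:-1, 1:-1]
        + ey[1:-1, :-1, 1:-1] + ey[1:-1, 1:, 1:-1]
        + ez[1:-1, 1:-1, :-1] + ez[1:-1, 1:-1, 1:]
        + lam[interior]
    )
    ii, jj, kk = np.indices(diag.shape)
    red = (ii + jj + kk) % 2 == 0
    black = ~red
    b_int = b[interior]
    b_norm = float(np.linalg.norm(b_int))

    def neighbor_sum() -> np.ndarray:
        return (
            ex[:-1, 1:-1, 1:-1] * phi[:-2, 1:-1, 1:-1]
            + ex[1:, 1:-1, 1:-1] * phi[2:, 1:-1, 1:-1]
            + ey[1:-1, :-1, 1:-1] * phi[1:-1, :-2, 1:-1]
            + ey[1:-1, 1:, 1:-1] * phi[1:-1, 2:, 1:-1]
            + ez[1:-1, 1:-1, :-1] * phi[1:-1, 1:-1, :-2]
            + ez[1:-1, 1:-1, 1:] * phi[1:-1, 1:-1, 2:]
        )

    view = phi[interior]
    residual = np.inf
    it = 0
    for it in range(1, max_iterations + 1):
        for mask in (red, black):
            s = neighbor_sum()
            gs = (s + b_int) / diag
            view[mask] += omega * (gs - view)[mask]
        if it % 10 == 0 or it == max_iterations:
            r = neighbor_sum() + b_int - diag * view
            residual = float(np.linalg.norm(r)) / b_norm
            if residual <= tolerance:
                break
    if residual > tolerance:
        raise ConvergenceError(
            f"SOR did not reach {tolerance:g} in {max_iterations} iterations "
            f"(residual {residual:.3g})",
            residual=residual,
        )
    if not np.all(np.isfinite(phi)):
        raise ConvergenceError("non-finite potential", residual=residual)
    return PotentialGrid(
        spec=spec, phi=phi, eps_in=eps_in, eps_out=eps_out,
        ionic_strength=ionic_strength, temperature=temperature,
        iterations=it, residual=residual,
        metadata={"model": "linearized PB", "omega": omega,
                  "kT_per_e_at_K": temperature},
    )


def surface_potential_map(
    grid: PotentialGrid,
    ps: ParameterizedStructure,
    probe: float = 1.4,
    points_per_atom: int = 960,
    threshold: float = 1.0,
) -> SurfaceMap:
    """Sample the probe-inflated molecular surface and label +-threshold kT/e."""
    pts, idx, w = accessible_points(
        ps.coords(), ps.radii, probe=probe, points_per_atom=points_per_atom
    )
    if len(pts) and not np.all(grid.contains(pts)):
        raise GeometryError("surface point outside grid")
    phi = grid.interpolate(pts) if len(pts) else np.empty(0)
    labels = np.zeros(len(pts), dtype=int)
    labels[phi >= threshold] = 1
    labels[phi <= -threshold] = -1
    return SurfaceMap(
        points=pts, atom_index=idx, potential=phi, sign_label=labels,
        weight=w, threshold=threshold,
    )


def _surface_tester(structures: list[ParameterizedStructure], probe: float):
    data = []
    for ps in structures:
        data.append((cKDTree(ps.coords()), ps.radii + probe, float((ps.radii + probe).max())))

    def hit(point: np.ndarray) -> int | None:
        for body, (tree, inflated, rmax) in enumerate(data):
            cand = tree.query_ball_point(point, rmax)
            if cand:
                d = np.linalg.norm(tree.data[cand] - point, axis=1)
                if np.any(d <= inflated[cand]):
                    return body
        return None

    return hit


def trace_field_lines(
    grid: PotentialGrid,
    seeds: np.ndarray,
    step: float = 0.25,
    max_steps: int = 2000,
    surfaces: list[ParameterizedStructure] | None = None,
    probe: float = 1.4,
    grad_floor: float = 1e-12,
) -> list[FieldLine]:
    """RK2 streamlines of the electric field E = -grad(phi).

    Each seed is integrated in both directions (downfield and upfield); the
    two half-lines are joined into one polyline.  A line stops on a molecular
    surface (when ``surfaces`` are given), at the grid boundary, or after
    ``max_steps`` steps per direction.  Seeds in a (numerically) field-free
    region are flagged ``degenerate_seed`` individually.
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    if not np.all(grid.contains(seeds)):
        raise GeometryError("seed outside grid")
    hit = _surface_tester(surfaces, probe) if surfaces else (lambda p: None)
    margin = grid.spec.spacing

    def march(seed: np.ndarray, sense: float):
        pts = [seed.copy()]
        reason, body = "max_steps", None
        x = seed.copy()
        for _ in range(max_steps):
            g = grid.gradient(x[None, :])[0]
            norm = float(np.linalg.norm(g))
            if norm < grad_floor:
                reason = "stalled"
                break
            d1 = -sense * g / norm
            mid = x + 0.5 * step * d1
            if not grid.contains(mid[None, :], margin)[0]:
                reason = "boundary"
                break
            g2 = grid.gradient(mid[None, :])[0]
            n2 = float(np.linalg.norm(g2))
            d2 = -sense * g2 / n2 if n2 >= grad_floor else d1
            nxt = x + step * d2
            if not grid.contains(nxt[None, :], margin)[0]:
                reason = "boundary"
                break
            b = hit(nxt)
            if b is not None:
                pts.append(nxt)
                reason, body = "surface", b
                break
            pts.append(nxt)
            x = nxt
        return pts, reason, body

    lines: list[FieldLine] = []
    for seed in seeds:
        g0 = grid.gradient(seed[None, :])[0]
        if float(np.linalg.norm(g0)) < grad_floor:
            lines.append(
                FieldLine(
                    polyline=seed[None, :].copy(), start_seed=seed.copy(),
                    termination_reason="degenerate_seed",
                )
            )
            continue
        fwd, reason_f, body_f = march(seed, +1.0)
        bwd, reason_b, body_b = march(seed, -1.0)
        poly = np.vstack([np.array(bwd[::-1]), np.array(fwd[1:])])
        # report the downfield (toward negative potential) termination first
        reason, body = reason_f, body_f
        if reason_f != "surface" and reason_b == "surface":
            reason, body = reason_b, body_b
        lines.append(
            FieldLine(
                polyline=poly, start_seed=seed.copy(),
                termination_reason=reason, terminal_body=body,
            )
        )
    return lines


def write_dx(grid: PotentialGrid) -> str:
    """OpenDX scalar-field text for the potential (kT/e)."""
    nx, ny, nz = grid.spec.dims
    o = grid.spec.origin
    h = grid.spec.spacing
    lines = [
        "# phosfold linearized PB potential, kT/e",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {o[0]:.6e} {o[1]:.6e} {o[2]:.6e}",
        f"delta {h:.6e} 0.000000e+00 0.000000e+00",
        f"delta 0.000000e+00 {h:.6e} 0.000000e+00",
        f"delta 0.000000e+00 0.000000e+00 {h:.6e}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    flat = grid.phi.ravel(order="C")
    for i in range(0, len(flat), 3):
        lines.append(" ".join(f"{v:.6e}" for v in flat[i : i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "regular positions regular connections" class field')
    lines.append('component "positions" value 1')
    lines.append('component "connections" value 2')
    lines.append('component "data" value 3')
    return "\n".join(lines) + "\n"
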