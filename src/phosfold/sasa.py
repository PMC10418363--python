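"""Shrake-Rupley accessible surface areas on a deterministic point set.

Each atom sphere is inflated by the probe radius and sampled with a golden
spiral (Fibonacci) point set, which is deterministic and close to uniform,
so no random number generator enters the surface calculation.  A point is
accessible when it lies outside every other inflated sphere; the accessible
fraction times the inflated sphere area gives the per-atom ASA.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError

__all__ = ["fibonacci_sphere", "shrake_rupley", "accessible_points"]

_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors on the sphere (golden spiral)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = 2.0 * np.pi * k / _GOLDEN
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _neighbor_lists(
    coords: np.ndarray, inflated: np.ndarray
) -> list[np.ndarray]:
    """Indices of atoms whose inflated spheres can occlude each atom."""
    tree = cKDTree(coords)
    rmax = float(inflated.max())
    out = []
    for i in range(len(coords)):
        cand = tree.query_ball_point(coords[i], inflated[i] + rmax)
        out.append(np.array([j for j in cand if j != i], dtype=int))
    return out


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    points_per_atom: int = 960,
) -> np.ndarray:
    """Per-atom accessible surface areas in Å²."""
    if points_per_atom < 92:
        raise ValidationError(
            f"points_per_atom = {points_per_atom} below the accuracy floor of 92"
        )
    if probe < 0:
        raise ValidationError("probe radius must be non-negative")
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float)
    inflated = radii + probe
    unit = fibonacci_sphere(points_per_atom)
    neighbors = _neighbor_lists(coords, inflated)
    areas = np.empty(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + inflated[i] * unit
        nbr = neighbors[i]
        if len(nbr) == 0:
            frac = 1.0
        else:
            d2 = ((pts[:, None, :] - coords[nbr][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (inflated[nbr] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        areas[i] = frac * 4.0 * np.pi * inflated[i] ** 2
    return areas


def accessible_points(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    points_per_atom: int = 960,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exterior Shrake-Rupley sample points.

    Returns ``(points, atom_index, weight)`` where ``weight`` is the surface
    area each point represents (inflated sphere area / points per atom).
    """
    if points_per_atom < 92:
        raise ValidationError(
            f"points_per_atom = {points_per_atom} below the accuracy floor of 92"
        )
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float)
    inflated = radii + probe
    unit = fibonacci_sphere(points_per_atom)
    neighbors = _neighbor_lists(coords, inflated)
    all_pts, all_idx, all_w = [], [], []
    for i in range(len(coords)):
        pts = coords[i] + inflated[i] * unit
        nbr = neighbors[i]
        if len(nbr):
            d2 = ((pts[:, None, :] - coords[nbr][None, :, :]) ** 2).sum(axis=2)
            keep = ~(d2 < (inflated[nbr] ** 2)[None, :]).any(axis=1)
            pts = pts[keep]
        if len(pts):
            all_pts.append(pts)
            all_idx.append(np.full(len(pts), i, dtype=int))
            all_w.append(
                np.full(len(pts), 4.0 * np.pi * inflated[i] ** 2 / points_per_atom)
            )
    if not all_pts:
        return np.empty((0, 3)), np.empty(0, dtype=int), np.empty(0)
    return np.vstack(all_pts), np.concatenate(all_idx), np.concatenate(all_w)
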