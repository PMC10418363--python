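import numpy as np
import pytest

import phosfold as pf
from phosfold.electrostatics import (
    GridSpec,
    solve_linear_pb,
    surface_potential_map,
    trace_field_lines,
    write_dx,
)
from phosfold.errors import GeometryError, ValidationError
from phosfold.parameters import ParameterizedStructure
from phosfold.structure import Atom, Structure

from conftest import C300, exterior_points


def two_charges(q1, q2, sep=10.0, radius=2.0):
    atoms = [
        Atom(1, "ION", "X", "ION", 1, "A", (-sep / 2, 0.0, 0.0)),
        Atom(2, "ION", "X", "ION", 2, "A", (sep / 2, 0.0, 0.0)),
    ]
    return ParameterizedStructure(
        structure=Structure(atoms=atoms),
        radii=np.array([radius, radius]),
        charges=np.array([q1, q2]),
    )


class TestSolver:
    def test_born_ion_exterior_within_5pct(self, born_grid):
        pts = exterior_points(seed=10)
        r = np.linalg.norm(pts, axis=1)
        exact = C300 / (80.0 * r)
        err = np.abs(born_grid.interpolate(pts) - exact) / exact
        assert err.max() < 0.05

    def test_homogeneous_medium_reproduces_coulomb(self, homogeneous_grid):
        pts = exterior_points(seed=11)
        r = np.linalg.norm(pts, axis=1)
        exact = C300 / (80.0 * r)
        err = np.abs(homogeneous_grid.interpolate(pts) - exact) / exact
        assert err.max() < 0.05

    def test_zero_charge_gives_zero_potential(self):
        ion = pf.make_born_ion(0.0, 2.0)
        spec = GridSpec(origin=(-8, -8, -8), spacing=0.5, dims=(33, 33, 33))
        g = solve_linear_pb(ion, spec)
        assert np.all(g.phi == 0.0)

    def test_charge_negation_negates_potential_exactly(self):
        spec = GridSpec(origin=(-8, -8, -8), spacing=0.5, dims=(33, 33, 33))
        gp = solve_linear_pb(pf.make_born_ion(1.0, 2.0), spec, ionic_strength=0.0)
        gn = solve_linear_pb(pf.make_born_ion(-1.0, 2.0), spec, ionic_strength=0.0)
        assert np.array_equal(gp.phi, -gn.phi)

    def test_superposition_of_charge_sets(self):
        """phi(q1 set) + phi(q2 set) = phi(q1+q2) on a fixed dielectric map."""
        spec = GridSpec(origin=(-10, -10, -10), spacing=0.5, dims=(41, 41, 41))
        a = two_charges(1.0, 0.0)
        b = two_charges(0.0, -0.5)
        ab = two_charges(1.0, -0.5)
        ga = solve_linear_pb(a, spec)
        gb = solve_linear_pb(b, spec)
        gab = solve_linear_pb(ab, spec)
        scale = np.abs(gab.phi).max()
        assert np.abs(ga.phi + gb.phi - gab.phi).max() < 1e-3 * scale

    def test_salt_screening_is_monotone(self):
        ion = pf.make_born_ion(1.0, 2.0)
        spec = GridSpec(origin=(-10, -10, -10), spacing=0.5, dims=(41, 41, 41))
        probe_pt = np.array([[6.0, 0.0, 0.0]])
        mags = [
            abs(solve_linear_pb(ion, spec, ionic_strength=I).interpolate(probe_pt)[0])
            for I in (0.0, 0.15, 0.5)
        ]
        assert mags[0] >= mags[1] >= mags[2]
        assert mags[0] > mags[2]  # screening actually acts

    def test_born_error_decreases_under_grid_refinement(self):
        ion = pf.make_born_ion(1.0, 2.0)
        errs = []
        for h, n in ((1.0, 25), (0.5, 49), (0.25, 97)):
            half = h * (n - 1) / 2
            spec = GridSpec(origin=(-half, -half, -half), spacing=h, dims=(n, n, n))
            g = solve_linear_pb(ion, spec, ionic_strength=0.0)
            pts = exterior_points(seed=12, n=100, rmin=4.0, rmax=9.0)
            r = np.linalg.norm(pts, axis=1)
            exact = C300 / (80.0 * r)
            errs.append((np.abs(g.interpolate(pts) - exact) / exact).max())
        assert errs[0] > errs[1] > errs[2]

    def test_atom_outside_grid_is_geometry_error(self):
        ion = pf.make_born_ion(1.0, 2.0)
        spec = GridSpec(origin=(10, 10, 10), spacing=0.5, dims=(17, 17, 17))
        with pytest.raises(GeometryError, match="outside grid"):
            solve_linear_pb(ion, spec)

    def test_grid_spec_invariants(self):
        with pytest.raises(ValidationError):
            GridSpec(origin=(0, 0, 0), spacing=0.0)
        with pytest.raises(ValidationError):
            GridSpec(origin=(0, 0, 0), spacing=0.5, dims=(9, 33, 33))


class TestSurfaceMap:
    def test_born_ion_surface_uniformly_positive(self, born_grid, born_ion):
        smap = surface_potential_map(born_grid, born_ion)
        assert len(smap.points) > 0
        assert np.all(smap.sign_label == 1)

    def test_dipole_hemispheres_carry_opposite_labels(self):
        dip = two_charges(1.0, -1.0)
        spec = GridSpec(origin=(-16, -16, -16), spacing=0.5, dims=(65, 65, 65))
        g = solve_linear_pb(dip, spec, ionic_strength=0.0)
        smap = surface_potential_map(g, dip)
        left = smap.points[:, 0] < 0
        assert set(smap.sign_label[left]) <= {0, 1}
        assert 1 in smap.sign_label[left]
        assert set(smap.sign_label[~left]) <= {0, -1}
        assert -1 in smap.sign_label[~left]

    def test_neutral_atoms_all_neutral_labels(self):
        ion = pf.make_born_ion(0.0, 2.0)
        spec = GridSpec(origin=(-8, -8, -8), spacing=0.5, dims=(33, 33, 33))
        g = solve_linear_pb(ion, spec)
        smap = surface_potential_map(g, ion)
        assert np.all(smap.sign_label == 0)

    def test_surface_points_lie_on_inflated_spheres(self, born_grid, born_ion):
        smap = surface_potential_map(born_grid, born_ion, probe=1.4)
        r = np.linalg.norm(smap.points, axis=1)
        assert np.allclose(r, 2.0 + 1.4, atol=1e-9)


class TestFieldLines:
    def test_radial_lines_from_point_charge(self, homogeneous_grid):
        """In a uniform medium the field of one charge is radial within 2°."""
        seeds = np.array([[6.0, 0, 0], [0, 6.0, 0], [0, 0, -6.0], [4.0, 4.0, 0]])
        lines = trace_field_lines(homogeneous_grid, seeds, step=0.25, max_steps=60)
        for fl in lines:
            mids = 0.5 * (fl.polyline[1:] + fl.polyline[:-1])
            keep = np.linalg.norm(mids, axis=1) >= 3.0
            tang = np.diff(fl.polyline, axis=0)
            tang /= np.linalg.norm(tang, axis=1)[:, None]
            rad = mids / np.linalg.norm(mids, axis=1)[:, None]
            ang = np.degrees(
                np.arccos(np.clip(np.abs((tang * rad).sum(1)), -1.0, 1.0))
            )
            assert ang[keep].max() < 2.0

    def test_dipole_midpoint_line_reaches_negative_source(self):
        dip = two_charges(1.0, -1.0)
        spec = GridSpec(origin=(-16, -16, -16), spacing=0.5, dims=(65, 65, 65))
        g = solve_linear_pb(dip, spec, ionic_strength=0.0)
        [line] = trace_field_lines(
            g, np.array([[0.0, 0.5, 0.0]]), step=0.2, surfaces=[dip]
        )
        assert line.termination_reason == "surface"
        end = line.polyline[-1]
        d_neg = np.linalg.norm(end - np.array([5.0, 0.0, 0.0]))
        assert d_neg <= 2.0 + 1.4 + 1e-6

    def test_zero_field_grid_degenerate_seeds(self):
        ion = pf.make_born_ion(0.0, 2.0)
        spec = GridSpec(origin=(-8, -8, -8), spacing=0.5, dims=(33, 33, 33))
        g = solve_linear_pb(ion, spec)
        lines = trace_field_lines(g, np.array([[1.0, 1.0, 1.0], [-2.0, 0.0, 0.0]]))
        assert all(fl.termination_reason == "degenerate_seed" for fl in lines)

    def test_seed_outside_grid_rejected(self, born_grid):
        with pytest.raises(GeometryError):
            trace_field_lines(born_grid, np.array([[99.0, 0.0, 0.0]]))


class TestOpenDx:
    def test_dx_header_and_item_count(self, born_grid):
        text = write_dx(born_grid)
        assert "object 1 class gridpositions counts 65 65 65" in text
        assert f"items {65**3} data follows" in text
        # all grid values serialized
        data_lines = [
            l for l in text.splitlines()
            if l and not l.startswith(("#", "object", "origin", "delta", "attribute", "component"))
        ]
        assert sum(len(l.split()) for l in data_lines) == 65**3
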