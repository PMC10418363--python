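import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import phosfold as pf
from phosfold.errors import GeometryError, ValidationError
from phosfold.parameters import ParameterizedStructure, TitratableSite
from phosfold.sasa import fibonacci_sphere
from phosfold.structure import Atom, Structure
from phosfold.titration import (
    GAS_CONSTANT_KCAL,
    PkaModelConfig,
    folding_energy_profile,
    net_charge,
    predict_pkas,
    stability_window,
    titration_curve,
)

RT_LN10_300 = GAS_CONSTANT_KCAL * 300.0 * np.log(10.0)


def site(model, shifted=None, acid=True, resnum=1, q=1.0):
    return TitratableSite(
        chain="A", residue_number=resnum, residue_type="ASP" if acid else "LYS",
        is_acid=acid, model_pka=model,
        shifted_pka=model if shifted is None else shifted,
        ionized_charge=-q if acid else q,
    )


class TestNetCharge:
    def test_acid_midpoint_is_minus_half(self):
        assert net_charge([site(5.0)], 5.0) == pytest.approx(-0.5)

    def test_base_midpoint_is_plus_half(self):
        assert net_charge([site(9.0, acid=False)], 9.0) == pytest.approx(0.5)

    def test_two_acids_one_base_at_ph7(self):
        sites = [site(4.0, resnum=1), site(4.0, resnum=2), site(10.0, acid=False, resnum=3)]
        expected = -2.0 / (1 + 10 ** (4.0 - 7.0)) + 1.0 / (1 + 10 ** (7.0 - 10.0))
        assert net_charge(sites, 7.0) == pytest.approx(expected)
        assert net_charge(sites, 7.0) == pytest.approx(-0.999, abs=1e-3)

    def test_out_of_range_ph_rejected(self):
        with pytest.raises(ValidationError):
            net_charge([site(5.0)], 14.5)

    @settings(max_examples=120, derandomize=True)
    @given(
        pkas=st.lists(
            st.tuples(st.floats(0.0, 14.0), st.booleans()), min_size=1, max_size=8
        )
    )
    def test_net_charge_monotone_non_increasing_in_ph(self, pkas):
        sites = [
            site(pka, acid=acid, resnum=i + 1) for i, (pka, acid) in enumerate(pkas)
        ]
        grid = np.linspace(0.0, 14.0, 141)
        q = [net_charge(sites, ph) for ph in grid]
        assert np.all(np.diff(q) <= 1e-12)


class TestFoldingEnergy:
    def test_zero_integrand_gives_zero_profile(self):
        sites = [site(5.0)]
        curve = titration_curve(sites)
        profile = folding_energy_profile(curve)
        assert np.allclose(profile.delta_g, 0.0)

    def test_single_site_plateau_closed_form(self):
        """Plateau dG(14) = RT ln10 (pKa_f - pKa_u) for one acid, 6 vs 4."""
        s = site(4.0, shifted=6.0)
        grid = np.arange(0.0, 14.0001, 0.01)
        profile = folding_energy_profile(titration_curve([s], grid), 300.0)
        expected = RT_LN10_300 * 2.0
        assert expected == pytest.approx(2.745, abs=1e-3)
        assert profile.delta_g[-1] == pytest.approx(expected, abs=2e-3)
        assert profile.delta_g[0] == 0.0

    def test_plateau_matches_adaptive_quadrature(self):
        s = site(4.0, shifted=6.0)

        def integrand(ph):
            return -1.0 / (1 + 10 ** (6.0 - ph)) + 1.0 / (1 + 10 ** (4.0 - ph))

        exact, _ = quad(integrand, 0.0, 14.0, epsabs=1e-10)
        grid = np.arange(0.0, 14.0001, 0.01)
        profile = folding_energy_profile(titration_curve([s], grid), 300.0)
        assert profile.delta_g[-1] == pytest.approx(RT_LN10_300 * exact, abs=2e-3)

    def test_quadrature_converges_under_grid_halving(self):
        s = site(4.0, shifted=6.0)
        coarse = folding_energy_profile(
            titration_curve([s], np.arange(0.0, 14.0001, 0.02)), 300.0
        )
        fine = folding_energy_profile(
            titration_curve([s], np.arange(0.0, 14.0001, 0.01)), 300.0
        )
        assert abs(coarse.delta_g[-1] - fine.delta_g[-1]) < 1e-3

    def test_profiles_add_over_disjoint_site_sets(self):
        """Linearity: dG of a union of sites is the sum of the parts."""
        set1 = [site(4.0, shifted=5.0, resnum=1)]
        set2 = [site(9.5, shifted=8.7, acid=False, resnum=2)]
        grid = np.arange(0.0, 14.0001, 0.05)
        p1 = folding_energy_profile(titration_curve(set1, grid))
        p2 = folding_energy_profile(titration_curve(set2, grid))
        p12 = folding_energy_profile(titration_curve(set1 + set2, grid))
        assert np.allclose(p1.delta_g + p2.delta_g, p12.delta_g, atol=1e-10)

    def test_non_positive_temperature_rejected(self):
        curve = titration_curve([site(5.0)])
        with pytest.raises(ValidationError):
            folding_energy_profile(curve, 0.0)

    def test_grid_not_starting_at_zero_rejected(self):
        with pytest.raises(ValidationError):
            folding_energy_profile(
                titration_curve([site(5.0)], np.linspace(1.0, 14.0, 50))
            )


class TestStabilityWindow:
    def test_flat_profile_spans_whole_range(self):
        profile = folding_energy_profile(titration_curve([site(5.0)]))
        assert stability_window(profile, 0.5) == (0.0, 14.0)

    def test_single_acid_excludes_transition_and_keeps_wider_flank(self):
        s = site(4.0, shifted=6.0)
        grid = np.arange(0.0, 14.0001, 0.01)
        profile = folding_energy_profile(titration_curve([s], grid))
        window = stability_window(profile, 0.1 * RT_LN10_300)
        lo, hi = window
        # the transition zone around pKa 4-6 is excluded; the upper flank wins
        assert lo > 6.0
        assert hi == 14.0
        # oracle: |Q_f - Q_u| <= 0.1 on the reported window, dense evaluation
        dense = np.linspace(lo, hi, 500)
        dq = np.abs(
            -1 / (1 + 10 ** (6.0 - dense)) + 1 / (1 + 10 ** (4.0 - dense))
        )
        assert dq.max() <= 0.1 + 5e-3

    def test_zero_tolerance_on_sloped_profile_is_empty(self):
        s = site(4.0, shifted=6.0)
        profile = folding_energy_profile(titration_curve([s]))
        assert stability_window(profile, 0.0) is None


def lone_asp(extra_atoms=(), extra_charges=()):
    atoms = [
        Atom(1, "CA", "C", "ASP", 1, "A", (0.0, 0.0, 40.0)),
        Atom(2, "SC", "X", "ASP", 1, "A", (0.0, 0.0, 0.0)),
    ] + list(extra_atoms)
    charges = np.concatenate([[0.0, -1.0], np.asarray(extra_charges, dtype=float)])
    radii = np.full(len(atoms), 2.0)
    s = Structure(atoms=atoms)
    sites = [
        TitratableSite(
            chain="A", residue_number=1, residue_type="ASP", is_acid=True,
            model_pka=3.8, shifted_pka=3.8, ionized_charge=-1.0,
            atom_name="SC", position=(0.0, 0.0, 0.0),
        )
    ]
    return ParameterizedStructure(
        structure=s, radii=radii, charges=charges, titratable_sites=sites
    )


class TestPkaPrediction:
    def test_isolated_site_keeps_model_pka(self):
        ps = lone_asp()
        [shifted] = predict_pkas(ps)
        assert shifted.shifted_pka == pytest.approx(3.8, abs=1e-9)

    def test_fixed_plus_one_at_4A_lowers_acid_pka_by_hand_value(self):
        """Coulomb term: -332.0637/(8*4*4)/(RT ln10) pKa units from +1 e."""
        ion = Atom(3, "ION", "X", "ION", 2, "A", (4.0, 0.0, 0.0))
        ps = lone_asp([ion], [1.0])
        config = PkaModelConfig(burial_max_shift=0.0)  # isolate the Coulomb term
        [shifted] = predict_pkas(ps, config)
        expected_shift = -332.0637 / (8.0 * 16.0) / RT_LN10_300
        assert shifted.shifted_pka == pytest.approx(3.8 + expected_shift, abs=1e-9)
        assert shifted.shifted_pka < shifted.model_pka

    def test_fully_buried_acid_gets_max_desolvation_shift(self):
        cage = [
            Atom(10 + i, "SC", "X", "ALA", 2 + i, "A", tuple(3.0 * u))
            for i, u in enumerate(fibonacci_sphere(24))
        ]
        ps = lone_asp(cage, np.zeros(24))
        config = PkaModelConfig(burial_max_shift=2.5)
        [shifted] = predict_pkas(ps, config)
        assert shifted.shifted_pka == pytest.approx(3.8 + 2.5, abs=1e-9)

    def test_overlapping_sites_raise_geometry_error(self):
        ps = pf.make_titratable_helix("DK")
        ps.titratable_sites[1].position = ps.titratable_sites[0].position
        with pytest.raises(GeometryError, match="overlap"):
            predict_pkas(ps)

    def test_no_sites_is_fine(self):
        assert predict_pkas(pf.make_born_ion(1.0, 2.0)) == []


class TestPhosphoPairWindows:
    def test_phospho_widens_stability_window(self):
        """The designed cluster reproduces the directional result: the
        phosphorylated variant's stable-pH window strictly contains the
        unmodified variant's (the low-pH flank extends)."""
        non, pho = pf.make_phospho_pair()
        sn = predict_pkas(non)
        sp = predict_pkas(pho)
        wn = stability_window(
            folding_energy_profile(titration_curve(sn)), slope_tol=0.2
        )
        wp = stability_window(
            folding_energy_profile(titration_curve(sp)), slope_tol=0.2
        )
        assert wp[0] < wn[0] - 1.0
        assert wp[1] >= wn[1]
        assert (wp[1] - wp[0]) > (wn[1] - wn[0])

    def test_phospho_cancels_the_cation_field_at_the_aspartate(self):
        non, pho = pf.make_phospho_pair()
        asp_n = next(s for s in predict_pkas(non) if s.residue_type == "ASP")
        asp_p = next(s for s in predict_pkas(pho) if s.residue_type == "ASP")
        assert asp_n.shifted_pka < asp_n.model_pka - 0.3
        assert asp_p.shifted_pka == pytest.approx(asp_p.model_pka, abs=0.05)
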