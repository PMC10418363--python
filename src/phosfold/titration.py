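"""pKa shifts, net-charge curves, and pH-dependent folding energy.

The pH-dependent part of the folding free energy follows the classical
proton-linkage (Tanford-Wyman) relation

    dG(pH) = R T ln10 * integral_0^pH (Q_f - Q_u) dpH'

where Q_f and Q_u are the net charges of the folded and unfolded states.
The unfolded state titrates with model-compound pKa values; the folded state
uses pKa values perturbed by a documented empirical model with two terms:

* a pairwise Coulomb term over the other sites' fully ionized charges with a
  distance-dependent dielectric eps(r) = slope * r, converted to pKa units by
  1/(R T ln10) -- a positive neighbouring charge favours deprotonation and
  therefore lowers any site's pKa, a negative one raises it;
* a burial desolvation penalty proportional to the Shrake-Rupley burial
  fraction of the site's titration atom, which disfavours charging buried
  groups (raises acid pKa, lowers base pKa).

This is an intentionally simple, fully specified stand-in for a dedicated
pKa predictor; it is deterministic given structure and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .errors import GeometryError, ValidationError
from .parameters import ParameterizedStructure, TitratableSite
from .sasa import fibonacci_sphere

__all__ = [
    "GAS_CONSTANT_KCAL",
    "COULOMB_KCAL",
    "PkaModelConfig",
    "TitrationCurve",
    "FoldingEnergyProfile",
    "predict_pkas",
    "net_charge",
    "titration_curve",
    "folding_energy_profile",
    "stability_window",
    "default_ph_grid",
    "curve_frame",
]

GAS_CONSTANT_KCAL = 1.9872e-3  # kcal/(mol K)
COULOMB_KCAL = 332.0637  # kcal Å / (mol e^2)
LN10 = np.log(10.0)


@dataclass(frozen=True)
class PkaModelConfig:
    """Tunable constants of the empirical folded-state pKa model.

    dielectric_slope: slope of the distance-dependent dielectric eps(r) = s*r.
    burial_max_shift: pKa shift (in pH units) applied at burial fraction 1.
    temperature: K, used only to convert interaction energies to pKa units.
    probe / points_per_atom: Shrake-Rupley settings for the burial fraction.
    """

    dielectric_slope: float = 8.0
    burial_max_shift: float = 3.0
    temperature: float = 300.0
    probe: float = 1.4
    points_per_atom: int = 960
    min_site_separation: float = 0.1  # Å, closer site atoms are a geometry error

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        if self.dielectric_slope <= 0:
            raise ValidationError("dielectric slope must be positive")


@dataclass
class TitrationCurve:
    """Folded and unfolded net charge on an ascending pH grid."""

    ph_grid: np.ndarray
    q_folded: np.ndarray
    q_unfolded: np.ndarray

    def __post_init__(self) -> None:
        self.ph_grid = np.asarray(self.ph_grid, dtype=float)
        self.q_folded = np.asarray(self.q_folded, dtype=float)
        self.q_unfolded = np.asarray(self.q_unfolded, dtype=float)
        if np.any(np.diff(self.ph_grid) <= 0):
            raise ValidationError("pH grid must be strictly ascending")
        if self.ph_grid[0] < 0 or self.ph_grid[-1] > 14:
            raise ValidationError("pH grid must lie within [0, 14]")


@dataclass
class FoldingEnergyProfile:
    """dG(pH) in kcal/mol, referenced so that dG(pH = 0) = 0 exactly."""

    ph_grid: np.ndarray
    delta_g: np.ndarray
    temperature: float
    gas_constant: float = GAS_CONSTANT_KCAL


def default_ph_grid(step: float = 0.1) -> np.ndarray:
    n = int(round(14.0 / step))
    return np.linspace(0.0, 14.0, n + 1)


def predict_pkas(
    ps: ParameterizedStructure, config: PkaModelConfig = PkaModelConfig()
) -> list[TitratableSite]:
    """Folded-state pKa values for every titratable site of ``ps``."""
    sites = ps.titratable_sites
    if not sites:
        return []
    pos = np.array([s.position for s in sites], dtype=float)
    if len(sites) > 1:
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
        off = d + np.eye(len(sites)) * 1e9
        if off.min() < config.min_site_separation:
            i, j = np.unravel_index(int(off.argmin()), off.shape)
            raise GeometryError(
                f"titratable sites {sites[i].residue_type}{sites[i].residue_number} "
                f"and {sites[j].residue_type}{sites[j].residue_number} overlap "
                f"({off.min():.3f} Å apart)"
            )

    rt_ln10 = GAS_CONSTANT_KCAL * config.temperature * LN10

    # Fixed background charges: atoms of residues that carry partial charge
    # but no titratable group (ions, cofactors).  Charges of titratable
    # residues are represented by the sites' reference charges instead, so
    # they are excluded here to avoid double counting.
    site_residues = {(s.chain, s.residue_number) for s in sites}
    bg_pos, bg_q = [], []
    for i, a in enumerate(ps.structure.atoms):
        if (a.chain, a.residue_number) not in site_residues and ps.charges[i] != 0.0:
            bg_pos.append(a.xyz)
            bg_q.append(ps.charges[i])
    bg_pos = np.array(bg_pos, dtype=float).reshape(-1, 3)
    bg_q = np.array(bg_q, dtype=float)

    atom_lookup = {
        (a.chain, a.residue_number, a.atom_name): i
        for i, a in enumerate(ps.structure.atoms)
    }
    coords = ps.coords()
    inflated = ps.radii + config.probe
    unit = fibonacci_sphere(config.points_per_atom)
    residue_of = [(a.chain, a.residue_number) for a in ps.structure.atoms]

    def burial_fraction(idx: int) -> float:
        # burial counts occlusion by OTHER residues only, so covalent /
        # intra-residue geometry (e.g. a phosphate burying its own oxygen)
        # is not mistaken for desolvation of the group
        pts = coords[idx] + inflated[idx] * unit
        others = [
            j for j in range(len(coords))
            if residue_of[j] != residue_of[idx]
        ]
        if not others:
            return 0.0
        oc = coords[others]
        orad = inflated[others]
        d2 = ((pts[:, None, :] - oc[None, :, :]) ** 2).sum(axis=2)
        buried = (d2 < (orad**2)[None, :]).any(axis=1)
        return float(buried.mean())

    out: list[TitratableSite] = []
    for i, site in enumerate(sites):
        coulomb = 0.0
        for j, other in enumerate(sites):
            if j == i:
                continue
            r = float(np.linalg.norm(pos[i] - pos[j]))
            # eps(r) = slope * r  ->  energy term q/(slope * r^2)
            coulomb += other.reference_charge / (config.dielectric_slope * r * r)
        for p_bg, q_bg in zip(bg_pos, bg_q):
            r = float(np.linalg.norm(pos[i] - p_bg))
            if r < config.min_site_separation:
                raise GeometryError(
                    f"fixed charge overlaps site {sites[i].residue_type}"
                    f"{sites[i].residue_number} ({r:.3f} Å apart)"
                )
            coulomb += q_bg / (config.dielectric_slope * r * r)
        delta_coulomb = -COULOMB_KCAL * coulomb / rt_ln10

        idx = atom_lookup.get((site.chain, site.residue_number, site.atom_name))
        burial = burial_fraction(idx) if idx is not None else 0.0
        direction = 1.0 if site.is_acid else -1.0
        delta_burial = direction * config.burial_max_shift * burial

        out.append(
            replace(site, shifted_pka=site.model_pka + delta_coulomb + delta_burial)
        )
    return out


def net_charge(
    sites: list[TitratableSite], ph: float, state: str = "folded"
) -> float:
    """Henderson-Hasselbalch net charge at one pH.

    Q = sum_bases 1/(1+10^(pH-pKa)) - sum_acids 1/(1+10^(pKa-pH)), plus any
    pH-independent fixed charges carried by the sites.  The folded state uses
    shifted pKa values, the unfolded state model-compound values.
    """
    if not 0.0 <= ph <= 14.0:
        raise ValidationError(f"pH {ph} outside [0, 14]")
    if state not in ("folded", "unfolded"):
        raise ValidationError(f"unknown state {state!r}")
    q = 0.0
    for s in sites:
        pka = s.shifted_pka if state == "folded" else s.model_pka
        if s.is_acid:
            q -= abs(s.ionized_charge) / (1.0 + 10.0 ** (pka - ph))
        else:
            q += abs(s.ionized_charge) / (1.0 + 10.0 ** (ph - pka))
        q += s.fixed_charge
    return q


def titration_curve(
    sites: list[TitratableSite], ph_grid: np.ndarray | None = None
) -> TitrationCurve:
    if ph_grid is None:
        ph_grid = default_ph_grid()
    qf = np.array([net_charge(sites, ph, "folded") for ph in ph_grid])
    qu = np.array([net_charge(sites, ph, "unfolded") for ph in ph_grid])
    return TitrationCurve(ph_grid=ph_grid, q_folded=qf, q_unfolded=qu)


def folding_energy_profile(
    curve: TitrationCurve, temperature: float = 300.0
) -> FoldingEnergyProfile:
    """Integrate R T ln10 (Q_f - Q_u) from the pH-0 reference by trapezoid."""
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    if abs(curve.ph_grid[0]) > 1e-12:
        raise ValidationError("pH grid must start at the pH 0 reference")
    integrand = curve.q_folded - curve.q_unfolded
    dg = GAS_CONSTANT_KCAL * temperature * LN10 * cumulative_trapezoid(
        integrand, curve.ph_grid, initial=0.0
    )
    dg[0] = 0.0
    if not np.all(np.isfinite(dg)):
        raise ValidationError("non-finite folding energy profile")
    return FoldingEnergyProfile(
        ph_grid=curve.ph_grid.copy(), delta_g=dg, temperature=temperature
    )


def stability_window(
    profile: FoldingEnergyProfile, slope_tol: float = 0.5
) -> tuple[float, float] | None:
    """Widest contiguous pH interval with |d(dG)/dpH| <= slope_tol.

    Slopes are central differences (one-sided at the grid ends).  Because
    d(dG)/dpH = R T ln10 (Q_f - Q_u), this is the region where folded and
    unfolded net charges nearly coincide.  Returns ``None`` when no grid
    point satisfies the tolerance.
    """
    if len(profile.ph_grid) < 3:
        raise ValidationError("profile needs at least 3 points")
    slope = np.gradient(profile.delta_g, profile.ph_grid)
    ok = np.abs(slope) <= slope_tol
    best: tuple[float, float] | None = None
    best_width = -1.0
    start = None
    for i, flag in enumerate(np.append(ok, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            lo, hi = profile.ph_grid[start], profile.ph_grid[i - 1]
            if hi - lo > best_width:
                best_width = hi - lo
                best = (float(lo), float(hi))
            start = None
    return best


def curve_frame(
    curve: TitrationCurve, profile: FoldingEnergyProfile
) -> pd.DataFrame:
    """Tabular pH / Q_folded / Q_unfolded / delta_G view for CSV export."""
    return pd.DataFrame(
        {
            "pH": curve.ph_grid,
            "Q_folded": curve.q_folded,
            "Q_unfolded": curve.q_unfolded,
            "delta_G_kcal_mol": profile.delta_g,
        }
    )
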