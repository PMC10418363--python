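"""End-to-end analyses: pH-stability comparison and dimer complementarity.

Two entry points mirror the two computational results the package exists
for: ``run_stability`` compares the pH-dependent folding-energy profile of
a structure with and without a phosphotyrosine and reports both stability
windows; ``run_dimer`` solves per-monomer electrostatics, docks the two
monomers rigidly, selects the pose with the largest buried interface, and
produces the open-book charge-complementarity report with field lines.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import __version__
from .errors import ValidationError
from .electrostatics import GridSpec, solve_linear_pb, write_dx
from .interface import dock_rigid, open_book_complementarity, select_pose
from .parameters import ParameterizedStructure, default_parameter_table, parameterize
from .structure import apply_phospho_tyrosine, read_structure, write_pdb
from .synthetic import make_patch_dimer, make_phospho_pair, make_titratable_helix
from .titration import (
    PkaModelConfig,
    curve_frame,
    default_ph_grid,
    folding_energy_profile,
    predict_pkas,
    stability_window,
    titration_curve,
)

log = logging.getLogger("phosfold")

__all__ = ["PipelineConfig", "StabilityReport", "DimerReport", "run_stability", "run_dimer"]


@dataclass
class PipelineConfig:
    """Resolved settings for both pipelines; defaults follow the study
    conditions (eps 2/80, 0.15 M salt, probe 1.4 Å, 2 grids/Å, fill 0.70,
    300 K)."""

    # input selection: either a PDB path or a toy spec kind
    structure_path: str | None = None
    toy: str | None = "phospho_pair"  # phospho_pair | helix:<SEQ> | patch_dimer
    phospho_chain: str = "A"
    phospho_residue: int = 3
    # titration
    ph_step: float = 0.1
    temperature: float = 300.0
    slope_tol: float = 0.5  # kcal/mol per pH unit
    dielectric_slope: float = 8.0
    burial_max_shift: float = 3.0
    # electrostatics
    eps_in: float = 2.0
    eps_out: float = 80.0
    ionic_strength: float = 0.15
    probe: float = 1.4
    grids_per_angstrom: float = 2.0
    fill_ratio: float = 0.70
    surface_threshold: float = 1.0  # kT/e
    # docking / complementarity
    n_rotations: int = 500
    seed: int = 0
    n_patch_pairs: int = 5
    pairing_cutoff: float = 10.0
    open_book_angle: float = 90.0
    open_book_separation: float = 15.0
    points_per_atom: int = 960
    trace_spacing: float = 1.0

    def validate(self) -> None:
        if self.eps_in <= 0 or self.eps_out <= 0:
            raise ValidationError("dielectric constants must be positive")
        if self.eps_out <= self.eps_in:
            raise ValidationError("eps_out must exceed eps_in")
        for name in ("temperature", "probe", "grids_per_angstrom", "fill_ratio",
                     "ph_step", "pairing_cutoff", "points_per_atom"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.ionic_strength < 0:
            raise ValidationError("ionic strength must be non-negative")
        if self.n_rotations < 1:
            raise ValidationError("n_rotations must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def grid_spacing(self) -> float:
        return 1.0 / self.grids_per_angstrom

    def pka_config(self) -> PkaModelConfig:
        return PkaModelConfig(
            dielectric_slope=self.dielectric_slope,
            burial_max_shift=self.burial_max_shift,
            temperature=self.temperature,
            probe=self.probe,
            points_per_atom=self.points_per_atom,
        )


@dataclass
class StabilityReport:
    config: dict
    nonphospho: dict
    phospho: dict
    window_nonphospho: tuple[float, float] | None
    window_phospho: tuple[float, float] | None
    window_width_difference: float
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)


@dataclass
class DimerReport:
    config: dict
    found: bool
    pose: dict | None
    buried_asa: float
    pair_count: int
    pairs: list[dict]
    field_line_count: int
    field_lines_to_partner: int
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)


def _stability_variants(
    config: PipelineConfig,
) -> tuple[ParameterizedStructure, ParameterizedStructure]:
    table = default_parameter_table()
    if config.toy == "phospho_pair":
        return make_phospho_pair(seed=config.seed)
    if config.toy and config.toy.startswith("helix:"):
        seq = config.toy.split(":", 1)[1]
        non = make_titratable_helix(seq.replace("y", "Y"), seed=config.seed)
        pho = make_titratable_helix(seq, seed=config.seed)
        return non, pho
    if config.structure_path is None:
        raise ValidationError("no structure path and no toy spec configured")
    s = read_structure(Path(config.structure_path).read_text())
    non = parameterize(s, table)
    pho = parameterize(
        apply_phospho_tyrosine(s, config.phospho_chain, config.phospho_residue),
        table,
    )
    return non, pho


def _variant_result(ps: ParameterizedStructure, config: PipelineConfig) -> dict:
    sites = predict_pkas(ps, config.pka_config())
    grid = default_ph_grid(config.ph_step)
    curve = titration_curve(sites, grid)
    profile = folding_energy_profile(curve, config.temperature)
    window = stability_window(profile, config.slope_tol)
    return {
        "sites": [
            {
                "residue": f"{s.residue_type}{s.residue_number}",
                "model_pka": s.model_pka,
                "shifted_pka": round(s.shifted_pka, 6),
            }
            for s in sites
        ],
        "window": list(window) if window else None,
        "delta_g_ph14": float(profile.delta_g[-1]),
        "_curve": curve,
        "_profile": profile,
    }


def run_stability(config: PipelineConfig, out_dir: str | Path | None = None) -> StabilityReport:
    """Phospho vs non-phospho pH-stability comparison."""
    config.validate()
    non_ps, pho_ps = _stability_variants(config)
    log.info("stability: %d / %d atoms", len(non_ps.structure), len(pho_ps.structure))
    res_n = _variant_result(non_ps, config)
    res_p = _variant_result(pho_ps, config)

    def width(w):
        return (w[1] - w[0]) if w else 0.0

    wn = tuple(res_n["window"]) if res_n["window"] else None
    wp = tuple(res_p["window"]) if res_p["window"] else None
    report = StabilityReport(
        config=asdict(config),
        nonphospho={k: v for k, v in res_n.items() if not k.startswith("_")},
        phospho={k: v for k, v in res_p.items() if not k.startswith("_")},
        window_nonphospho=wn,
        window_phospho=wp,
        window_width_difference=width(wp) - width(wn),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "stability_report.json").write_text(report.to_json())
        for tag, res in (("nonphospho", res_n), ("phospho", res_p)):
            curve_frame(res["_curve"], res["_profile"]).to_csv(
                out / f"curve_{tag}.csv", index=False
            )
    return report


def _dimer_monomers(
    config: PipelineConfig,
) -> tuple[ParameterizedStructure, ParameterizedStructure]:
    if config.toy == "patch_dimer" or (config.toy == "phospho_pair" and config.structure_path is None):
        return make_patch_dimer(config.n_patch_pairs, seed=config.seed)
    if config.structure_path is None:
        raise ValidationError("no structure path and no toy spec configured")
    s = read_structure(Path(config.structure_path).read_text())
    table = default_parameter_table()
    mono = parameterize(
        apply_phospho_tyrosine(s, config.phospho_chain, config.phospho_residue),
        table,
    )
    return mono, mono


def run_dimer(config: PipelineConfig, out_dir: str | Path | None = None) -> DimerReport:
    """Docking, pose selection and open-book charge complementarity."""
    config.validate()
    a, b = _dimer_monomers(config)
    log.info("dimer: monomers with %d and %d atoms", len(a.structure), len(b.structure))
    poses = dock_rigid(
        a, b, n_rotations=config.n_rotations, seed=config.seed,
        probe=config.probe, points_per_atom=config.points_per_atom,
    )
    if not poses:
        return DimerReport(
            config=asdict(config), found=False, pose=None, buried_asa=0.0,
            pair_count=0, pairs=[], field_line_count=0, field_lines_to_partner=0,
        )
    best = select_pose(poses)
    log.info("selected pose %d, buried ASA %.1f Å^2", best.rotation_index, best.buried_asa)

    from .interface import transform_structure

    bp = transform_structure(b, best)
    pb_kwargs = dict(
        eps_in=config.eps_in, eps_out=config.eps_out,
        ionic_strength=config.ionic_strength,
        temperature=config.temperature, probe=config.probe,
    )
    grid_a = solve_linear_pb(
        a, GridSpec.around(a, config.grid_spacing, config.fill_ratio), **pb_kwargs
    )
    grid_b = solve_linear_pb(
        bp, GridSpec.around(bp, config.grid_spacing, config.fill_ratio), **pb_kwargs
    )
    report_cc = open_book_complementarity(
        best, a, b, (grid_a, grid_b),
        angle=config.open_book_angle,
        separation=config.open_book_separation,
        pairing_cutoff=config.pairing_cutoff,
        probe=config.probe,
        points_per_atom=config.points_per_atom,
        trace_spacing=config.trace_spacing,
    )
    to_partner = sum(
        1 for fl in report_cc.field_lines
        if fl.termination_reason == "surface" and fl.terminal_body == 1
    )
    report = DimerReport(
        config=asdict(config),
        found=True,
        pose={
            "rotation": best.rotation.tolist(),
            "translation": best.translation.tolist(),
            "rotation_index": best.rotation_index,
            "clash_count": best.clash_count,
        },
        buried_asa=best.buried_asa,
        pair_count=report_cc.pair_count,
        pairs=report_cc.pairs,
        field_line_count=len(report_cc.field_lines),
        field_lines_to_partner=to_partner,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "dimer_report.json").write_text(report.to_json())
        (out / "monomer_a.pdb").write_text(write_pdb(a.structure))
        (out / "monomer_b_posed.pdb").write_text(write_pdb(bp.structure))
        (out / "potential_a.dx").write_text(write_dx(grid_a))
        (out / "potential_b.dx").write_text(write_dx(grid_b))
        lines_csv = ["line,point,x,y,z"]
        for li, fl in enumerate(report_cc.field_lines):
            for pi, p in enumerate(fl.polyline):
                lines_csv.append(f"{li},{pi},{p[0]:.3f},{p[1]:.3f},{p[2]:.3f}")
        (out / "field_lines.csv").write_text("\n".join(lines_csv) + "\n")
    return report
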