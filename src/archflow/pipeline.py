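"""End-to-end orchestration: geometry -> solve -> WSS -> indices -> report.

`run_pipeline` executes the full chain for one or more morphological cases at
a given mesh-resolution tier and writes standard-format outputs (VTU/MSH
meshes, CSV tables, a JSON manifest with the configuration hash and all
diagnostics).  `compare_cases` assembles the cross-case table and evaluates
the qualitative remodeling orderings the study reports:

* the aneurysm enlarges the low-TAWSS (atheroprone) wall area;
* postoperative cases perfuse no LSA (it is occluded);
* arch curvature radius: 1-week < 6-month <= normal;
* reverse axial flow inside the preoperative sac at peak systole.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .geometry import (ArchCaseSpec, build_case_geometry, default_case_specs,
                       scaled_spec, spec_to_dict)
from .indices import (IndexMaps, RiskThresholds, classify_risk_regions,
                      compute_index_maps)
from .meshing import LabeledMesh
from .perfusion import (CenterlinePath, PerfusionSummary, extract_centerline,
                        outlet_flow_rates)
from .solver import (FluidProperties, SolverConfig, check_mass_conservation,
                     solve_pulsatile)
from .wallshear import compute_wss
from .waveforms import (inlet_velocity_waveform, outlet_pressure_waveform,
                        waveform_diagnostics)

#: Mesh-size tiers (target element edge, m).  Coarse is the desk/CI tier;
#: fine approaches the element counts of patient-scale studies and is not
#: meant for routine runs.
TIER_MESH_SIZE = {"coarse": 0.005, "medium": 0.003, "fine": 0.0018}

ALL_OUTLETS = ("RSA", "RCCA", "LCCA", "LSA", "descending")

#: Systolic peak of the inlet waveform (the velocity maximum at t = 0.15 s).
PEAK_SYSTOLE_TIME = 0.15


@dataclass(frozen=True)
class PipelineConfig:
    cases: tuple[str, ...] = ("normal", "preop", "postop1w", "postop6m")
    tier: str = "coarse"
    solver: SolverConfig = field(default_factory=lambda: SolverConfig(
        time_step=0.001, n_cycles=2, save_stride=10, stabilization=0.25))
    fluid: FluidProperties = field(default_factory=FluidProperties)
    thresholds: RiskThresholds = field(default_factory=RiskThresholds)
    output_dir: str = "archflow_out"
    custom_spec_file: str | None = None
    verbosity: int = 1

    def __post_init__(self):
        if self.tier not in TIER_MESH_SIZE:
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.custom_spec_file is not None \
                and not Path(self.custom_spec_file).exists():
            raise FileNotFoundError(self.custom_spec_file)

    def config_hash(self) -> str:
        blob = json.dumps({
            "cases": list(self.cases), "tier": self.tier,
            "solver": asdict(self.solver), "fluid": asdict(self.fluid),
            "thresholds": asdict(self.thresholds),
        }, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class CaseBundle:
    """In-memory results of one case plus the paths of its artifacts."""

    label: str
    tier: str
    spec: ArchCaseSpec
    mesh: LabeledMesh
    maps: IndexMaps
    risk: "object"
    perfusion: PerfusionSummary
    centerline: CenterlinePath
    diagnostics: dict
    sac_min_axial_velocity: float | None
    files: dict = field(default_factory=dict)


def _sac_axial_minimum(field, mesh: LabeledMesh) -> float | None:
    """Minimum axial (centerline-tangent) velocity over sac nodes at peak
    systole; negative values mean retrograde flow inside the aneurysm."""
    bulge = mesh.node_data.get("aneurysm_factor")
    if bulge is None or bulge.max() <= 0.1:
        return None
    sac_nodes = np.nonzero(bulge > 0.1)[0]
    i = int(np.argmin(np.abs(field.times % field.period - PEAK_SYSTOLE_TIME)))
    u = field.velocities[i][sac_nodes]
    tangents = mesh.node_data["tangent"][sac_nodes]
    axial = np.einsum("nd,nd->n", u, tangents)
    return float(axial.min())


def run_case(label: str, config: PipelineConfig,
             spec: ArchCaseSpec | None = None) -> CaseBundle:
    """Build, solve and post-process a single case; write its artifacts."""
    t_start = time.time()
    if spec is None:
        spec = default_case_specs()[label]
    spec = scaled_spec(spec, TIER_MESH_SIZE[config.tier])
    outdir = Path(config.output_dir) / label
    outdir.mkdir(parents=True, exist_ok=True)
    log = print if config.verbosity else (lambda *a, **k: None)

    stage = "geometry"
    files = {}
    try:
        mesh = build_case_geometry(spec)
        io.write_mesh_vtu(outdir / "mesh.vtu", mesh)
        io.write_msh(outdir / "mesh.msh", mesh)
        files["mesh_vtu"] = str(outdir / "mesh.vtu")
        files["mesh_msh"] = str(outdir / "mesh.msh")
        log(f"[{label}] mesh: {len(mesh.nodes)} nodes, {len(mesh.cells)} cells")

        stage = "solve"
        inlet = inlet_velocity_waveform()
        outlet = outlet_pressure_waveform()
        field = solve_pulsatile(mesh, inlet, outlet, config.fluid,
                                config.solver)
        imbalance = check_mass_conservation(field, mesh)
        log(f"[{label}] solve: {field.diagnostics['steps']} steps, "
            f"max CFL {field.diagnostics['max_cfl']:.2f}, "
            f"flux imbalance {imbalance:.2%}")

        io.write_field_series(outdir / "fields", mesh, field)
        files["fields_pvd"] = str(outdir / "fields" / "fields.pvd")

        stage = "wss"
        wss = compute_wss(field, mesh, config.fluid)
        wss.to_frame(time_stride=10).to_csv(outdir / "wss_timeseries.csv",
                                            index=False)

        stage = "indices"
        maps = compute_index_maps(wss)
        risk = classify_risk_regions(maps, mesh, config.thresholds)
        maps.to_frame().to_csv(outdir / "index_maps.csv", index=False)
        risk.to_frame().assign(case=label).to_csv(
            outdir / "risk_regions.csv", index=False)
        io.write_surface_vtu(outdir / "wall_indices.vtu", mesh, wss.facet_ids,
                             cell_data={"tawss": maps.tawss, "osi": maps.osi,
                                        "rrt": maps.rrt})
        files["risk_csv"] = str(outdir / "risk_regions.csv")

        stage = "perfusion"
        perf = outlet_flow_rates(field, mesh, expected_outlets=ALL_OUTLETS)
        perf.to_frame(case=label).to_csv(outdir / "perfusion.csv", index=False)
        files["perfusion_csv"] = str(outdir / "perfusion.csv")

        stage = "morphology"
        path = extract_centerline(spec)
        path.to_frame().to_csv(outdir / "centerline.csv", index=False)
        io.write_vtp_polyline(outdir / "centerline.vtp", path.points)
        files["centerline_csv"] = str(outdir / "centerline.csv")

        sac_min = _sac_axial_minimum(field, mesh)
        v_diag = waveform_diagnostics(inlet)
        p_diag = waveform_diagnostics(outlet)
        diagnostics = {
            "runtime_s": time.time() - t_start,
            "mass_imbalance": imbalance,
            "max_cfl": field.diagnostics["max_cfl"],
            "cfl_warning": field.diagnostics["cfl_warning"],
            "nodes": len(mesh.nodes), "cells": len(mesh.cells),
            "outlets": sorted(mesh.outlet_names()),
            "wss_excluded_facets": wss.excluded_facets,
            "inlet_waveform_max_jump": v_diag.max_jump,
            "outlet_waveform_max_jump": p_diag.max_jump,
            "sac_min_axial_velocity": sac_min,
        }
    except Exception as exc:
        manifest = {"case": label, "tier": config.tier, "failed_stage": stage,
                    "error": repr(exc), "config_hash": config.config_hash()}
        with open(outdir / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=2)
        raise

    bundle = CaseBundle(label=label, tier=config.tier, spec=spec, mesh=mesh,
                        maps=maps, risk=risk, perfusion=perf, centerline=path,
                        diagnostics=diagnostics,
                        sac_min_axial_velocity=sac_min, files=files)
    manifest = {
        "case": label, "tier": config.tier,
        "config_hash": config.config_hash(),
        "package_version": __version__,
        "numpy_version": np.__version__,
        "spec": spec_to_dict(spec),
        "diagnostics": diagnostics,
        "files": files,
    }
    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    with open(outdir / "spec.yaml", "w") as f:
        yaml.safe_dump(spec_to_dict(spec), f, sort_keys=False)
    bundle.files["manifest"] = str(outdir / "manifest.json")
    return bundle


def run_pipeline(config: PipelineConfig) -> dict[str, CaseBundle]:
    """All requested cases; writes per-case artifacts plus the comparison."""
    bundles = {}
    for label in config.cases:
        bundles[label] = run_case(label, config)
    if len(bundles) > 1:
        table, orderings = compare_cases(bundles)
        outdir = Path(config.output_dir)
        table.to_csv(outdir / "comparison.csv", index=False)
        with open(outdir / "orderings.json", "w") as f:
            json.dump(orderings, f, indent=2)
    return bundles


def _low_tawss_fraction(bundle: CaseBundle) -> float:
    key = next(k for k in bundle.risk.criteria if k.startswith("TAWSS"))
    return bundle.risk.criteria[key]["fraction"]


def compare_cases(bundles: dict[str, CaseBundle]):
    """Cross-case metric table plus the qualitative ordering flags.

    Bundles must come from the same resolution tier (mixed-tier comparisons
    are refused).  With a single case duplicated all orderings degenerate to
    ties, which is reported honestly (>= flags hold, strict ones do not).
    """
    if len(bundles) < 2:
        raise ValueError("need at least two case bundles to compare")
    tiers = {b.tier for b in bundles.values()}
    if len(tiers) > 1:
        raise ValueError(f"refusing mixed-tier comparison: {sorted(tiers)}")

    rows = []
    for label, b in bundles.items():
        fr = b.perfusion.fractions
        row = {
            "case": label,
            "low_tawss_area_fraction": _low_tawss_fraction(b),
            "min_curvature_radius_mm": b.centerline.min_curvature_radius * 1e3,
            "mass_imbalance": b.diagnostics["mass_imbalance"],
            "sac_min_axial_velocity": b.sac_min_axial_velocity,
        }
        for name in ALL_OUTLETS:
            row[f"perfusion_fraction_{name}"] = fr.get(name, 0.0)
        rows.append(row)
    table = pd.DataFrame(rows)

    def get(label, col):
        sel = table.loc[table["case"] == label, col]
        return float(sel.iloc[0]) if len(sel) else np.nan

    orderings = {}
    if {"normal", "preop"} <= set(bundles):
        orderings["preop_low_tawss_ge_normal"] = bool(
            get("preop", "low_tawss_area_fraction")
            >= get("normal", "low_tawss_area_fraction"))
    post = [c for c in ("postop1w", "postop6m") if c in bundles]
    if post:
        orderings["postop_lsa_perfusion_zero"] = bool(all(
            get(c, "perfusion_fraction_LSA") == 0.0 for c in post))
    if {"postop1w", "postop6m"} <= set(bundles):
        ok = get("postop1w", "min_curvature_radius_mm") \
            < get("postop6m", "min_curvature_radius_mm")
        if "normal" in bundles:
            ok = ok and (get("postop6m", "min_curvature_radius_mm")
                         <= get("normal", "min_curvature_radius_mm"))
        orderings["curvature_radius_order_1w_lt_6m_le_normal"] = bool(ok)
    if "preop" in bundles:
        v = bundles["preop"].sac_min_axial_velocity
        orderings["preop_sac_backflow_at_peak_systole"] = bool(
            v is not None and v < 0.0)
    return table, orderings
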