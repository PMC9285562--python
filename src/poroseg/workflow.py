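"""End-to-end pipeline: image -> porous model -> flow -> iso-surface.

Stages: crop, coarse threshold, isotropic resample, intensity-to-porosity,
solidify, shrunken-voxel resistance, creeping-flow solve, iso-value sweep,
spherical-model indicator, selection, surface export.  A single YAML config
drives the run; anatomy presets encode the per-anatomy defaults (aneurysm:
0.1 mm target spacing and a reference iso one decade below the inlet speed;
airway: 0.25 mm, dark fluid and the inlet speed as reference).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import imagepre, porous, segmentation as seg
from .calibration import run_campaign, friction_points_from_frame, \
    collapse_diagnostic
from .flow import FaceSelector, SolverConfig, build_domain, \
    solve_creeping_flow, mass_balance_report
from .imagepre import CoarseRange, RoiBox, VolumetricImage
from .porous import ConversionSpec, FLUID_PRESETS, FluidProps

log = logging.getLogger(__name__)

#: Anatomy presets: resample target (mm), reference-iso rule, fluid polarity.
ANATOMY_PRESETS = {
    "aneurysm": {"target_spacing_mm": 0.1, "iso0_rule": "inlet/10",
                 "fluid_bright": True, "fluid": "blood"},
    "airway": {"target_spacing_mm": 0.25, "iso0_rule": "inlet",
               "fluid_bright": False, "fluid": "air"},
}


@dataclass
class PipelineConfig:
    """Resolved configuration of one segmentation run."""

    input_path: str | None = None
    input_format: str | None = None
    preset: str | None = None
    roi: tuple | None = None  # ((x0,x1),(y0,y1),(z0,z1))
    coarse_range: tuple[float, float] | None = None
    fluid_bright: bool = True
    target_spacing_mm: float | None = None
    i_fluid: float | None = None  # explicit conversion overrides coarse bounds
    i_solid: float | None = None
    eps_min: float = porous.DEFAULT_EPS_MIN
    fluid: str = "blood"
    inlet_side: str | list = "x-"
    outlet_side: str | list = "x+"
    inlet_speed: float = 1e-4
    solver_tol: float = 1e-8
    sweep_bounds: tuple[float, float] = seg.DEFAULT_SWEEP_BOUNDS
    sweep_points: int = seg.DEFAULT_SWEEP_POINTS
    iso0: float | None = None  # derived from preset rule when None
    indicator: str = "dR"
    slope_fraction: float = 0.05
    iso_override: float | None = None
    log_interp: bool = True
    surface_format: str = "stl"
    persist_fields: bool = False
    output_dir: str = "poroseg_out"

    def __post_init__(self) -> None:
        if self.preset:
            if self.preset not in ANATOMY_PRESETS:
                raise ValueError(f"unknown preset {self.preset!r}")
            p = ANATOMY_PRESETS[self.preset]
            if self.target_spacing_mm is None:
                self.target_spacing_mm = p["target_spacing_mm"]
            self.fluid_bright = p["fluid_bright"]
            if self.fluid == "blood":
                self.fluid = p["fluid"]
            if self.iso0 is None:
                self.iso0 = (self.inlet_speed / 10.0
                             if p["iso0_rule"] == "inlet/10" else self.inlet_speed)
        if self.iso0 is None:
            self.iso0 = self.inlet_speed / 10.0
        if self.indicator not in ("dR", "dr"):
            raise ValueError("indicator must be 'dR' or 'dr'")
        if self.coarse_range is not None:
            CoarseRange(*self.coarse_range)  # validate

    def fluid_props(self) -> FluidProps:
        return FLUID_PRESETS[self.fluid] if isinstance(self.fluid, str) else self.fluid

    def conversion(self, rng: CoarseRange) -> ConversionSpec:
        if self.i_fluid is not None and self.i_solid is not None:
            return ConversionSpec(self.i_fluid, self.i_solid)
        return ConversionSpec.from_range(rng.i_min, rng.i_max, self.fluid_bright)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        doc = yaml.safe_load(text) or {}
        for key in ("roi", "coarse_range", "sweep_bounds"):
            if doc.get(key) is not None:
                doc[key] = tuple(tuple(v) if isinstance(v, list) else v
                                 for v in doc[key]) if key == "roi" else tuple(doc[key])
        return cls(**doc)


@dataclass
class RunReport:
    """Machine-readable account of a pipeline run."""

    stages: list = field(default_factory=list)  # {name, seconds, detail}
    voxel_counts: dict = field(default_factory=dict)
    chosen_iso: float | None = None
    selection_method: str | None = None
    mass_balance: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def add_stage(self, name: str, seconds: float, **detail) -> None:
        self.stages.append({"name": name, "seconds": round(seconds, 3),
                            "detail": detail})
        log.info("stage %-18s %7.2fs %s", name, seconds, detail or "")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = ["poroseg run report", "=" * 50]
        for s in self.stages:
            lines.append(f"{s['name']:<20} {s['seconds']:>8.2f} s  {s['detail']}")
        lines.append(f"voxel counts: {self.voxel_counts}")
        lines.append(f"chosen iso:   {self.chosen_iso} ({self.selection_method})")
        lines.append(f"mass balance: {self.mass_balance}")
        lines.append("outputs: " + ", ".join(self.outputs))
        return "\n".join(lines)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the original error is chained as the cause."""


class _Timer:
    def __init__(self, report: RunReport, name: str):
        self.report, self.name, self.detail = report, name, {}

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, etype, evalue, tb):
        if etype is None:
            self.report.add_stage(self.name, time.perf_counter() - self.t0,
                                  **self.detail)
            return False
        raise PipelineStageError(
            f"pipeline stage {self.name!r} failed: {evalue}") from evalue


def default_sweep_values(cfg: PipelineConfig) -> np.ndarray:
    """Log-spaced sweep over the configured bounds, reference iso included."""
    vals = np.geomspace(cfg.sweep_bounds[0], cfg.sweep_bounds[1],
                        cfg.sweep_points)
    if not np.any(np.isclose(vals, cfg.iso0, rtol=1e-9)):
        vals = np.sort(np.append(vals, cfg.iso0))
    return vals


def run_pipeline(cfg: PipelineConfig, image: VolumetricImage | None = None,
                 reference_mesh: seg.SurfaceMesh | None = None) -> RunReport:
    """Execute the full segmentation pipeline and write its outputs.

    ``image`` may be passed directly (e.g. a phantom); otherwise it is read
    from ``cfg.input_path``.  If a ground-truth ``reference_mesh`` is given,
    cloud-to-mesh statistics are added to the report.  Returns the
    :class:`RunReport`; all science outputs (sweep CSV, selection JSON,
    surface mesh) are deterministic for a fixed config and image.
    """
    import pandas as pd

    report = RunReport()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "resolved_config.yaml").write_text(cfg.to_yaml())

    if image is None:
        if cfg.input_path is None:
            raise ValueError("config has no input path and no image was passed")
        with _Timer(report, "read") as t:
            image = imagepre.read_volume(cfg.input_path, cfg.input_format)
            t.detail.update(shape=list(image.shape))
    original_pixel_mm = float(image.spacing[0])
    report.voxel_counts["input"] = int(np.prod(image.shape))

    if cfg.roi is not None:
        with _Timer(report, "crop") as t:
            roi = RoiBox(tuple(r[0] for r in cfg.roi), tuple(r[1] for r in cfg.roi))
            image = imagepre.crop(image, roi)
            t.detail.update(shape=list(image.shape))
    report.voxel_counts["after_crop"] = int(np.prod(image.shape))

    if cfg.coarse_range is None:
        rng = CoarseRange(float(image.data.min()), float(image.data.max()))
    else:
        rng = CoarseRange(*cfg.coarse_range)
    with _Timer(report, "coarse_threshold") as t:
        mask = imagepre.coarse_threshold(image, rng)
        t.detail.update(kept=int(mask.sum()))
    report.voxel_counts["coarse_candidates"] = int(mask.sum())

    if cfg.target_spacing_mm is not None and not np.allclose(
            image.spacing, cfg.target_spacing_mm):
        with _Timer(report, "resample") as t:
            image = imagepre.resample_isotropic(image, cfg.target_spacing_mm)
            mask = imagepre.coarse_threshold(image, rng)
            t.detail.update(shape=list(image.shape), kept=int(mask.sum()))
    elif not image.is_isotropic:
        raise ValueError("anisotropic image requires a target spacing")
    report.voxel_counts["resampled_candidates"] = int(mask.sum())

    with _Timer(report, "porosity"):
        pf = porous.porosity_from_intensity(image, cfg.conversion(rng), mask)
        pf = porous.solidify(pf, cfg.eps_min)
    report.voxel_counts["fluid_voxels"] = int(pf.fluid_mask.sum())

    with _Timer(report, "resistance"):
        rf = porous.shrunken_viscous_resistance(pf, cfg.fluid_props())

    with _Timer(report, "solve") as t:
        dom = build_domain(pf, rf, cfg.inlet_side, cfg.outlet_side)
        sol = solve_creeping_flow(dom, cfg.fluid_props(),
                                  SolverConfig(inlet_speed=cfg.inlet_speed,
                                               tol=cfg.solver_tol))
        t.detail.update(fluid=dom.n_fluid, removed=dom.n_removed_cells,
                        residuals=sol.residuals)
    report.voxel_counts["flow_domain"] = dom.n_fluid
    report.mass_balance = mass_balance_report(sol)

    if cfg.persist_fields:
        for name, arr in (("porosity", pf.epsilon), ("resistance", rf.P_v),
                          ("speed", sol.speed)):
            p = outdir / f"{name}.nii.gz"
            imagepre.write_volume(VolumetricImage(arr, image.spacing,
                                                  image.origin), p)
            report.outputs.append(str(p))

    with _Timer(report, "sweep") as t:
        iso_values = default_sweep_values(cfg)
        sweep = seg.iso_sweep(sol.speed, iso_values, image.spacing,
                              image.origin, log_interp=cfg.log_interp)
        t.detail.update(n_iso=len(iso_values))

    with _Timer(report, "select") as t:
        curve = seg.indicator_curve(sweep, cfg.iso0)
        sel = seg.select_iso(curve, indicator=cfg.indicator,
                             slope_fraction=cfg.slope_fraction,
                             override=cfg.iso_override)
        t.detail.update(method=sel.method, iso=sel.chosen_iso)
    report.chosen_iso = sel.chosen_iso
    report.selection_method = sel.method

    with _Timer(report, "extract") as t:
        mesh = seg.extract_isosurface(sol.speed, sel.chosen_iso, image.spacing,
                                      image.origin, log_interp=cfg.log_interp,
                                      largest_component=True)
        t.detail.update(vertices=len(mesh.vertices), watertight=mesh.watertight)

    sweep_csv = outdir / "sweep.csv"
    pd.DataFrame({"iso": sweep.iso_values, "volume_mm3": sweep.volumes,
                  "area_mm2": sweep.areas, "components": sweep.component_counts,
                  "dR_mm": curve.dR, "dr_mm": curve.dr}).to_csv(
        sweep_csv, index=False, float_format="%.10g")
    report.outputs.append(str(sweep_csv))

    sel_json = outdir / "selection.json"
    sel_json.write_text(json.dumps(
        {"chosen_iso": sel.chosen_iso, "method": sel.method,
         "diagnostics": sel.diagnostics, "R0_mm": curve.R0, "r0_mm": curve.r0},
        indent=2, sort_keys=True))
    report.outputs.append(str(sel_json))

    surf = outdir / f"surface.{cfg.surface_format}"
    seg.export_surface(mesh, surf)
    report.outputs.append(str(surf))

    if reference_mesh is not None:
        with _Timer(report, "evaluate") as t:
            c2m = seg.cloud_to_mesh_distance(mesh, reference_mesh,
                                             original_pixel_mm)
            t.detail.update(**c2m)
        report.mass_balance["c2m"] = c2m

    (outdir / "report.json").write_text(report.to_json())
    (outdir / "report.txt").write_text(report.to_text())
    return report


def run_calibration(resolution: int = 64, analytic: bool = False,
                    output_dir: str | Path | None = None, **kwargs) -> dict:
    """Run the channel calibration campaign; optionally write CSV + JSON.

    Returns the campaign table, the shrunken-voxel fit (A, B, rms) and the
    collapse diagnostics of both non-dimensionalisations.
    """
    df, fit = run_campaign(resolution=resolution, analytic=analytic, **kwargs)
    shrunken_cv = collapse_diagnostic(friction_points_from_frame(df, "shrunken"))
    packed_cv = collapse_diagnostic(friction_points_from_frame(df, "packed"))
    result = {"table": df, "fit": fit, "collapse_shrunken": shrunken_cv,
              "collapse_packed": packed_cv}
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "calibration.csv", index=False, float_format="%.10g")
        (out / "fit.json").write_text(json.dumps(
            {"A": fit.A, "B": fit.B, "rms_residual": fit.rms_residual,
             "n_points": fit.n_points,
             "collapse_cv_shrunken": shrunken_cv["cv"],
             "collapse_cv_packed": packed_cv["cv"]}, indent=2, sort_keys=True))
    return result
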