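"""Two-step decompressive-craniectomy simulation pipeline.

The planning procedure pairs two finite-element computations per swelling
level lambda_g:

1. closed-skull step: the skull is sealed (every boundary facet fixed) and
   the growth ramped up; the volume-averaged ICP loading is recorded.  In a
   rigid, fully-fixed cavity with uniform swelling this state is
   homogeneous, so the ICP-vs-lambda_g calibration is geometry-independent.
2. open-skull step: the same mesh with the craniectomy opening(s) active;
   swollen tissue bulges through the opening and the herniated volume,
   stress extrema, displacement maxima and midline shift are extracted.

A :class:`PlanningCurve` pairs the closed-skull ICP loading (x-axis) with
the open-skull outcomes (y-axes) across the swelling schedule — the
clinician-facing product.  Sweeps over opening size and tissue shear
modulus, and the injured/non-injured-side (hemispheric) study, reuse the
same two steps.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import postprocess as post
from .constitutive import MMHG_PA, GrowthField, MaterialParams, VascularParams
from .fe_core import SolutionState, SolverOptions, solve_growth_ramp
from .geometry import (
    REGION_LEFT,
    REGION_RIGHT,
    HeadGeometry,
    LabeledMesh,
    OpeningSpec,
    build_idealized_head,
    mesh_head,
    read_mesh,
)

__all__ = [
    "ScenarioConfig",
    "PlanningCurve",
    "closed_skull_step",
    "open_skull_step",
    "run_scenario",
    "hemispheric_injury_study",
    "shear_modulus_sweep",
]

CURVE_COLUMNS = ["lambda_g", "icp_mmHg", "herniated_ml", "max_comp_stress_kPa",
                 "max_disp_mm", "midline_shift_mm"]

_INJURED_CHOICES = ("whole_brain", "left_hemisphere", "right_hemisphere")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class ScenarioConfig:
    """One craniectomy scenario: geometry, opening(s), physics, schedule.

    Exactly one geometry source: either ``semi_axes_mm`` (idealized
    ellipsoidal head, the default) or ``mesh_path`` (an externally supplied
    labeled mesh).  ``injured_regions`` selects where swelling is
    prescribed; the default follows the whole-brain-injured convention.
    """

    semi_axes_mm: tuple[float, float, float] = (80.0, 66.0, 59.0)
    mesh_path: str | None = None
    openings: list[OpeningSpec] = field(default_factory=list)
    mat: MaterialParams = field(default_factory=MaterialParams)
    vasc: VascularParams = field(default_factory=VascularParams)
    lambda_target: float = 1.1
    schedule: list[float] = field(default_factory=list)
    injured_regions: str = "whole_brain"
    icp_method: str = "avg_total_pressure"
    solver: SolverOptions = field(default_factory=SolverOptions)
    h_mm: float = 16.0
    outdir: str | None = None

    def __post_init__(self):
        if self.injured_regions not in _INJURED_CHOICES:
            raise ValueError(f"injured_regions must be one of {_INJURED_CHOICES}")
        if self.icp_method not in ("avg_total_pressure", "avg_fluid_pressure"):
            raise ValueError("icp_method must be avg_total_pressure or "
                             "avg_fluid_pressure")
        if self.mesh_path is not None and self.semi_axes_mm is not None \
                and tuple(self.semi_axes_mm) != (80.0, 66.0, 59.0):
            raise ValueError("give either mesh_path or semi_axes_mm, not both")
        if not self.schedule:
            self.schedule = [round(x, 10) for x in
                             np.linspace(1.0, self.lambda_target, 5)[1:]]

    # -- derived objects ---------------------------------------------------

    def growth(self) -> GrowthField:
        """Growth field implied by the injury selection and schedule."""
        if self.injured_regions == "whole_brain":
            lam = self.lambda_target
        elif self.injured_regions == "left_hemisphere":
            lam = {REGION_LEFT: self.lambda_target}
        else:
            lam = {REGION_RIGHT: self.lambda_target}
        return GrowthField(lambda_g=lam, schedule=list(self.schedule))

    def geometry(self) -> HeadGeometry:
        return build_idealized_head(self.semi_axes_mm, self.openings)

    def build_mesh(self) -> LabeledMesh:
        if self.mesh_path is not None:
            return read_mesh(self.mesh_path)
        return mesh_head(self.geometry(), h=self.h_mm)


# ---------------------------------------------------------------------------
# planning curve
# ---------------------------------------------------------------------------


@dataclass
class PlanningCurve:
    """Herniated-volume-vs-ICP planning records over a swelling schedule.

    ``table`` has one row per lambda_g level with columns
    lambda_g, icp_mmHg, herniated_ml, max_comp_stress_kPa, max_disp_mm,
    midline_shift_mm; the lambda_g = 1 baseline row is all zeros.
    ``metadata`` records opening kind/area and a parameter fingerprint.
    """

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    #: per-level outcome reports (lambda_g > 1 rows), in table order
    reports: list = field(default_factory=list)

    def validate(self) -> None:
        t = self.table
        if not np.all(np.diff(t["lambda_g"]) > 0):
            raise ValueError("planning-curve rows must be ordered by lambda_g")
        hv = t["herniated_ml"].to_numpy()
        if np.any(hv < -1e-6):
            raise ValueError("herniated volume must be non-negative")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.8g")

    @classmethod
    def from_reports(cls, reports: list[post.DCCReport],
                     icp_by_level: dict[float, float],
                     metadata: dict | None = None) -> "PlanningCurve":
        rows = [{
            "lambda_g": 1.0, "icp_mmHg": 0.0, "herniated_ml": 0.0,
            "max_comp_stress_kPa": 0.0, "max_disp_mm": 0.0,
            "midline_shift_mm": 0.0,
        }]
        for rep in reports:
            rows.append({
                "lambda_g": rep.lambda_g,
                "icp_mmHg": icp_by_level[rep.lambda_g],
                "herniated_ml": rep.herniated_volume_ml,
                "max_comp_stress_kPa": rep.max_compressive_stress_kPa,
                "max_disp_mm": rep.max_displacement_mm,
                "midline_shift_mm": rep.midline_shift_mm,
            })
        return cls(table=pd.DataFrame(rows, columns=CURVE_COLUMNS),
                   metadata=metadata or {}, reports=list(reports))


def _param_fingerprint(config: ScenarioConfig) -> str:
    import hashlib
    items = (tuple(config.semi_axes_mm), config.h_mm, config.lambda_target,
             tuple(config.schedule), config.injured_regions, config.icp_method,
             dataclasses.astuple(config.mat),
             dataclasses.astuple(config.vasc))
    return hashlib.sha256(repr(items).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# the two steps
# ---------------------------------------------------------------------------


def closed_skull_step(config: ScenarioConfig,
                      mesh: LabeledMesh | None = None) -> list[tuple[float, float]]:
    """Closed-skull ICP calibration: (lambda_g, icp_loading_mmHg) per level.

    Openings are sealed (every boundary facet treated as fixed interface)
    and the growth ramped through the schedule; the volume-averaged ICP
    loading per ``config.icp_method`` is recorded relative to the
    lambda_g = 1 baseline.  Strictly increasing in lambda_g.
    """
    mesh = mesh or config.build_mesh()
    growth = config.growth()
    records, _ = solve_growth_ramp(mesh, growth, config.mat, config.vasc,
                                   config.solver, record_at=growth.schedule,
                                   sealed=True)
    baseline = 0.0 if config.icp_method == "avg_total_pressure" \
        else config.vasc.p_infinity / MMHG_PA
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for level in growth.schedule:
            icp = post.icp_loading(records[level], mesh, config.icp_method)
            out.append((level, icp - baseline))
    return out


def open_skull_step(config: ScenarioConfig, lambda_g: float,
                    mesh: LabeledMesh | None = None) -> SolutionState:
    """Open-skull craniectomy solve at one swelling level.

    The brain bulges through the opening(s); the returned state carries the
    converged displacement/pressure fields for post-processing.
    """
    if not config.openings and config.mesh_path is None:
        raise ValueError("open_skull_step requires at least one opening")
    mesh = mesh or config.build_mesh()
    scaled = GrowthField(
        lambda_g=(lambda_g if config.injured_regions == "whole_brain"
                  else {(REGION_LEFT if config.injured_regions == "left_hemisphere"
                         else REGION_RIGHT): lambda_g}),
        schedule=[lambda_g] if lambda_g > 1 else [1.0])
    records, final = solve_growth_ramp(mesh, scaled, config.mat, config.vasc,
                                       config.solver,
                                       record_at=[lambda_g] if lambda_g > 1 else [])
    return records.get(lambda_g, final)


# ---------------------------------------------------------------------------
# scenario runner and sweeps
# ---------------------------------------------------------------------------


def run_scenario(config: ScenarioConfig,
                 mesh: LabeledMesh | None = None,
                 export_states: bool = False) -> PlanningCurve:
    """Run the full two-step procedure over the swelling schedule.

    Pairs each level's closed-skull ICP loading with the open-skull
    herniated volume and stress/displacement summaries.  Writes
    ``curve.csv`` (and per-level VTU snapshots when requested) under
    ``config.outdir`` if set.  On a solver failure the rows completed so
    far are persisted with a failure marker before the error propagates.
    """
    mesh = mesh or config.build_mesh()
    icp = dict(closed_skull_step(config, mesh))
    growth = config.growth()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    metadata = {
        "openings": [(op.kind, op.area_mm2) for op in config.openings],
        "fingerprint": _param_fingerprint(config),
        "icp_method": config.icp_method,
    }
    opened = bool(config.openings) or config.mesh_path is not None
    reports: list[post.DCCReport] = []
    try:
        # for a sealed scenario the "open" step degenerates to the sealed
        # solve itself (zero herniation, confined stress state)
        records, _ = solve_growth_ramp(mesh, growth, config.mat, config.vasc,
                                       config.solver,
                                       record_at=growth.schedule,
                                       sealed=not opened)
        for level in growth.schedule:
            if level == 1.0:
                continue
            st = records[level]
            reports.append(post.dcc_report(st, mesh))
            if outdir and export_states:
                post.export_fields(st, mesh, outdir / f"state_lg{level:.4f}.vtu")
    except Exception:
        if outdir:
            partial = PlanningCurve.from_reports(
                reports, {r.lambda_g: icp[r.lambda_g] for r in reports},
                metadata)
            partial.metadata["failed"] = True
            partial.to_csv(outdir / "curve_partial_FAILED.csv")
        raise
    curve = PlanningCurve.from_reports(
        reports, {r.lambda_g: icp[r.lambda_g] for r in reports}, metadata)
    curve.validate()
    if outdir:
        curve.to_csv(outdir / "curve.csv")
    return curve


def hemispheric_injury_study(config: ScenarioConfig,
                             mesh_h: float | None = None) -> dict:
    """Injured- vs non-injured-side craniectomy and midline shift.

    Three runs with single-hemisphere swelling (the left hemisphere is the
    injured one): (a) sealed skull — the pre-surgical control; (b) opening
    contralateral to the injury (right side); (c) opening ipsilateral
    (left side).  Returns per-case midline shift (mm) and states.  The
    expected clinical ordering is |ipsilateral| < |control| <
    |contralateral|.
    """
    h = mesh_h or config.h_mm
    template = config.openings[0] if config.openings \
        else OpeningSpec.unilateral(40.0)
    if template.kind != "unilateral_circular":
        raise ValueError("hemispheric study requires a unilateral circular "
                         "opening template")
    r = template.radius_mm
    cases = {
        "control": [],
        "contralateral": [OpeningSpec.unilateral(r, axis=(-1.0, 0.0, 0.0))],
        "ipsilateral": [OpeningSpec.unilateral(r, axis=(1.0, 0.0, 0.0))],
    }
    out = {}
    for name, openings in cases.items():
        cfg = dataclasses.replace(
            config, openings=openings, injured_regions="left_hemisphere",
            h_mm=h, outdir=None)
        mesh = cfg.build_mesh()
        growth = cfg.growth()
        records, final = solve_growth_ramp(
            mesh, growth, cfg.mat, cfg.vasc, cfg.solver,
            record_at=[growth.target], sealed=(name == "control"))
        st = records.get(growth.target, final)
        out[name] = {
            "midline_shift_mm": post.midline_shift(st, mesh),
            "state": st,
            "mesh": mesh,
        }
    return out


def shear_modulus_sweep(config: ScenarioConfig,
                        mu_values=(5e3, 10e3, 20e3)) -> dict[float, PlanningCurve]:
    """Planning curves for a range of tissue shear moduli, K fixed.

    Mirrors the biomechanical-property sensitivity study: stiffer tissue
    herniates less at the same ICP loading, while peak displacement is
    nearly modulus-independent and peak compressive stress scales with mu.
    """
    out = {}
    for mu in mu_values:
        cfg = dataclasses.replace(
            config, mat=dataclasses.replace(config.mat, mu=float(mu)),
            outdir=None)
        out[float(mu)] = run_scenario(cfg)
    return out
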