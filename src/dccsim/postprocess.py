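"""Scalar outcomes and field exports from converged craniectomy states.

Extracts the clinically reported quantities: herniated brain volume (two
independent estimators), volume-averaged ICP loading, midline shift at the
mid-sagittal plane, and solid-stress / displacement extrema.  Reporting
units follow clinical convention: ml, mm-Hg, mm (cm in field exports for
displacement), kPa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import constitutive as con
from .constitutive import MMHG_PA
from .fe_core import MixedModel, SolutionState, _gather
from .geometry import LabeledMesh, write_vtu

__all__ = [
    "DCCReport",
    "herniated_volume",
    "icp_loading",
    "midline_shift",
    "stress_displacement_extrema",
    "export_fields",
    "dcc_report",
]

M3_TO_ML = 1e6
M_TO_MM = 1e3

# VTK quadratic-tetra midside ordering relative to TET_EDGES
_VTK_EDGE_PERM = (0, 3, 1, 2, 4, 5)


def _require_model(state: SolutionState, mesh: LabeledMesh) -> MixedModel:
    if state.model is None:
        state.model = MixedModel(mesh)
    return state.model


def _deformation(state: SolutionState):
    model = state.model
    lam = state.lam_cells if state.lam_cells is not None \
        else np.ones(len(model.mesh.cells))
    F, pq, gradp = _gather(model, state.u, state.p_i)
    return F, pq, gradp, np.repeat(lam[:, None], len(model.qw), axis=1)


def state_mat(state: SolutionState):
    """Material parameters attached to a state (set by the solver pipeline)."""
    mat = getattr(state, "mat", None)
    if mat is None:
        raise ValueError("state carries no material parameters; pass the "
                         "state produced by the pipeline or set state.mat")
    return mat


# ---------------------------------------------------------------------------
# herniated volume
# ---------------------------------------------------------------------------


def _facet6(model: MixedModel) -> np.ndarray:
    """Boundary facets as 6-node quadratic triangles (3 vertices + midnodes)."""
    facets = model.mesh.facets
    m01 = model.edge_midnode(np.sort(facets[:, (0, 1)], axis=1))
    m12 = model.edge_midnode(np.sort(facets[:, (1, 2)], axis=1))
    m20 = model.edge_midnode(np.sort(facets[:, (2, 0)], axis=1))
    return np.column_stack([facets, m01, m12, m20])


def _tri_rule(n: int = 3):
    """Conical-product Gauss rule on the reference triangle (degree 2n-1)."""
    from scipy.special import roots_jacobi

    t, wu = roots_jacobi(n, 1.0, 0.0)
    u, wu = (1.0 + t) / 2.0, wu / 4.0
    s, wv = roots_jacobi(n, 0.0, 0.0)
    v, wv = (1.0 + s) / 2.0, wv / 2.0
    U, V = np.meshgrid(u, v, indexing="ij")
    pts = np.column_stack([U.ravel(), (V * (1.0 - U)).ravel()])
    w = (wu[:, None] * wv[None, :]).ravel()
    return pts, w


def _p2_tri_shape(pts: np.ndarray):
    """Quadratic triangle shapes: vertices then midnodes (01), (12), (20)."""
    x, y = pts.T
    L = np.column_stack([1.0 - x - y, x, y])
    dL = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])
    nq = len(pts)
    N = np.empty((nq, 6))
    dN = np.empty((nq, 6, 2))
    for i in range(3):
        N[:, i] = L[:, i] * (2 * L[:, i] - 1)
        dN[:, i] = (4 * L[:, i] - 1)[:, None] * dL[i]
    for e, (i, j) in enumerate(((0, 1), (1, 2), (2, 0))):
        N[:, 3 + e] = 4 * L[:, i] * L[:, j]
        dN[:, 3 + e] = 4 * (L[:, i][:, None] * dL[j] + L[:, j][:, None] * dL[i])
    return N, dN


_TRI_PTS, _TRI_W = _tri_rule(3)
_TRI_N, _TRI_dN = _p2_tri_shape(_TRI_PTS)


def _enclosed_volume(coords: np.ndarray, facet6: np.ndarray) -> float:
    """Volume enclosed by the (outward-oriented) curved quadratic boundary,
    via the divergence theorem V = (1/3) surf_int x . n dA with a degree-5
    rule, exact for the piecewise-quadratic surface."""
    X = coords[facet6]                                   # (nf, 6, 3)
    xq = np.einsum("qa,fai->fqi", _TRI_N, X)
    xu = np.einsum("qa,fai->fqi", _TRI_dN[:, :, 0], X)
    xv = np.einsum("qa,fai->fqi", _TRI_dN[:, :, 1], X)
    integrand = np.einsum("fqi,fqi->fq", xq, np.cross(xu, xv))
    return float((integrand @ _TRI_W).sum() / 3.0)


def herniated_volume(state: SolutionState, mesh: LabeledMesh,
                     rtol_warn: float = 0.02) -> tuple[float, float]:
    """Herniated brain volume in ml: (primary, secondary) estimators.

    Primary: the volume change of the brain, int (det F - 1) dV0 over the
    reference domain.  Secondary: the change in the volume enclosed by the
    deformed boundary surface (the bulge through the openings; the fixed
    interface does not move).  The two are analytically identical; their
    discrete difference measures surface-resolution error, and a
    disagreement beyond ``rtol_warn`` triggers a warning.
    """
    model = _require_model(state, mesh)
    F, _, _, _ = _deformation(state)
    J = con.det33(F)
    primary = float(((J - 1.0) * model.dV).sum()) * M3_TO_ML

    f6 = _facet6(model)
    x_ref = model.nodes2
    x_def = model.nodes2 + state.u
    secondary = (_enclosed_volume(x_def, f6) - _enclosed_volume(x_ref, f6)) * M3_TO_ML
    scale = max(abs(primary), abs(secondary))
    if scale > 0.05 and abs(primary - secondary) > rtol_warn * scale:
        warnings.warn(
            f"herniated-volume estimators disagree by more than {rtol_warn:.0%}: "
            f"{primary:.3f} vs {secondary:.3f} ml (under-resolved opening?)",
            stacklevel=2)
    return primary, secondary


# ---------------------------------------------------------------------------
# ICP estimators
# ---------------------------------------------------------------------------


def icp_loading(state: SolutionState, mesh: LabeledMesh,
                method: str = "avg_total_pressure") -> float:
    """Volume-averaged intracranial pressure loading in mm-Hg.

    ``avg_total_pressure``: mean of -tr(sigma_tot)/3 over the (deformed)
    brain.  ``avg_fluid_pressure``: mean interstitial fluid pressure.  The
    closed-skull value at the target swelling is the x-axis of the planning
    curves; applying either estimator to an open-skull state is legal but
    not the planning-curve usage, so it warns.
    """
    if method not in ("avg_total_pressure", "avg_fluid_pressure"):
        raise ValueError(f"unknown icp method {method!r}")
    model = _require_model(state, mesh)
    if (mesh.facet_tags > 1).any() and np.abs(state.u).max() > 0:
        warnings.warn("icp_loading applied to an open-skull state; the "
                      "planning curves use the closed-skull value", stacklevel=2)
    F, pq, _, lamq = _deformation(state)
    J = con.det33(F)
    w = J * model.dV
    if method == "avg_fluid_pressure":
        return float((pq * w).sum() / w.sum()) / MMHG_PA
    Fe = F / lamq[..., None, None]
    sig = con.cauchy_stress_from_Fe(Fe, state_mat(state))
    tr = sig[..., 0, 0] + sig[..., 1, 1] + sig[..., 2, 2] - 3.0 * pq
    return float((-(tr / 3.0) * w).sum() / w.sum()) / MMHG_PA


# ---------------------------------------------------------------------------
# midline shift
# ---------------------------------------------------------------------------


def midline_shift(state: SolutionState, mesh: LabeledMesh,
                  band_mm: float | None = None) -> float:
    """Signed midline shift in mm.

    The proxy for the cerebral falx is the set of P2 nodes within half an
    element size of the mid-sagittal plane; the shift is the displacement
    component along the sagittal normal with the largest magnitude there
    (positive = toward the left hemisphere, x > 0).
    """
    model = _require_model(state, mesh)
    band = band_mm if band_mm is not None else 0.5 * mesh.characteristic_h_mm
    normal = mesh.geometry.sagittal_normal if mesh.geometry is not None \
        else np.array([1.0, 0.0, 0.0])
    dist = model.nodes2_mm @ normal
    sel = np.abs(dist) <= band
    if not np.any(sel):
        raise ValueError(f"no nodes within {band:.2f} mm of the mid-sagittal "
                         "plane; refine the mesh or widen the band")
    un = (state.u @ normal) * M_TO_MM
    i = np.argmax(np.abs(un[sel]))
    return float(un[sel][i])


# ---------------------------------------------------------------------------
# stress and displacement extrema
# ---------------------------------------------------------------------------


def stress_displacement_extrema(state: SolutionState, mesh: LabeledMesh):
    """Solid-stress and displacement extrema of a converged state.

    Returns (max_compressive_stress_kPa, max_displacement_mm, percentiles)
    where max compressive stress is the largest magnitude of the most
    negative principal Cauchy stress of the solid phase over quadrature
    points, and ``percentiles`` carries its volume-weighted 99th/95th
    percentiles (raw maxima can grow at the reentrant craniectomy edge
    under refinement; the percentiles are the mesh-stable summary).
    """
    model = _require_model(state, mesh)
    F, pq, _, lamq = _deformation(state)
    Fe = F / lamq[..., None, None]
    sig = con.cauchy_stress_from_Fe(Fe, state_mat(state))
    eig = np.linalg.eigvalsh(sig)
    comp = np.maximum(0.0, -eig[..., 0])      # compressive magnitude, Pa
    w = model.dV.ravel()
    c = comp.ravel()
    order = np.argsort(c)
    cum = np.cumsum(w[order])
    cum /= cum[-1]
    p99 = float(c[order][min(np.searchsorted(cum, 0.99), len(c) - 1)])
    p95 = float(c[order][min(np.searchsorted(cum, 0.95), len(c) - 1)])
    imax = int(np.argmax(c))
    e, q = np.unravel_index(imax, comp.shape)
    loc = model.N2[q] @ model.nodes2_mm[model.cells10[e]]
    disp = float(np.linalg.norm(state.u, axis=1).max() * M_TO_MM)
    return (float(c.max() / 1e3), disp,
            {"p99_kPa": p99 / 1e3, "p95_kPa": p95 / 1e3,
             "max_location_mm": loc})


# ---------------------------------------------------------------------------
# report and field export
# ---------------------------------------------------------------------------


@dataclass
class DCCReport:
    """Scalar outcome summary of one converged craniectomy state."""

    lambda_g: float
    herniated_volume_ml: float
    herniated_volume_surface_ml: float
    icp_loading_mmHg: dict[str, float]
    midline_shift_mm: float
    max_compressive_stress_kPa: float
    max_displacement_mm: float
    stress_percentiles: dict = field(default_factory=dict)
    estimator_agreement: float = 0.0


def dcc_report(state: SolutionState, mesh: LabeledMesh) -> DCCReport:
    """Assemble the full outcome report for one state."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hv, hv2 = herniated_volume(state, mesh)
        icp = {m: icp_loading(state, mesh, m)
               for m in ("avg_total_pressure", "avg_fluid_pressure")}
    smax, dmax, pct = stress_displacement_extrema(state, mesh)
    agreement = abs(hv - hv2) / max(abs(hv), abs(hv2), 1e-9)
    return DCCReport(
        lambda_g=state.lambda_g_achieved,
        herniated_volume_ml=hv, herniated_volume_surface_ml=hv2,
        icp_loading_mmHg=icp,
        midline_shift_mm=midline_shift(state, mesh),
        max_compressive_stress_kPa=smax, max_displacement_mm=dmax,
        stress_percentiles=pct, estimator_agreement=agreement)


def export_fields(state: SolutionState, mesh: LabeledMesh, path) -> None:
    """Write a VTU snapshot of a converged state.

    Point data: "displacement" (cm, quadratic tets), "p_i" (mm-Hg).
    Cell data: "principal_stress_min" (kPa, most negative principal solid
    stress, cell-averaged) and the region tag.
    """
    model = _require_model(state, mesh)
    F, pq, _, lamq = _deformation(state)
    Fe = F / lamq[..., None, None]
    sig = con.cauchy_stress_from_Fe(Fe, state_mat(state))
    eig = np.linalg.eigvalsh(sig)
    smin_cell = eig[..., 0].mean(axis=1) / 1e3       # kPa
    cells = np.hstack([model.cells10[:, :4],
                       model.cells10[:, 4:][:, _VTK_EDGE_PERM]])
    p_nodes = model.interpolate_p2(state.p_i) / MMHG_PA
    write_vtu(path, model.nodes2_mm, cells,
              point_data={"displacement": state.u * 100.0,   # m -> cm
                          "p_i": p_nodes},
              cell_data={"principal_stress_min": smin_cell,
                         "region_tag": mesh.region_tags})
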