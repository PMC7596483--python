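"""Closed-form reference solutions used as solver oracles.

Each reference is a pure function of position and parameters, and is
self-checking: substituting it into the governing equation it claims to
solve yields residuals at numerical precision.  The test suite compares
finite-element solutions against these references.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .constitutive import MaterialParams, VascularParams, starling_source
from .geometry import FIXED_INTERFACE_TAG, REGION_LEFT, REGION_RIGHT, LabeledMesh

__all__ = [
    "ReferenceSolution",
    "confined_growth_reference",
    "reaction_diffusion_sphere_reference",
    "small_strain_confined_compression_reference",
    "vascular_params_for_alpha_R",
    "box_mesh",
]


@dataclass
class ReferenceSolution:
    """A closed-form field with its comparison contract."""

    description: str
    evaluate: Callable
    tolerance: float
    norm: str = "L2"


def confined_growth_reference(lambda_g: float, mat: MaterialParams):
    """Homogeneous state of a fully confined, uniformly swelling brain.

    With u = 0 enforced on the whole rigid interface and uniform growth,
    u identically zero is the exact solution: Fe = lambda_g^-1 I, the
    deviatoric stress vanishes, and

        sigma_s = K (lambda_g^-3 - 1) I  (compressive for lambda_g > 1).

    Returns (sigma_s tensor, total-pressure ICP in Pa).
    """
    if lambda_g < 1.0:
        raise ValueError("lambda_g must be >= 1")
    pressure = -mat.Kbulk * (lambda_g ** -3 - 1.0)
    return -pressure * np.eye(3), pressure


def reaction_diffusion_sphere_reference(radius_m: float, mat: MaterialParams,
                                        vasc: VascularParams):
    """Radial interstitial-pressure profile in a rigid drained sphere.

    Stationary pressure equation with v_s = 0 and p = 0 at the surface:
    -k lap(p) = Q(p).  With alpha^2 = (Lp S/V + Lpl Sl/Vl)/k and
    p_inf the root of Q,

        p(r) = p_inf [1 - R sinh(alpha r) / (r sinh(alpha R))].

    For alpha R -> 0 the Poisson limit p(r) = Q(0) (R^2 - r^2) / (6 k) is
    returned instead.  Gives (p(r) callable, alpha, p_inf).
    """
    k = mat.k_hyd
    alpha = np.sqrt(vasc.reaction_coefficient / k)
    p_inf = vasc.p_infinity
    R = radius_m
    if alpha * R < 1e-8:
        q0 = starling_source(0.0, vasc)

        def profile(r):
            r = np.asarray(r, float)
            return q0 * (R ** 2 - r ** 2) / (6.0 * k)
    else:
        def profile(r):
            r = np.asarray(r, float)
            small = r < 1e-12 * R
            rr = np.where(small, 1e-12 * R, r)
            # sinh(ar)/sinh(aR) = exp(a(r-R)) (1-e^-2ar)/(1-e^-2aR), stable
            # for large alpha R
            ratio = np.exp(alpha * (rr - R)) * (-np.expm1(-2 * alpha * rr)) \
                / (-np.expm1(-2 * alpha * R))
            out = p_inf * (1.0 - R / rr * ratio)
            lim = p_inf * (1.0 - 2 * alpha * R * np.exp(-alpha * R)
                           / (-np.expm1(-2 * alpha * R)))
            return np.where(small, lim, out)
    return profile, float(alpha), float(p_inf)


def vascular_params_for_alpha_R(alpha_R: float, radius_m: float,
                                mat: MaterialParams,
                                base: VascularParams | None = None) -> VascularParams:
    """Rescale the lymphatic conductivity so the pressure boundary layer is
    mesh-resolvable: alpha R hits the requested value.

    With physiological drainage the layer is ~1.6 um (alpha R ~ 4e4) and no
    practical mesh resolves it; oracles use alpha R of a few.
    """
    base = base or VascularParams()
    alpha2 = (alpha_R / radius_m) ** 2
    total = alpha2 * mat.k_hyd
    lpl_slvl = total - base.Lp * base.SV
    if lpl_slvl < 0:
        raise ValueError("requested alpha R is below the vascular-only limit; "
                         "reduce Lp as well")
    return VascularParams(Lp=base.Lp, SV=base.SV, pv=base.pv,
                          Lpl=lpl_slvl / base.SlVl, SlVl=base.SlVl,
                          pl=base.pl, phi_f=base.phi_f)


def small_strain_confined_compression_reference(mat: MaterialParams,
                                                applied_strain: float) -> float:
    """Uniaxially confined (oedometer) axial stress at small strain.

    sigma_axial = (K + 4 mu / 3) * strain to first order; used to verify
    the solver's linear-elastic limit (|strain| <= 1e-4).
    """
    if abs(applied_strain) > 1e-4:
        raise ValueError("reference is first-order accurate; |strain| <= 1e-4")
    return (mat.Kbulk + 4.0 * mat.mu / 3.0) * applied_strain


# ---------------------------------------------------------------------------
# structured box mesh (verification problems only)
# ---------------------------------------------------------------------------


def box_mesh(lengths_mm=(10.0, 10.0, 10.0), n=(2, 2, 2)) -> LabeledMesh:
    """Structured tetrahedral box mesh, all boundary tagged fixed interface.

    Each grid cell is split into 6 positively oriented tetrahedra.  Used by
    verification problems that need prescribed-displacement boundary states
    (patch test, oedometer); the craniectomy pipeline never uses it.
    """
    nx, ny, nz = n
    lx, ly, lz = lengths_mm
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    # Kuhn subdivision of the unit cube into 6 tets (all share diagonal 0-7)
    kuhn = [(0, 1, 3, 7), (0, 3, 2, 7), (0, 2, 6, 7),
            (0, 6, 4, 7), (0, 4, 5, 7), (0, 5, 1, 7)]
    corner = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
              (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1)]
    cells = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                ids = [nid(i + c[0], j + c[1], k + c[2]) for c in corner]
                for t in kuhn:
                    cells.append([ids[v] for v in t])
    cells = np.asarray(cells, np.int64)
    x = nodes[cells]
    vol = np.einsum("ij,ij->i", np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]),
                    x[:, 3] - x[:, 0]) / 6.0
    flip = vol < 0
    cells[flip] = cells[flip][:, (0, 2, 1, 3)]

    from .geometry import _tet_faces
    faces = _tet_faces(cells).reshape(-1, 3)
    key = np.sort(faces, axis=1)
    uniq, idx, counts = np.unique(key, axis=0, return_index=True,
                                  return_counts=True)
    facets = faces[idx[counts == 1]]
    region = np.where(nodes[cells].mean(axis=1)[:, 0] > lx / 2,
                      REGION_LEFT, REGION_RIGHT).astype(np.int64)
    return LabeledMesh(
        nodes=nodes, cells=cells, facets=facets,
        facet_tags=np.full(len(facets), FIXED_INTERFACE_TAG, np.int64),
        region_tags=region,
        characteristic_h_mm=float(max(lx / nx, ly / ny, lz / nz)))
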