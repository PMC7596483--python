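"""Mixed displacement-pressure finite elements for the swelling brain.

Discretization: quadratic Lagrange (P2) vector displacement and linear
Lagrange (P1) interstitial fluid pressure on shared tetrahedra (a
Taylor-Hood-style pair), with degree-5 conical-product quadrature.  The
coupled stationary system solved per growth level is

    div( sigma_s(Fe) - p_i I ) = 0            (momentum, current config)
    -div( k grad p_i ) = Q(p_i) - div v_s     (fluid pressure)

assembled in the reference configuration: the momentum residual through the
first Piola transform P = J sigma_tot F^-T, the pressure operator pulled
back by J F^-1 k F^-T, and the Starling source weighted by J.  In the
default stationary mode v_s = 0; quasistatic mode adds the backward-Euler
coupling term tr(dF/dt F^-1).

Linearization is exact to machine precision: per-quadrature-point tangents
are obtained by complex-step differentiation of the flux functions (the
constitutive module is complex-safe), so the Jacobian is consistent with
the residual by construction.  Newton iteration with incremental growth
loading and a backtracking line search solves each level; the sparse
systems go to a direct LU factorization after Jacobi equilibration (the
momentum and pressure blocks differ by many orders of magnitude in natural
units).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import roots_jacobi

from . import constitutive as con
from .geometry import FIXED_INTERFACE_TAG, LabeledMesh

__all__ = [
    "SolverOptions",
    "SolutionState",
    "DirichletBC",
    "MixedModel",
    "ElementInversionError",
    "NonConvergenceError",
    "assemble_residual",
    "assemble_system",
    "apply_boundary_conditions",
    "solve_equilibrium",
    "solve_growth_ramp",
]

MM_TO_M = 1e-3

# P2 tetrahedron: 4 vertices + midnodes of the 6 edges, in this edge order
TET_EDGES = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


class ElementInversionError(RuntimeError):
    """An element reached det(F) <= 0 (or has a non-positive map Jacobian)."""

    def __init__(self, cell: int, msg: str | None = None):
        self.cell = cell
        super().__init__(msg or f"element inversion in cell {cell}; "
                         "consider more load steps or a finer mesh")


class NonConvergenceError(RuntimeError):
    """Newton iteration failed; carries the convergence log."""

    def __init__(self, msg: str, log: list[str]):
        self.convergence_log = log
        super().__init__(msg + "\n" + "\n".join(log[-10:]))


# ---------------------------------------------------------------------------
# reference element: shape functions and quadrature
# ---------------------------------------------------------------------------


def tet_quadrature(n: int = 3):
    """Conical-product Gauss rule on the reference tetrahedron.

    Exact for polynomials of total degree <= 2n - 1 (n = 3: 27 points,
    degree 5, comfortably covering the degree-4 integrands of the P2/P1
    pair on affine cells).
    """
    def gauss01(alpha):
        t, w = roots_jacobi(n, alpha, 0.0)
        return (1.0 + t) / 2.0, w / 2.0 ** (alpha + 1)

    u, wu = gauss01(2.0)
    v, wv = gauss01(1.0)
    w_, ww = gauss01(0.0)
    U, V, W = np.meshgrid(u, v, w_, indexing="ij")
    x = U
    y = V * (1.0 - U)
    z = W * (1.0 - U) * (1.0 - V)
    wq = (wu[:, None, None] * wv[None, :, None] * ww[None, None, :])
    pts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    return pts, wq.ravel()


def p1_shape(pts: np.ndarray):
    """P1 barycentric shape functions: values (nq, 4) and gradients (nq, 4, 3)."""
    x, y, z = pts.T
    N = np.column_stack([1.0 - x - y - z, x, y, z])
    dN = np.array([[-1.0, -1.0, -1.0],
                   [1.0, 0.0, 0.0],
                   [0.0, 1.0, 0.0],
                   [0.0, 0.0, 1.0]])
    return N, np.broadcast_to(dN, (len(pts), 4, 3)).copy()


def p2_shape(pts: np.ndarray):
    """P2 shape functions on the reference tet: values (nq, 10) and
    reference gradients (nq, 10, 3)."""
    x, y, z = pts.T
    L = np.column_stack([1.0 - x - y - z, x, y, z])     # (nq, 4)
    dL = np.array([[-1.0, -1.0, -1.0],
                   [1.0, 0.0, 0.0],
                   [0.0, 1.0, 0.0],
                   [0.0, 0.0, 1.0]])                     # (4, 3)
    nq = len(pts)
    N = np.empty((nq, 10))
    dN = np.empty((nq, 10, 3))
    for i in range(4):
        N[:, i] = L[:, i] * (2.0 * L[:, i] - 1.0)
        dN[:, i] = (4.0 * L[:, i] - 1.0)[:, None] * dL[i]
    for e, (i, j) in enumerate(TET_EDGES):
        N[:, 4 + e] = 4.0 * L[:, i] * L[:, j]
        dN[:, 4 + e] = 4.0 * (L[:, i][:, None] * dL[j] + L[:, j][:, None] * dL[i])
    return N, dN


# ---------------------------------------------------------------------------
# the discrete model
# ---------------------------------------------------------------------------


class MixedModel:
    """Geometry, spaces and quadrature data for one labeled mesh.

    Displacement dofs are interleaved (node*3 + component) over the P2
    nodes; pressure dofs follow, one per P1 vertex.  Boundary midside nodes
    are snapped onto the curved cavity surface when the mesh carries its
    generating geometry (isoparametric P2 boundary).
    """

    def __init__(self, mesh: LabeledMesh, quad_n: int = 3):
        self.mesh = mesh
        nv = len(mesh.nodes)
        cells = mesh.cells
        # unique edges -> midside nodes
        edges = np.vstack([cells[:, e] for e in TET_EDGES])
        edges_sorted = np.sort(edges, axis=1)
        uniq, inv = np.unique(edges_sorted, axis=0, return_inverse=True)
        self.edges = uniq
        ne = len(uniq)
        self.cells10 = np.hstack([cells, nv + inv.reshape(6, -1).T]).astype(np.int64)

        nodes2 = np.vstack([mesh.nodes,
                            0.5 * (mesh.nodes[uniq[:, 0]] + mesh.nodes[uniq[:, 1]])])
        if mesh.geometry is not None and len(mesh.facets):
            bedges = np.unique(np.sort(np.vstack(
                [mesh.facets[:, (0, 1)], mesh.facets[:, (1, 2)],
                 mesh.facets[:, (2, 0)]]), axis=1), axis=0)
            bset = set(map(tuple, bedges))
            is_bedge = np.fromiter((tuple(e) in bset for e in uniq), bool, ne)
            nodes2[nv:][is_bedge] = mesh.geometry.project_to_surface(
                nodes2[nv:][is_bedge])
        self.nodes2_mm = nodes2
        self.nodes2 = nodes2 * MM_TO_M
        self.n_vertices = nv
        self.n_p2_nodes = len(nodes2)
        self.n_udofs = 3 * self.n_p2_nodes
        self.n_pdofs = nv
        self.n_dofs = self.n_udofs + self.n_pdofs

        qpts, qw = tet_quadrature(quad_n)
        self.qpts, self.qw = qpts, qw
        N1, dN1 = p1_shape(qpts)
        N2, dN2 = p2_shape(qpts)
        self.N1, self.N2 = N1, N2

        Xe = self.nodes2[self.cells10]                       # (ncell, 10, 3)
        # isoparametric map: dX/dxi at each qpoint
        Jmap = np.einsum("eai,qaj->eqij", Xe, dN2)           # J_ij = dX_i/dxi_j
        detJ = con.det33(Jmap)
        if np.any(detJ <= 0):
            bad = int(np.argwhere(detJ <= 0)[0][0])
            raise ElementInversionError(
                bad, f"non-positive map Jacobian in cell {bad} "
                "(curved element inverted)")
        Jinv = con.inv33(Jmap, detJ)                         # dxi/dX
        self.grad2 = np.einsum("qaj,eqji->eqai", dN2, Jinv)  # (e, q, 10, 3)
        self.grad1 = np.einsum("qaj,eqji->eqai", dN1, Jinv)  # (e, q, 4, 3)
        self.dV = detJ * qw[None, :]                          # (e, q) in m^3
        self.ref_volume = float(self.dV.sum())

        # element dof matrix: 30 u-dofs then 4 p-dofs
        udofs = (3 * self.cells10[:, :, None]
                 + np.arange(3)[None, None, :]).reshape(-1, 30)
        pdofs = self.n_udofs + cells
        self.edofs = np.hstack([udofs, pdofs]).astype(np.int32)

    # -- boundary dof sets -------------------------------------------------

    def edge_midnode(self, edges: np.ndarray) -> np.ndarray:
        """Midside node ids of the given (sorted) vertex pairs."""
        key = self.edges[:, 0].astype(np.int64) * (1 << 32) + self.edges[:, 1]
        order = np.argsort(key)
        want = edges[:, 0].astype(np.int64) * (1 << 32) + edges[:, 1]
        pos = np.searchsorted(key[order], want)
        return self.n_vertices + order[pos]

    def facet_p2_nodes(self, facet_mask: np.ndarray) -> np.ndarray:
        """All P2 node ids lying on the selected boundary facets."""
        facets = self.mesh.facets[facet_mask]
        if len(facets) == 0:
            return np.empty(0, np.int64)
        vids = np.unique(facets)
        fedges = np.unique(np.sort(np.vstack(
            [facets[:, (0, 1)], facets[:, (1, 2)], facets[:, (2, 0)]]), axis=1), axis=0)
        return np.concatenate([vids, self.edge_midnode(fedges)])

    def interpolate_p2(self, vertex_field: np.ndarray) -> np.ndarray:
        """Extend a per-vertex field to all P2 nodes (edge midpoints averaged)."""
        mid = 0.5 * (vertex_field[self.edges[:, 0]] + vertex_field[self.edges[:, 1]])
        return np.concatenate([vertex_field, mid])


# ---------------------------------------------------------------------------
# boundary conditions
# ---------------------------------------------------------------------------


@dataclass
class DirichletBC:
    """Essential constraints: global dof indices and prescribed values."""

    dofs: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.dofs = np.asarray(self.dofs, np.int64)
        self.values = np.asarray(self.values, float)


def apply_boundary_conditions(model: MixedModel, sealed: bool = False,
                              pressure_only: bool = False) -> DirichletBC:
    """Standard craniectomy boundary conditions.

    u = 0 on the fixed skull interface (all P2 nodes of fixed facets);
    openings are traction-free for the solid and carry p_i = 0 (free CSF
    drainage); the fixed interface is a natural zero-flux boundary for the
    fluid.  ``sealed`` treats every boundary facet as fixed interface (the
    closed-skull configuration).  ``pressure_only`` additionally pins every
    displacement dof (used by pressure-equation verification problems); in
    that mode, if the mesh has no openings the whole boundary carries
    p_i = 0.
    """
    mesh = model.mesh
    tags = mesh.facet_tags
    fixed_facets = np.ones_like(tags, bool) if sealed else (tags == FIXED_INTERFACE_TAG)
    opening_facets = ~fixed_facets
    if not pressure_only and not np.any(fixed_facets):
        raise ValueError("mesh has no fixed_interface facets: rigid-body motion "
                         "is unconstrained")
    if pressure_only:
        unodes = np.arange(model.n_p2_nodes)
    else:
        unodes = np.unique(model.facet_p2_nodes(fixed_facets))
    udofs = (3 * unodes[:, None] + np.arange(3)[None, :]).ravel()
    if pressure_only and not np.any(opening_facets):
        pverts = np.unique(mesh.facets)
    elif np.any(opening_facets):
        pverts = np.unique(mesh.facets[opening_facets])
    else:
        pverts = np.empty(0, np.int64)
    pdofs = model.n_udofs + pverts
    dofs = np.concatenate([udofs, pdofs])
    return DirichletBC(dofs=dofs, values=np.zeros(len(dofs)))


# ---------------------------------------------------------------------------
# residual and Jacobian assembly
# ---------------------------------------------------------------------------


def _point_fluxes(F, pq, gradp, lam, mat, vasc, Fprev=None, dt=None,
                  check_inversion=True):
    """Pointwise reference-configuration fluxes at quadrature points.

    Returns (P, flux, src, J, Finv):
      P    = J sigma_tot F^-T      (first Piola of the total stress)
      flux = k J C^-1 grad0 p      (pulled-back Darcy flux)
      src  = J Q(p) [- J tr(dF/dt F^-1) in quasistatic mode]
    Complex-safe in F for complex-step linearization.
    """
    J = con.det33(F)
    if check_inversion and np.any(J.real <= 0.0):
        flat = np.nonzero((J.real <= 0.0).reshape(J.shape[0], -1).any(axis=1))[0]
        raise ElementInversionError(int(flat[0]))
    Fe = F / lam[..., None, None]
    sig = con.cauchy_stress_from_Fe(Fe, mat)
    sig = sig - pq[..., None, None] * np.eye(3, dtype=sig.dtype)
    Finv = con.inv33(F, J)
    FinvT = np.swapaxes(Finv, -1, -2)
    P = J[..., None, None] * (sig @ FinvT)
    Cinv = Finv @ FinvT
    flux = mat.k_hyd * J[..., None] * np.einsum("...ij,...j->...i", Cinv, gradp)
    src = J * con.starling_source(pq, vasc)
    if Fprev is not None:
        Fdot = (F - Fprev) / dt
        src = src - J * np.einsum("...ij,...ji->...", Fdot, Finv)
    return P, flux, src, J, Finv


def _stationary_tangent(F, pq, gradp, lam, mat, vasc, J, Finv):
    """Closed-form tangents of the stationary pointwise fluxes.

    For this material P_total = c1 F + c3 F^-T with
      c1 = mu J^(-2/3) lam^3,
      c3 = K (J^2/lam^3 - J) - c1 I1/3 - p J,      I1 = tr(F F^T),
    which differentiates compactly in terms of F and F^-1.  Verified against
    the complex-step linearization (see tests).
    """
    G3 = lam ** 3
    I1 = np.einsum("...ij,...ij->...", F, F)
    c1 = mat.mu * J ** (-2.0 / 3.0) * G3
    c3 = mat.Kbulk * (J ** 2 / G3 - J) - c1 * I1 / 3.0 - pq * J
    # dc3/dF_kL = coefA * Finv_Lk - (2/3) c1 F_kL
    coefA = mat.Kbulk * (2.0 * J ** 2 / G3 - J) + (2.0 / 9.0) * c1 * I1 - pq * J
    FinvT = np.swapaxes(Finv, -1, -2)
    eye4 = np.einsum("ik,JL->iJkL", np.eye(3), np.eye(3))
    A = c1[..., None, None, None, None] * eye4
    A += (-2.0 / 3.0) * c1[..., None, None, None, None] \
        * F[..., :, :, None, None] * FinvT[..., None, None, :, :]
    dc3 = coefA[..., None, None] * FinvT - (2.0 / 3.0) * c1[..., None, None] * F
    A += FinvT[..., :, :, None, None] * dc3[..., None, None, :, :]
    A -= c3[..., None, None, None, None] \
        * FinvT[..., :, None, None, :] * Finv[..., None, :, :, None]
    # Darcy flux tangent: k J [Finv_Lk w_m - Finv_mk w_L - Cinv_mL t_k]
    Cinv = Finv @ FinvT
    w = np.einsum("...mn,...n->...m", Cinv, gradp)
    t = np.einsum("...nm,...n->...m", Finv, gradp)      # F^-T gradp
    kJ = mat.k_hyd * J
    dflux = kJ[..., None, None, None] * (
        w[..., :, None, None] * FinvT[..., None, :, :]
        - Finv[..., :, :, None] * w[..., None, None, :]
        - Cinv[..., :, None, :] * t[..., None, :, None])
    dsrc = (J * con.starling_source(pq, vasc))[..., None, None] * FinvT
    return A, dflux, dsrc


def _gather(model, u, p):
    ue = u.reshape(-1, 3)[model.cells10]               # (e, 10, 3)
    pe = p[model.mesh.cells]                           # (e, 4)
    gradu = np.einsum("eqaj,eai->eqij", model.grad2, ue)
    F = gradu + np.eye(3)
    pq = np.einsum("qa,ea->eq", model.N1, pe)
    gradp = np.einsum("eqaj,ea->eqj", model.grad1, pe)
    return F, pq, gradp


def assemble_system(model: MixedModel, u: np.ndarray, p: np.ndarray,
                    lam_cells: np.ndarray, mat, vasc,
                    want_jacobian: bool = True,
                    u_prev: np.ndarray | None = None, dt: float | None = None,
                    chunk: int = 4096, tangent: str = "analytic"):
    """Assemble the coupled residual (and consistent Jacobian).

    u : (n_p2_nodes, 3) displacement in m;  p : (n_vertices,) pressure in Pa;
    lam_cells : (ncells,) growth stretch per cell.  Returns (R, K) with K a
    CSR matrix (None unless requested).  The Jacobian is generated by
    complex-step differentiation of the pointwise fluxes, so it matches a
    finite difference of the residual to finite-difference accuracy by
    construction.
    """
    lam_cells = np.asarray(lam_cells, float)
    nq = len(model.qw)
    lamq_all = np.repeat(lam_cells[:, None], nq, axis=1)
    F_all, pq_all, gradp_all = _gather(model, u, p)
    Fprev_all = None
    if u_prev is not None:
        Fprev_all, _, _ = _gather(model, u_prev, np.zeros(model.n_pdofs))
    R = np.zeros(model.n_dofs)
    blocks = [] if want_jacobian else None
    ncell = len(model.cells10)
    for s in range(0, ncell, chunk):
        e = slice(s, min(s + chunk, ncell))
        Fc, pc, gc, lc = F_all[e], pq_all[e], gradp_all[e], lamq_all[e]
        Fpc = Fprev_all[e] if Fprev_all is not None else None
        dV = model.dV[e]
        g2, g1, N1 = model.grad2[e], model.grad1[e], model.N1
        try:
            P, flux, src, J, Finv = _point_fluxes(Fc, pc, gc, lc, mat, vasc, Fpc, dt)
        except ElementInversionError as err:
            raise ElementInversionError(err.cell + s) from None
        Ru = np.einsum("eqaj,eqij,eq->eai", g2, P, dV)
        Rp = (np.einsum("eqaj,eqj,eq->ea", g1, flux, dV)
              - np.einsum("qa,eq,eq->ea", N1, src, dV))
        Re = np.concatenate([Ru.reshape(-1, 30), Rp], axis=1)
        np.add.at(R, model.edofs[e].astype(np.int64), Re)
        if not want_jacobian:
            continue
        nel = Fc.shape[0]
        if tangent == "analytic" and Fpc is None:
            A, dflux_dF, dsrc_dF = _stationary_tangent(
                Fc, pc, gc, lc, mat, vasc, J, Finv)
        else:
            # complex-step tangents w.r.t. the 9 components of F
            A = np.empty((nel, nq, 3, 3, 3, 3))       # dP/dF
            dflux_dF = np.empty((nel, nq, 3, 3, 3))
            dsrc_dF = np.empty((nel, nq, 3, 3))
            hstep = 1e-30
            Fcx = Fc.astype(complex)
            for k in range(3):
                for l in range(3):
                    Fp = Fcx.copy()
                    Fp[..., k, l] += 1j * hstep
                    Pp, fluxp, srcp, _, _ = _point_fluxes(
                        Fp, pc, gc, lc, mat, vasc, Fpc, dt, check_inversion=False)
                    A[..., k, l] = Pp.imag / hstep
                    dflux_dF[..., k, l] = fluxp.imag / hstep
                    dsrc_dF[..., k, l] = srcp.imag / hstep
        # analytic p-derivatives
        FinvT = np.swapaxes(Finv, -1, -2)
        dP_dp = -J[..., None, None] * FinvT
        M = mat.k_hyd * J[..., None, None] * (Finv @ FinvT)   # dflux/dgradp
        dsrc_dp = -J * vasc.reaction_coefficient
        # element blocks via batched matmuls (einsum is too slow here)
        Aw = A * dV[..., None, None, None, None]
        g2f = np.ascontiguousarray(g2.reshape(nel * nq, 10, 3))
        g2fT = np.ascontiguousarray(np.swapaxes(g2f, 1, 2))
        g1f = np.ascontiguousarray(g1.reshape(nel * nq, 4, 3))
        # Kuu[a,i;b,k] = sum_q g2[a,j] Aw[i,j,k,l] g2[b,l]
        T1 = np.matmul(Aw.reshape(nel * nq, 27, 3), g2fT)       # (i,j,k) x b
        T1 = T1.reshape(nel * nq, 3, 3, 3, 10).transpose(0, 2, 1, 3, 4)  # j,(i,k,b)
        T2 = np.matmul(g2f, T1.reshape(nel * nq, 3, 90))         # a x (i,k,b)
        Kuu = T2.reshape(nel, nq, 10, 3, 3, 10).sum(axis=1)      # (a,i,k,b)
        Kuu = Kuu.transpose(0, 1, 2, 4, 3)                       # (a,i,b,k)
        Kup = np.einsum("eqaj,eqij,qb,eq->eaib", g2, dP_dp, N1, dV, optimize=True)
        # Kpu flux part: sum_q g1[a,j] dflux_dF[j,k,l] g2[b,l]
        T3 = np.matmul(dflux_dF.reshape(nel * nq, 9, 3), g2fT)   # (j,k) x b
        T4 = np.matmul(g1f, T3.reshape(nel * nq, 3, 30))         # a x (k,b)
        T4 = (T4.reshape(nel, nq, 4, 3, 10)
              * dV[:, :, None, None, None]).sum(axis=1)          # (a,k,b)
        # Kpu source part: sum_q N1[a] dV dsrc_dF[k,l] g2[b,l]
        T5 = np.matmul(dsrc_dF.reshape(nel * nq, 3, 3), g2fT)    # k x b
        T6 = np.einsum("qa,eq,eqkb->eakb", N1, dV, T5.reshape(nel, nq, 3, 10))
        Kpu = (T4 - T6).transpose(0, 1, 3, 2)                    # (a,b,k)
        Kpp = (np.einsum("eqaj,eqjl,eqbl,eq->eab", g1, M, g1, dV, optimize=True)
               - np.einsum("qa,eq,qb,eq->eab", N1, dsrc_dp, N1, dV, optimize=True))
        Ke = np.empty((nel, 34, 34))
        Ke[:, :30, :30] = Kuu.reshape(nel, 30, 30)
        Ke[:, :30, 30:] = Kup.reshape(nel, 30, 4)
        Ke[:, 30:, :30] = Kpu.reshape(nel, 4, 30)
        Ke[:, 30:, 30:] = Kpp
        blocks.append(Ke)
    K = None
    if want_jacobian:
        Ke_all = np.concatenate(blocks, axis=0)
        rows = np.repeat(model.edofs, 34, axis=1).ravel()
        cols = np.tile(model.edofs, (1, 34)).ravel()
        K = sp.coo_matrix((Ke_all.ravel(), (rows, cols)),
                          shape=(model.n_dofs, model.n_dofs)).tocsr()
    return R, K


def assemble_residual(mesh: LabeledMesh, state: "SolutionState", growth, mat, vasc,
                      want_jacobian: bool = True):
    """Residual (and consistent Jacobian) of a solution state."""
    model = state.model if state.model is not None else MixedModel(mesh)
    if hasattr(growth, "cell_targets"):
        lam = growth.cell_targets(mesh.region_tags)
    else:
        lam = np.asarray(growth, float) * np.ones(len(mesh.cells))
    return assemble_system(model, state.u, state.p_i, lam, mat, vasc,
                           want_jacobian=want_jacobian)


# ---------------------------------------------------------------------------
# nonlinear solution
# ---------------------------------------------------------------------------


@dataclass
class SolverOptions:
    """Newton / load-stepping controls.

    newton_rtol is on the reduction of the free-dof residual norm within a
    load step; newton_atol the absolute floor.  ``n_load_steps`` splits the
    growth ramp from 1 to the target.  ``mode`` selects stationary
    (equilibrium, v_s = 0; the regime all craniectomy outputs use) or
    quasistatic (backward-Euler v_s) physics.  ``seed`` feeds any randomized
    component; the default direct solver uses none, making runs bit-identical
    for identical inputs.
    """

    newton_rtol: float = 1e-8
    newton_atol: float = 1e-10
    max_newton_iters: int = 25
    n_load_steps: int = 10
    mode: str = "stationary"
    dt: float = 1.0
    linear_solver: str = "direct"
    seed: int = 0
    initial_pressure: str | float = "p_inf"
    max_line_search: int = 8

    def __post_init__(self):
        if self.newton_rtol <= 0 or self.newton_atol <= 0:
            raise ValueError("tolerances must be positive")
        if self.n_load_steps < 1:
            raise ValueError("n_load_steps must be >= 1")
        if self.mode not in ("stationary", "quasistatic"):
            raise ValueError("mode must be 'stationary' or 'quasistatic'")
        if self.linear_solver not in ("direct", "iterative"):
            raise ValueError("linear_solver must be 'direct' or 'iterative'")


@dataclass
class SolutionState:
    """Converged nodal fields at one growth level.

    u is the P2 displacement (n_p2_nodes, 3) in metres; p_i the P1
    interstitial pressure (n_vertices,) in Pa; v_s the solid velocity
    (quasistatic mode only).
    """

    u: np.ndarray
    p_i: np.ndarray
    lambda_g_achieved: float
    convergence_log: list[str] = field(default_factory=list)
    v_s: np.ndarray | None = None
    model: MixedModel | None = None
    lam_cells: np.ndarray | None = None
    mat: object = None
    vasc: object = None


def _linear_solve(K: sp.csr_matrix, rhs: np.ndarray, opts: SolverOptions) -> np.ndarray:
    # Jacobi equilibration: momentum and fluid rows live on wildly different
    # scales; symmetric diagonal scaling keeps the LU well conditioned.
    d = np.sqrt(np.abs(K.diagonal()))
    d[d == 0] = 1.0
    Dinv = sp.diags(1.0 / d)
    Ks = (Dinv @ K @ Dinv).tocsc()
    bs = rhs / d
    if opts.linear_solver == "direct":
        x = spla.splu(Ks).solve(bs)
    else:
        ilu = spla.spilu(Ks, drop_tol=1e-8, fill_factor=30)
        x, info = spla.gmres(Ks, bs, M=spla.LinearOperator(Ks.shape, ilu.solve),
                             rtol=1e-10, atol=0.0, maxiter=500)
        if info != 0:
            raise RuntimeError(f"iterative linear solver failed (info={info})")
    return x / d


def solve_growth_ramp(mesh: LabeledMesh, growth, mat, vasc,
                      opts: SolverOptions | None = None,
                      record_at=None, sealed: bool = False,
                      pressure_only: bool = False,
                      model: MixedModel | None = None,
                      bc: DirichletBC | None = None):
    """Ramp the growth field from 1 to its target, recording requested levels.

    The per-cell growth stretch is scaled proportionally between 1 and its
    regional target as the global level advances.  Returns
    ``(records, final_state)`` where ``records`` maps each level in
    ``record_at`` (default: ``growth.schedule``) to its converged
    :class:`SolutionState`.  Deterministic for fixed inputs and options.
    """
    opts = opts or SolverOptions()
    model = model or MixedModel(mesh)
    if bc is None:
        bc = apply_boundary_conditions(model, sealed=sealed,
                                       pressure_only=pressure_only)
    free = np.ones(model.n_dofs, bool)
    free[bc.dofs] = False

    targets = growth.cell_targets(mesh.region_tags)
    # load-level bookkeeping stays in nominal lambda_g units (schedule units)
    lam_max = getattr(growth, "nominal_target", float(targets.max()))
    record_at = list(record_at if record_at is not None else growth.schedule)
    ramp = np.linspace(1.0, lam_max, opts.n_load_steps + 1)[1:] if lam_max > 1 \
        else np.array([1.0])
    levels = np.unique(np.concatenate([ramp, np.asarray(record_at, float)]))
    levels = levels[levels >= 1.0]

    p0 = float(vasc.p_infinity) if opts.initial_pressure == "p_inf" \
        else float(opts.initial_pressure)
    x = np.concatenate([np.zeros(model.n_udofs), np.full(model.n_pdofs, p0)])
    x[bc.dofs] = bc.values
    log: list[str] = []
    records: dict[float, SolutionState] = {}
    u_prev = None
    quasi = opts.mode == "quasistatic"
    lam_cells = np.ones(len(mesh.cells))

    def residual(xv, want_jac):
        uu = xv[:model.n_udofs].reshape(-1, 3)
        pp = xv[model.n_udofs:]
        return assemble_system(model, uu, pp, lam_cells, mat, vasc,
                               want_jacobian=want_jac,
                               u_prev=u_prev if quasi else None,
                               dt=opts.dt if quasi else None)

    def snapshot(level):
        st = SolutionState(
            u=x[:model.n_udofs].reshape(-1, 3).copy(),
            p_i=x[model.n_udofs:].copy(),
            lambda_g_achieved=float(level),
            convergence_log=list(log), model=model,
            lam_cells=lam_cells.copy(), mat=mat, vasc=vasc)
        if quasi and u_prev is not None:
            st.v_s = (st.u - u_prev.reshape(-1, 3)) / opts.dt
        return st

    for step, level in enumerate(levels):
        frac = 0.0 if lam_max <= 1.0 else (level - 1.0) / (lam_max - 1.0)
        lam_cells = 1.0 + frac * (targets - 1.0)
        if quasi:
            u_prev = x[:model.n_udofs].copy()
        R, _ = residual(x, False)
        norm0 = np.linalg.norm(R[free])
        log.append(f"step {step} lambda_g={level:.6f} it 0 |R|={norm0:.6e}")
        norm = norm0
        it = 0
        while norm > max(opts.newton_atol, opts.newton_rtol * norm0):
            if it >= opts.max_newton_iters:
                raise NonConvergenceError(
                    f"Newton did not converge at lambda_g={level:.4f} "
                    f"after {it} iterations", log)
            _, K = residual(x, True)
            dx = np.zeros(model.n_dofs)
            dx[free] = _linear_solve(K[free][:, free].tocsr(), -R[free], opts)
            # backtracking line search on the free-dof residual norm
            alpha = 1.0
            best = None
            accepted = False
            for _ in range(opts.max_line_search + 1):
                try:
                    Rn, _ = residual(x + alpha * dx, False)
                    nn = np.linalg.norm(Rn[free])
                    if best is None or nn < best[2]:
                        best = (alpha, Rn, nn)
                    if nn < norm:
                        accepted = True
                        break
                except ElementInversionError:
                    pass
                alpha *= 0.5
            if not accepted:
                if best is None:
                    raise NonConvergenceError(
                        f"line search failed at lambda_g={level:.4f} "
                        "(element inversion); increase n_load_steps", log)
            alpha, R, norm = best if not accepted else (alpha, Rn, nn)
            x = x + alpha * dx
            it += 1
            log.append(f"step {step} lambda_g={level:.6f} it {it} "
                       f"|R|={norm:.6e} alpha={alpha:g}")
        if any(abs(level - r) < 1e-12 for r in record_at):
            records[float(level)] = snapshot(level)
    return records, snapshot(levels[-1])


def solve_equilibrium(mesh: LabeledMesh, growth, mat, vasc,
                      opts: SolverOptions | None = None,
                      sealed: bool = False, pressure_only: bool = False,
                      model: MixedModel | None = None,
                      bc: DirichletBC | None = None) -> SolutionState:
    """Solve the coupled equilibrium problem at the growth target.

    Newton iteration with incremental growth loading; returns the converged
    state at the final lambda_g.  Raises :class:`NonConvergenceError` (with
    the convergence log attached) or :class:`ElementInversionError` on
    failure.
    """
    _, final = solve_growth_ramp(mesh, growth, mat, vasc, opts,
                                 record_at=[], sealed=sealed,
                                 pressure_only=pressure_only, model=model, bc=bc)
    return final
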