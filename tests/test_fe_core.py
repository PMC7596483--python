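"""Mixed P2/P1 discretization, assembly consistency and Newton solver."""

import math

import numpy as np
import pytest

from dccsim import constitutive as C
from dccsim import fe_core as FE
from dccsim import verification as V
from dccsim.constitutive import GrowthField
from dccsim.fe_core import (
    DirichletBC,
    MixedModel,
    SolverOptions,
    apply_boundary_conditions,
    assemble_system,
    solve_equilibrium,
    solve_growth_ramp,
    tet_quadrature,
)
from dccsim.geometry import OpeningSpec, build_idealized_head, mesh_head, opening_tag


class TestReferenceElement:
    def test_quadrature_integrates_degree_five_exactly(self):
        pts, w = tet_quadrature(3)
        for a in range(6):
            for b in range(6 - a):
                for c in range(6 - a - b):
                    num = np.sum(w * pts[:, 0] ** a * pts[:, 1] ** b
                                 * pts[:, 2] ** c)
                    exact = (math.factorial(a) * math.factorial(b)
                             * math.factorial(c)
                             / math.factorial(a + b + c + 3))
                    assert num == pytest.approx(exact, rel=1e-13)

    def test_shape_functions_partition_unity(self):
        pts, _ = tet_quadrature(3)
        N1, dN1 = FE.p1_shape(pts)
        N2, dN2 = FE.p2_shape(pts)
        assert np.allclose(N1.sum(axis=1), 1.0)
        assert np.allclose(N2.sum(axis=1), 1.0)
        assert np.allclose(dN2.sum(axis=1), 0.0, atol=1e-13)


class TestAssembly:
    def test_reference_state_has_zero_residual(self, coarse_model, params):
        mat, vasc = params
        model = coarse_model
        u = np.zeros((model.n_p2_nodes, 3))
        p = np.full(model.n_pdofs, vasc.p_infinity)
        R, _ = assemble_system(model, u, p, np.ones(len(model.mesh.cells)),
                               mat, vasc, want_jacobian=False)
        bc = apply_boundary_conditions(model, sealed=True)
        free = np.ones(model.n_dofs, bool)
        free[bc.dofs] = False
        assert np.linalg.norm(R[free]) < 1e-16

    def test_homogeneous_confined_state_is_exact_discrete_solution(
            self, coarse_model, params):
        """u = 0, p = p_inf solves the sealed problem at any growth level."""
        mat, vasc = params
        model = coarse_model
        u = np.zeros((model.n_p2_nodes, 3))
        p = np.full(model.n_pdofs, vasc.p_infinity)
        lam = np.full(len(model.mesh.cells), 1.1)
        R, _ = assemble_system(model, u, p, lam, mat, vasc,
                               want_jacobian=False)
        bc = apply_boundary_conditions(model, sealed=True)
        free = np.ones(model.n_dofs, bool)
        free[bc.dofs] = False
        # residual scale: stress ~ 7.5 kPa times element face areas
        assert np.linalg.norm(R[free]) < 1e-8

    def test_jacobian_matches_finite_difference(self, coarse_model, params,
                                                rng):
        mat, vasc = params
        model = coarse_model
        x0 = np.concatenate([np.zeros(model.n_udofs),
                             np.full(model.n_pdofs, vasc.p_infinity)])
        x0 += rng.normal(0, 1e-4, model.n_dofs)
        lam = np.full(len(model.mesh.cells), 1.02)

        def res(x):
            return assemble_system(model, x[:model.n_udofs].reshape(-1, 3),
                                   x[model.n_udofs:], lam, mat, vasc,
                                   want_jacobian=False)[0]

        _, K = assemble_system(model, x0[:model.n_udofs].reshape(-1, 3),
                               x0[model.n_udofs:], lam, mat, vasc)
        for _ in range(3):
            v = rng.normal(size=model.n_dofs)
            v /= np.linalg.norm(v)
            eps = 1e-7
            fd = (res(x0 + eps * v) - res(x0 - eps * v)) / (2 * eps)
            Jv = K @ v
            assert np.linalg.norm(fd - Jv) / np.linalg.norm(Jv) < 1e-5

    def test_analytic_tangent_equals_complex_step(self, coarse_model, params,
                                                  rng):
        mat, vasc = params
        model = coarse_model
        u = rng.normal(0, 1e-4, (model.n_p2_nodes, 3))
        p = rng.normal(0, 10.0, model.n_pdofs)
        lam = np.full(len(model.mesh.cells), 1.05)
        _, Ka = assemble_system(model, u, p, lam, mat, vasc, tangent="analytic")
        _, Kc = assemble_system(model, u, p, lam, mat, vasc, tangent="complex")
        diff = abs(Ka - Kc).max()
        assert diff < 1e-10 * abs(Kc).max()


class TestBoundaryConditions:
    def test_closed_skull_fixes_all_boundary_u_and_no_pressure_rows(
            self, coarse_model):
        bc = apply_boundary_conditions(coarse_model, sealed=True)
        nb = len(np.unique(coarse_model.facet_p2_nodes(
            np.ones(len(coarse_model.mesh.facets), bool))))
        assert len(bc.dofs) == 3 * nb
        assert np.all(bc.dofs < coarse_model.n_udofs)

    def test_opening_pressure_rows_match_patch_vertices(self):
        geom = build_idealized_head(openings=[OpeningSpec.unilateral(40.0)])
        mesh = mesh_head(geom, h=20)
        model = MixedModel(mesh)
        bc = apply_boundary_conditions(model)
        pdofs = bc.dofs[bc.dofs >= model.n_udofs]
        open_verts = np.unique(mesh.facets[mesh.facet_tags == opening_tag(1)])
        assert len(pdofs) == len(open_verts)
        # opening u-nodes stay free
        open_nodes = model.facet_p2_nodes(mesh.facet_tags == opening_tag(1))
        interior = np.setdiff1d(
            open_nodes,
            model.facet_p2_nodes(mesh.facet_tags == 1))
        fixed_unodes = np.unique(bc.dofs[bc.dofs < model.n_udofs] // 3)
        assert not np.intersect1d(interior, fixed_unodes).size

    def test_two_openings_both_drained(self):
        geom = build_idealized_head(openings=[
            OpeningSpec.unilateral(40.0, axis=(1, 0, 0)),
            OpeningSpec.unilateral(40.0, axis=(-1, 0, 0))])
        mesh = mesh_head(geom, h=20)
        model = MixedModel(mesh)
        bc = apply_boundary_conditions(model)
        pverts = bc.dofs[bc.dofs >= model.n_udofs] - model.n_udofs
        for k in (1, 2):
            verts_k = np.unique(mesh.facets[mesh.facet_tags == opening_tag(k)])
            assert np.isin(verts_k, pverts).all()

    def test_unconstrained_mesh_rejected(self):
        mesh = V.box_mesh((5, 5, 5), (1, 1, 1))
        mesh.facet_tags[:] = opening_tag(1)   # opening everywhere, nothing fixed
        model = MixedModel(mesh)
        with pytest.raises(ValueError, match="rigid-body"):
            apply_boundary_conditions(model)


class TestSolver:
    def test_no_growth_converges_immediately_to_zero(self, coarse_mesh, params):
        mat, vasc = params
        st = solve_equilibrium(coarse_mesh, GrowthField(1.0), mat, vasc,
                               SolverOptions(), sealed=True)
        assert np.abs(st.u).max() == 0.0
        assert st.lambda_g_achieved == 1.0

    def test_confined_growth_reproduces_homogeneous_state(self, confined_state,
                                                          params):
        mat, _ = params
        st, mesh = confined_state
        sig_ref, icp_ref = V.confined_growth_reference(1.1, mat)
        assert np.abs(st.u).max() < 1e-12
        from dccsim.postprocess import stress_displacement_extrema
        smax, dmax, _ = stress_displacement_extrema(st, mesh)
        assert smax * 1e3 == pytest.approx(icp_ref, rel=1e-6)

    def test_patch_test_prescribed_affine_boundary(self, params):
        """A boundary-prescribed homogeneous state is reproduced exactly."""
        mat, vasc = params
        mesh = V.box_mesh((10., 10., 10.), (2, 2, 2))
        model = MixedModel(mesh)
        eps = -1e-4
        bnodes = np.unique(model.facet_p2_nodes(
            np.ones(len(mesh.facets), bool)))
        dofs = np.concatenate([3 * bnodes, 3 * bnodes + 1, 3 * bnodes + 2])
        vals = np.concatenate([np.zeros(2 * len(bnodes)),
                               eps * model.nodes2[bnodes, 2]])
        st = solve_equilibrium(mesh, GrowthField(1.0), mat, vasc,
                               SolverOptions(), model=model,
                               bc=DirichletBC(dofs, vals))
        u_exact = np.zeros_like(st.u)
        u_exact[:, 2] = eps * model.nodes2[:, 2]
        assert np.abs(st.u - u_exact).max() < 1e-14

    def test_oedometer_matches_small_strain_modulus(self, params):
        mat, vasc = params
        mesh = V.box_mesh((10., 10., 10.), (2, 2, 2))
        model = MixedModel(mesh)
        eps = -1e-4
        bnodes = np.unique(model.facet_p2_nodes(
            np.ones(len(mesh.facets), bool)))
        dofs = np.concatenate([3 * bnodes, 3 * bnodes + 1, 3 * bnodes + 2])
        vals = np.concatenate([np.zeros(2 * len(bnodes)),
                               eps * model.nodes2[bnodes, 2]])
        st = solve_equilibrium(mesh, GrowthField(1.0), mat, vasc,
                               SolverOptions(), model=model,
                               bc=DirichletBC(dofs, vals))
        F, _, _ = FE._gather(model, st.u, st.p_i)
        sig = C.cauchy_stress_from_Fe(F, mat)
        ref = V.small_strain_confined_compression_reference(mat, eps)
        assert sig[..., 2, 2].mean() == pytest.approx(ref, rel=5e-3)

    def test_load_step_invariance(self, params):
        """The converged state must not depend on the load-step count."""
        mat, vasc = params
        geom = build_idealized_head(openings=[OpeningSpec.unilateral(50.0)])
        mesh = mesh_head(geom, h=24)
        states = []
        for nsteps in (1, 4):
            st = solve_equilibrium(mesh, GrowthField(1.04), mat, vasc,
                                   SolverOptions(n_load_steps=nsteps))
            states.append(st)
        du = np.abs(states[0].u - states[1].u).max()
        assert du < 1e-7 * np.abs(states[0].u).max()

    def test_deterministic_convergence_log(self, params):
        mat, vasc = params
        geom = build_idealized_head(openings=[OpeningSpec.unilateral(50.0)])
        mesh = mesh_head(geom, h=24)
        logs = []
        for _ in range(2):
            st = solve_equilibrium(mesh, GrowthField(1.03), mat, vasc,
                                   SolverOptions(n_load_steps=1))
            logs.append(tuple(st.convergence_log))
        assert logs[0] == logs[1]

    def test_pressure_only_mode_freezes_displacement(self, params):
        mat, _ = params
        vasc5 = V.vascular_params_for_alpha_R(5.0, 0.07, mat)
        geom = build_idealized_head(semi_axes=(70, 70, 70))
        mesh = mesh_head(geom, h=20)
        st = solve_equilibrium(mesh, GrowthField(1.0), mat, vasc5,
                               SolverOptions(initial_pressure=0.0),
                               pressure_only=True)
        assert np.abs(st.u).max() == 0.0
        assert st.p_i.max() > 0.5 * vasc5.p_infinity
        # surface vertices are drained
        bverts = np.unique(mesh.facets)
        assert np.abs(st.p_i[bverts]).max() == 0.0

    def test_sphere_pressure_error_decreases_under_refinement(self, params):
        """L2 error against the drained-sphere closed form shrinks as the
        mesh is refined."""
        mat, _ = params
        vasc = V.vascular_params_for_alpha_R(5.0, 0.07, mat)
        profile, _, _ = V.reaction_diffusion_sphere_reference(0.07, mat, vasc)
        geom = build_idealized_head(semi_axes=(70, 70, 70))
        errs = []
        for nsub, layers in ((2, 4), (3, 8)):
            mesh = mesh_head(geom, h=12, nsub=nsub, n_layers=layers)
            st = solve_equilibrium(mesh, GrowthField(1.0), mat, vasc,
                                   SolverOptions(initial_pressure=0.0),
                                   pressure_only=True)
            model = st.model
            _, pq, _ = FE._gather(model, st.u, st.p_i)
            Xq = np.einsum("qa,eai->eqi", model.N2,
                           model.nodes2[model.cells10])
            pex = profile(np.linalg.norm(Xq, axis=2))
            errs.append(np.sqrt(((pq - pex) ** 2 * model.dV).sum()
                                / ((pex ** 2) * model.dV).sum()))
        assert errs[1] < errs[0]

    def test_quasistatic_mode_reports_solid_velocity(self, params):
        mat, vasc = params
        mesh = V.box_mesh((10., 10., 10.), (1, 1, 1))
        st = solve_equilibrium(mesh, GrowthField(1.02), mat, vasc,
                               SolverOptions(mode="quasistatic", dt=10.0,
                                             n_load_steps=2), sealed=True)
        assert st.v_s is not None
        assert st.v_s.shape == st.u.shape

    def test_solver_options_validation(self):
        with pytest.raises(ValueError):
            SolverOptions(newton_rtol=-1)
        with pytest.raises(ValueError):
            SolverOptions(n_load_steps=0)
        with pytest.raises(ValueError):
            SolverOptions(mode="dynamic")
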