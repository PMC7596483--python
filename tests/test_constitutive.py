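"""Growth kinematics, hyperelastic stresses, Starling exchange, Darcy flux."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dccsim import constitutive as C
from dccsim.constitutive import (
    GrowthField,
    MaterialParams,
    VascularParams,
    darcy_relative_flux,
    elastic_decomposition,
    fluid_stress,
    fluid_velocity,
    growth_tensor,
    solid_cauchy_stress,
    starling_source,
    strain_energy,
    total_stress,
)

MAT = MaterialParams()
VASC = VascularParams()


def random_F(rng, scale=0.2):
    """A random deformation gradient with comfortable positive determinant."""
    while True:
        F = np.eye(3) + rng.uniform(-scale, scale, (3, 3))
        if np.linalg.det(F) > 0.3:
            return F


class TestGrowthKinematics:
    def test_growth_tensor_is_isotropic_dilation(self):
        assert np.allclose(growth_tensor(1.1), np.diag([1.1, 1.1, 1.1]))
        assert np.allclose(growth_tensor(1.0), np.eye(3))

    @pytest.mark.parametrize("lam", [1.02, 1.05, 1.1])
    def test_growth_determinant_is_lambda_cubed(self, lam):
        assert np.linalg.det(growth_tensor(lam)) == pytest.approx(lam ** 3)

    def test_resorption_rejected(self):
        with pytest.raises(ValueError, match="resorption"):
            growth_tensor(0.95)

    def test_confined_decomposition(self):
        # fully confined closed-skull state: F = I under 10% growth
        state = elastic_decomposition(np.eye(3), 1.1)
        assert np.allclose(state.Fe, np.eye(3) / 1.1)
        assert state.Je == pytest.approx(1.1 ** -3)
        assert state.Je == pytest.approx(0.751315, abs=1e-6)
        assert state.I1bar == pytest.approx(3.0)

    def test_stress_free_swelling(self):
        state = elastic_decomposition(1.1 * np.eye(3), 1.1)
        assert np.allclose(state.Fe, np.eye(3))
        assert state.Je == pytest.approx(1.0)
        assert state.I1bar == pytest.approx(3.0)

    def test_identity_without_growth(self):
        state = elastic_decomposition(np.eye(3), 1.0)
        assert np.allclose(state.Fe, np.eye(3))

    def test_inverted_deformation_rejected(self):
        with pytest.raises(ValueError, match="inversion"):
            elastic_decomposition(-np.eye(3), 1.0)

    def test_invariant_I1bar_at_least_three(self, rng):
        for _ in range(50):
            state = elastic_decomposition(random_F(rng), 1.05)
            assert state.I1bar >= 3.0 - 1e-12


class TestStrainEnergy:
    def test_zero_at_reference(self):
        state = elastic_decomposition(np.eye(3), 1.0)
        assert strain_energy(state, MAT) == 0.0

    def test_confined_growth_energy_value(self):
        # W = 0.5 K (1.1^-3 - 1)^2: pure volumetric, deviatoric term vanishes
        state = elastic_decomposition(np.eye(3), 1.1)
        expected = 0.5 * 30e3 * (1.1 ** -3 - 1.0) ** 2
        assert strain_energy(state, MAT) == pytest.approx(expected, rel=1e-10)
        assert strain_energy(state, MAT) == pytest.approx(927.6, abs=0.1)

    def test_small_shear_energy_is_half_mu_gamma_squared(self):
        gamma = 1e-4
        F = np.eye(3)
        F[0, 1] = gamma
        state = elastic_decomposition(F, 1.0)
        assert strain_energy(state, MAT) == pytest.approx(
            0.5 * MAT.mu * gamma ** 2, rel=1e-6)

    def test_energy_nonnegative_on_random_states(self, rng):
        for _ in range(100):
            state = elastic_decomposition(random_F(rng), 1.03)
            assert strain_energy(state, MAT) >= -1e-12


class TestSolidStress:
    def test_zero_at_reference(self):
        state = elastic_decomposition(np.eye(3), 1.0)
        assert np.allclose(solid_cauchy_stress(state, MAT), 0.0)

    def test_confined_growth_stress_is_pure_pressure(self):
        state = elastic_decomposition(np.eye(3), 1.1)
        sig = solid_cauchy_stress(state, MAT)
        expected = MAT.Kbulk * (1.1 ** -3 - 1.0)
        assert np.allclose(sig, expected * np.eye(3), rtol=1e-12)
        assert expected == pytest.approx(-7460.6, abs=0.5)  # ~ -7.46 kPa

    def test_stress_matches_numerical_energy_gradient(self, rng):
        """sigma_s = Je^-1 Fe dW/dFe^T, checked by central differences."""
        for _ in range(10):
            lam = rng.uniform(1.0, 1.1)
            F = random_F(rng)
            state = elastic_decomposition(F, lam)
            Fe = state.Fe
            eps = 1e-6
            dWdFe = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    for sgn in (+1, -1):
                        Fp = Fe.copy()
                        Fp[i, j] += sgn * eps
                        sp = elastic_decomposition(Fp * lam, lam)
                        dWdFe[i, j] += sgn * strain_energy(sp, MAT) / (2 * eps)
            sigma_fd = Fe @ dWdFe.T / np.linalg.det(Fe)
            sigma = solid_cauchy_stress(state, MAT)
            assert np.allclose(sigma, sigma_fd,
                               atol=1e-6 * max(1.0, np.abs(sigma).max()))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_frame_indifference(self, seed):
        """sigma(R Fe) = R sigma(Fe) R^T for any rotation R."""
        rng = np.random.default_rng(seed)
        F = random_F(rng)
        lam = rng.uniform(1.0, 1.1)
        A = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(A)
        R = Q * np.sign(np.linalg.det(Q))
        sig = solid_cauchy_stress(elastic_decomposition(F, lam), MAT)
        sig_rot = solid_cauchy_stress(elastic_decomposition(R @ F, lam), MAT)
        assert np.allclose(sig_rot, R @ sig @ R.T,
                           atol=1e-8 * max(1.0, np.abs(sig).max()))

    def test_linear_elastic_limit(self, rng):
        """First-order stress: lambda_Lame tr(eps) I + 2 mu dev(eps)."""
        eps = 1e-6 * rng.standard_normal((3, 3))
        eps = 0.5 * (eps + eps.T)
        F = np.eye(3) + eps
        sig = solid_cauchy_stress(elastic_decomposition(F, 1.0), MAT)
        tr = np.trace(eps)
        dev = eps - tr / 3 * np.eye(3)
        sig_lin = MAT.Kbulk * tr * np.eye(3) + 2 * MAT.mu * dev
        assert np.allclose(sig, sig_lin, atol=1e-4 * np.abs(sig_lin).max())

    def test_confined_stress_linear_in_bulk_modulus(self):
        state = elastic_decomposition(np.eye(3), 1.08)
        s1 = solid_cauchy_stress(state, MaterialParams(Kbulk=30e3))[0, 0]
        s2 = solid_cauchy_stress(state, MaterialParams(Kbulk=60e3))[0, 0]
        assert s2 == pytest.approx(2 * s1, rel=1e-12)


class TestFluidStressAndTransport:
    def test_total_stress_reduces_to_solid_without_pressure(self):
        state = elastic_decomposition(np.eye(3), 1.1)
        assert np.allclose(total_stress(state, 0.0, MAT),
                           solid_cauchy_stress(state, MAT))

    def test_positive_pressure_is_compressive(self):
        state = elastic_decomposition(np.eye(3), 1.0)
        tot = total_stress(state, 1000.0, MAT)
        assert -np.trace(tot) / 3 == pytest.approx(1000.0)
        assert np.allclose(fluid_stress(1000.0), -1000.0 * np.eye(3))

    def test_confined_growth_total_pressure_in_mmHg(self):
        state = elastic_decomposition(np.eye(3), 1.1)
        tot = total_stress(state, 0.0, MAT)
        mmHg = -np.trace(tot) / 3 / C.MMHG_PA
        assert mmHg == pytest.approx(56.0, abs=0.1)

    def test_starling_source_values(self):
        assert starling_source(0.0, VASC) == pytest.approx(
            2.7e-12 * 7000 * 4000, rel=1e-12)          # 7.56e-5 1/s
        p_inf = VASC.p_infinity
        assert p_inf == pytest.approx(2.9e-5, rel=0.02)
        assert starling_source(p_inf, VASC) == pytest.approx(0.0, abs=1e-18)

    def test_starling_degenerate_conductivities(self):
        off = VascularParams(Lp=0.0, Lpl=0.0)
        assert starling_source(12345.0, off) == 0.0
        assert off.p_infinity == 0.0

    def test_darcy_flux_value_and_linearity(self):
        g = np.array([1000.0, 0.0, 0.0])
        assert np.allclose(darcy_relative_flux(g, MAT),
                           [-6.7e-9, 0.0, 0.0])
        assert np.allclose(darcy_relative_flux(2 * g, MAT),
                           2 * darcy_relative_flux(g, MAT))
        assert np.allclose(darcy_relative_flux(np.zeros(3), MAT), 0.0)

    def test_fluid_velocity_requires_volume_fraction(self):
        g = np.array([100.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="phi_f"):
            fluid_velocity(g, np.zeros(3), MAT, VASC)
        v = fluid_velocity(g, np.zeros(3), MAT,
                           VascularParams(phi_f=0.2))
        assert np.allclose(v, darcy_relative_flux(g, MAT) / 0.2)


class TestParameterValidation:
    def test_material_positivity(self):
        with pytest.raises(ValueError):
            MaterialParams(mu=-1.0)
        with pytest.raises(ValueError):
            MaterialParams(mu=10e3, Kbulk=1e3)  # K < 2/3 mu

    def test_vascular_ranges(self):
        with pytest.raises(ValueError):
            VascularParams(Lp=-1e-12)
        with pytest.raises(ValueError):
            VascularParams(phi_f=1.5)

    def test_growth_field_schedule(self):
        gf = GrowthField(1.1)
        assert gf.schedule[-1] == pytest.approx(1.1)
        assert np.all(np.diff(gf.schedule) > 0)
        with pytest.raises(ValueError):
            GrowthField(0.9)
        with pytest.raises(ValueError):
            GrowthField(1.1, schedule=[1.1, 1.05])

    def test_volumetric_interpretation_uses_cube_root(self):
        gf = GrowthField(1.1, interpretation="volumetric")
        tags = np.array([1, 2])
        assert np.allclose(gf.cell_targets(tags), 1.1 ** (1 / 3))
        lin = GrowthField(1.1)
        assert np.allclose(lin.cell_targets(tags), 1.1)
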