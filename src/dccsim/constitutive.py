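"""Constitutive laws of the biphasic, growth-driven brain tissue model.

The tissue is a saturated biphasic continuum: a hyperelastic solid skeleton
permeated by interstitial fluid.  Swelling after traumatic injury is modelled
as isotropic inelastic growth, F = Fe Fg with Fg = lambda_g I, so only the
elastic part Fe carries stress.  The solid follows a modified neo-Hookean
energy

    W = 1/2 [ mu (I1bar - 3) + K (Je - 1)^2 ],

with Je = det Fe and I1bar = Je^(-2/3) tr(Fe^T Fe) the isochoric first
invariant, giving the Cauchy stress

    sigma_s = mu Je^(-5/3) dev(be) + K (Je - 1) I,      be = Fe Fe^T.

The fluid phase contributes sigma_f = -p_i I (positive interstitial pressure
loads the solid compressively), moves by Darcy's law, and exchanges volume
with the vasculature and lymphatics through Starling's approximation

    Q = Lp (S/V) (p_v - p_i) - Lpl (Sl/Vl) (p_i - p_l).

All quantities are SI (Pa, m, s); mm-Hg / kPa / ml conversions happen only
at reporting boundaries.

The tensor functions in this module are vectorized over leading axes and
accept complex input, which the finite-element core exploits for
complex-step linearization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MMHG_PA",
    "MaterialParams",
    "VascularParams",
    "GrowthField",
    "DeformationState",
    "growth_tensor",
    "elastic_decomposition",
    "strain_energy",
    "solid_cauchy_stress",
    "fluid_stress",
    "total_stress",
    "starling_source",
    "darcy_relative_flux",
    "fluid_velocity",
    "det33",
    "inv33",
]

#: pascals per millimetre of mercury
MMHG_PA = 133.322


# ---------------------------------------------------------------------------
# parameter sets
# ---------------------------------------------------------------------------


@dataclass
class MaterialParams:
    """Solid-skeleton elasticity and tissue hydraulic conductivity.

    mu : shear modulus, Pa (brain tissue, 10 kPa)
    Kbulk : bulk modulus, Pa (30 kPa)
    k_hyd : tissue hydraulic conductivity, m^2 Pa^-1 s^-1
    """

    mu: float = 10e3
    Kbulk: float = 30e3
    k_hyd: float = 6.7e-12

    def __post_init__(self):
        if self.mu <= 0 or self.Kbulk <= 0 or self.k_hyd <= 0:
            raise ValueError("material parameters must be strictly positive")
        if self.Kbulk < 2.0 / 3.0 * self.mu:
            raise ValueError("Kbulk >= 2/3 mu required for a positive-definite "
                             "small-strain stiffness")


@dataclass
class VascularParams:
    """Starling exchange coefficients for blood and lymphatic vessels.

    Lp, Lpl : vessel-wall conductivities, m Pa^-1 s^-1
    SV, SlVl : vessel surface densities S/V, m^-1
    pv, pl : microvascular and lymphatic pressures, Pa
    phi_f : interstitial fluid volume fraction in [0, 1); optional, needed
        only to recover the intrinsic fluid velocity from the Darcy flux.
    """

    Lp: float = 2.7e-12
    SV: float = 7000.0
    pv: float = 4e3
    Lpl: float = 3.75e-4
    SlVl: float = 7000.0
    pl: float = 0.0
    phi_f: float | None = None

    def __post_init__(self):
        if min(self.Lp, self.Lpl, self.SV, self.SlVl) < 0:
            raise ValueError("conductivities and vessel densities must be >= 0")
        if self.phi_f is not None and not (0 <= self.phi_f < 1):
            raise ValueError("phi_f must lie in [0, 1)")

    @property
    def reaction_coefficient(self) -> float:
        """Slope magnitude of the Starling source, Lp S/V + Lpl Sl/Vl (1/(Pa s))."""
        return self.Lp * self.SV + self.Lpl * self.SlVl

    @property
    def p_infinity(self) -> float:
        """Equilibrium interstitial pressure, the root of Q(p) (Pa)."""
        c = self.reaction_coefficient
        if c == 0:
            return 0.0
        return (self.Lp * self.SV * self.pv + self.Lpl * self.SlVl * self.pl) / c


@dataclass
class GrowthField:
    """Per-region growth stretch ratios and their loading schedule.

    lambda_g maps region tags to the target stretch ratio (>= 1); a plain
    float applies to every region.  ``schedule`` is the ordered list of
    intermediate lambda_g levels at which the pipeline records outputs,
    ending at the target.
    """

    lambda_g: dict[int, float] | float = 1.1
    schedule: list[float] = field(default_factory=list)
    #: "linear": lambda_g is the linear stretch ratio (default; 10% swelling
    #: means lambda_g = 1.1, Jg = 1.331).  "volumetric": lambda_g is the
    #: volume ratio Jg and the linear stretch used is lambda_g^(1/3).
    interpretation: str = "linear"

    def __post_init__(self):
        if self.interpretation not in ("linear", "volumetric"):
            raise ValueError("interpretation must be 'linear' or 'volumetric'")
        values = (self.lambda_g.values() if isinstance(self.lambda_g, dict)
                  else [self.lambda_g])
        if any(v < 1.0 for v in values):
            raise ValueError("lambda_g must be >= 1 in every region "
                             "(tissue resorption is not modelled)")
        if not self.schedule:
            target = max(values)
            if target > 1.0:
                self.schedule = list(np.linspace(1.0, target, 6)[1:])
            else:
                self.schedule = [1.0]
        if any(b <= a for a, b in zip(self.schedule, self.schedule[1:])):
            raise ValueError("schedule must be strictly increasing")
        if self.schedule[0] < 1.0:
            raise ValueError("schedule must start at or above 1")

    @property
    def target(self) -> float:
        return self.schedule[-1]

    @property
    def nominal_target(self) -> float:
        """Largest lambda_g as given (before any volumetric conversion)."""
        values = (self.lambda_g.values() if isinstance(self.lambda_g, dict)
                  else [self.lambda_g])
        return float(max(values))

    def region_value(self, region_tag: int) -> float:
        if isinstance(self.lambda_g, dict):
            return self.lambda_g.get(region_tag, 1.0)
        return self.lambda_g

    def cell_targets(self, region_tags: np.ndarray) -> np.ndarray:
        """Target linear growth stretch per cell."""
        if not isinstance(self.lambda_g, dict):
            out = np.full(len(region_tags), float(self.lambda_g))
        else:
            out = np.ones(len(region_tags))
            for tag, val in self.lambda_g.items():
                out[region_tags == tag] = val
        if self.interpretation == "volumetric":
            out = out ** (1.0 / 3.0)
        return out


# ---------------------------------------------------------------------------
# small dense linear algebra, complex-safe and vectorized over leading axes
# ---------------------------------------------------------------------------


def det33(A: np.ndarray) -> np.ndarray:
    """Determinant of (..., 3, 3) arrays (complex-safe closed form)."""
    return (A[..., 0, 0] * (A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1])
            - A[..., 0, 1] * (A[..., 1, 0] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 0])
            + A[..., 0, 2] * (A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0]))


def inv33(A: np.ndarray, det: np.ndarray | None = None) -> np.ndarray:
    """Inverse of (..., 3, 3) arrays via the adjugate (complex-safe)."""
    if det is None:
        det = det33(A)
    adj = np.empty_like(A)
    adj[..., 0, 0] = A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1]
    adj[..., 0, 1] = A[..., 0, 2] * A[..., 2, 1] - A[..., 0, 1] * A[..., 2, 2]
    adj[..., 0, 2] = A[..., 0, 1] * A[..., 1, 2] - A[..., 0, 2] * A[..., 1, 1]
    adj[..., 1, 0] = A[..., 1, 2] * A[..., 2, 0] - A[..., 1, 0] * A[..., 2, 2]
    adj[..., 1, 1] = A[..., 0, 0] * A[..., 2, 2] - A[..., 0, 2] * A[..., 2, 0]
    adj[..., 1, 2] = A[..., 0, 2] * A[..., 1, 0] - A[..., 0, 0] * A[..., 1, 2]
    adj[..., 2, 0] = A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0]
    adj[..., 2, 1] = A[..., 0, 1] * A[..., 2, 0] - A[..., 0, 0] * A[..., 2, 1]
    adj[..., 2, 2] = A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0]
    return adj / det[..., None, None]


def _eye_like(A: np.ndarray) -> np.ndarray:
    return np.broadcast_to(np.eye(3, dtype=A.dtype), A.shape)


# ---------------------------------------------------------------------------
# growth kinematics
# ---------------------------------------------------------------------------


@dataclass
class DeformationState:
    """Multiplicative growth kinematics at a material point.

    F = Fe Fg with Fg = lambda_g I; Je = det Fe; I1bar is the isochoric
    first invariant Je^(-2/3) tr(Fe^T Fe).
    """

    F: np.ndarray
    Fg: np.ndarray
    Fe: np.ndarray
    Je: np.ndarray
    I1bar: np.ndarray
    lambda_g: np.ndarray


def growth_tensor(lambda_g) -> np.ndarray:
    """Isotropic growth tensor Fg = lambda_g I (lambda_g >= 1)."""
    lam = np.asarray(lambda_g, dtype=float)
    if np.any(lam < 1.0):
        raise ValueError("lambda_g < 1 (tissue resorption) is not modelled")
    return lam[..., None, None] * np.eye(3)


def elastic_decomposition(F: np.ndarray, lambda_g) -> DeformationState:
    """Split a total deformation gradient into elastic and growth parts."""
    F = np.asarray(F, dtype=float)
    J = det33(F)
    if np.any(J.real <= 0):
        raise ValueError("det(F) <= 0: element inversion")
    lam = np.asarray(lambda_g, dtype=float)
    Fg = growth_tensor(lam)
    Fe = F / lam[..., None, None]
    Je = det33(Fe)
    Ce_tr = np.einsum("...ij,...ij->...", Fe, Fe)
    I1bar = Je ** (-2.0 / 3.0) * Ce_tr
    return DeformationState(F=F, Fg=Fg, Fe=Fe, Je=Je, I1bar=I1bar,
                            lambda_g=lam)


# ---------------------------------------------------------------------------
# energy and stresses
# ---------------------------------------------------------------------------


def strain_energy(state: DeformationState, mat: MaterialParams) -> np.ndarray:
    """Strain energy density W (Pa); zero iff Fe is a rotation."""
    return 0.5 * (mat.mu * (state.I1bar - 3.0)
                  + mat.Kbulk * (state.Je - 1.0) ** 2)


def cauchy_stress_from_Fe(Fe: np.ndarray, mat: MaterialParams) -> np.ndarray:
    """Solid Cauchy stress from the elastic deformation gradient.

    sigma_s = mu Je^(-5/3) dev(be) + K (Je - 1) I, complex-safe and
    vectorized over leading axes.
    """
    Je = det33(Fe)
    be = Fe @ np.swapaxes(Fe, -1, -2)
    tr = be[..., 0, 0] + be[..., 1, 1] + be[..., 2, 2]
    dev = be - (tr / 3.0)[..., None, None] * _eye_like(be)
    return (mat.mu * Je[..., None, None] ** (-5.0 / 3.0) * dev
            + mat.Kbulk * (Je - 1.0)[..., None, None] * _eye_like(be))


def solid_cauchy_stress(state: DeformationState, mat: MaterialParams) -> np.ndarray:
    """Solid-phase Cauchy stress sigma_s (Pa), derived from W."""
    return cauchy_stress_from_Fe(state.Fe, mat)


def fluid_stress(p_i) -> np.ndarray:
    """Fluid-phase stress -p_i I: positive interstitial pressure is compressive."""
    p = np.asarray(p_i)
    return -p[..., None, None] * np.eye(3)


def total_stress(state: DeformationState, p_i, mat: MaterialParams) -> np.ndarray:
    """Total Cauchy stress sigma_s + sigma_f."""
    return solid_cauchy_stress(state, mat) + fluid_stress(p_i)


# ---------------------------------------------------------------------------
# fluid exchange and transport
# ---------------------------------------------------------------------------


def starling_source(p_i, vasc: VascularParams) -> np.ndarray:
    """Volumetric fluid exchange rate Q(p_i) (1/s), linear with negative slope."""
    p = np.asarray(p_i)
    return (vasc.Lp * vasc.SV * (vasc.pv - p)
            - vasc.Lpl * vasc.SlVl * (p - vasc.pl))


def darcy_relative_flux(grad_p, mat: MaterialParams) -> np.ndarray:
    """phi_f-weighted relative fluid flux (v_f - v_s) phi_f = -k grad p (m/s)."""
    return -mat.k_hyd * np.asarray(grad_p)


def fluid_velocity(grad_p, v_s, mat: MaterialParams, vasc: VascularParams) -> np.ndarray:
    """Intrinsic fluid velocity v_f = v_s - (k/phi_f) grad p.

    Requires ``vasc.phi_f``; the momentum/pressure system itself never needs
    it (the fluid mass balance is eliminated into the pressure equation).
    """
    if vasc.phi_f is None or vasc.phi_f == 0:
        raise ValueError("fluid-velocity recovery requires a fluid volume "
                         "fraction: set VascularParams.phi_f")
    return np.asarray(v_s) + darcy_relative_flux(grad_p, mat) / vasc.phi_f
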