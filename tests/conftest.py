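"""Shared fixtures: coarse meshes and pre-solved states reused across tests.

Solves are expensive, so session-scoped fixtures cache one coarse
open-skull solve and one confined (sealed) solve that many tests inspect.
"""

import numpy as np
import pytest

from dccsim import constitutive as con
from dccsim import fe_core, geometry
from dccsim.dcc_pipeline import ScenarioConfig
from dccsim.fe_core import SolverOptions
from dccsim.geometry import OpeningSpec


@pytest.fixture(scope="session")
def default_geometry():
    return geometry.build_idealized_head()


@pytest.fixture(scope="session")
def coarse_mesh(default_geometry):
    """Closed head, ~2k tets: cheap enough for assembly-level tests."""
    return geometry.mesh_head(default_geometry, h=24)


@pytest.fixture(scope="session")
def coarse_model(coarse_mesh):
    return fe_core.MixedModel(coarse_mesh)


@pytest.fixture(scope="session")
def params():
    return con.MaterialParams(), con.VascularParams()


@pytest.fixture(scope="session")
def open_scenario():
    """Unilateral r = 40 mm scenario at sweep resolution."""
    return ScenarioConfig(
        openings=[OpeningSpec.unilateral(40.0)], h_mm=20,
        schedule=[1.05, 1.1], solver=SolverOptions(n_load_steps=2))


@pytest.fixture(scope="session")
def open_state(open_scenario):
    """One converged open-skull solve at lambda_g = 1.1 (r = 40 mm)."""
    from dccsim.dcc_pipeline import open_skull_step
    mesh = open_scenario.build_mesh()
    state = open_skull_step(open_scenario, 1.1, mesh)
    return state, mesh


@pytest.fixture(scope="session")
def confined_state(coarse_mesh, params):
    """Sealed-skull solve at lambda_g = 1.1 on the coarse mesh."""
    mat, vasc = params
    state = fe_core.solve_equilibrium(
        coarse_mesh, con.GrowthField(1.1), mat, vasc,
        SolverOptions(n_load_steps=2), sealed=True)
    return state, coarse_mesh


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
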