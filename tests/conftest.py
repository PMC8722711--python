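"""Shared fixtures: configurations, meshes, and solved fields are expensive,
so the standard ones are session-scoped and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from injectsim import (
    DriveSpec,
    assemble,
    build_default_configuration,
    generate_mesh,
    solve,
)


@pytest.fixture(scope="session")
def simplified_config():
    return build_default_configuration("simplified")


@pytest.fixture(scope="session")
def coarse_mesh(simplified_config):
    return generate_mesh(simplified_config, "coarse")


@pytest.fixture(scope="session")
def coarse_system(simplified_config, coarse_mesh):
    return assemble(coarse_mesh, simplified_config)


@pytest.fixture(scope="session")
def dc_solution(coarse_system):
    return solve(coarse_system, DriveSpec("current", 19e-3, 0.0))


@pytest.fixture(scope="session")
def hf_solution(coarse_system):
    return solve(coarse_system, DriveSpec("current", 19e-3, 1e4))


@pytest.fixture(scope="session")
def full_config():
    return build_default_configuration(
        "full_biophysical", patch_side=0.02, separation=0.02)


@pytest.fixture(scope="session")
def full_solution(full_config):
    mesh = generate_mesh(full_config, "coarse")
    return solve(assemble(mesh, full_config), DriveSpec("current", 1.0, 0.0))


@pytest.fixture(scope="session")
def rc_oracle():
    """Surrogate circuit with bench-scale parameters (interface dominated)."""
    from injectsim.oracles import LumpedRCOracle

    return LumpedRCOracle(
        interface_resistance=3000.0,
        interface_capacitance=50e-9,
        series_tissue_resistance=500.0,
        load_resistance=1000.0,
    )
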