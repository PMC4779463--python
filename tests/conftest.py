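"""Shared fixtures: materials, geometries and cached coarse solves."""

from __future__ import annotations

import numpy as np
import pytest

from osteoflux.geometry import PlateDimensions, build_initial_trabecula
from osteoflux.materials import bone_poroelastic
from osteoflux.meshing import generate_mesh
from osteoflux.poroelastic import LoadPulse, solve_transient, standard_bcs
from osteoflux.study import f_target_amplitude


@pytest.fixture(scope="session")
def bone():
    """Bone material in the remodelling-default permeability reading."""
    return bone_poroelastic()


@pytest.fixture(scope="session")
def bone_intrinsic():
    """Bone material with the literature intrinsic permeability."""
    return bone_poroelastic("intrinsic")


@pytest.fixture(scope="session")
def f_target():
    return f_target_amplitude()


@pytest.fixture(scope="session")
def plated_trabecula():
    """Initial upright 1 x 0.2 mm trabecula with end plates."""
    return build_initial_trabecula(1.0, 0.2, 0.0, PlateDimensions())


@pytest.fixture(scope="session")
def coarse_mesh(plated_trabecula):
    """Coarse (h = 0.03 mm) study mesh, shared across tests."""
    return generate_mesh(plated_trabecula, h=0.03)


@pytest.fixture(scope="session")
def compression_result(coarse_mesh, bone, f_target):
    """Transient solve of pure compression at F_target on the coarse mesh."""
    pulse = LoadPulse(amplitude=f_target, theta=np.pi)
    return solve_transient(coarse_mesh, bone, pulse, standard_bcs(coarse_mesh, pulse))
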