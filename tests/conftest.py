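"""Shared fixtures: phantoms, forward systems and the study runs."""

from __future__ import annotations

import numpy as np
import pytest

from bladdereit import forward as fw
from bladdereit.mesh import lattice_mesh
from bladdereit.phantom import make_conductivity_field, phantom_preset


@pytest.fixture(scope="session")
def coarse_phantom():
    """Coarse (~9k tet) tank + 8x8 layout for fast forward-model tests."""
    return phantom_preset("coarse")


@pytest.fixture(scope="session")
def coarse_system(coarse_phantom):
    tank, layout, mesh = coarse_phantom
    field = make_conductivity_field(mesh)
    system = fw.CEMSystem(
        mesh, field.values, layout.face_sets(mesh), layout.contact_impedances()
    )
    return system


@pytest.fixture(scope="session")
def coarse_frame(coarse_phantom, coarse_system):
    tank, layout, mesh = coarse_phantom
    field = make_conductivity_field(mesh)
    return fw.simulate_frame(mesh, field, layout, system=coarse_system)


@pytest.fixture(scope="session")
def coarse_jacobian(coarse_phantom, coarse_system):
    tank, layout, mesh = coarse_phantom
    field = make_conductivity_field(mesh)
    return fw.compute_jacobian(mesh, field, layout, system=coarse_system)


@pytest.fixture(scope="session")
def unit_lattice():
    """Uniform 6 mm lattice over a 120 mm cube, for boundary-field oracles."""
    xs = np.arange(0.0, 120.1, 6.0)
    return lattice_mesh(xs, xs, xs)


@pytest.fixture(scope="session")
def study_results():
    """The three-model simulated bladder-filling series (shared, ~1 min)."""
    from bladdereit.pipeline import run_study

    return run_study(seed=1)
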