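"""Shared fixtures: miniature validation geometry and cached meshes.

The miniature cell pair (R = 2 um, L = 6 um) keeps the solver-level
physics tests (rest stability, RC relaxation, scheme convergence,
collapsed-vs-explicit validation) fast while exercising the full
machinery.  Session scope avoids re-meshing across tests.
"""

import numpy as np
import pytest

from cleftsim import (DomainConductivities, GeometryParams, IDLayout,
                      MembraneParams, SolverParams, StimulusProtocol,
                      build_cell_pair_mesh, build_explicit_pair_mesh)
from cleftsim.mesh import MeshResolution


@pytest.fixture(scope="session")
def mini_geom():
    return GeometryParams(R_ID=2.0, L=6.0, Lx=30.0, Ly=12.0, Lz=12.0,
                          r_Na=0.3, r_GJ=0.3, r_peri=0.31,
                          patch_radius=0.8, patch_offset=2.0)


@pytest.fixture(scope="session")
def mini_res():
    return MeshResolution(h_cluster=0.2, h_feature=0.45, r_feature=1.2,
                          h_coarse=0.85, n_rim=16, h_axial0=0.35,
                          axial_growth=1.8, h_axial_max=2.0,
                          cap_h0=0.8, cap_growth=2.0, ann_layers=3)


@pytest.fixture(scope="session")
def mini_mesh(mini_geom, mini_res):
    return build_cell_pair_mesh(mini_geom, None, mini_res)


@pytest.fixture(scope="session")
def mini_explicit_mesh(mini_geom, mini_res):
    return build_explicit_pair_mesh(mini_geom, 100.0, mini_res)


@pytest.fixture(scope="session")
def default_geom():
    return GeometryParams()


@pytest.fixture(scope="session")
def coarse_mesh(default_geom):
    """The shared production mesh (coarse preset, uniform layout tags)."""
    return build_cell_pair_mesh(default_geom, IDLayout(), "coarse")


@pytest.fixture
def passive_membrane():
    """Leak-only membrane: Na+ conductance disabled."""
    return MembraneParams(gbar_Na=0.0)
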