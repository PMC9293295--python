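"""Operator assembly: stiffness, mass, gap and cleft matrices, partitioning."""

from types import SimpleNamespace

import numpy as np
import pytest
import scipy.sparse.linalg as spla

from cleftsim import mesh as M
from cleftsim.fem import (DomainConductivities, StimulusProtocol,
                          assemble_cleft_stiffness, assemble_gap_matrix,
                          assemble_mass_matrices, assemble_system,
                          assemble_volume_stiffness, build_incidence,
                          partition_system)
from cleftsim.geometry import IDLayout
from cleftsim.mesh import _split_prisms, gap_conductivity_field


def _fake_volume_mesh(nodes, tets, domain=None):
    return SimpleNamespace(nodes=np.asarray(nodes, float),
                           tets=np.asarray(tets, np.int64),
                           tet_domain=np.zeros(len(tets), np.int8) if domain is None
                           else domain,
                           n_nodes=len(nodes))


class TestVolumeStiffness:
    def test_reference_tetrahedron(self):
        """Unit-sigma local stiffness of the reference tet equals the
        hand-computed gradient Gram matrix."""
        mesh = _fake_volume_mesh([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
                                 [[0, 1, 2, 3]])
        K = assemble_volume_stiffness(mesh, 1.0, 1.0).toarray()
        expect = np.array([[3, -1, -1, -1],
                           [-1, 1, 0, 0],
                           [-1, 0, 1, 0],
                           [-1, 0, 0, 1]]) / 6.0
        assert np.allclose(K, expect)

    def test_constant_in_nullspace(self, mini_mesh):
        K = assemble_volume_stiffness(mini_mesh, 3.333, 6.666)
        assert np.abs(K @ np.ones(mini_mesh.n_nodes)).max() < 1e-10

    def test_conductivity_scaling(self, mini_mesh):
        K1 = assemble_volume_stiffness(mini_mesh, 1.0, 1.0)
        K2 = assemble_volume_stiffness(mini_mesh, 2.0, 2.0)
        assert abs(K2 - 2 * K1).max() < 1e-12

    def test_degenerate_tet_rejected(self):
        mesh = _fake_volume_mesh([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]],
                                 [[0, 1, 2, 3]])
        with pytest.raises(M.MeshingError, match="degenerate"):
            assemble_volume_stiffness(mesh, 1.0, 1.0)

    def test_laplace_box_linear_profile(self):
        """Extruded brick with opposite faces clamped at 0 and V0 recovers
        the exact linear potential (P1 elements are exact for it)."""
        sec = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        tris = np.array([[0, 1, 2], [0, 2, 3]])
        xs = np.linspace(0.0, 1.0, 5)
        nodes = np.vstack([np.column_stack([np.full(4, x), sec]) for x in xs])
        ids = [np.arange(4) + 4 * k for k in range(5)]
        tets = np.vstack([_split_prisms(tris, ids[k], ids[k + 1], np.arange(4))
                          for k in range(4)])
        mesh = _fake_volume_mesh(nodes, tets)
        K = assemble_volume_stiffness(mesh, 1.0, 1.0).tolil()
        v0 = 7.5
        dirichlet = np.concatenate([ids[0], ids[-1]])
        values = np.concatenate([np.zeros(4), np.full(4, v0)])
        free = np.setdiff1d(np.arange(20), dirichlet)
        Kc = K.tocsr()
        rhs = -Kc[free][:, dirichlet] @ values
        sol = spla.spsolve(Kc[free][:, free].tocsc(), rhs)
        assert np.allclose(sol, v0 * nodes[free, 0], atol=1e-10)


class TestMassMatrices:
    def test_total_membrane_area(self, mini_mesh):
        G, Q = assemble_mass_matrices(mini_mesh, C_m=1.0)
        g = mini_mesh.geom
        R, L = g.R_ID * 1e-4, g.L * 1e-4
        per_cell = 2 * np.pi * R ** 2 + 2 * np.pi * R * L
        # two cells; the junctional and outer discs plus lateral walls
        assert G.sum() == pytest.approx(2 * per_cell, rel=0.02)

    def test_q_equals_cm_g(self, mini_mesh):
        G, Q = assemble_mass_matrices(mini_mesh, C_m=1.0)
        assert abs(Q - G).max() == 0.0
        _, Q2 = assemble_mass_matrices(mini_mesh, C_m=2.0)
        assert abs(Q2 - 2 * G).max() < 1e-18

    def test_unit_square_hand_value(self):
        """Two-triangle unit square: consistent P1 mass matrix assembled by
        hand from A/12 * [[2,1,1],[1,2,1],[1,1,2]]."""
        mesh = SimpleNamespace(
            nodes=np.array([[0, 0, 0], [0, 1, 0], [0, 1, 1], [0, 0, 1.0]]),
            mem_pairs=np.array([[0, 0], [1, 1], [2, 2], [3, 3]]),
            mem_tris=np.array([[0, 1, 2], [0, 2, 3]]),
        )
        G, _ = assemble_mass_matrices(mesh, 1.0)
        a = 0.5 / 12.0
        # nodes 0 and 2 belong to both triangles, nodes 1 and 3 to one each
        expect = np.array([[4, 1, 2, 1], [1, 2, 1, 0],
                           [2, 1, 4, 1], [1, 0, 1, 2.0]]) * a
        assert np.allclose(G.toarray(), expect)


class TestCleftStiffness:
    def test_radial_disc_closed_form(self, coarse_mesh):
        """Uniform sheet, grounded rim, uniform areal sink 2J (both membranes):
        V_e(r) = -J (R^2 - r^2) / (2 w sigma), the radial Poisson solution."""
        mb = coarse_mesh
        w, sigma = 40e-7, 6.666
        s = w * sigma
        Kc = assemble_cleft_stiffness(mb, np.full(len(mb.disc.tris), s))
        cleft = mb.cleft_nodes
        lump = M._disc_lumped_areas(mb.disc) * 1e-8          # cm^2
        J = 1000.0                                           # uA/cm^2 out of the cleft
        rhs_full = np.zeros(mb.n_nodes)
        rhs_full[cleft] += -2 * J * lump
        interior = np.setdiff1d(cleft, mb.junction_nodes)
        A = Kc[interior][:, interior].tocsc()
        b = rhs_full[interior]                               # rim held at 0
        v = spla.spsolve(A, b)
        r_cm = np.hypot(*mb.disc.nodes.T) * 1e-4
        R_cm = mb.geom.R_ID * 1e-4
        exact_all = -J * (R_cm ** 2 - r_cm ** 2) / (2 * s)
        order = {n: k for k, n in enumerate(interior)}
        idx = np.array([order[n] for n in cleft if n in order])
        mask = np.array([n in order for n in cleft])
        err = np.abs(v[idx] - exact_all[mask]).max()
        assert err < 0.02 * np.abs(exact_all).max()   # within discretization error

    def test_width_doubling_halves_drop(self, coarse_mesh):
        K1 = assemble_cleft_stiffness(coarse_mesh,
                                      np.full(len(coarse_mesh.disc.tris), 1e-5))
        K2 = assemble_cleft_stiffness(coarse_mesh,
                                      np.full(len(coarse_mesh.disc.tris), 2e-5))
        assert abs(K2 - 2 * K1).max() < 1e-18

    def test_plaque_sheet_conductance_contrast(self, default_geom):
        lay = IDLayout("close", 40, 40)
        mb = M.build_cell_pair_mesh(default_geom, lay, "coarse")
        w, f_sigma = M.build_cleft_property_fields(lay, mb)
        sheet = w * f_sigma
        plaque = sheet[mb.id_region == M.REG_PLAQUE][0]
        bulk = sheet[mb.id_region == M.REG_BULK][0]
        assert bulk / plaque == pytest.approx(200.0)  # (40/2) / 0.1


class TestGapMatrix:
    def test_equal_layers_zero_current(self, default_geom):
        lay = IDLayout("close", 50, 10, has_perinexus=True)
        mb = M.build_cell_pair_mesh(default_geom, lay, "coarse")
        Kg = assemble_gap_matrix(mb, gap_conductivity_field(lay, mb, 25.3e-6))
        v = np.zeros(mb.n_nodes)
        v[np.unique(mb.id_tris_vi1)] = 3.0
        v[np.unique(mb.id_tris_vi2)] = 3.0
        assert np.abs(Kg @ v).max() < 1e-18

    def test_two_terminal_conductance(self, default_geom):
        lay = IDLayout("close", 50, 10, has_perinexus=True)
        mb = M.build_cell_pair_mesh(default_geom, lay, "coarse")
        G_gap = 25.3e-6
        Kg = assemble_gap_matrix(mb, gap_conductivity_field(lay, mb, G_gap))
        x = np.zeros(mb.n_nodes)
        x[np.unique(mb.id_tris_vi1)] = 1.0      # layer 1 at 1 V, layer 2 at 0
        assert x @ (Kg @ x) == pytest.approx(G_gap, rel=1e-9)

    def test_zero_conductance_zero_matrix(self, coarse_mesh):
        Kg = assemble_gap_matrix(coarse_mesh,
                                 np.zeros(len(coarse_mesh.disc.tris)))
        assert Kg.nnz == 0


@pytest.fixture(scope="module")
def mini_system_like(mini_mesh):
    return assemble_system(mini_mesh, None, DomainConductivities(), 0.0)


class TestPartitionAndSystem:
    def test_full_stiffness_exactly_symmetric(self, default_geom):
        lay = IDLayout("close", 50, 10, has_perinexus=True)
        mb = M.build_cell_pair_mesh(default_geom, lay, "coarse")
        sys_ = assemble_system(mb, lay, DomainConductivities(), G_gap=25.3e-6)
        assert abs(sys_.K - sys_.K.T).max() == 0.0

    def test_incidence_structure(self, mini_mesh):
        U = build_incidence(mini_mesh)
        UT = U.T.tocsr()
        for row in range(0, UT.shape[0], 97):
            vals = sorted(UT[row].data)
            assert vals == [-1.0, 1.0]

    def test_stimulus_current_conserved(self, mini_mesh):
        stim = StimulusProtocol(cell=1, amplitude=11.5, duration=0.5)
        sys_ = assemble_system(mini_mesh, None, DomainConductivities(),
                               0.0, stimuli=(stim,))
        f = sys_.neumann_source(0.1)
        assert f.sum() == pytest.approx(11.5e-3)     # nA -> uA
        assert sys_.neumann_source(0.9).sum() == 0.0

    def test_voltage_clamp_enters_dirichlet(self, mini_mesh):
        stim = StimulusProtocol(cell=2, mode="voltage_clamp", amplitude=-20.0,
                                duration=1.0)
        sys_ = assemble_system(mini_mesh, None, DomainConductivities(),
                               0.0, stimuli=(stim,))
        assert np.isin(mini_mesh.patch_nodes[2], sys_.dirichlet).all()
        vd = sys_.dirichlet_values(0.5)
        assert set(np.unique(vd)) == {-20.0, 0.0}

    def test_operator_export_round_trip(self, mini_system_like, tmp_path):
        import scipy.io as sio
        from cleftsim.fem import export_operators
        paths = export_operators(mini_system_like, tmp_path)
        K2 = sio.mmread(paths[0]).tocsr()
        assert abs(K2 - mini_system_like.K).max() == 0.0

    def test_resistive_current_conservation(self, mini_mesh, passive_membrane):
        """Stationary passive state: current injected at the patch equals the
        current leaving through the grounded faces."""
        amp = 0.5  # nA
        stim = StimulusProtocol(cell=1, amplitude=amp, duration=1e9)
        sys_ = assemble_system(mini_mesh, None, DomainConductivities(),
                               0.0, stimuli=(stim,))
        p = passive_membrane
        A = (sys_.K_N + p.gbar_K * (sys_.U_N @ sys_.G @ sys_.U_N.T)).tocsc()
        b = sys_.neumann_source(0.0) + p.gbar_K * (sys_.U_N @ sys_.G
                                                   @ np.full(sys_.U.shape[1], p.E_K))
        V_N = spla.spsolve(A, b)
        V = np.zeros(mini_mesh.n_nodes)
        V[sys_.free] = V_N
        i_ground = (sys_.K[sys_.dirichlet] @ V).sum()
        assert i_ground == pytest.approx(-amp * 1e-3, rel=1e-6)
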