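"""Mesh generation: conformity, determinism, tagging, property fields."""

import numpy as np
import pytest

from cleftsim.geometry import GeometryParams, IDLayout, compute_membrane_areas
from cleftsim import mesh as M
from cleftsim.mesh import (MeshResolution, MeshingError, audit_mesh,
                           build_cell_pair_mesh, build_channel_density_field,
                           build_cleft_property_fields, disc_triangle_areas,
                           gap_conductivity_field, membrane_triangle_areas)


class TestConformity:
    def test_audit_passes_mini(self, mini_mesh):
        stats = audit_mesh(mini_mesh)
        assert stats["n_tets"] > 0
        assert stats["min_tet_volume"] > 0

    def test_audit_passes_explicit(self, mini_explicit_mesh):
        audit_mesh(mini_explicit_mesh)
        assert not mini_explicit_mesh.collapsed
        assert mini_explicit_mesh.mid_cleft_node >= 0

    def test_audit_passes_default(self, coarse_mesh):
        audit_mesh(coarse_mesh)

    def test_id_layers_coincide(self, coarse_mesh):
        mb = coarse_mesh
        assert np.abs(mb.nodes[mb.id_tris_vi1] - mb.nodes[mb.id_tris_ve]).max() == 0.0
        assert np.abs(mb.nodes[mb.id_tris_vi1] - mb.nodes[mb.id_tris_vi2]).max() == 0.0

    def test_junction_nodes_shared_with_volume(self, coarse_mesh):
        mb = coarse_mesh
        ext_nodes = np.unique(mb.tets[mb.tet_domain == M.DOM_EXTRA])
        assert np.isin(mb.junction_nodes, ext_nodes).all()
        interior = np.setdiff1d(mb.cleft_nodes, mb.junction_nodes)
        assert not np.isin(interior, np.unique(mb.tets)).any()


class TestDeterminismAndSharing:
    def test_byte_identical_rebuild(self, default_geom):
        a = build_cell_pair_mesh(default_geom, IDLayout(), "coarse")
        b = build_cell_pair_mesh(default_geom, IDLayout(), "coarse")
        assert a.nodes.tobytes() == b.nodes.tobytes()
        assert a.tets.tobytes() == b.tets.tobytes()

    def test_configurations_share_id_triangulation(self, default_geom):
        """The three ID configurations must run on one common mesh so that
        configuration differences are not meshing artefacts."""
        meshes = [build_cell_pair_mesh(default_geom, lay, "coarse") for lay in (
            IDLayout("uniform", 50, 50),
            IDLayout("close", 50, 10, has_perinexus=True),
            IDLayout("remote", 50, 10, has_perinexus=True))]
        ref = meshes[0]
        for mb in meshes[1:]:
            assert mb.disc.nodes.tobytes() == ref.disc.nodes.tobytes()
            assert mb.disc.tris.tobytes() == ref.disc.tris.tobytes()
            assert mb.nodes.tobytes() == ref.nodes.tobytes()

    def test_refinement_increases_id_triangles(self, default_geom):
        counts = []
        for level in range(3):
            res = MeshResolution().refined(level)
            counts.append(len(M.graded_disc_section(default_geom.R_ID, res).tris))
        assert counts[0] < counts[1] < counts[2]


@pytest.fixture(scope="module")
def close_mesh(default_geom):
    lay = IDLayout("close", 50, 10, has_perinexus=True)
    return build_cell_pair_mesh(default_geom, lay, "coarse"), lay


class TestRegionTags:
    def test_every_triangle_tagged_once(self, close_mesh):
        mb, _ = close_mesh
        assert set(np.unique(mb.id_region)) <= {M.REG_BULK, M.REG_CLUSTER,
                                                M.REG_PLAQUE, M.REG_PERINEXUS}
        assert len(mb.id_region) == len(mb.disc.tris)

    def test_cluster_centred_plaque_displaced(self, close_mesh):
        mb, lay = close_mesh
        cent = mb.disc.nodes[mb.disc.tris].mean(axis=1)
        r0 = np.hypot(cent[:, 0], cent[:, 1])
        assert r0[mb.id_region == M.REG_CLUSTER].max() <= mb.geom.r_Na
        d = lay.plaque_distance(mb.geom)
        rp = np.hypot(cent[:, 0], cent[:, 1] - d)
        assert rp[mb.id_region == M.REG_PLAQUE].max() <= mb.geom.r_GJ

    def test_width_field_three_values(self, close_mesh):
        mb, lay = close_mesh
        w, f_sigma = build_cleft_property_fields(lay, mb)
        widths_nm = set(np.round(w / 1e-7, 6))
        assert widths_nm == {2.0, 10.0, 50.0}
        assert set(np.unique(f_sigma)) == {0.1, 1.0}

    def test_cluster_sits_in_narrowed_perinexus(self, close_mesh):
        """In the close configuration the Na+ cluster lies inside the
        perinexal disc and must feel the narrowed width w_peri."""
        mb, lay = close_mesh
        w, _ = build_cleft_property_fields(lay, mb)
        cluster = mb.id_region == M.REG_CLUSTER
        assert np.allclose(w[cluster] / 1e-7, lay.w_peri)

    def test_uniform_layout_constant_field(self, default_geom):
        lay = IDLayout("uniform", 40, 40)
        mb = build_cell_pair_mesh(default_geom, lay, "coarse")
        w, f_sigma = build_cleft_property_fields(lay, mb)
        assert np.allclose(w, 40e-7)
        assert np.allclose(f_sigma, 1.0)

    def test_equal_widths_hide_perinexus(self, default_geom):
        lay = IDLayout("close", 50, 50, has_perinexus=True)
        mb = build_cell_pair_mesh(default_geom, lay, "coarse")
        w, _ = build_cleft_property_fields(lay, mb)
        assert set(np.round(w / 1e-7, 6)) == {2.0, 50.0}   # plaque + bulk only


class TestChannelDensity:
    @pytest.mark.parametrize("P", [0.25, 0.5, 0.9])
    def test_channel_count_conserved(self, default_geom, coarse_mesh, P):
        f = build_channel_density_field(default_geom, IDLayout(), coarse_mesh, P)
        areas = membrane_triangle_areas(coarse_mesh)
        A_cell, _, _ = compute_membrane_areas(default_geom)
        for sheets in ((M.MEM_LAT1, M.MEM_OUT1, M.MEM_ID1),
                       (M.MEM_LAT2, M.MEM_OUT2, M.MEM_ID2)):
            sel = np.isin(coarse_mesh.mem_sheet, sheets)
            total = (f.mem_tri_gna[sel] * areas[sel]).sum()
            assert total == pytest.approx(A_cell, rel=0.01)

    def test_id_current_confined_to_cluster(self, default_geom, coarse_mesh):
        f = build_channel_density_field(default_geom, IDLayout(), coarse_mesh)
        id1 = coarse_mesh.mem_sheet == M.MEM_ID1
        region = coarse_mesh.id_region[coarse_mesh.mem_tri_disc[id1]]
        assert np.all(f.mem_tri_gna[id1][region != M.REG_CLUSTER] == 0.0)
        assert np.all(f.mem_tri_gna[id1][region == M.REG_CLUSTER] > 0.0)

    def test_cluster_to_disc_area_ratio(self, default_geom):
        g = default_geom
        assert (g.r_Na / g.R_ID) ** 2 == pytest.approx(1.0 / 256.0)


class TestGapField:
    def test_two_terminal_conductance_exact(self, default_geom):
        lay = IDLayout("close", 50, 10, has_perinexus=True)
        mb = build_cell_pair_mesh(default_geom, lay, "coarse")
        sigma = gap_conductivity_field(lay, mb, 25.3e-6)
        areas = disc_triangle_areas(mb.disc) * 1e-8
        assert (sigma * areas).sum() == pytest.approx(25.3e-6, rel=1e-12)
        assert np.all(sigma[mb.id_region != M.REG_PLAQUE] == 0.0)

    def test_uniform_layout_spreads_around_cluster(self, default_geom):
        lay = IDLayout("uniform", 50, 50)
        mb = build_cell_pair_mesh(default_geom, lay, "coarse")
        sigma = gap_conductivity_field(lay, mb, 25.3e-6)
        assert np.all(sigma[mb.id_region == M.REG_CLUSTER] == 0.0)
        areas = disc_triangle_areas(mb.disc) * 1e-8
        assert (sigma * areas).sum() == pytest.approx(25.3e-6, rel=1e-12)

    def test_zero_coupling_zero_field(self, default_geom, coarse_mesh):
        sigma = gap_conductivity_field(IDLayout(), coarse_mesh, 0.0)
        assert np.all(sigma == 0.0)


class TestPatchAndGround:
    def test_patch_inside_cell(self, coarse_mesh):
        for c in (1, 2):
            xyz = coarse_mesh.nodes[coarse_mesh.patch_nodes[c]]
            r = np.hypot(xyz[:, 1], xyz[:, 2]) / 1e-4
            assert np.all(r <= coarse_mesh.geom.patch_radius + 1e-9)
            x_um = xyz[:, 0] / 1e-4
            expect = (coarse_mesh.geom.L - coarse_mesh.geom.patch_offset)
            assert np.allclose(np.abs(x_um), expect)
            w = coarse_mesh.patch_weights[c]
            assert w.sum() == pytest.approx(1.0)

    def test_ground_on_box_ends(self, coarse_mesh):
        x = coarse_mesh.nodes[coarse_mesh.ground_nodes][:, 0] / 1e-4
        assert np.allclose(np.abs(x), coarse_mesh.geom.Lx / 2)
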