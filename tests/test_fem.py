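"""Forward finite-element model: meshing, contact, and solid-mechanics
sanity (symmetry, scaling, energy balance, linear limit)."""

import math

import numpy as np
import pytest

from palpquant.fem import (
    LABEL_CANCER,
    LABEL_HEALTHY,
    LABEL_INTERFACE,
    ForceProfile,
    IndentationProtocol,
    TissueDomain,
    build_mesh,
    indent_once,
    linear_elastic_force,
    sweep,
)
from palpquant.geometry import NoduleSpec
from palpquant.materials import CANCEROUS_NODULE, HEALTHY_PROSTATE


class TestMesh:
    def test_circle_label_area(self):
        dom = TissueDomain(100, 100, mesh_size=2.5)
        mesh = build_mesh(dom, NoduleSpec(shape="circle", diameter=16.0,
                                          depth=30.0, center_x=50.0))
        assert mesh.cancer_area == pytest.approx(math.pi * 64, rel=0.02)
        assert set(np.unique(mesh.labels)) == {LABEL_HEALTHY, LABEL_INTERFACE,
                                               LABEL_CANCER}

    def test_homogeneous_mesh_all_healthy(self):
        mesh = build_mesh(TissueDomain(60, 60, mesh_size=4.0))
        assert np.all(mesh.labels == LABEL_HEALTHY)
        assert mesh.cancer_area == 0.0

    def test_diffuse_annulus_three_labels_and_area(self):
        dom = TissueDomain(100, 100, mesh_size=2.5)
        mesh = build_mesh(
            dom,
            NoduleSpec(shape="diffuse_annulus", diameter=20.0, outer_diameter=30.0,
                       depth=30.0, center_x=50.0),
        )
        assert set(np.unique(mesh.labels)) == {LABEL_HEALTHY, LABEL_INTERFACE,
                                               LABEL_CANCER}
        inner_area, shell_area = mesh.region_areas
        assert inner_area == pytest.approx(math.pi * 100, rel=0.02)
        assert shell_area == pytest.approx(math.pi * (15**2 - 10**2), rel=0.02)

    def test_nodule_on_boundary_rejected(self):
        dom = TissueDomain(60, 60, mesh_size=4.0)
        with pytest.raises(ValueError, match="boundary"):
            build_mesh(dom, NoduleSpec(shape="circle", diameter=20.0, depth=8.0,
                                       center_x=30.0))

    def test_text_export_round_figures(self):
        mesh = build_mesh(TissueDomain(20, 20, mesh_size=5.0))
        text = mesh.to_text()
        header = text.splitlines()[0].split()
        assert int(header[0]) == mesh.n_nodes
        assert int(header[1]) == mesh.n_elements


class TestProtocolAndProfiles:
    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            IndentationProtocol(positions=(10.0,), depths=())
        with pytest.raises(ValueError):
            IndentationProtocol(positions=(10.0,), depths=(5.0, 1.0))
        with pytest.raises(ValueError):
            IndentationProtocol(positions=(10.0,), depths=(1.0,), indenter_radius=0)

    def test_force_profile_validation(self):
        with pytest.raises(ValueError):
            ForceProfile(1.0, np.array([0.0, 1.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            ForceProfile(1.0, np.array([1.0, 0.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            ForceProfile(1.0, np.array([0.0, 1.0]), np.array([1.0, -1.0]))


class TestIndentation:
    def test_zero_depth_zero_force(self, small_meshes, prostate_materials,
                                   small_protocol):
        f = indent_once(small_meshes["homogeneous"], prostate_materials, 30.0,
                        0.0, small_protocol)
        assert f == 0.0

    def test_symmetry_about_centerline(self, small_sweeps):
        for prof in small_sweeps["homogeneous"]:
            assert np.allclose(prof.forces, prof.forces[::-1], rtol=5e-3)

    def test_force_monotone_in_depth(self, small_sweeps):
        shallow, deep = small_sweeps["homogeneous"]
        assert np.all(deep.forces > shallow.forces)

    def test_force_superlinear_in_depth(self, small_sweeps):
        # spherical-tip contact: growing contact width makes F(d) convex
        shallow, deep = small_sweeps["homogeneous"]
        ratio_depth = deep.indentation_depth / shallow.indentation_depth
        assert np.all(deep.forces / shallow.forces > ratio_depth)

    def test_stiff_nodule_raises_force_above_it(self, small_sweeps):
        for homog, nod in zip(small_sweeps["homogeneous"], small_sweeps["nodule"]):
            center = np.argmin(np.abs(homog.positions - 30.0))
            assert nod.forces[center] > homog.forces[center]

    def test_modulus_doubling_doubles_force(self, small_meshes, small_protocol,
                                            prostate_materials):
        doubled = {k: m.scaled(2.0) for k, m in prostate_materials.items()}
        f1 = indent_once(small_meshes["nodule"], prostate_materials, 30.0, 4.0,
                         small_protocol)
        f2 = indent_once(small_meshes["nodule"], doubled, 30.0, 4.0, small_protocol)
        assert f2 == pytest.approx(2.0 * f1, rel=1e-3)

    def test_frictionless_horizontal_reaction_vanishes(
        self, small_meshes, prostate_materials, small_protocol
    ):
        res = indent_once(small_meshes["homogeneous"], prostate_materials, 30.0,
                          4.0, small_protocol, return_state=True)
        assert abs(res.horizontal_force) < 0.01 * res.force

    def test_sweep_single_point_matches_indent_once(
        self, small_meshes, prostate_materials
    ):
        prot = IndentationProtocol(positions=(30.0,), depths=(2.0,), increments=8)
        profs = sweep(small_meshes["homogeneous"], prostate_materials, prot)
        f = indent_once(small_meshes["homogeneous"], prostate_materials, 30.0,
                        2.0, prot)
        assert len(profs) == 1 and len(profs[0]) == 1
        assert profs[0].forces[0] == pytest.approx(f, rel=1e-9)


class TestMechanicsInvariants:
    mats = {"healthy": HEALTHY_PROSTATE, "cancerous": CANCEROUS_NODULE}

    def test_external_work_matches_stored_energy(self):
        mesh = build_mesh(TissueDomain(60, 60, mesh_size=2.0))
        prot = IndentationProtocol(positions=(30.0,), depths=(5.0,), increments=20)
        res = indent_once(mesh, self.mats, 30.0, 5.0, prot, return_state=True)
        assert res.external_work >= res.stored_energy * 0.99
        assert res.external_work == pytest.approx(res.stored_energy, rel=0.01)

    def test_linear_elastic_limit_at_small_depth(self):
        mesh = build_mesh(TissueDomain(60, 60, mesh_size=3.0))
        prot = IndentationProtocol(positions=(30.0,), depths=(0.1,), increments=4)
        f_nl = indent_once(mesh, self.mats, 30.0, 0.1, prot)
        f_lin = linear_elastic_force(mesh, self.mats, 30.0, 0.1)
        assert f_nl == pytest.approx(f_lin, rel=0.03)

    def test_penalty_contact_matches_prescribed(self):
        mesh = build_mesh(TissueDomain(60, 60, mesh_size=2.0))
        prot = IndentationProtocol(positions=(30.0,), depths=(5.0,), increments=10)
        f_presc = indent_once(mesh, self.mats, 30.0, 5.0, prot)
        res_pen = indent_once(mesh, self.mats, 30.0, 5.0, prot, mode="penalty",
                              return_state=True)
        assert res_pen.force == pytest.approx(f_presc, rel=0.03)
        assert res_pen.max_penetration < 0.01  # fraction of indentation depth
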