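"""Shared fixtures: one small palpation scenario solved once per session.

The scenario is a 60 x 60 mm block (coarse 4-mm mesh) with a 12-mm
circular nodule at 20 mm center depth, probed at 9 symmetric positions
with indentation depths 1 and 4 mm — small enough to solve in seconds,
large enough to exhibit the physics the tests assert.
"""

import numpy as np
import pytest

from palpquant.fem import IndentationProtocol, TissueDomain, build_mesh, sweep
from palpquant.geometry import NoduleSpec
from palpquant.materials import CANCEROUS_NODULE, HEALTHY_PROSTATE


@pytest.fixture(scope="session")
def prostate_materials():
    return {"healthy": HEALTHY_PROSTATE, "cancerous": CANCEROUS_NODULE}


@pytest.fixture(scope="session")
def small_domain():
    return TissueDomain(width=60.0, height=60.0, mesh_size=4.0)


@pytest.fixture(scope="session")
def small_protocol():
    return IndentationProtocol(
        positions=tuple(np.linspace(14.0, 46.0, 9)),
        depths=(1.0, 4.0),
        indenter_radius=5.0,
        increments=8,
    )


@pytest.fixture(scope="session")
def small_nodule():
    return NoduleSpec(shape="circle", diameter=12.0, depth=20.0, center_x=30.0)


@pytest.fixture(scope="session")
def small_meshes(small_domain, small_nodule):
    return {
        "homogeneous": build_mesh(small_domain),
        "nodule": build_mesh(small_domain, small_nodule),
    }


@pytest.fixture(scope="session")
def small_sweeps(small_meshes, prostate_materials, small_protocol):
    """Force profiles of the homogeneous block and the nodule phantom."""
    return {
        name: sweep(mesh, prostate_materials, small_protocol)
        for name, mesh in small_meshes.items()
    }
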