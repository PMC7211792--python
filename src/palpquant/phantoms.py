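"""Synthetic tissue-phantom generator.

Bundles of (domain, nodule, materials, protocol) reproduce the study
configurations used throughout the package: a 100 x 100 mm in-silico block
probed at 40 equally spaced surface locations with indentation depths
1/5/10 mm and a 10-mm spherical-tip probe; a set of irregular nodule
scenarios (intersecting circles, an arbitrary polygon, a diffuse-interface
annulus, a rectangle); and a 2D mid-section of a gelatin phantom
(100 x 31 mm, 20 x 12 mm rectangular nodule with its top face 10 mm below
the surface, probed at 2/4/6 mm over 5 locations spaced 20 mm).

:func:`synth_measurement` turns a bundle into "experimental" force
profiles by running the forward model and perturbing it with a
measurement-noise model: zero-mean Gaussian force noise scaled to the
per-profile maximum, and a per-probing contact-finding offset applied as a
re-evaluation of the local force-depth curve at depth + offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.interpolate import PchipInterpolator

from .fem import ForceProfile, IndentationProtocol, TissueDomain, build_mesh, sweep
from .geometry import (
    ARBITRARY_POLYGON_XY,
    NoduleGeometry,
    NoduleSpec,
    circle_union_area,
    make_nodule,
)
from .materials import (
    CANCEROUS_NODULE,
    HEALTHY_PROSTATE,
    NeoHookeanMaterial,
)

__all__ = [
    "NoiseModel",
    "PhantomBundle",
    "NoduleSpec",
    "make_nodule",
    "standard_configurations",
    "apply_noise",
    "synth_measurement",
]

MAX_CONTACT_OFFSET = 0.5  # mm; bound on the contact-finding error


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise model for synthetic palpation data.

    ``force_sigma`` is the standard deviation of zero-mean Gaussian force
    noise as a fraction of the per-profile maximum force;
    ``contact_offset_sd`` is the standard deviation (mm) of the
    contact-finding error, drawn per probing event and clipped to
    +-0.5 mm.  Fully reproducible from ``seed``.
    """

    force_sigma: float = 0.0
    contact_offset_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.force_sigma < 0 or self.contact_offset_sd < 0:
            raise ValueError("noise magnitudes must be >= 0")


@dataclass(frozen=True)
class PhantomBundle:
    """Complete, ready-to-run study configuration."""

    name: str
    domain: TissueDomain
    nodule: NoduleSpec | None
    materials: Mapping
    protocol: IndentationProtocol
    notes: str = ""

    def mesh(self, **kwargs):
        return build_mesh(self.domain, self.nodule, **kwargs)

    def nodule_geometry(self) -> NoduleGeometry | None:
        return None if self.nodule is None else make_nodule(self.nodule)


def _insilico_protocol(n_positions: int = 40) -> IndentationProtocol:
    # 40 equally spaced probe locations inset one indenter radius from the
    # lateral edges, indentation depths 1/5/10 mm, 10-mm spherical-tip probe
    return IndentationProtocol(
        positions=tuple(np.linspace(5.0, 95.0, n_positions)),
        depths=(1.0, 5.0, 10.0),
        indenter_radius=5.0,
        increments=10,
    )


def standard_configurations() -> dict[str, PhantomBundle]:
    """Registry of ready-made study configurations.

    All in-silico bundles use the published Ogden parameters for healthy
    prostate-mimicking tissue and a 2:1-stiffer cancerous nodule in a
    100 x 100 mm block; the gelatin bundle uses the fitted incompressible
    neo-Hookean constants (E = 28.1 / 39.5 kPa).
    """
    domain = TissueDomain(width=100.0, height=100.0, mesh_size=2.5)
    mats = {"healthy": HEALTHY_PROSTATE, "cancerous": CANCEROUS_NODULE}
    protocol = _insilico_protocol()
    reg: dict[str, PhantomBundle] = {}

    def add(name, nodule, notes="", dom=domain, m=mats, prot=protocol):
        reg[name] = PhantomBundle(
            name=name, domain=dom, nodule=nodule, materials=m, protocol=prot,
            notes=notes,
        )

    add(
        "homogeneous",
        None,
        "healthy block without nodule (localization baseline)",
    )
    add(
        "insilico_example1",
        NoduleSpec(shape="circle", diameter=16.0, depth=30.0, center_x=50.0),
        "16-mm circular nodule at 30 mm center depth (worked example 1)",
    )
    add(
        "insilico_example2",
        NoduleSpec(shape="circle", diameter=30.0, depth=45.0, center_x=50.0),
        "30-mm circular nodule at 45 mm center depth (worked example 2)",
    )
    add(
        "intersecting_circles_small",
        NoduleSpec(
            shape="intersecting_circles",
            diameters=(10.0, 15.0),
            offset=6.25,  # mean radius: circles genuinely intersect
            depth=30.0,
            center_x=50.0,
        ),
        "union of 10-mm and 15-mm circles, centers 6.25 mm apart",
    )
    add(
        "intersecting_circles_large",
        NoduleSpec(
            shape="intersecting_circles",
            diameters=(15.0, 15.0),
            offset=7.5,
            depth=30.0,
            center_x=50.0,
        ),
        "union of two 15-mm circles, centers 7.5 mm apart",
    )
    add(
        "arbitrary_polygon",
        NoduleSpec(
            shape="polygon",
            vertices=ARBITRARY_POLYGON_XY,
            depth=30.0,
            center_x=50.0,
        ),
        "irregular nodule (synthetic fixed polygon stand-in, ~15 mm extent)",
    )
    add(
        "diffuse_annulus",
        NoduleSpec(
            shape="diffuse_annulus",
            diameter=20.0,
            outer_diameter=30.0,
            depth=30.0,
            center_x=50.0,
            mixture_fraction=0.5,
        ),
        "20-mm cancerous core in a 30-mm shell of 50/50 mixed tissue",
    )
    add(
        "rectangular_nodule",
        NoduleSpec(
            shape="rectangle", width=12.5, height=25.0, depth=30.0, center_x=50.0
        ),
        "rectangular nodule 25 mm high x 12.5 mm wide",
    )
    gel_domain = TissueDomain(width=100.0, height=31.0, mesh_size=2.0)
    gel_mats = {
        "healthy": NeoHookeanMaterial(c1=4.6898e-3),  # E = 28.1 kPa
        "cancerous": NeoHookeanMaterial(c1=6.5872e-3),  # E = 39.5 kPa
    }
    gel_protocol = IndentationProtocol(
        positions=(10.0, 30.0, 50.0, 70.0, 90.0),  # 5 sites, 20 mm spacing
        depths=(2.0, 4.0, 6.0),
        indenter_radius=5.0,
        increments=10,
    )
    add(
        "gelatin_phantom_2d",
        NoduleSpec(
            shape="rectangle",
            width=20.0,
            height=12.0,
            depth=10.0,
            depth_reference="top",
            center_x=50.0,
        ),
        "2D mid-section of the gelatin phantom: 20 x 12 mm nodule, top face "
        "10 mm below the surface",
        dom=gel_domain,
        m=gel_mats,
        prot=gel_protocol,
    )
    return reg


def apply_noise(sims: list[ForceProfile], noise: NoiseModel) -> list[ForceProfile]:
    """Perturb simulated profiles with the measurement-noise model.

    The contact-finding offset is applied per probing event by
    re-evaluating the local force-depth curve (monotone PCHIP through the
    origin) at depth + offset; Gaussian force noise is added afterwards,
    scaled to the per-profile maximum.  Negative perturbed forces are
    clipped to zero with a warning.  Deterministic given ``noise.seed``.
    """
    rng = np.random.default_rng(noise.seed)
    depths = np.array([p.indentation_depth for p in sims])
    forces = np.vstack([p.forces for p in sims])  # (ndepth, npos)
    out = forces.copy()
    if noise.contact_offset_sd > 0:
        offsets = np.clip(
            rng.normal(0.0, noise.contact_offset_sd, size=forces.shape),
            -MAX_CONTACT_OFFSET,
            MAX_CONTACT_OFFSET,
        )
        d_grid = np.concatenate([[0.0], depths])
        for j in range(forces.shape[1]):
            f_grid = np.concatenate([[0.0], forces[:, j]])
            curve = PchipInterpolator(d_grid, f_grid, extrapolate=True)
            out[:, j] = curve(depths + offsets[:, j])
    if noise.force_sigma > 0:
        scale = noise.force_sigma * out.max(axis=1, keepdims=True)
        out = out + rng.normal(0.0, 1.0, size=out.shape) * scale
    n_clipped = int(np.sum(out < 0))
    if n_clipped:
        warnings.warn(f"{n_clipped} noisy force value(s) clipped at zero")
        out = np.clip(out, 0.0, None)
    return [
        ForceProfile(
            indentation_depth=d,
            positions=sims[i].positions,
            forces=out[i],
            source="synthetic",
        )
        for i, d in enumerate(depths)
    ]


def synth_measurement(
    bundle: PhantomBundle,
    noise: NoiseModel,
    mesh=None,
    protocol: IndentationProtocol | None = None,
    **solver_kwargs,
) -> list[ForceProfile]:
    """Simulated "experimental" palpation of a phantom bundle: a forward
    sweep perturbed by :func:`apply_noise` and tagged ``synthetic``."""
    protocol = protocol or bundle.protocol
    if mesh is None:
        mesh = build_mesh(bundle.domain, bundle.nodule)
    sims = sweep(mesh, bundle.materials, protocol, **solver_kwargs)
    return apply_noise(sims, noise)
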