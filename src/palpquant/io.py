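"""Configuration, serialization and the end-to-end pipeline.

All artifacts are plain text: force profiles as CSV (columns
``position_mm, depth_mm, force_N_per_mm, source``), calibration libraries
and quantification results as JSON with a schema-version field, materials
and run configurations as YAML.  Units are fixed to mm / N / MPa and
asserted on load.  The pipeline logs one structured line per stage with
wall time and input/output hashes, and is a pure function of
(configuration, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pydantic
import yaml

from .fem import ForceProfile, IndentationProtocol, TissueDomain, build_mesh, sweep
from .geometry import NoduleSpec
from .materials import (
    NeoHookeanMaterial,
    OgdenMaterial,
)
from .phantoms import NoiseModel, PhantomBundle, synth_measurement
from .profiles import NoNoduleDetected, curvature_profile, localize_nodule, second_derivative
from .quantify import (
    CalibrationLibrary,
    QuantificationResult,
    build_library,
    intersect_curves,
    invert_to_curve,
    quantification_errors,
)

__all__ = [
    "SchemaError",
    "RunConfig",
    "PipelineOutcome",
    "read_profiles",
    "write_profiles",
    "read_library",
    "write_library",
    "write_result",
    "read_config",
    "run_pipeline",
]

logger = logging.getLogger("palpquant")

PROFILE_COLUMNS = ["position_mm", "depth_mm", "force_N_per_mm", "source"]


class SchemaError(ValueError):
    """A serialized artifact violates its schema."""


# ---------------------------------------------------------------------------
# force-profile CSV round trip
# ---------------------------------------------------------------------------


def write_profiles(profiles: Sequence[ForceProfile], path) -> None:
    """Write profiles as CSV, lossless to 12 significant digits."""
    rows = []
    for p in profiles:
        for x, f in zip(p.positions, p.forces):
            rows.append(
                {
                    "position_mm": float(f"{x:.12g}"),
                    "depth_mm": float(f"{p.indentation_depth:.12g}"),
                    "force_N_per_mm": float(f"{f:.12g}"),
                    "source": p.source,
                }
            )
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_profiles(path) -> list[ForceProfile]:
    """Read a profiles CSV; schema violations name the offending row."""
    df = pd.read_csv(path)
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"profiles CSV missing column(s): {missing}")
    profiles = []
    for (depth, source), grp in df.groupby(["depth_mm", "source"], sort=True):
        grp = grp.reset_index()
        pos = grp["position_mm"].to_numpy(dtype=float)
        frc = grp["force_N_per_mm"].to_numpy(dtype=float)
        bad = np.where(np.diff(pos) <= 0)[0]
        if len(bad):
            raise SchemaError(
                f"non-ascending position at row {int(grp['index'][bad[0] + 1]) + 2} "
                f"(depth {depth} mm)"
            )
        neg = np.where(frc < 0)[0]
        if len(neg):
            raise SchemaError(
                f"negative force at row {int(grp['index'][neg[0]]) + 2} "
                f"(depth {depth} mm)"
            )
        profiles.append(
            ForceProfile(
                indentation_depth=float(depth),
                positions=pos,
                forces=frc,
                source=str(source),
            )
        )
    profiles.sort(key=lambda p: p.indentation_depth)
    return profiles


# ---------------------------------------------------------------------------
# JSON artifacts
# ---------------------------------------------------------------------------


def write_library(lib: CalibrationLibrary, path) -> None:
    Path(path).write_text(json.dumps(lib.to_dict(), indent=1))


def read_library(path) -> CalibrationLibrary:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != 1:
        raise SchemaError("unsupported or missing library schema_version")
    return CalibrationLibrary.from_dict(doc)


def write_result(result_doc: Mapping, path) -> None:
    Path(path).write_text(json.dumps(result_doc, indent=1, sort_keys=True))


def _hash_obj(obj) -> str:
    text = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# run configuration (schema-validated, unknown keys rejected)
# ---------------------------------------------------------------------------


class _Base(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")


class UnitsCfg(_Base):
    length: Literal["mm"] = "mm"
    force: Literal["N"] = "N"
    pressure: Literal["MPa"] = "MPa"


class DomainCfg(_Base):
    width: float
    height: float
    mesh_size: float = 2.5
    grading: float = 1.0

    def build(self) -> TissueDomain:
        return TissueDomain(**self.model_dump())


class MaterialCfg(_Base):
    model: Literal["ogden", "neo_hookean"]
    mu: Optional[list[float]] = None
    alpha: Optional[list[float]] = None
    d: Optional[list[float]] = None
    c1: Optional[float] = None

    def build(self):
        if self.model == "ogden":
            if self.mu is None or self.alpha is None:
                raise SchemaError("ogden material requires mu and alpha")
            return OgdenMaterial(mu=tuple(self.mu), alpha=tuple(self.alpha),
                                 d=tuple(self.d or ()))
        if self.c1 is None:
            raise SchemaError("neo_hookean material requires c1")
        return NeoHookeanMaterial(c1=self.c1)


class ProtocolCfg(_Base):
    positions: list[float]
    depths: list[float]
    indenter_radius: float = 5.0
    increments: int = 10

    def build(self) -> IndentationProtocol:
        return IndentationProtocol(
            positions=tuple(self.positions),
            depths=tuple(self.depths),
            indenter_radius=self.indenter_radius,
            increments=self.increments,
        )


class NoduleCfg(_Base):
    shape: str
    depth: float = 0.0
    center_x: float = 0.0
    depth_reference: str = "center"
    diameter: Optional[float] = None
    diameters: Optional[tuple[float, float]] = None
    offset: Optional[float] = None
    outer_diameter: Optional[float] = None
    width: Optional[float] = None
    height: Optional[float] = None
    vertices: Optional[list[tuple[float, float]]] = None
    mixture_fraction: float = 0.5

    def build(self) -> NoduleSpec:
        kw = self.model_dump()
        if kw["vertices"] is not None:
            kw["vertices"] = tuple(tuple(v) for v in kw["vertices"])
        return NoduleSpec(**kw)


class NoiseCfg(_Base):
    force_sigma: float = 0.0
    contact_offset_sd: float = 0.0
    seed: Optional[int] = None


class LibraryCfg(_Base):
    depths: Optional[list[float]] = None
    diameters: Optional[list[float]] = None
    path: Optional[str] = None
    smoothing: str | float = "auto"


class SolverCfg(_Base):
    mode: Literal["prescribed", "penalty"] = "prescribed"
    kappa_ratio: float = 100.0


class RunConfig(_Base):
    """Schema-validated end-to-end run configuration (units mm / N / MPa)."""

    units: UnitsCfg = UnitsCfg()
    seed: int = 0
    domain: DomainCfg
    materials: dict[str, MaterialCfg]
    protocol: ProtocolCfg
    nodule: Optional[NoduleCfg] = None
    noise: NoiseCfg = NoiseCfg()
    library: LibraryCfg = LibraryCfg()
    solver: SolverCfg = SolverCfg()

    @pydantic.model_validator(mode="after")
    def _check_materials(self):
        if "healthy" not in self.materials:
            raise ValueError("materials must define at least 'healthy'")
        return self


def read_config(path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        return RunConfig.model_validate(doc)
    except pydantic.ValidationError as exc:
        raise SchemaError(str(exc)) from exc


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineOutcome:
    """Result of a full localization/quantification run."""

    status: str  # "ok" | "no_nodule"
    result: QuantificationResult | None
    localized_position: float | None
    measured_d2: dict  # indentation depth -> curvature at nodule position
    stages: list  # provenance log: (stage, seconds, input hash, output hash)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "status": self.status,
            "localized_position_mm": self.localized_position,
            "measured_d2": {str(k): v for k, v in self.measured_d2.items()},
            "result": self.result.to_dict() if self.result else None,
            "stages": [list(s) for s in self.stages],
        }


def _stage(stages, name, t0, inp, out):
    dt = time.time() - t0
    hin, hout = _hash_obj(inp), _hash_obj(out)
    logger.info("stage=%s wall_s=%.3f in=%s out=%s", name, dt, hin, hout)
    stages.append((name, round(dt, 3), hin, hout))


def run_pipeline(config: RunConfig) -> PipelineOutcome:
    """Execute localize -> curvature -> invert -> intersect end to end.

    The measurement is generated synthetically from the configured nodule
    (with the configured noise), the baseline from the homogeneous domain,
    and the calibration library is loaded from ``library.path`` or built
    from the configured grids.  Deterministic given the configuration seed.
    """
    stages: list = []
    domain = config.domain.build()
    materials = {k: v.build() for k, v in config.materials.items()}
    protocol = config.protocol.build()
    solver = config.solver.model_dump()
    nodule = config.nodule.build() if config.nodule else None

    t0 = time.time()
    if config.library.path:
        lib = read_library(config.library.path)
    else:
        if not (config.library.depths and config.library.diameters):
            raise SchemaError("library requires either a path or depth/diameter grids")
        lib = build_library(
            domain, materials, protocol,
            diameters=config.library.diameters,
            depths=config.library.depths,
            smoothing=config.library.smoothing,
            mode=solver["mode"], kappa_ratio=solver["kappa_ratio"],
        )
    _stage(stages, "library", t0, config.library.model_dump(), lib.to_dict())

    t0 = time.time()
    noise = NoiseModel(
        force_sigma=config.noise.force_sigma,
        contact_offset_sd=config.noise.contact_offset_sd,
        seed=config.noise.seed if config.noise.seed is not None else config.seed,
    )
    bundle = PhantomBundle(
        name="configured", domain=domain, nodule=nodule,
        materials=materials, protocol=protocol,
    )
    measured = synth_measurement(bundle, noise, **solver)
    _stage(stages, "measurement", t0, _hash_obj(str(nodule)),
           [p.forces.tolist() for p in measured])

    t0 = time.time()
    baseline = sweep(build_mesh(domain, None), materials, protocol, **solver)
    _stage(stages, "baseline", t0, "homogeneous", [p.forces.tolist() for p in baseline])

    t0 = time.time()
    try:
        position = localize_nodule(measured[-1], baseline[-1])
    except NoNoduleDetected:
        _stage(stages, "localize", t0, "-", "no_nodule")
        return PipelineOutcome("no_nodule", None, None, {}, stages)
    _stage(stages, "localize", t0, "-", position)

    t0 = time.time()
    smoothing = config.library.smoothing
    curves, d2s = [], {}
    for prof in measured:
        d2 = second_derivative(prof, at=position, smoothing=smoothing)
        d2s[prof.indentation_depth] = d2
        curves.append(invert_to_curve(lib, d2, prof.indentation_depth))
    _stage(stages, "invert", t0, d2s, [c.points.tolist() for c in curves])

    t0 = time.time()
    result = intersect_curves(curves)
    if nodule is not None:
        size_err, depth_err, area_err = quantification_errors(result, nodule)
        result = QuantificationResult(
            candidates=result.candidates,
            chosen=result.chosen,
            equivalent_radius=result.equivalent_radius,
            area=result.area,
            errors={
                "size_percent": size_err,
                "depth_percent": depth_err,
                "area_percent": area_err,
            },
        )
    _stage(stages, "intersect", t0, [c.points.tolist() for c in curves],
           result.to_dict())
    return PipelineOutcome("ok", result, position, d2s, stages)
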