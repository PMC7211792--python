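"""Decoupling nodule size from depth via a calibration-library inversion.

A single indentation depth cannot separate nodule size from nodule depth: a
small shallow nodule and a large deep one can produce the same local force
feedback (see :func:`ambiguity_envelope`).  The decoupling method works on
the *curvature* of the force profile at the nodule position, measured at
several indentation depths:

1. forward simulations over a grid of (nodule depth x diameter x
   indentation depth) store the profile curvature at the nodule position —
   the calibration library;
2. a measured curvature at one indentation depth is inverted, depth by
   depth, along the (monotone) diameter axis, yielding a depth-diameter
   curve of all (depth, diameter) pairs consistent with that measurement;
3. curves from different indentation depths respond differently to size
   and depth, so they intersect (nearly) at the true (depth, diameter);
   when noise prevents an exact intersection the closest-approach point in
   span-normalized coordinates is taken, and near-optimal candidates are
   reported alongside.

The equivalent radius converts an irregular nodule's volume (or area, in
2D) to the radius of the sphere (circle) of the same content.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq, minimize

from .fem import (
    ForceProfile,
    IndentationProtocol,
    TissueDomain,
    build_mesh,
    sweep,
)
from .geometry import NoduleSpec, make_nodule
from .materials import material_to_yaml
from .profiles import second_derivative

__all__ = [
    "CalibrationLibrary",
    "DepthDiameterCurve",
    "QuantificationResult",
    "EmptyCurveError",
    "InconsistentMeasurementsError",
    "build_library",
    "invert_to_curve",
    "intersect_curves",
    "equivalent_radius",
    "equivalent_radius_2d",
    "percent_error",
    "quantification_errors",
    "ambiguity_envelope",
    "AmbiguityEnvelope",
]


class EmptyCurveError(RuntimeError):
    """Measured curvature outside the calibrated envelope at every depth."""


class InconsistentMeasurementsError(RuntimeError):
    """No candidate intersection point fits all curves within the ceiling."""


@dataclass(frozen=True)
class CalibrationLibrary:
    """Grid of force-profile curvature values at the nodule position.

    ``values[i, j, k]`` is the second derivative for indentation depth
    ``indentation_depths[i]``, nodule (center) depth ``depths[j]`` and
    nodule diameter ``diameters[k]``.
    """

    diameters: np.ndarray
    depths: np.ndarray
    indentation_depths: np.ndarray
    values: np.ndarray
    provenance: Mapping = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        dia = np.asarray(self.diameters, dtype=float)
        dep = np.asarray(self.depths, dtype=float)
        ind = np.asarray(self.indentation_depths, dtype=float)
        val = np.asarray(self.values, dtype=float)
        for name, a in (("diameters", dia), ("depths", dep), ("indentation_depths", ind)):
            if a.ndim != 1 or len(a) == 0 or np.any(np.diff(a) <= 0):
                raise ValueError(f"{name} must be a non-empty ascending 1D grid")
        if val.shape != (len(ind), len(dep), len(dia)):
            raise ValueError(
                f"values shape {val.shape} does not match grids "
                f"({len(ind)}, {len(dep)}, {len(dia)})"
            )
        if not np.all(np.isfinite(val)):
            raise ValueError("library values must be finite")
        object.__setattr__(self, "diameters", dia)
        object.__setattr__(self, "depths", dep)
        object.__setattr__(self, "indentation_depths", ind)
        object.__setattr__(self, "values", val)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "diameters_mm": self.diameters.tolist(),
            "depths_mm": self.depths.tolist(),
            "indentation_depths_mm": self.indentation_depths.tolist(),
            "values": self.values.tolist(),
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "CalibrationLibrary":
        return cls(
            diameters=np.asarray(doc["diameters_mm"]),
            depths=np.asarray(doc["depths_mm"]),
            indentation_depths=np.asarray(doc["indentation_depths_mm"]),
            values=np.asarray(doc["values"]),
            provenance=doc.get("provenance", {}),
        )


@dataclass(frozen=True)
class DepthDiameterCurve:
    """Locus of (nodule depth, diameter) pairs consistent with one measured
    curvature at one indentation depth; points sorted by depth."""

    indentation_depth: float
    points: np.ndarray  # (n, 2): [depth_mm, diameter_mm]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(pts) > 1 and np.any(np.diff(pts[:, 0]) <= 0):
            raise ValueError("curve points must be sorted by strictly ascending depth")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class QuantificationResult:
    """Chosen (depth, diameter) with ranked candidates and derived sizes."""

    candidates: tuple  # of (depth_mm, diameter_mm, residual)
    chosen: tuple  # (depth_mm, diameter_mm)
    equivalent_radius: float
    area: float
    errors: Mapping | None = None

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError("at least one candidate required")
        res = [c[2] for c in self.candidates]
        if min(res) != self.candidates[0][2]:
            raise ValueError("candidates must be sorted by residual")
        if any(r < 0 for r in res):
            raise ValueError("residuals must be non-negative")
        if self.equivalent_radius <= 0:
            raise ValueError("equivalent radius must be positive")

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "chosen_depth_mm": self.chosen[0],
            "chosen_diameter_mm": self.chosen[1],
            "equivalent_radius_mm": self.equivalent_radius,
            "area_mm2": self.area,
            "candidates": [list(c) for c in self.candidates],
            "errors": dict(self.errors) if self.errors else None,
        }


def equivalent_radius(volume: float) -> float:
    """Radius (mm) of the sphere with the given volume: (3V/4pi)^(1/3)."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    return (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)


def equivalent_radius_2d(area: float) -> float:
    """Radius (mm) of the circle with the given area: sqrt(A/pi)."""
    if area <= 0:
        raise ValueError("area must be positive")
    return math.sqrt(area / math.pi)


def _material_hash(materials: Mapping) -> str:
    text = "".join(material_to_yaml(materials[k]) for k in sorted(materials))
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _symmetric_half(positions: np.ndarray, center: float):
    """Indices of the unique half of a position grid symmetric about
    ``center``, or None when the grid is not symmetric."""
    mirrored = np.sort(2.0 * center - positions)
    if not np.allclose(mirrored, positions, atol=1e-9):
        return None
    half = np.where(positions <= center + 1e-9)[0]
    return half


def _sweep_symmetric(mesh, materials, protocol, center, **solver_kwargs):
    """Sweep exploiting mirror symmetry about ``center`` when available."""
    positions = np.asarray(protocol.positions)
    half = _symmetric_half(positions, center)
    if half is None:
        return sweep(mesh, materials, protocol, **solver_kwargs)
    half_prot = IndentationProtocol(
        positions=tuple(positions[half]),
        depths=protocol.depths,
        indenter_radius=protocol.indenter_radius,
        increments=protocol.increments,
    )
    half_profiles = sweep(mesh, materials, half_prot, **solver_kwargs)
    profiles = []
    for hp in half_profiles:
        forces = np.empty(len(positions))
        forces[half] = hp.forces
        mirror_idx = len(positions) - 1 - half
        forces[mirror_idx] = hp.forces
        profiles.append(
            ForceProfile(
                indentation_depth=hp.indentation_depth,
                positions=positions,
                forces=forces,
                source=hp.source,
            )
        )
    return profiles


def build_library(
    domain: TissueDomain,
    materials: Mapping,
    protocol: IndentationProtocol,
    diameters: Sequence[float],
    depths: Sequence[float],
    nodule_x: float | None = None,
    smoothing="auto",
    progress: bool = False,
    **solver_kwargs,
) -> CalibrationLibrary:
    """Run forward models over the (depth x diameter) grid and tabulate the
    profile curvature at the nodule position for every indentation depth.

    Library nodules are circles centered at ``nodule_x`` (default: the
    domain midline); ``depths`` refer to the circle center.  The probe-
    position grid is mirrored about the nodule when symmetric, halving the
    number of forward solves.
    """
    diameters = np.asarray(sorted(float(d) for d in diameters))
    depths_grid = np.asarray(sorted(float(d) for d in depths))
    if nodule_x is None:
        nodule_x = 0.5 * domain.width
    values = np.empty((len(protocol.depths), len(depths_grid), len(diameters)))
    for j, dep in enumerate(depths_grid):
        for k, dia in enumerate(diameters):
            spec = NoduleSpec(shape="circle", diameter=dia, depth=dep, center_x=nodule_x)
            mesh = build_mesh(domain, spec)
            profiles = _sweep_symmetric(
                mesh, materials, protocol, nodule_x, **solver_kwargs
            )
            for i, prof in enumerate(profiles):
                values[i, j, k] = second_derivative(prof, at=nodule_x, smoothing=smoothing)
            if progress:
                print(f"library: depth {dep} mm, diameter {dia} mm done")
    provenance = {
        "mesh_size_mm": domain.mesh_size,
        "material_hash": _material_hash(materials),
        "positions_mm": list(protocol.positions),
        "nodule_x_mm": nodule_x,
        "smoothing": str(smoothing),
    }
    return CalibrationLibrary(
        diameters=diameters,
        depths=depths_grid,
        indentation_depths=np.asarray(protocol.depths),
        values=values,
        provenance=provenance,
    )


def invert_to_curve(
    lib: CalibrationLibrary, measured_d2: float, indentation_depth: float
) -> DepthDiameterCurve:
    """Invert one measured curvature into a depth-diameter curve.

    For each tabulated nodule depth the diameter whose library value equals
    ``measured_d2`` is found by monotone (shape-preserving PCHIP)
    interpolation along the diameter axis; depths where the measured value
    is out of range are omitted.  Raises :class:`EmptyCurveError` when no
    depth brackets the measurement.
    """
    match = np.where(np.abs(lib.indentation_depths - indentation_depth) < 1e-9)[0]
    if len(match) == 0:
        raise ValueError(
            f"indentation depth {indentation_depth} mm not in library "
            f"({lib.indentation_depths.tolist()})"
        )
    i = int(match[0])
    pts = []
    for j, dep in enumerate(lib.depths):
        row = lib.values[i, j]
        lo, hi = row.min(), row.max()
        if not (lo <= measured_d2 <= hi):
            continue
        steps = np.diff(row)
        if np.all(steps > 0) or np.all(steps < 0):
            interp = PchipInterpolator(lib.diameters, row)
            f = lambda d: float(interp(d)) - measured_d2
            if f(lib.diameters[0]) == 0.0:
                dia = float(lib.diameters[0])
            elif f(lib.diameters[-1]) == 0.0:
                dia = float(lib.diameters[-1])
            else:
                dia = float(brentq(f, lib.diameters[0], lib.diameters[-1]))
        else:
            # non-monotone row (numerical noise): fall back to linear
            # interpolation on the sorted branch closest to the measurement
            order = np.argsort(row)
            dia = float(np.interp(measured_d2, row[order], lib.diameters[order]))
        pts.append((float(dep), dia))
    if not pts:
        raise EmptyCurveError(
            f"measured d2 {measured_d2:.4e} outside the calibrated envelope "
            f"at indentation depth {indentation_depth} mm"
        )
    pts.sort()
    return DepthDiameterCurve(indentation_depth=indentation_depth, points=np.array(pts))


def _point_polyline_dist2(p: np.ndarray, poly: np.ndarray) -> float:
    """Squared distance from point to polyline (both in normalized coords)."""
    if len(poly) == 1:
        d = p - poly[0]
        return float(d @ d)
    a = poly[:-1]
    b = poly[1:]
    ab = b - a
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / np.einsum("ij,ij->i", ab, ab), 0, 1)
    proj = a + t[:, None] * ab
    d2 = np.sum((p - proj) ** 2, axis=1)
    return float(d2.min())


def intersect_curves(
    curves: Sequence[DepthDiameterCurve],
    residual_ceiling: float = 0.5,
    candidate_window: float = 0.10,
) -> QuantificationResult:
    """Find the (depth, diameter) most consistent with all curves.

    Curves are joined linearly between tabulated depths; candidate points
    minimize the sum of squared distances to every curve in coordinates
    normalized by the depth and diameter spans (so both contribute
    comparably).  All local minima within ``candidate_window`` relative
    residual of the best are reported (measurements frequently admit two
    near-solutions); the minimal-residual candidate is chosen.
    """
    if len(curves) < 2:
        raise ValueError("at least two depth-diameter curves are required")
    for c in curves:
        if len(c) == 0:
            raise EmptyCurveError(
                f"empty curve at indentation depth {c.indentation_depth} mm"
            )
    all_pts = np.vstack([c.points for c in curves])
    lo = all_pts.min(axis=0)
    hi = all_pts.max(axis=0)
    span = np.where(hi - lo > 1e-12, hi - lo, 1.0)
    polys = [(c.points - lo) / span for c in curves]

    def objective(p):
        return sum(_point_polyline_dist2(p, poly) for poly in polys)

    n = 121
    gx, gy = np.meshgrid(np.linspace(-0.05, 1.05, n), np.linspace(-0.05, 1.05, n))
    grid = np.c_[gx.ravel(), gy.ravel()]
    vals = np.array([objective(p) for p in grid]).reshape(n, n)
    # local minima of the sampled objective (8-neighborhood)
    pad = np.pad(vals, 1, constant_values=np.inf)
    neigh = np.stack(
        [pad[1 + di : n + 1 + di, 1 + dj : n + 1 + dj]
         for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    )
    is_min = vals <= neigh.min(axis=0)
    cand_idx = np.argsort(vals[is_min])
    starts = grid[is_min.ravel()][cand_idx][:8]
    refined = []
    for s in starts:
        r = minimize(objective, s, method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 400})
        refined.append((float(r.fun), r.x))
    refined.sort(key=lambda t: t[0])
    dedup: list[tuple[float, np.ndarray]] = []
    for fv, x in refined:
        if all(np.linalg.norm(x - x0) > 1e-3 for _f, x0 in dedup):
            dedup.append((fv, x))
    best = dedup[0][0]
    if best > residual_ceiling:
        raise InconsistentMeasurementsError(
            f"best residual {best:.4f} exceeds ceiling {residual_ceiling}"
        )
    window = best * (1.0 + candidate_window) + 1e-12
    cands = []
    for fv, x in dedup:
        if fv <= window or fv == best:
            depth, dia = x * span + lo
            cands.append((float(depth), float(dia), float(fv)))
    chosen = (cands[0][0], cands[0][1])
    radius = 0.5 * chosen[1]
    return QuantificationResult(
        candidates=tuple(cands),
        chosen=chosen,
        equivalent_radius=radius,
        area=math.pi * radius**2,
    )


def percent_error(predicted: float, true: float) -> float:
    """Relative error |predicted - true| / true in percent."""
    if true == 0:
        raise ValueError("true value must be nonzero")
    return abs(predicted - true) / abs(true) * 100.0


def quantification_errors(
    result: QuantificationResult, truth: NoduleSpec
) -> tuple[float, float, float]:
    """Relative errors (%) of the prediction vs a ground-truth nodule:
    (equivalent-radius error, depth error, area error), each
    |predicted - true| / true * 100."""
    geom = make_nodule(truth)
    true_area = geom.area
    true_radius = equivalent_radius_2d(true_area)
    true_depth = truth.center_depth
    if true_radius <= 0 or true_depth <= 0 or true_area <= 0:
        raise ValueError("ground truth has zero size or depth")
    size_err = percent_error(result.equivalent_radius, true_radius)
    depth_err = percent_error(result.chosen[0], true_depth)
    area_err = percent_error(result.area, true_area)
    return size_err, depth_err, area_err


@dataclass(frozen=True)
class AmbiguityEnvelope:
    """Maximum force feedback per (nodule depth, size) at one indentation
    depth, with the pairs that are indistinguishable within tolerance."""

    table: pd.DataFrame  # columns: depth_mm, size_mm, max_force
    near_pairs: tuple  # of ((depth, size), (depth, size), rel_diff)
    indentation_depth: float


def ambiguity_envelope(
    domain: TissueDomain,
    materials: Mapping,
    protocol: IndentationProtocol,
    depth_grid: Sequence[float],
    size_grid: Sequence[float],
    near_tolerance: float = 0.01,
    nodule_x: float | None = None,
    **solver_kwargs,
) -> AmbiguityEnvelope:
    """Demonstrate the single-depth size/depth ambiguity.

    For every (nodule depth, nodule diameter) combination — size 0 denotes
    the homogeneous block — the maximum force over the probe positions is
    recorded at the protocol's single indentation depth.  Pairs of distinct
    combinations whose maxima differ by less than ``near_tolerance``
    (relative) are reported: those are indistinguishable from a
    single-depth palpation.
    """
    if len(protocol.depths) != 1:
        raise ValueError("ambiguity envelope is defined for a single indentation depth")
    if nodule_x is None:
        nodule_x = 0.5 * domain.width
    rows = []
    for dep in depth_grid:
        for size in size_grid:
            if size == 0:
                mesh = build_mesh(domain, None)
            else:
                spec = NoduleSpec(
                    shape="circle", diameter=size, depth=dep, center_x=nodule_x
                )
                mesh = build_mesh(domain, spec)
            profiles = _sweep_symmetric(
                mesh, materials, protocol, nodule_x, **solver_kwargs
            )
            rows.append(
                {
                    "depth_mm": float(dep),
                    "size_mm": float(size),
                    "max_force": float(profiles[0].forces.max()),
                }
            )
    table = pd.DataFrame(rows)
    pairs = []
    for a in range(len(rows)):
        for b in range(a + 1, len(rows)):
            fa, fb = rows[a]["max_force"], rows[b]["max_force"]
            rel = abs(fa - fb) / max(fa, fb)
            if rel < near_tolerance:
                pairs.append(
                    (
                        (rows[a]["depth_mm"], rows[a]["size_mm"]),
                        (rows[b]["depth_mm"], rows[b]["size_mm"]),
                        rel,
                    )
                )
    return AmbiguityEnvelope(
        table=table, near_pairs=tuple(pairs), indentation_depth=protocol.depths[0]
    )
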