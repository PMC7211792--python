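"""Parametric nodule geometries in a 2D tissue section.

Coordinate convention (package-wide): x runs along the palpated top surface
in [0, width]; y is positive *downward* from the top surface, so the "depth"
of a feature is its y-coordinate.  All lengths in mm.

A nodule is described by a :class:`NoduleSpec` and realized by
:func:`make_nodule` as one or more shapely polygons, each carrying a
"cancer fraction": 1.0 for fully cancerous regions and an intermediate value
for diffuse-interface shells where healthy and cancerous tissue are mixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union

__all__ = ["NoduleSpec", "NoduleGeometry", "make_nodule", "circle_union_area"]

_SHAPES = {
    "circle",
    "intersecting_circles",
    "polygon",
    "diffuse_annulus",
    "rectangle",
    "none",
}

#: Fixed irregular-polygon stand-in (synthetic, ~15 mm extent) used for the
#: "arbitrary shape" nodule scenario; vertices in mm relative to the nodule
#: reference point, y positive downward.
ARBITRARY_POLYGON_XY: tuple[tuple[float, float], ...] = (
    (-7.5, 0.0),
    (-5.0, -5.5),
    (-1.0, -7.0),
    (4.0, -5.0),
    (7.5, -1.0),
    (6.0, 4.0),
    (2.0, 7.0),
    (-3.0, 6.0),
    (-6.5, 3.0),
)


@dataclass(frozen=True)
class NoduleSpec:
    """Declarative description of an embedded nodule.

    ``depth`` is measured to the nodule center (``depth_reference ==
    "center"``) or to its top face (``"top"``); ``center_x`` is the lateral
    position of the nodule reference point.
    """

    shape: str
    depth: float = 0.0
    center_x: float = 0.0
    depth_reference: str = "center"
    diameter: float | None = None  # circle / diffuse_annulus inner
    diameters: tuple[float, float] | None = None  # intersecting_circles
    offset: float | None = None  # intersecting_circles center spacing
    outer_diameter: float | None = None  # diffuse_annulus shell
    width: float | None = None  # rectangle
    height: float | None = None  # rectangle
    vertices: tuple[tuple[float, float], ...] | None = None  # polygon
    mixture_fraction: float = 0.5  # diffuse shell cancer fraction

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown nodule shape {self.shape!r}")
        if self.depth_reference not in ("center", "top"):
            raise ValueError("depth_reference must be 'center' or 'top'")
        if self.shape == "none":
            return
        if self.depth <= 0.0:
            raise ValueError("nodule depth must be positive")
        if self.shape == "circle" and not (self.diameter and self.diameter > 0):
            raise ValueError("circle requires a positive diameter")
        if self.shape == "intersecting_circles":
            if not self.diameters or len(self.diameters) != 2:
                raise ValueError("intersecting_circles requires two diameters")
            if any(d <= 0 for d in self.diameters):
                raise ValueError("diameters must be positive")
        if self.shape == "diffuse_annulus":
            if not (self.diameter and self.outer_diameter):
                raise ValueError("diffuse_annulus requires inner and outer diameters")
            if not 0 < self.diameter < self.outer_diameter:
                raise ValueError("need 0 < inner diameter < outer diameter")
        if self.shape == "rectangle":
            if not (self.width and self.height and self.width > 0 and self.height > 0):
                raise ValueError("rectangle requires positive width and height")
        if self.shape == "polygon" and (
            self.vertices is None or len(self.vertices) < 3
        ):
            raise ValueError("polygon requires >= 3 vertices")

    @property
    def extent(self) -> float:
        """Characteristic vertical size (mm), used for depth conversions."""
        if self.shape == "circle":
            return self.diameter
        if self.shape == "intersecting_circles":
            return max(self.diameters)
        if self.shape == "diffuse_annulus":
            return self.outer_diameter
        if self.shape == "rectangle":
            return self.height
        if self.shape == "polygon":
            ys = [v[1] for v in self.vertices]
            return max(ys) - min(ys)
        return 0.0

    @property
    def center_depth(self) -> float:
        """Depth of the nodule center, converting from a top-face reference
        via depth_center = depth_top + extent/2 when needed."""
        if self.depth_reference == "center":
            return self.depth
        return self.depth + 0.5 * self.extent


@dataclass(frozen=True)
class NoduleGeometry:
    """Realized nodule: disjoint regions with cancer fractions.

    ``area`` is the area (mm^2) of the union of all regions; ``regions``
    holds ``(polygon, cancer_fraction)`` pairs with fractions in (0, 1].
    """

    regions: tuple[tuple[Polygon, float], ...]
    area: float
    spec: NoduleSpec = field(compare=False)

    @property
    def union(self) -> Polygon:
        return unary_union([p for p, _ in self.regions])


def _circle(cx: float, cy: float, r: float, n: int) -> Polygon:
    t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    return Polygon(np.c_[cx + r * np.cos(t), cy + r * np.sin(t)])


def make_nodule(spec: NoduleSpec, angular_resolution: int = 256) -> NoduleGeometry:
    """Realize a nodule spec as polygonal regions with cancer fractions.

    Circles are discretized with ``angular_resolution`` vertices (area error
    well below 0.5% at the default).  Raises on self-intersecting polygon
    input and on the shape "none" (which has no geometry).
    """
    if spec.shape == "none":
        raise ValueError("shape 'none' has no geometry")
    cx, cy = spec.center_x, spec.center_depth
    n = angular_resolution
    if spec.shape == "circle":
        poly = _circle(cx, cy, 0.5 * spec.diameter, n)
        regions = ((poly, 1.0),)
    elif spec.shape == "intersecting_circles":
        r1, r2 = (0.5 * d for d in spec.diameters)
        off = spec.offset if spec.offset is not None else 0.5 * (r1 + r2)
        c1 = _circle(cx - 0.5 * off, cy, r1, n)
        c2 = _circle(cx + 0.5 * off, cy, r2, n)
        regions = ((unary_union([c1, c2]), 1.0),)
    elif spec.shape == "rectangle":
        w, h = spec.width, spec.height
        regions = (
            (box(cx - 0.5 * w, cy - 0.5 * h, cx + 0.5 * w, cy + 0.5 * h), 1.0),
        )
    elif spec.shape == "polygon":
        pts = [(cx + vx, cy + vy) for vx, vy in spec.vertices]
        poly = Polygon(pts)
        if not poly.is_valid:
            raise ValueError("self-intersecting polygon")
        regions = ((poly, 1.0),)
    elif spec.shape == "diffuse_annulus":
        inner = _circle(cx, cy, 0.5 * spec.diameter, n)
        outer = _circle(cx, cy, 0.5 * spec.outer_diameter, n)
        shell = outer.difference(inner)
        regions = ((inner, 1.0), (shell, spec.mixture_fraction))
    else:  # pragma: no cover
        raise ValueError(spec.shape)
    area = float(unary_union([p for p, _ in regions]).area)
    return NoduleGeometry(regions=regions, area=area, spec=spec)


def circle_union_area(r1: float, r2: float, center_distance: float) -> float:
    """Analytic area of the union of two circles (lens-subtraction formula)."""
    if r1 <= 0 or r2 <= 0 or center_distance < 0:
        raise ValueError("radii must be positive and distance non-negative")
    d = center_distance
    a1, a2 = math.pi * r1 * r1, math.pi * r2 * r2
    if d >= r1 + r2:
        return a1 + a2
    if d <= abs(r1 - r2):
        return max(a1, a2)
    alpha = 2.0 * math.acos((d * d + r1 * r1 - r2 * r2) / (2.0 * d * r1))
    beta = 2.0 * math.acos((d * d + r2 * r2 - r1 * r1) / (2.0 * d * r2))
    lens = 0.5 * r1 * r1 * (alpha - math.sin(alpha)) + 0.5 * r2 * r2 * (
        beta - math.sin(beta)
    )
    return a1 + a2 - lens


def require_inside(geom: NoduleGeometry, width: float, height: float, margin: float = 1e-9) -> None:
    """Raise if the nodule is not strictly inside the tissue domain."""
    minx, miny, maxx, maxy = geom.union.bounds
    if minx <= margin or miny <= margin or maxx >= width - margin or maxy >= height - margin:
        raise ValueError(
            "nodule intersects the domain boundary: "
            f"bounds=({minx:.3f},{miny:.3f},{maxx:.3f},{maxy:.3f}), "
            f"domain={width}x{height} mm"
        )
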