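"""2D plane-strain hyperelastic finite elements for instrumented palpation.

The forward model is a quasi-static, displacement-controlled, frictionless
rigid-indenter indentation of a rectangular soft block with an embedded
stiffer nodule, solved in a total-Lagrangian setting:

* geometry: rectangle [0, width] x [0, height], x along the palpated top
  surface, y positive downward; the bottom edge is fully fixed (sample on a
  rigid platform), lateral edges traction-free;
* discretization: structured grid of quadrilateral cells, each split into
  four linear triangles through the cell center ("crossed" pattern, which
  behaves well under near-incompressibility); element-wise material
  blending by the local cancer area fraction;
* material: Ogden strain energy on the isochoric principal stretches with
  a volumetric penalty kappa/2 (J-1)^2, kappa = kappa_ratio * mu0, which
  enforces near-incompressibility;
* contact: the indenter is the circular cross-section (radius R) of the
  spherical-tipped probe.  Default mode "prescribed" drives the surface
  nodes inside the geometric overlap onto the indenter arc (vertical dof
  prescribed, horizontal free = frictionless); mode "penalty" applies
  frictionless normal penalty forces against the analytic rigid circle;
* solution: incremental loading with Newton iteration (finite-difference
  consistent tangent, LU reuse while convergence is fast, automatic
  substepping on failure); forces are reported per unit out-of-plane
  thickness (N/mm).

Each probe point is solved from the undeformed configuration: indentations
are independent, emulating an experimental protocol with full relaxation
between probings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from shapely.geometry import Polygon

from .geometry import NoduleGeometry, NoduleSpec, make_nodule, require_inside
from .materials import NeoHookeanMaterial, OgdenMaterial

__all__ = [
    "TissueDomain",
    "IndentationProtocol",
    "ForceProfile",
    "Mesh",
    "IndentResult",
    "IndentError",
    "build_mesh",
    "indent_once",
    "sweep",
    "linear_elastic_force",
]

LABEL_HEALTHY, LABEL_INTERFACE, LABEL_CANCER = 0, 1, 2


@dataclass(frozen=True)
class TissueDomain:
    """Rectangular 2D tissue section (mm).

    ``mesh_size`` is the target element edge length at the top surface;
    ``grading`` > 1 coarsens the rows geometrically toward the bottom,
    concentrating resolution near the indented surface and the nodule.
    """

    width: float
    height: float
    mesh_size: float = 2.5
    grading: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("domain dimensions must be positive")
        if self.mesh_size <= 0:
            raise ValueError("mesh_size must be positive")
        if self.grading < 1.0:
            raise ValueError("grading must be >= 1")


@dataclass(frozen=True)
class IndentationProtocol:
    """Displacement-controlled palpation protocol.

    ``increments`` is the number of quasi-static load steps used at the
    largest indentation depth; shallower depths use proportionally fewer
    (minimum 2), and the solver substeps automatically if an increment
    fails to converge.
    """

    positions: tuple[float, ...]
    depths: tuple[float, ...]
    indenter_radius: float = 5.0
    increments: int = 10

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", tuple(float(p) for p in self.positions))
        object.__setattr__(self, "depths", tuple(float(d) for d in self.depths))
        if self.indenter_radius <= 0:
            raise ValueError("indenter_radius must be positive")
        if not self.depths or any(d <= 0 for d in self.depths):
            raise ValueError("depths must be strictly positive")
        if list(self.depths) != sorted(self.depths) or len(set(self.depths)) != len(self.depths):
            raise ValueError("depths must be strictly ascending")
        if self.increments < 1:
            raise ValueError("increments must be >= 1")

    def steps_for(self, depth: float) -> int:
        return max(2, math.ceil(self.increments * depth / max(self.depths)))


@dataclass(frozen=True)
class ForceProfile:
    """Force-vs-position sweep at one indentation depth (N per mm
    out-of-plane thickness)."""

    indentation_depth: float
    positions: np.ndarray
    forces: np.ndarray
    source: str = "simulated"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        frc = np.asarray(self.forces, dtype=float)
        if pos.shape != frc.shape or pos.ndim != 1:
            raise ValueError("positions and forces must be 1D arrays of equal length")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly ascending")
        if np.any(frc < -1e-9):
            raise ValueError("forces must be non-negative")
        frc = np.clip(frc, 0.0, None)
        if self.source not in ("simulated", "measured", "synthetic"):
            raise ValueError("source must be simulated|measured|synthetic")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "forces", frc)

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class Mesh:
    """Conforming triangular mesh with per-element material data."""

    nodes: np.ndarray  # (nn, 2) reference coordinates, y down
    tris: np.ndarray  # (ne, 3) node indices
    area: np.ndarray  # (ne,)
    grads: np.ndarray  # (ne, 3, 2) shape-function gradients
    labels: np.ndarray  # (ne,) LABEL_*
    cancer_fraction: np.ndarray  # (ne,) effective cancer fraction in [0,1]
    region_coverage: np.ndarray  # (ne, nregions) area coverage per region
    region_fractions: tuple[float, ...]  # cancer fraction of each region
    domain: TissueDomain
    nodule: NoduleSpec | None
    top_nodes: np.ndarray = field(init=False)
    bottom_nodes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        y = self.nodes[:, 1]
        self.top_nodes = np.where(np.abs(y) < 1e-9)[0]
        self.bottom_nodes = np.where(np.abs(y - self.domain.height) < 1e-9)[0]
        if np.any(self.area <= 0):
            raise ValueError("mesh contains degenerate or inverted elements")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tris)

    @property
    def cancer_area(self) -> float:
        """Cancer-fraction-weighted area (mm^2)."""
        return float(np.sum(self.cancer_fraction * self.area))

    @property
    def region_areas(self) -> np.ndarray:
        """Mesh-resolved area of each nodule region (mm^2)."""
        return np.asarray(self.region_coverage.T @ self.area)

    def to_text(self) -> str:
        """Export in a simple unstructured-mesh text format (OFF-like)."""
        lines = [f"{self.n_nodes} {self.n_elements}"]
        for x, y in self.nodes:
            lines.append(f"{x:.9g} {y:.9g}")
        for (a, b, c), lab in zip(self.tris, self.labels):
            lines.append(f"{a} {b} {c} {lab}")
        return "\n".join(lines) + "\n"


def _axis_coords(length: float, h: float, grading: float) -> np.ndarray:
    n = max(3, round(length / h))
    if grading <= 1.0 + 1e-12:
        return np.linspace(0.0, length, n + 1)
    # geometric spacings, ratio grading between last and first row height
    r = grading ** (1.0 / (n - 1))
    w = r ** np.arange(n)
    w = w / w.sum() * length
    return np.concatenate([[0.0], np.cumsum(w)])


def build_mesh(
    domain: TissueDomain,
    nodule: NoduleSpec | None = None,
    angular_resolution: int = 256,
) -> Mesh:
    """Build a crossed-triangle mesh of the domain with material labels.

    Elements are classified as healthy / cancerous / interface-mixture from
    the exact (shapely-clipped) overlap of each triangle with the nodule
    regions, so the labeled cancer area matches the nodule area to the
    accuracy of the circle discretization.
    """
    xs = _axis_coords(domain.width, domain.mesh_size, 1.0)
    ys = _axis_coords(domain.height, domain.mesh_size, domain.grading)
    ncx, ncy = len(xs) - 1, len(ys) - 1
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    grid_nodes = np.c_[gx.ravel(), gy.ravel()]  # row-major: j*(ncx+1)+i
    nid = lambda i, j: j * (ncx + 1) + i
    centers = []
    tris = []
    cid0 = len(grid_nodes)
    for j in range(ncy):
        for i in range(ncx):
            n00, n10 = nid(i, j), nid(i + 1, j)
            n01, n11 = nid(i, j + 1), nid(i + 1, j + 1)
            c = cid0 + j * ncx + i
            centers.append(
                [0.5 * (xs[i] + xs[i + 1]), 0.5 * (ys[j] + ys[j + 1])]
            )
            tris += [[n00, n10, c], [n10, n11, c], [n11, n01, c], [n01, n00, c]]
    nodes = np.vstack([grid_nodes, np.array(centers)])
    tris = np.asarray(tris, dtype=np.int64)

    p = nodes[tris]  # (ne,3,2)
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    det = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    flip = det < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    p = nodes[tris]
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    det = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    area = 0.5 * det
    # linear shape-function gradients
    grads = np.empty((len(tris), 3, 2))
    grads[:, 1, 0] = e2[:, 1] / det
    grads[:, 1, 1] = -e2[:, 0] / det
    grads[:, 2, 0] = -e1[:, 1] / det
    grads[:, 2, 1] = e1[:, 0] / det
    grads[:, 0] = -grads[:, 1] - grads[:, 2]

    ne = len(tris)
    if nodule is None or nodule.shape == "none":
        labels = np.full(ne, LABEL_HEALTHY, dtype=np.int8)
        mesh = Mesh(
            nodes, tris, area, grads, labels,
            np.zeros(ne), np.zeros((ne, 0)), (), domain, None,
        )
        return mesh

    geom = make_nodule(nodule, angular_resolution=angular_resolution)
    require_inside(geom, domain.width, domain.height)
    coverage = np.zeros((ne, len(geom.regions)))
    cent = p.mean(axis=1)
    for k, (poly, _frac) in enumerate(geom.regions):
        minx, miny, maxx, maxy = poly.bounds
        diag = math.hypot(domain.mesh_size, domain.mesh_size)
        cand = np.where(
            (cent[:, 0] > minx - diag)
            & (cent[:, 0] < maxx + diag)
            & (cent[:, 1] > miny - diag)
            & (cent[:, 1] < maxy + diag)
        )[0]
        for e in cand:
            tri_poly = Polygon(p[e])
            inter = tri_poly.intersection(poly)
            if not inter.is_empty:
                coverage[e, k] = inter.area / area[e]
    fracs = tuple(f for _p, f in geom.regions)
    cov_total = coverage.sum(axis=1)
    phi = coverage @ np.asarray(fracs)
    labels = np.full(ne, LABEL_HEALTHY, dtype=np.int8)
    inside = cov_total > 1e-3
    labels[inside] = LABEL_INTERFACE
    pure = (cov_total > 0.999) & (phi > 0.999)
    labels[pure] = LABEL_CANCER
    return Mesh(nodes, tris, area, grads, labels, phi, coverage, fracs, domain, nodule)


# ---------------------------------------------------------------------------
# hyperelastic solver
# ---------------------------------------------------------------------------


class IndentError(RuntimeError):
    """Newton/contact failure with increment trace."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


class _Inverted(RuntimeError):
    pass


def _as_ogden(mat) -> OgdenMaterial:
    if isinstance(mat, NeoHookeanMaterial):
        return mat.as_ogden()
    if isinstance(mat, OgdenMaterial):
        return mat
    raise TypeError(f"unsupported material {type(mat)!r}")


class _System:
    """Assembled hyperelastic system on a mesh with blended materials."""

    def __init__(
        self,
        mesh: Mesh,
        materials: Mapping[str, OgdenMaterial | NeoHookeanMaterial],
        kappa_ratio: float = 1000.0,
    ):
        self.mesh = mesh
        healthy = _as_ogden(materials["healthy"])
        cancer = _as_ogden(materials.get("cancerous", healthy))
        phi = mesh.cancer_fraction[:, None]
        if healthy.alpha == cancer.alpha:
            self.alphas = np.asarray(healthy.alpha)
            self.mu = (1.0 - phi) * np.asarray(healthy.mu) + phi * np.asarray(cancer.mu)
        else:
            self.alphas = np.concatenate([healthy.alpha, cancer.alpha])
            self.mu = np.concatenate(
                [(1.0 - phi) * np.asarray(healthy.mu), phi * np.asarray(cancer.mu)],
                axis=1,
            )
        self.kappa = kappa_ratio * self.mu.sum(axis=1)
        self.ndof = 2 * mesh.n_nodes
        edof = np.empty((mesh.n_elements, 6), dtype=np.int64)
        edof[:, 0::2] = 2 * mesh.tris
        edof[:, 1::2] = 2 * mesh.tris + 1
        self.edof = edof
        self.rows = np.repeat(edof, 6, axis=1).ravel()
        self.cols = np.tile(edof, (1, 6)).ravel()

    # -- constitutive law ---------------------------------------------------
    def _piola(self, F: np.ndarray) -> np.ndarray:
        J = F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0]
        if np.any(J <= 0.0) or not np.all(np.isfinite(J)):
            raise _Inverted("element inversion (J <= 0)")
        c11 = F[:, 0, 0] ** 2 + F[:, 1, 0] ** 2
        c22 = F[:, 0, 1] ** 2 + F[:, 1, 1] ** 2
        c12 = F[:, 0, 0] * F[:, 0, 1] + F[:, 1, 0] * F[:, 1, 1]
        half = 0.5 * (c11 + c22)
        disc = np.sqrt(np.maximum((0.5 * (c11 - c22)) ** 2 + c12**2, 0.0))
        l1s = np.maximum(half + disc, 1e-12)
        l2s = np.maximum(half - disc, 1e-12)
        lam1, lam2 = np.sqrt(l1s), np.sqrt(l2s)
        jm13 = J ** (-1.0 / 3.0)
        lb1, lb2, lb3 = jm13 * lam1, jm13 * lam2, jm13
        dw1 = np.zeros_like(J)
        dw2 = np.zeros_like(J)
        for k, a in enumerate(self.alphas):
            g = 2.0 * self.mu[:, k] / a
            p1 = lb1 ** (a - 1.0)
            p2 = lb2 ** (a - 1.0)
            p3 = lb3 ** (a - 1.0)
            dw1 += g * jm13 * ((2.0 / 3.0) * p1 - (lam2 * p2 + p3) / (3.0 * lam1))
            dw2 += g * jm13 * ((2.0 / 3.0) * p2 - (lam1 * p1 + p3) / (3.0 * lam2))
        dvol = self.kappa * (J - 1.0) * J
        dw1 += dvol / lam1
        dw2 += dvol / lam2
        s1 = dw1 / lam1
        s2 = dw2 / lam2
        # isotropic representation S = a*I + b*C avoids eigenvectors
        denom = l1s - l2s
        safe = np.abs(denom) > 1e-10
        b = np.where(safe, (s1 - s2) / np.where(safe, denom, 1.0), 0.0)
        a_co = s1 - b * l1s
        S = np.empty_like(F)
        S[:, 0, 0] = a_co + b * c11
        S[:, 1, 1] = a_co + b * c22
        S[:, 0, 1] = S[:, 1, 0] = b * c12
        return F @ S

    def energy_density(self, F: np.ndarray) -> np.ndarray:
        J = F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0]
        c11 = F[:, 0, 0] ** 2 + F[:, 1, 0] ** 2
        c22 = F[:, 0, 1] ** 2 + F[:, 1, 1] ** 2
        c12 = F[:, 0, 0] * F[:, 0, 1] + F[:, 1, 0] * F[:, 1, 1]
        half = 0.5 * (c11 + c22)
        disc = np.sqrt(np.maximum((0.5 * (c11 - c22)) ** 2 + c12**2, 0.0))
        lam1 = np.sqrt(np.maximum(half + disc, 1e-12))
        lam2 = np.sqrt(np.maximum(half - disc, 1e-12))
        jm13 = J ** (-1.0 / 3.0)
        w = 0.5 * self.kappa * (J - 1.0) ** 2
        for k, a in enumerate(self.alphas):
            w += (2.0 * self.mu[:, k] / a**2) * (
                (jm13 * lam1) ** a + (jm13 * lam2) ** a + jm13**a - 3.0
            )
        return w

    # -- kinematics and assembly -------------------------------------------
    def deformation_gradient(self, u: np.ndarray) -> np.ndarray:
        ue = u.reshape(-1, 2)[self.mesh.tris]  # (ne,3,2)
        F = np.einsum("eai,eaJ->eiJ", ue, self.mesh.grads)
        F[:, 0, 0] += 1.0
        F[:, 1, 1] += 1.0
        return F

    def internal_forces(self, u: np.ndarray) -> np.ndarray:
        F = self.deformation_gradient(u)
        P = self._piola(F)
        contrib = np.einsum("e,eiJ,eaJ->eai", self.mesh.area, P, self.mesh.grads)
        f = np.zeros((self.mesh.n_nodes, 2))
        np.add.at(f, self.mesh.tris, contrib)
        return f.ravel()

    def stored_energy(self, u: np.ndarray) -> float:
        return float(np.sum(self.mesh.area * self.energy_density(self.deformation_gradient(u))))

    def tangent(self, u: np.ndarray) -> sp.csr_matrix:
        F = self.deformation_gradient(u)
        h = 1e-6
        A4 = np.empty((len(F), 2, 2, 2, 2))
        for k in range(2):
            for L in range(2):
                Fp = F.copy()
                Fp[:, k, L] += h
                Pp = self._piola(Fp)
                Fm = F.copy()
                Fm[:, k, L] -= h
                Pm = self._piola(Fm)
                A4[:, :, :, k, L] = (Pp - Pm) / (2.0 * h)
        Ke = np.einsum(
            "e,eaJ,eiJkL,ebL->eaibk", self.mesh.area, self.mesh.grads, A4, self.mesh.grads
        ).reshape(len(F), 6, 6)
        K = sp.coo_matrix(
            (Ke.ravel(), (self.rows, self.cols)), shape=(self.ndof, self.ndof)
        )
        return K.tocsr()


def _contact_nodes(mesh: Mesh, position: float, radius: float, delta: float):
    """Top-surface nodes inside the indenter overlap and their arc heights."""
    x = mesh.nodes[mesh.top_nodes, 0]
    dx = x - position
    with np.errstate(invalid="ignore"):
        sag = radius - np.sqrt(np.maximum(radius**2 - dx**2, 0.0))
    pen = delta - sag
    active = (np.abs(dx) < radius) & (pen > 1e-12)
    return mesh.top_nodes[active], pen[active]


@dataclass
class IndentResult:
    """Rich result of a single indentation solve."""

    force: float
    displacement: np.ndarray
    depth: float
    position: float
    force_history: list  # (delta, force) per top-level increment
    stored_energy: float
    external_work: float
    newton_iterations: int
    max_penetration: float = 0.0  # penalty mode diagnostic

    @property
    def horizontal_force(self) -> float:
        return getattr(self, "_fx", 0.0)


def _newton(system, u, free, tol_rel=1e-8, max_iter=40):
    """Newton with LU reuse; returns (u, iterations). Raises on divergence."""
    try:
        r = system.internal_forces(u)
    except _Inverted as exc:
        raise IndentError(str(exc))
    rf = r[free]
    ref = np.linalg.norm(rf)
    floor = 1e-12 * max(1.0, np.linalg.norm(r))
    if ref <= floor:
        return u, 0
    tol = max(tol_rel * ref, floor)
    lu = None
    prev = ref
    for it in range(1, max_iter + 1):
        if lu is None:
            K = system.tangent(u)[free][:, free].tocsc()
            lu = splu(K)
        du = lu.solve(-rf)
        # backtracking line search: the volumetric penalty makes the energy
        # landscape stiff and a full step can overshoot
        step = 1.0
        for _ in range(10):
            u_try = u.copy()
            u_try[free] += step * du
            try:
                r = system.internal_forces(u_try)
            except _Inverted:
                step *= 0.5
                continue
            rf_try = r[free]
            nrm = np.linalg.norm(rf_try)
            if np.isfinite(nrm) and (nrm < prev or step < 0.1):
                break
            step *= 0.5
        else:
            raise IndentError("line search failed (persistent element inversion)")
        u, rf = u_try, rf_try
        if not np.isfinite(nrm) or nrm > 1e4 * ref:
            raise IndentError(f"Newton divergence (|R| {nrm:.3e} vs {ref:.3e})")
        if nrm <= tol:
            return u, it
        if nrm > 0.33 * prev or step < 1.0:
            lu = None  # convergence slowed; refresh tangent
        prev = nrm
    raise IndentError(f"Newton did not converge in {max_iter} iterations")


def _solve_prescribed(system, mesh, position, radius, delta_seq, tol_rel):
    u = np.zeros(system.ndof)
    fixed_base = np.zeros(system.ndof, dtype=bool)
    fixed_base[2 * mesh.bottom_nodes] = True
    fixed_base[2 * mesh.bottom_nodes + 1] = True
    history = [(0.0, 0.0)]
    total_iters = 0

    active_nodes: set = set()  # converged contact set, carried across increments

    def solve_active_set(u, idx, pen, start):
        """Unilateral contact by active-set iteration on the prescribed
        nodes: release nodes whose reaction turns adhesive (negative),
        re-add overlap nodes that penetrate the indenter arc."""
        nonlocal total_iters, active_nodes
        if active_nodes:
            # warm-start from the previous increment's contact set plus any
            # overlap node currently inside the indenter
            active = np.array(
                [n in active_nodes or u[2 * n + 1] < p - 1e-12 for n, p in zip(idx, pen)]
            )
            if not active.any():
                active = np.ones(len(idx), dtype=bool)
        else:
            active = np.ones(len(idx), dtype=bool)
        for _ in range(12):
            fixed = fixed_base.copy()
            fixed[2 * idx[active] + 1] = True
            start = start.copy()
            start[2 * idx[active] + 1] = pen[active]
            unew, it = _newton(system, start, ~fixed, tol_rel=tol_rel)
            total_iters += it
            f = system.internal_forces(unew)
            reactions = f[2 * idx + 1]
            scale = max(1e-30, np.abs(reactions[active]).max(initial=0.0))
            release = active & (reactions < -1e-9 * scale)
            # inactive overlap nodes above the arc are penetrating
            penetrate = (~active) & (unew[2 * idx + 1] < pen - 1e-12)
            if not release.any() and not penetrate.any():
                active_nodes = set(idx[active].tolist())
                return unew
            active = (active & ~release) | penetrate
            if not active.any():
                active_nodes = set()
                return unew
            start = unew
        active_nodes = set(idx[active].tolist())
        return unew  # active set cycling; accept last converged state

    def advance(u, d_from, d_to, level=0, guess=None):
        idx, pen = _contact_nodes(mesh, position, radius, d_to)
        if len(idx) == 0:
            return u
        start = guess if guess is not None else u
        try:
            return solve_active_set(u, idx, pen, start)
        except IndentError:
            if guess is not None:
                return advance(u, d_from, d_to, level)  # retry unpredicted
            if level >= 6:
                raise IndentError(
                    f"increment to depth {d_to:.4f} mm failed after substepping",
                    trace=history,
                )
            mid = 0.5 * (d_from + d_to)
            u = advance(u, d_from, mid, level + 1)
            return advance(u, mid, d_to, level + 1)

    d_prev = 0.0
    u_prev = None  # converged state one increment back, for extrapolation
    dd_prev = 0.0
    for d in delta_seq:
        guess = None
        if u_prev is not None and dd_prev > 0:
            guess = u + (u - u_prev) * ((d - d_prev) / dd_prev)
        u_new = advance(u, d_prev, d, guess=guess)
        u_prev, dd_prev = u, d - d_prev
        u = u_new
        history.append((d, _indenter_force(system, mesh, position, radius, d, u)))
        d_prev = d
    return u, history, total_iters


def _indenter_force(system, mesh, position, radius, delta, u):
    idx, _pen = _contact_nodes(mesh, position, radius, delta)
    if len(idx) == 0:
        return 0.0
    f = system.internal_forces(u)
    return float(np.sum(f[2 * idx + 1]))


def _penalty_forces(mesh, u, position, radius, delta, k_pen):
    """Contact force vector and per-node data for penalty mode."""
    un = u.reshape(-1, 2)
    top = mesh.top_nodes
    xy = mesh.nodes[top] + un[top]
    center = np.array([position, delta - radius])
    d = xy - center
    dist = np.linalg.norm(d, axis=1)
    pen = radius - dist
    active = pen > 0.0
    idx = top[active]
    dhat = d[active] / dist[active][:, None]
    fvec = np.zeros_like(un)
    fvec[idx] = k_pen * pen[active][:, None] * dhat
    return fvec.ravel(), idx, pen[active], dhat, dist[active]


class _PenaltySystem:
    """Hyperelastic system augmented with penalty contact at one depth."""

    def __init__(self, system, mesh, position, radius, delta, k_pen):
        self.base = system
        self.mesh = mesh
        self.position = position
        self.radius = radius
        self.delta = delta
        self.k_pen = k_pen
        self.ndof = system.ndof

    def internal_forces(self, u):
        fc, *_ = _penalty_forces(
            self.mesh, u, self.position, self.radius, self.delta, self.k_pen
        )
        return self.base.internal_forces(u) - fc

    def tangent(self, u):
        K = self.base.tangent(u)
        _fc, idx, pen, dhat, dist = _penalty_forces(
            self.mesh, u, self.position, self.radius, self.delta, self.k_pen
        )
        if len(idx):
            blocks, rows, cols = [], [], []
            for j, n in enumerate(idx):
                dd = np.outer(dhat[j], dhat[j])
                kc = self.k_pen * dd - self.k_pen * pen[j] / dist[j] * (np.eye(2) - dd)
                blocks.append(kc.ravel())
                base = 2 * n
                rows += [base, base, base + 1, base + 1]
                cols += [base, base + 1, base, base + 1]
            K = K + sp.coo_matrix(
                (np.concatenate(blocks), (rows, cols)), shape=(self.ndof, self.ndof)
            ).tocsr()
        return K


def _solve_penalty(system, mesh, position, radius, delta_seq, tol_rel, k_pen):
    u = np.zeros(system.ndof)
    fixed = np.zeros(system.ndof, dtype=bool)
    fixed[2 * mesh.bottom_nodes] = True
    fixed[2 * mesh.bottom_nodes + 1] = True
    free = ~fixed
    history = [(0.0, 0.0)]
    total_iters = 0
    max_pen_frac = 0.0
    for d in delta_seq:
        psys = _PenaltySystem(system, mesh, position, radius, d, k_pen)
        try:
            u, it = _newton(psys, u, free, tol_rel=tol_rel, max_iter=60)
        except IndentError as exc:
            raise IndentError(f"penalty contact failed at depth {d}: {exc}")
        total_iters += it
        _fc, idx, pen, dhat, _dist = _penalty_forces(mesh, u, position, radius, d, k_pen)
        fz = float(np.sum(k_pen * pen * dhat[:, 1])) if len(idx) else 0.0
        history.append((d, fz))
        if len(idx) and d > 0:
            max_pen_frac = max(max_pen_frac, float(pen.max()) / d)
    return u, history, total_iters, max_pen_frac


def _indent_pass(
    mesh: Mesh,
    materials: Mapping[str, OgdenMaterial | NeoHookeanMaterial],
    position: float,
    depths: Sequence[float],
    protocol: IndentationProtocol,
    mode: str = "prescribed",
    kappa_ratio: float = 100.0,
    tol_rel: float = 1e-8,
    penalty_stiffness: float | None = None,
):
    """One incremental loading pass recording forces at all ``depths``.

    The model is elastic and quasi-static, so the state at a given
    indentation depth is path independent: a single displacement-controlled
    ramp through all requested depths yields exactly the forces of
    independent from-scratch indentations.
    """
    depths = sorted(float(d) for d in depths)
    if not (0.0 <= position <= mesh.domain.width):
        raise ValueError("position outside the domain surface")
    system = _System(mesh, materials, kappa_ratio=kappa_ratio)
    dmax = depths[-1]
    n = protocol.steps_for(dmax)
    deltas = np.unique(np.concatenate([np.linspace(dmax / n, dmax, n), depths]))
    radius = protocol.indenter_radius
    max_pen = 0.0
    if mode == "prescribed":
        u, history, iters = _solve_prescribed(system, mesh, position, radius, deltas, tol_rel)
    elif mode == "penalty":
        if penalty_stiffness is None:
            # per-node normal stiffness (N/mm per mm penetration) sized so
            # penetration stays well below 1% of the indentation depth
            mu0 = float(system.mu.sum(axis=1).max())
            penalty_stiffness = 1000.0 * mu0
        u, history, iters, max_pen = _solve_penalty(
            system, mesh, position, radius, deltas, tol_rel, penalty_stiffness
        )
    else:
        raise ValueError("mode must be 'prescribed' or 'penalty'")
    hist = dict(history)
    forces = [hist[d] for d in depths]
    return forces, u, history, system, iters, max_pen


def indent_once(
    mesh: Mesh,
    materials: Mapping[str, OgdenMaterial | NeoHookeanMaterial],
    position: float,
    depth: float,
    protocol: IndentationProtocol,
    mode: str = "prescribed",
    kappa_ratio: float = 100.0,
    tol_rel: float = 1e-8,
    penalty_stiffness: float | None = None,
    return_state: bool = False,
):
    """Drive the rigid indenter to ``depth`` at ``position``; return the
    vertical reaction force (N/mm), or a full :class:`IndentResult`.

    The solve starts from the undeformed configuration, loads in quasi-static
    increments and requires Newton convergence (relative residual below
    ``tol_rel``) at every increment.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if depth == 0.0:
        if return_state:
            return IndentResult(0.0, np.zeros(2 * mesh.n_nodes), 0.0, position,
                                [(0.0, 0.0)], 0.0, 0.0, 0)
        return 0.0
    forces, u, history, system, iters, max_pen = _indent_pass(
        mesh, materials, position, [depth], protocol,
        mode=mode, kappa_ratio=kappa_ratio, tol_rel=tol_rel,
        penalty_stiffness=penalty_stiffness,
    )
    force = forces[0]
    if not return_state:
        return force
    hist = np.array(history)
    work = float(np.trapezoid(hist[:, 1], hist[:, 0]))
    res = IndentResult(
        force=force,
        displacement=u,
        depth=depth,
        position=position,
        force_history=history,
        stored_energy=system.stored_energy(u),
        external_work=work,
        newton_iterations=iters,
        max_penetration=max_pen,
    )
    idx, _ = _contact_nodes(mesh, position, protocol.indenter_radius, depth)
    if mode == "prescribed" and len(idx):
        f = system.internal_forces(u)
        res._fx = float(np.sum(f[2 * idx]))
    return res


def sweep(
    mesh_builder,
    materials: Mapping[str, OgdenMaterial | NeoHookeanMaterial],
    protocol: IndentationProtocol,
    source: str = "simulated",
    **solver_kwargs,
) -> list[ForceProfile]:
    """Point-wise palpation: one ForceProfile per indentation depth.

    ``mesh_builder`` is either a Mesh or a zero-argument callable producing
    one.  Indentations are mutually independent (each probe point starts
    from the undeformed configuration, emulating an experimental protocol
    with full relaxation between probings); for efficiency the depths at
    one position are collected along a single quasi-static ramp, which is
    exact for this path-independent elastic model.
    """
    mesh = mesh_builder() if callable(mesh_builder) else mesh_builder
    all_forces = np.empty((len(protocol.depths), len(protocol.positions)))
    for j, pos in enumerate(protocol.positions):
        try:
            forces, *_ = _indent_pass(
                mesh, materials, pos, protocol.depths, protocol, **solver_kwargs
            )
        except IndentError as exc:
            raise IndentError(
                f"indentation failed at position {pos} mm: {exc}",
                trace=exc.trace,
            ) from exc
        all_forces[:, j] = forces
    return [
        ForceProfile(
            indentation_depth=depth,
            positions=np.asarray(protocol.positions),
            forces=all_forces[i],
            source=source,
        )
        for i, depth in enumerate(protocol.depths)
    ]


def linear_elastic_force(
    mesh: Mesh,
    materials: Mapping[str, OgdenMaterial | NeoHookeanMaterial],
    position: float,
    depth: float,
    indenter_radius: float = 5.0,
    kappa_ratio: float = 1000.0,
) -> float:
    """Small-strain linear-elastic indentation force on the same mesh.

    Uses shear modulus mu0 per element and Lame lambda = kappa - 2*mu0/3
    (consistent with the hyperelastic volumetric penalty), with the same
    prescribed-arc contact; serves as the linear limit of the solver.
    """
    system = _System(mesh, materials, kappa_ratio=kappa_ratio)
    mu = system.mu.sum(axis=1)
    lam = system.kappa - 2.0 * mu / 3.0
    # plane-strain D matrix per element (Voigt xx, yy, xy)
    ne = mesh.n_elements
    D = np.zeros((ne, 3, 3))
    D[:, 0, 0] = D[:, 1, 1] = lam + 2 * mu
    D[:, 0, 1] = D[:, 1, 0] = lam
    D[:, 2, 2] = mu
    B = np.zeros((ne, 3, 6))
    g = mesh.grads
    B[:, 0, 0::2] = g[:, :, 0]
    B[:, 1, 1::2] = g[:, :, 1]
    B[:, 2, 0::2] = g[:, :, 1]
    B[:, 2, 1::2] = g[:, :, 0]
    Ke = np.einsum("e,eki,ekl,elj->eij", mesh.area, B, D, B)
    K = sp.coo_matrix(
        (Ke.ravel(), (system.rows, system.cols)), shape=(system.ndof, system.ndof)
    ).tocsr()
    idx, pen = _contact_nodes(mesh, position, indenter_radius, depth)
    if len(idx) == 0:
        return 0.0
    fixed = np.zeros(system.ndof, dtype=bool)
    fixed[2 * mesh.bottom_nodes] = True
    fixed[2 * mesh.bottom_nodes + 1] = True
    fixed[2 * idx + 1] = True
    u = np.zeros(system.ndof)
    u[2 * idx + 1] = pen
    free = ~fixed
    rhs = -(K[free][:, fixed] @ u[fixed])
    u[free] = splu(K[free][:, free].tocsc()).solve(rhs)
    f = K @ u
    return float(np.sum(f[2 * idx + 1]))
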