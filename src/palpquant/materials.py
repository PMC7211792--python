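"""Hyperelastic constitutive models for soft-tissue palpation simulation.

The tissue block and the embedded nodule are modeled as incompressible
isotropic hyperelastic solids.  Two strain-energy families are supported:

* a second-order Ogden model in the Abaqus normalization,

  .. math::

     \\Psi = \\sum_i \\frac{2\\mu_i}{\\alpha_i^2}
             (\\bar\\lambda_1^{\\alpha_i} + \\bar\\lambda_2^{\\alpha_i}
              + \\bar\\lambda_3^{\\alpha_i} - 3)
           + \\sum_i \\frac{1}{D_i} (J_{el} - 1)^{2i},

  with initial shear modulus :math:`\\mu_0 = \\sum_i \\mu_i` and, for an
  incompressible material, Young's modulus :math:`E = 3\\mu_0`;

* a one-parameter incompressible neo-Hookean model
  :math:`\\Psi = C_1 (\\bar I - 3)` with :math:`E = 6 C_1`.

Units are fixed package-wide: lengths in mm, forces in N and stress-like
quantities in MPa (N/mm^2).  Moduli reported to users are in kPa.

The module also provides Levenberg-Marquardt identification of the
neo-Hookean constant from indentation force data: the squared force misfit
summed over all indentation depths and probe positions,
``sum_depth sum_pos (F_sim(C1) - F_meas)^2``, is minimized with a damped
least-squares routine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import yaml
from scipy.optimize import brentq, least_squares

__all__ = [
    "OgdenMaterial",
    "NeoHookeanMaterial",
    "DeformationState",
    "FitResult",
    "FitConvergenceError",
    "HEALTHY_PROSTATE",
    "CANCEROUS_NODULE",
    "ogden_energy",
    "neo_hookean_energy",
    "ogden_from_modulus",
    "young_from_c1",
    "fit_neo_hookean",
    "material_to_yaml",
    "material_from_yaml",
]

_ISO_TOL = 1e-8


@dataclass(frozen=True)
class OgdenMaterial:
    """Ogden material parameters (mu_i in MPa, alpha_i dimensionless,
    D_i in 1/MPa; ``d`` empty means fully incompressible)."""

    mu: tuple[float, ...]
    alpha: tuple[float, ...]
    d: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", tuple(float(m) for m in self.mu))
        object.__setattr__(self, "alpha", tuple(float(a) for a in self.alpha))
        object.__setattr__(self, "d", tuple(float(x) for x in self.d))
        if len(self.mu) != len(self.alpha):
            raise ValueError("mu and alpha must have the same length")
        if self.d and len(self.d) != len(self.mu):
            raise ValueError("d must be empty or match the model order")
        if not self.mu:
            raise ValueError("at least one (mu, alpha) pair is required")
        if any(a == 0.0 for a in self.alpha):
            raise ValueError("all alpha_i must be nonzero")
        if self.mu0 <= 0.0:
            raise ValueError("initial shear modulus sum(mu_i) must be > 0")

    @property
    def order(self) -> int:
        return len(self.mu)

    @property
    def mu0(self) -> float:
        """Initial (small-strain) shear modulus, MPa."""
        return float(sum(self.mu))

    @property
    def young_modulus_kpa(self) -> float:
        """Small-strain Young's modulus 3*mu0 (incompressible, nu=1/2), kPa."""
        return 3.0e3 * self.mu0

    def scaled(self, factor: float) -> "OgdenMaterial":
        """Material with every mu_i scaled by ``factor`` (d by 1/factor)."""
        if factor <= 0.0:
            raise ValueError("scaling factor must be positive")
        return OgdenMaterial(
            mu=tuple(m * factor for m in self.mu),
            alpha=self.alpha,
            d=tuple(x / factor for x in self.d),
        )


@dataclass(frozen=True)
class NeoHookeanMaterial:
    """Incompressible neo-Hookean material, C1 in MPa."""

    c1: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "c1", float(self.c1))
        if self.c1 <= 0.0:
            raise ValueError("c1 must be positive")

    def as_ogden(self) -> OgdenMaterial:
        """Algebraically equivalent Ogden material (mu=2*C1, alpha=2)."""
        return OgdenMaterial(mu=(2.0 * self.c1,), alpha=(2.0,))

    @property
    def young_modulus_kpa(self) -> float:
        return young_from_c1(self)


# Published second-order Ogden fits for prostate-mimicking tissue
# (mu_i MPa, alpha_i dimensionless; fully incompressible).  The cancerous
# nodule has exactly twice the healthy mu_i (2:1 modulus ratio).
HEALTHY_PROSTATE = OgdenMaterial(mu=(0.02119, -0.01120), alpha=(2.244, -1.081))
CANCEROUS_NODULE = OgdenMaterial(mu=(0.04238, -0.02240), alpha=(2.244, -1.081))


@dataclass(frozen=True)
class DeformationState:
    """Pointwise isochoric deformation state.

    ``principal_stretches`` are the isochoric principal stretches
    (product 1); ``jel`` is the elastic volume ratio; ``i1bar`` the first
    isochoric invariant (derived from the stretches when not given).
    """

    principal_stretches: tuple[float, float, float]
    jel: float = 1.0
    i1bar: float | None = None

    def __post_init__(self) -> None:
        lams = tuple(float(x) for x in self.principal_stretches)
        object.__setattr__(self, "principal_stretches", lams)
        if len(lams) != 3 or any(l <= 0.0 for l in lams):
            raise ValueError("three positive principal stretches required")
        prod = lams[0] * lams[1] * lams[2]
        if abs(prod - 1.0) > _ISO_TOL:
            raise ValueError(
                f"isochoric stretches must multiply to 1 (got {prod!r})"
            )
        if self.jel <= 0.0:
            raise ValueError("jel must be positive")
        if self.i1bar is None:
            object.__setattr__(self, "i1bar", float(sum(l * l for l in lams)))
        if self.i1bar < 3.0 - _ISO_TOL:
            raise ValueError("i1bar must be >= 3")

    @classmethod
    def identity(cls) -> "DeformationState":
        return cls((1.0, 1.0, 1.0))

    @classmethod
    def uniaxial(cls, lam: float, jel: float = 1.0) -> "DeformationState":
        """Incompressible uniaxial stretch (lam, lam^-1/2, lam^-1/2)."""
        s = 1.0 / np.sqrt(lam)
        return cls((lam, s, s), jel=jel)

    @classmethod
    def from_first_invariant(cls, i1bar: float) -> "DeformationState":
        """Uniaxial state whose first isochoric invariant equals ``i1bar``."""
        if i1bar < 3.0:
            raise ValueError("i1bar must be >= 3")
        if i1bar == 3.0:
            return cls.identity()
        f = lambda lam: lam * lam + 2.0 / lam - i1bar
        lam = brentq(f, 1.0, 1.0 + np.sqrt(i1bar))
        return cls.uniaxial(lam)


def ogden_energy(state: DeformationState, mat: OgdenMaterial) -> float:
    """Ogden strain-energy density (MPa) at a deformation state.

    The deviatoric sum carries the conventional "-3" so the energy vanishes
    at the undeformed reference.  With ``mat.d`` empty the material is fully
    incompressible and ``state.jel`` must equal 1.
    """
    l1, l2, l3 = state.principal_stretches
    if not mat.d and abs(state.jel - 1.0) > _ISO_TOL:
        raise ValueError("incompressible material requires jel == 1")
    w = 0.0
    for mu_i, a_i in zip(mat.mu, mat.alpha):
        w += (2.0 * mu_i / a_i**2) * (l1**a_i + l2**a_i + l3**a_i - 3.0)
    for i, d_i in enumerate(mat.d, start=1):
        if d_i != 0.0:
            w += (1.0 / d_i) * (state.jel - 1.0) ** (2 * i)
    return w


def neo_hookean_energy(state: DeformationState, mat: NeoHookeanMaterial) -> float:
    """Incompressible neo-Hookean energy density C1*(I1bar - 3), MPa."""
    if abs(state.jel - 1.0) > _ISO_TOL:
        raise ValueError("incompressible material requires jel == 1")
    return mat.c1 * (state.i1bar - 3.0)


def ogden_from_modulus(
    reference: OgdenMaterial, e_ref_kpa: float, e_target_kpa: float
) -> OgdenMaterial:
    """Rescale an Ogden material to a target small-strain Young's modulus.

    The mu_i scale by e_target/e_ref (alpha_i unchanged, D_i inversely),
    which is how the stiffer-nodule parameters relate to the healthy ones
    when only the modulus ratio is prescribed.
    """
    if e_ref_kpa <= 0.0 or e_target_kpa <= 0.0:
        raise ValueError("moduli must be positive")
    return reference.scaled(e_target_kpa / e_ref_kpa)


def young_from_c1(mat: NeoHookeanMaterial) -> float:
    """Young's modulus in kPa from C1 in MPa: E = 6*C1 (nu = 1/2)."""
    return 6.0e3 * mat.c1


class FitConvergenceError(RuntimeError):
    """Raised when the material fit fails to converge; carries the trace of
    residual norms evaluated during the optimization."""

    def __init__(self, message: str, residual_trace: list[float]):
        super().__init__(message)
        self.residual_trace = residual_trace


@dataclass(frozen=True)
class FitResult:
    """Outcome of a neo-Hookean identification."""

    material: NeoHookeanMaterial
    per_point_error: tuple[float, ...]
    max_error: float = field(init=False)
    min_error: float = field(init=False)
    mean_error: float = field(init=False)
    young_modulus_kpa: float = field(init=False)

    def __post_init__(self) -> None:
        err = tuple(float(e) for e in self.per_point_error)
        if not err:
            raise ValueError("per_point_error must be non-empty")
        object.__setattr__(self, "per_point_error", err)
        object.__setattr__(self, "max_error", max(err))
        object.__setattr__(self, "min_error", min(err))
        object.__setattr__(self, "mean_error", float(np.mean(err)))
        object.__setattr__(
            self, "young_modulus_kpa", young_from_c1(self.material)
        )


def _flatten_forces(profiles: Iterable) -> np.ndarray:
    chunks = []
    for p in profiles:
        chunks.append(np.asarray(getattr(p, "forces", p), dtype=float).ravel())
    if not chunks:
        raise ValueError("at least one force profile is required")
    return np.concatenate(chunks)


def fit_neo_hookean(
    measured: Sequence,
    forward: Callable[[float], Sequence],
    init_c1: float = 5.0e-3,
    xtol: float = 1e-8,
    max_iter: int = 200,
) -> FitResult:
    """Identify the neo-Hookean C1 from measured indentation forces.

    Parameters
    ----------
    measured
        Force profiles (objects with ``.forces`` or plain arrays), one per
        indentation depth.
    forward
        Simulation oracle mapping C1 (MPa) to predicted forces with the
        same layout as ``measured``.
    init_c1
        Starting value for the damped least-squares (Levenberg-Marquardt)
        iteration, MPa.

    Returns the fitted material together with per-point relative errors
    |F_sim - F_meas| / F_meas.
    """
    f_meas = _flatten_forces(measured)
    if np.any(f_meas == 0.0):
        raise ValueError("measured forces contain zeros; relative error undefined")
    trace: list[float] = []

    def residuals(x: np.ndarray) -> np.ndarray:
        r = _flatten_forces(forward(float(x[0]))) - f_meas
        trace.append(float(np.linalg.norm(r)))
        return r

    res = least_squares(
        residuals,
        x0=np.array([float(init_c1)]),
        method="lm",
        xtol=xtol,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=max_iter,
    )
    if not res.success:
        raise FitConvergenceError(
            f"neo-Hookean fit did not converge: {res.message}", trace
        )
    c1 = float(res.x[0])
    f_fit = _flatten_forces(forward(c1))
    rel = np.abs(f_fit - f_meas) / np.abs(f_meas)
    return FitResult(
        material=NeoHookeanMaterial(c1=c1),
        per_point_error=tuple(rel.tolist()),
    )


def material_to_yaml(mat: OgdenMaterial | NeoHookeanMaterial) -> str:
    """Serialize a material as a YAML block (mu/c1 in MPa, D in 1/MPa)."""
    if isinstance(mat, OgdenMaterial):
        doc = {
            "model": "ogden",
            "mu": list(mat.mu),
            "alpha": list(mat.alpha),
            "d": list(mat.d),
        }
    elif isinstance(mat, NeoHookeanMaterial):
        doc = {"model": "neo_hookean", "c1": mat.c1}
    else:
        raise TypeError(f"unsupported material type {type(mat)!r}")
    return "# units: mu/c1 in MPa, d in 1/MPa\n" + yaml.safe_dump(
        doc, sort_keys=False
    )


def material_from_yaml(text: str) -> OgdenMaterial | NeoHookeanMaterial:
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "model" not in doc:
        raise ValueError("material YAML must be a mapping with a 'model' key")
    model = doc["model"]
    if model == "ogden":
        return OgdenMaterial(
            mu=tuple(doc["mu"]),
            alpha=tuple(doc["alpha"]),
            d=tuple(doc.get("d") or ()),
        )
    if model == "neo_hookean":
        return NeoHookeanMaterial(c1=doc["c1"])
    raise ValueError(f"unknown material model {model!r}")
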