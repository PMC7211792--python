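"""Nodule localization and force-profile curvature extraction.

A stiff nodule makes the palpation force profile locally "peaky": the force
above the nodule exceeds the healthy background and the profile's curvature
(second derivative with respect to probe position) at the nodule position
carries information about both nodule size and depth.  This module

* localizes the nodule as the position where the force profile deviates
  most from a healthy baseline profile, and
* estimates the second derivative of force with respect to position by
  fitting a cubic smoothing spline over all data points and differentiating
  it analytically.  The smoothing parameter defaults to generalized
  cross-validation ("auto"); ``smoothing=0`` gives an exact interpolating
  spline (which reproduces polynomials up to cubic exactly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_interp_spline, make_smoothing_spline

from .fem import ForceProfile

__all__ = [
    "CurvatureProfile",
    "NoNoduleDetected",
    "localize_nodule",
    "second_derivative",
    "curvature_profile",
]

MIN_POINTS = 5


class NoNoduleDetected(RuntimeError):
    """The profile does not deviate from the baseline above the noise floor."""


def _fit_spline(positions: np.ndarray, forces: np.ndarray, smoothing):
    if len(positions) < MIN_POINTS:
        raise ValueError(
            f"at least {MIN_POINTS} data points are required for the spline"
        )
    if smoothing == "auto":
        return make_smoothing_spline(positions, forces, lam=None)
    lam = float(smoothing)
    if lam < 0:
        raise ValueError("smoothing must be >= 0 or 'auto'")
    if lam == 0.0:
        return make_interp_spline(positions, forces, k=3)
    return make_smoothing_spline(positions, forces, lam=lam)


def second_derivative(profile: ForceProfile, at: float, smoothing="auto") -> float:
    """Second derivative of force w.r.t. position (N/mm^3 per unit
    thickness) from a cubic smoothing spline fit over all points.

    ``at`` must lie inside the measured position range (no extrapolation).
    """
    pos, frc = profile.positions, profile.forces
    if not (pos[0] <= at <= pos[-1]):
        raise ValueError(f"position {at} outside measured range [{pos[0]}, {pos[-1]}]")
    spline = _fit_spline(pos, frc, smoothing)
    return float(spline.derivative(2)(at))


@dataclass(frozen=True)
class CurvatureProfile:
    """Second-derivative values of one force profile at every position.

    ``reliable`` flags positions further than one indenter radius from the
    profile ends; edge values are excluded from inversion.
    """

    indentation_depth: float
    positions: np.ndarray
    values: np.ndarray
    smoothing: object
    reliable: np.ndarray

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.values):
            raise ValueError("positions and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curvature values must be finite")


def curvature_profile(
    profile: ForceProfile, smoothing="auto", edge_margin: float = 5.0
) -> CurvatureProfile:
    """Curvature at every profile position with edge-reliability flags."""
    spline = _fit_spline(profile.positions, profile.forces, smoothing)
    values = spline.derivative(2)(profile.positions)
    pos = profile.positions
    reliable = (pos >= pos[0] + edge_margin) & (pos <= pos[-1] - edge_margin)
    return CurvatureProfile(
        indentation_depth=profile.indentation_depth,
        positions=pos,
        values=np.asarray(values, dtype=float),
        smoothing=smoothing,
        reliable=reliable,
    )


def localize_nodule(
    profile: ForceProfile,
    baseline: ForceProfile,
    noise_floor: float | None = None,
) -> float:
    """Locate the nodule as the position of maximal deviation from the
    healthy-background profile.

    The noise floor defaults to 3x the robust spread of the baseline
    residuals about a smoothing-spline fit of the baseline itself; if the
    maximal deviation does not exceed it, :class:`NoNoduleDetected` is
    raised.  Ties are broken toward the center of the scanned range.
    """
    if profile.indentation_depth != baseline.indentation_depth:
        raise ValueError("profile and baseline indentation depths differ")
    if not np.array_equal(profile.positions, baseline.positions):
        raise ValueError("profile and baseline positions differ")
    diff = np.abs(profile.forces - baseline.forces)
    if noise_floor is None:
        if len(baseline) >= MIN_POINTS:
            fit = _fit_spline(baseline.positions, baseline.forces, "auto")
            resid = baseline.forces - fit(baseline.positions)
            spread = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        else:
            spread = 0.0
        noise_floor = 3.0 * float(spread)
    dmax = float(diff.max())
    if dmax <= max(noise_floor, 1e-12 * max(1.0, float(profile.forces.max()))):
        raise NoNoduleDetected(
            f"max |dF| = {dmax:.3e} below noise floor {noise_floor:.3e}"
        )
    center = 0.5 * (profile.positions[0] + profile.positions[-1])
    best = np.where(diff >= dmax * (1.0 - 1e-12))[0]
    idx = best[np.argmin(np.abs(profile.positions[best] - center))]
    return float(profile.positions[idx])
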