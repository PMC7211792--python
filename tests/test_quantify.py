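"""Calibration-library inversion, curve intersection and derived sizes.

Most tests use an analytic stand-in library,
``v(U, z, D) = -D / (z - U)^2`` (indentation depth U, nodule depth z,
diameter D): monotone in D, decaying in z, and — crucially — a deeper
indentation effectively brings the nodule closer to the probe, so the
depth-diameter curves ``D(z) = |v| (z - U)^2`` from different indentation
depths are genuinely different parabolas that intersect only at the truth,
mimicking the decoupling the forward model provides.  FEM-backed closed
loops live in the acceptance suite.
"""

import math

import numpy as np
import pytest

from palpquant.geometry import NoduleSpec
from palpquant.quantify import (
    CalibrationLibrary,
    DepthDiameterCurve,
    EmptyCurveError,
    InconsistentMeasurementsError,
    QuantificationResult,
    equivalent_radius,
    equivalent_radius_2d,
    intersect_curves,
    invert_to_curve,
    percent_error,
    quantification_errors,
)

IND = np.array([1.0, 5.0, 10.0])
DEPTHS = np.array([30.0, 40.0, 50.0])
DIAMS = np.array([10.0, 16.0, 22.0, 30.0])


def analytic_value(u, z, d):
    return -d / (z - u) ** 2


@pytest.fixture()
def analytic_library():
    vals = analytic_value(IND[:, None, None], DEPTHS[None, :, None],
                          DIAMS[None, None, :])
    return CalibrationLibrary(diameters=DIAMS, depths=DEPTHS,
                              indentation_depths=IND, values=vals)


class TestLibrary:
    def test_grid_validation(self, analytic_library):
        with pytest.raises(ValueError):
            CalibrationLibrary(diameters=[10, 5], depths=DEPTHS,
                               indentation_depths=IND,
                               values=np.zeros((3, 3, 2)))
        with pytest.raises(ValueError):
            CalibrationLibrary(diameters=DIAMS, depths=DEPTHS,
                               indentation_depths=IND,
                               values=np.zeros((2, 3, 4)))
        bad = analytic_library.values.copy()
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            CalibrationLibrary(diameters=DIAMS, depths=DEPTHS,
                               indentation_depths=IND, values=bad)

    def test_dict_round_trip(self, analytic_library):
        doc = analytic_library.to_dict()
        back = CalibrationLibrary.from_dict(doc)
        assert np.array_equal(back.values, analytic_library.values)
        assert np.array_equal(back.diameters, analytic_library.diameters)


class TestInvertToCurve:
    def test_exact_grid_value_recovered(self, analytic_library):
        measured = analytic_value(5.0, 40.0, 16.0)
        curve = invert_to_curve(analytic_library, measured, 5.0)
        row = dict(zip(curve.points[:, 0], curve.points[:, 1]))
        assert row[40.0] == pytest.approx(16.0, abs=1e-9)

    def test_monotone_interpolation_between_grid_points(self, analytic_library):
        measured = analytic_value(5.0, 40.0, 19.0)  # off-grid diameter
        curve = invert_to_curve(analytic_library, measured, 5.0)
        row = dict(zip(curve.points[:, 0], curve.points[:, 1]))
        assert row[40.0] == pytest.approx(19.0, rel=1e-3)

    def test_out_of_range_depths_omitted(self, analytic_library):
        # value only reachable at the shallowest nodule depth
        measured = analytic_value(5.0, 30.0, 29.0)
        curve = invert_to_curve(analytic_library, measured, 5.0)
        assert set(curve.points[:, 0]) == {30.0}

    def test_fully_out_of_range_raises_empty_curve(self, analytic_library):
        with pytest.raises(EmptyCurveError):
            invert_to_curve(analytic_library, 0.0, 5.0)
        with pytest.raises(EmptyCurveError):
            invert_to_curve(analytic_library, -1e3, 5.0)

    def test_unknown_indentation_depth_rejected(self, analytic_library):
        with pytest.raises(ValueError, match="not in library"):
            invert_to_curve(analytic_library, -1.0, 7.0)


class TestIntersectCurves:
    def test_exact_common_point(self):
        curves = [
            DepthDiameterCurve(u, np.array([[20.0, 16 - (30 - 20) * s],
                                            [30.0, 16.0],
                                            [40.0, 16 + (40 - 30) * s]]))
            for u, s in [(1.0, 0.1), (5.0, 0.3), (10.0, 0.6)]
        ]
        res = intersect_curves(curves)
        assert res.chosen[0] == pytest.approx(30.0, abs=1e-6)
        assert res.chosen[1] == pytest.approx(16.0, abs=1e-6)
        assert res.candidates[0][2] < 1e-10

    def test_analytic_closed_loop_off_grid(self, analytic_library):
        z_true, d_true = 35.0, 18.0
        curves = [
            invert_to_curve(analytic_library, analytic_value(u, z_true, d_true), u)
            for u in IND
        ]
        res = intersect_curves(curves)
        assert res.chosen[0] == pytest.approx(z_true, abs=1.0)
        assert res.chosen[1] == pytest.approx(d_true, abs=1.0)

    def test_closest_approach_when_curves_do_not_intersect(self):
        # two parallel-ish curves offset in diameter: no intersection, the
        # closest-approach point lies between them
        c1 = DepthDiameterCurve(1.0, np.array([[30.0, 15.0], [50.0, 15.0]]))
        c2 = DepthDiameterCurve(5.0, np.array([[30.0, 17.0], [50.0, 17.0]]))
        res = intersect_curves([c1, c2])
        assert res.candidates[0][2] > 0
        assert 15.0 <= res.chosen[1] <= 17.0

    def test_two_crossings_reported_as_candidates(self):
        flat = DepthDiameterCurve(1.0, np.array([[20.0, 16.0], [60.0, 16.0]]))
        vee = DepthDiameterCurve(
            5.0, np.array([[20.0, 20.0], [40.0, 12.0], [60.0, 20.0]])
        )
        third = DepthDiameterCurve(
            10.0, np.array([[20.0, 20.0], [40.0, 12.0], [60.0, 20.0]])
        )
        res = intersect_curves([flat, vee, third])
        assert len(res.candidates) >= 2
        depths = sorted(c[0] for c in res.candidates[:2])
        assert depths[0] < 40.0 < depths[1]

    def test_residual_ceiling(self):
        c1 = DepthDiameterCurve(1.0, np.array([[30.0, 10.0], [50.0, 10.0]]))
        c2 = DepthDiameterCurve(5.0, np.array([[30.0, 30.0], [50.0, 30.0]]))
        with pytest.raises(InconsistentMeasurementsError):
            intersect_curves([c1, c2], residual_ceiling=1e-4)

    def test_empty_curve_names_depth(self):
        good = DepthDiameterCurve(1.0, np.array([[30.0, 16.0], [40.0, 18.0]]))
        empty = DepthDiameterCurve(5.0, np.empty((0, 2)))
        with pytest.raises(EmptyCurveError, match="5.0"):
            intersect_curves([good, empty])


class TestBuildLibrary:
    def test_single_cell_library_matches_direct_pipeline(
        self, small_domain, prostate_materials, small_protocol, small_sweeps
    ):
        """A 1x1 library grid must equal the direct composition of
        forward sweep + curvature at the nodule position."""
        from palpquant.profiles import second_derivative
        from palpquant.quantify import build_library

        lib = build_library(
            small_domain, prostate_materials, small_protocol,
            diameters=[12.0], depths=[20.0],
        )
        for i, prof in enumerate(small_sweeps["nodule"]):
            direct = second_derivative(prof, at=30.0)
            assert lib.values[i, 0, 0] == pytest.approx(direct, rel=1e-9)


class TestDerivedSizes:
    def test_equivalent_radius_of_phantom_nodule(self):
        r = equivalent_radius(20.0 * 12.0 * 12.0)
        assert float(f"{r:.3g}") == 8.83

    def test_equivalent_radius_unit_sphere(self):
        assert equivalent_radius(4.0 * math.pi / 3.0) == pytest.approx(1.0)

    def test_equivalent_radius_2d(self):
        assert equivalent_radius_2d(math.pi * 25.0) == pytest.approx(5.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            equivalent_radius(0.0)
        with pytest.raises(ValueError):
            equivalent_radius_2d(-1.0)

    @pytest.mark.parametrize(
        "predicted, true, expected",
        [(9.05, 8.83, 2.5), (9.94, 8.83, 12.6), (11.0, 10.0, 10.0)],
    )
    def test_percent_error_printed_values(self, predicted, true, expected):
        assert round(percent_error(predicted, true), 1) == expected

    def test_quantification_errors_zero_for_exact_prediction(self):
        truth = NoduleSpec(shape="circle", diameter=16.0, depth=30.0, center_x=50.0)
        res = QuantificationResult(
            candidates=((30.0, 16.0, 0.0),),
            chosen=(30.0, 16.0),
            equivalent_radius=8.0,
            area=math.pi * 64.0,
        )
        size_err, depth_err, area_err = quantification_errors(res, truth)
        assert size_err == pytest.approx(0.0, abs=0.2)  # circle discretization
        assert depth_err == 0.0
        assert area_err == pytest.approx(0.0, abs=0.2)


class TestResultInvariants:
    def test_candidates_must_be_sorted(self):
        with pytest.raises(ValueError):
            QuantificationResult(
                candidates=((30.0, 16.0, 1.0), (40.0, 20.0, 0.5)),
                chosen=(30.0, 16.0),
                equivalent_radius=8.0,
                area=1.0,
            )

    def test_negative_residual_rejected(self):
        with pytest.raises(ValueError):
            QuantificationResult(
                candidates=((30.0, 16.0, -1.0),),
                chosen=(30.0, 16.0),
                equivalent_radius=8.0,
                area=1.0,
            )
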