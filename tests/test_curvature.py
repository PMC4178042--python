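"""Stencil curvature, physical scaling and dense resampling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import octfundus as of
from octfundus.curvature import local_curvature, resample_dense, curvature_profile
from octfundus.segmentation import BoundaryTrace
from octfundus.oct_io import Calibration


def stencil_oracle(f_minus, f0, f_plus, h):
    """Literal transcription of the central-difference curvature equations."""
    fp = (f_plus - f_minus) / (2 * h)
    fpp = (f_plus - 2 * f0 + f_minus) / h**2
    return fpp / (1 + fp**2) ** 1.5


class TestLocalCurvature:
    def test_collinear_points_give_exactly_zero(self):
        assert local_curvature(100.0, 150.0, 200.0, 500.0) == 0.0
        assert local_curvature(5.0, 5.0, 5.0, 500.0) == 0.0

    def test_posterior_bowl_is_negative(self):
        # symmetric bowl, floor 25 um deeper than the +-500 um shoulders
        assert local_curvature(25.0, 50.0, 25.0, 500.0) == pytest.approx(-2e-4)

    def test_anterior_bump_is_positive(self):
        assert local_curvature(25.0, 0.0, 25.0, 500.0) == pytest.approx(2e-4)

    def test_circle_apex_matches_independent_oracle(self):
        # posterior bowl of radius 2000 um, apex the deepest point
        R = 2000.0
        h = 500.0
        shoulder = -(R - np.sqrt(R * R - h * h))
        expected = stencil_oracle(shoulder, 0.0, shoulder, h)
        got = local_curvature(shoulder, 0.0, shoulder, h)
        assert got == pytest.approx(expected, abs=1e-7)
        assert got == pytest.approx(-5.081e-4, abs=1e-6)

    def test_nonfinite_input_raises(self):
        with pytest.raises(ValueError):
            local_curvature(np.nan, 0.0, 1.0, 500.0)

    @given(
        f=st.tuples(*[st.floats(-500, 500) for _ in range(3)]),
        offset=st.floats(-5000, 5000),
    )
    def test_translation_invariance(self, f, offset):
        a = local_curvature(*f, 500.0)
        b = local_curvature(f[0] + offset, f[1] + offset, f[2] + offset, 500.0)
        assert b == pytest.approx(a, abs=1e-12)

    @given(f=st.tuples(*[st.floats(-500, 500) for _ in range(3)]))
    def test_reflection_and_depth_flip(self, f):
        k = local_curvature(*f, 500.0)
        # left-right reflection leaves kappa unchanged
        assert local_curvature(f[2], f[1], f[0], 500.0) == pytest.approx(k, abs=1e-15)
        # flipping the depth axis flips the sign
        assert local_curvature(-f[0], -f[1], -f[2], 500.0) == pytest.approx(-k, abs=1e-15)


class TestToPhysical:
    def test_direct_scaling(self):
        depth = np.zeros(201)
        depth[150] = 50.0
        trace = BoundaryTrace(depth, np.ones(201, bool), np.zeros(201, bool))
        pt = of.to_physical(trace, Calibration(10.0, 10.0), center_col=50)
        assert pt.position_um[150] == pytest.approx(1000.0)
        assert pt.depth_um[150] == pytest.approx(500.0)

    def test_isotropic_unit_calibration_is_identity(self):
        depth = np.arange(10.0)
        trace = BoundaryTrace(depth, np.ones(10, bool), np.zeros(10, bool))
        pt = of.to_physical(trace, Calibration(1.0, 1.0), center_col=0)
        np.testing.assert_allclose(pt.position_um, np.arange(10.0))
        np.testing.assert_allclose(pt.depth_um, depth)

    def test_anisotropic_slope_transform(self):
        # a 45-degree line in pixel space with axial 5, lateral 20 um/px
        depth = np.arange(20.0)
        trace = BoundaryTrace(depth, np.ones(20, bool), np.zeros(20, bool))
        pt = of.to_physical(trace, Calibration(5.0, 20.0), center_col=0)
        slope = np.diff(pt.depth_um) / np.diff(pt.position_um)
        np.testing.assert_allclose(slope, 0.25)

    def test_too_few_valid_columns_raises(self):
        trace = BoundaryTrace(np.zeros(5), np.zeros(5, bool), np.zeros(5, bool))
        with pytest.raises(ValueError):
            of.to_physical(trace, Calibration(1.0, 1.0), 0)


class TestResampleDense:
    def test_two_points_give_straight_line(self):
        pt = of.PhysicalTrace([0.0, 1000.0], [0.0, 100.0], [True, True])
        dense = resample_dense(pt)
        assert dense.position_um.size == 1001
        np.testing.assert_allclose(dense.depth_um, dense.position_um * 0.1)
        assert dense.valid.all()

    def test_nodes_are_preserved(self):
        pos = np.arange(0.0, 2001.0, 1.0)
        dep = np.sin(pos / 300.0)
        pt = of.PhysicalTrace(pos, dep, np.ones(pos.size, bool))
        dense = resample_dense(pt)
        np.testing.assert_allclose(dense.depth_um, dep)

    def test_wide_gap_stays_invalid(self):
        pos = np.array([0.0, 500.0, 2500.0, 3000.0])
        pt = of.PhysicalTrace(pos, np.zeros(4), np.ones(4, bool))
        dense = resample_dense(pt)
        in_gap = (dense.position_um > 500) & (dense.position_um < 2500)
        assert not dense.valid[in_gap].any()
        assert dense.valid[~in_gap].all()


class TestCurvatureProfile:
    def test_straight_trace_is_flat(self):
        pos = np.arange(-2000.0, 2001.0)
        pt = of.PhysicalTrace(pos, 0.3 * pos + 40.0, np.ones(pos.size, bool))
        prof = curvature_profile(pt)
        assert prof.valid.all()
        np.testing.assert_allclose(prof.kappa, 0.0, atol=1e-12)

    def test_margins_are_trimmed_to_8000_um(self):
        pos = np.arange(-4500.0, 4501.0)
        pt = of.PhysicalTrace(pos, np.zeros(pos.size), np.ones(pos.size, bool))
        prof = curvature_profile(pt)
        assert prof.position_um[0] == -4000.0
        assert prof.position_um[-1] == 4000.0

    def test_sphere_section_recovers_minus_inverse_radius(self):
        R = 13000.0
        pos = np.arange(-4500.0, 4501.0)
        depth = np.sqrt(R * R - pos * pos) - R
        pt = of.PhysicalTrace(pos, depth, np.ones(pos.size, bool))
        prof = curvature_profile(pt)
        k = prof.kappa[prof.valid]
        np.testing.assert_allclose(k, -1.0 / R, rtol=0.02)

    def test_stencil_reaches_exactly_500_um(self):
        """Perturbing one sample moves kappa only at centres 0 and +-h."""
        pos = np.arange(-2000.0, 2001.0)
        flat = of.PhysicalTrace(pos, np.zeros(pos.size), np.ones(pos.size, bool))
        bumped_depth = np.zeros(pos.size)
        bumped_depth[pos == 0.0] = 10.0
        bumped = of.PhysicalTrace(pos, bumped_depth, np.ones(pos.size, bool))
        k0 = curvature_profile(flat).kappa
        k1 = curvature_profile(bumped).kappa
        changed = curvature_profile(flat).position_um[np.abs(k1 - k0) > 1e-15]
        np.testing.assert_array_equal(changed, [-500.0, 0.0, 500.0])

    def test_short_trace_warns_and_returns_empty(self):
        pos = np.arange(0.0, 800.0)
        pt = of.PhysicalTrace(pos, np.zeros(pos.size), np.ones(pos.size, bool))
        with pytest.warns(UserWarning):
            prof = curvature_profile(pt)
        assert prof.position_um.size == 0

    def test_invalid_span_masks_adjacent_centres(self):
        pos = np.arange(-3000.0, 3001.0)
        valid = np.ones(pos.size, bool)
        valid[(pos >= -100) & (pos <= 100)] = False
        pt = of.PhysicalTrace(pos, np.zeros(pos.size), valid)
        prof = curvature_profile(pt)
        # centres whose stencil touches the masked span are invalid
        assert not prof.valid[np.abs(prof.position_um) <= 600].any()
        assert prof.valid[np.abs(prof.position_um) >= 700].all()

    def test_convergence_order_in_h(self):
        """On a smooth analytic trace the stencil error shrinks ~ h^2."""
        R = 10000.0
        pos = np.arange(-3000.0, 3001.0)
        depth = np.sqrt(R * R - pos * pos) - R
        pt = of.PhysicalTrace(pos, depth, np.ones(pos.size, bool))
        errs = []
        for h in (500.0, 250.0, 125.0):
            prof = curvature_profile(pt, h_um=h)
            center = prof.kappa[prof.position_um == 0.0][0]
            errs.append(abs(center + 1.0 / R))
        assert errs[0] > errs[1] > errs[2]
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.2)
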