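import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from refractive_outcomes.refraction import Refraction, convert_cyl_sign, propagate_vertex
from refractive_outcomes.vectors import (
    AstigVector,
    angle_of_error,
    correction_index,
    sia,
    tia,
    to_double_angle,
    vector_outcome,
)


def crossed_cylinder_matrix(mag1, ax1, mag2, ax2):
    """Independent oracle: combine two cylinders via 2x2 dioptric power
    matrices and decompose the resultant into magnitude and axis."""
    def power_matrix(c, axis_deg):
        t = math.radians(axis_deg)
        return c * np.array(
            [
                [math.sin(t) ** 2, -math.sin(t) * math.cos(t)],
                [-math.sin(t) * math.cos(t), math.cos(t) ** 2],
            ]
        )

    m = power_matrix(mag1, ax1) + power_matrix(mag2, ax2)
    x = m[1, 1] - m[0, 0]
    y = -2.0 * m[0, 1]
    mag = math.hypot(x, y)
    axis = (math.degrees(math.atan2(y, x)) / 2.0) % 180.0
    return mag, 180.0 if axis == 0 else axis


class TestDoubleAngle:
    @pytest.mark.parametrize(
        "mag,axis,expected",
        [
            (1.0, 90.0, (-1.0, 0.0)),
            (1.0, 45.0, (0.0, 1.0)),
            (0.0, 123.0, (0.0, 0.0)),
        ],
    )
    def test_examples(self, mag, axis, expected):
        v = to_double_angle(mag, axis)
        assert v.x == pytest.approx(expected[0], abs=1e-12)
        assert v.y == pytest.approx(expected[1], abs=1e-12)

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ValueError, match="positive-cylinder"):
            to_double_angle(-1.0, 90.0)

    @settings(max_examples=300, derandomize=True)
    @given(st.floats(1e-6, 8.0), st.floats(0.001, 180.0))
    def test_axis_recovery_inverts(self, mag, axis):
        v = to_double_angle(mag, axis)
        assert v.magnitude == pytest.approx(mag, rel=1e-12)
        assert v.axis == pytest.approx(axis, abs=1e-9)

    @settings(max_examples=300, derandomize=True)
    @given(
        st.floats(0, 6), st.floats(0.001, 180),
        st.floats(0, 6), st.floats(0.001, 180),
    )
    def test_crossed_cylinder_matrix_oracle(self, m1, a1, m2, a2):
        combined = to_double_angle(m1, a1) + to_double_angle(m2, a2)
        mag, axis = crossed_cylinder_matrix(m1, a1, m2, a2)
        assert combined.magnitude == pytest.approx(mag, abs=1e-9)
        if mag > 1e-6:
            delta = abs(combined.axis - axis) % 180.0
            assert min(delta, 180.0 - delta) < 1e-9


class TestTiaSia:
    def test_full_correction_magnitude(self):
        preop = Refraction(0, 1.0, 90, 0)
        plano = Refraction(0, 0, 180, 0)
        assert tia(preop, plano).magnitude == pytest.approx(1.0)
        assert sia(preop, plano).magnitude == pytest.approx(1.0)

    def test_no_intended_change(self):
        r = Refraction(0, 1.0, 90, 0)
        assert tia(r, r).magnitude == pytest.approx(0.0)
        assert sia(r, r).magnitude == pytest.approx(0.0)

    def test_antipodal_axes_add(self):
        preop = Refraction(0, 1.0, 90, 0)
        target = Refraction(0, 1.0, 180, 0)
        assert tia(preop, target).magnitude == pytest.approx(2.0)

    def test_component_subtraction(self):
        preop = Refraction(0, 2.0, 180, 0)
        postop = Refraction(0, 1.0, 180, 0)
        v = sia(preop, postop)
        assert v.magnitude == pytest.approx(1.0)
        assert v.axis in (90.0, 180.0)  # antiparallel family

    def test_negative_cylinder_inputs_are_transposed(self):
        neg = Refraction(-1.0, -1.0, 90, 0)
        pos = convert_cyl_sign(neg)
        plano = Refraction(0, 0, 180, 0)
        v1, v2 = tia(neg, plano), tia(pos, plano)
        assert v1.x == pytest.approx(v2.x) and v1.y == pytest.approx(v2.y)

    def test_nonzero_vertex_rejected(self):
        spectacle = Refraction(0, -1.0, 90, 12)
        plano = Refraction(0, 0, 180, 0)
        with pytest.raises(ValueError, match="corneal plane"):
            tia(spectacle, plano)


class TestCiAoe:
    def test_perfect_magnitude_correction(self):
        t = to_double_angle(1.0, 90)
        assert correction_index(t, t) == pytest.approx(1.0)

    def test_zero_sia(self):
        t = to_double_angle(1.0, 90)
        assert correction_index(t, AstigVector(0, 0)) == pytest.approx(0.0)

    def test_undefined_at_zero_tia(self):
        assert correction_index(AstigVector(0, 0), to_double_angle(1, 90)) is None
        assert angle_of_error(AstigVector(0, 0), to_double_angle(1, 90)) is None
        assert angle_of_error(to_double_angle(1, 90), AstigVector(0, 0)) is None

    def test_parallel_gives_zero_angle(self):
        t = to_double_angle(1.0, 37)
        assert angle_of_error(t, to_double_angle(2.5, 37)) == pytest.approx(0.0)

    def test_ccw_positive_sign(self):
        t = to_double_angle(1.0, 180)  # axis "0" family
        s = to_double_angle(1.0, 10)
        assert angle_of_error(t, s) == pytest.approx(+10.0, abs=1e-9)

    def test_range_half_open(self):
        t = to_double_angle(1.0, 180)
        s = to_double_angle(1.0, 90)  # orthogonal correction
        assert angle_of_error(t, s) == pytest.approx(90.0)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(0.1, 5), st.floats(1, 180), st.floats(0.1, 5),
           st.floats(-80, 80))
    def test_antisymmetric_under_axis_reflection(self, tm, ta, sm, delta):
        t = to_double_angle(tm, ta)
        s = to_double_angle(sm, ta + delta)
        s_reflected = to_double_angle(sm, ta - delta)
        a1 = angle_of_error(t, s)
        a2 = angle_of_error(t, s_reflected)
        assert a1 == pytest.approx(-a2, abs=1e-9)


class TestVectorOutcome:
    def test_postop_equals_target_gives_ci_one_aoe_zero(self, perfect_cohort):
        for rec in perfect_cohort.records:
            out = vector_outcome(
                propagate_vertex(rec.preop, 0),
                propagate_vertex(rec.target, 0),
                propagate_vertex(rec.postop, 0),
            )
            assert out.tia.magnitude > 0
            assert out.correction_index == pytest.approx(1.0, abs=1e-12)
            assert out.angle_of_error == pytest.approx(0.0, abs=1e-9)
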