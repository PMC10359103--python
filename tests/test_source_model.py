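"""Rosenfalck waveform, section decomposition and traveling tripoles."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from semgiz.source_model import (
    ActionPotentialShape,
    eval_im,
    eval_vm,
    concentrated_source,
    section_bounds,
    travel_bounds,
    tripole_arrays,
    tripole_state,
)
from semgiz.motor_unit import MuscleFiber

MM = 1e-3


class TestTransmembrane:
    def test_resting_branch(self, shape):
        assert eval_vm(-5 * MM, shape) == pytest.approx(-80e-3)
        assert eval_vm(0.0, shape) == pytest.approx(-80e-3)
        # exponential dominates the cubic far along the fiber
        assert eval_vm(1.0, shape) == pytest.approx(-80e-3)

    def test_depolarization_peak(self, shape):
        # stationary point of the active branch sits at zeta = 3/lambda
        res = minimize_scalar(
            lambda z: -eval_vm(z, shape),
            bounds=(1e-6, 20 * MM),
            method="bounded",
            options={"xatol": 1e-12},
        )
        assert res.x == pytest.approx(3.0 / shape.lambda_shape, rel=1e-5)
        assert -res.fun == pytest.approx(96.0 * 27.0 * math.exp(-3.0) * 1e-3 - 80e-3, rel=1e-6)

    def test_current_density_roots_and_signs(self, shape):
        lam = shape.lambda_shape
        assert eval_im(0.0, shape) == 0.0
        for root in ((3 - math.sqrt(3)) / lam, (3 + math.sqrt(3)) / lam):
            assert eval_im(root, shape) == pytest.approx(0.0, abs=1e-9)
        s1, s2, s3 = section_bounds(shape)
        assert eval_im(0.5 * (s1.e + s1.f), shape) > 0
        assert eval_im(0.5 * (s2.e + s2.f), shape) < 0
        assert eval_im(s3.e + 1.0 / lam, shape) > 0

    def test_current_density_is_second_derivative_of_vm(self, shape):
        # core-conductor consistency: I_m = V'' / r, checked numerically
        z = np.linspace(0.2 * MM, 8 * MM, 25)
        h = 1e-7
        vpp = (eval_vm(z + h, shape) - 2 * eval_vm(z, shape) + eval_vm(z - h, shape)) / h**2
        np.testing.assert_allclose(eval_im(z, shape) * shape.r_axial_sum, vpp, rtol=1e-4)


class TestSections:
    def test_bounds_scale_inversely_with_lambda(self):
        a = section_bounds(ActionPotentialShape())
        b = section_bounds(ActionPotentialShape(lambda_shape=2e3))
        for sa, sb in zip(a, b):
            assert sb.e == pytest.approx(sa.e / 2)
            if math.isfinite(sa.f):
                assert sb.f == pytest.approx(sa.f / 2)

    def test_contiguous_and_ordered(self, shape):
        s1, s2, s3 = section_bounds(shape)
        assert s1.e == 0.0
        assert s1.f == s2.e
        assert s2.f == s3.e
        assert math.isinf(s3.f)
        assert s1.f == pytest.approx((3 - math.sqrt(3)) / shape.lambda_shape)
        assert s2.f == pytest.approx((3 + math.sqrt(3)) / shape.lambda_shape)


class TestConcentratedSource:
    def test_currents_balance_and_match_quadrature(self, shape):
        secs = section_bounds(shape)
        total = 0.0
        for s in secs:
            cur, cen = concentrated_source(s, shape)
            hi = s.f if math.isfinite(s.f) else 60.0 / shape.lambda_shape
            q, _ = quad(lambda z: eval_im(z, shape), s.e, hi, limit=200)
            assert cur == pytest.approx(q, rel=1e-8)
            assert s.e <= cen <= hi
            total += cur
        scale = max(abs(concentrated_source(s, shape)[0]) for s in secs)
        assert abs(total) < 1e-9 * scale

    def test_centroid_matches_weighted_quadrature(self, shape):
        for s in section_bounds(shape):
            cur, cen = concentrated_source(s, shape)
            hi = s.f if math.isfinite(s.f) else 60.0 / shape.lambda_shape
            num, _ = quad(lambda z: z * eval_im(z, shape), s.e, hi, limit=200)
            assert cen == pytest.approx(num / cur, rel=1e-8)

    def test_degenerate_section(self, shape):
        from semgiz.source_model import SectionBounds

        cur, cen = concentrated_source(SectionBounds(1 * MM, 1 * MM, "I"), shape)
        assert cur == 0.0 and cen == 1 * MM

    def test_amplitude_scaling(self, shape):
        doubled = ActionPotentialShape(a=2 * shape.a)
        for s, sd in zip(section_bounds(shape), section_bounds(doubled)):
            c1, p1 = concentrated_source(s, shape)
            c2, p2 = concentrated_source(sd, doubled)
            assert c2 == pytest.approx(2 * c1, rel=1e-12)
            assert p2 == pytest.approx(p1, rel=1e-12)


class TestTravelBounds:
    def test_emergence_is_zero_width_at_the_innervation_point(self, shape, symmetric_fiber):
        for side in ("left", "right"):
            for s in section_bounds(shape):
                lo, hi = travel_bounds(s, 0.0, symmetric_fiber, side)
                assert lo == hi == symmetric_fiber.innervation_coord

    def test_mid_travel_equals_unclamped_translation(self, shape, symmetric_fiber):
        s1 = section_bounds(shape)[0]
        t = 5e-3  # 20 mm of travel, interval fully interior
        shift = symmetric_fiber.innervation_coord - symmetric_fiber.cv * t
        lo, hi = travel_bounds(s1, t, symmetric_fiber, "left")
        assert lo == pytest.approx(s1.e + shift)
        assert hi == pytest.approx(s1.f + shift)

    def test_extinction_clamps_to_the_junction(self, shape, symmetric_fiber):
        s1 = section_bounds(shape)[0]
        t = 1.0  # far beyond fiber transit time
        lo, hi = travel_bounds(s1, t, symmetric_fiber, "left")
        assert lo == hi == 0.0
        lo, hi = travel_bounds(s1, t, symmetric_fiber, "right")
        assert lo == hi == symmetric_fiber.length


class TestTripoleState:
    def test_all_currents_zero_at_onset(self, shape, symmetric_fiber):
        for side in ("left", "right"):
            st = tripole_state(0.0, symmetric_fiber, shape, side)
            np.testing.assert_array_equal(st.currents, 0.0)

    def test_fully_emerged_interior_triplet_matches_stationary_sources(
        self, shape, symmetric_fiber
    ):
        # by t = 10 ms the wave has traveled 40 mm: all sections interior and
        # the unemerged tail is below e^-40 of peak, so conservation is exact
        # to numerical precision
        t = 10e-3
        st = tripole_state(t, symmetric_fiber, shape, "left")
        shift = symmetric_fiber.innervation_coord - symmetric_fiber.cv * t
        for k, s in enumerate(section_bounds(shape)):
            cur, cen = concentrated_source(s, shape)
            if math.isfinite(s.f):
                assert st.currents[k] == pytest.approx(cur, rel=1e-9)
                assert st.positions[k] == pytest.approx(cen + shift, rel=1e-9)
        assert abs(st.currents.sum()) < 1e-9 * np.abs(st.currents).max()

    def test_right_side_mirrors_left(self, shape, symmetric_fiber):
        t = np.linspace(0.0, 30e-3, 40)
        cl, pl = tripole_arrays(t, symmetric_fiber, shape, "left")
        cr, pr = tripole_arrays(t, symmetric_fiber, shape, "right")
        ip = symmetric_fiber.innervation_coord
        np.testing.assert_allclose(cr, cl, rtol=1e-12, atol=1e-15)
        np.testing.assert_allclose(pr - ip, ip - pl, rtol=1e-9, atol=1e-12)

    @pytest.mark.parametrize("side", ["left", "right"])
    def test_sections_match_quadrature_through_emergence_and_extinction(
        self, shape, symmetric_fiber, side, rng
    ):
        """Each clamped section current equals adaptive quadrature of the
        translated density, at random times covering all source phases."""
        fiber = symmetric_fiber
        times = rng.uniform(0.0, 1.2 * fiber.length / fiber.cv, size=12)
        for t in times:
            cur, pos = (a[:, 0] for a in tripole_arrays(np.array([t]), fiber, shape, side))
            for k, s in enumerate(section_bounds(shape)):
                lo, hi = travel_bounds(s, t, fiber, side)
                if side == "left":
                    shift = fiber.innervation_coord - fiber.cv * t
                    f = lambda x: eval_im(x - shift, shape)
                else:
                    front = fiber.innervation_coord + fiber.cv * t
                    f = lambda x: eval_im(front - x, shape)
                q, _ = quad(f, lo, hi, limit=300)
                assert cur[k] == pytest.approx(q, rel=1e-8, abs=1e-12)
                assert lo - 1e-12 <= pos[k] <= hi + 1e-12

    def test_positions_stay_inside_the_fiber(self, shape, symmetric_fiber):
        t = np.linspace(0.0, 0.06, 200)
        for side in ("left", "right"):
            _, pos = tripole_arrays(t, symmetric_fiber, shape, side)
            assert pos.min() >= 0.0
            assert pos.max() <= symmetric_fiber.length

    def test_currents_scale_with_amplitude_positions_do_not(self, symmetric_fiber, shape):
        k = 3.7
        scaled = ActionPotentialShape(a=k * shape.a)
        t = np.linspace(0.0, 0.03, 30)
        c1, p1 = tripole_arrays(t, symmetric_fiber, shape, "left")
        c2, p2 = tripole_arrays(t, symmetric_fiber, scaled, "left")
        np.testing.assert_allclose(c2, k * c1, rtol=1e-12)
        np.testing.assert_allclose(p2, p1, rtol=0, atol=1e-12)


def test_invalid_shape_rejected():
    with pytest.raises(ValueError):
        ActionPotentialShape(a=-1.0)
    with pytest.raises(ValueError):
        ActionPotentialShape(b=0.01)
    with pytest.raises(ValueError):
        MuscleFiber((0, 0, 0), 0, 0, 0.1, 0.2, 4.0)
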