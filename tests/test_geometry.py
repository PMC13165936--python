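"""Conic fitting, ellipse conversion, distances and robust fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pupilkit.errors import DegenerateInputError, NonEllipseError
from pupilkit.geometry import (
    ConicCoefficients,
    EllipseGeometry,
    RobustFitConfig,
    conic_to_ellipse,
    ellipse_distances,
    ellipse_to_conic,
    fit_conic_lsq,
    point_ellipse_distance,
    robust_fit_ellipse,
)

from conftest import ellipse_points


def oracle_conic_fit(points):
    """Independent re-implementation of the normalised SVD conic fit.

    Direct formula path: shift to the centroid, scale to RMS radius √2,
    take the smallest-singular-value right singular vector of the
    monomial design matrix, then substitute the transform back through
    the conic symbolically via numpy.polynomial-free algebra.
    """
    p = np.asarray(points, float)
    t = p.mean(0)
    s = np.sqrt(((p - t) ** 2).sum(1).mean() / 2.0)
    q = (p - t) / s
    m = np.stack([q[:, 0] ** 2, q[:, 0] * q[:, 1], q[:, 1] ** 2, q[:, 0], q[:, 1], np.ones(len(q))], 1)
    v = np.linalg.svd(m, full_matrices=True)[2][-1]
    # conic in u-coords; map u = (X - t)/s by explicit substitution
    A, B, C, D, E, F = v
    a = A / s**2
    b = B / s**2
    c = C / s**2
    d = (-2 * A * t[0] - B * t[1]) / s**2 + D / s
    e = (-B * t[0] - 2 * C * t[1]) / s**2 + E / s
    f = (A * t[0] ** 2 + B * t[0] * t[1] + C * t[1] ** 2) / s**2 - (D * t[0] + E * t[1]) / s + F
    w = np.array([a, b, c, d, e, f])
    w /= np.linalg.norm(w)
    for coef in w:
        if coef != 0:
            if coef < 0:
                w = -w
            break
    return w


class TestConicFit:
    def test_unit_circle_octagon(self, octagon_angles):
        pts = np.column_stack([np.cos(octagon_angles), np.sin(octagon_angles)])
        got = fit_conic_lsq(pts).as_array()
        expected = np.array([1, 0, 1, 0, 0, -1]) / np.sqrt(3)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_axis_aligned_ellipse_five_points(self):
        r2 = np.sqrt(2)
        pts = [(2, 0), (-2, 0), (0, 1), (0, -1), (r2, r2 / 2)]
        got = fit_conic_lsq(pts).as_array()
        expected = np.array([1, 0, 4, 0, 0, -4], float)
        expected /= np.linalg.norm(expected)
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_noisy_fit_matches_independent_svd_oracle(self, reference_ellipse, octagon_angles):
        rng = np.random.default_rng(42)
        sigma = 0.01
        pts = ellipse_points(reference_ellipse, octagon_angles)
        pts = pts + rng.normal(0, sigma, pts.shape)
        got = fit_conic_lsq(pts).as_array()
        np.testing.assert_allclose(got, oracle_conic_fit(pts), atol=1e-10)
        # algebraic residual stays at the noise level
        x, y = pts[:, 0], pts[:, 1]
        design = np.stack([x * x, x * y, y * y, x, y, np.ones(len(x))], 1)
        assert np.linalg.norm(design @ got) <= 10 * sigma

    @pytest.mark.parametrize(
        "points",
        [
            [(0, 0), (1, 1), (2, 2), (3, 3), (4, 4)],  # collinear
            [(0, 0), (1, 0), (2, 0), (3, 0)],  # too few
            [(1, 1)] * 6,  # coincident
        ],
    )
    def test_degenerate_inputs_raise(self, points):
        with pytest.raises(DegenerateInputError):
            fit_conic_lsq(points)


class TestConicEllipseConversion:
    def test_unit_circle_conic(self):
        conic = ConicCoefficients(*(np.array([1, 0, 1, 0, 0, -1]) / np.sqrt(3)))
        e = conic_to_ellipse(conic)
        assert e.xc == pytest.approx(0, abs=1e-12)
        assert e.yc == pytest.approx(0, abs=1e-12)
        assert e.a_semi == pytest.approx(1, rel=1e-12)
        assert e.b_semi == pytest.approx(1, rel=1e-12)

    def test_recovers_parameters_from_symbolic_expansion(self):
        """Oracle: expand the rotated-ellipse equation with sympy and feed
        the resulting coefficients through the closed-form conversion."""
        sympy = pytest.importorskip("sympy")
        xc, yc, a, b = 5, 4, 3, 2
        x, y = sympy.symbols("x y")
        phi = sympy.pi / 6
        u = (x - xc) * sympy.cos(phi) + (y - yc) * sympy.sin(phi)
        v = -(x - xc) * sympy.sin(phi) + (y - yc) * sympy.cos(phi)
        poly = sympy.Poly(sympy.expand(u**2 / a**2 + v**2 / b**2 - 1), x, y)
        coef = [
            float(poly.coeff_monomial(m))
            for m in (x**2, x * y, y**2, x, y, 1)
        ]
        e = conic_to_ellipse(ConicCoefficients(*(np.array(coef) / np.linalg.norm(coef))))
        assert e.xc == pytest.approx(xc, abs=1e-9)
        assert e.yc == pytest.approx(yc, abs=1e-9)
        assert e.a_semi == pytest.approx(a, rel=1e-9)
        assert e.b_semi == pytest.approx(b, rel=1e-9)
        assert e.phi == pytest.approx(np.pi / 6, abs=1e-9)

    def test_hyperbola_raises_non_ellipse(self):
        conic = ConicCoefficients(*(np.array([1, 0, -1, 0, 0, -1]) / np.sqrt(3)))
        with pytest.raises(NonEllipseError):
            conic_to_ellipse(conic)

    @given(
        xc=st.floats(-50, 50),
        yc=st.floats(-50, 50),
        a=st.floats(1.0, 30.0),
        ratio=st.floats(0.3, 1.0),
        phi=st.floats(0.01, 3.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_ellipse_conic_roundtrip(self, xc, yc, a, ratio, phi):
        e = EllipseGeometry(xc, yc, a, max(a * ratio, 0.3), phi % np.pi)
        back = conic_to_ellipse(ellipse_to_conic(e))
        assert back.xc == pytest.approx(e.xc, abs=1e-7 * (1 + abs(e.xc)))
        assert back.yc == pytest.approx(e.yc, abs=1e-7 * (1 + abs(e.yc)))
        assert back.a_semi == pytest.approx(e.a_semi, rel=1e-8)
        assert back.b_semi == pytest.approx(e.b_semi, rel=1e-8)


class TestPointEllipseDistance:
    def test_outside_circle(self):
        assert point_ellipse_distance((2, 0), EllipseGeometry(0, 0, 1, 1, 0)) == pytest.approx(1.0)

    def test_centre_distance_is_semi_minor(self):
        assert point_ellipse_distance((0, 0), EllipseGeometry(0, 0, 2, 1, 0)) == pytest.approx(1.0)

    def test_matches_dense_sweep(self):
        ell = EllipseGeometry(0, 0, 2, 1, 0)
        theta = np.linspace(0, 2 * np.pi, 400_000)
        bx, by = 2 * np.cos(theta), np.sin(theta)
        d_sweep = np.hypot(3 - bx, 1 - by).min()
        assert point_ellipse_distance((3, 1), ell) == pytest.approx(d_sweep, abs=1e-6)

    def test_random_points_match_sweep(self):
        rng = np.random.default_rng(7)
        theta = np.linspace(0, 2 * np.pi, 200_000)
        for _ in range(25):
            e = EllipseGeometry(
                rng.uniform(-5, 5), rng.uniform(-5, 5),
                rng.uniform(1, 6), rng.uniform(0.5, 1), rng.uniform(0, np.pi),
            )
            e = EllipseGeometry(e.xc, e.yc, e.a_semi, e.b_semi * e.a_semi, e.phi)
            pts = rng.uniform(-10, 10, (8, 2))
            ca, sa = np.cos(e.phi), np.sin(e.phi)
            bx = e.xc + ca * e.a_semi * np.cos(theta) - sa * e.b_semi * np.sin(theta)
            by = e.yc + sa * e.a_semi * np.cos(theta) + ca * e.b_semi * np.sin(theta)
            got = ellipse_distances(pts, e)
            for p, g in zip(pts, got):
                assert g == pytest.approx(np.hypot(p[0] - bx, p[1] - by).min(), abs=1e-5)

    def test_boundary_point_has_zero_distance(self, reference_ellipse, octagon_angles):
        pts = ellipse_points(reference_ellipse, octagon_angles)
        np.testing.assert_allclose(ellipse_distances(pts, reference_ellipse), 0, atol=1e-10)


class TestRobustFit:
    def test_clean_octagon_keeps_all_points(self, reference_ellipse, octagon_angles):
        pts = ellipse_points(reference_ellipse, octagon_angles)
        res = robust_fit_ellipse(pts)
        assert res.valid
        assert res.inlier_flags.all()
        assert res.n_points_used == 8
        assert res.area_px2 == pytest.approx(6 * np.pi, rel=1e-9)

    def test_radial_outlier_excluded_and_truth_recovered(self, reference_ellipse, octagon_angles):
        """A point displaced radially outward by 0.5·a must fail the α·a₀
        rule; the refit on the remaining exact points recovers the truth."""
        pts = ellipse_points(reference_ellipse, octagon_angles)
        centre = np.array([reference_ellipse.xc, reference_ellipse.yc])
        for i in range(8):
            p2 = pts.copy()
            u = p2[i] - centre
            p2[i] = p2[i] + 0.5 * reference_ellipse.a_semi * u / np.linalg.norm(u)
            res = robust_fit_ellipse(p2)
            assert res.valid
            assert not res.inlier_flags[i]
            assert res.ellipse.a_semi == pytest.approx(3.0, abs=1e-6)
            assert res.ellipse.b_semi == pytest.approx(2.0, abs=1e-6)
            assert res.ellipse.xc == pytest.approx(5.0, abs=1e-6)
            assert res.ellipse.yc == pytest.approx(4.0, abs=1e-6)

    def test_four_points_is_invalid(self):
        res = robust_fit_ellipse([(1, 0), (0, 1), (-1, 0), (0, -1)])
        assert not res.valid
        assert np.isnan(res.area_px2)

    def test_empty_and_nan_inputs_are_invalid_not_errors(self):
        assert not robust_fit_ellipse([]).valid
        assert not robust_fit_ellipse(np.full((8, 2), np.nan)).valid

    def test_outlier_rule_monotone_in_thresholds(self, reference_ellipse, octagon_angles):
        rng = np.random.default_rng(3)
        pts = ellipse_points(reference_ellipse, octagon_angles) + rng.normal(0, 0.05, (8, 2))
        n_prev = -1
        for k in (0.5, 1.0, 1.5, 3.0, 10.0):
            res = robust_fit_ellipse(pts, RobustFitConfig(k_iqr=k))
            assert res.n_points_used >= n_prev
            n_prev = res.n_points_used
        n_prev = -1
        for alpha in (0.05, 0.1, 0.3, 0.9):
            res = robust_fit_ellipse(pts, RobustFitConfig(alpha=alpha))
            assert res.n_points_used >= n_prev
            n_prev = res.n_points_used

    def test_translate_scale_equivariance_on_noisy_points(self):
        """Translation and scaling commute with the fit to 1e-9 even on
        noisy data (the canonical-frame SVD sees identical coordinates)."""
        rng = np.random.default_rng(11)
        ellipse = EllipseGeometry(5.0, 4.0, 3.0, 2.0, np.pi / 6)
        angles = np.deg2rad(np.arange(8) * 45.0)
        pts = ellipse_points(ellipse, angles) + rng.normal(0, 0.3, (8, 2))
        base = robust_fit_ellipse(pts).ellipse
        s, shift = 1.7, np.array([37.5, -12.25])
        got = robust_fit_ellipse(s * pts + shift).ellipse
        assert got.a_semi == pytest.approx(s * base.a_semi, rel=1e-9)
        assert got.b_semi == pytest.approx(s * base.b_semi, rel=1e-9)
        assert got.xc == pytest.approx(s * base.xc + shift[0], rel=1e-9)
        assert got.yc == pytest.approx(s * base.yc + shift[1], rel=1e-9)
        assert got.phi == pytest.approx(base.phi, abs=1e-9)

    @given(
        dx=st.floats(-100, 100),
        dy=st.floats(-100, 100),
        rot=st.floats(0, 3.1),
        scale=st.floats(0.1, 10.0),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_similarity_equivariance(self, dx, dy, rot, scale):
        """Translating/rotating the points moves the fit identically;
        scaling scales the semi-axes and leaves shape alone."""
        ellipse = EllipseGeometry(5.0, 4.0, 3.0, 2.0, np.pi / 6)
        angles = np.deg2rad(np.arange(8) * 45.0)
        pts = ellipse_points(ellipse, angles)
        base = robust_fit_ellipse(pts).ellipse
        c, s = np.cos(rot), np.sin(rot)
        rotation = np.array([[c, -s], [s, c]])
        moved = scale * pts @ rotation.T + [dx, dy]
        got = robust_fit_ellipse(moved).ellipse
        assert got.a_semi == pytest.approx(scale * base.a_semi, rel=1e-9)
        assert got.b_semi == pytest.approx(scale * base.b_semi, rel=1e-9)
        expect_centre = scale * rotation @ [base.xc, base.yc] + [dx, dy]
        assert got.xc == pytest.approx(expect_centre[0], abs=1e-8 * (1 + abs(expect_centre[0])))
        assert got.yc == pytest.approx(expect_centre[1], abs=1e-8 * (1 + abs(expect_centre[1])))

    def test_six_exact_points_two_gross_outliers_recovered(self, reference_ellipse):
        angles = np.deg2rad([0, 50, 110, 160, 220, 300])
        pts = ellipse_points(reference_ellipse, angles)
        centre = np.array([reference_ellipse.xc, reference_ellipse.yc])
        rng = np.random.default_rng(5)
        for _ in range(20):
            extra = ellipse_points(reference_ellipse, rng.uniform(0, 2 * np.pi, 2))
            u = extra - centre
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            outl = extra + rng.uniform(0.5, 1.0, (2, 1)) * reference_ellipse.a_semi * u
            res = robust_fit_ellipse(np.vstack([pts, outl]))
            assert res.valid
            assert not res.inlier_flags[6:].any()
            assert res.ellipse.a_semi == pytest.approx(3.0, abs=1e-6)
            assert res.ellipse.b_semi == pytest.approx(2.0, abs=1e-6)
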