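"""Boundary tracing, ellipse fitting, thickness/g-ratio/diameter measurement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.measure import EllipseModel

import myelometry as m
from myelometry.morphometry import equivalent_diameter_g_ratio

from conftest import ellipse_points, make_annulus_scene


def offset_ellipse_ray_oracle(a, b, t, theta):
    """Analytic ray crossings for an elliptical annulus of uniform width ``t``.

    Returns (d_in, d_out): distances from the ellipse center to the inner
    ellipse and to its outward offset curve along the ray at angle ``theta``
    (ellipse frame). The offset curve is sampled densely and interpolated in
    polar angle.
    """
    d_in = a * b / np.hypot(b * np.cos(theta), a * np.sin(theta))
    phi = np.linspace(0, 2 * np.pi, 40000, endpoint=False)
    nx, ny = b * np.cos(phi), a * np.sin(phi)
    nn = np.hypot(nx, ny)
    px = a * np.cos(phi) + t * nx / nn
    py = b * np.sin(phi) + t * ny / nn
    ang = np.arctan2(py, px) % (2 * np.pi)
    r = np.hypot(px, py)
    order = np.argsort(ang)
    d_out = np.interp(theta % (2 * np.pi), ang[order], r[order], period=2 * np.pi)
    return d_in, float(d_out)


def labeled_annulus(**kwargs):
    spec, axon, image, truth_mask, _ = make_annulus_scene(**kwargs)
    labels = m.label_sheaths(truth_mask)
    assert labels.accepted_ids == [1]
    return spec, axon, labels


class TestTraceBoundaries:
    def test_circular_contours_at_half_pixel_midline(self, annulus_scene):
        _, axon, _, truth_mask, _ = annulus_scene
        labels = m.label_sheaths(truth_mask)
        inner, outer = m.trace_boundaries(labels, 1)
        ri = np.hypot(*(inner - axon.center).T)
        ro = np.hypot(*(outer - axon.center).T)
        # half-pixel midline plus the raster-quantization allowance of the
        # supersampled ring rendering (~0.1 px)
        assert np.all(np.abs(ri - 70.0) <= 0.6)
        assert np.all(np.abs(ro - 100.0) <= 0.6)
        assert abs(ri.mean() - 70.0) < 0.2
        assert abs(ro.mean() - 100.0) < 0.2

    def test_elliptical_inner_contour_residual(self):
        a_in, b_in = 100.0, 60.0
        spec = m.SceneSpec(image_shape=(512, 512), n_axons=0, layer1_depth_px=128, noise_sd=0)
        axon = m.AxonSpec(0, (256.0, 256.0), (a_in, b_in), 0.0, 0.75, 20.0)
        _, truth_mask, _ = m.render_scene([axon], spec)
        labels = m.label_sheaths(truth_mask)
        inner, _ = m.trace_boundaries(labels, 1)
        u = inner[:, 0] - 256.0
        v = inner[:, 1] - 256.0
        # radial offset from the implicit ellipse: (|.|-1) * local ellipse radius
        val = np.hypot(u / a_in, v / b_in)
        ang = np.arctan2(v, u)
        local_r = a_in * b_in / np.hypot(b_in * np.cos(ang), a_in * np.sin(ang))
        rms = np.sqrt(np.mean(((val - 1) * local_r) ** 2))
        assert rms < 0.5

    def test_rejected_id_raises(self, annulus_scene):
        _, _, _, truth_mask, _ = annulus_scene
        labels = m.label_sheaths(truth_mask)
        with pytest.raises(ValueError, match="not an accepted label"):
            m.trace_boundaries(labels, 99)


class TestFitEllipse:
    def test_exact_circle(self):
        fit = m.fit_ellipse(ellipse_points((0, 0), 50, 50, 0.0))
        assert fit.a == pytest.approx(50, abs=0.01)
        assert fit.b == pytest.approx(50, abs=0.01)
        assert fit.residual_rms < 1e-6

    def test_axis_aligned_ellipse(self):
        fit = m.fit_ellipse(ellipse_points((10, -5), 100, 60, 0.0))
        assert fit.a == pytest.approx(100, abs=0.05)
        assert fit.b == pytest.approx(60, abs=0.05)
        assert min(fit.orientation, np.pi - fit.orientation) == pytest.approx(0, abs=1e-6)
        assert fit.center[0] == pytest.approx(10, abs=0.05)
        assert fit.center[1] == pytest.approx(-5, abs=0.05)

    def test_rotated_ellipse_with_jitter(self):
        rng = np.random.default_rng(5)
        pts = ellipse_points((0, 0), 100, 60, np.deg2rad(30), n=72)
        radial = pts / np.hypot(pts[:, 0], pts[:, 1])[:, None]
        pts = pts + radial * rng.uniform(-0.25, 0.25, size=(72, 1))
        fit = m.fit_ellipse(pts)
        assert fit.a == pytest.approx(100, abs=0.5)
        assert fit.b == pytest.approx(60, abs=0.5)
        assert np.rad2deg(fit.orientation) == pytest.approx(30, abs=1.0)

    def test_matches_independent_direct_fit(self):
        # cross-check against scikit-image's EllipseModel on jittered data
        rng = np.random.default_rng(11)
        pts = ellipse_points((40, 70), 80, 55, 1.1, n=60)
        pts = pts + rng.normal(0, 0.2, size=pts.shape)
        fit = m.fit_ellipse(pts)
        model = EllipseModel.from_estimate(pts)
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
        if b > a:
            a, b = b, a
            theta += np.pi / 2
        assert fit.center == pytest.approx((xc, yc), abs=0.05)
        assert fit.a == pytest.approx(a, abs=0.05)
        assert fit.b == pytest.approx(b, abs=0.05)
        assert fit.orientation == pytest.approx(theta % np.pi, abs=0.01)

    def test_too_few_points(self):
        with pytest.raises(m.EllipseFitError, match="underdetermined"):
            m.fit_ellipse(ellipse_points((0, 0), 50, 30, 0.0, n=5))

    def test_collinear_points(self):
        t = np.linspace(0, 1, 20)
        pts = np.column_stack([t, 2 * t + 1])
        with pytest.raises(m.EllipseFitError):
            m.fit_ellipse(pts)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        a=st.floats(20, 120),
        ratio=st.floats(0.3, 1.0),
        theta=st.floats(0, np.pi),
        cr=st.floats(-50, 50),
        cc=st.floats(-50, 50),
    )
    def test_roundtrip_recovers_parameters(self, a, ratio, theta, cr, cc):
        b = max(a * ratio, 5.0)
        fit = m.fit_ellipse(ellipse_points((cr, cc), a, b, theta, n=48))
        assert fit.a == pytest.approx(max(a, b), rel=1e-4)
        assert fit.b == pytest.approx(min(a, b), rel=1e-4)
        assert fit.center[0] == pytest.approx(cr, abs=1e-3)
        assert fit.center[1] == pytest.approx(cc, abs=1e-3)


class TestMeasureThickness:
    def test_circular_annulus_samples(self, annulus_scene):
        _, _, _, truth_mask, _ = annulus_scene
        labels = m.label_sheaths(truth_mask)
        inner, outer = m.trace_boundaries(labels, 1)
        fit = m.fit_ellipse(inner)
        thickness, d_in, d_out = m.measure_thickness(fit, inner, outer)
        assert thickness.shape == (10,)
        assert np.all(np.abs(thickness - 30.0) <= 0.6)
        assert abs(thickness.mean() - 30.0) <= 0.3
        assert d_in.shape == (5,) and d_out.shape == (5,)

    def test_elliptical_annulus_vs_ray_oracle(self):
        a_in, b_in, t = 100.0, 60.0, 20.0
        spec = m.SceneSpec(image_shape=(512, 512), n_axons=0, layer1_depth_px=128, noise_sd=0)
        axon = m.AxonSpec(0, (256.0, 256.0), (a_in, b_in), 0.0, 0.8, t)
        _, truth_mask, _ = m.render_scene([axon], spec)
        labels = m.label_sheaths(truth_mask)
        inner, outer = m.trace_boundaries(labels, 1)
        fit = m.fit_ellipse(inner)
        thickness, _, _ = m.measure_thickness(fit, inner, outer)
        angles = 2 * np.pi * np.arange(10) / 10
        expected = np.array(
            [np.subtract(*offset_ellipse_ray_oracle(a_in, b_in, t, th)[::-1]) for th in angles]
        )
        assert np.all(np.abs(thickness - expected) < 1.0)

    def test_exactly_n_positions_samples(self, annulus_scene):
        _, _, _, truth_mask, _ = annulus_scene
        labels = m.label_sheaths(truth_mask)
        inner, outer = m.trace_boundaries(labels, 1)
        fit = m.fit_ellipse(inner)
        for n in (4, 10, 16):
            thickness, d_in, d_out = m.measure_thickness(fit, inner, outer, n_positions=n)
            assert len(thickness) == n and len(d_in) == n // 2

    def test_broken_ring_raises(self):
        # outer contour covering only the upper half-plane: downward rays miss
        inner = ellipse_points((0, 0), 10, 10, 0.0, n=36)
        t = np.linspace(0, np.pi, 30)
        outer_arc = np.column_stack([20 * np.cos(t), 20 * np.sin(t)])
        fit = m.fit_ellipse(inner)
        with pytest.raises(m.BrokenRingError, match="no outer crossing|misses"):
            m.measure_thickness(fit, inner, outer_arc)


class TestGRatio:
    def test_circular_ratio(self):
        g = m.compute_g_ratio(np.full(5, 140.0), np.full(5, 200.0))
        assert g == pytest.approx(0.700, abs=0.005)

    def test_zero_thickness_is_inverted(self):
        with pytest.raises(m.InvertedRingError, match="inverted ring geometry"):
            m.compute_g_ratio(np.full(5, 140.0), np.full(5, 140.0))

    def test_equivalent_diameter_mode_on_circle(self, annulus_scene):
        _, _, _, truth_mask, _ = annulus_scene
        labels = m.label_sheaths(truth_mask)
        inner, outer = m.trace_boundaries(labels, 1)
        g = equivalent_diameter_g_ratio(inner, outer)
        assert g == pytest.approx(0.7, abs=0.01)

    def test_recovery_vs_ground_truth(self, noiseless_cohort):
        err = np.abs(noiseless_cohort.g_ratio - noiseless_cohort.g_true)
        assert err.mean() < 0.02


class TestDiameterAndUnits:
    def test_circular_lumen_diameter(self):
        assert m.measure_axon_diameter(ellipse_points((0, 0), 50, 50, 0.3)) == pytest.approx(100, abs=0.1)

    def test_short_axis_rule(self):
        pts = ellipse_points((0, 0), 100, 60, 0.7)
        assert m.measure_axon_diameter(pts) == pytest.approx(120, abs=0.5)

    @pytest.mark.parametrize("px,scale,expected", [(1, 12, 12), (0, 12, 0), (2.5, 10, 25), (100, 12, 1200)])
    def test_unit_conversion(self, px, scale, expected):
        assert m.to_physical_units(px, scale) == pytest.approx(expected)

    def test_nonpositive_pixel_size_rejected(self):
        with pytest.raises(ValueError):
            m.to_physical_units(1.0, 0.0)


class TestDemyelinationFlag:
    @pytest.mark.parametrize("g,expected", [(0.85, True), (0.70, False), (0.8, False)])
    def test_strict_threshold(self, g, expected):
        assert m.flag_demyelination(g) is expected

    def test_invalid_g_rejected(self):
        with pytest.raises(ValueError):
            m.flag_demyelination(1.5)


class TestInvariances:
    @staticmethod
    def _measure_mask(mask):
        labels = m.label_sheaths(mask)
        assert len(labels.accepted_ids) == 1
        inner, outer = m.trace_boundaries(labels, 1)
        fit = m.fit_ellipse(inner)
        thickness, d_in, d_out = m.measure_thickness(fit, inner, outer)
        return thickness.mean(), m.compute_g_ratio(d_in, d_out), 2 * fit.b

    def test_outer_always_exceeds_inner(self, noiseless_cohort):
        assert (noiseless_cohort.g_ratio < 1).all()
        assert (noiseless_cohort[[f"t{i}" for i in range(1, 11)]] > 0).all().all()

    def test_rotation_90_invariance(self):
        # a well-resolved sheath in the generator's default ellipticity range
        spec = m.SceneSpec(image_shape=(512, 512), n_axons=0, layer1_depth_px=128, noise_sd=0)
        axon = m.AxonSpec(0, (256.0, 256.0), (95.0, 80.0), 0.4, 0.72, 28.0)
        _, truth_mask, _ = m.render_scene([axon], spec)
        t0, g0, d0 = self._measure_mask(truth_mask)
        t1, g1, d1 = self._measure_mask(np.rot90(truth_mask))
        assert abs(t1 - t0) / t0 < 0.01
        assert abs(g1 - g0) / g0 < 0.01
        assert abs(d1 - d0) / d0 < 0.01

    def test_scale_equivariance(self):
        base = dict(orientation=0.9, g=0.7)
        results = {}
        for s in (1.0, 2.0):
            spec = m.SceneSpec(image_shape=(int(512 * s),) * 2, n_axons=0,
                               layer1_depth_px=128 * s, noise_sd=0)
            r_in = 45.0 * s
            t = r_in * (1 - base["g"]) / base["g"]
            axon = m.AxonSpec(0, (256.0 * s, 256.0 * s), (r_in * 1.2, r_in),
                              base["orientation"], base["g"], t)
            _, truth_mask, _ = m.render_scene([axon], spec)
            results[s] = self._measure_mask(truth_mask)
        t1, g1, d1 = results[1.0]
        t2, g2, d2 = results[2.0]
        assert t2 / t1 == pytest.approx(2.0, rel=0.01)
        assert d2 / d1 == pytest.approx(2.0, rel=0.01)
        assert g2 == pytest.approx(g1, rel=0.01)
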