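"""Shape analysis: polar conversion, Fourier smoothing, axis detection,
curvature and the closed-form volume/area polynomials."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scwhydro.shape import (FourierShape, FullFourierSeries, PolarContour,
                            curvature, detect_av_axis, fourier_smooth,
                            radial_velocity, symmetrise, to_polar, volume_area)
from scwhydro.synthetic import lab_frame_series


def polygon(fn, n=256, centre=(0.0, 0.0)):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = fn(t)
    return np.column_stack([centre[0] + r * np.cos(t),
                            centre[1] + r * np.sin(t)])


class TestToPolar:
    def test_circle_any_centre(self):
        pc = to_polar(polygon(lambda t: 90.0 + 0 * t, centre=(13.0, -7.0)))
        assert np.allclose(pc.radius, 90.0, atol=0.05)
        assert pc.centre_of_mass == pytest.approx((13.0, -7.0), abs=0.05)

    def test_ellipse_semiaxes(self):
        # polar ellipse radius about the centre: r = ab/sqrt((b cos)^2+(a sin)^2)
        a, b = 90.0, 80.0
        pts = polygon(lambda t: a * b / np.hypot(b * np.cos(t), a * np.sin(t)),
                      n=2048)
        pc = to_polar(pts)
        r0 = np.interp(0.0, pc.theta, pc.radius)
        r90 = np.interp(np.pi / 2, pc.theta, pc.radius)
        assert r0 == pytest.approx(90.0, abs=0.1)
        assert r90 == pytest.approx(80.0, abs=0.1)

    def test_coarse_polygon_radius_error(self):
        pc = to_polar(polygon(lambda t: 100.0 + 0 * t, n=64))
        assert np.max(np.abs(pc.radius - 100.0)) / 100.0 < 0.005

    def test_non_star_shaped_rejected(self):
        # U-shaped polygon: rays from the centroid cross the slit walls twice
        outer = [(0, 0), (10, 0), (10, 10), (0, 10)]
        slit = [(6, 10), (6, 2), (4, 2), (4, 10)]
        base = np.array(outer[:2] + [outer[2]] + slit[:2] + slit[2:]
                        + [outer[3]], dtype=float)
        # densify edges so the >=64 point requirement holds
        pts = []
        for i in range(len(base)):
            a, b = base[i], base[(i + 1) % len(base)]
            for f in np.linspace(0, 1, 12, endpoint=False):
                pts.append(a + f * (b - a))
        with pytest.raises(ValueError, match="star-shaped"):
            to_polar(np.array(pts))


class TestFourierSmooth:
    def grid(self, r):
        return PolarContour(theta=np.linspace(0, 2 * np.pi, len(r), endpoint=False),
                            radius=r, centre_of_mass=(0, 0))

    def test_pure_mode_recovered(self):
        t = np.linspace(0, 2 * np.pi, 512, endpoint=False)
        s = fourier_smooth(self.grid(50 + 3 * np.cos(3 * t)))
        assert s.a_cos[3] == pytest.approx(3.0, abs=1e-10)
        assert s.a_cos[0] == pytest.approx(50.0, abs=1e-10)
        others = np.delete(np.concatenate([s.a_cos, s.b_sin]), [0, 3])
        assert np.allclose(others, 0.0, atol=1e-10)

    def test_circle(self):
        s = fourier_smooth(self.grid(np.full(256, 42.0)))
        assert s.a_cos[0] == pytest.approx(42.0)
        assert np.allclose(s.a_cos[1:], 0) and np.allclose(s.b_sin, 0)

    def test_noise_variance_suppression(self, rng):
        # Parseval: keeping 2*6+1 of N real dofs keeps <= 13/N of the noise power
        N = 1024
        noise = rng.normal(0, 1.0, N)
        s = fourier_smooth(self.grid(80 + noise))
        t = np.linspace(0, 2 * np.pi, N, endpoint=False)
        recon = s.radius(t)
        var_kept = np.var(recon - 80)
        assert var_kept <= 13 / N * np.var(noise) * 1.5


class TestAvAxis:
    def make_series(self, orientation):
        from scwhydro.synthetic import ScwParams, generate_shape_series

        p = ScwParams(n_frames=24, frame_interval=420 / 23,
                      orientation=orientation)
        return lab_frame_series(generate_shape_series(p))

    def test_known_orientation_recovered(self):
        alpha = np.deg2rad(30.0)
        found = detect_av_axis(self.make_series(alpha))
        assert found == pytest.approx(alpha, abs=2 * np.pi / 4096 + 1e-4)

    def test_rotation_equivariance(self):
        base = detect_av_axis(self.make_series(0.4))
        shifted = detect_av_axis(self.make_series(0.4 + 0.25))
        assert (shifted - base) % (2 * np.pi) == pytest.approx(0.25, abs=1e-3)

    def test_time_reversal_swaps_poles(self):
        series = self.make_series(1.0)
        fwd = detect_av_axis(series)
        rev = detect_av_axis(series[::-1])
        assert (rev - fwd) % (2 * np.pi) == pytest.approx(np.pi, abs=1e-2)

    def test_static_series_rejected(self):
        s = FullFourierSeries(a_cos=np.array([90.0, 0, 0]), b_sin=np.zeros(3))
        with pytest.raises(ValueError, match="signature"):
            detect_av_axis([s] * 10)


class TestSymmetrise:
    def test_idempotent(self):
        s = FullFourierSeries(a_cos=np.array([90, 1.0, -2.0, 0.5]),
                              b_sin=np.array([0, 0.3, -0.1, 0.2]))
        once = symmetrise(s, 0.7)
        again = symmetrise(FullFourierSeries(a_cos=once.a, b_sin=np.zeros_like(once.a)), 0.0)
        assert np.allclose(once.a, again.a)

    def test_shifted_cosine_recovered(self):
        alpha = 0.6
        k = np.arange(4)
        target = np.array([90, 2.0, -1.5, 0.7])
        s = FullFourierSeries(a_cos=target * np.cos(k * alpha),
                              b_sin=target * np.sin(k * alpha))
        assert np.allclose(symmetrise(s, alpha).a, target, atol=1e-12)

    def test_antisymmetric_content_removed(self):
        s = FullFourierSeries(a_cos=np.array([90.0, 0, 0, 0]),
                              b_sin=np.array([0.0, 1.0, -0.5, 0.25]))
        out = symmetrise(s, 0.0)
        assert np.allclose(out.a[1:], 0.0) and out.a[0] == 90.0


class TestRadialVelocity:
    def test_constant_shapes_zero(self):
        shapes = [FourierShape.sphere(90.0) for _ in range(5)]
        for v in radial_velocity(shapes, 1.0):
            assert np.allclose(v.v_radial, 0.0)

    def test_linear_coefficient_exact_slope(self):
        eps = 0.01
        shapes = []
        for i in range(6):
            a = np.zeros(7)
            a[0] = 90.0
            a[2] = eps * i
            shapes.append(FourierShape(a=a, frame_index=i))
        vels = radial_velocity(shapes, dt=1.0, mode_cutoffs=None)
        th = vels[0].theta
        for v in vels:
            assert np.allclose(v.v_radial, eps * np.cos(2 * th), atol=1e-12)

    def test_kymograph_band_slope(self, scw_params_small, scw_shapes_small,
                                  scw_velocities_small):
        """The surface-velocity kymograph shows one band drifting V->A at
        the imposed angular speed pi/T."""
        p = scw_params_small
        mid = slice(12, 25)  # near-peak frames: band amplitude ~constant
        th = scw_velocities_small[0].theta
        centres = [th[np.argmin(v.v_radial)] for v in scw_velocities_small[mid]]
        t = p.times[:-1][mid] + p.frame_interval / 2
        slope = np.polyfit(t, np.unwrap(centres), 1)[0]
        assert slope == pytest.approx(-np.pi / p.wave_duration, rel=0.1)


class TestCurvature:
    def test_unit_sphere_signs(self):
        prof = curvature(FourierShape.sphere(1.0), np.linspace(0, np.pi, 91))
        assert np.allclose(prof.a_phiphi, -1.0, atol=1e-12)
        assert np.allclose(prof.a_thetatheta, -1.0, atol=1e-12)
        assert np.allclose(prof.H, -1.0) and np.allclose(prof.K, 1.0)

    def test_h_k_identities(self, rng):
        a = np.array([90.0, *rng.uniform(-3, 3, 6)])
        prof = curvature(FourierShape(a=a), np.linspace(0, np.pi, 181))
        assert np.allclose(prof.H, 0.5 * (prof.a_phiphi + prof.a_thetatheta),
                           rtol=1e-15)
        assert np.allclose(prof.K, prof.a_phiphi * prof.a_thetatheta,
                           rtol=1e-15)

    def test_matches_fd_meridian_oracle(self, rng):
        """Independent surface-of-revolution curvature from central
        differences of the meridian curve (rho, z)(theta)."""
        a = np.array([90.0, *rng.uniform(-4, 4, 6)])
        shape = FourierShape(a=a)
        th = np.linspace(0.15, np.pi - 0.15, 301)
        h = 1e-5
        R0, Rp, Rm = (shape.radius(th + d) for d in (0.0, h, -h))
        rho = lambda t: shape.radius(t) * np.sin(t)
        z = lambda t: shape.radius(t) * np.cos(t)
        d = lambda f: (f(th + h) - f(th - h)) / (2 * h)
        dd = lambda f: (f(th + h) - 2 * f(th) + f(th - h)) / h**2
        rp, zp, rpp, zpp = d(rho), d(z), dd(rho), dd(z)
        k_mer = (rp * zpp - zp * rpp) / (rp**2 + zp**2) ** 1.5
        k_par = zp / (rho(th) * np.sqrt(rp**2 + zp**2))
        prof = curvature(shape, th)
        assert np.max(np.abs(prof.a_thetatheta - k_mer)
                      / np.abs(k_mer)) < 1e-3
        assert np.max(np.abs(prof.a_phiphi - k_par) / np.abs(k_par)) < 1e-3

    def test_pole_regularity(self, scw_shapes_small):
        th = np.array([0.0, 1e-12, np.pi - 1e-12, np.pi])
        for shape in scw_shapes_small[::8]:
            prof = curvature(shape, th)
            assert np.all(np.isfinite(prof.a_phiphi))
            assert np.all(np.isfinite(prof.a_thetatheta))

    def test_saddle_in_band_mid_wave(self, scw_shapes_small):
        """As the flattening band passes the equator the surface transiently
        becomes saddle-shaped: K < 0 somewhere in the band region."""
        mid = scw_shapes_small[len(scw_shapes_small) // 2]
        prof = curvature(mid, np.linspace(0.2, np.pi - 0.2, 361))
        assert prof.K.min() < 0

    def test_vanishing_radius_rejected(self):
        shape = FourierShape(a=np.array([1.0, 0.9, -0.9]))  # r(pi) < 0
        with pytest.raises(ValueError, match="positive"):
            curvature(shape, np.linspace(0, np.pi, 50))


class TestVolumeArea:
    def quadrature(self, a):
        th = np.linspace(0, np.pi, 20001)
        r = sum(a[k] * np.cos(k * th) for k in range(len(a)))
        V = 2 * np.pi / 3 * np.trapezoid(r**3 * np.sin(th), th)
        A = 2 * np.pi * np.trapezoid(r**2 * np.sin(th), th)
        return V, A

    def test_sphere_closed_form(self):
        V, A = volume_area(FourierShape.sphere(90.0))
        assert V == pytest.approx(4 / 3 * np.pi * 90**3, rel=1e-14)
        assert A == pytest.approx(4 * np.pi * 90**2, rel=1e-14)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=4, max_size=4))
    def test_polynomials_match_quadrature(self, perturb):
        a = np.array([90.0, *perturb])
        V, A = volume_area(FourierShape(a=a))
        Vq, Aq = self.quadrature(a)
        assert V == pytest.approx(Vq, rel=1e-6)
        assert A == pytest.approx(Aq, rel=1e-6)

    def test_high_modes_warn(self):
        a = np.zeros(7)
        a[0], a[5] = 90.0, 1.0
        with pytest.warns(UserWarning, match="k <= 4"):
            volume_area(FourierShape(a=a))
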