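"""Interior Stokes solver: harmonic decomposition, sphere solve, perturbation."""

import numpy as np
import pytest
from scipy.special import eval_legendre, lpmv

from scwhydro.stokes import (BoundaryCondition, BoundaryHarmonics,
                             decompose_boundary, evaluate, solve_perturbed,
                             solve_sphere)

A_CELL = 90.0
MU = 5.0  # mPa s


def legendre_bc(cx, ct):
    """Boundary velocity from Legendre coefficients (radial, tangential)."""
    ur = lambda th: sum(c * eval_legendre(n, np.cos(th))
                        for n, c in enumerate(cx))
    ut = lambda th: sum(c * lpmv(1, n, np.cos(th))
                        for n, c in enumerate(ct) if n >= 1)
    return ur, ut


class TestDecompose:
    def test_legendre_orthogonality(self):
        ur, _ = legendre_bc([0, 0, 1.0], [])
        h = decompose_boundary((ur, None), n_max=8)
        assert h.x[2] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(np.delete(h.x, 2), 0.0, atol=1e-12)
        assert np.allclose(h.z, 0.0)

    def test_rigid_translation_is_pure_n1(self):
        U = 0.7
        h = decompose_boundary((lambda th: U * np.cos(th),
                                lambda th: -U * np.sin(th)), n_max=8)
        assert h.x[1] == pytest.approx(U, abs=1e-12)
        assert h.y[1] == pytest.approx(0.0, abs=1e-12)  # divergence-free
        assert np.allclose(np.delete(h.x, 1), 0, atol=1e-12)
        assert np.allclose(np.delete(h.y, 1), 0, atol=1e-12)

    def test_zero_velocity_zero_harmonics(self):
        h = decompose_boundary((lambda th: 0 * th, None), n_max=6)
        assert np.allclose(h.x, 0) and np.allclose(h.y, 0)

    def test_monopole_projected_and_reported(self):
        h = decompose_boundary((lambda th: 1.0 + np.cos(th), None), n_max=6)
        assert h.net_flux_x0 == pytest.approx(1.0, abs=1e-10)
        assert h.x[0] == 0.0

    def test_hand_built_monopole_rejected(self):
        x = np.zeros(5)
        x[0] = 1.0
        h = BoundaryHarmonics(x=x, y=np.zeros(5), z=np.zeros(5))
        with pytest.raises(ValueError, match="monopole"):
            solve_sphere(h, MU, A_CELL)


class TestSphereSolve:
    def test_rigid_translation_uniform_interior(self, rng):
        U = 0.2
        h = decompose_boundary((lambda th: U * np.cos(th),
                                lambda th: -U * np.sin(th)), n_max=10)
        sol = solve_sphere(h, MU, A_CELL)
        r = rng.uniform(0, A_CELL, 60)
        th = rng.uniform(0, np.pi, 60)
        f = evaluate(sol, r, th)
        assert np.allclose(f.u_z, U, atol=1e-12)
        assert np.allclose(f.u_x, 0.0, atol=1e-12)
        assert f.p.max() - f.p.min() == pytest.approx(0.0, abs=1e-15)

    def test_zero_boundary_zero_flow(self):
        h = decompose_boundary((lambda th: 0 * th, None), n_max=6)
        sol = solve_sphere(h, MU, A_CELL)
        f = evaluate(sol, [10.0, 50.0], [0.3, 2.0])
        assert np.allclose(f.u_r, 0) and np.allclose(f.p, 0)

    def test_linearity_of_superposed_boundary_conditions(self, rng):
        cx1, ct1 = rng.normal(size=4), rng.normal(size=4)
        cx2, ct2 = rng.normal(size=4), rng.normal(size=4)
        cx1[0] = cx2[0] = 0.0
        sols = []
        for cx, ct in ((cx1, ct1), (cx2, ct2),
                       (cx1 + cx2, np.asarray(ct1) + ct2)):
            h = decompose_boundary(legendre_bc(cx, ct), n_max=8)
            sols.append(solve_sphere(h, MU, A_CELL))
        r = rng.uniform(1, 85, 40)
        th = rng.uniform(0.05, np.pi - 0.05, 40)
        u1 = np.array(sols[0].velocity(r, th))
        u2 = np.array(sols[1].velocity(r, th))
        u12 = np.array(sols[2].velocity(r, th))
        assert np.allclose(u12, u1 + u2, rtol=1e-12, atol=1e-14)
        assert np.allclose(sols[2].pressure(r, th),
                           sols[0].pressure(r, th) + sols[1].pressure(r, th),
                           rtol=1e-12, atol=1e-18)

    def test_boundary_closure(self, rng):
        cx, ct = rng.normal(size=5), rng.normal(size=5)
        cx[0] = 0.0
        ur_f, ut_f = legendre_bc(cx, ct)
        h = decompose_boundary((ur_f, ut_f), n_max=10)
        sol = solve_sphere(h, MU, A_CELL)
        th = np.linspace(0.02, np.pi - 0.02, 257)
        ur, ut = sol.velocity(np.full_like(th, A_CELL), th)
        scale = np.max(np.abs(ur_f(th)))
        assert np.max(np.abs(ur - ur_f(th))) < 5e-3 * scale
        assert np.max(np.abs(ut - ut_f(th))) < 5e-3 * scale

    def test_incompressibility_at_random_points(self, rng):
        cx, ct = rng.normal(size=5), rng.normal(size=5)
        cx[0] = 0.0
        h = decompose_boundary(legendre_bc(cx, ct), n_max=8)
        sol = solve_sphere(h, MU, A_CELL)
        # 4th-order FD divergence in cartesian 3D; the fields are low-order
        # polynomials so the stencil error is far below the tolerance
        x0 = rng.uniform(5, 55, 40)
        z0 = rng.uniform(-55, 55, 40)
        y0 = np.zeros_like(x0)
        hh = 0.05

        def u3(x, y, z):
            rho = np.hypot(x, y)
            r = np.sqrt(x * x + y * y + z * z)
            th = np.arctan2(rho, z)
            ur, ut = sol.velocity(r, th)
            urho = ur * np.sin(th) + ut * np.cos(th)
            uz = ur * np.cos(th) - ut * np.sin(th)
            phi = np.arctan2(y, x)
            return urho * np.cos(phi), urho * np.sin(phi), uz

        div = np.zeros_like(x0)
        for d in range(3):
            def comp(shift):
                q = [x0.copy(), y0.copy(), z0.copy()]
                q[d] += shift
                return u3(*q)[d]

            div += (-comp(2 * hh) + 8 * comp(hh)
                    - 8 * comp(-hh) + comp(-2 * hh)) / (12 * hh)
        umax = np.max(np.hypot(*sol.velocity(np.hypot(x0, z0),
                                             np.arctan2(x0, z0))))
        assert np.max(np.abs(div)) < 1e-6 * umax / A_CELL

    def test_pressure_scales_with_viscosity_and_speed(self, rng):
        cx = [0, 0, 1.0, 0.3]
        h = decompose_boundary(legendre_bc(cx, []), n_max=6)
        r, th = rng.uniform(1, 80, 30), rng.uniform(0, np.pi, 30)
        p1 = solve_sphere(h, MU, A_CELL).pressure(r, th)
        p2 = solve_sphere(h, 2 * MU, A_CELL).pressure(r, th)
        assert np.allclose(p2, 2 * p1, rtol=1e-12)
        h3 = BoundaryHarmonics(x=3 * h.x, y=3 * h.y, z=3 * h.z)
        p3 = solve_sphere(h3, MU, A_CELL).pressure(r, th)
        assert np.allclose(p3, 3 * p1, rtol=1e-12)


class TestFdOracle:
    def test_three_random_bcs_match_fd_solver(self, fd_oracle, rng):
        """Spot check vs the 200x200 streamfunction solve (full 20-BC sweep
        lives in the acceptance suite)."""
        for _ in range(3):
            cx, ct = rng.normal(size=5), rng.normal(size=5)
            cx[0] = 0.0
            h = decompose_boundary(legendre_bc(cx, ct), n_max=8)
            sol = solve_sphere(h, MU, A_CELL)
            assert fd_oracle.relative_l2(sol) < 0.01


class TestPerturbed:
    def make_bc(self, ur_f, ut_f, eps, f_cos):
        th = np.linspace(0, np.pi, 513)
        return BoundaryCondition(
            radius=A_CELL, viscosity=MU, theta=th, u_radial=ur_f(th),
            u_tangential=None if ut_f is None else ut_f(th),
            f_cos=np.asarray(f_cos, float), eps=eps)

    def test_eps_zero_matches_sphere(self, rng):
        cx, ct = rng.normal(size=4), rng.normal(size=4)
        cx[0] = 0.0
        ur_f, ut_f = legendre_bc(cx, ct)
        bc = self.make_bc(ur_f, ut_f, 0.0, [0.0])
        pert = solve_perturbed(bc, n_max=10, k_max_order=2)
        h = decompose_boundary(bc, n_max=10, n_quad=96)
        sol = solve_sphere(h, MU, A_CELL)
        r, th = rng.uniform(1, 85, 30), rng.uniform(0, np.pi, 30)
        assert np.allclose(pert.velocity(r, th), sol.velocity(r, th),
                           rtol=1e-10, atol=1e-14)

    def test_rigid_translation_of_deformed_sphere_uniform(self):
        """Rigid motion must stay uniform inside any no-slip boundary; the
        residual measures the O(eps^3) truncation of the expansion."""
        U, eps = 0.2, 0.1
        # f = P2(cos theta) as a cosine series: (3cos^2-1)/2 = 1/4 + 3/4 cos 2t
        f_cos = [0.25, 0.0, 0.75]
        bc = self.make_bc(lambda th: U * np.cos(th),
                          lambda th: -U * np.sin(th), eps, f_cos)
        pert = solve_perturbed(bc, n_max=14, k_max_order=2)
        rng = np.random.default_rng(7)
        th = rng.uniform(0, np.pi, 80)
        r = rng.uniform(0, 0.85, 80) * A_CELL
        ur, ut = pert.velocity(r, th)
        uz = ur * np.cos(th) - ut * np.sin(th)
        ux = ur * np.sin(th) + ut * np.cos(th)
        dev = max(np.max(np.abs(uz - U)), np.max(np.abs(ux)))
        assert dev < 5 * eps**3 * U

    def test_boundary_residual_decreases_with_order(self):
        """Higher perturbation orders satisfy the no-slip condition on the
        true deformed surface progressively better.

        The forcing is P3 with an f = P2 deformation so the net flux through
        the deformed surface vanishes by parity (the problem stays compatible
        with incompressibility at every order).  The per-order contraction is
        about eps*n for an order-n boundary harmonic.
        """
        eps = 0.1
        f_cos = [0.25, 0.0, 0.75]  # P2 as a cosine series
        bc = self.make_bc(lambda th: 0.1 * eval_legendre(3, np.cos(th)),
                          None, eps, f_cos)
        th = np.linspace(0.05, np.pi - 0.05, 181)
        residuals = []
        for order in (0, 1, 2):
            pert = solve_perturbed(bc, n_max=14, k_max_order=order)
            rb = pert.boundary_radius(th)
            ur, ut = pert.velocity(rb, th)
            target = 0.1 * eval_legendre(3, np.cos(th))
            residuals.append(np.max(np.hypot(ur - target, ut)))
        assert residuals[1] < 0.6 * residuals[0]
        assert residuals[2] < 0.6 * residuals[1]

    def test_eps_too_large_rejected(self):
        bc = self.make_bc(lambda th: np.cos(th), None, 0.5, [0.25, 0, 0.75])
        with pytest.raises(ValueError, match="eps"):
            solve_perturbed(bc, n_max=8, k_max_order=2)


class TestEvaluate:
    def test_origin_for_translation(self):
        h = decompose_boundary((lambda th: np.cos(th),
                                lambda th: -np.sin(th)), n_max=6)
        sol = solve_sphere(h, MU, A_CELL)
        f = evaluate(sol, [0.0], [0.0])
        assert f.u_z[0] == pytest.approx(1.0, abs=1e-12)

    def test_outside_point_rejected(self):
        h = decompose_boundary((lambda th: np.cos(th), None), n_max=4)
        sol = solve_sphere(h, MU, A_CELL)
        with pytest.raises(ValueError, match="inside"):
            evaluate(sol, [A_CELL * 1.2], [0.5])
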