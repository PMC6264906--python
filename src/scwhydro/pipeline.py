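"""End-to-end drivers tying the kinematic, hydrodynamic and fitting stages together."""

from __future__ import annotations

import numpy as np

from .cortex import CortexParams
from .shape import FourierShape, SurfaceVelocity
from .stokes import (BoundaryCondition, PerturbedSolution, decompose_boundary,
                     solve_perturbed, solve_sphere)
from .synthetic import ScwParams, scw_boundary_velocities

__all__ = ["scw_solutions", "pressure_timecourse", "meridian_grid",
           "end_to_end_band_recovery", "residual_comparison"]


def scw_solutions(params: ScwParams, viscosity: float = 5.0,
                  n_max: int = 12, order: int = 2, tangential: bool = True,
                  cortex: CortexParams = None):
    """Solve the interior Stokes problem for every frame pair of a synthetic SCW.

    Returns ``(shapes, velocities, solutions)`` where ``solutions[i]`` is the
    perturbed interior solution for the i-th frame interval (the shape of the
    earlier frame sets the deformed boundary).
    """
    shapes, vels = scw_boundary_velocities(params, tangential=tangential,
                                           cortex=cortex)
    sols = []
    for shape, sv in zip(shapes[:-1], vels):
        bc = BoundaryCondition.from_surface_velocity(sv, shape, viscosity)
        if order == 0 or bc.eps == 0:
            harm = decompose_boundary(bc, n_max=n_max)
            sols.append(solve_sphere(harm, viscosity, bc.radius))
        else:
            sols.append(solve_perturbed(bc, n_max=n_max, k_max_order=order))
    return shapes, vels, sols


def meridian_grid(radius: float, n_r: int = 40, n_theta: int = 80,
                  r_max_frac: float = 0.98):
    """Polar sampling of the meridian half-plane interior (excludes the rim)."""
    r = np.linspace(0.0, r_max_frac * radius, n_r + 1)[1:]
    th = np.linspace(0.0, np.pi, n_theta)
    R, T = np.meshgrid(r, th, indexing="ij")
    return R.ravel(), T.ravel()


def pressure_timecourse(params: ScwParams, viscosity: float = 5.0,
                        n_max: int = 12, order: int = 2,
                        tangential: bool = True,
                        n_r: int = 40, n_theta: int = 80) -> dict:
    """Per-frame interior pressure summaries for a synthetic SCW, in Pa.

    For each frame interval the pressure is evaluated on a meridian grid
    inside the (possibly deformed) boundary; returns arrays of the max-min
    difference and of the max |deviation from the mean| over the grid.
    """
    shapes, vels, sols = scw_solutions(params, viscosity=viscosity, n_max=n_max,
                                       order=order, tangential=tangential)
    p_range = np.empty(len(sols))
    p_dev = np.empty(len(sols))
    for i, sol in enumerate(sols):
        if isinstance(sol, PerturbedSolution):
            rb_fn = sol.boundary_radius
        else:
            rb_fn = lambda th: np.full_like(np.asarray(th, float), sol.radius)
        r, th = meridian_grid(params.cell_radius, n_r=n_r, n_theta=n_theta)
        rb = rb_fn(th)
        keep = r < 0.98 * rb
        p = sol.pressure(r[keep], th[keep])
        p_range[i] = p.max() - p.min()
        p_dev[i] = np.max(np.abs(p - p.mean()))
    return {"shapes": shapes, "velocities": vels, "solutions": sols,
            "p_max_minus_min": p_range, "p_max_abs_dev": p_dev}


def _solve_sphere_bc(sv: SurfaceVelocity, radius: float, viscosity: float,
                     n_max: int = 12):
    harm = decompose_boundary(
        (lambda t, sv=sv: np.interp(t, sv.theta, sv.v_radial),
         lambda t, sv=sv: np.interp(t, sv.theta, sv.v_tangential)),
        n_max=n_max)
    return solve_sphere(harm, viscosity, radius)


def _field_at(sol, pts_xz):
    """(u_x, u_z) of an axisymmetric solution at meridian-plane points."""
    x, z = pts_xz[:, 0], pts_xz[:, 1]
    r = np.minimum(np.hypot(x, z), sol.radius * (1 - 1e-9))
    th = np.arctan2(np.abs(x), z)
    ur, ut = sol.velocity(r, th)
    sgn = np.where(x >= 0, 1.0, -1.0)
    return (ur * np.sin(th) + ut * np.cos(th)) * sgn, ur * np.cos(th) - ut * np.sin(th)


def end_to_end_band_recovery(seed: int = 0, dt_pair: float = 10.0,
                             frame: int = None, n_max: int = 12) -> dict:
    """Full synthetic round trip: flows -> speckle -> PIV -> brute-force fit.

    A mid-wave frame of the default stated-world SCW drives a known interior
    flow (radial surface motion plus a cortical band of known centre and
    strength); speckle frames separated by ``dt_pair`` are rendered, measured
    by windowed cross-correlation PIV, filtered, and the contraction band is
    re-fitted from the vectors.  Returns true and fitted band parameters and
    the fitted CM velocity.
    """
    from .fitting import (band_flow_basis, fit_cm_velocity, fit_contraction)
    from .piv import PivFilters, filter_cascade, piv_pair
    from .synthetic import SpeckleParams, attach_tangential, render_speckle_pair

    params = ScwParams(n_frames=36, frame_interval=12.0, seed=seed)
    shapes, vels = scw_boundary_velocities(params, tangential=False)
    vels_t = attach_tangential(vels, params)
    if frame is None:
        frame = 17  # near mid-wave
    sv = vels_t[frame]
    a = params.cell_radius
    mu = 5.0

    # ground truth: band centre/strength implied by the generator kinematics
    t_mid = params.times[frame] + params.frame_interval / 2
    x0_true = float(params.band_centre_angle(t_mid) / np.pi)
    scale = np.max(np.abs(sv.v_tangential))
    from .cortex import ContractionBand, cortical_velocity
    _, v_unit = cortical_velocity(
        ContractionBand(amplitude=1.0, centre=x0_true), x=sv.theta / np.pi)
    A_true = float(scale / np.max(np.abs(v_unit)))

    sol_full = _solve_sphere_bc(sv, a, mu, n_max)
    sol_radial = _solve_sphere_bc(
        SurfaceVelocity(theta=sv.theta, v_radial=sv.v_radial), a, mu, n_max)

    sp = SpeckleParams(seed=seed)
    img_a, img_b = render_speckle_pair(lambda x, z: _field_at(
        sol_full, np.column_stack([x, z])), sp, dt_pair, cell_radius=a)
    grid = piv_pair(img_a, img_b, window=64, overlap=32, dt=dt_pair,
                    pixel_size=sp.pixel_size)

    c = sp.image_size / 2.0
    yy, xx = np.mgrid[0:sp.image_size, 0:sp.image_size]
    mask = np.hypot(xx - c, yy - c) * sp.pixel_size < 0.92 * a
    grid = filter_cascade(grid, cell_mask=mask, thresholds=PivFilters())

    ok = grid.valid
    pts = np.column_stack([(grid.x[ok] - c) * sp.pixel_size,
                           (c - grid.y[ok]) * sp.pixel_size])
    u_meas = grid.u[ok] * sp.pixel_size / dt_pair
    v_meas = -grid.v[ok] * sp.pixel_size / dt_pair  # image y -> meridian -z

    ur_u, ur_v = _field_at(sol_radial, pts)
    cm = fit_cm_velocity(ur_u, ur_v, u_meas, v_meas, axis_angle=np.pi / 2)
    ur_v_cm = ur_v + cm

    x0_grid = np.arange(0.0, 1.0001, 0.02)
    basis = band_flow_basis(pts, a, mu, x0_grid, n_max=n_max)
    fit = fit_contraction(u_meas, v_meas, ur_u, ur_v_cm, basis, x0_grid)
    return {"x0_true": x0_true, "A_true": A_true, "cm_fitted": cm,
            "fit": fit, "n_valid": int(ok.sum())}


def residual_comparison(params: ScwParams = None, viscosity: float = 5.0,
                        n_max: int = 12, noise_frac: float = 0.05,
                        seed: int = 0, n_points: int = 300) -> dict:
    """Radial vs tangential displacement model residuals per frame.

    'Measured' fields are the full (radial + cortical) interior flows of the
    synthetic wave sampled at random interior points with a small additive
    noise; both models are then fitted exactly as for PIV data.  Returns
    per-frame normalised residuals of both models and the band amplitude
    profile (to locate the mid-wave frames).
    """
    from .fitting import (band_flow_basis, fit_cm_velocity, fit_contraction,
                          normalized_residuals)
    from .synthetic import attach_tangential

    if params is None:
        params = ScwParams(n_frames=36, frame_interval=12.0)
    a = params.cell_radius
    rng = np.random.default_rng(seed)
    rr = a * np.sqrt(rng.uniform(0.02, 0.85, n_points))
    ang = rng.uniform(0, 2 * np.pi, n_points)
    pts = np.column_stack([rr * np.sin(ang), rr * np.cos(ang)])

    shapes, vels = scw_boundary_velocities(params, tangential=False)
    vels_t = attach_tangential(vels, params)
    x0_grid = np.arange(0.0, 1.0001, 0.02)
    basis = band_flow_basis(pts, a, viscosity, x0_grid, n_max=n_max)

    res_radial, res_tangential, amp = [], [], []
    t_mid = params.times[:-1] + params.frame_interval / 2
    for i, (sv_r, sv_t) in enumerate(zip(vels, vels_t)):
        sol_full = _solve_sphere_bc(sv_t, a, viscosity, n_max)
        u_true, v_true = _field_at(sol_full, pts)
        sig = np.sqrt(np.mean(u_true**2 + v_true**2))
        u_meas = u_true + rng.normal(0, noise_frac * sig, n_points)
        v_meas = v_true + rng.normal(0, noise_frac * sig, n_points)

        sol_rad = _solve_sphere_bc(
            SurfaceVelocity(theta=sv_r.theta, v_radial=sv_r.v_radial),
            a, viscosity, n_max)
        ur_u, ur_v = _field_at(sol_rad, pts)
        cm = fit_cm_velocity(ur_u, ur_v, u_meas, v_meas, axis_angle=np.pi / 2)
        ur_v = ur_v + cm
        res_radial.append(normalized_residuals(ur_u, ur_v, u_meas, v_meas))
        fit = fit_contraction(u_meas, v_meas, ur_u, ur_v, basis, x0_grid)
        res_tangential.append(fit.residual)
        amp.append(float(params.amplitude_profile(t_mid[i])))
    return {"radial": np.array(res_radial),
            "tangential": np.array(res_tangential),
            "amplitude": np.array(amp)}
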