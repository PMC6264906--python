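"""Physical summaries: tracer trajectories, mixing, pressure and scale estimates.

Includes the worked scalar estimates used to interpret the hydrodynamics:
the Laplace pressure across the cortex (2 gamma / R), the surface speed
implied by a trans-surface volume flux (dV / (A T)), the cytoplasm/water
viscosity ratio from Stokes-Einstein diffusivities, and the Reynolds number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Trajectory", "integrate_trajectories", "flow_sampler_from_solutions",
    "flow_sampler_from_grids", "pressure_summary", "laplace_pressure",
    "outflow_surface_velocity", "viscosity_ratio", "reynolds_number",
    "mixing_statistics",
]


@dataclass
class Trajectory:
    """A tracer path through the time-dependent flow (meridian-plane um)."""

    seed: tuple[float, float]
    t: np.ndarray
    x: np.ndarray
    z: np.ndarray
    clamped: bool = False

    @property
    def net_displacement(self) -> float:
        return float(np.hypot(self.x[-1] - self.x[0], self.z[-1] - self.z[0]))

    @property
    def path_length(self) -> float:
        return float(np.sum(np.hypot(np.diff(self.x), np.diff(self.z))))


def flow_sampler_from_solutions(solutions, times, boundary_radius=None):
    """Time-interpolating sampler over analytic interior solutions.

    ``solutions[i]`` must expose ``velocity(r, theta)``; ``times`` are the
    frame times.  Outside the (optional) boundary radius the velocity is
    zero and the caller's clamping applies.
    """
    times = np.asarray(times, float)

    def eval_one(sol, x, z):
        r = np.hypot(x, z)
        th = np.arctan2(np.abs(x), z)
        rb = boundary_radius(th) if boundary_radius is not None else getattr(
            sol, "radius", np.inf)
        rc = np.minimum(r, np.asarray(rb) * (1 - 1e-9))
        ur, ut = sol.velocity(rc, th)
        sgn = np.where(x >= 0, 1.0, -1.0)
        ux = (ur * np.sin(th) + ut * np.cos(th)) * sgn
        uz = ur * np.cos(th) - ut * np.sin(th)
        return ux, uz

    def sampler(t, x, z):
        if t <= times[0]:
            return eval_one(solutions[0], x, z)
        if t >= times[-1]:
            return eval_one(solutions[-1], x, z)
        i = int(np.searchsorted(times, t) - 1)
        w = (t - times[i]) / (times[i + 1] - times[i])
        ux0, uz0 = eval_one(solutions[i], x, z)
        ux1, uz1 = eval_one(solutions[i + 1], x, z)
        return (1 - w) * ux0 + w * ux1, (1 - w) * uz0 + w * uz1

    return sampler


def flow_sampler_from_grids(grids, times):
    """Bilinear-in-space, linear-in-time sampler over measured flow grids.

    ``grids`` are :class:`scwhydro.piv.FlowGrid` objects on a common regular
    grid; invalid vectors contribute zero velocity.  Positions are in the
    grids' pixel coordinates, output in um/s converted to the image frame.
    """
    from scipy.interpolate import RegularGridInterpolator

    times = np.asarray(times, float)
    interps = []
    for g in grids:
        xs, ys = g.x[0, :], g.y[:, 0]
        u = np.where(g.valid, g.u_um_s, 0.0)
        v = np.where(g.valid, g.v_um_s, 0.0)
        fu = RegularGridInterpolator((ys, xs), u, bounds_error=False, fill_value=0.0)
        fv = RegularGridInterpolator((ys, xs), v, bounds_error=False, fill_value=0.0)
        interps.append((fu, fv))

    def sampler(t, x, y):
        pts = np.column_stack([np.atleast_1d(y), np.atleast_1d(x)])
        if t <= times[0]:
            i, w = 0, 0.0
        elif t >= times[-1]:
            i, w = len(times) - 2, 1.0
        else:
            i = int(np.searchsorted(times, t) - 1)
            w = (t - times[i]) / (times[i + 1] - times[i])
        fu0, fv0 = interps[i]
        fu1, fv1 = interps[min(i + 1, len(interps) - 1)]
        return ((1 - w) * fu0(pts) + w * fu1(pts),
                (1 - w) * fv0(pts) + w * fv1(pts))

    return sampler


def integrate_trajectories(sampler, seeds, times, max_step_displacement: float = 1.0,
                           boundary_radius=None) -> list[Trajectory]:
    """Advect tracer seeds through a time-dependent flow (midpoint / RK2).

    ``sampler(t, x, z)`` returns the velocity components; substeps between
    stored frames are chosen so no step moves a tracer further than
    ``max_step_displacement`` (um or px, matching the sampler's units).
    Tracers that would leave the domain are clamped to the boundary radius
    and flagged.
    """
    times = np.asarray(times, float)
    seeds = np.asarray(seeds, float)
    X = seeds[:, 0].astype(float).copy()
    Z = seeds[:, 1].astype(float).copy()
    clamped = np.zeros(len(seeds), dtype=bool)
    xs = [X.copy()]
    zs = [Z.copy()]
    for i in range(len(times) - 1):
        t0, t1 = times[i], times[i + 1]
        ux, uz = sampler(t0, X, Z)
        vmax = float(np.max(np.hypot(ux, uz))) + 1e-30
        n_sub = max(1, int(np.ceil(vmax * (t1 - t0) / max_step_displacement)))
        h = (t1 - t0) / n_sub
        for k in range(n_sub):
            t = t0 + k * h
            ux, uz = sampler(t, X, Z)
            xm, zm = X + 0.5 * h * ux, Z + 0.5 * h * uz
            ux, uz = sampler(t + 0.5 * h, xm, zm)
            X, Z = X + h * ux, Z + h * uz
            if boundary_radius is not None:
                r = np.hypot(X, Z)
                th = np.arctan2(np.abs(X), Z)
                rb = np.asarray(boundary_radius(th), float)
                out = r > rb
                if np.any(out):
                    f = rb[out] / r[out]
                    X[out] *= f
                    Z[out] *= f
                    clamped[out] = True
        xs.append(X.copy())
        zs.append(Z.copy())
    xs = np.array(xs)
    zs = np.array(zs)
    return [Trajectory(seed=(seeds[j, 0], seeds[j, 1]), t=times.copy(),
                       x=xs[:, j], z=zs[:, j], clamped=bool(clamped[j]))
            for j in range(len(seeds))]


def pressure_summary(p: np.ndarray) -> tuple[float, float]:
    """(max - min, max |deviation from mean|) of a sampled pressure field, Pa."""
    p = np.asarray(p, float).ravel()
    return float(p.max() - p.min()), float(np.max(np.abs(p - p.mean())))


def laplace_pressure(tension_mN_per_m: float, radius_um: float) -> float:
    """Pressure jump 2 gamma / R across a curved surface, in Pa."""
    if tension_mN_per_m < 0 or radius_um <= 0:
        raise ValueError("tension must be >= 0 and radius positive")
    return 2.0 * tension_mN_per_m * 1e-3 / (radius_um * 1e-6)


def outflow_surface_velocity(delta_V_um3: float, area_um2: float,
                             duration_s: float) -> float:
    """Apparent surface speed v = dV / (A T) of a trans-surface volume flux, um/s."""
    if area_um2 <= 0 or duration_s <= 0:
        raise ValueError("area and duration must be positive")
    return delta_V_um3 / (area_um2 * duration_s)


def viscosity_ratio(D_water: float, D_cyto: float) -> float:
    """mu_cyto / mu_water = D_water / D_cyto (Stokes-Einstein, same tracer)."""
    if D_water <= 0 or D_cyto <= 0:
        raise ValueError("diffusivities must be positive")
    return D_water / D_cyto


def reynolds_number(density_kg_m3: float, speed_um_s: float, length_um: float,
                    viscosity_mPa_s: float) -> float:
    """Re = rho v L / mu for user-supplied characteristic scales."""
    return (density_kg_m3 * speed_um_s * 1e-6 * length_um * 1e-6
            / (viscosity_mPa_s * 1e-3))


def mixing_statistics(trajectories: list[Trajectory],
                      neighbour_radius: float = 10.0) -> tuple[float, float]:
    """(median return ratio, neighbour parallelism) of a trajectory ensemble.

    The return ratio is net displacement over path length per tracer (0 for
    a closed orbit).  Parallelism is the mean cosine similarity of the
    displacement-increment sequences of seed pairs closer than
    ``neighbour_radius``; 1 when nearby tracers move in lockstep.
    """
    if len(trajectories) < 2:
        raise ValueError("need at least two trajectories")
    ratios = []
    for tr in trajectories:
        L = tr.path_length
        ratios.append(tr.net_displacement / L if L > 0 else 0.0)
    sims = []
    for i, ti in enumerate(trajectories):
        for tj in trajectories[i + 1:]:
            d = np.hypot(ti.seed[0] - tj.seed[0], ti.seed[1] - tj.seed[1])
            if d > neighbour_radius or d == 0:
                continue
            di = np.column_stack([np.diff(ti.x), np.diff(ti.z)])
            dj = np.column_stack([np.diff(tj.x), np.diff(tj.z)])
            ni = np.linalg.norm(di, axis=1)
            nj = np.linalg.norm(dj, axis=1)
            ok = (ni > 1e-12) & (nj > 1e-12)
            if not ok.any():
                continue
            sims.append(float(np.mean(np.sum(di[ok] * dj[ok], axis=1)
                                      / (ni[ok] * nj[ok]))))
    parallelism = float(np.mean(sims)) if sims else np.nan
    return float(np.median(ratios)), parallelism
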