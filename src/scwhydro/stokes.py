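"""Analytical interior Stokes flow driven by the motion of a sphere-like boundary.

The creeping-flow (Stokes) problem inside a sphere of radius ``a`` with a
prescribed no-slip surface velocity is solved with the classical
spherical-harmonic series of Lamb, in the interior-regular form: the
velocity is assembled from three families of solid harmonics (pressure,
potential and toroidal),

    u = sum_n [ grad(phi_n) + curl(r chi_n) + A_n r^2 grad(p_n) + B_n r p_n ],
    A_n = (n+3) / (2 mu (n+1)(2n+3)),   B_n = -n / (mu (n+1)(2n+3)),

where the harmonics of order n >= 1 are matched to three scalar surface
fields built from the boundary velocity: its radial component, minus r times
its divergence, and its radial vorticity.  For axisymmetric meridional flow
the toroidal family vanishes and every harmonic reduces to a Legendre
polynomial P_n(cos theta); this axisymmetric fast path is what the module
implements.

Slightly aspherical boundaries r(theta) = a (1 + eps f(theta)) are handled by
a perturbation expansion in eps: each order k > 0 solves a fresh sphere
problem whose boundary data are radial Taylor shifts of the lower orders.

Units: lengths um, velocities um/s, viscosity mPa s, pressures Pa.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import eval_legendre, lpmv

from .shape import FourierShape, SurfaceVelocity

__all__ = [
    "BoundaryCondition",
    "BoundaryHarmonics",
    "SphereSolution",
    "PerturbedSolution",
    "InteriorField",
    "decompose_boundary",
    "solve_sphere",
    "solve_perturbed",
    "evaluate",
]

MPA_S_TO_PA_S = 1e-3


def _dP_dtheta(n: int, x: np.ndarray) -> np.ndarray:
    """d P_n(cos theta) / d theta = P_n^1(cos theta) (Condon-Shortley)."""
    return lpmv(1, n, x)


@dataclass
class BoundaryCondition:
    """No-slip surface velocity on a (slightly deformed) sphere.

    ``u_radial``/``u_tangential`` are samples on ``theta`` (radians, 0 at the
    A-pole).  ``f_cos`` are cosine coefficients of the normalised deformation
    f(theta) (max |f| ~ 1) and ``eps`` its amplitude, so the boundary sits at
    r(theta) = radius * (1 + eps f(theta)).
    """

    radius: float
    viscosity: float  # mPa s
    theta: np.ndarray
    u_radial: np.ndarray
    u_tangential: np.ndarray = None
    f_cos: np.ndarray = None
    eps: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.viscosity <= 0:
            raise ValueError("radius and viscosity must be positive")
        if not 0 <= self.eps < 1:
            raise ValueError("deformation amplitude eps must be in [0, 1)")
        self.theta = np.asarray(self.theta, dtype=float)
        self.u_radial = np.asarray(self.u_radial, dtype=float)
        if self.u_tangential is None:
            self.u_tangential = np.zeros_like(self.u_radial)
        else:
            self.u_tangential = np.asarray(self.u_tangential, dtype=float)
        if self.f_cos is None:
            self.f_cos = np.zeros(1)

    @classmethod
    def from_surface_velocity(cls, sv: SurfaceVelocity, shape: FourierShape,
                              viscosity: float) -> "BoundaryCondition":
        """Build the solver input from a shape and its surface velocity.

        The reference radius is a_0; the deformation amplitude is
        eps = max |r/a0 - 1| with f normalised accordingly.
        """
        a0 = shape.a[0]
        f = shape.a.copy() / a0
        f[0] = 0.0
        eps = float(np.max(np.abs(shape.radius(np.linspace(0, np.pi, 721)) / a0 - 1.0)))
        f_cos = f / eps if eps > 1e-12 else np.zeros_like(f)
        return cls(radius=a0, viscosity=viscosity, theta=sv.theta,
                   u_radial=sv.v_radial, u_tangential=sv.v_tangential,
                   f_cos=f_cos, eps=eps if eps > 1e-12 else 0.0)

    def boundary_radius(self, theta: np.ndarray) -> np.ndarray:
        k = np.arange(len(self.f_cos))
        f = np.cos(np.multiply.outer(np.asarray(theta, float), k)) @ self.f_cos
        return self.radius * (1.0 + self.eps * f)


@dataclass
class BoundaryHarmonics:
    """Legendre coefficients of the three boundary fields X_n, Y_n, Z_n.

    ``x[n]`` multiplies P_n in the radial velocity, ``y[n]`` in -r div(u),
    ``z[n]`` in the radial vorticity (identically zero for axisymmetric
    meridional flow).  ``net_flux_x0`` records the removed monopole.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    net_flux_x0: float = 0.0

    @property
    def n_max(self) -> int:
        return len(self.x) - 1


def decompose_boundary(bc_or_funcs, n_max: int = 12,
                       n_quad: int = None) -> BoundaryHarmonics:
    """Project an axisymmetric surface velocity onto boundary harmonics.

    Accepts a :class:`BoundaryCondition` (samples are interpolated onto
    Legendre-Gauss nodes) or a pair of callables ``(u_r(theta), u_t(theta))``.
    The n = 0 radial monopole (net flux through the surface, non-zero in real
    data because the cell volume is not exactly conserved) is projected out
    and reported, since an interior Stokes flow admits no source term.
    Emits a warning when the top two orders carry more than 10% of the
    boundary energy (aliasing).
    """
    if n_quad is None:
        n_quad = max(64, 4 * n_max)
    xq, wq = leggauss(n_quad)
    thq = np.arccos(xq)
    if isinstance(bc_or_funcs, BoundaryCondition):
        bc = bc_or_funcs
        ur = np.interp(thq, bc.theta, bc.u_radial)
        ut = np.interp(thq, bc.theta, bc.u_tangential)
    else:
        ur_f, ut_f = bc_or_funcs
        ur = np.asarray(ur_f(thq), dtype=float)
        ut = np.zeros_like(ur) if ut_f is None else np.asarray(ut_f(thq), dtype=float)

    x = np.zeros(n_max + 1)
    t = np.zeros(n_max + 1)
    for n in range(n_max + 1):
        Pn = eval_legendre(n, xq)
        x[n] = (2 * n + 1) / 2.0 * np.sum(wq * ur * Pn)
        if n >= 1:
            dPn = _dP_dtheta(n, xq)
            t[n] = (2 * n + 1) / (2.0 * n * (n + 1)) * np.sum(wq * ut * dPn)
    y = np.zeros(n_max + 1)
    n_arr = np.arange(1, n_max + 1)
    y[1:] = -2 * x[1:] + n_arr * (n_arr + 1) * t[1:]

    energy = x[1:] ** 2 / (2 * n_arr + 1) + n_arr * (n_arr + 1) * t[1:] ** 2 / (2 * n_arr + 1)
    tot = energy.sum()
    if tot > 0 and energy[-2:].sum() > 0.10 * tot:
        warnings.warn("boundary velocity is under-resolved at n_max "
                      "(top two orders carry >10% of the energy)", stacklevel=2)
    x0 = float(x[0])
    x[0] = 0.0
    return BoundaryHarmonics(x=x, y=y, z=np.zeros(n_max + 1), net_flux_x0=x0)


@dataclass
class SphereSolution:
    """Lamb-series solution inside an undeformed sphere.

    Stores per order n the solid-harmonic coefficients c_phi[n], c_p[n] such
    that phi_n = c_phi[n] r^n P_n(cos theta) and p_n = c_p[n] r^n P_n.
    """

    c_phi: np.ndarray
    c_p: np.ndarray
    radius: float
    viscosity: float  # mPa s

    @property
    def n_max(self) -> int:
        return len(self.c_phi) - 1

    def _coeff_ur(self) -> tuple[np.ndarray, np.ndarray]:
        """Radial-velocity radial powers: ur = sum (g1 r^{n-1} + g2 r^{n+1}) P_n."""
        mu = self.viscosity * MPA_S_TO_PA_S
        n = np.arange(self.n_max + 1, dtype=float)
        g1 = self.c_phi * n
        with np.errstate(divide="ignore", invalid="ignore"):
            g2 = self.c_p * n / (2 * mu * (2 * n + 3))
        g2[0] = 0.0
        return g1, g2

    def _coeff_ut(self) -> tuple[np.ndarray, np.ndarray]:
        """Meridional-velocity radial powers: ut = sum (h1 r^{n-1} + h2 r^{n+1}) dP_n/dtheta."""
        mu = self.viscosity * MPA_S_TO_PA_S
        n = np.arange(self.n_max + 1, dtype=float)
        h1 = self.c_phi.copy()
        with np.errstate(divide="ignore", invalid="ignore"):
            A = (n + 3) / (2 * mu * (n + 1) * (2 * n + 3))
        A[np.isnan(A)] = 0.0
        h2 = A * self.c_p
        return h1, h2

    def velocity(self, r, theta, d_dr: int = 0):
        """(u_r, u_theta) at (r, theta); ``d_dr`` selects the j-th radial derivative."""
        r = np.asarray(r, dtype=float)
        theta = np.asarray(theta, dtype=float)
        xc = np.cos(theta)
        g1, g2 = self._coeff_ur()
        h1, h2 = self._coeff_ut()
        ur = np.zeros(np.broadcast(r, theta).shape)
        ut = np.zeros_like(ur)
        for n in range(1, self.n_max + 1):
            Pn = eval_legendre(n, xc)
            dPn = _dP_dtheta(n, xc)
            lo = _dpow(r, n - 1, d_dr)
            hi = _dpow(r, n + 1, d_dr)
            ur = ur + (g1[n] * lo + g2[n] * hi) * Pn
            ut = ut + (h1[n] * lo + h2[n] * hi) * dPn
        return ur, ut

    def pressure(self, r, theta):
        """Pressure in Pa (no additive constant: the series starts at n = 1)."""
        r = np.asarray(r, dtype=float)
        xc = np.cos(np.asarray(theta, dtype=float))
        p = np.zeros(np.broadcast(r, xc).shape)
        for n in range(1, self.n_max + 1):
            p = p + self.c_p[n] * r**n * eval_legendre(n, xc)
        return p


def _dpow(r: np.ndarray, p: int, j: int) -> np.ndarray:
    """j-th derivative of r^p (p >= 0)."""
    if j == 0:
        return r**p
    if p < j:
        return np.zeros_like(r)
    c = math.factorial(p) / math.factorial(p - j)
    return c * r ** (p - j)


def solve_sphere(harmonics: BoundaryHarmonics, viscosity: float,
                 radius: float, flux_tol: float = 1e-8) -> SphereSolution:
    """Match the Lamb series to boundary harmonics on a sphere.

    Requires the radial monopole to have been removed (no interior source);
    ``flux_tol`` is relative to the largest harmonic amplitude.
    """
    scale = max(np.max(np.abs(harmonics.x)), np.max(np.abs(harmonics.y)), 1e-300)
    if abs(harmonics.x[0]) > flux_tol * scale and scale > 1e-250:
        # decompose_boundary projects the monopole out; reaching this point
        # means the caller assembled harmonics by hand without doing so
        raise ValueError(
            f"net radial flux X0 = {harmonics.x[0]:.3g} exceeds tolerance: "
            "remove the monopole before solving")
    mu = viscosity * MPA_S_TO_PA_S
    a = radius
    n_max = harmonics.n_max
    c_p = np.zeros(n_max + 1)
    c_phi = np.zeros(n_max + 1)
    for n in range(1, n_max + 1):
        c_p[n] = mu * (2 * n + 3) / (n * a) * (harmonics.y[n] - (n - 1) * harmonics.x[n]) / a**n
        c_phi[n] = a / (2 * n) * ((n + 1) * harmonics.x[n] - harmonics.y[n]) / a**n
    return SphereSolution(c_phi=c_phi, c_p=c_p, radius=a, viscosity=viscosity)


@dataclass
class PerturbedSolution:
    """Perturbation series for a deformed boundary: sum_k eps^k * orders[k]."""

    orders: list
    eps: float
    f_cos: np.ndarray
    radius: float
    viscosity: float

    @property
    def n_max(self) -> int:
        return self.orders[0].n_max

    def f(self, theta) -> np.ndarray:
        k = np.arange(len(self.f_cos))
        return np.cos(np.multiply.outer(np.asarray(theta, float), k)) @ self.f_cos

    def boundary_radius(self, theta) -> np.ndarray:
        return self.radius * (1.0 + self.eps * self.f(theta))

    def velocity(self, r, theta):
        ur = ut = 0.0
        for k, sol in enumerate(self.orders):
            u1, u2 = sol.velocity(r, theta)
            ur = ur + self.eps**k * u1
            ut = ut + self.eps**k * u2
        return ur, ut

    def pressure(self, r, theta):
        return sum(self.eps**k * sol.pressure(r, theta)
                   for k, sol in enumerate(self.orders))


def solve_perturbed(bc: BoundaryCondition, n_max: int = 12,
                    k_max_order: int = 2) -> PerturbedSolution:
    """Solve the interior problem for a slightly deformed sphere.

    Order 0 solves the sphere with the prescribed surface velocity; each
    order k > 0 solves a sphere problem with boundary velocity

        u^(k)|_a = - sum_{j=1..k} (a f)^j / j! * d^j u^(k-j) / dr^j |_a,

    and the fields are summed as sum_k eps^k u^(k).  Warns when successive
    correction magnitudes grow (the expansion is outside its validity range).
    """
    if bc.eps * 1.0 >= 0.3:
        raise ValueError("perturbation expansion requires eps < 0.3")
    a = bc.radius
    nq = max(96, 4 * n_max)
    xq, _ = leggauss(nq)
    thq = np.arccos(xq)
    k_idx = np.arange(len(bc.f_cos))
    f_q = np.cos(np.outer(thq, k_idx)) @ bc.f_cos

    harm0 = decompose_boundary(bc, n_max=n_max, n_quad=nq)
    orders = [solve_sphere(harm0, bc.viscosity, a)]
    norms = [np.max(np.hypot(*orders[0].velocity(np.full_like(thq, a), thq))) + 1e-300]
    for k in range(1, k_max_order + 1):
        ur_k = np.zeros_like(thq)
        ut_k = np.zeros_like(thq)
        for j in range(1, k + 1):
            dur, dut = orders[k - j].velocity(np.full_like(thq, a), thq, d_dr=j)
            fac = (a * f_q) ** j / math.factorial(j)
            ur_k -= fac * dur
            ut_k -= fac * dut
        harm_k = decompose_boundary(
            (lambda th, v=ur_k: np.interp(th, thq[::-1], v[::-1]),
             lambda th, v=ut_k: np.interp(th, thq[::-1], v[::-1])),
            n_max=n_max, n_quad=nq)
        orders.append(solve_sphere(harm_k, bc.viscosity, a))
        norms.append(bc.eps**k * (np.max(np.hypot(ur_k, ut_k)) + 1e-300))
        if k >= 2 and norms[-1] > norms[-2] > norms[-3]:
            warnings.warn(
                f"perturbation corrections are growing (ratios "
                f"{norms[-2] / norms[-3]:.2g}, {norms[-1] / norms[-2]:.2g})",
                stacklevel=2)
    return PerturbedSolution(orders=orders, eps=bc.eps, f_cos=np.asarray(bc.f_cos, float),
                             radius=a, viscosity=bc.viscosity)


@dataclass
class InteriorField:
    """Velocity and pressure sampled on meridian-plane points inside the cell.

    Coordinates: z along the AV-axis (A-pole at +z), x the in-plane
    perpendicular; (r, theta) are the matching spherical coordinates.
    """

    r: np.ndarray
    theta: np.ndarray
    u_r: np.ndarray
    u_theta: np.ndarray
    p: np.ndarray
    perturbation_order: int = 0

    @property
    def x(self) -> np.ndarray:
        return self.r * np.sin(self.theta)

    @property
    def z(self) -> np.ndarray:
        return self.r * np.cos(self.theta)

    @property
    def u_x(self) -> np.ndarray:
        return self.u_r * np.sin(self.theta) + self.u_theta * np.cos(self.theta)

    @property
    def u_z(self) -> np.ndarray:
        return self.u_r * np.cos(self.theta) - self.u_theta * np.sin(self.theta)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "r": self.r, "theta": self.theta, "x": self.x, "z": self.z,
            "u_x": self.u_x, "u_z": self.u_z, "p": self.p,
        })


def evaluate(solution, r, theta, tol: float = 1e-9) -> InteriorField:
    """Closed-form evaluation of a solution at interior points (r, theta).

    Raises for points outside the (possibly deformed) boundary.
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    r, theta = np.broadcast_arrays(r, theta)
    if isinstance(solution, PerturbedSolution):
        rb = solution.boundary_radius(theta)
        order = len(solution.orders) - 1
    else:
        rb = np.full_like(r, solution.radius)
        order = 0
    if np.any(r > rb * (1 + tol)):
        raise ValueError("evaluation points must lie inside the boundary")
    ur, ut = solution.velocity(r, theta)
    p = solution.pressure(r, theta)
    return InteriorField(r=r.copy(), theta=theta.copy(), u_r=ur, u_theta=ut,
                         p=p, perturbation_order=order)
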