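"""Independent finite-difference axisymmetric Stokes oracle.

Solves the interior creeping-flow problem in the Stokes streamfunction
formulation, E^2(E^2 psi) = 0 on the meridian half-disk, with
E^2 = d_rr + (1/r^2)(d_tt - cot(theta) d_t).  The boundary velocity enters
through psi(a, theta) (integral of the radial component) and
d psi/d r |_a (the tangential component, via a ghost-node Thom closure);
psi and E^2 psi vanish on the axis and at the origin for regular flow.
The discretised biharmonic system is factorised once per grid and reused
across boundary conditions.

This route (streamfunction + sparse FD) shares no code or derivation with
the spherical-harmonic solver it cross-checks.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.integrate import cumulative_trapezoid


class FDStokesOracle:
    def __init__(self, radius: float, n_r: int = 200, n_theta: int = 200):
        self.a = radius
        self.n_r, self.n_t = n_r, n_theta
        self.hr = radius / n_r
        self.ht = np.pi / n_theta
        self.r = np.linspace(0.0, radius, n_r + 1)
        self.th = np.linspace(0.0, np.pi, n_theta + 1)
        self._factorise()

    def _idx(self, i, j, f):
        return f * (self.n_r + 1) * (self.n_t + 1) + i * (self.n_t + 1) + j

    def _factorise(self):
        Nr, Nt, hr, ht = self.n_r, self.n_t, self.hr, self.ht
        rows, cols, vals = [], [], []

        def add(r_, c_, v_):
            rows.append(r_)
            cols.append(c_)
            vals.append(v_)

        def e2(i, j, f):
            ri, tj = self.r[i], self.th[j]
            c = np.cos(tj) / np.sin(tj)
            return [
                (self._idx(i - 1, j, f), 1 / hr**2),
                (self._idx(i + 1, j, f), 1 / hr**2),
                (self._idx(i, j, f), -2 / hr**2 - 2 / (ri**2 * ht**2)),
                (self._idx(i, j - 1, f), (1 / ht**2 + c / (2 * ht)) / ri**2),
                (self._idx(i, j + 1, f), (1 / ht**2 - c / (2 * ht)) / ri**2),
            ]

        for i in range(1, Nr):
            for j in range(1, Nt):
                row = self._idx(i, j, 0)  # omega - E2 psi = 0
                add(row, self._idx(i, j, 1), 1.0)
                for cix, cv in e2(i, j, 0):
                    add(row, cix, -cv)
                row = self._idx(i, j, 1)  # E2 omega = 0
                for cix, cv in e2(i, j, 1):
                    add(row, cix, cv)
        for j in range(Nt + 1):
            add(self._idx(0, j, 0), self._idx(0, j, 0), 1.0)
            add(self._idx(Nr, j, 0), self._idx(Nr, j, 0), 1.0)
            add(self._idx(0, j, 1), self._idx(0, j, 1), 1.0)
        for i in range(1, Nr):
            for j in (0, Nt):
                add(self._idx(i, j, 0), self._idx(i, j, 0), 1.0)
                add(self._idx(i, j, 1), self._idx(i, j, 1), 1.0)
        for j in range(Nt + 1):
            row = self._idx(Nr, j, 1)
            if j in (0, Nt):
                add(row, row, 1.0)
                continue
            add(row, row, 1.0)
            add(row, self._idx(Nr - 1, j, 0), -2 / hr**2)
        n = 2 * (Nr + 1) * (Nt + 1)
        M = sp.csr_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
        self._lu = spla.splu(M)

    def solve(self, u_r_boundary: np.ndarray, u_t_boundary: np.ndarray):
        """Streamfunction for boundary velocity samples on self.th."""
        Nr, Nt, hr, ht, a = self.n_r, self.n_t, self.hr, self.ht, self.a
        psi_b = a**2 * cumulative_trapezoid(u_r_boundary * np.sin(self.th),
                                            self.th, initial=0.0)
        dpsidr_b = -a * np.sin(self.th) * u_t_boundary
        b = np.zeros(2 * (Nr + 1) * (Nt + 1))
        for j in range(Nt + 1):
            b[self._idx(Nr, j, 0)] = psi_b[j]
        for j in range(1, Nt):
            c = np.cos(self.th[j]) / np.sin(self.th[j])
            ang = (psi_b[j - 1] * (1 / ht**2 + c / (2 * ht))
                   + psi_b[j + 1] * (1 / ht**2 - c / (2 * ht))
                   - 2 * psi_b[j] / ht**2) / a**2
            b[self._idx(Nr, j, 1)] = -2 * psi_b[j] / hr**2 + 2 * dpsidr_b[j] / hr + ang
        sol = self._lu.solve(b)
        n_nodes = (Nr + 1) * (Nt + 1)
        return sol[:n_nodes].reshape(Nr + 1, Nt + 1)

    def velocities(self, psi: np.ndarray):
        """(u_r, u_theta) from psi by central differences; NaN on the axis."""
        R, T = np.meshgrid(self.r, self.th, indexing="ij")
        ur = np.full_like(psi, np.nan)
        ut = np.full_like(psi, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            ur[:, 1:-1] = (psi[:, 2:] - psi[:, :-2]) / (2 * self.ht)
            ur /= R**2 * np.sin(T)
            ut[1:-1, :] = -(psi[2:, :] - psi[:-2, :]) / (2 * self.hr)
            ut /= R * np.sin(T)
        return ur, ut

    def comparison_mask(self) -> np.ndarray:
        """Interior region where the FD derivatives are trustworthy."""
        R, T = np.meshgrid(self.r, self.th, indexing="ij")
        return (R > 0.1 * self.a) & (R < 0.9 * self.a) & (np.sin(T) > 0.15)

    def relative_l2(self, analytic_solution) -> float:
        """Relative L2 velocity error of an analytic solution vs this FD solve.

        The analytic solution provides the boundary condition; returns
        ||u_FD - u_analytic||_2 / ||u_analytic||_2 over the comparison mask.
        """
        ur_b, ut_b = analytic_solution.velocity(np.full_like(self.th, self.a),
                                                self.th)
        psi = self.solve(ur_b, ut_b)
        ur_fd, ut_fd = self.velocities(psi)
        mask = self.comparison_mask()
        R, T = np.meshgrid(self.r, self.th, indexing="ij")
        ur_an, ut_an = analytic_solution.velocity(R[mask], T[mask])
        num = np.sqrt(np.nansum((ur_fd[mask] - ur_an) ** 2
                                + (ut_fd[mask] - ut_an) ** 2))
        den = np.sqrt(np.sum(ur_an**2 + ut_an**2))
        return float(num / den)
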