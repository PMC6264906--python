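"""Fit the displacement models to measured flow fields.

Two model flavours are compared against PIV measurements frame by frame:

* the *radial displacement model*: interior Stokes flow driven by the radial
  surface velocity, plus a fitted rigid translation of the whole cell along
  the AV-axis (the centre-of-mass drift, the model's single free parameter);
* the *tangential displacement model*: the radial model plus the interior
  flow driven by the cortical velocity of a Gaussian contraction band, whose
  centre and strength are found by exhaustive grid search.

Model quality is scored by the normalised residual: the root-sum-square
model-measurement mismatch divided by the root-sum-square measurement
magnitude (1 for a zero model by construction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cortex import ContractionBand, CortexParams, tangential_boundary
from .stokes import BoundaryHarmonics, decompose_boundary, solve_sphere

__all__ = ["FitResult", "fit_cm_velocity", "fit_contraction",
           "normalized_residuals", "band_flow_basis"]


@dataclass
class FitResult:
    """Per-frame fit of a displacement model."""

    cm_velocity: float = 0.0       # um/s along the AV-axis (+z toward A-pole)
    band_centre: float = np.nan    # x0 in [0, 1]
    band_amplitude: float = 0.0    # um/s per unit cortical response
    residual: float = np.nan       # normalised residual
    model: str = "radial"
    frame_index: int = 0
    on_grid_boundary: bool = False


def normalized_residuals(u_model, v_model, u_meas, v_meas) -> float:
    """sqrt(sum |u_model - u_meas|^2) / sqrt(sum |u_meas|^2) over valid vectors."""
    u_model, v_model = np.asarray(u_model, float), np.asarray(v_model, float)
    u_meas, v_meas = np.asarray(u_meas, float), np.asarray(v_meas, float)
    den = np.sqrt(np.sum(u_meas**2 + v_meas**2))
    if den == 0:
        raise ValueError("measured field is identically zero")
    num = np.sqrt(np.sum((u_model - u_meas) ** 2 + (v_model - v_meas) ** 2))
    return float(num / den)


def fit_cm_velocity(u_model, v_model, u_meas, v_meas,
                    axis_angle: float = 0.0) -> float:
    """Least-squares rigid-translation speed along the AV-axis.

    Inside a no-slip boundary a rigid translation of the whole cell is a
    uniform velocity field, so the optimal shift is the mean projection of
    the model-measurement difference onto the axis direction
    (cos(axis_angle), sin(axis_angle)) in the meridian plane.
    """
    u_meas = np.asarray(u_meas, float).ravel()
    if u_meas.size == 0:
        raise ValueError("no valid vectors to fit")
    du = u_meas - np.asarray(u_model, float).ravel()
    dv = np.asarray(v_meas, float).ravel() - np.asarray(v_model, float).ravel()
    ex, ey = np.cos(axis_angle), np.sin(axis_angle)
    return float(np.mean(du * ex + dv * ey))


def band_flow_basis(points_xz: np.ndarray, radius: float, viscosity: float,
                    x0_grid: np.ndarray, cortex: CortexParams = None,
                    n_max: int = 12):
    """Unit-amplitude interior band flows evaluated at measurement points.

    Returns an array of shape (len(x0_grid), 2, n_points) with (u_x, u_z)
    for a contraction band of unit strength at each candidate centre.  The
    Stokes problem is linear, so the flow for amplitude A is A times these.
    """
    pts = np.asarray(points_xz, float)
    r = np.hypot(pts[:, 0], pts[:, 1])
    th = np.arctan2(np.abs(pts[:, 0]), pts[:, 1])
    r = np.minimum(r, radius * (1 - 1e-9))
    basis = np.empty((len(x0_grid), 2, len(pts)))
    sign_x = np.sign(pts[:, 0])
    sign_x[sign_x == 0] = 1.0
    for i, x0 in enumerate(x0_grid):
        band = ContractionBand(amplitude=1.0, centre=float(x0))
        sv = tangential_boundary(band, cortex)
        harm = decompose_boundary(
            (lambda t: np.zeros_like(t),
             lambda t, sv=sv: np.interp(t, sv.theta, sv.v_tangential)),
            n_max=n_max)
        sol = solve_sphere(harm, viscosity, radius)
        ur, ut = sol.velocity(r, th)
        ux = ur * np.sin(th) + ut * np.cos(th)
        uz = ur * np.cos(th) - ut * np.sin(th)
        basis[i, 0] = ux * sign_x  # mirror the meridian field to x < 0
        basis[i, 1] = uz
    return basis


def fit_contraction(u_meas, v_meas, u_radial_model, v_radial_model,
                    basis: np.ndarray, x0_grid: np.ndarray,
                    amp_grid: np.ndarray = None,
                    frame_index: int = 0) -> FitResult:
    """Brute-force fit of the contraction band centre and strength.

    ``basis`` comes from :func:`band_flow_basis` on the same points as the
    measurements; the radial model (including the fitted CM shift) is held
    fixed.  The (x0, A) pair minimising the RMS model-measurement deviation
    on the exhaustive grid is selected; optima on the grid edge trigger a
    warning.  When no amplitude grid is given, 50 log-spaced values spanning
    three decades around a data-scaled estimate are used.
    """
    du = np.asarray(u_meas, float).ravel() - np.asarray(u_radial_model, float).ravel()
    dv = np.asarray(v_meas, float).ravel() - np.asarray(v_radial_model, float).ravel()
    if amp_grid is None:
        meas_rms = np.sqrt(np.mean(du**2 + dv**2))
        basis_rms = max(np.sqrt(np.mean(basis[:, 0] ** 2 + basis[:, 1] ** 2)), 1e-30)
        a_mid = max(meas_rms / basis_rms, 1e-12)
        amp_grid = a_mid * np.logspace(-1.5, 1.5, 50)
    cost = np.empty((len(x0_grid), len(amp_grid)))
    for i in range(len(x0_grid)):
        bu, bv = basis[i, 0], basis[i, 1]
        for j, A in enumerate(amp_grid):
            cost[i, j] = np.mean((du - A * bu) ** 2 + (dv - A * bv) ** 2)
    i, j = np.unravel_index(np.argmin(cost), cost.shape)
    on_edge = i in (0, len(x0_grid) - 1) or j in (0, len(amp_grid) - 1)
    if on_edge:
        warnings.warn("contraction-band optimum lies on the search-grid edge",
                      stacklevel=2)
    A = float(amp_grid[j])
    res = normalized_residuals(
        np.asarray(u_radial_model, float).ravel() + A * basis[i, 0],
        np.asarray(v_radial_model, float).ravel() + A * basis[i, 1],
        u_meas, v_meas)
    return FitResult(band_centre=float(x0_grid[i]), band_amplitude=A,
                     residual=res, model="tangential", frame_index=frame_index,
                     on_grid_boundary=on_edge)
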