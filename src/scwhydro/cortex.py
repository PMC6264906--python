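"""Tangential cortical flow driven by a localised contraction band.

The cell cortex is treated as a thin viscous film in one dimension (the
meridian, rescaled to x in [0, 1]).  A band of increased active contraction
C(x) drives a flow v(x) obeying

    -dC/dx = d^2 v / dx^2 - b^2 v,

where b = L / l is the ratio of the system length to the hydrodynamic decay
length of the film (default b = 3).  For a Gaussian band
C(x) = A exp(-(x - x0)^2 / s^2) the equation is solved in closed form with
exponential homogeneous solutions and error-function particular integrals.

The poles of an axisymmetric cell are stagnation points, so the Dirichlet
conditions v(0) = v(1) = 0 are enforced exactly; the no-stress pair
v'(0) = v'(1) = 0 would over-determine a second-order equation and is
instead reported as a residual diagnostic (small whenever the band is far
from the poles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .shape import FourierShape, SurfaceVelocity

__all__ = ["ContractionBand", "CortexParams", "cortical_velocity",
           "tangential_boundary"]


@dataclass
class ContractionBand:
    """Gaussian contraction band C(x) = amplitude * exp(-(x - centre)^2 / width^2).

    ``centre`` lives on [0, 1] (0 = A-pole, 1 = V-pole after the angular map);
    the default width is the fitted angular width s = 0.63 rad expressed in
    band coordinates, s / pi.
    """

    amplitude: float = 1.0
    centre: float = 0.5
    width: float = 0.63 / np.pi

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")

    def profile(self, x: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-((x - self.centre) / self.width) ** 2)


@dataclass
class CortexParams:
    """Dimensionless film parameter b = system length / decay length."""

    b: float = 3.0

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("b must be positive")


def cortical_velocity(band: ContractionBand, params: CortexParams = None,
                      x: np.ndarray = None) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form cortical flow profile v(x) on [0, 1].

    Returns ``(x, v)``.  The solution is antisymmetric about the band centre
    for a mid-cell band and points toward the band from both sides (material
    is drawn into the contracting region).
    """
    if params is None:
        params = CortexParams()
    if x is None:
        x = np.linspace(0.0, 1.0, 513)
    x = np.asarray(x, dtype=float)
    A, x0, s, b = band.amplitude, band.centre, band.width, params.b

    pref = A * np.sqrt(np.pi) * s / 4.0

    def v_part(xx):
        # particular integral of v'' - b^2 v = -C'(x); exponents are combined
        # before exponentiating to stay finite for large b*x
        e_m = np.exp(b * b * s * s / 4 - b * (x0 - xx)) * erf((xx - x0) / s + b * s / 2)
        e_p = np.exp(b * b * s * s / 4 + b * (x0 - xx)) * erf((xx - x0) / s - b * s / 2)
        return -pref * (e_m + e_p)

    vp = v_part(x)
    vp0 = float(v_part(np.array([0.0]))[0])
    vp1 = float(v_part(np.array([1.0]))[0])
    M = np.array([[1.0, 1.0], [np.exp(b), np.exp(-b)]])
    c1, c2 = np.linalg.solve(M, [-vp0, -vp1])
    v = vp + c1 * np.exp(b * x) + c2 * np.exp(-b * x)
    return x, v


def end_slope_residuals(band: ContractionBand, params: CortexParams = None,
                        h: float = 1e-6) -> tuple[float, float]:
    """Residual slopes v'(0), v'(1) of the Dirichlet solution (diagnostic)."""
    xs = np.array([0.0, h, 1.0 - h, 1.0])
    _, v = cortical_velocity(band, params, xs)
    return float((v[1] - v[0]) / h), float((v[3] - v[2]) / h)


def tangential_boundary(band: ContractionBand, params: CortexParams = None,
                        theta: np.ndarray = None,
                        shape: FourierShape = None) -> SurfaceVelocity:
    """Meridional surface velocity from a contraction band, as a boundary condition.

    The band coordinate maps linearly onto the polar angle, x = theta / pi
    (the cell is near-spherical, so angle and normalised arc length almost
    coincide).  The physical velocity scale is carried by ``band.amplitude``
    (um/s per unit dimensionless response); doubling the amplitude doubles
    the flow everywhere.
    """
    if theta is None:
        theta = np.linspace(0.0, np.pi, 257)
    theta = np.asarray(theta, dtype=float)
    _, v = cortical_velocity(band, params, theta / np.pi)
    return SurfaceVelocity(theta=theta, v_radial=np.zeros_like(theta),
                           v_tangential=v)
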