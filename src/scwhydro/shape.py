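"""Shape quantification for near-spherical cells from 2D meridian contours.

The cell outline in a meridian plane is expressed in polar coordinates about
its centre of mass, smoothed by Fourier truncation, aligned with the
animal-vegetal (AV) symmetry axis, and symmetrised to a pure cosine series

    r(theta) = sum_{k=0..6} a_k cos(k theta),        theta = 0 at the A-pole.

From this representation the module computes radial surface velocities,
the Weingarten (shape-operator) diagonal, mean and Gaussian curvature of the
axisymmetric 3D surface, and closed-form volume / surface area.

Sign convention: curvatures are computed with the inward-pointing normal, so
a sphere of radius R has principal curvatures -1/R and Gaussian curvature
+1/R^2.  A saddle region therefore shows K < 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PolarContour",
    "FullFourierSeries",
    "FourierShape",
    "CurvatureProfile",
    "SurfaceVelocity",
    "to_polar",
    "fourier_smooth",
    "detect_av_axis",
    "symmetrise",
    "radial_velocity",
    "curvature",
    "volume_area",
]

K_MAX = 6  # highest retained spatial Fourier mode


@dataclass
class PolarContour:
    """Cell outline as radius samples on a uniform angle grid (CM frame).

    theta is the in-plane lab angle on [0, 2pi); radius in micrometres.
    """

    theta: np.ndarray
    radius: np.ndarray
    centre_of_mass: tuple[float, float]
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        if np.any(self.radius <= 0):
            raise ValueError("polar radius must be positive everywhere")
        if np.any(np.diff(self.theta) <= 0):
            raise ValueError("theta grid must be strictly increasing")


@dataclass
class FullFourierSeries:
    """Untruncated-symmetry Fourier outline: cos and sin coefficients, k <= k_max."""

    a_cos: np.ndarray
    b_sin: np.ndarray
    frame_index: int = 0

    @property
    def k_max(self) -> int:
        return len(self.a_cos) - 1

    def radius(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        k = np.arange(self.k_max + 1)
        return (np.cos(np.outer(theta, k)) @ self.a_cos
                + np.sin(np.outer(theta, k)) @ self.b_sin)

    def rotated(self, alpha: float) -> "FullFourierSeries":
        """Series of the same curve with angles measured from lab angle alpha."""
        k = np.arange(self.k_max + 1)
        ca, sa = np.cos(k * alpha), np.sin(k * alpha)
        return FullFourierSeries(
            a_cos=self.a_cos * ca + self.b_sin * sa,
            b_sin=-self.a_cos * sa + self.b_sin * ca,
            frame_index=self.frame_index,
        )


@dataclass
class FourierShape:
    """Symmetrised meridian radius: cosine coefficients a_0..a_6 (micrometres).

    ``orientation`` is the lab-frame angle of the A-pole (radians); all shape
    quantities are computed in the symmetric frame where theta=0 is the A-pole.
    """

    a: np.ndarray
    orientation: float = 0.0
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        if self.a[0] <= 0:
            raise ValueError("mean radius a0 must be positive")
        if np.any(np.abs(self.a[1:]) >= self.a[0]):
            raise ValueError("mode amplitudes must stay below the mean radius")

    @classmethod
    def sphere(cls, radius: float, k_max: int = K_MAX, **kw) -> "FourierShape":
        a = np.zeros(k_max + 1)
        a[0] = radius
        return cls(a=a, **kw)

    def radius(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        k = np.arange(len(self.a))
        return np.cos(np.multiply.outer(theta, k)) @ self.a

    def d_radius(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        k = np.arange(len(self.a))
        return -np.sin(np.multiply.outer(theta, k)) @ (k * self.a)

    def dd_radius(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        k = np.arange(len(self.a))
        return -np.cos(np.multiply.outer(theta, k)) @ (k * k * self.a)


@dataclass
class CurvatureProfile:
    """Weingarten diagonal and scalar curvatures on a polar-angle grid."""

    theta: np.ndarray
    a_phiphi: np.ndarray
    a_thetatheta: np.ndarray
    H: np.ndarray = field(default=None)
    K: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.H is None:
            self.H = 0.5 * (self.a_phiphi + self.a_thetatheta)
        if self.K is None:
            self.K = self.a_phiphi * self.a_thetatheta


@dataclass
class SurfaceVelocity:
    """Axisymmetric surface velocity components on a polar-angle grid (um/s).

    ``v_tangential`` is the meridional component, positive toward
    increasing theta (A-pole to V-pole).
    """

    theta: np.ndarray
    v_radial: np.ndarray
    v_tangential: np.ndarray = None
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.v_radial = np.asarray(self.v_radial, dtype=float)
        if self.v_tangential is None:
            self.v_tangential = np.zeros_like(self.v_radial)
        else:
            self.v_tangential = np.asarray(self.v_tangential, dtype=float)
        if not (np.all(np.isfinite(self.v_radial))
                and np.all(np.isfinite(self.v_tangential))):
            raise ValueError("surface velocities must be finite")

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.v_radial, self.v_tangential)


# ----------------------------------------------------------------- contours


def to_polar(contour, n_theta: int = 512) -> PolarContour:
    """Express a closed contour in polar coordinates about its area centroid.

    The contour (a :class:`scwhydro.contours.Contour` or an (N, 2) point
    array in pixels with known pixel size) is resampled by periodic linear
    interpolation onto a uniform grid of ``n_theta`` angles.  Raises if the
    outline is not star-shaped about the centroid.
    """
    from shapely.geometry import Polygon

    pts = np.asarray(getattr(contour, "points", contour), dtype=float)
    pixel_size = float(getattr(contour, "pixel_size", 1.0))
    frame_index = int(getattr(contour, "frame_index", 0))
    poly = Polygon(pts)
    if not poly.is_valid:
        raise ValueError("contour must be a simple closed polygon")
    cx, cy = poly.centroid.x, poly.centroid.y

    ang = np.arctan2(pts[:, 1] - cy, pts[:, 0] - cx)
    rad = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
    # star-shaped about the centroid <=> the vertex angle winds monotonically
    # through exactly one turn
    ang_u = np.unwrap(ang)
    if ang_u[-1] < ang_u[0]:  # clockwise orientation: flip
        ang_u, rad = -ang_u[::-1], rad[::-1]
    dd = np.diff(ang_u)
    if np.any(dd <= 0):
        j = int(np.argmax(dd <= 0))
        raise ValueError(
            f"contour is not star-shaped about its centroid near angle "
            f"{np.mod(ang_u[j], 2 * np.pi):.3f} rad")
    ang = np.mod(ang_u, 2 * np.pi)
    roll = int(np.argmin(ang))
    ang, rad = np.roll(ang, -roll), np.roll(rad, -roll)
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    ang_ext = np.concatenate([ang, ang[:1] + 2 * np.pi])
    rad_ext = np.concatenate([rad, rad[:1]])
    # shift into [ang[0], ang[0]+2pi) before interpolating
    th_q = ang[0] + np.mod(theta - ang[0], 2 * np.pi)
    r = np.interp(th_q, ang_ext, rad_ext)
    return PolarContour(
        theta=theta,
        radius=r * pixel_size,
        centre_of_mass=(cx * pixel_size, cy * pixel_size),
        frame_index=frame_index,
    )


def fourier_smooth(polar: PolarContour, k_max: int = K_MAX) -> FullFourierSeries:
    """Truncate the radius function to spatial Fourier modes k <= k_max."""
    r = polar.radius
    n = len(r)
    c = np.fft.rfft(r) / n
    a = np.zeros(k_max + 1)
    b = np.zeros(k_max + 1)
    a[0] = c[0].real
    kk = min(k_max, len(c) - 1)
    a[1:kk + 1] = 2 * c[1:kk + 1].real
    b[1:kk + 1] = -2 * c[1:kk + 1].imag
    # account for a grid that does not start at theta = 0
    series = FullFourierSeries(a_cos=a, b_sin=b, frame_index=polar.frame_index)
    if polar.theta[0] != 0.0:
        series = series.rotated(-polar.theta[0])
    return series


def detect_av_axis(series: list[FullFourierSeries], n_grid: int = 4096) -> float:
    """Locate the lab-frame angle of the animal pole from a shape time series.

    The axis orientation (mod pi) minimises the total antisymmetric (sine)
    energy of the outline over the series.  Of the two antipodal candidates,
    the A-pole is the one whose radius extremum (deepest transient deviation)
    occurs *later*: the wave travels from the V-pole to the A-pole, so the
    V-pole shows the earlier extremum.
    """
    k_max = series[0].k_max
    A = np.stack([s.a_cos for s in series])  # (T, k+1)
    B = np.stack([s.b_sin for s in series])
    alphas = np.linspace(0.0, np.pi, n_grid, endpoint=False)
    k = np.arange(k_max + 1)
    ca = np.cos(np.outer(alphas, k))  # (n_grid, k+1)
    sa = np.sin(np.outer(alphas, k))
    # sine coefficient after rotating frame by alpha: -A sin(k a) + B cos(k a)
    b_rot = B[None, :, :] * ca[:, None, :] - A[None, :, :] * sa[:, None, :]
    energy = (b_rot ** 2).sum(axis=(1, 2))
    g = int(np.argmin(energy))
    alpha = alphas[g]
    # parabolic refinement on the energy minimum
    em, e0, ep = energy[(g - 1) % n_grid], energy[g], energy[(g + 1) % n_grid]
    denom = em - 2 * e0 + ep
    if denom > 0:
        alpha += 0.5 * (em - ep) / denom * (alphas[1] - alphas[0])

    r_a = np.array([s.radius(np.array([alpha]))[0] for s in series])
    r_v = np.array([s.radius(np.array([alpha + np.pi]))[0] for s in series])
    dev_a = np.abs(r_a - np.median(r_a))
    dev_v = np.abs(r_v - np.median(r_v))
    if dev_a.max() < 1e-12 and dev_v.max() < 1e-12:
        raise ValueError("no angle exhibits the travelling-wave radius signature")
    t_a, t_v = int(np.argmax(dev_a)), int(np.argmax(dev_v))
    if t_a < t_v:  # wave reached this candidate first: it is the V-pole
        alpha = np.mod(alpha + np.pi, 2 * np.pi)
    return float(np.mod(alpha, 2 * np.pi))


def symmetrise(series: FullFourierSeries, orientation: float) -> FourierShape:
    """Rotate the outline so theta=0 is the A-pole and keep the even part."""
    rot = series.rotated(orientation)
    return FourierShape(a=rot.a_cos.copy(), orientation=float(orientation),
                        frame_index=series.frame_index)


# ------------------------------------------------------------- kinematics


def smooth_coefficients(shapes: list[FourierShape], dt: float,
                        mode_cutoffs=None) -> np.ndarray:
    """Per-mode temporal low-pass of the coefficient traces a_k(t).

    ``mode_cutoffs`` maps mode index k to a cutoff frequency in Hz (array or
    dict); frequencies above the cutoff are zeroed in a hard FFT cutoff.
    ``None`` disables smoothing.
    """
    A = np.stack([s.a for s in shapes])  # (T, K+1)
    if mode_cutoffs is None:
        return A
    T = A.shape[0]
    freqs = np.fft.rfftfreq(T, d=dt)
    out = np.empty_like(A)
    for k in range(A.shape[1]):
        fc = mode_cutoffs[k] if not np.isscalar(mode_cutoffs) else mode_cutoffs
        c = np.fft.rfft(A[:, k])
        c[freqs > fc] = 0.0
        out[:, k] = np.fft.irfft(c, n=T)
    return out


def radial_velocity(shapes: list[FourierShape], dt: float, mode_cutoffs=None,
                    n_theta: int = 256) -> list[SurfaceVelocity]:
    """Radial surface velocity from finite differences of the coefficients.

    v(theta, t) = sum_k (a_k(t+dt) - a_k(t)) cos(k theta) / dt, with the
    coefficient traces optionally low-passed per mode.  Returns one
    :class:`SurfaceVelocity` per frame pair (len(shapes) - 1 entries).
    """
    if len(shapes) < 2:
        raise ValueError("need at least two frames for a velocity")
    A = smooth_coefficients(shapes, dt, mode_cutoffs)
    theta = np.linspace(0.0, np.pi, n_theta)
    k = np.arange(A.shape[1])
    cosk = np.cos(np.outer(theta, k))
    out = []
    for i in range(len(shapes) - 1):
        v = cosk @ ((A[i + 1] - A[i]) / dt)
        out.append(SurfaceVelocity(theta=theta, v_radial=v,
                                   frame_index=shapes[i].frame_index))
    return out


# -------------------------------------------------------------- curvature


def curvature(shape: FourierShape, theta: np.ndarray) -> CurvatureProfile:
    """Weingarten diagonal and H, K of the axisymmetric surface at ``theta``.

    Derivatives of R(theta) are taken analytically from the cosine series.
    With the inward normal, a_phiphi = -(1 - R' cot(theta)/R)/sqrt(R^2+R'^2)
    and a_thetatheta = -(R^2 + 2 R'^2 - R R'')/(R^2+R'^2)^{3/2}; at the poles
    both entries tend to the common umbilic value.
    """
    theta = np.asarray(theta, dtype=float)
    R = shape.radius(theta)
    if np.any(R <= 0):
        raise ValueError("radius must stay positive")
    R1 = shape.d_radius(theta)
    R2 = shape.dd_radius(theta)
    den = np.sqrt(R * R + R1 * R1)
    a_tt = -(R * R + 2 * R1 * R1 - R * R2) / den**3
    sin = np.sin(theta)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_pp = -(1.0 - R1 * np.cos(theta) / (sin * R)) / den
    pole = np.abs(sin) < 1e-9
    if np.any(pole):
        a_pp = np.where(pole, a_tt, a_pp)  # poles are umbilic points
    return CurvatureProfile(theta=theta, a_phiphi=a_pp, a_thetatheta=a_tt)


# ----------------------------------------------------------- volume, area

# Exact quadrature of V = (2 pi / 3) Int r^3 sin(theta) dtheta and
# A = 2 pi Int r^2 sin(theta) dtheta for r = sum_{k<=4} a_k cos(k theta),
# reduced once symbolically to polynomials in the coefficients.
_V_TERMS = [
    (2, (3, 0, 0, 0, 0)), (-2, (2, 0, 1, 0, 0)),
    (-2 / 5, (2, 0, 0, 0, 1)), (2, (1, 2, 0, 0, 0)),
    (-12 / 5, (1, 1, 0, 1, 0)), (14 / 5, (1, 0, 2, 0, 0)),
    (-76 / 35, (1, 0, 1, 0, 1)), (102 / 35, (1, 0, 0, 2, 0)),
    (62 / 21, (1, 0, 0, 0, 2)), (2 / 5, (0, 2, 1, 0, 0)),
    (-26 / 35, (0, 2, 0, 0, 1)), (12 / 7, (0, 1, 1, 1, 0)),
    (28 / 15, (0, 1, 0, 1, 1)), (-18 / 35, (0, 0, 3, 0, 0)),
    (134 / 105, (0, 0, 2, 0, 1)), (-118 / 105, (0, 0, 1, 2, 0)),
    (-1222 / 1155, (0, 0, 1, 0, 2)), (-118 / 165, (0, 0, 0, 2, 1)),
    (-74 / 715, (0, 0, 0, 0, 3)),
]
_A_TERMS = [
    (2, (2, 0, 0, 0, 0)), (-4 / 3, (1, 0, 1, 0, 0)), (-4 / 15, (1, 0, 0, 0, 1)),
    (2 / 3, (0, 2, 0, 0, 0)), (-4 / 5, (0, 1, 0, 1, 0)), (14 / 15, (0, 0, 2, 0, 0)),
    (-76 / 105, (0, 0, 1, 0, 1)), (34 / 35, (0, 0, 0, 2, 0)), (62 / 63, (0, 0, 0, 0, 2)),
]


def volume_area(shape: FourierShape) -> tuple[float, float]:
    """Volume (um^3) and surface area (um^2) from the cosine coefficients.

    The closed forms hold for modes k <= 4; higher modes are dropped with a
    warning.  For a sphere a_0 = R they reduce to 4 pi R^3 / 3 and 4 pi R^2.
    """
    a = shape.a
    if len(a) > 5 and np.any(np.abs(a[5:]) > 1e-12 * max(a[0], 1.0)):
        warnings.warn("volume_area uses modes k <= 4 only; truncating a5, a6",
                      stacklevel=2)
    a = a[:5] if len(a) >= 5 else np.pad(a, (0, 5 - len(a)))
    V = (2 * np.pi / 3) * sum(
        c * np.prod([a[i] ** p for i, p in enumerate(pw)]) for c, pw in _V_TERMS
    )
    A = 2 * np.pi * sum(
        c * np.prod([a[i] ** p for i, p in enumerate(pw)]) for c, pw in _A_TERMS
    )
    return float(V), float(A)
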