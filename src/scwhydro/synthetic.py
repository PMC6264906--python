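"""Synthetic surface-contraction-wave kinematics and speckle imagery.

Stands in for the microscope and for the mesh-based shape simulation: a
Gaussian band of local flattening travels from the vegetal pole (theta = pi)
to the animal pole (theta = 0) at constant angular speed, the cell volume is
held fixed (the interior is incompressible, so an equatorial dip makes the
poles bulge), and the resulting shapes are truncated to cosine modes
k <= 6.  Defaults reproduce the measured regime of the starfish oocyte:
radius 90 um, 7 min pole-to-pole transit, band width s = 0.63 rad, 10% peak
radial deformation and ~0.2 um/s peak surface speed.

Speckle image pairs (yolk-granule-like texture advected by a known interior
flow) provide ground truth for the PIV stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .cortex import ContractionBand, CortexParams, cortical_velocity
from .shape import K_MAX, FourierShape, FullFourierSeries, SurfaceVelocity

__all__ = ["ScwParams", "SpeckleParams", "generate_shape_series",
           "surface_velocity_series", "attach_tangential",
           "scw_boundary_velocities", "render_speckle_pair",
           "lab_frame_series", "render_cell_frame"]

# fraction of the peak band amplitude present while the band sits at a pole;
# keeps the wave visible during onset/arrival, mimicking the persistent
# deformation seen at the animal pole in experiment
_AMPLITUDE_FLOOR = 0.25


@dataclass
class ScwParams:
    """Stated-world parameters of the synthetic contraction wave.

    ``band_width_s`` is the angular width of the *contraction* (tension)
    band, shared with the cortex-flow model.  ``dip_width`` is the width of
    the radius dip the band imprints on the shape; it is narrower than the
    tension band and was calibrated once (0.50 rad) so that, at 10% peak
    deformation and with the k <= 6 truncation, the mid-wave surface
    transiently reaches negative Gaussian curvature (the observed saddle)
    while the peak radial surface speed stays at ~0.2 um/s.
    """

    cell_radius: float = 90.0          # um
    wave_duration: float = 420.0       # s, pole-to-pole transit
    band_width_s: float = 0.63         # rad, contraction-band width
    dip_width: float = 0.50            # rad, width of the radius dip
    peak_deformation_fraction: float = 0.10
    peak_surface_speed: float = 0.2    # um/s, combined radial + tangential
    n_frames: int = 141
    frame_interval: float = 3.0        # s
    orientation: float = 0.0           # lab angle of the A-pole
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_radius <= 0:
            raise ValueError("cell_radius must be positive")
        if self.wave_duration <= 0:
            raise ValueError("wave_duration must be positive")
        if not 0 <= self.peak_deformation_fraction < 1:
            raise ValueError("peak_deformation_fraction must be in [0, 1)")
        if self.n_frames < 2 or self.frame_interval <= 0:
            raise ValueError("need n_frames >= 2 and a positive frame_interval")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def band_centre_angle(self, t) -> np.ndarray:
        """Band centre moves V-pole (pi) to A-pole (0) at constant angular speed."""
        return np.pi * (1.0 - np.clip(np.asarray(t, float) / self.wave_duration, 0, 1))

    def amplitude_profile(self, t) -> np.ndarray:
        """Smooth rise-and-fall of the band amplitude (unit peak)."""
        u = np.clip(np.asarray(t, float) / self.wave_duration, 0, 1)
        return _AMPLITUDE_FLOOR + (1 - _AMPLITUDE_FLOOR) * np.sin(np.pi * u)


@dataclass
class SpeckleParams:
    """Granule texture and camera model for synthetic speckle frames."""

    image_size: int = 640
    pixel_size: float = 0.325          # um / px
    granule_density: float = 0.05      # granules / um^2
    granule_radius_px: float = 2.0     # Gaussian sigma; ~1.3 um diameter blobs
    noise_sd: float = 0.05             # additive Gaussian, units of peak blob intensity
    seed: int = 0


def _dip_field(theta: np.ndarray, centre: float, s: float) -> np.ndarray:
    """Gaussian flattening profile with mirror images so the even extension
    through both poles stays smooth."""
    g = lambda u: np.exp(-(u / s) ** 2)
    return g(theta - centre) + g(theta + centre) + g(theta - (2 * np.pi - centre))


def _project_cosine(r: np.ndarray, theta: np.ndarray, k_max: int = K_MAX) -> np.ndarray:
    a = np.empty(k_max + 1)
    for k in range(k_max + 1):
        w = np.cos(k * theta)
        a[k] = np.trapezoid(r * w, theta) / np.pi * (1.0 if k == 0 else 2.0)
    return a


def generate_shape_series(params: ScwParams) -> list[FourierShape]:
    """Generate the travelling-flattening shape series with fixed volume.

    The deformation scale is calibrated (two fixed-point passes) so that the
    maximum of |r - a| / a over the whole truncated series equals
    ``peak_deformation_fraction``.
    """
    a0 = params.cell_radius
    theta = np.linspace(0.0, np.pi, 1441)
    sin_t = np.sin(theta)
    times = params.times
    scale = 1.0
    for _ in range(3 if params.peak_deformation_fraction > 0 else 1):
        shapes = []
        peak = 0.0
        for i, t in enumerate(times):
            amp = scale * params.peak_deformation_fraction * params.amplitude_profile(t)
            delta = -amp * _dip_field(theta, params.band_centre_angle(t),
                                      params.dip_width)
            r = a0 * (1.0 + delta)
            # volume-preserving rescale: the cytoplasm is incompressible
            V = np.trapezoid(r**3 * sin_t, theta)
            V0 = 2.0 * a0**3
            r = r * (V0 / V) ** (1.0 / 3.0)
            coeffs = _project_cosine(r, theta)
            rk = np.cos(np.outer(theta, np.arange(K_MAX + 1))) @ coeffs
            peak = max(peak, float(np.max(np.abs(rk / a0 - 1.0))))
            shapes.append(FourierShape(a=coeffs, orientation=params.orientation,
                                       frame_index=i))
        if params.peak_deformation_fraction == 0 or peak == 0:
            break
        scale *= params.peak_deformation_fraction / peak
        if abs(peak - params.peak_deformation_fraction) < 1e-4:
            break
    return shapes


def surface_velocity_series(shapes: list[FourierShape],
                            frame_interval: float) -> list[SurfaceVelocity]:
    """Radial surface velocity between consecutive frames (finite differences)."""
    from .shape import radial_velocity

    if len(shapes) < 2:
        raise ValueError("need at least two frames")
    n_modes = {len(s.a) for s in shapes}
    if len(n_modes) != 1:
        raise ValueError("all frames must carry the same number of modes")
    return radial_velocity(shapes, frame_interval)


def attach_tangential(velocities: list[SurfaceVelocity], params: ScwParams,
                      cortex: CortexParams = None) -> list[SurfaceVelocity]:
    """Add the cortical-flow tangential component, scaled to the stated world.

    The band position and relative amplitude follow the generator kinematics;
    the overall tangential scale is set so that the peak *combined* surface
    speed over the series equals ``params.peak_surface_speed`` (the published
    "typical surface movement" figure; pure radial kinematics with a 10%
    deformation over 7 min cap out at roughly half that).
    """
    if cortex is None:
        cortex = CortexParams()
    t_mid = params.times[:-1] + params.frame_interval / 2.0
    profiles = []
    for i, sv in enumerate(velocities):
        band = ContractionBand(amplitude=float(params.amplitude_profile(t_mid[i])),
                               centre=float(params.band_centre_angle(t_mid[i]) / np.pi),
                               width=params.band_width_s / np.pi)
        _, v = cortical_velocity(band, cortex, sv.theta / np.pi)
        profiles.append(v)
    vr_peak = max(float(np.max(np.abs(sv.v_radial))) for sv in velocities)
    vt_peak = max(float(np.max(np.abs(v))) for v in profiles)
    target = params.peak_surface_speed
    if vt_peak == 0:
        sigma = 0.0
    elif vr_peak >= target:
        warnings.warn("radial speed alone exceeds peak_surface_speed; "
                      "tangential component left unscaled")
        sigma = 1.0
    else:
        # max_theta,t sqrt(vr^2 + (sigma vt)^2) = target; monotone in sigma
        lo, hi = 0.0, 2 * target / vt_peak
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            peak = max(float(np.max(np.hypot(sv.v_radial, mid * v)))
                       for sv, v in zip(velocities, profiles))
            lo, hi = (lo, mid) if peak > target else (mid, hi)
        sigma = 0.5 * (lo + hi)
    return [replace(sv, v_tangential=sigma * v)
            for sv, v in zip(velocities, profiles)]


def scw_boundary_velocities(params: ScwParams, tangential: bool = True,
                            cortex: CortexParams = None
                            ) -> tuple[list[FourierShape], list[SurfaceVelocity]]:
    """Full stated-world kinematics: shapes plus surface velocities."""
    shapes = generate_shape_series(params)
    vels = surface_velocity_series(shapes, params.frame_interval)
    if tangential:
        vels = attach_tangential(vels, params, cortex)
    return shapes, vels


def lab_frame_series(shapes: list[FourierShape]) -> list[FullFourierSeries]:
    """Full cos/sin outline series in the lab frame (for axis detection tests)."""
    out = []
    for s in shapes:
        k = np.arange(len(s.a))
        out.append(FullFourierSeries(a_cos=s.a * np.cos(k * s.orientation),
                                     b_sin=s.a * np.sin(k * s.orientation),
                                     frame_index=s.frame_index))
    return out


# ------------------------------------------------------------------ imaging


def _render_granules(pos_px: np.ndarray, sp: SpeckleParams) -> np.ndarray:
    """Paint unit-peak Gaussian blobs at subpixel positions."""
    n = sp.image_size
    img = np.zeros((n, n))
    sig = sp.granule_radius_px
    half = int(np.ceil(4 * sig))
    ax = np.arange(-half, half + 1)
    for cx, cy in pos_px:
        ix, iy = int(round(cx)), int(round(cy))
        if not (-half <= ix < n + half and -half <= iy < n + half):
            continue
        gx = np.exp(-((ix + ax - cx) ** 2) / (2 * sig**2))
        gy = np.exp(-((iy + ax - cy) ** 2) / (2 * sig**2))
        x0, x1 = max(ix - half, 0), min(ix + half + 1, n)
        y0, y1 = max(iy - half, 0), min(iy + half + 1, n)
        img[y0:y1, x0:x1] += np.outer(gy[y0 - (iy - half):y1 - (iy - half)],
                                      gx[x0 - (ix - half):x1 - (ix - half)])
    return img


def render_speckle_pair(flow, sp: SpeckleParams, dt: float, cell_radius: float,
                        piv_window: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Render two speckle frames separated by ``dt`` with granules advected by ``flow``.

    ``flow`` maps meridian-plane positions (um, cell centre at the origin,
    arrays x, z) to velocities (u_x, u_z in um/s); pass ``None`` for a static
    pair.  The image centre is the cell centre; image x is meridian x and
    image y is -z (A-pole up).  Warns when the advection displacement exceeds
    half a PIV interrogation window.
    """
    rng = np.random.default_rng(sp.seed)
    area = np.pi * cell_radius**2
    n_gran = rng.poisson(sp.granule_density * area)
    rr = cell_radius * np.sqrt(rng.uniform(size=n_gran))
    aa = rng.uniform(0, 2 * np.pi, size=n_gran)
    x, z = rr * np.cos(aa), rr * np.sin(aa)

    if flow is None:
        x2, z2 = x, z
    else:
        ux, uz = flow(x, z)
        xm, zm = x + 0.5 * dt * ux, z + 0.5 * dt * uz  # midpoint advection
        ux, uz = flow(xm, zm)
        x2, z2 = x + dt * ux, z + dt * uz
        disp = np.max(np.hypot(x2 - x, z2 - z)) / sp.pixel_size
        if disp > piv_window / 2:
            warnings.warn(f"peak displacement {disp:.1f} px exceeds half a "
                          f"{piv_window} px PIV window")

    c = sp.image_size / 2.0
    to_px = lambda xx, zz: np.column_stack([c + xx / sp.pixel_size,
                                            c - zz / sp.pixel_size])
    img_a = _render_granules(to_px(x, z), sp)
    img_b = _render_granules(to_px(x2, z2), sp)
    if sp.noise_sd > 0:
        img_a = img_a + rng.normal(0, sp.noise_sd, img_a.shape)
        img_b = img_b + rng.normal(0, sp.noise_sd, img_b.shape)
    return img_a, img_b


def render_cell_frame(shape: FourierShape, sp: SpeckleParams,
                      rim_sigma_px: float = 1.5) -> np.ndarray:
    """Bright-cell silhouette image of a shape (for contour-tracking tests).

    Intensity is a smoothed indicator of the cell interior, evaluated from
    the polar outline; the A-pole points up (image y = -z).
    """
    n = sp.image_size
    c = n / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    x_um = (xx - c) * sp.pixel_size
    z_um = (c - yy) * sp.pixel_size
    r = np.hypot(x_um, z_um)
    th = np.arctan2(np.abs(x_um), z_um)  # axisymmetric: meridian angle
    rb = shape.radius(th)
    edge = (rb - r) / (rim_sigma_px * sp.pixel_size)
    return 1.0 / (1.0 + np.exp(-np.clip(edge, -40, 40)))
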