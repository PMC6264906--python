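# Methods

`scwhydro` quantifies a surface contraction wave (SCW) — a travelling band
of cortical flattening that crosses a near-spherical oocyte from the vegetal
(V) to the animal (A) pole — and predicts the cytoplasmic flow and pressure
field the moving surface drives. This note records the models, the
numerical choices, and what the synthetic-data tests do and do not
establish.

## Shape representation

The cell outline in a meridian plane is tracked (active contour on the
Sobel edge of the Gaussian-filtered frame), expressed in polar coordinates
about the area centroid, truncated to spatial Fourier modes k ≤ 6, aligned
with the AV symmetry axis, and symmetrised to a cosine series

    r(θ, t) = Σ_{k=0}^{6} a_k(t) cos(kθ),    θ = 0 at the A-pole.

The AV axis is found as the orientation (mod π) minimising the antisymmetric
(sine) energy of the outline over the whole wave; of the two antipodal
candidates the A-pole is the one whose radius extremum occurs *later*,
because the wave runs V → A. Assuming axisymmetry, the full 3D geometry
follows: the Weingarten (shape-operator) diagonal gives the principal
curvatures (inward-normal sign convention, so a sphere of radius R has
curvatures −1/R and Gaussian curvature K = +1/R²), and volume and surface
area are closed-form polynomials in a₀..a₄ (re-derived symbolically and
property-tested against quadrature to 6 significant digits).

Radial surface velocities are finite differences of the (optionally
per-mode temporally low-passed) coefficients. Temporal smoothing is off by
default: the synthetic series is noise-free, and cutoffs are a per-dataset
choice.

## Interior Stokes solver

The cytoplasm is modelled as an incompressible Newtonian fluid at
Re ≈ 10⁻⁶–10⁻⁴, so each frame is an independent Stokes problem with the
no-slip surface velocity as boundary data. The solver uses the classical
interior spherical-harmonic (Lamb) series: three scalar surface fields —
the radial velocity, −r·div(u), and the radial vorticity (zero for
axisymmetric meridional flow) — are projected onto Legendre polynomials by
Gauss–Legendre quadrature and matched, order by order (n ≥ 1), to pressure,
potential and toroidal solid harmonics. Closed-form evaluation gives
velocity and pressure anywhere inside; pressure is reported both as
max − min and as max |deviation from the volume mean| because either
convention may be meant by a single printed number.

The n = 0 radial monopole (net flux, present in real data because the
apparent volume is not conserved) is projected out before solving and its
magnitude reported: an interior Stokes flow admits no source.

Slightly aspherical boundaries r(θ) = a(1 + εf(θ)), with a := a₀,
ε := max|r/a − 1| (≈ 0.10 here) and max|f| = 1, are handled by a
perturbation expansion: each order k > 0 solves a fresh sphere problem
whose boundary velocity is built from radial Taylor shifts of the lower
orders, and fields are summed as Σ εᵏ u⁽ᵏ⁾. Defaults n_max = 12, k ≤ 2
(truncation O(ε³) ≲ 10⁻³ for 10% deformations). Two caveats established
during testing:

* the per-order contraction is ≈ ε·n for an order-n boundary harmonic, so
  high harmonics on a 10%-deformed boundary converge slowly (ratio ~0.5 at
  n = 3–5); a warning is emitted when corrections grow;
* a boundary condition is only consistent with incompressibility if its net
  flux through the *deformed* surface vanishes; otherwise the series stalls
  at the residual flux level (the monopole of each order is projected out).

The solver is cross-checked against an independent finite-difference
streamfunction solve (E⁴ψ = 0 on a 200×200 meridian grid, ghost-node Thom
closure at the rim): 20 random zero-net-flux boundary conditions agree to
< 1% relative L2 (typically 0.03–0.08%).

## Cortical flow model

The tangential boundary component comes from a 1D viscous-film model of the
cortex: −∂C/∂x = ∂²v/∂x² − b²v on x ∈ [0, 1] (x = θ/π), with a Gaussian
contraction band C(x) = A exp(−(x−x₀)²/s²) and b = L/l = 3. The closed form
uses exponential homogeneous solutions and error-function integrals, and is
verified against `solve_bvp` to 10⁻¹⁰. The Dirichlet pair v(0) = v(1) = 0
(pole stagnation points) is enforced exactly; the additional no-stress pair
stated for symmetry would over-determine a second-order ODE and is reported
as a residual diagnostic instead. Measured robustness: over b ∈ [2, 4] the
amplitude-normalised profile changes by < 3% (the raw amplitude by ~12%,
which the fitted band strength absorbs).

## PIV and filtering

Flow is measured by windowed cross-correlation (64 px windows, 50% overlap
≈ 10 µm vector spacing at 0.325 µm/px), subpixel three-point Gaussian peak
fit, and a peak-to-second-peak SNR with an exclusion half-width of 4 px
(wider than the correlation peak of 1–2 µm granules, otherwise the "second
peak" is the main lobe's shoulder). Outliers are flagged — never edited or
interpolated — by a fixed cascade: normalised local-median test (level 3,
0.2 px floor), global magnitude limit, SNR ≥ 1.3, inside-cell mask, global
per-component 3σ test with a 0.05 px floor. Each stage iterates to a fixed
point, making the whole cascade idempotent; the per-component form of the
σ-test matters because iterating a 3σ cut on the 2D residual *norm*
(Rayleigh-tailed) removes ~15% per pass and erodes clean fields.

## Model fitting

Because Stokes flow is linear, model components superpose. The radial
displacement model is the interior flow of the radial surface velocity plus
one fitted scalar: a rigid translation along the AV axis (closed-form mean
projection of the model–measurement difference — a rigid translation inside
a no-slip boundary is a uniform field). The tangential displacement model
adds the interior flow of a cortical band, with centre x₀ (grid 0..1, step
0.02) and strength (50 log-spaced values over three decades around a
data-scaled estimate) found by exhaustive search minimising the RMS
deviation; grid-edge optima raise a warning. Model quality is the
normalised residual ‖u_model − u_meas‖₂ / ‖u_meas‖₂ (1 for a zero model by
construction). Near-orthogonality of the translation and mid-cell band
fields on the sampling grid (< 10% cross-projection) justifies the
sequential fit.

## Synthetic stated world

The generator emulates the published regime: radius 90 µm, pole-to-pole
transit 420 s, contraction-band width s = 0.63 rad (full width 72°), 10%
peak radial deformation, ~0.2 µm/s peak surface speed, viscosity 5 mPa·s.
Kinematics: a Gaussian dip in local radius travels V → A at constant
angular speed π/T; the cell volume is held exactly constant (incompressible
interior), so an equatorial dip makes the poles bulge — which also produces
the min → max → min pole-radius signature used for axis detection. The band
amplitude follows a smooth rise-and-fall with a 25% floor (the wave is
visible while traversing the poles, mimicking the persistent deformation
observed at the A-pole); the published data constrain only the qualitative
profile. The deformation scale is calibrated so the post-truncation peak
|r − a|/a equals the 10% parameter exactly.

Two coupled calibrations deserve emphasis:

* **Dip width.** The width of the *radius dip* is a separate parameter
  (0.50 rad) from the tension-band width s = 0.63. A 0.63 rad Gaussian dip
  at 10% depth leaves the Gaussian curvature positive everywhere (K < 0
  needs R″ > R, i.e. ~18% depth at that width), contradicting the observed
  transient saddle. 0.50 rad is the unique neighbourhood in which the
  truncated series shows the saddle (min K ≈ −5·10⁻⁵ µm⁻²) *and* the peak
  radial surface speed is 0.199 µm/s, matching the published ~0.2 µm/s.
  This mirrors the published procedure of adjusting the band to reproduce
  the measured curvatures.
* **Tangential scale.** The cortical component is scaled so the peak
  *combined* surface speed equals the 0.2 µm/s parameter (the published
  "typical speed of surface movement", which is not decomposed by
  component).

Speckle frames place ~1.3 µm Gaussian granules (0.05 µm⁻² density) at
uniform random positions in the cell disk and advect them through the known
interior flow (midpoint rule); all randomness flows through one stored
seed. What a green synthetic test does *not* establish: robustness to
uneven illumination, granule polydispersity and occlusion, out-of-plane
motion, an off-plane AV axis, or non-axisymmetric deformation — all present
in real recordings.

## Trajectories, mixing, summary numbers

Tracer paths are integrated with midpoint (RK2) stepping, substeps capped
so no step exceeds 0.5 grid cell (or 1 µm for analytic fields), linear
interpolation in time, bilinear in space for gridded flows; tracers leaving
the domain are clamped to the boundary and flagged. Mixing is summarised by
the per-seed return ratio (net displacement / path length) and by the mean
cosine similarity of displacement increments of neighbouring seeds
(< 10 µm). Scalar helpers implement the Laplace pressure 2γ/R (44.4 Pa at
γ = 2 mN/m, R = 90 µm), the trans-surface outflow speed ΔV/(A·T)
(8.3·10⁻⁴ µm/s for the worked example), the Stokes–Einstein viscosity ratio
D_water/D_cyto, and Re = ρvL/µ with no default characteristic scales.

On the default stated world the tangential displacement model gives a peak
instantaneous interior pressure difference of ~3·10⁻⁴ Pa (max − min;
~1.6·10⁻⁴ Pa as max deviation from the mean) — five orders of magnitude
below the ~44 Pa cortical Laplace pressure, which is the physical point of
the analysis. `scripts/acceptance.py` recomputes this number from scratch.

## Known limitations

* Only the axisymmetric (Zₙ ≡ 0) specialisation of the solver is exercised;
  the φ-dependent machinery exists at the type level only.
* The perturbation expansion degrades for boundary harmonics with
  ε·n ≳ 0.5 and for boundary data with net flux through the deformed
  surface (see above).
* The active-contour weights are tuned on synthetic silhouettes; real
  transmission-light rims with texture and jelly coats will need their own
  weights/σ.
* `volume_area` is exact only for k ≤ 4, as printed; higher modes are
  truncated with a warning.
* No CLI is shipped: the library functions and `scripts/acceptance.py` are
  the interface.
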