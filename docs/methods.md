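# Methods

This note documents the models, conventions and numerical choices
behind `stereoloc`, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Geometry and conventions

**World frame.** Origin at the intersection of the two optical axes
(the nominal focal plane); `z` points away from the cameras along the
bisector of the boresights, so depth into the sample increases with
`z`; `x` runs horizontally along the baseline and `y` is vertical.
This makes the vergence half-angle θ and the disparity–depth relation
explicit: near the axis, raw disparity changes by `2·sinθ/p_obj` pixels
per unit depth, where `p_obj = pixel pitch / magnification` is the
object-plane pixel (40.54 µm for 15 µm pitch at ×0.37).  Note that the
*rectified* disparity slope carries an extra `1/cos²θ`; the stated
relation is for raw projected coordinates.

**Pixels** are 0-based with centers on integer coordinates; `u` is the
column, `v` the row.  All world lengths are mm except where a column
name carries a unit suffix.

**Camera model.** Pinhole with zero skew, independent `fx`/`fy`, and a
two-coefficient radial distortion `1 + k1·r² + k2·r⁴` on normalized
coordinates.  Undistortion inverts this by damped fixed-point
iteration (≤50 iterations, tolerance 1e-10 in normalized units), which
round-trips to <1e-6 px for |k1|,|k2| ≤ 0.5 over the tested radius
range.

**Rectification** rotates both cameras to a common orientation whose
x-axis lies along the baseline and whose z-axis is the mean boresight
projected orthogonal to it; shared rectified intrinsics use the mean
focal length and the sensor-center principal point.  Rectified
correspondences then agree in `v` to <1e-6 px noiselessly.

**Triangulation** uses the ray-midpoint construction (midpoint of the
shortest segment between the two back-projected rays) rather than a
reprojection-minimizing solution: it is exact in the noiseless case,
cheap, and the skew distance between the rays is reported as a
per-point quality metric.  Near-parallel rays (denominator < 1e-12)
are an error.

**Refraction.** Apparent depth below a flat air/medium interface is
multiplied by the refractive index (1.33 for aqueous baths); lateral
coordinates are unchanged and no ray bending is modeled.  This is a
scalar rescale valid for small-angle imaging through a flat interface;
a full refractive camera model is out of scope.

## Calibration

Per-camera intrinsics are initialized in closed form from view
homographies (zero-skew absolute-conic constraints, ≥3 views required)
with k1 = k2 = 0, then refined by Levenberg–Marquardt jointly with the
per-view board poses (axis-angle parameterization).  Stereo calibration
initializes the relative pose by chordal averaging of the per-view pose
compositions and refines everything — both intrinsics and distortion
pairs, the relative pose, and per-view board poses expressed in
camera 1 — against all corners of both cameras.  Convergence tolerances
are 1e-12 (relative cost/step/gradient); all corners are weighted
equally and no outlier rejection is performed.  The mean reprojection
error is the mean Euclidean distance between detected and reprojected
corners over all corners, views and cameras.

A practical observability note: at the long focal length of the
nominal rig (~4567 px) the board subtends normalized radii of only
~0.09, so k2 (an r⁴ term) is nearly unobservable and its fitted value
is not meaningful even when the reprojection error is excellent.  The
parameter-recovery tests therefore use a wide-field test camera
(f = 800 px, radii to ~0.5) where distortion is well constrained; the
reprojection-error criterion is evaluated on the nominal geometry.

Corner detection for rendered boards uses a quadrant-contrast template
(strong only at interior black/white crossings, so corners of the board
outline are ignored), Förstner sub-pixel refinement, principal-axis
grid ordering, and canonicalization so the first corner is the one
nearest the image top-left (a 180° board rotation maps to the same
ordering).

## Localization

The detection chain is the standard sparse-emitter recipe: optional
flat-field correction `(I − offset)/gain` (dark current folded into the
offset), subtraction of the temporal-mean image (removes static
background; a spot present in one of T frames keeps 1 − 1/T of its
amplitude), à-trous B3-spline wavelet decomposition with detection on
plane 2, and isotropic Gaussian fitting in a 7×7 window.

**Detection threshold.**  Candidates are strict 8-neighborhood maxima
of the detail plane above `k_sigma` (default 4) times a robust noise
scale.  The noise scale is the larger of the MAD estimate
(1.4826·MAD) and an upper inter-quantile estimate
((Q99 − Q95)/0.680).  The two agree on symmetric noise; on
background-subtracted frames whose negatives were clipped the plane is
zero-inflated and the MAD underestimates the surviving positive noise
tail by ~30%, which floods the detector with false candidates — the
quantile spread is immune to the clipped core and barely affected by
the sparse spots.  A guard band of the dilated kernel half-width is
excluded at the frame border, where reflective boundary handling
correlates the noise; plateau ties (exactly symmetric or saturated
spots) collapse to one deterministic candidate.

**Gaussian fit.**  Five parameters (amplitude, center, σ, constant
background), Levenberg–Marquardt with an analytic Jacobian.  Fits are
rejected when the center leaves the window, σ falls outside
[0.3, window radius], the amplitude is non-positive, or the amplitude
is below 3× the per-pixel residual RMS.  The last criterion is the
significance gate that rejects ≥95% of pure-noise candidates while
passing real spots of peak SNR ≥ ~4; it does not affect noiseless
fits.  The fit window (radius 3 px) reflects the undersampled optics:
the diffraction limit (≈27.7 µm FWHM) is smaller than one object-plane
pixel (40.5 µm), so real spots span only a few pixels.

**Single-camera depth.**  `diffusion_depth` inverts a monotone σ(z)
calibration table by linear interpolation, clamping and flagging
out-of-range spot sizes.  Because σ varies weakly near the surface
while the localization noise on σ is fixed, single-camera depth is
intrinsically far noisier than stereo triangulation — the simulator
reproduces this contrast (≥3× the stereo depth scatter in the test
conditions).

## Matching and exclusion

After rectification, a pair is accepted only when each spot is the
unique candidate of the other within `y_threshold` (reciprocal
uniqueness); any spot with two or more candidates voids all its
pairings, since coincident rows usually mean several droplets in close
proximity.  The default threshold of 1.0 rectified px is ≈3× the
rectification residual under 0.1 px localization noise and is
configurable; disparity-range gating is available but off by default.
On scenes certified sparse (no two droplets within the threshold in
rectified `v` in either view) this rule provably admits no
wrong-identity pair, which the ground-truth tests confirm.

## Tracking and velocimetry

Frame-to-frame linking minimizes the summed squared displacement over
one-to-one matchings whose links all satisfy d ≤ MLD, with a cost of
MLD²/2 per unlinked endpoint, solved exactly by the Hungarian algorithm
on the standard augmented cost matrix.  This reduces to
nearest-neighbor linking in sparse scenes, is strictly better on
crossings, and is deterministic; it matches exhaustive enumeration on
small frames.  The MLD (default 300 µm) with the frame rate bounds the
measurable speed (12 mm/s at 40 Hz, 5.4 mm/s at 18 Hz).  Gap closing
defaults to 0; the minimum track length (default 5 frames) removes
false connections and stalled droplets.  Velocities are finite
differences times the frame rate; the axial component keeps its sign,
which is what discriminates descending from ascending penetrating
vessels.

## Rendering

Track segments are sampled at steps of at most half a voxel and
accumulated as visit counts (the compounded localization volume,
default 10 µm voxels ≈ 3× the best expected localization SD) and as
per-voxel arithmetic means of the velocity samples — component-wise
for the vector channels (opposite flows cancel) and magnitude-wise for
the speed channel (they do not).  Maximum-intensity projections,
depth-at-maximum maps (quantitative arrays, not baked RGB) and
widefield-equivalent frame sums support the comparison figures; a
Gaussian-fit FWHM utility measures line profiles.

## The simulator: what it emulates and what it does not

The generator reproduces the study conditions: a 640×512 sensor pair
at ±20° vergence, 15 µm pitch at ×0.37 (working distance and pixel
focal length follow from 50 mm thin-lens conjugates), droplet
diameters lognormal with mean 4.73 µm and SD 2.25 µm, brightness
proportional to droplet volume (d³), phantom flows of 2–4 mm/s at
18 Hz and in vivo timing of 20 ms + 5 ms at 40 Hz.  Scenes include a
static droplet, the axial checkerboard scan (5 µm steps over 3 mm, 6×9
squares of 1.34 mm; the calibration board is 5×6 squares of 2 mm), a
tilted tube (constant dz/dy), a knot (two crossing arcs separated
axially by the 231 µm outer tube diameter), and a cortical network on
a spherical cap with penetrating vessels to 600 µm depth.  Droplets
arrive as a Poisson process, advect at constant speed along the
centerline (optionally riding a fixed laminar streamline offset within
the 137 µm lumen), and are sampled at exposure midpoints; a minimum
arrival gap enforces the sparse regime and `certify_sparsity` checks
it against the actual projections.

Scattering is modeled phenomenologically: the object-plane PSF sigma
grows linearly with depth below the interface,
σ(z) = σ₀(1 + β·depth) with σ₀ = 27.7/2.355 ≈ 11.8 µm (the system's
diffraction limit expressed as a Gaussian sigma), and the collected
signal decays as exp(−µ·depth).  β = 0.35 /mm and µ = 0.6 /mm are
simulator choices tuned to reproduce the qualitative blur and SNR
decay of imaging through a ~1% lipid emulsion bath; they are not
fitted optical constants.  The rendered pixel-domain sigma combines
the scattering sigma with a 0.8 px system floor in quadrature —
Gaussian convolution adds variances — which keeps fitting well-posed
on the undersampled sensor while remaining strictly increasing with
depth.  Sensor noise is Poisson shot noise on signal plus a constant
background (default 100 counts), Gaussian read noise (2 counts), and
16-bit clipping.  Identical seeds give bit-identical ground truth and
stacks.

Not modeled: physical light transport (Monte-Carlo scattering),
speckle, motion blur (at ≤12 mm/s and 20 ms exposure the smear can
reach ~6 object pixels at the speed ceiling; positions are sampled at
the exposure midpoint, so tests at phantom speeds are unaffected but
the ceiling regime is idealized), droplet–wall interactions, capillary
arrest, and non-uniform illumination beyond the flat-field maps.
Passing tests on these scenes therefore demonstrate the correctness of
the geometry, detection statistics and assignment logic under
realistic noise — not robustness to tissue heterogeneity or to
non-Gaussian PSFs of real scattering media.

## Measurement definitions used by the acceptance computations

- *Axial checkerboard scan*: corners of the 6×9 grid are projected
  through the nominal rig at 601 planes spaced 5 µm with 0.1 px corner
  noise, triangulated per layer; the reported value is the mean over
  corners and adjacent layers of the depth differences.
- *Calibration replica*: 20 random in-view poses of the 5×6 board with
  k1 = −0.1, k2 = 0.05 ground truth and 0.1 px noise; the reported
  value is the joint refinement's mean reprojection error.
- *Axial-to-lateral spread ratio*: the 3D scatter of a static droplet
  localized over repeated frames.  Under isotropic pixel noise the
  per-axis ratios are cot θ (x) and 1/sin θ (y), while the ratio of
  the axial spread to the in-plane *radial* spread √(σx²+σy²) is
  ≈ √2/(2 sin θ) ≈ 2.07 at θ = 20°; the package measures the latter,
  which is also the quantity consistent with the ~2.4 anisotropy of
  the published characterization.
- *Flow-speed recovery*: per-track mean speeds from the full pipeline
  on rendered tilted-tube stacks at 2 and 4 mm/s, 18 Hz, ~45 frames.
- *Knot separation*: triangulated points within 0.5 mm laterally of
  the crossing, split at the midpoint of their depth range; the value
  is the difference of the two cluster means.

Test problem sizes (hundreds of frames, 10⁴ round-trip points, 601
scan layers) are the package's chosen desk-scale replicas; each
measurement is also exposed as a plain function so larger runs are one
argument away.

## Known limitations

- The matcher is built for sparse scenes; dense fields need the
  temporal-fingerprint matching that is explicitly out of scope.
- k2 is effectively unconstrained at the nominal focal length (see
  above); consumers of the rig file should treat it as a nuisance
  parameter there.
- The refraction correction assumes a flat interface normal to the
  bisector axis.
- Velocity assumes per-frame displacements well below the MLD; at the
  speed ceiling, fragmentation (not bias) is the failure mode.
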