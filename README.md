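# stereoloc

Stereovision localization microangiography: super-resolved 3D
reconstruction of microvascular structure and blood-flow velocity from
dual-view fluorescence image stacks of flowing micro-droplet tracers.

## The problem

Widefield fluorescence imaging through scattering tissue blurs rapidly
with depth and projects everything onto one plane, so overlapping
vessels cannot be separated and flow cannot be quantified in 3D.  The
approach implemented here images sparse, bright micro-droplets (oil
droplets loaded with short-wave-infrared quantum dots) flowing through
the vasculature with **two cameras at a ±20° vergence angle**.  Because
each droplet is an isolated point emitter, its center can be fitted
with sub-pixel precision in both views; the horizontal offset between
the two rectified projections — the *disparity* — encodes depth.
Compounding many droplet positions over time yields a vascular volume
far below the diffraction limit of the optics, and linking positions
over frames yields 3D velocity, including the axial component that a
single camera cannot sign.

This package is aimed at microscopists and image-analysis developers
who want a complete, testable implementation of that pipeline —
including a synthetic scene simulator with exact ground truth, so every
stage can be validated at desk scale without the instrument.

## The method

For a pinhole camera with focal lengths $f_x, f_y$, principal point
$(c_x, c_y)$ and two-coefficient radial distortion, a world point
$\mathbf{X}$ maps to pixels through

$$u = f_x\,x_n\,(1 + k_1 r^2 + k_2 r^4) + c_x,\qquad r^2 = x_n^2+y_n^2,$$

with $(x_n, y_n)$ the normalized camera-frame coordinates.  The
pipeline runs in four stages:

1. **Localization** — flat-field correction, subtraction of the
   temporal-mean background, à-trous B3-spline wavelet detection of
   candidate spots, and least-squares fitting of an isotropic 2D
   Gaussian for sub-pixel centroids.
2. **Matching** — both views are undistorted and rectified so
   corresponding points share the vertical coordinate; spots are paired
   when each is the *unique* candidate of the other within a vertical
   threshold, and any spot with multiple candidates voids all its
   pairings (ambiguity exclusion).
3. **Stereovision** — each pair is triangulated as the midpoint of the
   shortest segment between the two back-projected rays; for a vergence
   half-angle $\theta$ the disparity-to-depth sensitivity is
   $\partial d/\partial z = 2\sin\theta / p_\mathrm{obj}$ with
   $p_\mathrm{obj}$ the object-plane pixel (40.5 µm here).  Depth
   extents below an air/medium interface are rescaled by the refractive
   index (1.33 for water).
4. **Flow tracking** — per-frame 3D points are linked by optimal
   (Hungarian) assignment gated by a max-linking-distance (MLD); short
   tracks are discarded; velocities are finite differences times the
   frame rate, and trajectories plus per-voxel mean velocities are
   compounded into volumes.

Stereo calibration (Zhang-style closed-form initialization + joint
bundle refinement of both intrinsics, distortion and the inter-camera
pose from checkerboard views) and a forward simulator (droplet size
distribution, depth-dependent PSF broadening and attenuation, Poisson
shot noise + read noise) complete the toolkit.

## Worked example

Simulate a tilted micro-tube phantom (depth increasing linearly along
y) with droplets flowing at 3 mm/s, then run the full pipeline:

```sh
stereoloc simulate --scene tilted_tube --speed 3.0 --rate 3.0 \
    --duration 5 --frame-rate 18 --seed 1 --out sim/
stereoloc run --stack1 sim/cam1.tiff --stack2 sim/cam2.tiff \
    --rig sim/rig.txt --frame-rate 18 --out recon/
```

which prints

```
wrote 90 frames per camera to sim
pipeline complete: 424 points, 21 tracks
```

`recon/tracks.csv` holds the 3D trajectories with per-step velocities.
The per-track mean speeds cluster at 2.8–3.1 mm/s around the 3 mm/s
ground truth (long tracks sit within 1–2%; five-frame fragments
scatter more), and the mean axial velocity ≈ 0.84 mm/s matches the
configured depth gradient (3 mm/s × 0.3 / √1.09 = 0.86).
`recon/density.tiff` is
the compounded localization volume (10 µm voxels, z-pages) and
`recon/speed.tiff` the per-voxel mean-speed map.  Derived acquisition
constants are available at any time:

```
$ stereoloc constants
object_pixel_um = 40.5405
frame_rate_hz = 40
frame_period_ms = 25
max_trackable_speed_mm_s = 12
```

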