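"""Spot detection, Gaussian fitting and diffusion-depth estimation."""

import numpy as np
import pytest

from stereoloc.localization import (
    FlatField,
    ImageStack,
    LocalizationParams,
    SpotCandidate,
    diffusion_depth,
    fit_gaussian,
    flat_field_correct,
    localize_frame,
    localize_stack,
    subtract_background,
    wavelet_detect,
)


def gaussian_spot(shape, u, v, amplitude, sigma, background=0.0):
    h, w = shape
    vv, uu = np.mgrid[0:h, 0:w]
    return background + amplitude * np.exp(
        -((uu - u) ** 2 + (vv - v) ** 2) / (2 * sigma**2)
    )


class TestImageStack:
    def test_timing_consistency_checked(self):
        frames = np.zeros((2, 8, 8))
        ImageStack(frames, 40.0, 20.0, 5.0)  # consistent
        with pytest.raises(ValueError, match="inconsistent"):
            ImageStack(frames, 40.0, 20.0, 10.0)

    def test_negative_intensities_rejected(self):
        with pytest.raises(ValueError):
            ImageStack(-np.ones((1, 4, 4)))


class TestFlatField:
    def test_identity(self):
        stack = ImageStack(np.random.default_rng(0).poisson(50, (3, 8, 8)).astype(float))
        ff = FlatField(np.ones((8, 8)), np.zeros((8, 8)))
        out = flat_field_correct(stack, ff)
        np.testing.assert_array_equal(out.frames, stack.frames)

    def test_constant_offset_gives_zeros(self):
        stack = ImageStack(np.full((2, 8, 8), 7.0))
        ff = FlatField(np.ones((8, 8)), np.full((8, 8), 7.0))
        assert flat_field_correct(stack, ff).frames.max() == 0.0

    def test_inverts_synthesized_nonuniformity(self):
        rng = np.random.default_rng(1)
        gain = rng.uniform(0.5, 2.0, (16, 16))
        offset = rng.uniform(0.0, 10.0, (16, 16))
        truth = rng.uniform(20.0, 100.0, (4, 16, 16))
        stack = ImageStack(truth * gain + offset)
        out = flat_field_correct(stack, FlatField(gain, offset))
        np.testing.assert_allclose(out.frames, truth, rtol=1e-12)

    def test_shape_mismatch_raises(self):
        stack = ImageStack(np.zeros((2, 8, 8)))
        with pytest.raises(ValueError, match="shape"):
            flat_field_correct(stack, FlatField(np.ones((4, 4)), np.zeros((4, 4))))


class TestBackgroundSubtraction:
    def test_static_scene_goes_to_zero(self):
        stack = ImageStack(np.full((5, 8, 8), 13.0))
        assert subtract_background(stack).frames.max() == 0.0

    def test_transient_spot_keeps_most_amplitude(self):
        T = 10
        frames = np.zeros((T, 16, 16))
        frames[3] = gaussian_spot((16, 16), 8, 8, 100.0, 1.5)
        out = subtract_background(ImageStack(frames))
        expected = 100.0 * (1 - 1 / T)
        assert out.frames[3].max() == pytest.approx(expected, rel=1e-9)

    def test_invariant_to_constant_offset(self):
        rng = np.random.default_rng(2)
        frames = rng.uniform(0, 50, (4, 8, 8))
        a = subtract_background(ImageStack(frames)).frames
        b = subtract_background(ImageStack(frames + 100.0)).frames
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_single_frame_raises(self):
        with pytest.raises(ValueError):
            subtract_background(ImageStack(np.zeros((1, 8, 8))))


class TestWaveletDetect:
    def test_zero_frame_gives_no_candidates(self):
        assert wavelet_detect(np.zeros((64, 64))) == []

    def test_level_too_deep_raises(self):
        with pytest.raises(ValueError, match="level"):
            wavelet_detect(np.zeros((16, 16)), level=5)

    def test_single_spot_detected_at_true_position(self):
        rng = np.random.default_rng(3)
        frame = gaussian_spot((64, 64), 30.2, 25.7, 100.0, 1.5)
        frame = frame + rng.normal(0, 5.0, frame.shape)  # SNR 20
        cands = wavelet_detect(frame, level=2, k_sigma=4.0)
        assert len(cands) == 1
        assert abs(cands[0].u - 30.2) <= 1.0
        assert abs(cands[0].v - 25.7) <= 1.0

    def test_many_spots_all_found_none_spurious_after_fit(self):
        """50 well-separated spots on a noisy frame: all recovered, and
        the Gaussian fit stage admits no spurious detection."""
        rng = np.random.default_rng(4)
        frame = np.zeros((360, 360))
        truth = []
        for i in range(50):
            u = 20 + 45 * (i % 8) + rng.uniform(-5, 5)
            v = 20 + 48 * (i // 8) + rng.uniform(-5, 5)
            truth.append((u, v))
            frame += gaussian_spot(frame.shape, u, v, 200.0, 1.3)
        frame += rng.normal(0, 10.0, frame.shape)
        spots = localize_frame(frame, LocalizationParams())
        truth = np.array(truth)
        found = np.array([[s.u, s.v] for s in spots])
        d = np.linalg.norm(found[:, None, :] - truth[None, :, :], axis=2)
        assert (d.min(axis=1) < 1.0).all()  # nothing spurious
        assert len(set(d.argmin(axis=1))) == 50  # every true spot recovered

    def test_increasing_threshold_never_adds_detections(self):
        rng = np.random.default_rng(5)
        frame = gaussian_spot((64, 64), 30, 30, 60.0, 1.5)
        frame += rng.normal(0, 8.0, frame.shape)
        n = [len(wavelet_detect(frame, 2, k)) for k in (2.0, 4.0, 8.0)]
        assert n[0] >= n[1] >= n[2]


class TestFitGaussian:
    def test_noiseless_subpixel_accuracy(self):
        frame = gaussian_spot((40, 40), 10.30, 20.70, 150.0, 1.5, background=5.0)
        spot = fit_gaussian(frame, SpotCandidate(0, 10, 21, 1.0), window_radius=5)
        assert spot is not None
        assert spot.u == pytest.approx(10.30, abs=0.01)
        assert spot.v == pytest.approx(20.70, abs=0.01)
        assert spot.sigma_px == pytest.approx(1.5, rel=0.01)
        assert spot.amplitude == pytest.approx(150.0, rel=0.01)
        assert spot.background == pytest.approx(5.0, abs=0.5)

    def test_pure_noise_candidates_mostly_rejected(self):
        rng = np.random.default_rng(6)
        rejected = 0
        n_seeds = 40
        for _ in range(n_seeds):
            frame = rng.normal(0.0, 10.0, (21, 21))
            spot = fit_gaussian(frame, SpotCandidate(0, 10, 10, 1.0), 3)
            if spot is None:
                rejected += 1
        assert rejected >= 0.95 * n_seeds

    def test_precision_improves_with_photon_count(self):
        """Centroid scatter shrinks as 1/sqrt(N) over two decades."""
        rng = np.random.default_rng(7)
        photon_counts = [300, 1000, 3000, 10000, 30000]
        sds = []
        for n_ph in photon_counts:
            centers = []
            for _ in range(150):
                model = gaussian_spot((15, 15), 7.2, 6.8, 1.0, 1.3)
                model *= n_ph / model.sum()
                frame = rng.poisson(model + 2.0).astype(float)
                spot = fit_gaussian(frame, SpotCandidate(0, 7, 7, 1.0), 5)
                if spot is not None:
                    centers.append((spot.u, spot.v))
            centers = np.array(centers)
            sds.append(centers.std(axis=0).mean())
        slope = np.polyfit(np.log(photon_counts), np.log(sds), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.05)


class TestLocalizeStack:
    def test_empty_stack_gives_no_spots(self):
        stack = ImageStack(np.zeros((4, 32, 32)))
        assert sum(map(len, localize_stack(stack))) == 0

    def test_translation_equivariance(self):
        """Integer-pixel shifts move every fitted centroid exactly."""
        rng = np.random.default_rng(8)
        base = np.zeros((96, 96))
        for u, v in [(30.3, 40.6), (60.1, 25.4), (45.7, 70.2)]:
            base += gaussian_spot(base.shape, u, v, 300.0, 1.4)
        noise = rng.normal(0, 3.0, base.shape)
        du, dv = 5, -3
        shifted = np.roll(np.roll(base, dv, axis=0), du, axis=1) + np.roll(
            np.roll(noise, dv, axis=0), du, axis=1
        )
        params = LocalizationParams(subtract_background=False)
        s0 = localize_frame(base + noise, params)
        s1 = localize_frame(shifted, params)
        assert len(s0) == len(s1) == 3
        c0 = sorted((s.u, s.v) for s in s0)
        c1 = sorted((s.u - du, s.v - dv) for s in s1)
        np.testing.assert_allclose(c0, c1, atol=1e-9)

    def test_higher_threshold_never_detects_more(self):
        rng = np.random.default_rng(9)
        frames = rng.poisson(50, (3, 64, 64)).astype(float)
        frames[1, 30, 30] += 400.0
        stack = ImageStack(frames)
        n4 = sum(map(len, localize_stack(stack, LocalizationParams(k_sigma=4))))
        n8 = sum(map(len, localize_stack(stack, LocalizationParams(k_sigma=8))))
        assert n8 <= n4


class TestDiffusionDepth:
    def test_inverse_of_forward_curve(self):
        z = np.linspace(0.0, 3.0, 31)
        curve = 0.85 + 0.3 * z
        depth, clamped = diffusion_depth(np.interp(1.0, z, curve), z, curve)
        assert depth[0] == pytest.approx(1.0, abs=1e-9)
        assert not clamped[0]

    def test_out_of_range_clamped_and_flagged(self):
        z = np.linspace(0.0, 3.0, 31)
        curve = 0.85 + 0.3 * z
        depth, clamped = diffusion_depth(0.1, z, curve)
        assert depth[0] == 0.0
        assert clamped[0]

    def test_non_monotone_curve_rejected(self):
        z = np.linspace(0.0, 3.0, 31)
        curve = np.sin(z)
        with pytest.raises(ValueError, match="monotone"):
            diffusion_depth(1.0, z, curve)

    def test_decreasing_curve_accepted(self):
        z = np.linspace(0.0, 3.0, 31)
        curve = 2.0 - 0.3 * z
        depth, _ = diffusion_depth(np.interp(2.0, z, curve), z, curve)
        assert depth[0] == pytest.approx(2.0, abs=1e-9)


class TestDiffusionVsStereoDepth:
    def test_single_camera_depth_noisier_than_stereo(self):
        """Depth from the fitted spot size (diffusion calibration) shows
        much larger frame-to-frame fluctuations than dual-view
        triangulation of the same acquisitions."""
        from stereoloc.geometry import OpticsConfig, symmetric_rig
        from stereoloc.matching import match_frame, pairs_to_points
        from stereoloc.simulate import (
            FlowSpec,
            ScatteringModel,
            SceneSpec,
            build_scene,
            render_stack,
            sigma_z_curve,
            simulate_flow,
        )

        optics = OpticsConfig(sensor_width=128, sensor_height=128)
        rig = symmetric_rig(optics=optics)
        scat = ScatteringModel()
        scene = build_scene(SceneSpec(variant="static_point", point_mm=(0, 0, 2.0)))
        truth = simulate_flow(
            scene, FlowSpec(diameter_sd_um=0.0), 150 / 18.0, 18.0, seed=31
        )
        s1, s2 = render_stack(truth, rig, optics, scattering=scat, seed=31)
        params = LocalizationParams(subtract_background=False)
        z_grid = np.linspace(0.0, 5.0, 101)
        curve = sigma_z_curve(scat, optics, z_grid)
        stereo_z, diff_z = [], []
        for f in range(truth.n_frames):
            sp1 = localize_frame(s1.frames[f], params, f, 1)
            sp2 = localize_frame(s2.frames[f], params, f, 2)
            pairs = match_frame(sp1, sp2, rig)
            if len(pairs) != 1:
                continue
            stereo_z.append(pairs_to_points(pairs, rig)[0].z)
            depth, _ = diffusion_depth(sp1[0].sigma_px, z_grid, curve)
            diff_z.append(depth[0])
        assert len(stereo_z) > 100
        assert np.std(diff_z) > 3.0 * np.std(stereo_z)
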