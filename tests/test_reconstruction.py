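import numpy as np
import pytest

from particlesieve import (
    FSCCurve,
    MaskSpec,
    Pose,
    VoxelGrid,
    forward_project,
    fsc,
    make_mask,
    make_phantom,
    reconstruct,
    resolution_at_threshold,
)


def _lowpass(data, max_shell):
    L = data.shape[0]
    k = np.fft.fftfreq(L) * L
    kz, ky, kx = np.meshgrid(k, k, k, indexing="ij")
    F = np.fft.fftn(data)
    F[np.sqrt(kx**2 + ky**2 + kz**2) > max_shell] = 0
    return np.fft.ifftn(F).real


class TestReconstruct:
    def test_round_trip_correlation(self, smooth_volume, projection_stack):
        """500 noise-free projections rebuild the phantom: real-space
        correlation > 0.99 after lowpass to 2/3 Nyquist."""
        rec = reconstruct(projection_stack)
        L = smooth_volume.edge
        lim = int((2 / 3) * (L // 2))
        a = _lowpass(rec.data, lim).ravel()
        b = _lowpass(smooth_volume.data, lim).ravel()
        assert np.corrcoef(a, b)[0, 1] > 0.99

    @pytest.mark.parametrize("pose,min_cc", [
        (Pose(), 0.999),  # grid-aligned: the one-term average is exact
        (Pose(rot=25, tilt=60, psi=-40), 0.98),  # plus interpolation spread
    ])
    def test_single_particle_slice_consistency(self, smooth_volume, pose,
                                               min_cc):
        """A one-particle reconstruction holds (a Wiener-damped, globally
        rescaled copy of) the inserted slice: re-projecting at the same
        pose recovers the input image up to scale."""
        from particlesieve import ParticleRecord, ParticleStack

        img = forward_project(smooth_volume, pose, None)
        stack = ParticleStack(
            images=img[None].astype(np.float32),
            pixel_size=smooth_volume.voxel_size,
            records=[ParticleRecord(image_index=0, pose=pose, ctf=None,
                                    half_set=1)],
        )
        rec = reconstruct(stack)
        reproj = forward_project(rec, pose, None)
        cc = np.corrcoef(reproj.ravel(), img.ravel())[0, 1]
        assert cc > min_cc

    def test_duplication_invariance(self, projection_stack):
        sub = [projection_stack.records[i] for i in range(50)]
        a = reconstruct(projection_stack, sub)
        b = reconstruct(projection_stack, sub + sub)
        np.testing.assert_allclose(b.data, a.data, rtol=1e-8, atol=1e-10)

    def test_wiener_eps_insensitivity(self, projection_stack, smooth_volume):
        a = reconstruct(projection_stack, wiener_eps_rel=1e-4)
        b = reconstruct(projection_stack, wiener_eps_rel=1e-2)
        rel = np.linalg.norm(a.data - b.data) / np.linalg.norm(a.data)
        assert rel < 0.01

    def test_empty_subset_rejected(self, projection_stack):
        with pytest.raises(ValueError):
            reconstruct(projection_stack, [])

    def test_half_set_images_isolated(self, smooth_volume, projection_stack):
        """Reconstructing half-set 1 never reads a half-set-2 image:
        poisoning those images with NaN leaves the result finite."""
        import copy

        stack = copy.deepcopy(projection_stack)
        half1 = [r for r in stack.records if r.half_set == 1]
        for r in stack.records:
            if r.half_set == 2:
                stack.images[r.image_index] = np.nan
        rec = reconstruct(stack, half1)
        assert np.all(np.isfinite(rec.data))


class TestMakeMask:
    def test_ball_mask_structure(self):
        L = 32
        ball = make_phantom("ball", L, 1.0)
        mask = make_mask(ball, MaskSpec())
        c = L // 2
        assert mask.data[c, c, c] == 1.0
        assert mask.data[0, 0, 0] == 0.0
        assert mask.data.min() >= 0.0 and mask.data.max() <= 1.0
        profile = mask.data[c, c, c:]
        assert np.all(np.diff(profile) <= 1e-12)  # monotone across the edge

    def test_extend_monotone(self):
        ball = make_phantom("ball", 32, 1.0)
        m1 = make_mask(ball, MaskSpec(extend_px=2))
        m2 = make_mask(ball, MaskSpec(extend_px=5))
        assert np.all(m2.data >= m1.data - 1e-12)

    def test_cosine_edge_profile(self):
        """Along an axis ray the soft edge equals 0.5*(1+cos(pi t)) at
        integer voxel offsets t from the dilated support."""
        L = 48
        ball = make_phantom("ball", L, 1.0)
        edge = 6
        mask = make_mask(ball, MaskSpec(cosine_edge_px=edge))
        c = L // 2
        ray = mask.data[c, c, c:]
        (ones,) = np.nonzero(ray == 1.0)
        last = ones[-1]
        for t in range(1, edge + 1):
            if last + t < ray.size:
                expected = 0.5 * (1 + np.cos(np.pi * t / edge))
                assert ray[last + t] == pytest.approx(expected, abs=1e-6)

    def test_all_zero_rejected(self):
        zero = VoxelGrid(data=np.zeros((16, 16, 16)), voxel_size=1.0)
        with pytest.raises(ValueError):
            make_mask(zero)


class TestFSC:
    def test_self_correlation_is_one(self, smooth_volume):
        curve = fsc(smooth_volume, smooth_volume)
        assert np.allclose(curve.correlation, 1.0, atol=1e-10)

    def test_scale_invariance(self, smooth_volume):
        scaled = VoxelGrid(data=3.7 * smooth_volume.data,
                           voxel_size=smooth_volume.voxel_size)
        curve = fsc(smooth_volume, scaled)
        assert np.allclose(curve.correlation, 1.0, atol=1e-10)

    def test_white_noise_null_bound(self):
        rng = np.random.default_rng(7)
        L = 32
        a = VoxelGrid(data=rng.normal(size=(L, L, L)), voxel_size=1.0)
        b = VoxelGrid(data=rng.normal(size=(L, L, L)), voxel_size=1.0)
        curve = fsc(a, b)
        k = np.fft.fftfreq(L) * L
        kz, ky, kx = np.meshgrid(k, k, k, indexing="ij")
        shell = np.rint(np.sqrt(kx**2 + ky**2 + kz**2)).astype(int).ravel()
        counts = np.bincount(shell)
        for s in range(L // 2):
            if counts[s] > 500:
                assert abs(curve.correlation[s]) < 3.0 / np.sqrt(counts[s])

    def test_dimension_mismatch_rejected(self, smooth_volume):
        other = VoxelGrid(data=np.zeros((16, 16, 16)), voxel_size=1.0)
        with pytest.raises(ValueError):
            fsc(smooth_volume, other)


class TestResolution:
    def test_never_crossing_flags_nyquist(self):
        curve = FSCCurve(shell_freq=np.linspace(0, 0.4, 9),
                         correlation=np.ones(9))
        est = resolution_at_threshold(curve, 0.143)
        assert not est.crossed
        assert est.resolution_A == pytest.approx(1.0 / 0.45)

    def test_hand_interpolated_crossing(self):
        curve = FSCCurve(shell_freq=np.array([0.1, 0.2]),
                         correlation=np.array([1.0, 0.0]))
        est = resolution_at_threshold(curve, 0.143)
        assert est.crossed
        assert est.resolution_A == pytest.approx(5.385, abs=1e-3)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(9)
        corr = np.sort(rng.uniform(0, 1, 20))[::-1]
        curve = FSCCurve(shell_freq=np.linspace(0.01, 0.4, 20),
                         correlation=corr)
        res = [resolution_at_threshold(curve, t).resolution_A
               for t in (0.5, 0.3, 0.143)]
        assert res[0] >= res[1] >= res[2]

    def test_empty_curve_rejected(self):
        curve = FSCCurve(shell_freq=np.array([]), correlation=np.array([]))
        with pytest.raises(ValueError):
            resolution_at_threshold(curve, 0.143)
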