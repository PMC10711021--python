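import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from particlesieve import (
    FourierProjector,
    ParticleRecord,
    ParticleStack,
    Pose,
    SieveSchedule,
    SimSpec,
    VoxelGrid,
    cryosieve_score,
    cutoff_schedule,
    forward_project,
    highpass,
    make_mask,
    make_phantom,
    ncc_score,
    run_sieve,
    simulate_stack,
)
from particlesieve.sieve import _score_half_set


class TestCutoffSchedule:
    def test_endpoints(self):
        sched = SieveSchedule()
        assert cutoff_schedule(1, sched) == pytest.approx(40.0)
        assert cutoff_schedule(9, sched) == pytest.approx(3.0)

    def test_linear_in_frequency_midpoint(self):
        sched = SieveSchedule()
        assert cutoff_schedule(5, sched) == pytest.approx(5.5814, abs=1e-3)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            cutoff_schedule(0, SieveSchedule())
        with pytest.raises(ValueError):
            cutoff_schedule(10, SieveSchedule())


class TestHighpass:
    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 1000), cutoff=st.floats(2.5, 30.0))
    def test_projector_properties(self, seed, cutoff):
        """Idempotent and energy-contracting for any cutoff above 2 px."""
        img = np.random.default_rng(seed).normal(size=(32, 32))
        h1 = highpass(img, cutoff, 1.0)
        h2 = highpass(h1, cutoff, 1.0)
        np.testing.assert_allclose(h2, h1, atol=1e-10)
        assert np.sum(h1 * h1) <= np.sum(img * img) + 1e-9

    def test_constant_image_zeroed(self):
        img = np.full((16, 16), 3.3)
        assert np.max(np.abs(highpass(img, 100.0, 1.0))) < 1e-12

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            highpass(np.zeros((16, 16)), 1.5, 1.0)  # Nyquist is 2 A at 1 A/px


class TestScore:
    def test_zero_reference_scores_zero(self):
        rng = np.random.default_rng(0)
        b = rng.normal(size=(32, 32))
        assert cryosieve_score(b, np.zeros_like(b), 8.0, 1.0) == 0.0

    def test_perfect_particle_scores_band_energy(self):
        rng = np.random.default_rng(1)
        b = rng.normal(size=(32, 32))
        hp = highpass(b, 30.0, 1.0)
        g = cryosieve_score(b, b, 30.0, 1.0)
        assert g == pytest.approx(np.sum(hp * hp), rel=1e-10)
        assert g >= 0

    def test_two_form_algebraic_identity(self):
        """Definition ||Hb||^2 - ||H(b-p)||^2 equals the expansion
        2<Hb,Hp> - ||Hp||^2 on random pairs."""
        rng = np.random.default_rng(2)
        for _ in range(50):
            b = rng.normal(size=(32, 32))
            p = rng.normal(size=(32, 32))
            cutoff = rng.uniform(2.5, 20.0)
            hb = highpass(b, cutoff, 1.0)
            hp = highpass(p, cutoff, 1.0)
            expanded = 2.0 * np.sum(hb * hp) - np.sum(hp * hp)
            g = cryosieve_score(b, p, cutoff, 1.0)
            assert g == pytest.approx(expanded, rel=1e-8, abs=1e-10)

    def test_scaling_preserves_ranking(self):
        rng = np.random.default_rng(3)
        b = [rng.normal(size=(16, 16)) for _ in range(10)]
        p = [rng.normal(size=(16, 16)) for _ in range(10)]
        g = [cryosieve_score(bi, pi, 6.0, 1.0) for bi, pi in zip(b, p)]
        g_scaled = [cryosieve_score(3.0 * bi, 3.0 * pi, 6.0, 1.0)
                    for bi, pi in zip(b, p)]
        np.testing.assert_allclose(g_scaled, 9.0 * np.array(g), rtol=1e-10)
        assert list(np.argsort(g)) == list(np.argsort(g_scaled))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cryosieve_score(np.zeros((8, 8)), np.zeros((16, 16)), 4.0, 1.0)


class TestNCC:
    def test_self_and_negation(self):
        rng = np.random.default_rng(4)
        b = rng.normal(size=(16, 16))
        assert ncc_score(b, b) == pytest.approx(1.0)
        assert ncc_score(b, -b) == pytest.approx(-1.0)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.normal(size=(16, 16))
            b = rng.normal(size=(16, 16))
            am, bm = a - a.mean(), b - b.mean()
            oracle = np.sum(am * bm) / np.sqrt(np.sum(am**2) * np.sum(bm**2))
            assert ncc_score(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ncc_score(np.ones((8, 8)), np.zeros((8, 8)) + 1.0)


def _tiny_sieve_inputs(n=200, L=32, px=1.5, seed=11, **spec_kw):
    spec = SimSpec(n_particles=n, L=L, pixel_size=px, seed=seed, **spec_kw)
    phantom = make_phantom("gaussian_blobs", L, px, seed=seed)
    stack, truth = simulate_stack(phantom, spec)
    return phantom, stack, truth


class TestSieveIterations:
    def test_retained_counts_and_nesting(self):
        _, stack, _ = _tiny_sieve_inputs(n=200, target_snr=1.0)
        sched = SieveSchedule(n_iterations=3, retention=0.8,
                              cutoff_start_A=40, cutoff_final_A=8)
        res = run_sieve(stack, sched)
        assert [s.n_retained[1] for s in res.states] == [80, 64, 51]
        assert [s.n_retained[2] for s in res.states] == [80, 64, 51]
        prev = {1: set(range(0, 200, 2)), 2: set(range(1, 200, 2))}
        for s in res.states:
            for h in (1, 2):
                cur = set(map(int, s.retained[h]))
                assert cur <= prev[h]
                prev[h] = cur
        assert list(res.report["cumulative_pct"]) == [80.0, 64.0, 51.2]

    def test_identical_particles_tie_broken_by_index(self):
        """Degenerate ties: equal scores remove highest indices first and
        leave the maps unchanged across iterations."""
        L, px = 32, 1.5
        phantom = make_phantom("gaussian_blobs", L, px, seed=5)
        pose = Pose(rot=10, tilt=50, psi=20)
        img = forward_project(phantom, pose, None)
        n = 80
        recs = [ParticleRecord(image_index=i, pose=pose, ctf=None,
                               half_set=1 + i % 2) for i in range(n)]
        stack = ParticleStack(images=np.repeat(img[None], n, 0).astype(np.float32),
                              pixel_size=px, records=recs)
        res = run_sieve(stack, SieveSchedule(n_iterations=2, cutoff_start_A=40,
                                             cutoff_final_A=8))
        for h, start in ((1, 0), (2, 1)):
            kept = res.states[-1].retained[h]
            expected = np.arange(start, start + 2 * len(kept), 2)
            np.testing.assert_array_equal(kept, expected)
        m0 = res.states[0].maps[1].data
        m1 = res.states[1].maps[1].data
        assert np.corrcoef(m0.ravel(), m1.ravel())[0, 1] > 0.999

    def test_half_set_leakage(self):
        """Permuting half-set-2 images never changes half-set-1 scores."""
        phantom, stack, _ = _tiny_sieve_inputs(n=80, target_snr=0.5)
        ref = VoxelGrid(data=phantom.data * make_mask(phantom).data,
                        voxel_size=phantom.voxel_size)
        half1 = np.array([i for i, r in enumerate(stack.records)
                          if r.half_set == 1])
        half2 = np.array([i for i, r in enumerate(stack.records)
                          if r.half_set == 2])
        s_before = _score_half_set(stack, half1, ref, 8.0, "cryosieve")
        stack.images[half2] = stack.images[np.roll(half2, 1)]
        s_after = _score_half_set(stack, half1, ref, 8.0, "cryosieve")
        np.testing.assert_array_equal(s_before, s_after)

    def test_halts_when_half_set_too_small(self):
        _, stack, _ = _tiny_sieve_inputs(n=50, target_snr=1.0)
        res = run_sieve(stack, SieveSchedule(n_iterations=5, cutoff_start_A=40,
                                             cutoff_final_A=8))
        assert res.halted
        assert "half-set" in res.halt_reason


class TestWrongPoseRemoval:
    def test_beats_random_baseline(self):
        """Single scoring pass at 8 A removes mostly pose-corrupted
        particles; accuracy significantly above the 50% random baseline
        (one-sample t-test over seeds, p < 0.01)."""
        accs = []
        for seed in (1, 2, 3):
            phantom, stack, truth = _tiny_sieve_inputs(
                n=200, L=48, px=1.5, seed=seed,
                target_snr=0.05, wrong_pose_fraction=0.5)
            ref = VoxelGrid(data=phantom.data * make_mask(phantom).data,
                            voxel_size=phantom.voxel_size)
            proj = FourierProjector(ref)
            scores = np.array([
                cryosieve_score(
                    stack.images[i].astype(float),
                    forward_project(ref, stack.records[i].pose,
                                    stack.records[i].ctf, projector=proj),
                    8.0, 1.5)
                for i in range(len(stack))
            ])
            removed = np.argsort(scores)[: len(stack) // 2]
            accs.append(truth.loc[removed, "wrong_pose"].mean())
        t, p = stats.ttest_1samp(accs, 0.5, alternative="greater")
        assert p < 0.01
        assert np.mean(accs) > 0.7

    def test_damage_removed_before_undamaged(self):
        """Labeled strong-damage simulation: the mean dose of removed
        particles is at least that of retained particles at every
        iteration."""
        _, stack, truth = _tiny_sieve_inputs(
            n=200, target_snr=2.0, seed=5,
            damage_levels=[(0.3, 30.0)], damage_b_per_dose=20.0)
        res = run_sieve(stack, SieveSchedule(n_iterations=3,
                                             cutoff_start_A=40,
                                             cutoff_final_A=3.2))
        dose = truth.dose_e_per_A2.values
        prev = set(range(len(stack)))
        for s in res.states:
            kept = {int(i) for h in s.retained for i in s.retained[h]}
            removed = prev - kept
            assert np.mean(dose[list(removed)]) >= np.mean(dose[list(kept)])
            prev = kept
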