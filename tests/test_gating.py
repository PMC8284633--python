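"""Retrospective gating: period estimation, shift recovery, synchronization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardioflow import (
    AperiodicSignalError,
    IndistinguishablePhasesError,
    PhantomConfig,
    SliceScan,
    make_beating_heart,
    simulate_slice_scan,
)
from cardioflow import gating


@pytest.fixture(scope="module")
def noisy_scan():
    # phase propagation off: these tests score recovered shifts against the
    # acquisition offsets alone, without the physiological apex-base lag
    cfg = PhantomConfig(shape=(16, 32, 32), radii_um=(11.0, 20.0, 17.0),
                        wall_thickness_um=6.0, noise_sigma=0.1, seed=4,
                        phase_rate_rad_per_um=0.0)
    vol, truth = make_beating_heart(cfg)
    scan, truth = simulate_slice_scan(vol, cfg, truth)
    return cfg, scan, truth


class TestEstimatePeriod:
    def test_recovers_phantom_period(self, noisy_scan):
        cfg, scan, _ = noisy_scan
        p, conf = gating.estimate_period(scan.sequences[8])
        assert p == pytest.approx(cfg.period_frames, abs=0.5)
        assert conf > 0.1

    def test_subsampled_sequence_halves_period(self, noisy_scan):
        cfg, scan, _ = noisy_scan
        p, _ = gating.estimate_period(scan.sequences[8][::2])
        assert p == pytest.approx(cfg.period_frames / 2, abs=0.5)

    def test_constant_sequence_is_aperiodic(self):
        with pytest.raises(AperiodicSignalError):
            gating.estimate_period(np.ones((64, 4, 4)))

    def test_noise_only_sequence_is_aperiodic(self):
        rng = np.random.default_rng(0)
        with pytest.raises(AperiodicSignalError):
            gating.estimate_period(rng.normal(size=(64, 8, 8)))


class TestSequenceDistance:
    def test_identical_sequences_zero(self):
        rng = np.random.default_rng(1)
        seq = rng.uniform(size=(10, 4, 4))
        assert gating.sequence_distance(seq, seq, 0, 10) == 0.0

    def test_hand_evaluated_two_frame_example(self):
        a = np.array([0.0, 1.0]).reshape(2, 1, 1)
        b = np.array([1.0, 0.0]).reshape(2, 1, 1)
        assert gating.sequence_distance(a, b, 0, 2) == pytest.approx(2.0)
        assert gating.sequence_distance(a, b, 1, 2) == pytest.approx(0.0)

    @given(shift=st.integers(-20, 40), L=st.integers(3, 8),
           seed=st.integers(0, 2 ** 16))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_swap_symmetry_and_shift_modulo(self, shift, L, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(size=(L, 3, 3))
        b = rng.uniform(size=(L, 3, 3))
        d = gating.sequence_distance(a, b, shift, L)
        assert d == pytest.approx(gating.sequence_distance(a, b, shift % L, L))
        assert d == pytest.approx(
            gating.sequence_distance(b, a, (L - shift) % L, L)
        )


class TestRelativeShift:
    def test_recovers_circular_shift_against_brute_force(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(size=(100, 6, 6))
        shifted = np.roll(base, 17, axis=0)     # shifted[t] = base[t - 17]
        s, prof = gating.estimate_relative_shift(base, shifted, 100)
        assert s == 17
        brute = [gating.sequence_distance(base / base.mean(),
                                          shifted / shifted.mean(), k, 100)
                 for k in range(100)]
        assert s == int(np.argmin(brute))
        assert np.allclose(prof, brute)

    def test_identical_gives_zero(self):
        rng = np.random.default_rng(4)
        seq = rng.uniform(size=(20, 4, 4))
        s, _ = gating.estimate_relative_shift(seq, seq, 20)
        assert s == 0

    def test_constant_sequences_indistinguishable(self):
        seq = np.ones((12, 4, 4))
        with pytest.raises(IndistinguishablePhasesError):
            gating.estimate_relative_shift(seq, seq, 12)

    def test_shift_equivariance(self, noisy_scan):
        """Pre-rolling one input by k moves the estimated shift by k (mod L)."""
        cfg, scan, _ = noisy_scan
        L = cfg.period_frames
        a, b = scan.sequences[7], scan.sequences[8]
        s0, _ = gating.estimate_relative_shift(a, b, L)
        for k in (3, 11):
            s, _ = gating.estimate_relative_shift(a, np.roll(b, k, axis=0), L)
            assert s == (s0 + k) % L


class TestSynchronizeScan:
    def test_recovers_true_offsets(self, noisy_scan):
        """Every adjacent pair within +/-1 frame; chained drift stays small.

        (The mean-error bound at full acquisition scale is exercised by the
        dedicated accuracy suite; this fixture is deliberately small.)
        """
        cfg, scan, truth = noisy_scan
        vol, sync = gating.synchronize_scan(scan)
        p = cfg.period_frames
        for k in range(scan.n_slices - 1):
            s, _ = gating.estimate_relative_shift(
                scan.sequences[k], scan.sequences[k + 1], sync.period_int
            )
            true_s = (truth.slice_offsets[k] - truth.slice_offsets[k + 1]) % p
            d = (s - true_s) % p
            assert min(d, p - d) <= 1
        true_rel = (truth.slice_offsets - truth.slice_offsets[0]) % p
        err = (sync.shifts - true_rel) % p
        err = np.minimum(err, p - err)
        assert err.mean() <= 2.0
        assert vol.data.shape[0] == sync.period_int
        assert vol.data.shape[1] == scan.n_slices

    def test_zero_offsets_roundtrip(self, heart_small):
        cfg, vol, _ = heart_small
        p = cfg.period_frames
        scan = SliceScan(
            z_positions_um=np.arange(cfg.shape[0]) * cfg.voxel_size_um,
            sequences=[np.tile(vol.data[:p, k], (3, 1, 1)) for k in range(cfg.shape[0])],
            frame_rate_hz=cfg.frame_rate_hz,
            pixel_size_um=cfg.voxel_size_um,
        )
        out, sync = gating.synchronize_scan(scan)
        assert np.all(sync.shifts == 0)
        assert np.allclose(out.data, vol.data[:p])

    def test_reversed_z_matches_after_flip(self, noisy_scan):
        cfg, scan, _ = noisy_scan
        fwd, _ = gating.synchronize_scan(scan, canonical_phase=True)
        rev_scan = SliceScan(
            z_positions_um=scan.z_positions_um,
            sequences=scan.sequences[::-1],
            frame_rate_hz=scan.frame_rate_hz,
            pixel_size_um=scan.pixel_size_um,
        )
        rev, _ = gating.synchronize_scan(rev_scan, canonical_phase=True)
        assert np.allclose(fwd.data, rev.data[:, ::-1], atol=1e-5)

    def test_idempotent_on_synchronized_scan(self, noisy_scan):
        cfg, scan, _ = noisy_scan
        vol, sync = gating.synchronize_scan(scan)
        resynced = SliceScan(
            z_positions_um=scan.z_positions_um,
            sequences=[np.tile(vol.data[:, k], (3, 1, 1))
                       for k in range(vol.data.shape[1])],
            frame_rate_hz=scan.frame_rate_hz,
            pixel_size_um=scan.pixel_size_um,
        )
        _, sync2 = gating.synchronize_scan(resynced)
        assert np.all(sync2.shifts == 0)

    def test_needs_two_slices(self, noisy_scan):
        _, scan, _ = noisy_scan
        single = SliceScan(
            z_positions_um=scan.z_positions_um[:1],
            sequences=scan.sequences[:1],
            frame_rate_hz=scan.frame_rate_hz,
            pixel_size_um=scan.pixel_size_um,
        )
        with pytest.raises(ValueError):
            gating.synchronize_scan(single)


class TestTimestampPhases:
    def test_phase_zero_at_origin_and_periodic_equality(self, noisy_scan):
        cfg, scan, _ = noisy_scan
        _, sync = gating.synchronize_scan(scan)
        fps = cfg.frame_rate_hz
        ref = scan.sequences[0]
        phases = gating.assign_phases_by_timestamp(
            ref, np.array([sync.phase_origin / fps]), sync, fps
        )
        assert phases[0] == pytest.approx(0.0, abs=1e-9)
        p_s = sync.period_frames / fps
        ph = gating.assign_phases_by_timestamp(
            ref, np.array([0.1, 0.1 + p_s]), sync, fps
        )
        assert ph[0] == pytest.approx(ph[1], abs=1e-6)

    def test_phantom_particle_frames_get_generating_phase(self, noisy_scan):
        cfg, scan, truth = noisy_scan
        _, sync = gating.synchronize_scan(scan)
        fps = cfg.frame_rate_hz
        frames = np.arange(0, 60, 7)
        phases = gating.assign_phases_by_timestamp(
            scan.sequences[0], frames / fps, sync, fps
        )
        generating = (frames % cfg.period_frames) / cfg.period_frames
        err = np.abs(phases - generating)
        err = np.minimum(err, 1 - err)
        assert err.max() <= 1.0 / cfg.period_frames + 1e-6

    def test_times_outside_span_error(self, noisy_scan):
        cfg, scan, _ = noisy_scan
        _, sync = gating.synchronize_scan(scan)
        with pytest.raises(ValueError):
            gating.assign_phases_by_timestamp(
                scan.sequences[0], np.array([1e6]), sync, cfg.frame_rate_hz
            )
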