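"""Simulator tests: profile sampling, signal physics, SNR calibration,
dataset composition and determinism."""

import numpy as np
import pytest

from radarcough.config import DatasetSpec, RadarConfig
from radarcough.pipeline import preprocess, range_fft, remove_clutter
from radarcough.simulate import (SCENE_ACTIVITIES, DatasetManifest,
                                 MotionProfile, Scatterer, TransientEvent,
                                 cube_for_record, generate_manifest,
                                 sample_motion_profile, synthesize_cube)

from conftest import static_cube


class TestMotionProfiles:
    def test_breathing_has_no_transients(self):
        p = sample_motion_profile("breathing", "bed", np.random.default_rng(0))
        assert p.transient_events == []
        assert p.scatterers[0].breathing_amplitude > 0
        assert p.label == 0

    def test_cough_has_transient_and_positive_label(self):
        p = sample_motion_profile("cough", "sitting", np.random.default_rng(1))
        assert len(p.transient_events) >= 1
        assert p.label == 1
        ev = p.transient_events[0]
        assert 0.3 <= ev.duration <= 0.6
        assert 0.3 <= ev.peak_speed <= 1.0

    def test_transients_fit_inside_recording(self):
        rng = np.random.default_rng(2)
        for scene, activities in SCENE_ACTIVITIES.items():
            for activity in activities:
                p = sample_motion_profile(activity, scene, rng)
                for ev in p.transient_events:
                    assert ev.onset >= 0
                    assert ev.onset + ev.duration <= 3.0

    def test_same_seed_identical_profiles(self):
        a = sample_motion_profile("cough", "bed", np.random.default_rng(42))
        b = sample_motion_profile("cough", "bed", np.random.default_rng(42))
        assert a == b

    def test_unknown_activity_named_in_error(self):
        with pytest.raises(ValueError, match="jumping"):
            sample_motion_profile("jumping", "bed", np.random.default_rng(0))
        with pytest.raises(ValueError, match="head_move"):
            # valid activity but not in the bed-scene inventory
            sample_motion_profile("head_move", "bed", np.random.default_rng(0))


class TestTransientEvent:
    def test_pulse_shape_and_peak_speed(self):
        ev = TransientEvent(onset=1.0, duration=0.4, peak_displacement=0.05)
        t = np.linspace(0, 3, 3001)
        d = ev.displacement(t)
        assert d[t < 1.0].max() == 0
        assert d[t > 1.4].max() == 0
        assert d.max() == pytest.approx(0.05, rel=1e-3)
        speed = np.gradient(d, t)
        assert speed.max() == pytest.approx(ev.peak_speed, rel=1e-2)


class TestSynthesizeCube:
    def test_default_shape(self):
        cube = static_cube()
        assert cube.data.shape == (1500, 1, 4, 108)
        assert np.isfinite(cube.data).all()

    def test_empty_scene_noiseless_is_zero(self):
        profile = MotionProfile([], "breathing", "bed")
        cube = synthesize_cube(profile, snr_db=None)
        assert not cube.data.any()

    def test_static_scatterer_range_bin(self):
        """Beat frequency of 1.0 m -> fractional bin 21.6 -> argmax at 22."""
        cube = static_cube(range_m=1.0)
        spectra = np.abs(range_fft(cube).data)
        assert (spectra[:, 0, :].argmax(axis=-1) == 22).all()

    def test_constant_velocity_doppler_offset(self):
        """v = +0.1 m/s -> 40 Hz -> +10 Doppler bins from center ("away")."""
        cube = static_cube(range_m=1.0, velocity=0.1)
        seq = preprocess(cube)
        cols = [np.unravel_index(seq.data[t, 0].argmax(), seq.data[t, 0].shape)[1]
                for t in range(seq.num_frames)]
        assert all(abs(c - (62 + 10)) <= 1 for c in cols)

    def test_toward_radar_is_negative_side(self):
        cube = static_cube(range_m=1.5, velocity=-0.1)
        seq = preprocess(cube)
        frame = seq.data[17, 0]
        col = np.unravel_index(frame.argmax(), frame.shape)[1]
        assert col < 62

    def test_determinism_given_seed(self):
        rng_a = np.random.default_rng(5)
        rng_b = np.random.default_rng(5)
        prof_a = sample_motion_profile("cough", "bed", rng_a)
        prof_b = sample_motion_profile("cough", "bed", rng_b)
        cube_a = synthesize_cube(prof_a, snr_db=20, rng=rng_a)
        cube_b = synthesize_cube(prof_b, snr_db=20, rng=rng_b)
        np.testing.assert_array_equal(cube_a.data, cube_b.data)

    def test_realized_snr_matches_request(self, small_radar):
        """Realized SNR within +-1 dB of target, averaged over trials."""
        target_db = 15.0
        ratios = []
        for seed in range(30):
            profile = MotionProfile([Scatterer(base_range=1.0)],
                                    "breathing", "bed")
            clean = synthesize_cube(profile, small_radar, snr_db=None).data
            noisy = synthesize_cube(profile, small_radar, snr_db=target_db,
                                    rng=seed).data
            noise = noisy - clean
            ratios.append(np.mean(np.abs(clean) ** 2)
                          / np.mean(np.abs(noise) ** 2))
        realized_db = 10 * np.log10(np.mean(ratios))
        assert abs(realized_db - target_db) < 1.0

    def test_out_of_range_scatterer_rejected(self):
        profile = MotionProfile([Scatterer(base_range=8.0)], "breathing", "bed")
        with pytest.raises(ValueError, match="unambiguous"):
            synthesize_cube(profile)

    def test_nonfinite_parameters_rejected(self):
        profile = MotionProfile([Scatterer(base_range=np.nan)],
                                "breathing", "bed")
        with pytest.raises(ValueError, match="finite"):
            synthesize_cube(profile)


class TestStaticNull:
    def test_clutter_removal_nulls_static_scene(self):
        """Noiseless static scene: post-removal energy <= 1e-10 of input."""
        cube = static_cube(range_m=1.3)
        rp = range_fft(cube)
        e_pre = np.sum(np.abs(rp.data) ** 2)
        e_post = np.sum(np.abs(remove_clutter(rp).data) ** 2)
        assert e_post <= 1e-10 * e_pre


class TestDatasetComposition:
    def test_default_composition_counts(self):
        manifest = generate_manifest(DatasetSpec())
        assert len(manifest) == 3165
        assert len(manifest.filter(scene="bed")) == 1545
        assert len(manifest.filter(scene="sitting")) == 1620
        assert len(manifest.filter(label=1)) == 15 * (21 + 18)

    def test_zero_subjects_empty_manifest(self):
        manifest = generate_manifest(DatasetSpec(num_subjects=0))
        assert len(manifest) == 0

    def test_manifest_records_unique_and_seeded(self, tiny_dataset_spec):
        manifest = generate_manifest(tiny_dataset_spec)
        ids = [r.sample_id for r in manifest.records]
        assert len(set(ids)) == len(ids)
        seeds = {r.seed for r in manifest.records}
        assert len(seeds) == len(ids)  # distinct derived seeds

    def test_duplicate_sample_ids_rejected(self, tiny_dataset_spec):
        manifest = generate_manifest(tiny_dataset_spec)
        with pytest.raises(ValueError, match="duplicate"):
            DatasetManifest(manifest.records + manifest.records[:1])

    def test_record_replay_is_bit_identical(self, tiny_dataset_spec):
        manifest = generate_manifest(tiny_dataset_spec)
        rec = manifest.records[3]
        a = cube_for_record(rec, tiny_dataset_spec)
        b = cube_for_record(rec, tiny_dataset_spec)
        np.testing.assert_array_equal(a.data, b.data)
        assert a.label == rec.label
        assert a.scene == rec.scene


class TestSpectralSpread:
    @staticmethod
    def _max_doppler_spread(seq):
        mag = np.exp(seq.data[:, 0]) - 1e-6       # back to linear magnitude
        marginal = mag.sum(axis=1)                # (T, doppler bins)
        bins = np.arange(marginal.shape[1])
        spreads = []
        for t in range(marginal.shape[0]):
            w = marginal[t]
            peak = w.argmax()
            spreads.append(np.sqrt(np.sum(w * (bins - peak) ** 2) / w.sum()))
        return max(spreads)

    def test_cough_spreads_wider_than_breathing(self):
        """Cough transients broaden the Doppler spectrum vs quiet breathing."""
        wins = 0
        n = 20
        for seed in range(n):
            rng = np.random.default_rng(1000 + seed)
            cough = sample_motion_profile("cough", "bed", rng)
            breath = sample_motion_profile("breathing", "bed", rng)
            s_cough = self._max_doppler_spread(
                preprocess(synthesize_cube(cough, snr_db=20, rng=seed)))
            s_breath = self._max_doppler_spread(
                preprocess(synthesize_cube(breath, snr_db=20, rng=seed)))
            wins += s_cough > s_breath
        assert wins >= n - 2
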