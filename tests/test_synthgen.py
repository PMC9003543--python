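"""Generators: alarm tones, speech surrogate, RSSI traces, keypoints, env pairs."""

import numpy as np
import pytest
from scipy.fft import rfft, rfftfreq

from ambientkit import synthgen
from ambientkit.synthgen import (
    NOTE_TABLE,
    AlarmSpec,
    KeypointSimConfig,
    RssiSimConfig,
    default_alarm_corpus,
    synth_alarm,
    synth_keypoints,
    synth_paired_env,
    synth_rssi,
    synth_speech_surrogate,
)

FS = 22050


def _nonzero_runs(w):
    """(start, end) index pairs of maximal nonzero runs."""
    nz = np.flatnonzero(w != 0)
    if nz.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(nz) > 1)
    starts = np.r_[nz[0], nz[breaks + 1]]
    ends = np.r_[nz[breaks], nz[-1]]
    return list(zip(starts, ends + 1))


class TestAlarmSynthesis:
    def test_medium_alarm_three_bursts_with_exact_zero_gaps(self):
        spec = AlarmSpec("general", "medium", notes=("C4", "E4", "G4"))
        w = synth_alarm(spec)
        runs = _nonzero_runs(w)
        assert len(runs) == 3
        assert len(w) / FS == pytest.approx(0.9, abs=0.05)  # "about one second"
        # gap samples are exactly zero
        for (_, e1), (s2, _) in zip(runs, runs[1:]):
            assert np.all(w[e1:s2] == 0.0)

    def test_high_alarm_five_notes_twice(self):
        w = synth_alarm(AlarmSpec("general", "high"))
        assert len(_nonzero_runs(w)) == 10
        assert len(w) / FS == pytest.approx(4.5, abs=0.1)

    def test_zero_amplitude_gives_silence(self):
        w = synth_alarm(AlarmSpec("general", "medium", amplitude=0.0))
        assert np.all(w == 0.0)

    def test_unknown_note_rejected_with_name(self):
        spec = AlarmSpec("general", "medium", notes=("C4", "Q9", "G4"))
        with pytest.raises(KeyError, match="Q9"):
            synth_alarm(spec)

    @pytest.mark.parametrize("priority", ["medium", "high"])
    def test_burst_fundamentals_match_note_table(self, priority):
        """Periodogram peak of each burst lies within 1 Hz of the note's
        fundamental frequency."""
        for spec in default_alarm_corpus():
            if spec.priority != priority:
                continue
            w = synth_alarm(spec)
            expected = list(spec.notes) * spec.repeats
            runs = _nonzero_runs(w)
            assert len(runs) == len(expected)
            for (s, e), name in zip(runs, expected):
                burst = w[s:e]
                n_fft = 1 << 19
                mags = np.abs(rfft(burst, n=n_fft))
                peak = rfftfreq(n_fft, 1 / FS)[np.argmax(mags)]
                assert peak == pytest.approx(NOTE_TABLE[name], abs=1.0)

    def test_defaults_cover_all_nine_notes(self):
        used = {n for spec in default_alarm_corpus() for n in spec.notes}
        assert used == set(NOTE_TABLE)

    def test_wrong_note_count_rejected(self):
        with pytest.raises(ValueError, match="3 notes"):
            AlarmSpec("general", "medium", notes=("C4",))


class TestSpeechSurrogate:
    def test_deterministic_under_seed(self):
        a = synth_speech_surrogate(1.0, seed=42)
        b = synth_speech_surrogate(1.0, seed=42)
        np.testing.assert_array_equal(a, b)
        assert not np.allclose(a, synth_speech_surrogate(1.0, seed=43))

    def test_length_arithmetic(self):
        assert len(synth_speech_surrogate(2.0, sample_rate=FS)) == 44100

    def test_broadband_flatter_than_any_pure_tone(self):
        def flatness(x):
            p = np.abs(rfft(x)) ** 2 + 1e-30
            return np.exp(np.mean(np.log(p))) / np.mean(p)

        speech = synth_speech_surrogate(1.0, seed=0)
        t = np.arange(len(speech)) / FS
        tone = np.sin(2 * np.pi * 440.0 * t)
        assert flatness(speech) > flatness(tone)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            synth_speech_surrogate(0.0)


class TestRssiSim:
    def test_noiseless_in_room_receivers_read_exact_mean(self):
        cfg = RssiSimConfig(noise_sd=1e-300, missing_prob=0.0, seed=0)
        traces, room_map, sched = synth_rssi(cfg)
        # t=0..145 the subject stays in room 1
        for rx, room in room_map.items():
            vals = traces[rx][:146, 1]
            want = cfg.in_room_mean if room == 1 else cfg.out_room_mean
            np.testing.assert_allclose(vals, want, atol=1e-9)

    def test_retained_sample_count_binomial(self):
        cfg = RssiSimConfig(missing_prob=0.3, seed=5)
        traces, _, _ = synth_rssi(cfg)
        total = sum(len(t) for t in traces.values())
        n, p = 600 * 9, 0.7
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(total - n * p) < 3 * sigma

    def test_schedule_spans_600_seconds(self):
        _, _, sched = synth_rssi(RssiSimConfig(seed=0))
        assert sched[-1][1] == 600
        traces, _, _ = synth_rssi(RssiSimConfig(missing_prob=0.0, seed=0))
        assert all(len(t) == 600 for t in traces.values())

    def test_room_label_permutation_permutes_traces(self):
        """Relabelling rooms in the schedule renames each receiver's room
        without changing any generated values."""
        base = RssiSimConfig(seed=9)
        perm = {1: 7, 2: 5, 3: 6}
        permuted_sched = tuple(
            (s, e, tuple(perm[r] for r in rooms)) for s, e, rooms in base.schedule
        )
        t1, m1, _ = synth_rssi(base)
        t2, m2, _ = synth_rssi(RssiSimConfig(schedule=permuted_sched, seed=9))
        for rx in t1:
            np.testing.assert_array_equal(t1[rx], t2[rx])
            assert m2[rx] == perm[m1[rx]]

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            RssiSimConfig(schedule=())
        with pytest.raises(ValueError):
            RssiSimConfig(missing_prob=1.0)
        with pytest.raises(ValueError):
            RssiSimConfig(in_room_mean=-80, out_room_mean=-60)


class TestKeypointSim:
    def test_zero_jitter_standing_track_is_static(self):
        cfg = KeypointSimConfig(n_subjects=1, standing_jitter_sd=0.0, seed=1)
        frames, labels = synth_keypoints(cfg, activities=("standing",))
        assert labels == ("standing",)
        for f in frames[1:]:
            np.testing.assert_array_equal(f[0], frames[0][0])

    def test_exercise_wrist_range_matches_sinusoid_oracle(self):
        cfg = KeypointSimConfig(
            n_subjects=1, n_frames=60, standing_jitter_sd=0.0,
            exercise_amplitude=30.0, exercise_period=10, seed=2,
        )
        frames, _ = synth_keypoints(cfg, activities=("exercising",))
        wrist_y = np.array([f[0][synthgen.HAND_KEYPOINTS["left_wrist"], 1] for f in frames])
        osc = 30.0 * np.sin(2 * np.pi * np.arange(60) / 10)
        assert np.ptp(wrist_y) == pytest.approx(np.ptp(osc), abs=1e-9)

    def test_absent_subjects_emit_zero_arrays(self):
        cfg = KeypointSimConfig(n_subjects=3, seed=3)
        frames, truth = synthgen.synth_occupancy_session(cfg)
        assert truth[0] == 1
        # subjects beyond the occupancy count are all-zero arrays
        assert np.all(frames[0][1] == 0) and np.all(frames[0][2] == 0)
        assert truth[70] == 3 and all(np.any(p != 0) for p in frames[70])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            KeypointSimConfig(n_frames=1)
        with pytest.raises(ValueError):
            KeypointSimConfig(standing_jitter_sd=5.0, exercise_amplitude=4.0)


class TestPairedEnv:
    def test_zero_bias_zero_noise_aligns_exactly(self):
        fast, slow = synth_paired_env(7200, slow_period=600, bias=0.0, noise_sd=0.0)
        from ambientkit.envstats import align_windows

        aligned, slow_vals, missing = align_windows(fast, slow)
        assert missing == 0
        np.testing.assert_allclose(aligned, slow_vals, atol=1e-12)

    def test_slow_sample_count_72h(self):
        _, slow = synth_paired_env(72 * 3600, slow_period=600)
        assert len(slow) == 432

    def test_deterministic_under_seed(self):
        a = synth_paired_env(3600, noise_sd=0.5, seed=4)
        b = synth_paired_env(3600, noise_sd=0.5, seed=4)
        np.testing.assert_array_equal(a[1], b[1])
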