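"""RSSI decay interpolation, room averaging, softmax assignment, scoring."""

import numpy as np
import pytest

from ambientkit.geoloc import (
    DecayConfig,
    geolocate,
    resample_decay,
    room_average,
    room_probabilities,
    score_accuracy,
)
from ambientkit.synthgen import TRACKING_SCHEDULE, RssiSimConfig, synth_rssi


class TestResampleDecay:
    def test_short_gap_holds_previous_value(self):
        # gap of 3 s with beta=0.2: max(0.6, 1) = 1, value held
        trace = np.array([[0.0, -50.0], [10.0, -55.0]])
        out = resample_decay(trace, DecayConfig(beta=0.2), 0, 11)
        assert out[3] == -50.0

    def test_long_gap_decays_multiplicatively(self):
        trace = np.array([[0.0, -50.0]])
        out = resample_decay(trace, DecayConfig(beta=0.2), 0, 11)
        assert out[10] == pytest.approx(-50.0 * 2.0)  # max(0.2*10, 1) = 2

    def test_hold_boundary_is_five_seconds(self):
        """With beta=0.2 the previous value is maintained for gaps up to
        exactly 5 s and decays strictly beyond."""
        trace = np.array([[0.0, -50.0]])
        out = resample_decay(trace, DecayConfig(beta=0.2), 0, 30)
        held = [g for g in range(1, 30) if out[g] == -50.0]
        assert max(held) == 5
        assert all(out[g] < out[g - 1] for g in range(6, 30) if out[g] > -200)

    def test_clamp_floor(self):
        trace = np.array([[0.0, -150.0]])
        out = resample_decay(trace, DecayConfig(beta=0.2), 0, 11)
        assert out[10] == -200.0  # raw -300 clamps

    def test_grid_has_no_gaps_and_prefix_floor(self):
        trace = np.array([[5.0, -60.0]])
        out = resample_decay(trace, DecayConfig(), 0, 10)
        assert len(out) == 10 and np.all(np.isfinite(out))
        assert np.all(out[:5] == -200.0)  # no predecessor before first reading

    def test_last_write_wins_within_a_second(self):
        trace = np.array([[2.2, -40.0], [2.4, -45.0]])
        out = resample_decay(trace, DecayConfig(), 0, 4)
        assert out[2] == -45.0

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            resample_decay(np.empty((0, 2)))


class TestRoomAverage:
    def test_three_receiver_mean(self):
        series = {1: np.array([-60.0]), 2: np.array([-70.0]), 3: np.array([-80.0])}
        rooms, means = room_average(series, {1: "A", 2: "A", 3: "A"})
        assert rooms == ["A"] and means[0, 0] == -70.0

    def test_single_receiver_room_identity(self):
        series = {1: np.array([-55.0, -65.0])}
        _, means = room_average(series, {1: "A"})
        np.testing.assert_array_equal(means[:, 0], [-55.0, -65.0])

    def test_matches_per_second_loop_oracle(self, rng):
        series = {rx: rng.uniform(-90, -50, 20) for rx in range(1, 7)}
        room_map = {rx: 1 + (rx - 1) // 3 for rx in range(1, 7)}
        rooms, means = room_average(series, room_map)
        for t in range(20):
            for j, room in enumerate(rooms):
                vals = [series[rx][t] for rx in series if room_map[rx] == room]
                assert means[t, j] == pytest.approx(np.mean(vals))

    def test_unmapped_receiver_rejected(self):
        with pytest.raises(ValueError):
            room_average({1: np.zeros(3)}, {})


class TestRoomProbabilities:
    def test_equal_means_uniform(self):
        p = room_probabilities(np.full((4, 3), -70.0))
        np.testing.assert_allclose(p, 1 / 3)

    def test_shift_invariance(self):
        m = np.array([[-60.0, -70.0, -80.0]])
        np.testing.assert_allclose(
            room_probabilities(m), room_probabilities(m + 17.5), atol=1e-12
        )

    def test_exp_normalize_oracle(self):
        m = np.array([[-60.0, -70.0, -80.0]])
        e = np.exp(m[0] - m[0].max())
        np.testing.assert_allclose(room_probabilities(m)[0], e / e.sum(), rtol=1e-12)

    def test_rows_sum_to_one(self, rng):
        p = room_probabilities(rng.uniform(-100, -40, (50, 3)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(p >= 0)

    def test_single_room_rejected(self):
        with pytest.raises(ValueError):
            room_probabilities(np.full((4, 1), -70.0))


class TestScoring:
    def test_perfect_assignment(self):
        assigned = np.empty(600, dtype=int)
        for start, end, rooms in TRACKING_SCHEDULE:
            assigned[start:end] = rooms[0]
        assert score_accuracy(assigned, [1, 2, 3], TRACKING_SCHEDULE) == 1.0

    def test_known_eight_wrong_of_600(self):
        assigned = np.empty(600, dtype=int)
        for start, end, rooms in TRACKING_SCHEDULE:
            assigned[start:end] = rooms[0]
        assigned[:8] = 2  # corrupt 8 stay-in-room-1 seconds
        assert score_accuracy(assigned, [1, 2, 3], TRACKING_SCHEDULE) == 592 / 600

    def test_transition_seconds_accept_either_endpoint(self):
        assigned = np.empty(600, dtype=int)
        for start, end, rooms in TRACKING_SCHEDULE:
            assigned[start:end] = rooms[0]
        assigned[146:159] = 2  # destination room during the 1->2 transition
        assert score_accuracy(assigned, [1, 2, 3], TRACKING_SCHEDULE) == 1.0

    def test_uncovered_series_rejected(self):
        with pytest.raises(ValueError):
            score_accuracy(np.ones(100, dtype=int), [1], TRACKING_SCHEDULE)


class TestEndToEnd:
    def test_noiseless_traces_recover_schedule_exactly(self):
        cfg = RssiSimConfig(noise_sd=1e-300, missing_prob=0.0, seed=0)
        traces, room_map, sched = synth_rssi(cfg)
        _, _, assigned = geolocate(traces, room_map, t_start=0, t_end=600)
        from ambientkit.synthgen import room_membership

        for t in range(600):
            members = room_membership(sched, float(t))
            if len(members) == 1:  # non-transition seconds
                assert assigned[t] == next(iter(members))

    def test_default_noise_meets_reported_accuracy(self):
        traces, room_map, sched = synth_rssi(RssiSimConfig(seed=11))
        rooms, probs, assigned = geolocate(traces, room_map, t_start=0, t_end=600)
        assert probs.shape == (600, 3)
        assert score_accuracy(assigned, rooms, sched) >= 0.9867
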