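"""Adaptive-duration grouping of gait events into walking bouts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitbouts import (
    GroupingParams,
    SimConfig,
    ThresholdSpec,
    ValidationError,
    bouts_to_labels,
    detect_walking_bouts,
    filter_true_locomotion,
    group_events,
    merge_bilateral,
    simulate_recording,
)
from gaitbouts.peaks import PeakSet


def brute_force_grouping(times, params):
    """Independent oracle: enumerate every contiguous partition and keep
    the one satisfying the duration-threshold rule at every position."""

    def th_after(block):
        th = params.init_gap
        for i in range(1, len(block)):
            mean_dur = (block[i] - block[0]) / i
            th = min(params.update_offset + mean_dur, params.gap_cap)
        return th

    def valid(blocks):
        for block in blocks:
            th = params.init_gap
            for i in range(1, len(block)):
                if block[i] - block[i - 1] > th:
                    return False
                mean_dur = (block[i] - block[0]) / i
                th = min(params.update_offset + mean_dur, params.gap_cap)
        for a, b in zip(blocks, blocks[1:]):
            if b[0] - a[-1] <= th_after(a):
                return False
        return True

    n = len(times)
    solutions = []
    for mask in range(2 ** (n - 1)):
        blocks, cur = [], [times[0]]
        for i in range(1, n):
            if (mask >> (i - 1)) & 1:
                blocks.append(cur)
                cur = [times[i]]
            else:
                cur.append(times[i])
        blocks.append(cur)
        if valid(blocks):
            solutions.append(blocks)
    assert len(solutions) == 1, "duration-threshold rule must pick one partition"
    return solutions[0]


class TestGroupEvents:
    def test_gap_above_updated_threshold_splits(self):
        # strides 1 s apart -> TH_d = min(3+1, 5) = 4 s; the 6 s gap splits
        bouts = group_events(
            np.array([0.0, 1, 2, 8, 9, 10, 11]), GroupingParams.single_imu()
        )
        assert [b.events.tolist() for b in bouts] == [[0, 1, 2], [8, 9, 10, 11]]

    def test_initial_gap_applies_to_first_pair(self):
        bouts = group_events(np.array([0.0, 4.9]), GroupingParams.single_imu())
        assert len(bouts) == 1

    def test_empty_input(self):
        assert group_events(np.array([]), GroupingParams.single_imu()) == []

    def test_unsorted_rejected(self):
        with pytest.raises(ValidationError):
            group_events(np.array([1.0, 0.5]), GroupingParams.single_imu())

    def test_slow_gait_held_together_by_cap(self):
        # 3 s strides (cadence ~40 steps/min): TH_d = min(3+3, 5) = 5 s
        times = np.arange(0.0, 30.0, 3.0)
        bouts = group_events(times, GroupingParams.single_imu())
        assert len(bouts) == 1
        assert bouts[0].n_events == times.size

    @pytest.mark.parametrize("params_factory", [GroupingParams.single_imu, GroupingParams.dual_imu])
    def test_matches_brute_force_oracle(self, params_factory):
        params = params_factory()
        rng = np.random.default_rng(2024)
        for _ in range(250):
            n = int(rng.integers(1, 13))
            times = np.cumsum(rng.uniform(0.2, 7.0, size=n))
            got = [b.events.tolist() for b in group_events(times, params)]
            assert got == brute_force_grouping(list(times), params)

    @given(gaps=st.lists(st.floats(0.1, 8.0), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_partition_property(self, gaps):
        """Bouts partition the events: order preserved, none lost or invented."""
        times = np.cumsum(np.asarray(gaps))
        bouts = group_events(times, GroupingParams.single_imu())
        recovered = np.concatenate([b.events for b in bouts])
        np.testing.assert_array_equal(recovered, times)
        for b in bouts:
            assert b.start == b.events[0]
            assert b.end == b.events[-1]
        # bouts are time-ordered and non-overlapping
        for a, b in zip(bouts, bouts[1:]):
            assert a.end < b.start


class TestMergeBilateral:
    @staticmethod
    def peak_set(times):
        times = np.asarray(times, float)
        return PeakSet(times=times, amplitudes=np.full(times.size, 200.0))

    def test_interleaved(self):
        merged = merge_bilateral(self.peak_set([0, 1, 2]), self.peak_set([0.5, 1.5, 2.5]))
        np.testing.assert_allclose(merged, [0, 0.5, 1, 1.5, 2, 2.5])

    def test_one_empty_side(self):
        merged = merge_bilateral(self.peak_set([]), self.peak_set([1.0, 2.0]))
        np.testing.assert_allclose(merged, [1.0, 2.0])

    def test_large_random_merge_is_sorted_union(self):
        rng = np.random.default_rng(3)
        left = np.sort(rng.uniform(0, 1000, 1000))
        right = np.sort(rng.uniform(0, 1000, 1000))
        merged = merge_bilateral(self.peak_set(left), self.peak_set(right))
        assert merged.size == 2000
        np.testing.assert_array_equal(merged, np.sort(np.concatenate([left, right])))


class TestFilterTrueLocomotion:
    @staticmethod
    def bout_with(n_events, config):
        from gaitbouts import WalkingBout

        ev = np.arange(n_events, dtype=float)
        return WalkingBout(ev[0], ev[-1], ev, config, "gyro")

    @pytest.mark.parametrize("n,kept", [(4, False), (5, True)])
    def test_five_step_rule_dual(self, n, kept):
        bouts = [self.bout_with(n, "dual_imu")]
        out = filter_true_locomotion(bouts, GroupingParams.dual_imu())
        assert (len(out) == 1) is kept

    @pytest.mark.parametrize("n,kept", [(2, False), (3, True)])
    def test_three_stride_rule_single(self, n, kept):
        bouts = [self.bout_with(n, "single_imu")]
        out = filter_true_locomotion(bouts, GroupingParams.single_imu())
        assert (len(out) == 1) is kept


class TestDetectWalkingBouts:
    def test_three_clean_bouts_recovered(self):
        rec, truth = simulate_recording(SimConfig(seed=7, artifact_rate=0.0))
        bouts = detect_walking_bouts(rec, ThresholdSpec(method="adaptive"))
        assert len(bouts) == 3
        for det, ref in zip(bouts, truth.bouts):
            overlap = min(det.end, ref.end) - max(det.start, ref.start)
            assert overlap / (ref.end - ref.start) > 0.9

    def test_rest_noise_yields_nothing(self):
        rec, _ = simulate_recording(SimConfig(seed=5, n_bouts=0, artifact_rate=0.0))
        assert detect_walking_bouts(rec) == []

    def test_fixed_labels_superset_of_adaptive(self, default_scenario):
        rec, _ = default_scenario
        fixed = bouts_to_labels(
            detect_walking_bouts(rec, ThresholdSpec(method="fixed")), rec.duration
        ).values
        adaptive = bouts_to_labels(
            detect_walking_bouts(rec, ThresholdSpec(method="adaptive")), rec.duration
        ).values
        assert np.all(fixed >= adaptive)

    def test_dual_configuration(self):
        (left, right), truth = simulate_recording(
            SimConfig(seed=9, bilateral=True, artifact_rate=0.0)
        )
        bouts = detect_walking_bouts((left, right))
        assert len(bouts) == len(truth.bouts)
        assert all(b.config == "dual_imu" for b in bouts)
        # merged step events: roughly twice the single-foot stride count
        total = sum(b.n_events for b in bouts)
        assert total > sum(bt.stride_times_right.size for bt in truth.bouts)

    def test_unsynchronized_pair_rejected(self):
        (left, right), _ = simulate_recording(
            SimConfig(seed=9, bilateral=True, artifact_rate=0.0)
        )
        from gaitbouts import ImuRecording

        shifted = ImuRecording(
            side="right", fs=right.fs, t=right.t + 0.5, gyro=right.gyro, acc=right.acc
        )
        with pytest.raises(ValidationError):
            detect_walking_bouts((left, shifted))
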