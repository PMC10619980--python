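"""The activity statistic: z-score, binarize, rolling-sum call, events, epochs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from dualsleep import activity as act
from dualsleep.synthetic import SimConfig, make_behavior_log, make_traces


# ---------------------------------------------------------------- oracles
def window_scan_oracle(row, window, min_count):
    """Exhaustive scan of every window of `window` consecutive frames."""
    return any(
        row[i : i + window].sum() >= min_count for i in range(len(row) - window + 1)
    )


def peak_oracle(row, min_height, min_separation):
    """Brute-force peak enumeration with tallest-first greedy suppression."""
    peaks = [
        i
        for i in range(1, len(row) - 1)
        if row[i] > row[i - 1] and row[i] > row[i + 1] and row[i] > min_height
    ]
    kept = []
    for i in sorted(peaks, key=lambda i: (-row[i], i)):
        if all(abs(i - j) >= min_separation for j in kept):
            kept.append(i)
    return len(kept)


# ---------------------------------------------------------------- zscore
class TestZscore:
    def test_constant_row_zeroed_and_flagged(self):
        z = act.zscore(np.full((1, 10), 4.0))
        assert np.array_equal(z.values, np.zeros((1, 10)))
        assert z.degenerate[0]

    def test_standardized_row_unchanged(self, rng):
        x = rng.normal(size=(1, 500))
        x = (x - x.mean()) / x.std()
        z = act.zscore(x)
        assert np.abs(z.values - x).max() < 1e-12
        assert not z.degenerate[0]

    def test_matches_direct_formula(self, rng):
        x = rng.normal(2.0, 3.0, size=(5, 100))
        z = act.zscore(x)
        for row, zrow in zip(x, z.values):
            assert np.allclose(zrow, (row - row.mean()) / row.std())

    def test_rows_have_zero_mean_unit_sd(self, rng):
        z = act.zscore(rng.normal(size=(4, 200)))
        assert np.allclose(z.values.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.values.std(axis=1), 1, atol=1e-12)


# ---------------------------------------------------------------- binarize
class TestBinarize:
    def test_all_zero_input_all_zero_output(self):
        assert act.binarize(np.zeros((2, 5))).values.sum() == 0

    def test_threshold_is_strict(self):
        b = act.binarize(np.array([[3.0, 3.0001, 2.9999]]))
        assert b.values.tolist() == [[0, 1, 0]]

    def test_matches_elementwise_comparison(self, rng):
        z = rng.normal(0, 2, size=(10, 50))
        assert np.array_equal(act.binarize(z).values, (z > 3.0).astype(int))


# ---------------------------------------------------------------- classify
class TestClassifyActive:
    @pytest.mark.parametrize("k,expected", [(6, False), (7, True), (8, True)])
    def test_k_ones_in_a_window(self, k, expected):
        row = np.zeros(100, dtype=int)
        row[10 : 10 + k] = 1
        (call,) = act.classify_active(row[None, :])
        assert call.is_active is expected

    def test_scattered_ones_max_window_sum_six_inactive(self):
        # 1s spaced so that no 10-frame window catches more than 6
        row = np.zeros(200, dtype=int)
        row[::2][:50] = 1  # alternating: any 10-window holds 5
        (call,) = act.classify_active(row[None, :])
        assert not call.is_active

    def test_all_zero_inactive(self):
        (call,) = act.classify_active(np.zeros((1, 20), dtype=int))
        assert not call.is_active

    def test_matches_exhaustive_scan_on_random_rows(self, rng):
        rows = (rng.random((1000, 200)) < 0.25).astype(int)
        calls = act.classify_active(rows)
        for row, call in zip(rows, calls):
            assert call.is_active == window_scan_oracle(row, 10, 7)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            act.classify_active(np.zeros((1, 5), dtype=int))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        row=hnp.arrays(np.int8, st.integers(10, 200), elements=st.integers(0, 1)),
        extra=st.integers(0, 5),
    )
    def test_monotone_adding_ones_never_deactivates(self, row, extra):
        row = row.astype(int)
        (before,) = act.classify_active(row[None, :])
        more = row.copy()
        if extra and (more == 0).any():
            zeros = np.flatnonzero(more == 0)[:extra]
            more[zeros] = 1
        (after,) = act.classify_active(more[None, :])
        assert after.is_active or not before.is_active


# ---------------------------------------------------------------- percent
class TestPercentActive:
    @pytest.mark.parametrize("flags,expected", [([0] * 10, 0.0), ([1] * 10, 100.0), ([1, 1, 1, 0, 0, 0, 0, 0], 37.5)])
    def test_arithmetic(self, flags, expected):
        assert act.percent_active(np.array(flags, dtype=bool)) == expected

    def test_zero_neurons_rejected(self):
        with pytest.raises(ValueError):
            act.percent_active(np.array([], dtype=bool))

    def test_per_slice_grouping(self):
        flags = np.array([1, 0, 1, 1], dtype=bool)
        groups = np.array([0, 0, 1, 1])
        assert act.percent_active(flags, groups) == {0: 50.0, 1: 100.0}

    def test_lower_threshold_never_lowers_percent_active(self, rng):
        z = rng.normal(0, 2, size=(50, 100))
        pct = [
            act.percent_active(act.classify_active(act.binarize(z, thr), window=10, min_count=3))
            for thr in (3.0, 2.0, 1.0)
        ]
        assert pct[0] <= pct[1] <= pct[2]


# ---------------------------------------------------------------- events
class TestCountEvents:
    def test_flat_trace_zero_events(self):
        assert act.count_events(np.zeros((1, 100)))[0] == 0

    def test_two_separated_bumps_counted_two(self):
        z = np.zeros((1, 300))
        z[0, 100] = z[0, 200] = 5.0
        assert act.count_events(z)[0] == 2

    def test_two_close_bumps_suppressed_to_one(self):
        z = np.zeros((1, 300))
        z[0, 100] = z[0, 110] = 5.0
        assert act.count_events(z)[0] == 1

    def test_bump_below_min_height_ignored(self):
        z = np.zeros((1, 100))
        z[0, 50] = 2.9
        assert act.count_events(z)[0] == 0

    def test_matches_bruteforce_oracle_on_random_traces(self, rng):
        traces = rng.normal(0, 2, size=(500, 300))
        counts = act.count_events(traces)
        for row, n in zip(traces, counts):
            assert n == peak_oracle(row, 3.0, 30)


# ---------------------------------------------------------------- overlap
class TestEpochOverlap:
    def test_identical_sets_full_overlap(self):
        pct, inter = act.epoch_overlap({1, 2, 3}, {1, 2, 3})
        assert pct == 100.0 and inter == {1, 2, 3}

    def test_disjoint_sets_zero(self):
        pct, inter = act.epoch_overlap({1, 2}, {3, 4})
        assert pct == 0.0 and inter == set()

    def test_half_overlap_against_a(self):
        pct, _ = act.epoch_overlap(set(range(1, 11)), set(range(6, 21)), denominator="a")
        assert pct == 50.0

    def test_union_denominator_is_symmetric(self, rng):
        a = set(rng.integers(0, 50, 20).tolist())
        b = set(rng.integers(0, 50, 20).tolist())
        ab, _ = act.epoch_overlap(a, b, denominator="union")
        ba, _ = act.epoch_overlap(b, a, denominator="union")
        assert ab == ba

    def test_empty_denominator_is_missing(self):
        pct, _ = act.epoch_overlap(set(), {1}, denominator="a")
        assert np.isnan(pct)


# ---------------------------------------------------------------- epochs
class TestDefineEpochs:
    def test_inactivity_from_frame_f(self):
        fs = 2.0
        movement = np.ones(int(20 * 60 * fs))
        F = 100
        movement[F:] = 0
        epochs = act.define_epochs(movement, fs)
        by_name = {e.name: e for e in epochs}
        onset_frames = int(30 * fs)
        ep_frames = int(5 * 60 * fs)
        assert by_name["early"].start_frame == F + onset_frames
        assert by_name["early"].end_frame == F + onset_frames + ep_frames
        assert by_name["mid"].start_frame == by_name["early"].end_frame

    def test_fully_active_no_sleep_epochs(self):
        epochs = act.define_epochs(np.ones(1000), fs=2.0)
        assert epochs == []

    def test_baseline_window_emitted(self):
        epochs = act.define_epochs(np.ones(500), fs=1.0, baseline_end_frame=300)
        assert epochs[0].name == "wake"
        assert (epochs[0].start_frame, epochs[0].end_frame) == (0, 300)

    def test_epochs_match_planted_state_sequence(self):
        # map a planted per-minute state sequence to frames and check the
        # epoch boundaries against the known sleep onset
        cfg = SimConfig(seed=21)
        log, truth = make_behavior_log(cfg, n_days=1)
        fs = 1.0 / 60.0  # one frame per minute
        movement = (truth.state_sequence == "wake").astype(float)
        first_sleep = next(
            s for s, d, state in truth.true_bouts if state == "sleep" and d >= 1
        )
        epochs = act.define_epochs(movement, fs, onset_quiescence_s=60.0, epoch_min=5.0)
        by_name = {e.name: e for e in epochs}
        assert by_name["early"].start_frame == first_sleep + 1  # 1 min of quiescence
        assert by_name["early"].n_frames == 5


# ------------------------------------------------- end-to-end recovery
class TestParameterRecovery:
    def test_sensitivity_and_specificity_on_default_traces(self):
        """With default synthetic traces (amplitude >= 5x noise SD), the
        z->binarize->rolling-sum chain recovers planted active neurons with
        sensitivity and specificity >= 0.95."""
        cfg = SimConfig(seed=11, n_active=100, n_silent=100)
        tm, truths = make_traces(cfg)
        calls = act.classify_active(act.binarize(act.zscore(tm)))
        flags = np.array([c.is_active for c in calls])
        truth = np.array([t.is_active for t in truths])
        eligible = np.array([t.event_times.size >= 2 for t in truths])
        assert flags[truth & eligible].mean() >= 0.95
        assert (~flags[~truth]).mean() >= 0.95
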