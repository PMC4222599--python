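"""Window sampling and scene-feature extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import intrumem as im
from intrumem.windows import FLASHBACK, INITIAL6, POST12, POTENTIAL, REMAINDER, SCENE_WINDOWS


def _loop_mean(series, start, end, tr):
    """Independent brute-force oracle: loop every timepoint, test membership."""
    total, count = 0.0, 0
    for i, value in enumerate(series):
        t = i * tr
        if start - 1e-9 <= t < end - 1e-9:
            total += value
            count += 1
    return total / count if count else None


class TestWindowSamples:
    @pytest.mark.parametrize(
        "window, expected",
        [
            (INITIAL6, [0, 1]),
            (REMAINDER, [2, 3, 4]),
            (POST12, [5, 6, 7, 8]),
        ],
    )
    def test_canonical_scene_tr3(self, window, expected):
        idx = im.window_samples(window, onset=0.0, duration=15.0, tr=3.0, n_timepoints=40)
        assert idx.tolist() == expected

    def test_offgrid_onset(self):
        # onset 4 s, TR 3: first acquisition inside [4, 10) is t=6 (index 2)
        idx = im.window_samples(INITIAL6, onset=4.0, duration=15.0, tr=3.0, n_timepoints=40)
        assert idx.tolist() == [2, 3]

    def test_six_second_scene_has_empty_remainder(self):
        idx = im.window_samples(REMAINDER, onset=0.0, duration=6.0, tr=3.0, n_timepoints=40)
        assert idx.size == 0

    def test_window_past_run_end_raises(self):
        with pytest.raises(ValueError, match="past the end"):
            im.window_samples(POST12, onset=3.0, duration=12.0, tr=3.0, n_timepoints=5)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        onset=st.floats(0.0, 60.0),
        duration=st.floats(6.0, 40.0),
        tr=st.sampled_from([1.0, 2.0, 3.0]),
    )
    def test_initial_and_remainder_partition_the_scene(self, onset, duration, tr):
        n = int((onset + duration) / tr) + 20
        initial = im.window_samples(INITIAL6, onset, duration, tr, n)
        remainder = im.window_samples(REMAINDER, onset, duration, tr, n)
        scene = [
            i for i in range(n) if onset - 1e-9 <= i * tr < onset + duration - 1e-9
        ]
        assert set(initial).isdisjoint(remainder)
        assert sorted([*initial, *remainder]) == scene

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        onset=st.floats(0.0, 30.0),
        duration=st.floats(7.0, 20.0),
        shift=st.integers(0, 10),
    )
    def test_shift_equivariance_by_whole_trs(self, onset, duration, shift):
        tr = 3.0
        n = 60
        for window in SCENE_WINDOWS:
            base = im.window_samples(window, onset, duration, tr, n)
            moved = im.window_samples(window, onset + shift * tr, duration, tr, n + shift)
            assert np.array_equal(moved, base + shift)


def _timecourses(values, tr=3.0, pid="sub-01"):
    return im.ComponentTimecourses(participant_id=pid, values=np.asarray(values, float), tr=tr)


def _schedule(onsets, durations, run_duration):
    return im.SceneSchedule(
        onsets=np.asarray(onsets, float),
        durations=np.asarray(durations, float),
        scene_ids=np.arange(1, len(onsets) + 1),
        run_duration=run_duration,
    )


def _labels(schedule, flashback_ids=()):
    return pd.Series(
        [FLASHBACK if s in flashback_ids else POTENTIAL for s in schedule.scene_ids],
        index=pd.Index(schedule.scene_ids, name="scene_id"),
    )


class TestSceneFeatures:
    def test_constant_timecourse_gives_constant_features(self):
        schedule = _schedule([6.0], [15.0], 60.0)
        tcs = _timecourses(np.full((2, 20), 7.5))
        table = im.extract_scene_features(tcs, schedule, _labels(schedule))
        assert np.allclose(table.X, 7.5)

    def test_39_components_give_117_features(self):
        schedule = _schedule([6.0], [15.0], 60.0)
        tcs = _timecourses(np.random.default_rng(0).standard_normal((39, 20)))
        table = im.extract_scene_features(tcs, schedule, _labels(schedule))
        assert table.n_features == 117
        assert table.X.shape == (1, 117)

    def test_features_match_bruteforce_loop(self, rng):
        # 100 random scenes against the independent loop-mean oracle
        onsets = np.cumsum(rng.uniform(19.0, 25.0, size=100)) - 15.0
        durations = rng.uniform(7.0, 18.0, size=100)
        run_duration = float(onsets[-1] + durations[-1] + 12.0)
        schedule = _schedule(onsets, durations, run_duration)
        n_time = int(np.ceil(run_duration / 3.0))
        tcs = _timecourses(rng.standard_normal((3, n_time)))
        table = im.extract_scene_features(tcs, schedule, _labels(schedule, flashback_ids={1}))
        for row_idx, (onset, duration) in enumerate(zip(onsets, durations)):
            for comp in range(3):
                for window in SCENE_WINDOWS:
                    start, end = window.bounds(onset, duration)
                    expected = _loop_mean(tcs.values[comp], start, end, 3.0)
                    if expected is None:  # remainder fallback
                        start, end = INITIAL6.bounds(onset, duration)
                        expected = _loop_mean(tcs.values[comp], start, end, 3.0)
                    got = table.frame.iloc[row_idx][im.feature_name(comp, window.tag)]
                    assert got == pytest.approx(expected, abs=1e-12)

    def test_short_scene_reuses_initial_mean_for_remainder(self):
        schedule = _schedule([6.0], [6.0], 60.0)
        tcs = _timecourses(np.random.default_rng(1).standard_normal((2, 20)))
        table = im.extract_scene_features(tcs, schedule, _labels(schedule))
        for comp in range(2):
            assert (
                table.frame.at[0, im.feature_name(comp, "remainder")]
                == table.frame.at[0, im.feature_name(comp, "initial6")]
            )

    def test_subsecond_scene_is_unusable(self):
        schedule = _schedule([1.0], [1.5], 60.0)
        tcs = _timecourses(np.zeros((1, 20)))
        with pytest.raises(ValueError, match="unusable"):
            im.extract_scene_features(tcs, schedule, _labels(schedule))

    def test_labels_carried_from_diary(self):
        schedule = _schedule([6.0, 40.0], [15.0, 15.0], 80.0)
        tcs = _timecourses(np.zeros((1, 27)))
        table = im.extract_scene_features(tcs, schedule, _labels(schedule, flashback_ids={2}))
        assert table.frame["label"].tolist() == [POTENTIAL, FLASHBACK]
        assert table.y.tolist() == [0, 1]


class TestVoxelFeatures:
    def test_subset_size_sets_feature_count(self, rng):
        run = im.BoldRun("sub-01", rng.standard_normal((10, 10, 20, 50)), tr=3.0)
        schedule = _schedule([6.0, 40.0], [15.0, 15.0], 150.0)
        subset = rng.choice(2000, size=1000, replace=False)
        table = im.extract_voxel_scene_features(run, schedule, subset)
        assert table.shape == (2, 1000)

    def test_single_timepoint_scene_equals_that_sample(self, rng):
        run = im.BoldRun("sub-01", rng.standard_normal((4, 4, 2, 30)), tr=3.0)
        schedule = _schedule([6.0], [3.0], 90.0)  # exactly one acquisition (t=6)
        table = im.extract_voxel_scene_features(run, schedule)
        assert np.allclose(table.to_numpy()[0], run.flat()[2])

    def test_matches_bruteforce_loop(self, rng):
        run = im.BoldRun("sub-01", rng.standard_normal((4, 4, 2, 60)), tr=3.0)
        schedule = _schedule([6.0, 40.0, 90.0], [15.0, 10.0, 20.0], 180.0)
        table = im.extract_voxel_scene_features(run, schedule)
        flat = run.flat()
        for row, (onset, duration) in enumerate(zip(schedule.onsets, schedule.durations)):
            for voxel in range(flat.shape[1]):
                expected = _loop_mean(flat[:, voxel], onset, onset + duration, 3.0)
                assert table.iloc[row, voxel] == pytest.approx(expected, abs=1e-12)

    def test_empty_subset_rejected(self, rng):
        run = im.BoldRun("sub-01", rng.standard_normal((4, 4, 2, 30)), tr=3.0)
        schedule = _schedule([6.0], [15.0], 90.0)
        with pytest.raises(ValueError, match="non-empty"):
            im.extract_voxel_scene_features(run, schedule, np.array([], dtype=int))
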