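"""Generator behaviour: schedules, diaries, planted BOLD signal."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import intrumem as im
from intrumem.windows import FLASHBACK, POTENTIAL, SCENE_WINDOWS


def _scan_schedule(schedule: im.SceneSchedule, gap: float, tail: float) -> None:
    """Brute-force row scan of the schedule invariants."""
    rows = list(zip(schedule.onsets, schedule.durations))
    for (o1, d1), (o2, _d2) in zip(rows, rows[1:]):
        assert o2 > o1
        assert o2 - (o1 + d1) >= gap - 1e-9, "post-scene window overlaps next scene"
    worst = max(o + d + tail for o, d in rows)
    assert worst <= schedule.run_duration + 1e-9


class TestSceneSchedule:
    def test_default_schedule_has_20_nonoverlapping_scenes(self):
        cfg = im.default_config(seed=3)
        schedule = im.make_scene_schedule(cfg)
        assert schedule.n_scenes == 20
        _scan_schedule(schedule, cfg.inter_scene_gap, cfg.post_run_tail)

    def test_degenerate_single_scene(self):
        cfg = im.default_config(
            seed=0, n_scenes=1, scene_duration_range=(9.0, 9.0), initial_rest=0.0
        )
        schedule = im.make_scene_schedule(cfg)
        assert schedule.onsets[0] == 0.0
        assert schedule.durations[0] == 9.0

    def test_run_too_short_names_deficit(self):
        cfg = im.default_config(seed=0, run_duration=100.0)
        with pytest.raises(ValueError, match="short"):
            im.make_scene_schedule(cfg)

    def test_deterministic_given_seed(self):
        a = im.make_scene_schedule(im.default_config(seed=9))
        b = im.make_scene_schedule(im.default_config(seed=9))
        assert np.array_equal(a.onsets, b.onsets)
        assert np.array_equal(a.durations, b.durations)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        n_scenes=st.integers(1, 12),
        seed=st.integers(0, 10_000),
        dur_lo=st.floats(4.0, 15.0),
        extra=st.floats(0.0, 10.0),
    )
    def test_any_schedule_fits_its_run(self, n_scenes, seed, dur_lo, extra):
        cfg = im.default_config(
            seed=seed, n_scenes=n_scenes, scene_duration_range=(dur_lo, dur_lo + extra)
        )
        schedule = im.make_scene_schedule(cfg)
        _scan_schedule(schedule, cfg.inter_scene_gap, cfg.post_run_tail)


class TestDiaries:
    def test_unconditioned_mean_flashback_count_is_three(self):
        cfg = im.default_config(seed=11, n_participants=10_000)
        schedule = im.make_scene_schedule(cfg)
        diaries = im.sample_diaries(schedule, cfg, resample_zero=False)
        counts = diaries.flashback_counts()
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - 0.15 * 20) < 2 * se

    def test_conditional_mean_matches_closed_form(self):
        # E[count | count >= 1] = np / (1 - (1-p)^n)
        cfg = im.default_config(seed=12, n_participants=20_000)
        schedule = im.make_scene_schedule(cfg)
        diaries = im.sample_diaries(schedule, cfg, resample_zero=True)
        counts = diaries.flashback_counts()
        expected = (0.15 * 20) / (1 - 0.85**20)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert counts.min() >= 1
        assert abs(counts.mean() - expected) < 3 * se

    def test_p_near_one_makes_every_scene_flashback(self):
        cfg = im.default_config(seed=0, n_participants=5, intrusion_prob=1 - 1e-12)
        schedule = im.make_scene_schedule(cfg)
        diaries = im.sample_diaries(schedule, cfg)
        assert (diaries.frame["label"] == FLASHBACK).all()

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.2])
    def test_invalid_probability_rejected(self, p):
        with pytest.raises(ValueError, match="intrusion_prob"):
            im.default_config(intrusion_prob=p)

    def test_cohort_label_ratio_tracks_probability(self):
        cfg = im.default_config(seed=13, n_participants=1000)
        schedule = im.make_scene_schedule(cfg)
        diaries = im.sample_diaries(schedule, cfg, resample_zero=False)
        counts = diaries.class_counts()
        share = counts[FLASHBACK] / counts.sum()
        # potential:flashback ~ 17:3 at p = 0.15
        assert abs(share - 0.15) < 3 * np.sqrt(0.15 * 0.85 / counts.sum())

    def test_one_label_per_pair_enforced(self):
        frame = pd.DataFrame(
            {
                "participant_id": ["a", "a"],
                "scene_id": [1, 1],
                "label": [FLASHBACK, POTENTIAL],
            }
        )
        with pytest.raises(ValueError, match="more than one label"):
            im.DiaryLabels(frame)


def _single_network_setup(effect):
    cfg = im.default_config(
        seed=21,
        n_participants=1,
        n_scenes=4,
        grid_shape=(8, 8, 4),
        noise_sd=0.0,
        amplitude_jitter=0.0,
    )
    nets = im.make_networks(cfg, n_networks=1, n_predictive=1, effect=effect)
    schedule = im.make_scene_schedule(cfg)
    labels = pd.Series(
        [FLASHBACK, POTENTIAL, POTENTIAL, POTENTIAL],
        index=pd.Index(schedule.scene_ids, name="scene_id"),
    )
    return cfg, nets, schedule, labels


class TestBoldSimulation:
    def test_null_signal_equals_baseline_convolution(self):
        cfg, nets, schedule, labels = _single_network_setup(effect=0.0)
        run = im.simulate_participant_bold(schedule, labels, nets, cfg)
        baseline = im.convolve_events(
            schedule.onsets,
            schedule.durations,
            np.full(schedule.n_scenes, nets[0].baseline_amplitude),
            cfg.tr,
            run.n_timepoints,
        )
        expected = np.outer(nets[0].flat_map, baseline)
        assert np.allclose(run.flat().T, expected, atol=1e-10)

    def test_least_squares_recovers_planted_amplitudes(self):
        """Regressing the known convolved design on noiseless data returns
        the baseline and flashback-effect amplitudes exactly."""
        cfg, nets, schedule, labels = _single_network_setup(effect=2.0)
        run = im.simulate_participant_bold(schedule, labels, nets, cfg)
        n = run.n_timepoints
        scene_reg = im.convolve_events(
            schedule.onsets, schedule.durations, np.ones(schedule.n_scenes), cfg.tr, n
        )
        onset, duration = schedule.onsets[0], schedule.durations[0]
        starts, lengths = [], []
        for window in SCENE_WINDOWS:
            s, e = window.bounds(onset, duration)
            starts.append(s)
            lengths.append(e - s)
        effect_reg = im.convolve_events(starts, lengths, np.ones(3), cfg.tr, n)
        design = np.column_stack([scene_reg, effect_reg])
        voxel = np.abs(nets[0].flat_map).argmax()
        coef, *_ = np.linalg.lstsq(design, run.flat()[:, voxel], rcond=None)
        map_value = nets[0].flat_map[voxel]
        assert np.allclose(
            coef, [nets[0].baseline_amplitude * map_value, 2.0 * map_value], atol=1e-8
        )

    def test_same_seed_bit_identical(self):
        cfg, nets, schedule, labels = _single_network_setup(effect=1.0)
        cfg_noise = im.SimulationConfig(
            **{**cfg.__dict__, "noise_sd": 1.0, "amplitude_jitter": 2.0}
        )
        rng_a = np.random.default_rng(55)
        rng_b = np.random.default_rng(55)
        a = im.simulate_participant_bold(schedule, labels, nets, cfg_noise, rng=rng_a)
        b = im.simulate_participant_bold(schedule, labels, nets, cfg_noise, rng=rng_b)
        assert np.array_equal(a.data, b.data)

    def test_grid_mismatch_raises(self):
        cfg, nets, schedule, labels = _single_network_setup(effect=0.0)
        bad_cfg = im.default_config(
            seed=21, n_participants=1, n_scenes=4, grid_shape=(6, 6, 4)
        )
        with pytest.raises(ValueError, match="grid"):
            im.simulate_participant_bold(schedule, labels, nets, bad_cfg)


class TestStudy:
    def test_default_cohort_has_35_runs(self, default_study):
        assert len(default_study.runs) == 35
        assert len(set(default_study.participant_ids)) == 35

    def test_study_of_one_is_well_formed(self):
        cfg = im.default_config(
            seed=4, n_participants=1, n_scenes=5, grid_shape=(6, 6, 3)
        )
        study = im.simulate_study(cfg, im.make_networks(cfg, n_networks=3))
        assert len(study.runs) == 1
        assert study.runs[0].n_timepoints == int(
            np.ceil(study.schedule.run_duration / cfg.tr)
        )

    def test_same_seed_reproduces_study(self):
        cfg = im.default_config(seed=6, n_participants=2, n_scenes=4, grid_shape=(6, 6, 3))
        nets = im.make_networks(cfg, n_networks=3, n_predictive=1)
        a = im.simulate_study(cfg, nets)
        b = im.simulate_study(cfg, nets)
        for ra, rb in zip(a.runs, b.runs):
            assert np.array_equal(ra.data, rb.data)
        assert a.diaries.frame.equals(b.diaries.frame)

    def test_every_participant_keeps_at_least_one_flashback(self, default_study):
        assert (default_study.diaries.flashback_counts() >= 1).all()
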