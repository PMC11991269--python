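import dataclasses

import numpy as np
import pytest

from sleepstream import (
    ConfigError,
    DataError,
    FeatureFrame,
    HrOnlyConfig,
    NightConfig,
    OnsetConfig,
    PhysioConfig,
    Recording,
    ScorerState,
    StagingConfig,
    calibrate,
    classify_second_hr_only,
    classify_second_motion_aware,
    config_grid,
    detect_sleep_onset,
    load_config,
    save_config,
    score_recording,
    simulate_night,
    step,
    stream_score,
)

STAGE_SET = {"WAKE", "LIGHT", "DEEP", "REM"}


def asleep_state():
    return ScorerState(asleep=True)


class TestOnsetDetector:
    def test_constant_hr_never_falls(self):
        assert detect_sleep_onset(np.full(3600, 70.0), OnsetConfig(), 30) is None

    def test_rising_hr_never_falls(self):
        assert detect_sleep_onset(np.linspace(60, 90, 3600), OnsetConfig(), 30) is None

    def test_short_prefix_is_insufficient_evidence(self):
        assert detect_sleep_onset(np.full(100, 70.0), OnsetConfig(), 30) is None

    def test_step_drop_bracketed(self):
        # HR steps 70 -> 55 bpm at t=600 under mild noise; onset must land
        # inside [drop, drop + stab_dur + smooth_win].
        rng = np.random.default_rng(1)
        hr = np.concatenate([np.full(600, 70.0), np.full(2400, 55.0)])
        hr = hr + rng.normal(0, 0.5, hr.size)
        cfg = OnsetConfig(baseline_win=300, drop_delta=8.0, stab_tol=1.5, stab_dur=120)
        onset = detect_sleep_onset(hr, cfg, 30)
        assert onset is not None and 600 <= onset <= 600 + 120 + 30


class TestCascadeRules:
    def test_wake_rule_fires_first(self, short_cfg):
        frame = FeatureFrame(
            t=0, smoothed_hr_std=0.0, frac_hr_above=1.0, frac_rr_below=1.0,
            movement_count=short_cfg.win_size,
        )
        # std of 0 would satisfy DEEP, but WAKE short-circuits it
        assert classify_second_motion_aware(frame, asleep_state(), short_cfg) == "WAKE"

    def test_deep_rule_with_dwell_satisfied(self, short_cfg):
        cfg = dataclasses.replace(short_cfg, x3=1)
        frame = FeatureFrame(
            t=0, smoothed_hr_std=0.0, frac_hr_above=0.0, frac_rr_below=0.0
        )
        assert classify_second_motion_aware(frame, asleep_state(), cfg) == "DEEP"

    def test_rem_rule(self, short_cfg):
        cfg = dataclasses.replace(short_cfg, x5=1)
        frame = FeatureFrame(
            t=0, smoothed_hr_std=10.0, frac_hr_above=0.0, frac_rr_below=0.0,
            frac_sdnn_above=1.0, movement_count=0,
        )
        assert classify_second_motion_aware(frame, asleep_state(), cfg) == "REM"

    def test_default_branch_is_light(self, short_cfg):
        frame = FeatureFrame(
            t=0, smoothed_hr_std=10.0, frac_hr_above=0.0, frac_rr_below=0.0
        )
        assert classify_second_motion_aware(frame, asleep_state(), short_cfg) == "LIGHT"

    def test_hr_only_wake_ignores_movement(self):
        cfg = HrOnlyConfig()
        frame = FeatureFrame(
            t=0, smoothed_hr_std=0.0, frac_hr_above=1.0, frac_rr_below=1.0,
            movement_count=0,
        )
        assert classify_second_hr_only(frame, asleep_state(), cfg) == "WAKE"

    def test_hr_only_rem_needs_both_sdnn_clauses(self):
        cfg = dataclasses.replace(HrOnlyConfig(), min_dwell_rem=1)
        base = dict(t=0, smoothed_hr_std=10.0, frac_hr_above=0.0, frac_rr_below=0.0)
        both = FeatureFrame(**base, frac_sdnn_above_1=1.0, frac_sdnn_above_2=1.0)
        one = FeatureFrame(**base, frac_sdnn_above_1=1.0, frac_sdnn_above_2=0.0)
        assert classify_second_hr_only(both, asleep_state(), cfg) == "REM"
        assert classify_second_hr_only(one, asleep_state(), cfg) == "LIGHT"

    def test_dwell_holds_previous_label_until_satisfied(self, short_cfg):
        cfg = dataclasses.replace(short_cfg, x3=5)
        state = asleep_state()
        deep_frame = FeatureFrame(
            t=0, smoothed_hr_std=0.0, frac_hr_above=0.0, frac_rr_below=0.0
        )
        labels = [
            classify_second_motion_aware(deep_frame, state, cfg) for _ in range(8)
        ]
        # previous label (WAKE at start) held for x3-1 seconds, then DEEP
        assert labels == ["WAKE"] * 4 + ["DEEP"] * 4

    def test_dwell_interrupted_condition_resets(self, short_cfg):
        cfg = dataclasses.replace(short_cfg, x3=3)
        state = asleep_state()
        deep = FeatureFrame(t=0, smoothed_hr_std=0.0, frac_hr_above=0.0, frac_rr_below=0.0)
        light = FeatureFrame(t=0, smoothed_hr_std=9.9, frac_hr_above=0.0, frac_rr_below=0.0)
        seq = [deep, deep, light, deep, deep, deep]
        labels = [classify_second_motion_aware(f, state, cfg) for f in seq]
        assert labels == ["WAKE", "WAKE", "LIGHT", "LIGHT", "LIGHT", "DEEP"]


def count_episodes(labels, stage):
    mask = np.asarray(labels) == stage
    return int(np.count_nonzero(np.diff(np.r_[0, mask.astype(int)]) == 1))


class TestCascadeProperties:
    def test_dwell_monotonicity(self, rng, short_cfg):
        """Raising the DEEP dwell never increases the number of DEEP episodes."""
        for _ in range(30):
            conds = rng.random(120) < 0.5
            episode_counts = []
            for x3 in (2, 8, 25):
                cfg = dataclasses.replace(short_cfg, x3=x3)
                state = asleep_state()
                labels = [
                    classify_second_motion_aware(
                        FeatureFrame(
                            t=0, smoothed_hr_std=0.0 if c else 9.9,
                            frac_hr_above=0.0, frac_rr_below=0.0,
                        ),
                        state, cfg,
                    )
                    for c in conds
                ]
                episode_counts.append(count_episodes(labels, "DEEP"))
            assert episode_counts[0] >= episode_counts[1] >= episode_counts[2]

    def test_std_threshold_monotonicity(self, short_night, short_cfg):
        """Raising std_th never decreases total seconds labelled DEEP."""
        rec, _ = short_night
        deep_seconds = []
        for std_th in (0.4, 0.8, 1.2, 2.0, 4.0):
            cfg = dataclasses.replace(short_cfg, std_th=std_th)
            hyp = score_recording(rec, cfg, "motion_aware")
            deep_seconds.append(int(np.count_nonzero(hyp.stages == "DEEP")))
        assert all(a <= b for a, b in zip(deep_seconds, deep_seconds[1:]))

    def test_stage_alphabet_closed(self, short_night, short_cfg):
        rec, _ = short_night
        assert set(score_recording(rec, short_cfg, "motion_aware").stages) <= STAGE_SET


class TestStreamingContract:
    def test_first_label_is_wake(self, rng, short_cfg):
        from conftest import make_recording

        rec = make_recording(rng, n=5)
        state = ScorerState()
        _, label = step(state, (rec.hr[0], rec.rr[0], rec.acc[0]), short_cfg)
        assert label == "WAKE"

    def test_fold_step_equals_batch(self, short_night, short_cfg):
        rec, _ = short_night
        batch = score_recording(rec, short_cfg, "motion_aware")
        streamed = stream_score(rec, short_cfg, "motion_aware")
        np.testing.assert_array_equal(batch.stages, streamed.stages)

    def test_truncation_never_changes_past_labels(self, short_night, short_cfg):
        rec, _ = short_night
        full = score_recording(rec, short_cfg, "motion_aware")
        for cut in (200, 450, 700, 1100):
            part = Recording(
                rec.start_time, rec.hr[:cut], rec.rr[:cut], rec.acc[:cut]
            )
            np.testing.assert_array_equal(
                score_recording(part, short_cfg, "motion_aware").stages,
                full.stages[:cut],
            )

    def test_out_of_range_sample_rejected(self, short_cfg):
        with pytest.raises(DataError):
            step(ScorerState(), (300.0, 850.0, np.zeros(3)), short_cfg)

    def test_variant_config_mismatch_rejected(self, short_night, short_cfg):
        rec, _ = short_night
        with pytest.raises(ConfigError):
            score_recording(rec, short_cfg, "hr_only")

    def test_all_wake_when_onset_never_found(self, short_cfg):
        rng = np.random.default_rng(7)
        n = 900
        hr = np.clip(rng.normal(85, 2, n), 30, 180)  # high HR throughout
        rr = np.clip(60000.0 / hr, 300, 2500)
        acc = np.array([0.0, 0.0, 1.0]) + rng.normal(0, 0.2, (n, 3))
        rec = Recording(0, hr, rr, acc)
        assert set(score_recording(rec, short_cfg, "motion_aware").stages) == {"WAKE"}


class TestVariantDeepAgreement:
    def test_deep_labels_coincide_when_other_clauses_inert(self, short_cfg):
        """With REM rules unreachable and wake clauses inert during deep
        segments, the two variants identify exactly the same DEEP seconds
        (deep sleep is identified from HR alone in both)."""
        m = dataclasses.replace(
            short_cfg, std_th=1.2, hr_th=68.0, x1=0.3, sdnn_th=1e5, x3=20
        )
        h = HrOnlyConfig(
            win_size=m.win_size, smooth_win=m.smooth_win, sdnn_win=m.sdnn_win,
            hr_th=m.hr_th, rr_th=m.rr_th, std_th=m.std_th, x1=m.x1, x2=m.x2,
            sdnn_th1=1e5, sdnn_th2=1e5, f1=0.5, f2=0.5,
            min_dwell_deep=m.x3, min_dwell_rem=m.x5, onset=m.onset,
        )
        night_cfg = NightConfig(
            duration=1500, wake_prologue=300, light_frac=0.65, deep_frac=0.35,
            rem_frac=0.0,
            mean_episode={"WAKE": 120.0, "LIGHT": 300.0, "DEEP": 240.0, "REM": 280.0},
            min_episode=40,
        )
        for seed in range(3):
            rec, _ = simulate_night(night_cfg, PhysioConfig.exaggerated(), 600 + seed)
            deep_m = score_recording(rec, m, "motion_aware").stages == "DEEP"
            deep_h = score_recording(rec, h, "hr_only").stages == "DEEP"
            np.testing.assert_array_equal(deep_m, deep_h)


class TestCalibrate:
    def test_single_point_grid_returns_it(self, short_night, short_cfg):
        rec, hyp = short_night
        assert calibrate([(rec, hyp)], [short_cfg]) is short_cfg

    def test_two_identical_nights_match_single_night(self, short_night, short_cfg):
        rec, hyp = short_night
        grid = config_grid(short_cfg, {"std_th": [0.6, 1.2, 2.4]})
        one = calibrate([(rec, hyp)], grid)
        two = calibrate([(rec, hyp), (rec, hyp)], grid)
        assert one is two

    def test_empty_grid_rejected(self, short_night):
        rec, hyp = short_night
        with pytest.raises(ConfigError):
            calibrate([(rec, hyp)], [])

    def test_grid_expansion_order_and_size(self, short_cfg):
        grid = config_grid(short_cfg, {"std_th": [1.0, 2.0], "x1": [0.3, 0.5]})
        assert len(grid) == 4
        assert [(c.std_th, c.x1) for c in grid] == [
            (1.0, 0.3), (1.0, 0.5), (2.0, 0.3), (2.0, 0.5)
        ]


class TestConfigIO:
    @pytest.mark.parametrize("cfg", [StagingConfig(), HrOnlyConfig()])
    def test_yaml_round_trip(self, cfg, tmp_path):
        path = tmp_path / "cfg.yaml"
        save_config(cfg, path)
        assert load_config(path) == cfg

    def test_invalid_values_rejected(self):
        with pytest.raises(ConfigError):
            StagingConfig(x1=1.5)
        with pytest.raises(ConfigError):
            StagingConfig(win_size=1)
        with pytest.raises(ConfigError):
            HrOnlyConfig(sdnn_th1=80.0, sdnn_th2=50.0)
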