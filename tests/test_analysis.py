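import numpy as np
import pandas as pd
import pytest

from rlwm.analysis import (
    apply_test_exclusions,
    apply_training_exclusions,
    derive_test_features,
    derive_training_features,
    fit_logistic,
    summarize_learning_curves,
)


def block_df(stims, corrects, subject=0, session="PBO", block=0, set_size=None):
    if set_size is None:
        set_size = len(set(stims))
    return pd.DataFrame(
        {
            "subject_id": subject,
            "session_label": session,
            "block_id": block,
            "set_size": set_size,
            "trial_index": range(len(stims)),
            "stimulus_id": stims,
            "action": 0,
            "correct": corrects,
            "points": [2 * c for c in corrects],
        }
    )


class TestTrainingFeatures:
    def test_hand_traced_counters(self):
        # stimulus A (id 0) correct at block positions 0 and 3, shown again at 6
        stims = [0, 1, 2, 0, 1, 2, 0, 1, 2]
        correct = [1, 0, 0, 1, 0, 0, 0, 0, 0]
        out = derive_training_features(block_df(stims, correct))
        row = out.iloc[6]
        assert row.previous_iterations == 2
        assert row.previous_correct == 2
        assert row.delay == 3

    def test_first_presentations_have_zero_counters(self):
        stims = [0, 1, 0, 1]
        out = derive_training_features(block_df(stims, [1, 1, 0, 0]))
        firsts = out[out.previous_iterations == 0]
        assert (firsts.previous_correct == 0).all()
        assert firsts.delay.isna().all()

    def test_delay_undefined_before_first_correct(self):
        stims = [0, 1, 0, 1, 0]
        correct = [0, 0, 0, 0, 1]
        out = derive_training_features(block_df(stims, correct))
        assert out[out.stimulus_id == 0].delay.isna().all()

    def test_counters_reset_across_blocks(self):
        b0 = block_df([0, 1, 0, 1], [1, 1, 1, 1], block=0)
        b1 = block_df([2, 3, 2, 3], [0, 0, 0, 0], block=1)
        out = derive_training_features(pd.concat([b0, b1], ignore_index=True))
        assert (out[out.block_id == 1].previous_correct == 0).all()

    def test_prefix_computability(self):
        rng = np.random.default_rng(3)
        stims = list(rng.integers(0, 3, size=30))
        correct = list(rng.integers(0, 2, size=30))
        full = derive_training_features(block_df(stims, correct))
        trunc = derive_training_features(block_df(stims[:17], correct[:17]))
        cols = ["previous_iterations", "previous_correct", "delay"]
        pd.testing.assert_frame_equal(full[cols].iloc[:17], trunc[cols])

    def test_two_early_late_definitions(self):
        stims = [0] * 9  # not realistic, but isolates the flag logic
        df = block_df(stims, [1] * 9, set_size=1)
        by_iter = derive_training_features(df, early_late="iterations")
        assert by_iter.early_flag.tolist() == [True, True] + [False] * 7
        assert by_iter.late_flag.tolist() == [False] * 7 + [True, True]
        by_pcor = derive_training_features(df, early_late="pcor")
        assert by_pcor.early_flag.tolist() == [True] * 3 + [False] * 6


class TestTrainingExclusions:
    def _subject(self, sid, accs):
        parts = []
        for k, acc in enumerate(accs):
            n = 20
            stims = [0, 1] * (n // 2)
            # spread correct trials evenly so every iteration (in particular
            # the late ones) carries the session's nominal accuracy
            correct = [
                int(np.floor((i + 1) * acc) - np.floor(i * acc)) for i in range(n)
            ]
            parts.append(
                block_df(stims, correct, subject=sid, session=f"S{k}", block=0)
            )
        return pd.concat(parts, ignore_index=True)

    def test_below_cutoff_in_all_sessions_excluded(self):
        df = pd.concat(
            [self._subject(0, [0.40, 0.45, 0.50]), self._subject(1, [0.9, 0.9, 0.9])],
            ignore_index=True,
        )
        kept, report = apply_training_exclusions(df)
        assert 0 not in kept.subject_id.values
        assert 1 in kept.subject_id.values

    def test_one_good_session_retains_subject(self):
        df = self._subject(0, [0.40, 0.80, 0.40])
        kept, _ = apply_training_exclusions(df)
        assert 0 in kept.subject_id.values

    def test_pre_first_correct_marked_not_dropped(self):
        df = self._subject(0, [0.9, 0.9, 0.9])
        kept, _ = apply_training_exclusions(df)
        assert "post_first_correct" in kept.columns
        assert len(kept) == len(df)


class TestTestExclusions:
    def _session(self, choices, rts, sid=0, sess="PBO"):
        return pd.DataFrame(
            {
                "subject_id": sid,
                "session_label": sess,
                "left_stimulus": 0,
                "right_stimulus": 1,
                "choice": choices,
                "rt": rts,
            }
        )

    def test_fast_trials_dropped(self):
        df = self._session(["left"] * 9 + ["right"], [0.2] + [1.0] * 9)
        kept, _ = apply_test_exclusions(df)
        assert len(kept) == 9
        assert (kept.rt >= 0.25).all()

    def test_alternation_above_threshold_excludes_session(self):
        # 21 trials, 16 switches -> rate 0.80 > 0.75
        choices = []
        for i in range(21):
            if i < 17:
                choices.append("left" if i % 2 == 0 else "right")
            else:
                choices.append("left")
        df = self._session(choices, [1.0] * 21)
        kept, report = apply_test_exclusions(df)
        assert report.session_excluded.iloc[0]
        assert len(kept) == 0

    def test_alternation_exactly_at_threshold_retained(self):
        # 5 trials, 3 switches -> rate 0.75, strictly-greater rule keeps it
        df = self._session(["left", "right", "left", "right", "right"], [1.0] * 5)
        kept, report = apply_test_exclusions(df)
        assert not report.session_excluded.iloc[0]
        assert len(kept) == 5

    def test_low_capture_rate_excludes_session(self):
        choices = ["left", "right"] * 4 + [None, None, "left"] * 1
        choices = ["left", "right", "left", None, None, "right", None, "left", "right", "left"]
        df = self._session(choices, [1.0] * len(choices))
        kept, report = apply_test_exclusions(df)
        assert report.capture_rate.iloc[0] == pytest.approx(0.7)
        assert report.session_excluded.iloc[0]


class TestTestFeatures:
    def test_worked_pair_arithmetic(self):
        # H earned 1.6 points/trial in a set-size-5 block; L earned 1.0 in size-2
        train = pd.concat(
            [
                block_df([0] * 5, [1] * 5, block=0, set_size=5).assign(
                    points=[2, 2, 2, 1, 1]
                ),
                block_df([1] * 4, [1] * 4, block=1, set_size=2).assign(
                    points=[1, 1, 1, 1]
                ),
            ],
            ignore_index=True,
        )
        test = pd.DataFrame(
            {
                "subject_id": [0],
                "session_label": ["PBO"],
                "left_stimulus": [1],
                "right_stimulus": [0],
                "choice": ["right"],
                "rt": [1.0],
            }
        )
        feats = derive_test_features(test, train)
        row = feats.iloc[0]
        assert row.delta_v == pytest.approx(0.6)
        assert row.delta_ns == 3
        assert row.mean_set_size == pytest.approx(3.5)
        assert row.mean_value == pytest.approx(1.3)
        assert row.accuracy == 1.0  # chose the more-rewarded (right) stimulus

    def test_tie_flagged_and_unscored(self):
        train = pd.concat(
            [
                block_df([0] * 3, [1] * 3, block=0).assign(points=2),
                block_df([1] * 3, [1] * 3, block=1).assign(points=2),
            ],
            ignore_index=True,
        )
        test = pd.DataFrame(
            {
                "subject_id": [0],
                "session_label": ["PBO"],
                "left_stimulus": [0],
                "right_stimulus": [1],
                "choice": ["left"],
                "rt": [1.0],
            }
        )
        feats = derive_test_features(test, train)
        assert feats.tie.iloc[0]
        assert np.isnan(feats.accuracy.iloc[0])

    def test_same_block_pair_has_zero_set_size_difference(self):
        train = block_df([0, 1, 0, 1], [1, 1, 1, 0], block=0).assign(
            points=[2, 1, 1, 0]
        )
        test = pd.DataFrame(
            {
                "subject_id": [0],
                "session_label": ["PBO"],
                "left_stimulus": [0],
                "right_stimulus": [1],
                "choice": ["left"],
                "rt": [1.0],
            }
        )
        feats = derive_test_features(test, train)
        assert feats.delta_ns.iloc[0] == 0

    def test_sum_statistic_option(self):
        train = pd.concat(
            [
                block_df([0] * 2, [1] * 2, block=0).assign(points=2),
                block_df([1] * 2, [1] * 2, block=1).assign(points=1),
            ],
            ignore_index=True,
        )
        test = pd.DataFrame(
            {
                "subject_id": [0],
                "session_label": ["PBO"],
                "left_stimulus": [0],
                "right_stimulus": [1],
                "choice": ["left"],
                "rt": [1.0],
            }
        )
        feats = derive_test_features(test, train, statistic="sum")
        assert feats.delta_v.iloc[0] == pytest.approx(2.0)  # 4 - 2


class TestLearningCurves:
    def test_perfect_agent_ceiling(self):
        df = block_df([0, 1] * 9, [1] * 18)
        curves = summarize_learning_curves(df, by="iteration")
        assert (curves.accuracy == 1.0).all()

    def test_uniform_random_agent_near_chance(self):
        rng = np.random.default_rng(11)
        parts = []
        for sid in range(60):
            stims = [0, 1, 2] * 9
            correct = list((rng.random(27) < 1 / 3).astype(int))
            parts.append(block_df(stims, correct, subject=sid, set_size=3))
        curves = summarize_learning_curves(pd.concat(parts, ignore_index=True))
        # each cell holds 180 Bernoulli(1/3) draws
        assert (abs(curves.accuracy - 1 / 3) < 4 * np.sqrt((1 / 3) * (2 / 3) / 180)).all()

    def test_row_count_is_cells_exactly(self):
        df = pd.concat(
            [
                block_df([0, 1] * 9, [1] * 18, block=0),
                block_df([2, 3, 4] * 9, [0] * 27, block=1, set_size=3),
            ],
            ignore_index=True,
        )
        curves = summarize_learning_curves(df, by="iteration")
        assert len(curves) == 2 * 9  # two set sizes x nine iterations


class TestLogistic:
    def test_two_by_two_closed_form_odds_ratio(self):
        rows = []
        # odds ratio 3: P(y=1|x=0)=0.25 (odds 1/3), P(y=1|x=1)=0.5 (odds 1)
        for x, n1, n0 in ((0, 250, 750), (1, 500, 500)):
            rows += [{"x": x, "y": 1}] * n1 + [{"x": x, "y": 0}] * n0
        tab = fit_logistic(pd.DataFrame(rows), "y ~ x")
        slope = float(tab.loc[tab.term == "x", "coef"].iloc[0])
        assert slope == pytest.approx(np.log(3), abs=1e-6)
        assert not tab.attrs["ridge_fallback"]

    def test_null_covariate_slope_near_zero(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {"y": rng.integers(0, 2, size=10_000), "x": rng.normal(size=10_000)}
        )
        tab = fit_logistic(df, "y ~ x", standardize_cols=["x"])
        row = tab[tab.term == "x"].iloc[0]
        assert abs(row.coef) < 3 * row.se

    def test_perfect_separation_triggers_ridge_fallback(self):
        df = pd.DataFrame({"y": [0] * 20 + [1] * 20, "x": list(range(40))})
        tab = fit_logistic(df, "y ~ x")
        assert tab.attrs["ridge_fallback"]
        assert np.isfinite(tab.coef).all() and np.isfinite(tab.se).all()
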