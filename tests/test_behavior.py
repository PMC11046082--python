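"""Trial classification, staircase rule, SSRT estimation, exclusion rules
and paired contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import conflictstop as cs
from conflictstop.behavior import apply_exclusions, summarize_group
from conflictstop.epochs import CONDITIONS
from conflictstop.synth import LOG_COLUMNS


def _toy_log(rows):
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


class TestNextSSD:
    @pytest.mark.parametrize(
        "current,stopped,expected",
        [(250, True, 300), (1000, True, 1000), (50, False, 50), (300, False, 250)],
    )
    def test_staircase_rule(self, current, stopped, expected):
        assert cs.next_ssd(current, stopped) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cs.next_ssd(40, True)
        with pytest.raises(ValueError):
            cs.next_ssd(1050, False)

    @settings(derandomize=True, max_examples=50)
    @given(
        ssd=st.floats(min_value=50, max_value=1000),
        stopped=st.booleans(),
    )
    def test_always_within_bounds(self, ssd, stopped):
        out = cs.next_ssd(ssd, stopped)
        assert 50 <= out <= 1000
        assert abs(out - ssd) <= 50


class TestClassify:
    def test_toy_log_tally(self):
        log = _toy_log(
            [
                ("s", 1, 1, "congruent", "left", 0, np.nan, 400.0, "left", "hit"),
                ("s", 1, 2, "congruent", "left", 0, np.nan, np.nan, "none", "miss"),
                ("s", 1, 3, "congruent", "left", 1, 250.0, np.nan, "none", "correct_rejection"),
                ("s", 1, 4, "congruent", "right", 1, 300.0, 420.0, "right", "failed_stop"),
            ]
        )
        counts = cs.classify_trials(log)
        assert counts.loc["congruent"].to_dict() == {
            "hit": 1, "incorrect": 0, "miss": 1, "correct_rejection": 1, "failed_stop": 1,
        }

    def test_empty_log(self):
        counts = cs.classify_trials(_toy_log([]))
        assert (counts.to_numpy() == 0).all()

    def test_unknown_outcome_rejected(self):
        log = _toy_log(
            [("s", 1, 1, "congruent", "left", 0, np.nan, 400.0, "left", "bogus")]
        )
        with pytest.raises(ValueError, match="unknown outcome"):
            cs.classify_trials(log)

    def test_counts_partition_full_session(self, default_session):
        counts = cs.classify_trials(default_session)
        assert counts[["hit", "incorrect", "miss"]].to_numpy().sum() == 720
        assert counts[["correct_rejection", "failed_stop"]].to_numpy().sum() == 216


class TestSSRT:
    def test_stated_formula(self):
        log = _toy_log(
            [
                ("s", 1, 1, "congruent", "left", 0, np.nan, 500.0, "left", "hit"),
                ("s", 1, 2, "congruent", "left", 0, np.nan, 500.0, "left", "hit"),
                ("s", 1, 3, "congruent", "left", 1, 230.0, np.nan, "none", "correct_rejection"),
                ("s", 1, 4, "congruent", "left", 1, 230.0, np.nan, "none", "correct_rejection"),
            ]
        )
        assert cs.estimate_ssrt(log, "congruent") == pytest.approx(270.0)

    def test_identical_means_give_zero(self):
        log = _toy_log(
            [
                ("s", 1, 1, "congruent", "left", 0, np.nan, 300.0, "left", "hit"),
                ("s", 1, 2, "congruent", "left", 1, 300.0, np.nan, "none", "correct_rejection"),
            ]
        )
        assert cs.estimate_ssrt(log, "congruent") == pytest.approx(0.0)

    def test_empty_cell_rejected(self):
        log = _toy_log(
            [("s", 1, 1, "congruent", "left", 0, np.nan, 400.0, "left", "hit")]
        )
        with pytest.raises(ValueError, match="cannot estimate SSRT"):
            cs.estimate_ssrt(log, "congruent")

    def test_recovery_against_generative_truth(self):
        # mean-method estimate tracks the generative mean stop latency
        race = cs.default_race_params()
        true_c = race.stop["congruent"].mean
        true_i = race.stop["incongruent"].mean
        est = {"congruent": [], "incongruent": []}
        for seed in range(25):
            df = cs.generate_session(seed=2000 + seed)
            for cond in CONDITIONS:
                est[cond].append(cs.estimate_ssrt(df, cond))
        assert abs(np.mean(est["congruent"]) - true_c) < 20
        assert abs(np.mean(est["incongruent"]) - true_i) < 20

    def test_summary_ssrt_identity(self, default_session):
        s = cs.summarize_subject(default_session)
        assert np.allclose(s.ssrt, s.mean_go_rt - s.mean_ssd)


def _summary_frame(values):
    """Build a (subject, condition)-indexed summary from per-subject dicts."""
    rows = []
    for sub, per_cond in values.items():
        for cond, vals in per_cond.items():
            rows.append({"subject": sub, "condition": cond, **vals})
    return pd.DataFrame(rows).set_index(["subject", "condition"])


def _normal_subject(rng):
    return {
        cond: {
            "mean_go_rt": rng.normal(500, 10),
            "go_accuracy": 0.97,
            "p_respond_stop": rng.normal(0.5, 0.02),
            "mean_ssd": 230.0,
            "ssrt": rng.normal(270, 5),
            "mean_failed_stop_rt": 450.0,
        }
        for cond in CONDITIONS
    }


class TestExclusions:
    def _cohort(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        return {f"sub-{i:02d}": _normal_subject(rng) for i in range(n)}

    def test_stop_probability_rule(self):
        cohort = self._cohort()
        cohort["sub-00"]["congruent"]["p_respond_stop"] = 0.20
        report = apply_exclusions(_summary_frame(cohort))
        assert report.reasons["sub-00"] == ["stop_probability"]

    def test_ssrt_direction_rule(self):
        cohort = self._cohort()
        cohort["sub-01"]["congruent"]["ssrt"] = 260.0
        cohort["sub-01"]["incongruent"]["ssrt"] = 320.0  # +60 ms
        report = apply_exclusions(_summary_frame(cohort))
        assert "ssrt_direction" in report.reasons["sub-01"]

    def test_tukey_rule_multiple_measurements(self):
        cohort = self._cohort()
        frame = _summary_frame(cohort)
        # brute-force fences for the two measures we will violate
        for measure in ("ssrt", "mean_go_rt"):
            col = frame.xs("congruent", level="condition")[measure].to_numpy()
            q1, q3 = np.percentile(col, [25, 75])
            hi = q3 + 1.5 * (q3 - q1)
            cohort["sub-02"]["congruent"][measure] = hi + 50
        report = apply_exclusions(_summary_frame(cohort))
        assert "tukey_outlier" in report.reasons["sub-02"]
        # a single outlying measurement is not enough
        cohort2 = self._cohort(seed=1)
        frame2 = _summary_frame(cohort2)
        col = frame2.xs("congruent", level="condition")["ssrt"].to_numpy()
        q1, q3 = np.percentile(col, [25, 75])
        cohort2["sub-03"]["congruent"]["ssrt"] = q3 + 1.5 * (q3 - q1) + 50
        report2 = apply_exclusions(_summary_frame(cohort2))
        assert "tukey_outlier" not in report2.reasons["sub-03"]

    def test_idempotence_of_absolute_rules(self):
        cohort = self._cohort(n=16, seed=2)
        cohort["sub-00"]["congruent"]["p_respond_stop"] = 0.1
        frame = _summary_frame(cohort)
        report = apply_exclusions(frame)
        kept = frame.loc[report.included]
        report2 = apply_exclusions(kept)
        for sub in report2.reasons:
            assert "stop_probability" not in report2.reasons[sub]
            assert "ssrt_direction" not in report2.reasons[sub]

    def test_small_cohort_skips_tukey_with_warning(self):
        cohort = self._cohort(n=3)
        with pytest.warns(UserWarning, match="Tukey"):
            report = apply_exclusions(_summary_frame(cohort))
        assert all("tukey_outlier" not in r for r in report.reasons.values())

    def test_real_simulated_cohort_mostly_included(self):
        logs = cs.generate_group_sessions(n_subjects=12, seed=11)
        report = apply_exclusions(summarize_group(logs))
        assert len(report.included) >= 9


class TestCongruencyContrast:
    def test_all_zero_differences_degenerate(self):
        stat, p = cs.congruency_contrast(np.ones(8), np.ones(8))
        assert p == 1.0

    def test_exact_p_six_positive(self):
        # all six differences positive: 2 of the 64 sign assignments are as
        # extreme, two-sided
        cong = np.zeros(6)
        incong = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        _, p = cs.congruency_contrast(cong, incong)
        assert p == pytest.approx(2 / 64)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cs.congruency_contrast(np.ones(4), np.ones(5))

    def test_detects_generative_ssrt_effect(self):
        # ~9 ms congruency effect on SSRT is detectable at the study's n
        rejections = 0
        for rep in range(5):
            logs = cs.generate_group_sessions(n_subjects=53, seed=900 + rep)
            summ = summarize_group(logs)
            c = summ.xs("congruent", level="condition")["ssrt"].to_numpy()
            i = summ.xs("incongruent", level="condition")["ssrt"].to_numpy()
            _, p = cs.congruency_contrast(c, i)
            rejections += p < 0.05
        assert rejections >= 3
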