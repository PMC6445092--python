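"""Tests of dependent variables, slopes and the linear-contrast engine."""

import numpy as np
import pandas as pd
import pytest

from percue.analysis import (
    NotApplicableError,
    RunMetrics,
    UndefinedCCIError,
    cohort_metrics,
    confidence_intervention_test,
    linear_interaction_test,
    run_metrics,
    session_slopes,
    slope_t_test,
    subject_slopes,
)


def _make_run(n_cc=8, n_ci=8, cc_correct=8, ci_correct=8, response_values=None):
    """Build a toy test run with given cue-congruency structure."""
    rows = []
    for i in range(n_cc):
        stim = i % 2
        correct = i < cc_correct
        rows.append({"cue": stim, "true_stimulus": stim, "decision": stim if correct else 1 - stim})
    for i in range(n_ci):
        stim = i % 2
        correct = i < ci_correct
        rows.append({"cue": 1 - stim, "true_stimulus": stim, "decision": stim if correct else 1 - stim})
    df = pd.DataFrame(rows)
    df["correct"] = (df["decision"] == df["true_stimulus"]).astype(int)
    if response_values is not None:
        df["response_value"] = response_values
    return df


class TestRunMetrics:
    def test_hand_enumerated_toy_run(self):
        m = run_metrics(_make_run(n_cc=8, n_ci=8, cc_correct=6, ci_correct=4))
        assert m.performance == pytest.approx(62.5)
        assert m.cci == pytest.approx(75.0 - 50.0)
        assert m.n_cue_congruent_trials == 8
        assert m.n_cue_incongruent_trials == 8

    def test_all_cue_following_gives_cci_100(self):
        # Responding with the cue's stimulus on every trial: 100% correct on
        # congruent trials, 0% on incongruent ones.
        df = _make_run(n_cc=48, n_ci=16, cc_correct=48, ci_correct=0)
        assert (df["decision"] == df["cue"]).all()
        m = run_metrics(df)
        assert m.cci == 100.0

    def test_all_correct_gives_cci_0(self):
        m = run_metrics(_make_run(n_cc=48, n_ci=16, cc_correct=48, ci_correct=16))
        assert m.cci == 0.0
        assert m.performance == 100.0

    def test_missing_cue_class_raises(self):
        df = _make_run(n_cc=8, n_ci=0)
        with pytest.raises(UndefinedCCIError):
            run_metrics(df)

    def test_no_cue_column_raises(self):
        df = pd.DataFrame({"true_stimulus": [0, 1], "decision": [0, 1], "cue": [np.nan] * 2})
        with pytest.raises(UndefinedCCIError):
            run_metrics(df)

    def test_continuous_responses(self):
        # Sign encodes the choice, magnitude the confidence.
        df = pd.DataFrame(
            {
                "cue": [0, 0, 1, 0],
                "true_stimulus": [0, 0, 1, 1],
                "response_value": [-0.8, 0.4, 0.9, 0.5],
            }
        )
        df["decision"] = (df["response_value"] > 0).astype(int)
        m = run_metrics(df)
        assert m.performance == pytest.approx(75.0)
        assert m.mean_confidence == pytest.approx(np.mean([0.8, 0.4, 0.9, 0.5]))

    def test_cci_invariant_to_uniform_shift_raw_rate_is_not(self):
        # Shifting correctness in both cue classes by the same percentage
        # points (a pure performance change) leaves the CCI alone, but under
        # the 75/25 contingency it moves the raw cue-following rate — the
        # coupling the CCI is designed to remove.
        lo = _make_run(n_cc=48, n_ci=16, cc_correct=36, ci_correct=8)
        hi = _make_run(n_cc=48, n_ci=16, cc_correct=42, ci_correct=10)
        assert run_metrics(lo).cci == run_metrics(hi).cci == 25.0
        follow_lo = (lo["decision"] == lo["cue"]).mean()
        follow_hi = (hi["decision"] == hi["cue"]).mean()
        assert follow_hi > follow_lo


class TestSessionSlopes:
    @staticmethod
    def _metrics(perfs, ccis):
        return [
            RunMetrics(p, c, None, 64, 48, 16) for p, c in zip(perfs, ccis)
        ]

    def test_constant_series_has_zero_slope(self):
        s = session_slopes(self._metrics([80] * 4, [5] * 4))
        assert s.performance_slope == 0.0
        assert s.cci_slope == 0.0

    def test_closed_form_examples(self):
        s = session_slopes(self._metrics([86, 84, 82, 80], [0, 5, 10, 15]))
        assert s.performance_slope == pytest.approx(-2.0)
        assert s.cci_slope == pytest.approx(5.0)

    def test_too_few_runs_raise(self):
        with pytest.raises(ValueError):
            session_slopes(self._metrics([80], [0]))


class TestSlopeTTest:
    def test_all_zero_slopes(self):
        r = slope_t_test([0.0, 0.0, 0.0])
        assert r.t == 0.0
        assert r.p == 1.0

    def test_hand_computed(self):
        r = slope_t_test([-1.0, -2.0, -3.0])
        assert r.mean == pytest.approx(-2.0)
        assert r.standard_error == pytest.approx(0.5774, abs=1e-4)
        assert r.t == pytest.approx(-3.464, abs=1e-3)
        assert r.df == 2

    def test_too_few_raise(self):
        with pytest.raises(ValueError):
            slope_t_test([1.0])


def _tidy_table(values: np.ndarray) -> pd.DataFrame:
    """values[subject, session, time] -> tidy frame."""
    n, _, T = values.shape
    rows = []
    for i in range(n):
        for j, session in enumerate(("corrupted", "uncorrupted")):
            for t in range(T):
                rows.append(
                    {
                        "subject": i,
                        "session": session,
                        "time": t + 1,
                        "value": values[i, j, t],
                    }
                )
    return pd.DataFrame(rows)


def _rm_linear_trend_interaction_F(values: np.ndarray) -> float:
    """Independent oracle: sums-of-squares decomposition of the linear-trend
    interaction in a 2 x T within-subject design.

    Projects each subject x session trajectory onto the normalised linear
    trend, then runs a one-way repeated-measures decomposition (session
    effect vs subject-by-session error) on the projections.
    """
    n, _, T = values.shape
    w = np.arange(1, T + 1) - (T + 1) / 2
    w = w / np.sqrt(np.sum(w**2))
    proj = values @ w  # (n, 2)
    grand = proj.mean()
    session_means = proj.mean(axis=0)
    subject_means = proj.mean(axis=1)
    ss_session = n * np.sum((session_means - grand) ** 2)
    resid = proj - session_means[None, :] - subject_means[:, None] + grand
    ss_error = np.sum(resid**2)
    return float(ss_session / (ss_error / (n - 1)))


class TestLinearInteraction:
    def test_identical_trajectories_give_zero(self):
        values = np.tile(np.array([80.0, 79.0, 78.0, 77.0]), (5, 2, 1))
        r = linear_interaction_test(_tidy_table(values))
        assert r.F == 0.0
        assert r.partial_eta_sq == 0.0
        assert r.p == 1.0

    def test_matches_brute_force_ss_decomposition(self):
        rng = np.random.default_rng(42)
        values = 80 + rng.normal(0, 3, size=(5, 2, 4))
        r = linear_interaction_test(_tidy_table(values))
        assert r.F == pytest.approx(_rm_linear_trend_interaction_F(values), abs=1e-8)
        assert r.df1 == 1 and r.df2 == 4
        assert r.partial_eta_sq == pytest.approx(r.F / (r.F + 4), abs=1e-12)

    def test_invariant_to_value_scaling_and_subject_offsets(self):
        rng = np.random.default_rng(0)
        values = 80 + rng.normal(0, 3, size=(8, 2, 4))
        r1 = linear_interaction_test(_tidy_table(values))
        shifted = 3.7 * values + rng.normal(0, 5, size=(8, 1, 1))
        r2 = linear_interaction_test(_tidy_table(shifted))
        assert r2.F == pytest.approx(r1.F, rel=1e-9)
        assert r2.partial_eta_sq == pytest.approx(r1.partial_eta_sq, rel=1e-9)

    def test_detects_decline_interaction_with_power(self):
        # Corrupted declines 1 unit/run, uncorrupted flat, noise SD 2:
        # at n = 200 the interaction should be detected nearly always.
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            base = rng.normal(0, 2, size=(200, 2, 4))
            base[:, 0, :] -= np.arange(4)
            r = linear_interaction_test(_tidy_table_fast(base))
            rejections += r.p < 0.05
        assert rejections / n_rep >= 0.95

    def test_unpaired_subjects_raise(self):
        values = 80 + np.zeros((4, 2, 4))
        table = _tidy_table(values)
        table = table[~((table.subject == 2) & (table.session == "uncorrupted"))]
        with pytest.raises(ValueError):
            linear_interaction_test(table)

    def test_missing_column_raises(self):
        with pytest.raises(ValueError, match="missing"):
            linear_interaction_test(pd.DataFrame({"subject": [], "session": []}))


def _tidy_table_fast(values: np.ndarray) -> pd.DataFrame:
    n, _, T = values.shape
    subj = np.repeat(np.arange(n), 2 * T)
    sess = np.tile(np.repeat(["corrupted", "uncorrupted"], T), n)
    time = np.tile(np.arange(1, T + 1), 2 * n)
    return pd.DataFrame(
        {"subject": subj, "session": sess, "time": time, "value": values.ravel()}
    )


class TestConfidenceInterventionTest:
    @staticmethod
    def _trials(test_conf, intervention_conf, n_subjects=6):
        rows = []
        for s in range(n_subjects):
            for run_index, run_type in enumerate(
                ["test", "intervention", "test", "intervention"], start=1
            ):
                conf = test_conf if run_type == "test" else intervention_conf
                for _ in range(10):
                    rows.append(
                        {
                            "subject_id": s,
                            "session_feedback": "corrupted",
                            "run_index": run_index,
                            "run_type": run_type,
                            "response_value": conf,
                        }
                    )
        return pd.DataFrame(rows)

    def test_identical_confidence_gives_zero(self):
        r = confidence_intervention_test(self._trials(0.5, 0.5))
        assert r.mean == 0.0
        assert r.t == 0.0

    def test_recovers_drop(self):
        r = confidence_intervention_test(self._trials(0.51, 0.35))
        assert r.mean == pytest.approx(0.16, abs=1e-12)

    def test_binary_dataset_not_applicable(self, small_cohort_trials):
        with pytest.raises(NotApplicableError):
            confidence_intervention_test(small_cohort_trials)


class TestCohortHelpers:
    def test_cohort_metrics_match_run_metrics(self, small_cohort_trials):
        metrics = cohort_metrics(small_cohort_trials)
        test_runs = small_cohort_trials.query("run_type == 'test'")
        # Cross-check one cell against the scalar path.
        one_run = test_runs.query(
            "subject_id == 3 and session_feedback == 'uncorrupted' and run_index == 5"
        )
        scalar = run_metrics(one_run)
        cell = metrics.query("subject == 3 and session == 'uncorrupted' and time == 3")
        assert cell["performance"].iloc[0] == pytest.approx(scalar.performance)
        assert cell["cci"].iloc[0] == pytest.approx(scalar.cci)

    def test_subject_slopes_shape(self, small_cohort_trials):
        metrics = cohort_metrics(small_cohort_trials)
        slopes = subject_slopes(metrics, "performance")
        assert len(slopes) == 12  # 6 subjects x 2 sessions
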