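"""Dependent variables and statistics for trial-level behavioural data.

Per test run two objective measures are computed: the percentage of correct
responses and the cue congruence index

    CCI = CR_CC - CR_CI,

the percent correct on cue-congruent trials (the cue's predicted stimulus
was shown) minus percent correct on cue-incongruent trials.  Because the
cue agrees with the stimulus on 75% of trials, a raw cue-following rate
rises and falls with overall performance; the CCI cancels that coupling.
CCI = 0 means the cue has no influence on responses and CCI = 100 occurs
when the response follows the cue on every trial.

Session-wise change is summarised by OLS slopes of each measure over the
four test runs, and the feedback-type x time interaction is tested with a
linear within-subject contrast (weights -3, -1, 1, 3): the paired t on the
per-subject contrast difference, reported as F = t^2 with df (1, n-1) and
partial eta squared F/(F + n - 1) — identical to the linear-trend
interaction of a 2x4 repeated-measures ANOVA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RunMetrics",
    "SessionSlopes",
    "ContrastResult",
    "OneSampleResult",
    "UndefinedCCIError",
    "NotApplicableError",
    "run_metrics",
    "session_slopes",
    "linear_interaction_test",
    "slope_t_test",
    "confidence_intervention_test",
    "cohort_metrics",
    "subject_slopes",
    "analyze_cohort",
]


class UndefinedCCIError(ValueError):
    """Raised when a run lacks cue-congruent or cue-incongruent trials."""


class NotApplicableError(ValueError):
    """Raised when an analysis needs data the dataset does not contain."""


@dataclass(frozen=True)
class RunMetrics:
    """Dependent variables of one test run."""

    performance: float  # percent correct, 0-100
    cci: float  # CR_CC - CR_CI, percentage points
    mean_confidence: float | None  # mean |response|, or None for binary data
    n_trials: int
    n_cue_congruent_trials: int
    n_cue_incongruent_trials: int


@dataclass(frozen=True)
class SessionSlopes:
    """OLS slopes of the run-wise measures against run number (1..n)."""

    performance_slope: float  # percent per run
    cci_slope: float  # points per run
    confidence_slope: float | None


@dataclass(frozen=True)
class ContrastResult:
    """Linear feedback-type x time interaction contrast."""

    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class OneSampleResult:
    """One-sample (or paired-difference) t-test summary."""

    mean: float
    standard_error: float
    t: float
    df: int
    p: float

    @property
    def mean_slope(self) -> float:
        return self.mean


def _one_sample_t(x: np.ndarray) -> OneSampleResult:
    """One-sample t against 0 with a defined value for constant data."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two observations")
    mean = float(x.mean())
    se = float(x.std(ddof=1) / np.sqrt(x.size))
    df = x.size - 1
    if se == 0.0:
        t = 0.0 if mean == 0.0 else math.copysign(math.inf, mean)
        p = 1.0 if mean == 0.0 else 0.0
    else:
        t = mean / se
        p = float(2.0 * stats.t.sf(abs(t), df))
    return OneSampleResult(mean=mean, standard_error=se, t=t, df=df, p=p)


def _correct_column(trials: pd.DataFrame) -> pd.Series:
    if "correct" in trials.columns:
        return trials["correct"].astype(float)
    if "response_value" in trials.columns and trials["response_value"].notna().all():
        chosen = (trials["response_value"] > 0).astype(int)
        return (chosen == trials["true_stimulus"]).astype(float)
    if "decision" in trials.columns:
        return (trials["decision"] == trials["true_stimulus"]).astype(float)
    raise ValueError("trials need a 'correct', 'decision' or 'response_value' column")


def run_metrics(trials: pd.DataFrame) -> RunMetrics:
    """Compute performance, CCI and mean confidence for one test run.

    Cue-congruent trials are those where the cue's predicted stimulus was
    actually shown; CR is percent correct within each subset.  A run with
    an empty cue class has no defined CCI and raises ``UndefinedCCIError``
    rather than returning 0.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    if "cue" not in trials.columns or trials["cue"].isna().all():
        raise UndefinedCCIError("run has no cue information; CCI undefined")
    correct = _correct_column(trials)
    congruent = trials["cue"].astype(float) == trials["true_stimulus"].astype(float)
    n_cc = int(congruent.sum())
    n_ci = int((~congruent).sum())
    if n_cc == 0 or n_ci == 0:
        raise UndefinedCCIError(
            f"CCI undefined: {n_cc} cue-congruent and {n_ci} cue-incongruent trials"
        )
    cr_cc = 100.0 * correct[congruent].mean()
    cr_ci = 100.0 * correct[~congruent].mean()
    confidence = None
    if "response_value" in trials.columns and trials["response_value"].notna().any():
        confidence = float(trials["response_value"].abs().mean())
    return RunMetrics(
        performance=float(100.0 * correct.mean()),
        cci=float(cr_cc - cr_ci),
        mean_confidence=confidence,
        n_trials=len(trials),
        n_cue_congruent_trials=n_cc,
        n_cue_incongruent_trials=n_ci,
    )


def _ols_slope(y: np.ndarray) -> float:
    x = np.arange(1, y.size + 1, dtype=float)
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


def session_slopes(metrics: Sequence[RunMetrics]) -> SessionSlopes:
    """OLS slope of each measure across test runs taken in run order."""
    if len(metrics) < 2:
        raise ValueError("need at least two runs to fit a slope")
    perf = np.array([m.performance for m in metrics], dtype=float)
    cci = np.array([m.cci for m in metrics], dtype=float)
    conf_slope = None
    if all(m.mean_confidence is not None for m in metrics):
        conf = np.array([m.mean_confidence for m in metrics], dtype=float)
        conf_slope = _ols_slope(conf)
    return SessionSlopes(
        performance_slope=_ols_slope(perf),
        cci_slope=_ols_slope(cci),
        confidence_slope=conf_slope,
    )


def linear_interaction_test(
    table: pd.DataFrame, value: str = "value"
) -> ContrastResult:
    """Feedback-type x time linear-contrast interaction on a tidy table.

    ``table`` needs columns ``subject``, ``session`` (exactly two levels,
    'corrupted' and 'uncorrupted'), ``time`` (1..T for every subject and
    session) and the value column.  Per subject and session the linear
    contrast L = sum_t w_t y_t is computed with centred integer weights
    (for T = 4: -3, -1, 1, 3); the paired t-test on L_corrupted -
    L_uncorrupted across subjects is reported as F = t^2 with df (1, n-1).
    """
    required = {"subject", "session", "time", value}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns: {sorted(missing)}")
    sessions = set(table["session"].unique())
    if sessions != {"corrupted", "uncorrupted"}:
        raise ValueError(f"expected sessions corrupted/uncorrupted, got {sorted(sessions)}")

    wide = table.pivot_table(
        index=["subject", "session"], columns="time", values=value, aggfunc="first"
    )
    if wide.isna().any().any():
        raise ValueError("every subject needs both sessions with all time points")
    times = np.asarray(wide.columns, dtype=float)
    weights = 2.0 * (times - times.mean())  # (-3,-1,1,3) for four levels
    scores = wide.to_numpy() @ weights
    contrast = pd.Series(scores, index=wide.index).unstack("session")
    if contrast.isna().any().any():
        raise ValueError("unpaired subjects: every subject needs both sessions")
    diff = (contrast["corrupted"] - contrast["uncorrupted"]).to_numpy()
    if diff.size < 2:
        raise ValueError("need at least two paired subjects")
    t_res = _one_sample_t(diff)
    F = float(t_res.t**2)
    df2 = t_res.df
    p = 1.0 if F == 0.0 else float(stats.f.sf(F, 1, df2))
    return ContrastResult(
        F=F, df1=1, df2=df2, p=p, partial_eta_sq=F / (F + df2)
    )


def slope_t_test(slopes: Iterable[float]) -> OneSampleResult:
    """Two-sided one-sample t-test of per-subject slopes against zero."""
    return _one_sample_t(np.asarray(list(slopes), dtype=float))


def confidence_intervention_test(
    trials: pd.DataFrame, session: str = "corrupted"
) -> OneSampleResult:
    """Paired test of mean confidence: test runs minus intervention runs.

    Applies to continuous-response datasets (confidence = |response|).
    Within the given session, each subject contributes the difference
    between mean confidence over test runs and over intervention runs; a
    one-sample t-test on these differences is returned.
    """
    if "response_value" not in trials.columns or trials["response_value"].isna().all():
        raise NotApplicableError(
            "confidence analysis needs continuous responses ('response_value')"
        )
    sub = trials[trials["session_feedback"] == session].copy()
    if sub.empty:
        raise ValueError(f"no trials for session {session!r}")
    sub["confidence"] = sub["response_value"].abs()
    means = sub.groupby(["subject_id", "run_type"])["confidence"].mean().unstack()
    if "test" not in means.columns or "intervention" not in means.columns:
        raise ValueError("both test and intervention runs are required")
    diff = (means["test"] - means["intervention"]).dropna().to_numpy()
    return _one_sample_t(diff)


def cohort_metrics(trials: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-subject, per-session, per-test-run metrics table.

    Returns columns subject, session, time (test-run number 1..T),
    performance, cci and, when continuous responses are present,
    mean_confidence.  Vectorised equivalent of calling ``run_metrics`` on
    every test run.
    """
    test = trials[trials["run_type"] == "test"].copy()
    if test.empty:
        raise ValueError("no test-run trials in table")
    test["correct_f"] = _correct_column(test)
    test["congruent"] = (
        test["cue"].astype(float) == test["true_stimulus"].astype(float)
    )
    keys = ["subject_id", "session_feedback", "run_index"]
    grouped = test.groupby(keys, sort=True)
    perf = grouped["correct_f"].mean() * 100.0
    cr = (
        test.groupby(keys + ["congruent"], sort=True)["correct_f"].mean().unstack(
            "congruent"
        )
        * 100.0
    )
    if True not in cr.columns or False not in cr.columns or cr.isna().any().any():
        raise UndefinedCCIError(
            "some test run lacks cue-congruent or cue-incongruent trials"
        )
    out = pd.DataFrame({"performance": perf, "cci": cr[True] - cr[False]})
    if "response_value" in test.columns and test["response_value"].notna().any():
        out["mean_confidence"] = grouped["response_value"].apply(
            lambda s: s.abs().mean()
        )
    out = out.reset_index().rename(
        columns={"subject_id": "subject", "session_feedback": "session"}
    )
    out["time"] = out.groupby(["subject", "session"])["run_index"].rank(
        method="dense"
    ).astype(int)
    return out.drop(columns="run_index")


def subject_slopes(metrics: pd.DataFrame, value: str) -> pd.DataFrame:
    """Per-subject, per-session OLS slope of ``value`` against time."""
    rows = []
    for (subject, session), grp in metrics.groupby(["subject", "session"]):
        grp = grp.sort_values("time")
        rows.append(
            {
                "subject": subject,
                "session": session,
                "slope": _ols_slope(grp[value].to_numpy(dtype=float)),
            }
        )
    return pd.DataFrame(rows)


def analyze_cohort(trials: pd.DataFrame) -> dict:
    """Full cohort analysis: run-wise means, slope tests and interactions.

    Returns a JSON-serialisable dict with, per measure (performance, cci
    and optionally mean_confidence): cohort means per session and time,
    per-session slope t-tests, and the feedback-type x time linear
    interaction.  Binary-response cohorts simply omit the confidence
    entries.
    """
    metrics = cohort_metrics(trials)
    measures = ["performance", "cci"]
    if "mean_confidence" in metrics.columns:
        measures.append("mean_confidence")
    results: dict = {"n_subjects": int(metrics["subject"].nunique()), "measures": {}}
    for measure in measures:
        cohort_means = (
            metrics.groupby(["session", "time"])[measure].mean().unstack("time")
        )
        slopes = subject_slopes(metrics, measure)
        slope_tests = {}
        for session, grp in slopes.groupby("session"):
            slope_tests[session] = asdict(slope_t_test(grp["slope"]))
        entry = {
            "cohort_means": {
                session: [float(v) for v in row]
                for session, row in cohort_means.iterrows()
            },
            "slope_tests": slope_tests,
        }
        if set(metrics["session"].unique()) == {"corrupted", "uncorrupted"}:
            entry["linear_interaction"] = asdict(
                linear_interaction_test(
                    metrics.rename(columns={measure: "value"}), "value"
                )
            )
        results["measures"][measure] = entry
    if "response_value" in trials.columns and trials["response_value"].notna().any():
        conf = {}
        for session in trials["session_feedback"].unique():
            conf[str(session)] = asdict(
                confidence_intervention_test(trials, session=session)
            )
        results["confidence_intervention_drop"] = conf
    return results
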