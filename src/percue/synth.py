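"""Synthetic trial-level datasets with the structure of the human task.

No human data ship with this package, so the analysis pipeline is
exercised on generated cohorts whose effect sizes are configurable — the
defaults reproduce the printed group-level statistics of the binary-report
experiment (performance slopes -3.05 / -0.05 percent per run, CCI slopes
2.76 / -0.41 points per run, 34 subjects).

Effects enter directly through the two conditional correctness rates: for
a target performance P and cue congruence index C,

    CR_CC = P + 0.25 * C        CR_CI = P - 0.75 * C,

so that with a 75/25 cue-stimulus contingency the identities
0.75*CR_CC + 0.25*CR_CI = P and CR_CC - CR_CI = C hold exactly.  Trial
outcomes are Bernoulli draws from those rates.  This route is deliberately
independent of the Bayesian observer: the generator and the simulator give
two unrelated paths into the same analysis code.

Continuous mode mimics the orientation-plus-confidence report: each
response is a signed value in [-1, 1] whose sign is the choice and whose
magnitude is a confidence drawn from a rescaled Beta distribution on
[0.03, 1] (responses in (-0.03, 0.03) cannot occur).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocol import _balanced_stimuli, _cue_schedule

__all__ = ["BehaviorGenConfig", "generate_cohort"]

#: Fixed concentration (a + b) of the Beta confidence distribution.
CONFIDENCE_CONCENTRATION = 8.0

#: Smallest selectable confidence; the response scale excludes (-0.03, 0.03).
CONFIDENCE_FLOOR = 0.03


@dataclass(frozen=True)
class BehaviorGenConfig:
    """Generator settings; defaults follow the binary-report experiment."""

    n_subjects: int = 34
    response_mode: str = "binary"  # or "continuous"
    baseline_performance: float = 80.0  # percent, the staircase target
    performance_slope_corrupted: float = -3.05  # percent per run
    performance_slope_uncorrupted: float = -0.05
    cci_baseline: float = 5.0  # points at test run 1
    cci_slope_corrupted: float = 2.76  # points per run
    cci_slope_uncorrupted: float = -0.41
    cue_validity: float = 0.75
    n_test_runs: int = 4
    trials_per_test_run: int = 64
    n_intervention_runs: int = 3
    trials_per_intervention_run: int = 128
    run_noise_sd: float = 6.0  # percent; subject/run-level performance jitter
    intervention_performance: float = 65.0  # percent correct in uncued runs
    confidence_mean_test: float = 0.51
    confidence_mean_intervention: float = 0.35
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.response_mode not in ("binary", "continuous"):
            raise ValueError("response_mode must be 'binary' or 'continuous'")
        if not (0.0 <= self.cue_validity <= 1.0):
            raise ValueError("cue_validity must be in [0, 1]")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for mean in (self.confidence_mean_test, self.confidence_mean_intervention):
            if not (CONFIDENCE_FLOOR < mean < 1.0):
                raise ValueError(
                    f"confidence means must lie in ({CONFIDENCE_FLOOR}, 1)"
                )


def _target_rates(config: BehaviorGenConfig, session: str, time: int) -> tuple[float, float]:
    """Noise-free CR_CC and CR_CI (percent) for one session x test run."""
    if session == "corrupted":
        p_slope, c_slope = (
            config.performance_slope_corrupted,
            config.cci_slope_corrupted,
        )
    else:
        p_slope, c_slope = (
            config.performance_slope_uncorrupted,
            config.cci_slope_uncorrupted,
        )
    perf = config.baseline_performance + p_slope * (time - 1)
    cci = config.cci_baseline + c_slope * (time - 1)
    cr_cc = perf + (1.0 - config.cue_validity) * cci
    cr_ci = perf - config.cue_validity * cci
    return cr_cc, cr_ci


def _check_feasible(config: BehaviorGenConfig) -> None:
    for session in ("corrupted", "uncorrupted"):
        for time in range(1, config.n_test_runs + 1):
            cr_cc, cr_ci = _target_rates(config, session, time)
            for name, value in (("CR_CC", cr_cc), ("CR_CI", cr_ci)):
                if not (0.0 <= value <= 100.0):
                    raise ValueError(
                        f"infeasible target: {name} = {value:.2f}% in session "
                        f"'{session}', test run {time}"
                    )


def _draw_confidence(
    mean: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Beta-distributed confidence rescaled to [CONFIDENCE_FLOOR, 1]."""
    span = 1.0 - CONFIDENCE_FLOOR
    m = (mean - CONFIDENCE_FLOOR) / span
    a = m * CONFIDENCE_CONCENTRATION
    b = (1.0 - m) * CONFIDENCE_CONCENTRATION
    return CONFIDENCE_FLOOR + span * rng.beta(a, b, size=size)


def generate_cohort(config: BehaviorGenConfig) -> pd.DataFrame:
    """Generate an analysis-ready trial table for a paired two-session cohort.

    Every subject contributes a corrupted and an uncorrupted session, each
    with the full T-I-T-I-T-I-T run structure.  Test-run outcomes are drawn
    Bernoulli from the per-run CR_CC / CR_CI targets (clipped to
    [2%, 98%] before sampling); intervention runs are cue-less at a flat
    performance level.  Continuous mode adds a ``response_value`` column
    with sign = choice and |value| = confidence.
    """
    _check_feasible(config)
    rng = np.random.default_rng(config.rng_seed)
    continuous = config.response_mode == "continuous"
    n_runs = config.n_test_runs + config.n_intervention_runs
    rows: list[pd.DataFrame] = []
    for subject in range(1, config.n_subjects + 1):
        for session in ("corrupted", "uncorrupted"):
            # Subject x session jitter of the performance trajectory, shared
            # across that session's runs plus an independent per-run part.
            subject_shift = rng.normal(0.0, config.run_noise_sd / 2.0)
            time = 0
            for run_index in range(1, n_runs + 1):
                is_test = run_index % 2 == 1
                if is_test:
                    time += 1
                    n = config.trials_per_test_run
                    stim = _balanced_stimuli(n, rng)
                    cue = _cue_schedule(stim, config.cue_validity, rng)
                    cr_cc, cr_ci = _target_rates(config, session, time)
                    noise = subject_shift + rng.normal(0.0, config.run_noise_sd / 2.0)
                    p_correct = np.where(cue == stim, cr_cc + noise, cr_ci + noise)
                else:
                    n = config.trials_per_intervention_run
                    stim = _balanced_stimuli(n, rng)
                    cue = np.full(n, np.nan)
                    p_correct = np.full(n, config.intervention_performance)
                p_correct = np.clip(p_correct / 100.0, 0.02, 0.98)
                correct = rng.random(n) < p_correct
                decision = np.where(correct, stim, 1 - stim)
                run = pd.DataFrame(
                    {
                        "subject_id": subject,
                        "session_feedback": session,
                        "run_index": run_index,
                        "run_type": "test" if is_test else "intervention",
                        "cue": cue,
                        "true_stimulus": stim,
                        "feedback_label": stim,
                        "sensvote": np.nan,
                        "cuevote": cue,
                        "prediction": np.nan,
                        "decision": decision,
                        "correct": correct.astype(int),
                        "cue_congruent": np.where(
                            np.isnan(cue), np.nan, (decision == cue).astype(float)
                        ),
                    }
                )
                if continuous:
                    if is_test:
                        conf_mean = config.confidence_mean_test
                    elif session == "corrupted":
                        conf_mean = config.confidence_mean_intervention
                    else:
                        conf_mean = config.confidence_mean_test
                    conf = _draw_confidence(conf_mean, n, rng)
                    sign = np.where(decision == 1, 1.0, -1.0)
                    run["response_value"] = sign * conf
                rows.append(run)
    return pd.concat(rows, ignore_index=True)
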