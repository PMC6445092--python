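"""Simulation of the full experimental session for artificial observers.

A session consists of four cued *test runs* interleaved with three uncued
*intervention runs* (T1 I1 T2 I2 T3 I3 T4).  Evidence for the two stimulus
classes is drawn from N(0, 4) ("target absent") and N(0.5, 4) ("target
present") by default; these moments are chosen so that an ideal observer
integrating 40 samples per trial performs at roughly the 80%-correct level
targeted by the staircase in the behavioural task.

During intervention runs the sensory classifier learns from feedback: the
belief named by the feedback label is updated with the trial's sample
batch.  With uncorrupted feedback the label always equals the true
stimulus; with corrupted feedback exactly half the trials of each stimulus
type carry the wrong label, so each class belief is trained on a 50/50
mixture of both classes — label noise that drives the two beliefs towards
each other.  During test runs the beliefs are frozen; decisions combine the
sensory vote with a 75%-valid cue through logistic weights fitted to the
true labels of that run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .observer import (
    NormalGammaBelief,
    SensoryClassifier,
    decide,
    fit_decision_weights,
    sensory_vote,
    sensory_vote_rows,
    update_belief,
)

__all__ = [
    "SimulationConfig",
    "TRIAL_COLUMNS",
    "pretrain",
    "run_intervention",
    "run_test",
    "simulate_subject",
    "simulate_cohort",
]

#: Column order of the trial-level log produced by the simulator.
TRIAL_COLUMNS = [
    "subject_id",
    "session_feedback",
    "run_index",
    "run_type",
    "cue",
    "true_stimulus",
    "feedback_label",
    "sensvote",
    "cuevote",
    "prediction",
    "decision",
    "correct",
    "cue_congruent",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the artificial-observer experiment.

    Defaults reproduce the reference simulation: stimulus classes
    N(0, 4) and N(0.5, 4), 40 evidence samples per trial, 20 pre-training
    stimuli per class, 4 test runs of 64 trials with a 75%-valid cue,
    3 intervention runs of 128 trials with half of each stimulus type
    mislabelled in the corrupted condition, 1000 subjects per condition.
    """

    mean_absent: float = 0.0
    mean_present: float = 0.5
    variance: float = 4.0
    samples_per_trial: int = 40
    pretrain_stimuli: int = 20
    n_test_runs: int = 4
    n_intervention_runs: int = 3
    trials_per_test_run: int = 64
    trials_per_intervention_run: int = 128
    cue_validity: float = 0.75
    corrupted_fraction: float = 0.5
    n_subjects: int = 1000
    rng_seed: int = 0
    # Weakly informative symmetric prior: located at the midpoint of the two
    # class means so that pre-training, not the prior, breaks the symmetry.
    prior_mu: float = 0.25
    prior_kappa: float = 0.1
    prior_alpha: float = 1.0
    prior_beta: float = 1.0
    # Fit decision weights on the current test run only (default) or
    # cumulatively over all test runs seen so far.
    cumulative_fit: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.cue_validity <= 1.0):
            raise ValueError("cue_validity must be in [0, 1]")
        if not (0.0 <= self.corrupted_fraction <= 1.0):
            raise ValueError("corrupted_fraction must be in [0, 1]")
        if self.variance <= 0:
            raise ValueError("variance must be > 0")
        for name in (
            "samples_per_trial",
            "n_test_runs",
            "n_intervention_runs",
            "trials_per_test_run",
            "trials_per_intervention_run",
            "n_subjects",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.pretrain_stimuli < 0:
            raise ValueError("pretrain_stimuli must be >= 0")
        if self.trials_per_test_run % 2 or self.trials_per_intervention_run % 2:
            raise ValueError(
                "per-run trial counts must be even (balanced stimulus types "
                "and exact half-mislabelling require it)"
            )

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))

    def prior_classifier(self) -> SensoryClassifier:
        prior = NormalGammaBelief(
            mu=self.prior_mu,
            kappa=self.prior_kappa,
            alpha=self.prior_alpha,
            beta=self.prior_beta,
        )
        return SensoryClassifier(belief_absent=prior, belief_present=prior)


def pretrain(config: SimulationConfig, rng: np.random.Generator) -> SensoryClassifier:
    """Train both class beliefs on correctly labelled stimuli of their class.

    Each class belief is updated with ``pretrain_stimuli`` virtual stimuli,
    every stimulus being a batch of ``samples_per_trial`` draws from that
    class's normal distribution (so 20 stimuli x 40 samples = 800 evidence
    samples by default — enough to mimic a trained human observer at
    baseline).  With zero pre-training stimuli the prior classifier is
    returned unchanged.
    """
    classifier = config.prior_classifier()
    if config.pretrain_stimuli == 0:
        return classifier
    n = config.pretrain_stimuli * config.samples_per_trial
    x0 = rng.normal(config.mean_absent, config.sd, size=n)
    x1 = rng.normal(config.mean_present, config.sd, size=n)
    return SensoryClassifier(
        belief_absent=update_belief(classifier.belief_absent, x0),
        belief_present=update_belief(classifier.belief_present, x1),
    )


def _balanced_stimuli(n: int, rng: np.random.Generator) -> np.ndarray:
    stim = np.repeat([0, 1], n // 2)
    return rng.permutation(stim)


def _corruption_schedule(
    stimuli: np.ndarray, corrupted_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Feedback labels mislabelling an exact fraction of each stimulus type."""
    labels = stimuli.copy()
    for s in (0, 1):
        idx = np.flatnonzero(stimuli == s)
        n_flip = round(corrupted_fraction * idx.size)
        flip = rng.permutation(idx)[:n_flip]
        labels[flip] = 1 - s
    return labels


def run_intervention(
    classifier: SensoryClassifier,
    config: SimulationConfig,
    corrupted: bool,
    rng: np.random.Generator,
) -> tuple[SensoryClassifier, pd.DataFrame]:
    """One uncued intervention run: classify, then learn from feedback.

    Per trial the observer draws a sample batch from the true stimulus
    distribution, records the sensory vote and the cue-free decision
    (sign of sensvote, with ties to "present"), and then updates the belief
    named by the feedback label with that batch.  In corrupted mode the
    label schedule mislabels exactly ``corrupted_fraction`` of each
    stimulus type in pseudo-random order.
    """
    n = config.trials_per_intervention_run
    m = config.samples_per_trial
    stimuli = _balanced_stimuli(n, rng)
    fraction = config.corrupted_fraction if corrupted else 0.0
    labels = _corruption_schedule(stimuli, fraction, rng)
    means = np.where(stimuli == 1, config.mean_present, config.mean_absent)
    batches = rng.normal(means[:, None], config.sd, size=(n, m))

    beliefs = [classifier.belief_absent, classifier.belief_present]
    sensvotes = np.empty(n)
    for t in range(n):
        batch = batches[t]
        sensvotes[t] = sensory_vote(
            SensoryClassifier(belief_absent=beliefs[0], belief_present=beliefs[1]),
            batch,
        )
        k = labels[t]
        beliefs[k] = update_belief(beliefs[k], batch)

    decisions = (sensvotes >= 0).astype(int)
    trials = pd.DataFrame(
        {
            "cue": np.nan,
            "true_stimulus": stimuli,
            "feedback_label": labels,
            "sensvote": sensvotes,
            "cuevote": np.nan,
            "prediction": np.nan,
            "decision": decisions,
            "correct": (decisions == stimuli).astype(int),
            "cue_congruent": np.nan,
        }
    )
    updated = SensoryClassifier(belief_absent=beliefs[0], belief_present=beliefs[1])
    return updated, trials


def _cue_schedule(
    stimuli: np.ndarray, validity: float, rng: np.random.Generator
) -> np.ndarray:
    """Cues agreeing with the stimulus on an exact fraction of each type.

    The contingency is scheduled (shuffled assignment), not sampled, so the
    realised validity equals ``validity`` in every run.
    """
    cues = np.empty_like(stimuli)
    for s in (0, 1):
        idx = rng.permutation(np.flatnonzero(stimuli == s))
        n_valid = round(validity * idx.size)
        cues[idx[:n_valid]] = s
        cues[idx[n_valid:]] = 1 - s
    return cues


def run_test(
    classifier: SensoryClassifier,
    config: SimulationConfig,
    rng: np.random.Generator,
    history: tuple | None = None,
) -> pd.DataFrame:
    """One cued test run: fit decision weights on true labels and decide.

    The beliefs are frozen (no learning).  The cue predicts the shown
    stimulus on exactly ``cue_validity`` of the trials of each type.
    Logistic decision weights are fitted to this run's (sensvote, cuevote,
    true label) triples — or, with ``cumulative_fit``, to all test-run
    triples seen so far (pass them via ``history``) — and applied to every
    trial of the run.
    """
    n = config.trials_per_test_run
    m = config.samples_per_trial
    stimuli = _balanced_stimuli(n, rng)
    cues = _cue_schedule(stimuli, config.cue_validity, rng)
    means = np.where(stimuli == 1, config.mean_present, config.mean_absent)
    batches = rng.normal(means[:, None], config.sd, size=(n, m))
    sensvotes = sensory_vote_rows(classifier, batches)

    fit_s, fit_c, fit_y = sensvotes, cues, stimuli
    if config.cumulative_fit and history is not None:
        fit_s = np.concatenate([history[0], sensvotes])
        fit_c = np.concatenate([history[1], cues])
        fit_y = np.concatenate([history[2], stimuli])
    weights = fit_decision_weights(fit_s, fit_c, fit_y)
    predictions, decisions = decide(weights, sensvotes, cues)

    return pd.DataFrame(
        {
            "cue": cues.astype(float),
            "true_stimulus": stimuli,
            "feedback_label": stimuli,  # test-run feedback is always correct
            "sensvote": sensvotes,
            "cuevote": cues.astype(float),
            "prediction": predictions,
            "decision": decisions,
            "correct": (decisions == stimuli).astype(int),
            "cue_congruent": (decisions == cues).astype(float),
        }
    )


def simulate_subject(
    config: SimulationConfig,
    feedback: str,
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Simulate one artificial subject's session under one feedback mode.

    Runs pre-training followed by the alternating sequence
    T1, I1, T2, I2, ..., ending on a test run.  ``feedback`` is
    ``"corrupted"`` or ``"uncorrupted"`` and applies to all intervention
    runs.  Returns the concatenated trial log.
    """
    if feedback not in ("corrupted", "uncorrupted"):
        raise ValueError("feedback must be 'corrupted' or 'uncorrupted'")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    corrupted = feedback == "corrupted"

    classifier = pretrain(config, rng)
    logs: list[pd.DataFrame] = []
    hist_s: list[np.ndarray] = []
    hist_c: list[np.ndarray] = []
    hist_y: list[np.ndarray] = []
    run_index = 0
    for i in range(config.n_test_runs + config.n_intervention_runs):
        run_index += 1
        if i % 2 == 0:  # test runs occupy odd positions 1, 3, 5, 7
            history = None
            if config.cumulative_fit and hist_s:
                history = (
                    np.concatenate(hist_s),
                    np.concatenate(hist_c),
                    np.concatenate(hist_y),
                )
            trials = run_test(classifier, config, rng, history=history)
            trials.insert(0, "run_type", "test")
            hist_s.append(trials["sensvote"].to_numpy())
            hist_c.append(trials["cue"].to_numpy())
            hist_y.append(trials["true_stimulus"].to_numpy())
        else:
            classifier, trials = run_intervention(classifier, config, corrupted, rng)
            trials.insert(0, "run_type", "intervention")
        trials.insert(0, "run_index", run_index)
        logs.append(trials)

    out = pd.concat(logs, ignore_index=True)
    out.insert(0, "session_feedback", feedback)
    return out


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Simulate every subject under both feedback conditions (paired design).

    Each subject x condition gets an independent, deterministically derived
    random substream, so cohorts are reproducible from the master seed and
    any subject can be re-simulated in isolation.
    """
    if config.n_subjects < 2:
        raise ValueError("a cohort needs n_subjects >= 2")
    if seed is None:
        seed = config.rng_seed
    subject_seeds = np.random.SeedSequence(seed).spawn(config.n_subjects)
    logs: list[pd.DataFrame] = []
    for subject_id, subject_seq in enumerate(subject_seeds, start=1):
        streams = subject_seq.spawn(2)
        for feedback, seq in zip(("corrupted", "uncorrupted"), streams):
            trials = simulate_subject(config, feedback, np.random.default_rng(seq))
            trials.insert(0, "subject_id", subject_id)
            logs.append(trials)
    return pd.concat(logs, ignore_index=True)[TRIAL_COLUMNS]
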