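# Methods

## The artificial observer

Each stimulus class is represented by a normal-gamma belief
`NG(μ, κ, α, β)` over the mean and precision of a normal evidence source.
A batch of n samples with mean x̄ and sum of squared deviations SS updates
the hyperparameters in closed form:

    κ' = κ + n
    α' = α + n/2
    μ' = (κμ + n·x̄) / κ'
    β' = β + SS/2 + κn(x̄ − μ)² / (2κ')

The update is exchangeable (one batch of n equals n single-sample updates),
and with unbounded correctly-labelled data the posterior predictive
converges to the true source distribution.  The predictive is a Student-t
with location μ, scale² β(κ+1)/(ακ) and 2α degrees of freedom; a trial's
batch is scored as the sum of per-sample log densities under this fixed
predictive (i.i.d. evaluation — the belief is not re-updated between the
samples of one batch).  The alternative, a joint predictive with
sequential updating inside the batch, was considered and rejected: the
sensory vote is defined as a single likelihood comparison per trial, and
the convergence argument above is stated for the fixed predictive.

The decision rule is the standard logistic
`σ(c + β_s·sensvote + β_c·cuevote)` with the boundary prediction 0.5
assigned to "target present".  A printed variant of this rule mapping
predictions to (1, 2) is not implementable against a 0.5 threshold, so the
standard sigmoid orientation is used.  Weights are fitted by maximum
likelihood with a small L2 penalty (1e-4 per coefficient, intercept
unpenalised) so that separable designs — possible at 64 trials — yield
finite coefficients.  The fitted slopes play the role of reliabilities
(precision-like weights) of the two information sources.

## Session structure and parameters

| parameter | default | meaning |
|---|---|---|
| mean_absent / mean_present | 0 / 0.5 | class means, evidence units |
| variance | 4 | class variance (both classes) |
| samples_per_trial | 40 | evidence batch size per trial |
| pretrain_stimuli | 20 | pre-training stimuli per class (×40 samples each) |
| trials_per_test_run | 64 | cued test-run length |
| trials_per_intervention_run | 128 | uncued intervention-run length |
| n_test_runs / n_intervention_runs | 4 / 3 | interleaved T-I-T-I-T-I-T |
| cue_validity | 0.75 | exact per-run cue-stimulus contingency |
| corrupted_fraction | 0.5 | mislabelled fraction per stimulus type |
| n_subjects | 1000 | cohort size per condition |
| prior (μ, κ, α, β) | 0.25, 0.1, 1, 1 | weakly informative symmetric prior |

The class moments put the ideal 40-sample discriminator at
Φ(0.5·√40/(2·2)) ≈ 78.5% correct, i.e. the ~80% level that the behavioural
staircase targets.  Pre-training is counted in stimuli, not raw samples:
each of the 20 pre-training stimuli per class is a full 40-sample batch, so
the observer starts near its converged accuracy — this is what makes the
uncorrupted session's curves flat, and it mirrors a human observer who
arrives at the main task already trained.  The prior is centred on the
midpoint of the class means with a small pseudo-count (κ = 0.1) so that
pre-training, not the prior, determines the starting beliefs; with 800
pre-training samples per class its influence is negligible.

Schedules are exact rather than Bernoulli: every run contains equal
numbers of both stimuli, cue-stimulus agreement is exactly 75% of each
stimulus type per test run (shuffled assignment), and corrupted feedback
mislabels exactly half of each stimulus type per intervention run.  This
matches a designed experiment and removes schedule variance from the
cohort statistics.

Decision weights are fitted per test run on that run's trials only
(cumulative fitting across test runs is available as a config option,
default off): the observer re-estimates the reliability of its two
information sources in every cued block, which is how the growing cue
reliance after corrupted interventions expresses itself.  Intervention-run
decisions, where no cue exists, are the sign of the sensory vote — the
logistic rule with the cue term absent degenerates to exactly this
threshold.

Randomness: one master seed spawns per-subject, per-condition substreams
(`numpy` SeedSequence), so cohorts are bit-reproducible and any subject can
be re-simulated in isolation.

## Analysis conventions

A *cue-congruent trial* is one where the cue's predicted stimulus was
actually shown (the 75% contingency), and CR_CC / CR_CI are percent
correct within those subsets.  This is the reading under which both
anchors hold: responding with the cue on every trial gives CCI = 100, and
cue-independent responding gives CCI = 0.  A run lacking either subset
raises an error rather than imputing 0 (with exact 75/25 scheduling at 64
trials this cannot occur in simulation).  For continuous responses in
[−1, 1], the sign is the choice and |response| ∈ [0.03, 1] the confidence.

The feedback-type × time test is a linear within-subject contrast: per
subject and session L = Σ w_t y_t with centred integer weights
(−3, −1, 1, 3 for four test runs; any positive rescaling of w leaves the
statistics unchanged), then a paired t on L_corrupted − L_uncorrupted,
reported as F = t² with df (1, n−1), p from the F distribution and
η_p² = F/(F + n − 1).  This is algebraically the linear-trend interaction
of a 2×4 repeated-measures ANOVA, verified in the tests against an
independent sums-of-squares decomposition.  Between-subject factors and
covariates of the original behavioural design (session order, cue-stimulus
association type, days between sessions) are out of scope here; they
require the unreleased human data and were reported non-significant.
Degenerate inputs (zero-variance differences) return t = 0, p = 1 rather
than NaN.  All tests are two-sided at α = 0.05.

## The synthetic behavioural generator

`synth.generate_cohort` emulates the *statistical structure* of the two
human experiments, not their mechanism: per subject × session × test run a
target performance and CCI trajectory (baseline plus linear slope,
defaults set to the binary-report experiment's group statistics: slopes
−3.05 / −0.05 percent per run, CCI slopes 2.76 / −0.41, n = 34, ~80%
baseline) is converted to the two conditional rates

    CR_CC = P + 0.25·C,   CR_CI = P − 0.75·C,

which satisfy 0.75·CR_CC + 0.25·CR_CI = P and CR_CC − CR_CI = C exactly,
and trial outcomes are drawn Bernoulli (probabilities clipped to
[0.02, 0.98]).  A subject×session level Gaussian jitter plus a per-run
jitter (total SD 6 percentage points, split evenly) produces
between-subject slope variability of realistic size; the CCI trajectory is
left unjittered because binomial noise at 48/16 trials already dominates
its variance.  Continuous mode draws confidence from a Beta distribution
(fixed concentration 8, mean-parameterised) rescaled to [0.03, 1] — the
response scale's dead zone — with test runs at mean 0.51 everywhere,
intervention runs at 0.35 in the corrupted session and at the test-run
level in the uncorrupted session; this plants the 0.16 test-minus-
intervention confidence drop that the analysis should recover.  Baseline
CCI defaults to 5 points, a small positive cue influence of the size seen
in trained human observers.

Because effects enter through the conditional rates rather than through a
latent observer, the generator is an oracle *independent* of the protocol
simulator: the analysis module is validated along two unrelated routes.
What passing recovery tests do **not** show: that real observers satisfy
the generator's assumptions (conditionally independent Bernoulli outcomes,
linear trajectories, Beta confidence, no lapses, no serial dependence).

## Psychophysics

Stimulus composition follows `I = 0.5(1 + w_s·G + w_n·N)` with
`w_s = w_n·s/(100−s)`, w_n = 0.25: an annular sinusoidal grating (±45°,
0.87 cycles/degree, diameters 9.94°/20.93°) and Gaussian-smoothed annular
noise, each min-max rescaled to [−0.5, 0.5] inside the annulus, background
mid-grey.  Grating phase, the noise-smoothing kernel (Gaussian, σ = 0.25°
default), pixel-per-degree mapping (auto-fitted to the image unless given)
and the hard annulus edge are not constrained by the design and are
exposed in `StimulusSpec`; none of them affects any quantitative result in
this package.

The staircase is 2-down-1-up with down/up step ratio 0.5548 (phase 1:
1%/0.5548%, phase 2: 0.5%/0.2774%), phase 1 ending at 8 reversals or 80
trials, phase 2 at 6 reversals by default (10 in the original protocol;
configurable) with the threshold taken as the mean signal at the last 4
reversals of phase 2.  Reversals are logged at the pre-step signal level.
The rule's equilibrium satisfies p²·Δdown = (1 − p²)·Δup, i.e.
p = (1/1.5548)^½ ≈ 0.802, so the estimate tracks the ~80.35%-correct point
of the psychometric function; the signal is floored at 0.1% to stay
positive.

## Problem sizes and tolerances

The test suite runs scaled versions of the expensive computations: a
200-subject paired cohort for the replication checks (slope means compared
with the 1000-subject reference values within 3 cohort standard errors,
effect sizes via a delta-method SE), 200 replicate synthetic cohorts for
slope recovery, 1000 replicate null cohorts for the type-I-error check
(5% ± 2 points), 500 staircase runs for threshold calibration (±1.5%
signal), and quadrature agreement of the predictive likelihood to 1e-4
nats.  Conjugacy identities are exact to 1e-10.  `scripts/acceptance.py`
runs the full 1000-subject cohort.

## Known limitations

- Simulated performance and CCI levels are only interpretable as *changes*;
  absolute levels depend on the arbitrary evidence moments.
- The observer has no lapses, no sequential effects, no learning during
  test runs and no reaction-time model.
- The logistic weight fit within a 64-trial run is noisy by design; this
  in-run variability is part of the simulated cohort variance.
- The analysis omits the multi-factor ANOVA covariates of the behavioural
  study and any awareness/motivation analyses, which need the unreleased
  human dataset.
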