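"""Bayesian sensory and decision classifiers of the artificial observer.

The observer learns two stimulus classes ("target absent" = class 0,
"target present" = class 1) by maintaining one normal-gamma belief per
class.  A normal-gamma distribution is the conjugate prior for a normal
likelihood with unknown mean and precision, so a belief can be updated in
closed form from a batch of evidence samples, and its posterior-predictive
distribution — the probability of new evidence under everything learned so
far — is a Student-t.

On each trial the observer receives a batch of evidence samples and forms a
*sensory vote*: the log-likelihood ratio (in nats) of the batch under the
class-1 versus the class-0 predictive distribution.  In cued runs the vote
is combined with a binary *cue vote* through a logistic decision rule whose
weights are fitted by (lightly ridge-penalised) maximum likelihood against
the true stimulus labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln
from sklearn.linear_model import LogisticRegression

__all__ = [
    "NormalGammaBelief",
    "SensoryClassifier",
    "DecisionWeights",
    "DegenerateDesignError",
    "update_belief",
    "predictive_log_likelihood",
    "sensory_vote",
    "fit_decision_weights",
    "decide",
]

#: Ridge penalty applied to the logistic decision weights so that separable
#: designs (possible at small trial counts) yield finite coefficients.
LOGISTIC_L2_PENALTY = 1e-4


class DegenerateDesignError(ValueError):
    """Raised when a logistic fit is requested on a single-class design."""


@dataclass(frozen=True)
class NormalGammaBelief:
    """Conjugate belief over the mean and precision of one stimulus class.

    Parameters
    ----------
    mu : float
        Location hyperparameter — the current point estimate of the class
        mean, in stimulus-evidence units.
    kappa : float
        Pseudo-count weighting the location estimate; grows by one per
        observed sample.  Strictly positive.
    alpha : float
        Shape hyperparameter of the gamma part; grows by 1/2 per observed
        sample.  Strictly positive.
    beta : float
        Rate hyperparameter of the gamma part, in squared-evidence units;
        accumulates observed sums of squares.  Strictly positive.
    """

    mu: float
    kappa: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("kappa", "alpha", "beta"):
            value = getattr(self, name)
            if not (value > 0.0) or not math.isfinite(value):
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")
        if not math.isfinite(self.mu):
            raise ValueError(f"mu must be finite, got {self.mu!r}")

    @property
    def predictive_df(self) -> float:
        """Degrees of freedom of the posterior-predictive Student-t."""
        return 2.0 * self.alpha

    @property
    def predictive_scale_sq(self) -> float:
        """Squared scale of the posterior-predictive Student-t."""
        return self.beta * (self.kappa + 1.0) / (self.alpha * self.kappa)

    @property
    def predictive_mean(self) -> float:
        """Mean of the posterior-predictive (defined for df > 1)."""
        return self.mu

    @property
    def predictive_variance(self) -> float:
        """Variance of the posterior-predictive Student-t (df > 2)."""
        nu = self.predictive_df
        if nu <= 2.0:
            return math.inf
        return self.predictive_scale_sq * nu / (nu - 2.0)

    def to_dict(self) -> dict[str, float]:
        return {"mu": self.mu, "kappa": self.kappa, "alpha": self.alpha, "beta": self.beta}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "NormalGammaBelief":
        return cls(mu=d["mu"], kappa=d["kappa"], alpha=d["alpha"], beta=d["beta"])


@dataclass(frozen=True)
class SensoryClassifier:
    """Pair of independent class beliefs: D0 (absent) and D1 (present)."""

    belief_absent: NormalGammaBelief
    belief_present: NormalGammaBelief

    def to_dict(self) -> dict[str, dict[str, float]]:
        return {
            "belief_absent": self.belief_absent.to_dict(),
            "belief_present": self.belief_present.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict[str, dict[str, float]]) -> "SensoryClassifier":
        return cls(
            belief_absent=NormalGammaBelief.from_dict(d["belief_absent"]),
            belief_present=NormalGammaBelief.from_dict(d["belief_present"]),
        )


@dataclass(frozen=True)
class DecisionWeights:
    """Logistic coefficients combining sensory and cue votes.

    ``prediction = logistic(intercept_c + beta_s * sensvote + beta_c * cuevote)``

    The two slopes act like reliabilities (precisions) of the corresponding
    information sources.
    """

    intercept_c: float
    beta_s: float
    beta_c: float

    def __post_init__(self) -> None:
        for name in ("intercept_c", "beta_s", "beta_c"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def _as_batch(samples) -> np.ndarray:
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("sample batch must contain at least one value")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample batch must be finite")
    return x


def update_belief(belief: NormalGammaBelief, samples) -> NormalGammaBelief:
    """Return the conjugate posterior of ``belief`` given a sample batch.

    The update uses only the batch count ``n``, mean ``x̄`` and sum of
    squared deviations ``SS``:

        kappa' = kappa + n
        alpha' = alpha + n/2
        mu'    = (kappa*mu + n*x̄) / kappa'
        beta'  = beta + SS/2 + kappa*n*(x̄ - mu)^2 / (2*kappa')

    It is exchangeable: one batch of n samples is equivalent to n
    sequential single-sample updates.  The input belief is not modified.
    """
    x = _as_batch(samples)
    n = x.size
    xbar = float(x.mean())
    ss = float(np.sum((x - xbar) ** 2))
    kappa_n = belief.kappa + n
    mu_n = (belief.kappa * belief.mu + n * xbar) / kappa_n
    alpha_n = belief.alpha + n / 2.0
    beta_n = (
        belief.beta
        + 0.5 * ss
        + belief.kappa * n * (xbar - belief.mu) ** 2 / (2.0 * kappa_n)
    )
    return NormalGammaBelief(mu=mu_n, kappa=kappa_n, alpha=alpha_n, beta=beta_n)


def _student_t_logpdf_terms(belief: NormalGammaBelief) -> tuple[float, float, float, float]:
    # (location, scale, df, log normalising constant) of the predictive.
    nu = belief.predictive_df
    scale = math.sqrt(belief.predictive_scale_sq)
    log_norm = (
        gammaln((nu + 1.0) / 2.0)
        - gammaln(nu / 2.0)
        - 0.5 * math.log(nu * math.pi)
        - math.log(scale)
    )
    return belief.mu, scale, nu, log_norm


def predictive_log_likelihood(belief: NormalGammaBelief, samples) -> float:
    """Sum of per-sample log densities under the posterior predictive.

    The predictive is a Student-t with location ``mu``, squared scale
    ``beta*(kappa+1)/(alpha*kappa)`` and ``2*alpha`` degrees of freedom.
    Samples are evaluated i.i.d. under this fixed predictive (the belief is
    not updated between samples).  Returned in nats.
    """
    x = _as_batch(samples)
    loc, scale, nu, log_norm = _student_t_logpdf_terms(belief)
    z = (x - loc) / scale
    return float(np.sum(log_norm - (nu + 1.0) / 2.0 * np.log1p(z * z / nu)))


def predictive_log_likelihood_rows(belief: NormalGammaBelief, batches: np.ndarray) -> np.ndarray:
    """Vectorised ``predictive_log_likelihood`` over rows of a 2-D array."""
    batches = np.asarray(batches, dtype=float)
    if batches.ndim != 2 or batches.shape[1] == 0:
        raise ValueError("batches must be a 2-D array with at least one column")
    loc, scale, nu, log_norm = _student_t_logpdf_terms(belief)
    z = (batches - loc) / scale
    return batches.shape[1] * log_norm - (nu + 1.0) / 2.0 * np.sum(
        np.log1p(z * z / nu), axis=1
    )


def sensory_vote(classifier: SensoryClassifier, samples) -> float:
    """Log-likelihood ratio of a batch: present (D1) minus absent (D0), nats.

    Positive values favour "target present".  Antisymmetric under swapping
    the two beliefs.
    """
    return predictive_log_likelihood(
        classifier.belief_present, samples
    ) - predictive_log_likelihood(classifier.belief_absent, samples)


def sensory_vote_rows(classifier: SensoryClassifier, batches: np.ndarray) -> np.ndarray:
    """Vectorised ``sensory_vote`` over rows of a 2-D batch array."""
    return predictive_log_likelihood_rows(
        classifier.belief_present, batches
    ) - predictive_log_likelihood_rows(classifier.belief_absent, batches)


def fit_decision_weights(sensvotes, cuevotes, true_labels) -> DecisionWeights:
    """Maximum-likelihood logistic weights for label ~ sensvote + cuevote.

    A small L2 penalty (1e-4 per coefficient) keeps the coefficients finite
    on separable designs.  Both label values must be present and at least
    three trials are required.
    """
    s = np.asarray(sensvotes, dtype=float).ravel()
    c = np.asarray(cuevotes, dtype=float).ravel()
    y = np.asarray(true_labels, dtype=float).ravel()
    if not (s.size == c.size == y.size):
        raise ValueError(
            f"length mismatch: sensvotes {s.size}, cuevotes {c.size}, labels {y.size}"
        )
    if s.size < 3:
        raise ValueError("at least 3 trials are required to fit decision weights")
    if np.unique(y).size < 2:
        raise DegenerateDesignError("true labels contain a single class")
    model = LogisticRegression(
        C=1.0 / LOGISTIC_L2_PENALTY, solver="lbfgs", max_iter=10_000
    )
    model.fit(np.column_stack([s, c]), y.astype(int))
    return DecisionWeights(
        intercept_c=float(model.intercept_[0]),
        beta_s=float(model.coef_[0, 0]),
        beta_c=float(model.coef_[0, 1]),
    )


def decide(weights: DecisionWeights, sensvote, cuevote):
    """Logistic prediction and binary decision for one trial (or an array).

    ``prediction = 1 / (1 + exp(-(c + beta_s*sensvote + beta_c*cuevote)))``
    and ``decision = 1`` iff ``prediction >= 0.5`` (the boundary is assigned
    to "target present").
    """
    eta = weights.intercept_c + weights.beta_s * np.asarray(sensvote, dtype=float) \
        + weights.beta_c * np.asarray(cuevote, dtype=float)
    prediction = expit(eta)
    decision = (prediction >= 0.5).astype(int)
    if np.ndim(prediction) == 0:
        return float(prediction), int(decision)
    return prediction, decision
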