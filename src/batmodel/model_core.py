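"""Closed-form probabilities of the two-process rule-task model.

The model decomposes performance on a bivalent rule trial into two latent
binary processes: *memory* (is the active rule correctly held in working
memory?), which succeeds with probability ``pi`` (memory integrity), and
*response accumulation* (is the rule correctly integrated with the visual
cue?), which succeeds with probability ``beta``. A trial outcome is correct
when both processes succeed or both fail ("fluke" corrects).

``beta`` doubles as the decision threshold of an evidence-accumulation
process: mean reaction time is ``mu`` times the log-odds threshold
``log(beta / (1 - beta))``. Bayesian Adaptive Thresholding (BAT) switches
between a low threshold ``beta_low`` (used after accumulation was inferred
correct) and a high threshold ``beta_high`` (used after it was inferred
faulty), so that inferred accumulation failures slow the next response.

All functions here are pure and accept scalars or numpy arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelParams",
    "SubjectParams",
    "p_correct_outcome",
    "posterior_faulty_accumulation",
    "me_focus",
    "threshold_log_odds",
    "expected_rt_given_state",
    "predictive_rt_after_outcome",
    "pi_from_correct_rate",
]


@dataclass(frozen=True)
class ModelParams:
    """Generative parameters for one session.

    Parameters
    ----------
    pi : float
        Memory integrity: probability the rule is correctly remembered,
        in [0, 1].
    beta_low : float
        Accumulation success probability at the low threshold (used when
        accumulation was inferred correct on the previous trial), in
        (0.5, 1).
    beta_high : float
        Accumulation success probability at the high threshold (used after
        inferred faulty accumulation), in (0.5, 1). That
        ``beta_high > beta_low`` is an empirical finding, not a constraint.
    mu : float
        Evidence-accumulation slope, ms per log-odds unit; > 0.
    sigma_rt : float
        Standard deviation of the Gaussian RT emission, ms; > 0.
    """

    pi: float
    beta_low: float
    beta_high: float
    mu: float
    sigma_rt: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError(f"pi must be in [0, 1], got {self.pi}")
        for name in ("beta_low", "beta_high"):
            b = getattr(self, name)
            if not 0.5 < b < 1.0:
                raise ValueError(f"{name} must be in (0.5, 1), got {b}")
        if self.mu <= 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if self.sigma_rt <= 0:
            raise ValueError(f"sigma_rt must be positive, got {self.sigma_rt}")

    def beta(self, prev_accumulation_ok: int) -> float:
        """Threshold level given the inferred previous accumulation state."""
        return self.beta_low if prev_accumulation_ok else self.beta_high

    def with_pi(self, pi: float) -> "ModelParams":
        return ModelParams(pi, self.beta_low, self.beta_high, self.mu, self.sigma_rt)


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject parameters: memory integrity per fitted session, shared rest.

    ``pi_session_first`` and ``pi_session_last`` are the memory integrities
    of the first and last fitted sessions; the threshold levels, slope and
    RT noise are shared across sessions.
    """

    pi_session_first: float
    pi_session_last: float
    beta_low: float
    beta_high: float
    mu: float
    sigma_rt: float

    def __post_init__(self) -> None:
        for name in ("pi_session_first", "pi_session_last"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        # delegate the shared-field checks
        ModelParams(0.5, self.beta_low, self.beta_high, self.mu, self.sigma_rt)

    def session_params(self, which: str) -> ModelParams:
        """ModelParams for ``which`` in {'first', 'last'}."""
        pi = {"first": self.pi_session_first, "last": self.pi_session_last}[which]
        return ModelParams(pi, self.beta_low, self.beta_high, self.mu, self.sigma_rt)


def _check_prob(value, name: str) -> None:
    if np.any(np.asarray(value) < 0) or np.any(np.asarray(value) > 1):
        raise ValueError(f"{name} must be in [0, 1], got {value}")


def p_correct_outcome(pi, beta):
    """Probability of a correct outcome: ``beta*pi + (1-beta)*(1-pi)``.

    A correct outcome arises when memory and accumulation both succeed, or
    both fail (the "fluke" route).
    """
    _check_prob(pi, "pi")
    _check_prob(beta, "beta")
    return beta * pi + (1.0 - beta) * (1.0 - pi)


def posterior_faulty_accumulation(pi, beta, outcome):
    """Posterior probability that accumulation was faulty, ``p(c=0 | b)``.

    By Bayes rule on the four (memory, accumulation) combinations:

    - after an error (``outcome=0``):   (1-b)p / [(1-b)p + b(1-p)]
    - after a correct (``outcome=1``):  (1-b)(1-p) / [(1-b)(1-p) + bp]

    with p = ``pi``, b = ``beta``. This is the quantity the BAT scheme
    thresholds on: high values trigger the high threshold next trial.
    """
    _check_prob(pi, "pi")
    _check_prob(beta, "beta")
    pi = np.asarray(pi, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if outcome == 0:
        num = (1.0 - beta) * pi
        den = (1.0 - beta) * pi + beta * (1.0 - pi)
    elif outcome == 1:
        num = (1.0 - beta) * (1.0 - pi)
        den = (1.0 - beta) * (1.0 - pi) + beta * pi
    else:
        raise ValueError(f"outcome must be 0 or 1, got {outcome}")
    if np.any(den == 0.0):
        raise ZeroDivisionError(
            "posterior over accumulation undefined: the conditioning outcome "
            f"has zero probability (pi={pi}, beta={beta}, outcome={outcome})"
        )
    return num / den


def me_focus(pi, beta, outcome):
    """Probability the memory process matches the outcome, ``p(m=b | b)``.

    Quantifies self-attribution ("me-focus"): after an error it is the
    posterior that memory failed; after a correct, that memory succeeded.
    Complementary (given the outcome) to the posterior over the opposite
    memory state.
    """
    _check_prob(pi, "pi")
    _check_prob(beta, "beta")
    pi = np.asarray(pi, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if outcome == 0:
        num = beta * (1.0 - pi)
        den = (1.0 - beta) * pi + beta * (1.0 - pi)
    elif outcome == 1:
        num = beta * pi
        den = (1.0 - beta) * (1.0 - pi) + beta * pi
    else:
        raise ValueError(f"outcome must be 0 or 1, got {outcome}")
    if np.any(den == 0.0):
        raise ZeroDivisionError(
            "me-focus undefined: the conditioning outcome has zero "
            f"probability (pi={pi}, beta={beta}, outcome={outcome})"
        )
    return num / den


def threshold_log_odds(beta):
    """Log-odds decision threshold ``log(beta / (1 - beta))``.

    Natural logarithm; any other base would simply rescale the slope ``mu``.
    """
    beta = np.asarray(beta, dtype=float)
    if np.any(beta <= 0.0) or np.any(beta >= 1.0):
        raise ValueError(f"beta must be strictly inside (0, 1), got {beta}")
    out = np.log(beta / (1.0 - beta))
    return float(out) if out.ndim == 0 else out


def expected_rt_given_state(mu, beta):
    """Mean RT when responding at threshold level ``beta``: ``mu * log-odds``."""
    if np.any(np.asarray(mu) <= 0):
        raise ValueError(f"mu must be positive, got {mu}")
    return mu * threshold_log_odds(beta)


def predictive_rt_after_outcome(params: ModelParams, prev_outcome: int):
    """Expected RT on trial t given the previous outcome (ms).

    Marginalizes the unknown accumulation state of the previous trial,
    assuming accumulation was correct two trials back: with mixture weight
    ``w = p(c_{t-1}=0 | b_{t-1})`` evaluated at the low threshold,

        E[y_t] = mu * [ (1-w) * theta(beta_low) + w * theta(beta_high) ].

    After an error, w is large and RT is pushed toward the slow
    high-threshold mean (post-error slowing); after a correct, w shrinks
    with ``pi``, so better memory predicts faster post-correct responses.
    """
    w = posterior_faulty_accumulation(params.pi, params.beta_low, prev_outcome)
    theta_low = threshold_log_odds(params.beta_low)
    theta_high = threshold_log_odds(params.beta_high)
    return params.mu * ((1.0 - w) * theta_low + w * theta_high)


def pi_from_correct_rate(beta, r):
    """Memory integrity implied by a correct rate: ``(r - 1 + beta)/(2 beta - 1)``.

    Inverts the outcome probability at threshold ``beta``, clamped to
    [0, 1] (the upper clamp keeps pi a probability when r exceeds beta; the
    lower clamp guards rates below 1 - beta, which the model cannot produce
    with pi >= 0 and is warned about).
    """
    _check_prob(r, "r")
    beta = np.asarray(beta, dtype=float)
    if np.any(beta == 0.5):
        raise ZeroDivisionError("pi_from_correct_rate undefined at beta = 0.5")
    raw = (np.asarray(r, dtype=float) - 1.0 + beta) / (2.0 * beta - 1.0)
    if np.any(raw < 0.0):
        warnings.warn(
            "correct rate below 1 - beta implies negative memory integrity; "
            "clamping to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    out = np.clip(raw, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out
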