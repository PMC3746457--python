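"""Sequence likelihoods under the Bayesian Adaptive Thresholding model.

A session is a sequence of bivalent trials t = 1..T with binary outcomes
``b_t`` and reaction times ``y_t``. The latent accumulation states ``c_t``
form a chain: the threshold in force on trial t is ``beta[c_{t-1}]``
(boundary state ``c_0 = 1``), the outcome probability follows the
two-process outcome rule at that threshold, the next state is drawn from
the Bayes-rule attribution posterior, and the RT is Gaussian around
``mu * log-odds(beta[c_{t-1}])``.

Marginalizing the latent chain exactly costs 2^T path enumerations; a
two-state forward recursion gives the identical value in O(T) and serves
as the exact reference at any length. The first-order approximation
conditions each trial on "accumulation was correct two trials back", which
decouples the chain into per-trial two-term mixtures; it is exact for
T <= 2 and empirically near-exact at the fitted parameter values.

All likelihoods are returned as natural-log values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .model_core import (
    ModelParams,
    posterior_faulty_accumulation,
    threshold_log_odds,
)

__all__ = [
    "TrialSequence",
    "LatentSequence",
    "MAX_ENUMERATION_LENGTH",
    "path_joint_log_likelihood",
    "exact_log_likelihood",
    "forward_log_likelihood",
    "approx_log_likelihood",
    "posterior_c_sequence",
]

#: largest T for which full 2^T latent-path enumeration is permitted
MAX_ENUMERATION_LENGTH = 16


@dataclass(frozen=True)
class TrialSequence:
    """Ordered outcomes b_1..b_T with optional reaction times y_1..y_T (ms).

    ``rts`` may be None (outcomes-only sequence) or an array aligned with
    ``outcomes`` in which NaN marks a missing RT; missing RTs simply
    contribute no RT factor to any likelihood.
    """

    outcomes: np.ndarray
    rts: np.ndarray | None = None

    def __post_init__(self) -> None:
        outcomes = np.asarray(self.outcomes, dtype=int)
        if outcomes.ndim != 1 or outcomes.size == 0:
            raise ValueError("outcomes must be a non-empty 1-d vector")
        if not np.isin(outcomes, (0, 1)).all():
            raise ValueError("outcomes must be binary")
        object.__setattr__(self, "outcomes", outcomes)
        if self.rts is not None:
            rts = np.asarray(self.rts, dtype=float)
            if rts.shape != outcomes.shape:
                raise ValueError("rts must align with outcomes")
            if np.any(rts[~np.isnan(rts)] <= 0):
                raise ValueError("reaction times must be positive where present")
            object.__setattr__(self, "rts", rts)

    def __len__(self) -> int:
        return self.outcomes.size


@dataclass(frozen=True)
class LatentSequence:
    """Ordered accumulation states c_1..c_T (1 = accumulation correct).

    The boundary state c_0 = 1 is implicit and fixed.
    """

    states: np.ndarray

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=int)
        if states.ndim != 1 or states.size == 0:
            raise ValueError("states must be a non-empty 1-d vector")
        if not np.isin(states, (0, 1)).all():
            raise ValueError("states must be binary")
        object.__setattr__(self, "states", states)

    def __len__(self) -> int:
        return self.states.size


def _trial_log_factors(seq: TrialSequence, params: ModelParams, rt_policy: str):
    """Per-trial log factors indexed by the previous latent state.

    Returns (log_pb, log_py, log_w) where, for prev state k in {0, 1} and
    trial t (0-based):

    - ``log_pb[k, t]`` = log p(b_t | c_{t-1}=k)
    - ``log_py[k, t]`` = log p(y_t | c_{t-1}=k)   (0 where no RT factor)
    - ``log_w[k, t]``  = log p(c_t = 0 | c_{t-1}=k, b_t)
    """
    if rt_policy not in ("all", "correct_only"):
        raise ValueError(f"rt_policy must be 'all' or 'correct_only', got {rt_policy!r}")
    b = seq.outcomes
    T = b.size
    betas = np.array([params.beta_high, params.beta_low])  # index by prev state
    pi = params.pi

    p_b1 = betas[:, None] * pi + (1.0 - betas[:, None]) * (1.0 - pi)  # (2, 1)
    with np.errstate(divide="ignore"):
        log_pb = np.where(b[None, :] == 1, np.log(p_b1), np.log(1.0 - p_b1))

        # attribution posterior p(c_t=0 | c_{t-1}, b_t), Bayes rule at beta[c_{t-1}]
        log_w = np.empty((2, T))
        for k, beta in enumerate(betas):
            w_err = posterior_faulty_accumulation(pi, beta, 0)
            w_cor = posterior_faulty_accumulation(pi, beta, 1)
            log_w[k] = np.where(b == 0, np.log(w_err), np.log(w_cor))

    log_py = np.zeros((2, T))
    if seq.rts is not None:
        mu_rt = params.mu * threshold_log_odds(betas)  # (2,)
        use = ~np.isnan(seq.rts)
        if rt_policy == "correct_only":
            use &= b == 1
        if use.any():
            z = (seq.rts[None, use] - mu_rt[:, None]) / params.sigma_rt
            log_py[:, use] = -0.5 * z * z - np.log(
                params.sigma_rt * np.sqrt(2.0 * np.pi)
            )
    return log_pb, log_py, log_w


def path_joint_log_likelihood(
    seq: TrialSequence,
    latent: LatentSequence,
    params: ModelParams,
    rt_policy: str = "all",
) -> float:
    """Joint log density of outcomes, RTs and one latent path, log p(b, y, c).

    The product of outcome factors p(b_t | c_{t-1}), latent transition
    factors p(c_t | c_{t-1}, b_t) and Gaussian RT factors p(y_t | c_{t-1}),
    with the boundary state c_0 = 1. ``rt_policy='correct_only'`` drops RT
    factors on error trials (mirroring analyses that exclude error RTs).
    """
    if len(latent) != len(seq):
        raise ValueError("latent sequence length must match the trial sequence")
    log_pb, log_py, log_w = _trial_log_factors(seq, params, rt_policy)
    c = latent.states
    prev = np.concatenate(([1], c[:-1]))
    t_idx = np.arange(len(seq))
    with np.errstate(divide="ignore"):
        log_trans = np.where(
            c == 0, log_w[prev, t_idx], np.log1p(-np.exp(log_w[prev, t_idx]))
        )
    return float(
        np.sum(log_pb[prev, t_idx]) + np.sum(log_py[prev, t_idx]) + np.sum(log_trans)
    )


def exact_log_likelihood(
    seq: TrialSequence, params: ModelParams, rt_policy: str = "all"
) -> float:
    """Marginal log likelihood by full enumeration of the 2^T latent paths.

    Only feasible for short sequences (T <= 16); longer sequences should use
    :func:`forward_log_likelihood`, which computes the same marginal in O(T).
    """
    T = len(seq)
    if T > MAX_ENUMERATION_LENGTH:
        raise ValueError(
            f"exact enumeration of 2^{T} latent paths refused (T > "
            f"{MAX_ENUMERATION_LENGTH}); use forward_log_likelihood"
        )
    log_pb, log_py, log_w = _trial_log_factors(seq, params, rt_policy)
    # all 2^T latent paths as a (2^T, T) bit matrix
    codes = np.arange(2**T, dtype=np.uint32)
    paths = (codes[:, None] >> np.arange(T, dtype=np.uint32)[None, :]) & 1
    prev = np.concatenate([np.ones((2**T, 1), dtype=int), paths[:, :-1]], axis=1)
    t_idx = np.arange(T)
    lw = log_w[prev, t_idx]
    with np.errstate(divide="ignore"):
        log_trans = np.where(paths == 0, lw, np.log1p(-np.exp(lw)))
    totals = (log_pb[prev, t_idx] + log_py[prev, t_idx] + log_trans).sum(axis=1)
    return float(logsumexp(totals))


def forward_log_likelihood(
    seq: TrialSequence, params: ModelParams, rt_policy: str = "all"
) -> float:
    """Marginal log likelihood via the two-state forward recursion.

    Propagates alpha_t(c) = log p(b_1..b_t, y_1..y_t, c_t = c); identical to
    :func:`exact_log_likelihood` up to floating-point error, at linear cost,
    so it serves as the exact reference at any sequence length.
    """
    log_pb, log_py, log_w = _trial_log_factors(seq, params, rt_policy)
    T = len(seq)
    with np.errstate(divide="ignore"):
        log_trans = np.stack([log_w, np.log1p(-np.exp(log_w))])  # (c_t, c_prev, t)
    alpha = np.array([-np.inf, 0.0])  # c_0 = 1
    for t in range(T):
        emit = alpha + log_pb[:, t] + log_py[:, t]
        alpha = np.array(
            [logsumexp(emit + log_trans[0, :, t]), logsumexp(emit + log_trans[1, :, t])]
        )
    return float(logsumexp(alpha))


def approx_log_likelihood(
    seq: TrialSequence, params: ModelParams, rt_policy: str = "all"
) -> float:
    """First-order approximate marginal log likelihood.

    Approximates the (t-1)th-order conditional of each trial by assuming
    accumulation was correct two trials back: the trial-t factor becomes a
    two-term mixture over c_{t-1} weighted by the attribution posterior
    p(c_{t-1} | c_{t-2}=1, b_{t-1}) at the low threshold, with the outcome
    and RT factors of trial t coupled through the shared c_{t-1}. Exact for
    T <= 2; the assumption is accurate whenever inferred accumulation
    failures are rare.
    """
    log_pb, log_py, log_w = _trial_log_factors(seq, params, rt_policy)
    T = len(seq)
    total = log_pb[1, 0] + log_py[1, 0]  # trial 1 conditions on c_0 = 1
    if T > 1:
        # mixture weight: attribution of trial t-1 assuming c_{t-2} = 1
        log_w_prev = log_w[1, :-1]
        with np.errstate(divide="ignore"):
            log_one_minus_w = np.log1p(-np.exp(log_w_prev))
        lo = log_pb[1, 1:] + log_py[1, 1:] + log_one_minus_w  # c_{t-1} = 1
        hi = log_pb[0, 1:] + log_py[0, 1:] + log_w_prev  # c_{t-1} = 0
        total += np.sum(np.logaddexp(lo, hi))
    return float(total)


def posterior_c_sequence(
    seq: TrialSequence,
    latent_candidate: LatentSequence,
    params: ModelParams,
    rt_policy: str = "all",
) -> float:
    """Posterior probability of one whole latent path, p(c | b, y).

    The ratio of the path's joint density to the enumerated marginal;
    normalized over all 2^T candidates by construction (T <= 16).
    """
    log_joint = path_joint_log_likelihood(seq, latent_candidate, params, rt_policy)
    log_marginal = exact_log_likelihood(seq, params, rt_policy)
    if not np.isfinite(log_marginal):
        raise ZeroDivisionError("marginal likelihood is zero; posterior undefined")
    return float(np.exp(log_joint - log_marginal))
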