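"""Metropolis-Hastings estimation of the model parameters.

Two fits are provided, mirroring the study's two-stage strategy:

1. **Group fit** — regress mean post-correct RT onto correct rate across
   the group. Each observed rate r is converted to a memory integrity
   ``pi(beta_low, r)`` by inverting the outcome rule, the model's predictive
   post-correct RT follows, and the pseudo log-likelihood is the negative
   sum of squared RT errors. Uniform priors: beta_low, beta_high ~ U(0.5, 1),
   mu ~ U(50, 1000) ms per log-odds.

2. **Subject fit** — the approximate joint likelihood of outcome + RT
   sequences from the first and last sessions of one prime, with a separate
   memory integrity per session (pi_first, pi_last) and shared thresholds
   and slope. Uniform priors informed by the group fit:
   pi ~ U(0, 1), beta_low ~ U(0.9, 0.94), beta_high ~ U(0.999, 1),
   mu ~ U(310, 420).

The sampler is a plain random-walk Metropolis-Hastings chain with hard
rejection outside the uniform prior box; defaults are 20,000 iterations
with the first 10,000 discarded as burn-in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .likelihood import TrialSequence, approx_log_likelihood
from .model_core import (
    SubjectParams,
    posterior_faulty_accumulation,
    threshold_log_odds,
)

__all__ = [
    "PriorSpec",
    "PosteriorSamples",
    "GroupPoint",
    "GROUP_PRIORS",
    "SUBJECT_PRIORS",
    "DEFAULT_N_ITER",
    "DEFAULT_N_BURN",
    "metropolis_hastings",
    "group_log_target",
    "fit_group",
    "subject_log_target",
    "fit_subject",
    "compare_memory_integrity",
]

DEFAULT_N_ITER = 20_000
DEFAULT_N_BURN = 10_000

#: fraction of each prior width used as the random-walk proposal step
DEFAULT_STEP_FRACTION = 0.05

#: proposal steps for the group fit (beta_low, beta_high, mu). The group
#: pseudo-likelihood is a negative sum of squared RT errors in ms^2, which
#: is extremely peaked along a curved (beta_low, mu) ridge; steps far below
#: the prior widths are needed for the chain to accept ridge moves at all.
GROUP_STEP_SCALES = np.array([2.5e-4, 5e-5, 0.5])


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors: parameter name -> (lower, upper)."""

    bounds: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"prior for {name!r} needs lower < upper, got ({lo}, {hi})")

    @property
    def names(self) -> list[str]:
        return list(self.bounds)

    @property
    def lower(self) -> np.ndarray:
        return np.array([lo for lo, _ in self.bounds.values()])

    @property
    def upper(self) -> np.ndarray:
        return np.array([hi for _, hi in self.bounds.values()])

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)

    def contains(self, x: np.ndarray) -> bool:
        x = np.asarray(x)
        return bool(np.all(x >= self.lower) and np.all(x <= self.upper))


GROUP_PRIORS = PriorSpec(
    {"beta_low": (0.5, 1.0), "beta_high": (0.5, 1.0), "mu": (50.0, 1000.0)}
)

SUBJECT_PRIORS = PriorSpec(
    {
        "pi_first": (0.0, 1.0),
        "pi_last": (0.0, 1.0),
        "beta_low": (0.9, 0.94),
        "beta_high": (0.999, 1.0),
        "mu": (310.0, 420.0),
    }
)


@dataclass(frozen=True)
class GroupPoint:
    """One group observation: a correct rate and its mean post-correct RT."""

    correct_rate: float
    mean_rt_after_correct: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.correct_rate <= 1.0:
            raise ValueError(f"correct_rate must be in [0, 1], got {self.correct_rate}")
        if self.mean_rt_after_correct <= 0:
            raise ValueError("mean_rt_after_correct must be positive")


@dataclass
class PosteriorSamples:
    """Retained draws of one Metropolis-Hastings run, with bookkeeping."""

    names: list[str]
    draws: np.ndarray  # (n_kept, n_params)
    log_scores: np.ndarray  # log target at each retained draw
    n_total: int
    n_burn: int
    acceptance_rate: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.draws.shape != (self.n_total - self.n_burn, len(self.names)):
            raise ValueError("draws shape inconsistent with iteration bookkeeping")

    @property
    def n_kept(self) -> int:
        return self.n_total - self.n_burn

    def mean(self) -> dict[str, float]:
        """Posterior mean of each parameter (the reported point estimate)."""
        return dict(zip(self.names, self.draws.mean(axis=0)))

    def credible_interval(self, level: float = 0.9) -> dict[str, tuple[float, float]]:
        """Central posterior interval per parameter."""
        tail = 100 * (1.0 - level) / 2.0
        lo, hi = np.percentile(self.draws, [tail, 100 - tail], axis=0)
        return {n: (float(a), float(b)) for n, a, b in zip(self.names, lo, hi)}

    def best_draw(self) -> dict[str, float]:
        """The retained draw with the highest target score."""
        return dict(zip(self.names, self.draws[np.argmax(self.log_scores)]))

    def prob_greater(self, a: str, b: str) -> float:
        """Posterior probability that parameter ``a`` exceeds parameter ``b``."""
        ia, ib = self.names.index(a), self.names.index(b)
        return float(np.mean(self.draws[:, ia] > self.draws[:, ib]))

    def correlation(self, a: str, b: str) -> float:
        """Posterior sample correlation between two parameters."""
        ia, ib = self.names.index(a), self.names.index(b)
        return float(np.corrcoef(self.draws[:, ia], self.draws[:, ib])[0, 1])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=self.names)
        df["log_score"] = self.log_scores
        return df

    def metadata(self) -> dict:
        return {
            "parameters": self.names,
            "n_total": int(self.n_total),
            "n_burn": int(self.n_burn),
            "n_kept": int(self.n_kept),
            "acceptance_rate": float(self.acceptance_rate),
            "seed": None if self.seed is None else int(self.seed),
        }


def metropolis_hastings(
    log_target: Callable[[np.ndarray], float],
    priors: PriorSpec,
    n_iter: int = DEFAULT_N_ITER,
    n_burn: int = DEFAULT_N_BURN,
    step_scales: np.ndarray | None = None,
    seed: int | None = None,
    init: np.ndarray | None = None,
) -> PosteriorSamples:
    """Random-walk Metropolis-Hastings restricted to the uniform prior box.

    Proposals are joint Gaussian perturbations with per-parameter standard
    deviations ``step_scales`` (default: a small fraction of each prior
    width); proposals outside the prior support have zero prior density and
    are rejected outright. The chain starts at the prior midpoint unless
    ``init`` is given, and is fully deterministic given ``seed``.
    """
    if not 0 <= n_burn < n_iter:
        raise ValueError("need 0 <= n_burn < n_iter")
    rng = np.random.default_rng(seed)
    steps = (
        DEFAULT_STEP_FRACTION * priors.width
        if step_scales is None
        else np.asarray(step_scales, dtype=float)
    )
    x = priors.midpoint.copy() if init is None else np.asarray(init, dtype=float)
    if not priors.contains(x):
        raise ValueError("initial point outside prior support")
    lt = float(log_target(x))
    if not np.isfinite(lt):
        raise ValueError("log target not finite at the initial point")

    n_params = len(priors.names)
    kept = np.empty((n_iter - n_burn, n_params))
    kept_scores = np.empty(n_iter - n_burn)
    n_accept = 0
    for i in range(n_iter):
        prop = x + rng.normal(0.0, steps)
        if priors.contains(prop):
            lt_prop = float(log_target(prop))
            if np.log(rng.uniform()) < lt_prop - lt:
                x, lt = prop, lt_prop
                n_accept += 1
        if i >= n_burn:
            kept[i - n_burn] = x
            kept_scores[i - n_burn] = lt
    return PosteriorSamples(
        names=priors.names,
        draws=kept,
        log_scores=kept_scores,
        n_total=n_iter,
        n_burn=n_burn,
        acceptance_rate=n_accept / n_iter,
        seed=seed,
    )


def _as_point_arrays(points) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(points, pd.DataFrame):
        return (
            points["correct_rate"].to_numpy(float),
            points["mean_rt_after_correct"].to_numpy(float),
        )
    rates = np.array([p.correct_rate for p in points], dtype=float)
    rts = np.array([p.mean_rt_after_correct for p in points], dtype=float)
    return rates, rts


def _group_predicted_rt(
    beta_low: float, beta_high: float, mu: float, rates: np.ndarray
) -> np.ndarray:
    """Model post-correct RT at each correct rate (vectorized, clamped pi)."""
    if beta_low == 0.5:
        raise ZeroDivisionError("beta_low = 0.5 leaves memory integrity unidentified")
    pi = np.clip((rates - 1.0 + beta_low) / (2.0 * beta_low - 1.0), 0.0, 1.0)
    w = posterior_faulty_accumulation(pi, beta_low, 1)
    theta_low = threshold_log_odds(beta_low)
    theta_high = threshold_log_odds(beta_high)
    return mu * ((1.0 - w) * theta_low + w * theta_high)


def _group_ls_init(rates: np.ndarray, rts: np.ndarray, priors: PriorSpec) -> np.ndarray:
    """Approximate mode of the group target by profile least squares.

    For fixed beta_low the predicted RT is linear in (mu*theta_low,
    mu*theta_high), so the inner minimization is a closed-form least-squares
    solve; scanning beta_low over its prior range and keeping the feasible
    point with the smallest squared error gives a deterministic
    near-mode starting point for the chain.
    """
    lo, hi = priors.lower, priors.upper
    best_score, best_x = -np.inf, None
    for beta_low in np.linspace(lo[0] + 0.01, hi[0] - 0.01, 97):
        pi = np.clip((rates - 1.0 + beta_low) / (2.0 * beta_low - 1.0), 0.0, 1.0)
        w = posterior_faulty_accumulation(pi, beta_low, 1)
        design = np.column_stack([1.0 - w, w])
        coef, *_ = np.linalg.lstsq(design, rts, rcond=None)
        mu = np.clip(coef[0] / threshold_log_odds(beta_low), lo[2] + 1e-9, hi[2] - 1e-9)
        theta_high = coef[1] / mu
        beta_high = 1.0 / (1.0 + np.exp(-theta_high)) if theta_high > 0 else lo[1] + 1e-3
        beta_high = np.clip(beta_high, lo[1] + 1e-9, min(hi[1] - 1e-9, 1.0 - 1e-9))
        x = np.array([beta_low, beta_high, mu])
        score = -np.sum((_group_predicted_rt(*x, rates) - rts) ** 2)
        if score > best_score:
            best_score, best_x = score, x
    return best_x


def group_log_target(beta_low: float, beta_high: float, mu: float, points) -> float:
    """Group pseudo log-likelihood: negative squared RT error.

    Each observed correct rate is inverted to a memory integrity at the low
    threshold (accumulation assumed correct on the previous trial), the
    model's predictive post-correct RT is computed, and the score is minus
    the sum of squared deviations from the observed mean RTs.
    """
    rates, rts = _as_point_arrays(points)
    predicted = _group_predicted_rt(beta_low, beta_high, mu, rates)
    return float(-np.sum((predicted - rts) ** 2))


def fit_group(
    points,
    priors: PriorSpec = GROUP_PRIORS,
    n_iter: int = DEFAULT_N_ITER,
    n_burn: int = DEFAULT_N_BURN,
    step_scales: np.ndarray | None = None,
    seed: int | None = None,
    init: np.ndarray | None = None,
) -> PosteriorSamples:
    """Posterior over (beta_low, beta_high, mu) from group rate-RT points.

    The chain is started at an approximate mode found by a deterministic
    profile least-squares scan (the pseudo-likelihood is far too peaked,
    in squared-ms units, for a random walk from the prior midpoint to reach
    the ridge within the default iteration budget), and uses the small
    :data:`GROUP_STEP_SCALES` proposal steps for the same reason. Both can
    be overridden.
    """
    rates, rts = _as_point_arrays(points)
    if rates.size < 3:
        raise ValueError("group fit needs at least 3 points")
    df = pd.DataFrame({"correct_rate": rates, "mean_rt_after_correct": rts})
    if init is None:
        init = _group_ls_init(rates, rts, priors)
    if step_scales is None:
        step_scales = GROUP_STEP_SCALES

    def log_target(x: np.ndarray) -> float:
        return group_log_target(x[0], x[1], x[2], df)

    return metropolis_hastings(
        log_target, priors, n_iter, n_burn, step_scales, seed, init
    )


def subject_log_target(
    params: SubjectParams,
    session_first: TrialSequence,
    session_last: TrialSequence,
    rt_policy: str = "all",
) -> float:
    """Joint approximate log likelihood of a subject's two fitted sessions.

    Each session uses its own memory integrity with the shared thresholds,
    slope and RT noise; sessions are conditionally independent, so the
    scores add.
    """
    return approx_log_likelihood(
        session_first, params.session_params("first"), rt_policy
    ) + approx_log_likelihood(session_last, params.session_params("last"), rt_policy)


def fit_subject(
    session_first: TrialSequence,
    session_last: TrialSequence,
    priors: PriorSpec = SUBJECT_PRIORS,
    sigma_rt: float = 100.0,
    rt_policy: str = "all",
    n_iter: int = DEFAULT_N_ITER,
    n_burn: int = DEFAULT_N_BURN,
    step_scales: np.ndarray | None = None,
    seed: int | None = None,
    init: np.ndarray | None = None,
) -> PosteriorSamples:
    """Posterior over (pi_first, pi_last, beta_low, beta_high, mu) for one
    subject and prime.

    ``sigma_rt`` is the fixed RT emission standard deviation (ms); it is not
    sampled.
    """
    if len(session_first) == 0 or len(session_last) == 0:
        raise ValueError("both sessions must be non-empty")

    def log_target(x: np.ndarray) -> float:
        params = SubjectParams(
            pi_session_first=x[0],
            pi_session_last=x[1],
            beta_low=x[2],
            beta_high=x[3],
            mu=x[4],
            sigma_rt=sigma_rt,
        )
        return subject_log_target(params, session_first, session_last, rt_policy)

    return metropolis_hastings(
        log_target, priors, n_iter, n_burn, step_scales, seed, init
    )


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    mean_first: float
    mean_last: float


def compare_memory_integrity(
    pi_first: Sequence[float], pi_last: Sequence[float], tail: str = "two"
) -> PairedTestResult:
    """Paired t-test of memory integrity across sessions.

    Takes the per-subject posterior means of pi for the first and last
    sessions and tests whether their difference is zero. ``tail='one'``
    halves the p-value in the direction of the observed mean difference.
    """
    a = np.asarray(pi_first, dtype=float)
    b = np.asarray(pi_last, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two aligned vectors with at least 2 pairs")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return PairedTestResult(0.0, a.size - 1, 1.0, float(a.mean()), float(b.mean()))
        raise ValueError("paired differences have zero variance; t undefined")
    res = stats.ttest_rel(a, b)
    p = float(res.pvalue)
    if tail == "one":
        p = p / 2.0
    elif tail != "two":
        raise ValueError(f"tail must be 'one' or 'two', got {tail!r}")
    return PairedTestResult(
        float(res.statistic), a.size - 1, p, float(a.mean()), float(b.mean())
    )
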