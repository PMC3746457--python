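"""Generative simulator of the self-concept priming study.

Emulates the study design: 15 subjects, each primed "clever" and "stupid",
three sessions per prime, 50 rule trials per session of which 70% are
bivalent (rule-dependent) and 30% univalent (rule-independent). Bivalent
trials follow the two-process Bayesian Adaptive Thresholding generative
model; univalent trials are decoration — emitted with fixed high accuracy
and baseline RT, flagged by ``trial_type`` and excluded from modelling.

The default memory-integrity trajectories are the fitted group means:
stupid prime declining 0.88 -> 0.80 from first to last session (the
confirmation-bias signature), clever prime mildly rising 0.85 -> 0.88; the
middle session interpolates linearly. Thresholds and slope default to the
high-probability group estimates beta_low = 0.92, beta_high = 0.9998,
mu = 360 ms per log-odds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .likelihood import LatentSequence
from .model_core import (
    ModelParams,
    p_correct_outcome,
    posterior_faulty_accumulation,
    threshold_log_odds,
)

__all__ = [
    "StudyDesign",
    "TRIAL_TABLE_COLUMNS",
    "simulate_session",
    "simulate_priming_study",
    "simulate_group_curve",
]

#: canonical trial-table schema (delimited text, comma separated)
TRIAL_TABLE_COLUMNS = [
    "subject_id",
    "prime",
    "session",
    "trial_index",
    "trial_type",
    "outcome",
    "rt_ms",
    "latent_c",
]


@dataclass(frozen=True)
class StudyDesign:
    """Full specification of one synthetic priming study.

    Together with ``seed`` this determines the dataset exactly. The
    per-prime memory-integrity trajectories give one pi per session;
    ``pi_jitter_sd`` adds one Gaussian offset per subject x prime
    (clamped into [0, 1]) to mimic between-subject variability.
    """

    n_subjects: int = 15
    sessions_per_prime: int = 3
    trials_per_session: int = 50
    bivalent_fraction: float = 0.7
    pi_trajectories: dict = field(
        default_factory=lambda: {
            "stupid": (0.88, 0.84, 0.80),
            "clever": (0.85, 0.865, 0.88),
        }
    )
    beta_low: float = 0.92
    beta_high: float = 0.9998
    mu: float = 360.0
    sigma_rt: float = 100.0
    pi_jitter_sd: float = 0.03
    univalent_accuracy: float = 0.96
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.bivalent_fraction <= 1.0:
            raise ValueError("bivalent_fraction must be in [0, 1]")
        if min(self.n_subjects, self.sessions_per_prime, self.trials_per_session) < 1:
            raise ValueError("counts must be positive")
        for prime, traj in self.pi_trajectories.items():
            if len(traj) != self.sessions_per_prime:
                raise ValueError(
                    f"pi trajectory for {prime!r} must give one value per session"
                )
            if any(not 0.0 <= p <= 1.0 for p in traj):
                raise ValueError(f"pi trajectory for {prime!r} outside [0, 1]")
        # validate the shared model parameters once
        ModelParams(0.5, self.beta_low, self.beta_high, self.mu, self.sigma_rt)

    @property
    def n_bivalent(self) -> int:
        return round(self.bivalent_fraction * self.trials_per_session)

    def session_params(self, prime: str, session: int, pi_offset: float = 0.0) -> ModelParams:
        """Model parameters for one prime x session (1-based), with jitter."""
        pi = float(np.clip(self.pi_trajectories[prime][session - 1] + pi_offset, 0.0, 1.0))
        return ModelParams(pi, self.beta_low, self.beta_high, self.mu, self.sigma_rt)


def _truncated_normal_rt(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Gaussian RT truncated at zero by redraw (negligible mass at defaults)."""
    for _ in range(1000):
        y = rng.normal(mean, sd)
        if y > 0:
            return float(y)
    raise RuntimeError("RT truncation failed; mean/sd imply mostly negative draws")


def simulate_session(
    params: ModelParams, n_trials: int, seed
) -> tuple[pd.DataFrame, LatentSequence]:
    """Simulate one session of bivalent trials under the BAT model.

    Trial t uses the threshold selected by the inferred accumulation state
    of trial t-1 (boundary state: correct): the outcome is Bernoulli with
    the two-process outcome probability, the next latent state is drawn
    from the Bayes-rule attribution posterior, and the RT is Gaussian
    around mu * log-odds(threshold), truncated at zero.

    ``seed`` may be an int or a ``numpy.random.Generator``. Returns the
    trial frame (columns trial_index, outcome, rt_ms, latent_c) and the
    latent accumulation sequence c_1..c_T.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = {1: threshold_log_odds(params.beta_low), 0: threshold_log_odds(params.beta_high)}
    c_prev = 1
    outcomes = np.empty(n_trials, dtype=int)
    rts = np.empty(n_trials)
    states = np.empty(n_trials, dtype=int)
    for t in range(n_trials):
        beta = params.beta(c_prev)
        b = int(rng.uniform() < p_correct_outcome(params.pi, beta))
        w = posterior_faulty_accumulation(params.pi, beta, b)
        c = int(rng.uniform() >= w)  # 1 = accumulation inferred correct
        y = _truncated_normal_rt(rng, params.mu * theta[c_prev], params.sigma_rt)
        outcomes[t], rts[t], states[t] = b, y, c
        c_prev = c
    frame = pd.DataFrame(
        {
            "trial_index": np.arange(1, n_trials + 1),
            "outcome": outcomes,
            "rt_ms": rts,
            "latent_c": states,
        }
    )
    return frame, LatentSequence(states)


def simulate_priming_study(design: StudyDesign) -> pd.DataFrame:
    """Simulate the full study: a canonical trial table for all subjects.

    Bivalent trials are generated by :func:`simulate_session` (the BAT chain
    runs over the bivalent subsequence of each session); univalent trials
    are interleaved at randomized positions with fixed accuracy and
    baseline (low-threshold) RT, and carry no latent state. Deterministic
    given ``design.seed``.
    """
    root = np.random.SeedSequence(design.seed)
    primes = sorted(design.pi_trajectories)
    spawn = iter(root.spawn(design.n_subjects * len(primes) * (design.sessions_per_prime + 1)))
    n_biv = design.n_bivalent
    n_uni = design.trials_per_session - n_biv
    baseline_rt = design.mu * threshold_log_odds(design.beta_low)

    rows = []
    for subject in range(1, design.n_subjects + 1):
        for prime in primes:
            jitter_rng = np.random.default_rng(next(spawn))
            pi_offset = jitter_rng.normal(0.0, design.pi_jitter_sd)
            for session in range(1, design.sessions_per_prime + 1):
                rng = np.random.default_rng(next(spawn))
                params = design.session_params(prime, session, pi_offset)
                biv, _ = simulate_session(params, n_biv, rng)
                positions = np.zeros(design.trials_per_session, dtype=bool)
                positions[rng.choice(design.trials_per_session, n_biv, replace=False)] = True
                it = iter(biv.itertuples())
                for idx in range(1, design.trials_per_session + 1):
                    if positions[idx - 1]:
                        trial = next(it)
                        rows.append(
                            (subject, prime, session, idx, "bivalent",
                             trial.outcome, trial.rt_ms, trial.latent_c)
                        )
                    else:
                        b = int(rng.uniform() < design.univalent_accuracy)
                        y = _truncated_normal_rt(rng, baseline_rt, design.sigma_rt)
                        rows.append((subject, prime, session, idx, "univalent", b, y, np.nan))
    table = pd.DataFrame(rows, columns=TRIAL_TABLE_COLUMNS)
    table["latent_c"] = table["latent_c"].astype("Int64")
    return table


def simulate_group_curve(
    params: ModelParams, r_grid, noise_sd: float, seed
) -> pd.DataFrame:
    """Synthetic group rate-RT points on the model's predictive curve.

    At each correct rate r the implied memory integrity is obtained by
    inverting the outcome rule at the low threshold, the model's predictive
    post-correct RT follows, and Gaussian noise of ``noise_sd`` ms is
    added. Returns a frame with columns correct_rate, mean_rt_after_correct.
    """
    r_grid = np.asarray(r_grid, dtype=float)
    if np.any(r_grid <= 0.5) or np.any(r_grid > 1.0):
        raise ValueError("correct rates must lie in (0.5, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pi = np.clip((r_grid - 1.0 + params.beta_low) / (2.0 * params.beta_low - 1.0), 0.0, 1.0)
    w = posterior_faulty_accumulation(pi, params.beta_low, 1)
    expected = params.mu * (
        (1.0 - w) * threshold_log_odds(params.beta_low)
        + w * threshold_log_odds(params.beta_high)
    )
    rts = expected + rng.normal(0.0, noise_sd, r_grid.size)
    return pd.DataFrame({"correct_rate": r_grid, "mean_rt_after_correct": rts})
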