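"""Trial-level behavioural analyses of the rule task.

Implements the descriptive analyses that motivated the model: classifying
correct trials by the preceding outcome (CC = correct following correct,
EC = correct following error), comparing early versus late epochs of CC/EC
reaction times, session error rates with paired tests, the subject-centred
regression of RT on error rate, and a grid-based prior x likelihood x
posterior demonstration of the confirmation-bias mechanism over memory
integrity.

All analyses operate on the canonical trial table (one row per trial;
see ``batmodel.synthetic.TRIAL_TABLE_COLUMNS``) restricted to bivalent
trials, since univalent trials are insensitive to the rule and excluded
from every analysis. Error-trial RTs never enter any RT summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .likelihood import (
    MAX_ENUMERATION_LENGTH,
    TrialSequence,
    forward_log_likelihood,
)
from .model_core import ModelParams

__all__ = [
    "EpochConfig",
    "GridPosterior",
    "classify_trials",
    "epoch_summary",
    "epoch_contrasts",
    "session_error_rates",
    "rt_rate_regression",
    "confirmation_bias_posterior",
]

#: trial labels: first trial of a session, correct-after-correct,
#: correct-after-error, error
FIRST, CC, EC, E = "FIRST", "CC", "EC", "E"


@dataclass(frozen=True)
class EpochConfig:
    """Early/late epoch lengths: ``n_cc`` CC trials and ``n_ec`` EC trials."""

    n_cc: int = 20
    n_ec: int = 3

    def __post_init__(self) -> None:
        if self.n_cc < 1 or self.n_ec < 1:
            raise ValueError("epoch lengths must be positive integers")
        if self.n_ec > self.n_cc:
            raise ValueError("n_ec must not exceed n_cc")


def classify_trials(outcomes) -> np.ndarray:
    """Label each trial of one session as FIRST, CC, EC or E.

    The first trial has no predecessor (FIRST if correct, E if error);
    thereafter a correct trial is CC after a correct and EC after an error,
    and every error is E. Classification never crosses a session boundary:
    call per session.
    """
    outcomes = np.asarray(outcomes)
    if outcomes.ndim != 1 or outcomes.size == 0:
        raise ValueError("outcomes must be a non-empty 1-d vector")
    if not np.isin(outcomes, (0, 1)).all():
        raise ValueError("outcomes must be binary")
    labels = np.empty(outcomes.size, dtype=object)
    labels[0] = FIRST if outcomes[0] == 1 else E
    prev = outcomes[:-1]
    curr = outcomes[1:]
    labels[1:] = np.select(
        [curr == 0, prev == 1], [E, CC], default=EC
    )
    return labels


def _bivalent(trials: pd.DataFrame) -> pd.DataFrame:
    if "trial_type" in trials.columns:
        return trials[trials["trial_type"] == "bivalent"]
    return trials


def _labelled(trials: pd.DataFrame) -> pd.DataFrame:
    """Bivalent trials with a CC/EC/E/FIRST label column added per session."""
    biv = _bivalent(trials).sort_values(["subject_id", "prime", "session", "trial_index"])
    parts = []
    for _, grp in biv.groupby(["subject_id", "prime", "session"], sort=False):
        grp = grp.copy()
        grp["label"] = classify_trials(grp["outcome"].to_numpy())
        parts.append(grp)
    return pd.concat(parts, ignore_index=True)


def epoch_summary(
    trials: pd.DataFrame, config: EpochConfig = EpochConfig()
) -> pd.DataFrame:
    """Early/late mean RTs per condition for each subject x prime.

    Early = the first ``n`` CC (or EC) trials of the first session; late =
    the last ``n`` of the last session, with ``n`` from ``config``. When a
    session holds fewer labelled trials than requested, all available are
    used and the row is flagged ``truncated``. Returns a tidy frame keyed by
    subject_id, prime, condition (CC/EC) and epoch (early/late) with
    mean_rt, n_trials and truncated columns.
    """
    labelled = _labelled(trials)
    rows = []
    for (subject, prime), grp in labelled.groupby(["subject_id", "prime"]):
        first, last = grp["session"].min(), grp["session"].max()
        for condition, n_req in ((CC, config.n_cc), (EC, config.n_ec)):
            for epoch, session in (("early", first), ("late", last)):
                pool = grp[(grp["session"] == session) & (grp["label"] == condition)]
                rts = pool["rt_ms"].dropna().to_numpy()
                take = rts[:n_req] if epoch == "early" else rts[-n_req:]
                rows.append(
                    {
                        "subject_id": subject,
                        "prime": prime,
                        "condition": condition,
                        "epoch": epoch,
                        "mean_rt": float(np.mean(take)) if take.size else np.nan,
                        "n_trials": int(take.size),
                        "truncated": bool(take.size < n_req),
                    }
                )
    return pd.DataFrame(rows)


def epoch_contrasts(summary: pd.DataFrame, tail: str = "two") -> pd.DataFrame:
    """Group-level early-vs-late paired t-tests per prime x condition.

    Pairs the per-subject early and late mean RTs from
    :func:`epoch_summary`; subjects lacking either epoch are dropped
    pairwise. ``tail='one'`` halves the p-value (direction: late > early).
    """
    rows = []
    for (prime, condition), grp in summary.groupby(["prime", "condition"]):
        wide = grp.pivot(index="subject_id", columns="epoch", values="mean_rt").dropna()
        if len(wide) < 2:
            continue
        res = stats.ttest_rel(wide["late"], wide["early"])
        p = float(res.pvalue)
        if tail == "one":
            p /= 2.0
        elif tail != "two":
            raise ValueError(f"tail must be 'one' or 'two', got {tail!r}")
        rows.append(
            {
                "prime": prime,
                "condition": condition,
                "mean_early": float(wide["early"].mean()),
                "mean_late": float(wide["late"].mean()),
                "t": float(res.statistic),
                "df": len(wide) - 1,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def session_error_rates(trials: pd.DataFrame, tail: str = "two") -> dict:
    """Per-session error percentages with paired session and prime tests.

    Uses bivalent trials only. Returns a dict with:

    - ``rates``: subject x prime x session error rates (%)
    - ``by_session``: group mean error rate (%) per prime x session
    - ``session_tests``: paired t-tests between session pairs within prime
    - ``prime_tests``: paired t-tests between primes within each session
    """
    biv = _bivalent(trials)
    if biv.empty:
        raise ValueError("no bivalent trials to analyse")
    rates = (
        biv.groupby(["subject_id", "prime", "session"])["outcome"]
        .apply(lambda b: 100.0 * (1.0 - b.mean()))
        .rename("error_rate_pct")
        .reset_index()
    )
    if (biv.groupby(["prime", "session"]).size() == 0).any():
        raise ValueError("empty session encountered")
    by_session = (
        rates.groupby(["prime", "session"])["error_rate_pct"].mean().reset_index()
    )

    def _pair_p(a, b):
        res = stats.ttest_rel(a, b)
        p = float(res.pvalue)
        return float(res.statistic), (p / 2.0 if tail == "one" else p)

    session_tests = []
    for prime, grp in rates.groupby("prime"):
        wide = grp.pivot(index="subject_id", columns="session", values="error_rate_pct")
        sessions = list(wide.columns)
        for i, s1 in enumerate(sessions):
            for s2 in sessions[i + 1 :]:
                t, p = _pair_p(wide[s2], wide[s1])
                session_tests.append(
                    {"prime": prime, "session_a": s1, "session_b": s2,
                     "t": t, "df": len(wide) - 1, "p": p}
                )
    prime_tests = []
    wide_all = rates.pivot_table(
        index="subject_id", columns=["prime", "session"], values="error_rate_pct"
    )
    primes = sorted(rates["prime"].unique())
    if len(primes) == 2:
        for session in sorted(rates["session"].unique()):
            a, b = wide_all[(primes[0], session)], wide_all[(primes[1], session)]
            t, p = _pair_p(a, b)
            prime_tests.append(
                {"session": session, "prime_a": primes[0], "prime_b": primes[1],
                 "t": t, "df": len(a) - 1, "p": p}
            )
    return {
        "rates": rates,
        "by_session": by_session,
        "session_tests": pd.DataFrame(session_tests),
        "prime_tests": pd.DataFrame(prime_tests),
    }


@dataclass(frozen=True)
class RegressionResult:
    r: float
    slope: float  # ms per percentage point of error rate
    intercept: float
    p: float
    n_points: int


def rt_rate_regression(
    trials: pd.DataFrame, after: str = "correct", sessions=(1, 3)
) -> RegressionResult:
    """Regress subject-centred RT onto error rate across subject x session
    points.

    ``after='correct'`` uses mean CC-trial RT per subject x session,
    ``after='error'`` mean EC-trial RT. Each subject's mean RT (over the
    included sessions) is subtracted before the least-squares fit, removing
    between-subject RT offsets; the predictor is the session error rate in
    percent. Returns the Pearson r, slope (ms per percentage point),
    intercept and two-tailed p.
    """
    label = {"correct": CC, "error": EC}.get(after)
    if label is None:
        raise ValueError(f"after must be 'correct' or 'error', got {after!r}")
    labelled = _labelled(trials)
    labelled = labelled[labelled["session"].isin(sessions)]
    err = (
        labelled.groupby(["subject_id", "session"])["outcome"]
        .apply(lambda b: 100.0 * (1.0 - b.mean()))
        .rename("error_rate_pct")
    )
    rt = (
        labelled[labelled["label"] == label]
        .groupby(["subject_id", "session"])["rt_ms"]
        .mean()
        .rename("mean_rt")
    )
    points = pd.concat([err, rt], axis=1).dropna().reset_index()
    points["mean_rt"] -= points.groupby("subject_id")["mean_rt"].transform("mean")
    if len(points) < 3:
        raise ValueError("need at least 3 subject x session points")
    if np.isclose(points["error_rate_pct"].std(), 0.0):
        raise ValueError("error rate is constant; regression undefined")
    fit = stats.linregress(points["error_rate_pct"], points["mean_rt"])
    return RegressionResult(
        r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p=float(fit.pvalue),
        n_points=len(points),
    )


@dataclass(frozen=True)
class GridPosterior:
    """Prior, likelihood and posterior over a memory-integrity grid.

    The posterior is prior x likelihood renormalized to unit trapezoidal
    integral over the grid; the likelihood is kept on its natural scale
    (it need not integrate to anything in particular over pi).
    """

    pi_grid: np.ndarray
    prior: np.ndarray
    likelihood: np.ndarray
    posterior: np.ndarray

    @property
    def prior_mode(self) -> float:
        return float(self.pi_grid[np.argmax(self.prior)])

    @property
    def likelihood_argmax(self) -> float:
        return float(self.pi_grid[np.argmax(self.likelihood)])

    @property
    def posterior_mode(self) -> float:
        return float(self.pi_grid[np.argmax(self.posterior)])

    @property
    def posterior_mean(self) -> float:
        return float(np.trapezoid(self.pi_grid * self.posterior, self.pi_grid))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pi": self.pi_grid,
                "prior": self.prior,
                "likelihood": self.likelihood,
                "posterior": self.posterior,
            }
        )


def confirmation_bias_posterior(
    outcomes_prefix,
    beta_low: float,
    beta_high: float,
    prior_shape: tuple[float, float] = (3.0, 6.0),
    pi_grid=None,
) -> GridPosterior:
    """Bayesian updating of memory integrity from a short outcome prefix.

    Computes the exact outcomes-only likelihood p(b | pi) on a grid of pi
    values (thresholds fixed at the supplied beta levels), multiplies by a
    beta-density prior over pi, and renormalizes. A prior placing its mass
    below the likelihood's maximum — the hypothesized effect of "stupid"
    priming — pulls the posterior mode below the maximum-likelihood value:
    believing you will do badly predicts doing badly.
    """
    if pi_grid is None:
        pi_grid = np.linspace(0.005, 0.995, 199)
    pi_grid = np.asarray(pi_grid, dtype=float)
    if pi_grid.size < 3 or np.any(np.diff(pi_grid) <= 0):
        raise ValueError("pi_grid must be increasing with at least 3 points")
    if np.any(pi_grid <= 0.0) or np.any(pi_grid >= 1.0):
        raise ValueError("pi_grid must lie strictly inside (0, 1)")
    seq = TrialSequence(np.asarray(outcomes_prefix, dtype=int))
    if len(seq) > MAX_ENUMERATION_LENGTH:
        raise ValueError(
            f"outcome prefix longer than {MAX_ENUMERATION_LENGTH}; "
            "the demonstration is meant for short, exactly-marginalized prefixes"
        )
    # forward recursion: identical to full enumeration, linear cost
    loglik = np.array(
        [
            forward_log_likelihood(
                seq, ModelParams(pi, beta_low, beta_high, 360.0, 100.0)
            )
            for pi in pi_grid
        ]
    )
    likelihood = np.exp(loglik - loglik.max())
    prior = stats.beta.pdf(pi_grid, *prior_shape)
    posterior = prior * likelihood
    norm = np.trapezoid(posterior, pi_grid)
    if norm <= 0:
        raise ValueError("posterior has zero mass on the grid")
    return GridPosterior(pi_grid, prior, likelihood, posterior / norm)
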