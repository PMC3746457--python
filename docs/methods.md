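# Methods

## Model

One bivalent rule trial involves two independent latent Bernoulli
processes: rule memory succeeds with probability π (memory integrity) and
response accumulation succeeds with probability β_t (accumulation
success). The outcome is correct iff the processes agree, so
p(b_t = 1) = β_t π + (1 − β_t)(1 − π). After each trial the observer
attributes the outcome by Bayes rule over the four process combinations;
the posterior that accumulation was faulty, p(c_t = 0 | b_t), is the
quantity that drives behaviour. The complementary attribution to the
memory ("me") process, p(m_t = b_t | b_t), quantifies me-focus; given the
outcome, the memory posterior and the accumulation posterior sum to one.

**Bayesian Adaptive Thresholding (BAT).** β_t is a two-level decision
threshold: β[1] (low/fast) when accumulation was inferred correct on the
previous trial, β[0] (high/slow) when it was inferred faulty. In the
generative model the inferred state c_t is *sampled* from the attribution
posterior, making the latent states a binary chain with outcome-dependent
transitions and the boundary condition c_0 = 1.

**Reaction times.** Mean RT is proportional to the log-odds threshold:
y_t ~ N(μ·θ_t, σ_y) with θ_t = log(β[c_{t−1}]/(1 − β[c_{t−1}])). Natural
logarithms throughout; any other base would be absorbed by a rescaled μ.
Within-trial accumulation dynamics are out of scope — only the threshold's
effect on the mean RT is modelled.

## Likelihoods

The exact marginal likelihood of a session sums the joint density of
outcomes, RTs and a latent path over all 2^T paths. Three routes are
implemented, all in log space:

- `exact_log_likelihood` — vectorized full enumeration, guarded at T ≤ 16;
- `forward_log_likelihood` — a two-state forward recursion, algebraically
  identical at any T and O(T); it is the exact reference used by tests and
  analyses at realistic lengths;
- `approx_log_likelihood` — the first-order approximation that conditions
  each trial on "accumulation was correct two trials back". The trial-t
  factor becomes a two-component mixture over c_{t−1}, with the outcome
  and RT factors of the trial coupled through the shared c_{t−1} and the
  mixture weight given by the attribution of trial t−1 at the low
  threshold. Exact for T ≤ 2; at the fitted parameter values its relative
  log-likelihood error at T = 10 is far below 1%, and its π-grid argmax on
  simulated sessions sits within ±0.05 of the generative value. The
  coupled (rather than independent) treatment of the outcome and RT
  factors within a trial is a design choice; the two coincide when the
  mixture weight is small, which is the regime the fits occupy.

RT factors on error trials are included by default (`rt_policy="all"`),
matching the unconditional product form of the joint density; a
`correct_only` switch restricts RT factors to correct trials for users who
prefer symmetry with the behavioural analyses, which never use error-trial
RTs. Missing RTs contribute no factor (exact marginalization of a Gaussian
emission). σ_y is a fixed, configurable constant (default 100 ms), not a
fitted parameter: the RT model only constrains μ·θ contrasts, and at
35-trial sessions treating σ_y as free mostly trades against μ.

## Fitting

Both fits use random-walk Metropolis-Hastings over a uniform prior box
with hard rejection outside the support, 20,000 iterations, the first
10,000 discarded; the retained-draw mean is the reported point estimate.
Chains are fully determined by an integer seed. Convergence tooling is
deliberately minimal (acceptance rate plus seed-replication checks); there
is no adaptive tuning.

**Group fit.** Observations are (correct rate r, mean post-correct RT)
pairs. Each r is inverted to π(β[1], r) = clamp((r − 1 + β[1])/(2β[1] − 1))
— clamped into [0, 1], since the inversion exceeds 1 for r > β[1] and is
negative for r < 1 − β[1] — and the model's predictive post-correct RT
(mixture over the previous latent state) is compared with the observed
RT. The pseudo log-likelihood is the negative sum of squared errors in
ms², used verbatim with no temperature or noise-variance scaling.
Priors: β[1], β[0] ~ U(0.5, 1), μ ~ U(50, 1000) ms per log-odds.

Two numerical choices matter here. The −SSE target in squared-ms units is
extremely peaked along a curved (β[1], μ) ridge (the identifiable
combination is essentially μ·θ(β[1]), the baseline RT): log-density
differences of thousands separate points a proposal step apart, so a chain
started at the prior midpoint with width-proportional steps never reaches
the ridge within the iteration budget. The group fit therefore (i) starts
the chain at a deterministic approximate mode found by profile least
squares — for fixed β[1] the predicted RT is linear in (μ·θ(β[1]),
μ·θ(β[0])), so an inner closed-form solve scanned over a β[1] grid locates
the ridge — and (ii) uses small fixed proposal steps (2.5e-4, 5e-5,
0.5 ms). The resulting posterior is, faithfully, very concentrated around
the least-squares optimum; credible intervals from this fit reflect the
pseudo-likelihood's implicit unit noise variance, not a calibrated noise
model, and the acceptance rate is low by construction. Parameter-recovery
runs on synthetic curves (30 points, 15 ms noise) recover β[1] and μ
without systematic bias, but single-realization estimates inherit genuine
sampling variability of roughly ±0.03 in β[1] and ±70 ms in μ, because the
predictive curve spans only ~30 ms over the 0.80–0.95 rate range relative
to 15 ms point noise, and rates above β[1] clamp to π = 1 where the curve
is flat.

**Subject fit.** The target is the approximate joint log-likelihood of the
first and last sessions of one prime, with a separate memory integrity per
session (π₁, π₂) and shared β[1], β[0], μ. Priors follow the group
results: π ~ U(0, 1), β[1] ~ U(0.9, 0.94), β[0] ~ U(0.999, 1),
μ ~ U(310, 420). This smooth target mixes well with the default
5%-of-width proposal steps (acceptance ≈ 0.2–0.3). Session comparison uses
a paired t-test on the per-subject posterior means of π₁ and π₂
(two-tailed by default; a one-tailed option halves the p-value). If all
paired differences are exactly zero the test reports t = 0, p = 1; a
nonzero constant difference has no defined t and raises.

## Behavioural analyses

Analyses use bivalent trials only; univalent trials are rule-insensitive
decoration. Within each session, trials are labelled FIRST/CC/EC/E
(correct-following-correct, correct-following-error, error); session
boundaries reset the classification because sessions are separated by a
priming block, and FIRST trials belong to neither pool. Error-trial RTs
never enter any RT summary.

- **Epochs**: early = first N_CC (default 20) CC trials of the first
  session, late = last N_CC of the last session, analogously N_EC
  (default 3) for EC; short pools use all available trials and are
  flagged. Group contrasts are paired t-tests across subjects.
- **Error rates**: per subject × prime × session percentages, with paired
  tests between sessions within prime and between primes within session.
- **RT-vs-rate regression**: points are subject × session aggregates from
  the first and last sessions; each subject's mean RT over the included
  sessions is subtracted before ordinary least squares of RT on error rate
  (%), removing between-subject offsets. Reported: Pearson r, slope in ms
  per percentage point, two-tailed p.
- **Confirmation bias**: the exact outcomes-only likelihood of a short
  (T ≤ 16) outcome prefix is evaluated on a π grid (via the forward
  recursion, which equals enumeration), multiplied by a beta-density prior
  and renormalized by trapezoid. The default prior shape (3, 6) places its
  mass below typical likelihood maxima; the demonstrated property — a
  pessimistic prior pulls the posterior mode strictly below the
  maximum-likelihood π — is robust to the shape, which is otherwise
  arbitrary.

## Synthetic data

`simulate_priming_study` emulates the study design: 15 subjects × 2 primes
× 3 sessions × 50 trials, 70% bivalent (35 per session, randomized
positions; positions do not affect the model). Bivalent trials follow the
BAT generative chain; univalent trials are emitted with fixed accuracy
0.96 and baseline (low-threshold) RT, carry no latent state, and are
excluded from modelling. Default memory-integrity trajectories are the
fitted group means — stupid 0.88 → 0.80 and clever 0.85 → 0.88 across
first/last sessions, middle session linearly interpolated — with shared
β[1] = 0.92, β[0] = 0.9998, μ = 360. Per-subject, per-prime π offsets are
Gaussian with sd 0.03 (clamped to [0, 1]), enough between-subject spread
to be realistic without boundary pile-up; μ is not jittered by default.
σ_y defaults to 100 ms, of the order of observed RT spreads while keeping
recovery feasible at 35 bivalent trials per session. RTs are truncated at
zero by redraw; at the default parameters the truncated mass is
negligible (< 1e−15), so no density correction is applied.

What the simulator does **not** emulate: the priming manipulation itself,
omitted responses, fatigue or learning outside the π trajectories, RT
autocorrelation beyond the threshold mechanism, and any non-Gaussian RT
shape (real RT distributions are right-skewed). Passing recovery tests
therefore demonstrate internal consistency of model + fitter, not that
the model captures all structure of human data.

## Problem sizes in tests

Simulation-based property tests choose cohort sizes so that the expected
effect dominates Monte-Carlo error rather than mirroring the 15-subject
study: the double-dissociation direction check uses 120 simulated subjects
(expected shifts ≈ +20 ms for CC under declining π and ≈ +130 ms for EC
under rising π), and the regression-sign check uses 60 subjects × 300
trials, where the binomial noise in per-session error rates no longer
swamps the ~1–2 ms-per-point attenuated slope. At the study's own size
these directions hold in expectation but individual simulated studies are,
as the printed example shows, only marginally powered — consistent with
the small effects in question. Parameter-recovery checks use the study
conditions themselves (15 subjects, 35 bivalent trials per session,
sessions at π = 0.88 and 0.80).

## Known limitations

- The group pseudo-likelihood's implicit unit variance makes its
  "posterior" an essentially degenerate distribution around the
  least-squares fit; interval summaries from it should not be interpreted
  as calibrated uncertainty.
- The first-order approximation degrades when π and β are jointly low
  (inferred accumulation failures frequent) or when RTs sit far from both
  component means; the exact forward recursion is available at any T for
  checking.
- `pi_from_correct_rate` is undefined at β = 0.5 and clamps outside
  [1 − β, β]; group fits on rates mostly above β[1] carry little
  information about the curve's shape.
- Subject fits assume the first/last sessions of a prime are conditionally
  independent given their parameters; no within-prime session pooling is
  offered.
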