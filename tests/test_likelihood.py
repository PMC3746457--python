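"""Sequence likelihoods: enumeration oracle, forward recursion, approximation."""

import itertools
import math

import numpy as np
import pytest

from batmodel.likelihood import (
    LatentSequence,
    TrialSequence,
    approx_log_likelihood,
    exact_log_likelihood,
    forward_log_likelihood,
    path_joint_log_likelihood,
    posterior_c_sequence,
)
from batmodel.model_core import ModelParams


def brute_force_log_likelihood(outcomes, rts, params, rt_policy="all"):
    """Independent oracle: plain-Python product over all latent paths."""
    T = len(outcomes)
    total = 0.0
    for states in itertools.product((0, 1), repeat=T):
        prob = 1.0
        prev = 1
        for t in range(T):
            beta = params.beta_low if prev == 1 else params.beta_high
            p1 = beta * params.pi + (1 - beta) * (1 - params.pi)
            prob *= p1 if outcomes[t] == 1 else 1 - p1
            if outcomes[t] == 0:
                w = (1 - beta) * params.pi / ((1 - beta) * params.pi + beta * (1 - params.pi))
            else:
                w = (1 - beta) * (1 - params.pi) / (
                    (1 - beta) * (1 - params.pi) + beta * params.pi
                )
            prob *= w if states[t] == 0 else 1 - w
            if rts is not None and not math.isnan(rts[t]) and not (
                rt_policy == "correct_only" and outcomes[t] == 0
            ):
                mean = params.mu * math.log(beta / (1 - beta))
                z = (rts[t] - mean) / params.sigma_rt
                prob *= math.exp(-0.5 * z * z) / (
                    params.sigma_rt * math.sqrt(2 * math.pi)
                )
            prev = states[t]
        total += prob
    return math.log(total)


class TestPathJoint:
    def test_single_trial_hand_product(self, fitted_params):
        """T=1, b=1, c=1: outcome term 0.8192 times transition term 0.98828."""
        seq = TrialSequence(np.array([1]))
        value = path_joint_log_likelihood(seq, LatentSequence(np.array([1])), fitted_params)
        assert math.exp(value) == pytest.approx(0.8192 * 0.98828125, rel=1e-9)

    def test_single_trial_marginalizes_to_outcome_probability(self, fitted_params):
        seq = TrialSequence(np.array([1]))
        total = sum(
            math.exp(
                path_joint_log_likelihood(seq, LatentSequence(np.array([c])), fitted_params)
            )
            for c in (0, 1)
        )
        assert total == pytest.approx(0.8192, rel=1e-12)

    def test_two_trial_hand_oracle(self, fitted_params):
        """Every T=2 path agrees with an independently coded factor product."""
        outcomes = [1, 0]
        rts = [850.0, 1600.0]
        for states in itertools.product((0, 1), repeat=2):
            got = path_joint_log_likelihood(
                TrialSequence(np.array(outcomes), np.array(rts)),
                LatentSequence(np.array(states)),
                fitted_params,
            )
            # oracle restricted to this single path
            prob = 1.0
            prev = 1
            for t in range(2):
                beta = fitted_params.beta_low if prev else fitted_params.beta_high
                p1 = beta * 0.88 + (1 - beta) * 0.12
                prob *= p1 if outcomes[t] else 1 - p1
                if outcomes[t] == 0:
                    w = (1 - beta) * 0.88 / ((1 - beta) * 0.88 + beta * 0.12)
                else:
                    w = (1 - beta) * 0.12 / ((1 - beta) * 0.12 + beta * 0.88)
                prob *= w if states[t] == 0 else 1 - w
                mean = fitted_params.mu * math.log(beta / (1 - beta))
                z = (rts[t] - mean) / 100.0
                prob *= math.exp(-0.5 * z * z) / (100.0 * math.sqrt(2 * math.pi))
                prev = states[t]
            assert got == pytest.approx(math.log(prob), rel=1e-12)

    def test_length_mismatch_rejected(self, fitted_params):
        with pytest.raises(ValueError):
            path_joint_log_likelihood(
                TrialSequence(np.array([1, 0])),
                LatentSequence(np.array([1])),
                fitted_params,
            )


class TestExactAndForward:
    def test_matches_independent_brute_force(self, fitted_params):
        rng = np.random.default_rng(7)
        for _ in range(5):
            b = rng.integers(0, 2, 6)
            y = rng.normal(900.0, 200.0, 6)
            seq = TrialSequence(b, y)
            oracle = brute_force_log_likelihood(list(b), list(y), fitted_params)
            assert exact_log_likelihood(seq, fitted_params) == pytest.approx(
                oracle, rel=1e-10
            )
            assert forward_log_likelihood(seq, fitted_params) == pytest.approx(
                oracle, rel=1e-10
            )

    def test_forward_equals_enumeration_on_random_sequences(self, fitted_params):
        rng = np.random.default_rng(11)
        for _ in range(100):
            b = rng.integers(0, 2, 10)
            y = rng.normal(900.0, 150.0, 10)
            seq = TrialSequence(b, y)
            e = exact_log_likelihood(seq, fitted_params)
            f = forward_log_likelihood(seq, fitted_params)
            assert f == pytest.approx(e, rel=1e-10)

    def test_single_trial_reduces_to_outcome_probability(self, fitted_params):
        seq = TrialSequence(np.array([1]))
        assert math.exp(exact_log_likelihood(seq, fitted_params)) == pytest.approx(
            0.8192, rel=1e-12
        )

    def test_outcomes_only_normalizes_over_outcome_space(self, fitted_params):
        """Summed over all 2^T outcome sequences the likelihood is one."""
        T = 8
        total = sum(
            math.exp(
                forward_log_likelihood(
                    TrialSequence(np.array([(code >> i) & 1 for i in range(T)])),
                    fitted_params,
                )
            )
            for code in range(2**T)
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_perfect_memory_all_correct_pins_latent_path(self, fitted_params):
        """With pi = 1 every correct is attributed to good accumulation, so an
        all-correct run scores T * log(beta_low)."""
        params = fitted_params.with_pi(1.0)
        seq = TrialSequence(np.ones(50, dtype=int))
        assert forward_log_likelihood(seq, params) == pytest.approx(
            50.0 * math.log(0.92), rel=1e-12
        )

    def test_enumeration_guard(self, fitted_params):
        with pytest.raises(ValueError, match="forward_log_likelihood"):
            exact_log_likelihood(TrialSequence(np.ones(17, dtype=int)), fitted_params)

    def test_missing_rts_drop_their_factors(self, fitted_params):
        b = np.array([1, 0, 1])
        y = np.array([850.0, np.nan, 900.0])
        with_missing = forward_log_likelihood(TrialSequence(b, y), fitted_params)
        outcomes_only = forward_log_likelihood(TrialSequence(b), fitted_params)
        assert with_missing < outcomes_only  # densities contribute negative logs
        oracle = brute_force_log_likelihood(list(b), list(y), fitted_params)
        assert with_missing == pytest.approx(oracle, rel=1e-10)

    def test_error_rt_policy_excludes_error_trials(self, fitted_params):
        b = np.array([1, 0, 1])
        y = np.array([850.0, 1600.0, 900.0])
        restricted = forward_log_likelihood(
            TrialSequence(b, y), fitted_params, rt_policy="correct_only"
        )
        oracle = brute_force_log_likelihood(
            list(b), list(y), fitted_params, rt_policy="correct_only"
        )
        assert restricted == pytest.approx(oracle, rel=1e-10)

    def test_swap_symmetry_outcomes_only(self):
        """With equal thresholds, flipping pi and all outcomes jointly leaves
        the outcome likelihood unchanged."""
        params = ModelParams(0.7, 0.85, 0.85, 360, 100)
        flipped = ModelParams(0.3, 0.85, 0.85, 360, 100)
        rng = np.random.default_rng(5)
        for _ in range(10):
            b = rng.integers(0, 2, 9)
            a = forward_log_likelihood(TrialSequence(b), params)
            c = forward_log_likelihood(TrialSequence(1 - b), flipped)
            assert c == pytest.approx(a, rel=1e-10)


class TestApproximation:
    def test_exact_for_short_sequences(self, fitted_params):
        """Only c_1 is marginalized at T <= 2, so no approximation is made."""
        rng = np.random.default_rng(3)
        for T in (1, 2):
            for _ in range(10):
                seq = TrialSequence(rng.integers(0, 2, T), rng.normal(900, 150, T))
                assert approx_log_likelihood(seq, fitted_params) == pytest.approx(
                    exact_log_likelihood(seq, fitted_params), rel=1e-12
                )

    def test_small_relative_error_at_fitted_values(self, fitted_params):
        rng = np.random.default_rng(13)
        for _ in range(20):
            b = rng.integers(0, 2, 10)
            y = rng.normal(900.0, 150.0, 10)
            seq = TrialSequence(b, y)
            e = exact_log_likelihood(seq, fitted_params)
            a = approx_log_likelihood(seq, fitted_params)
            assert abs(a - e) < 0.01 * abs(e)

    def test_becomes_exact_when_latent_path_deterministic(self):
        """As both thresholds approach one with perfect memory, accumulation
        states are pinned and the conditioning assumption holds exactly."""
        params = ModelParams(1.0, 1 - 1e-9, 1 - 1e-9, 360, 100)
        rng = np.random.default_rng(2)
        seq = TrialSequence(np.ones(10, dtype=int), rng.normal(7450, 100, 10))
        e = exact_log_likelihood(seq, params)
        a = approx_log_likelihood(seq, params)
        assert a == pytest.approx(e, abs=1e-7)

    def test_grid_argmax_recovers_generative_pi(self, fitted_params):
        """The approximate likelihood peaks near the true memory integrity on
        a long simulated sequence."""
        from batmodel.synthetic import simulate_session

        frame, _ = simulate_session(fitted_params, 200, seed=21)
        seq = TrialSequence(frame["outcome"].to_numpy(), frame["rt_ms"].to_numpy())
        grid = np.linspace(0.5, 0.995, 100)
        scores = [
            approx_log_likelihood(seq, fitted_params.with_pi(p)) for p in grid
        ]
        assert abs(grid[int(np.argmax(scores))] - 0.88) <= 0.05


class TestLatentPosterior:
    def test_normalizes_over_candidates(self, fitted_params):
        rng = np.random.default_rng(17)
        T = 8
        seq = TrialSequence(rng.integers(0, 2, T), rng.normal(950, 200, T))
        total = sum(
            posterior_c_sequence(
                seq,
                LatentSequence(np.array([(code >> i) & 1 for i in range(T)])),
                fitted_params,
            )
            for code in range(2**T)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_map_path_for_clean_run_is_all_ones(self, fitted_params):
        T = 8
        seq = TrialSequence(np.ones(T, dtype=int))
        posts = {
            code: posterior_c_sequence(
                seq,
                LatentSequence(np.array([(code >> i) & 1 for i in range(T)])),
                fitted_params,
            )
            for code in range(2**T)
        }
        assert max(posts, key=posts.get) == 2**T - 1

    def test_single_trial_posterior_matches_attribution(self, fitted_params):
        seq = TrialSequence(np.array([1]))
        assert posterior_c_sequence(
            seq, LatentSequence(np.array([1])), fitted_params
        ) == pytest.approx(0.98828125, rel=1e-9)


class TestTrialSequenceValidation:
    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            TrialSequence(np.array([0, 2]))
        with pytest.raises(ValueError):
            TrialSequence(np.array([1, 0]), np.array([100.0]))
        with pytest.raises(ValueError):
            TrialSequence(np.array([1]), np.array([-5.0]))
        with pytest.raises(ValueError):
            LatentSequence(np.array([0, 2]))
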