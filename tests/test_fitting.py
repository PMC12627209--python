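"""Exact sub-sampling likelihood: DP pmf, response mixing, MLE."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ffr
from ffr.fitting import (
    FitError,
    fit_mle,
    match_count_distribution,
    mix_multiplier,
    negative_log_likelihood,
    response_pmf,
    subset_match_count_distribution,
)
from ffr.observers import SubsamplingParams


def enumeration_oracle(ps, n_select):
    """Brute force: all subsets x all match outcomes."""
    n = len(ps)
    pmf = np.zeros(n_select + 1)
    for subset in itertools.combinations(range(n), n_select):
        for outcome in itertools.product([0, 1], repeat=n_select):
            prob = 1.0
            for i, hit in zip(subset, outcome):
                prob *= ps[i] if hit else 1 - ps[i]
            pmf[sum(outcome)] += prob
    return pmf / math.comb(n, n_select)


class TestSubsetMatchCountDistribution:
    @pytest.mark.parametrize(
        "ps,n_select",
        [
            ((1.0, 0.0, 0.5, 0.5), 2),
            ((0.3, 0.9, 0.1, 0.7, 0.5), 3),
            ((0.2, 0.2, 0.2, 0.8, 0.8, 0.4), 4),
        ],
    )
    def test_matches_enumeration_oracle(self, ps, n_select):
        dp = subset_match_count_distribution(ps, n_select)
        assert np.allclose(dp, enumeration_oracle(ps, n_select), atol=1e-12)

    @given(
        ps=st.lists(st.floats(0, 1), min_size=2, max_size=6),
        data=st.data(),
    )
    @settings(max_examples=50, deadline=None)
    def test_is_a_distribution(self, ps, data):
        n_select = data.draw(st.integers(1, len(ps)))
        pmf = subset_match_count_distribution(ps, n_select)
        assert np.all(pmf >= -1e-15)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-9)

    def test_full_sample_is_poisson_binomial(self):
        """N = n: the subset average collapses to one Poisson binomial."""
        rng = np.random.default_rng(5)
        ps = rng.uniform(0, 1, 36)
        # independent oracle: convolve Bernoulli pmfs one by one
        pb = np.array([1.0])
        for p in ps:
            pb = np.convolve(pb, [1 - p, p])
        assert np.allclose(subset_match_count_distribution(ps, 36), pb, atol=1e-10)


class TestMatchCountDistribution:
    def test_noiseless_gaussian_point_mass_at_true_count(self):
        trial = ffr.make_trial("gaussian", 3, 0)
        pmf = match_count_distribution(trial, SubsamplingParams(36, 1e-4))
        assert pmf[8] == pytest.approx(1.0, abs=1e-9)

    def test_equals_monte_carlo(self):
        """DP pmf vs simulation frequencies (multiplier inert at N=36)."""
        trial = ffr.make_trial("uniform", 9, 6)
        params = SubsamplingParams(36, 4.0)
        pmf = match_count_distribution(trial, params)
        rng = np.random.default_rng(6)
        n_sims = 20_000
        sims = np.array(
            [
                ffr.simulate_subsampling_response(trial, params, rng)
                for _ in range(n_sims)
            ]
        )
        # response = min(matches, 8) at N=36
        clipped = np.zeros(9)
        clipped[:8] = pmf[:8]
        clipped[8] = pmf[8:].sum()
        emp = np.bincount(sims, minlength=9) / n_sims
        se = np.sqrt(clipped * (1 - clipped) / n_sims)
        assert np.all(np.abs(emp - clipped) <= 3 * se + 1e-12)


class TestResponsePMF:
    def test_multiplier_spreads_point_mass(self):
        """k=3 with N=9: multipliers 1..4 give 3,6,8,8 at 1/4 each."""
        point = np.zeros(10)
        point[3] = 1.0
        out = mix_multiplier(point, 9)
        assert out[3] == pytest.approx(0.25)
        assert out[6] == pytest.approx(0.25)
        assert out[8] == pytest.approx(0.5)
        assert out.sum() == pytest.approx(1.0)

    def test_identity_for_large_n(self):
        pmf = np.zeros(20)
        pmf[5] = 1.0
        out = mix_multiplier(pmf, 20)
        assert out[5] == 1.0

    @pytest.mark.parametrize("N,sigma", [(1, 0.7), (7, 2.5), (19, 5.0), (36, 9.0)])
    def test_sums_to_one(self, N, sigma):
        trial = ffr.make_trial("bimodal", 30, -15)
        pmf = response_pmf(trial, SubsamplingParams(N, sigma)).pmf
        assert pmf.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(pmf >= 0)


class TestNegativeLogLikelihood:
    def test_certain_response_zero_nll(self):
        """A deterministic trial whose response has probability one."""
        session = ffr.Session(
            "x", [ffr.make_trial("uniform", 0, 21)]
        ).with_responses([0])
        params = SubsamplingParams(36, 1e-4)
        assert negative_log_likelihood(session, params) == pytest.approx(0.0, abs=1e-6)

    def test_additive_over_concatenation(self, small_filled_session):
        params = SubsamplingParams(20, 3.0)
        half = len(small_filled_session.trials) // 2
        first = ffr.Session("a", small_filled_session.trials[:half])
        second = ffr.Session("a", small_filled_session.trials[half:])
        total = negative_log_likelihood(small_filled_session, params)
        assert total == pytest.approx(
            negative_log_likelihood(first, params)
            + negative_log_likelihood(second, params),
            rel=1e-9,
        )

    def test_grouped_equals_per_trial(self, small_filled_session):
        """The grouped fast path equals the naive per-trial computation."""
        params = SubsamplingParams(17, 3.3)
        naive = -sum(
            np.log(response_pmf(t, params).pmf[t.response] + 1e-12)
            for t in small_filled_session.trials
        )
        assert negative_log_likelihood(small_filled_session, params) == pytest.approx(
            naive, rel=1e-9
        )

    def test_true_params_beat_distant_params(self):
        rng_seeds = range(3)
        truth = SubsamplingParams(30, 4.0)
        wins = 0
        for i in rng_seeds:
            s = ffr.generate_session(300, seed=700 + i)
            f = ffr.simulate_dataset(s, truth, seed=800 + i)
            if negative_log_likelihood(f, truth) < negative_log_likelihood(
                f, SubsamplingParams(5, 9.0)
            ):
                wins += 1
        assert wins == len(list(rng_seeds))

    def test_simulated_likelihood_tracks_exact(self, small_filled_session):
        """The simulation-based likelihood approximates the DP value."""
        from ffr.fitting import simulated_negative_log_likelihood

        params = SubsamplingParams(24, 4.0)
        exact = negative_log_likelihood(small_filled_session, params)
        approx = simulated_negative_log_likelihood(
            small_filled_session, params, n_sims=4000, seed=55
        )
        assert approx == pytest.approx(exact, rel=0.05)

    def test_empty_session_rejected(self):
        with pytest.raises(FitError):
            negative_log_likelihood(
                ffr.Session("x", []), SubsamplingParams(10, 1.0)
            )


class TestFitMLE:
    def test_self_consistency_large_session(self):
        """5,000 trials at (N=30, sigma=5): estimates land close."""
        session = ffr.generate_session(5000, seed=42)
        filled = ffr.simulate_dataset(session, SubsamplingParams(30, 5.0), seed=43)
        fit = fit_mle(filled)
        assert abs(fit.params_hat.N - 30) <= 3
        assert abs(fit.params_hat.sigma - 5.0) <= 0.5
        assert np.isfinite(fit.nll)
        assert len(fit.profile) == 36

    def test_near_deterministic_data(self):
        session = ffr.generate_session(200, seed=9)
        filled = ffr.simulate_dataset(session, SubsamplingParams(36, 0.1), seed=10)
        fit = fit_mle(filled)
        assert fit.params_hat.N == 36
        assert fit.params_hat.sigma < 0.5

    def test_deterministic_given_data(self, small_filled_session):
        a = fit_mle(small_filled_session)
        b = fit_mle(small_filled_session)
        assert a.params_hat == b.params_hat
        assert a.nll == b.nll


class TestParameterRecovery:
    def test_structure_and_reproducibility(self):
        a = ffr.parameter_recovery(3, trials_per_run=60, seed=77)
        b = ffr.parameter_recovery(3, trials_per_run=60, seed=77)
        assert a.table.equals(b.table)
        assert a.n_runs == 3
        assert -1 <= a.r_N <= 1 and -1 <= a.r_sigma <= 1 and -1 <= a.r_cross <= 1

    def test_rejects_too_few_runs(self):
        with pytest.raises(FitError):
            ffr.parameter_recovery(1, seed=0)
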