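"""Trial-level inference tests: policy enumeration, EFE terms, posteriors,
Dirichlet learning, and exhaustive-enumeration oracles on reduced tasks."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import digamma

from metabandit.lower import (LowerLevel, dirichlet_expectations,
                              enumerate_policies, lower_efe_terms,
                              lower_policy_posterior, lower_policy_prior,
                              option_info_terms, past_free_energy,
                              update_lower_dirichlet,
                              update_lower_state_beliefs)
from metabandit.task import default_context_tables


def known_counts(scale=1e6):
    """Counts whose Dirichlet means equal the true tables (limiting case)."""
    return np.maximum(default_context_tables().probs * scale, 1e-9 * scale)


class TestEnumeration:
    @pytest.mark.parametrize("n,T,expected", [(4, 5, 1024), (4, 1, 4), (3, 2, 9)])
    def test_sizes(self, n, T, expected):
        assert len(enumerate_policies(n, T).policies) == expected

    def test_lexicographic_and_stable(self):
        ps = enumerate_policies(3, 2)
        expected = list(itertools.product(range(3), repeat=2))
        assert [tuple(p) for p in ps.policies] == expected

    def test_overflow_guard(self):
        with pytest.raises(ValueError):
            enumerate_policies(10, 8)

    def test_consistency_mask(self):
        ps = enumerate_policies(4, 5)
        mask = ps.consistency_mask([2, 0])
        assert mask.sum() == 4**3
        assert np.all(ps.policies[mask][:, 0] == 2)
        assert np.all(ps.policies[mask][:, 1] == 0)


class TestDirichletExpectations:
    def test_means(self):
        mean, _ = dirichlet_expectations(np.array([1.0, 1.0, 1.0]))
        assert np.allclose(mean, 1 / 3)
        mean, _ = dirichlet_expectations(np.array([8.0, 1.0, 1.0]))
        assert np.allclose(mean, [0.8, 0.1, 0.1])

    def test_expected_log_via_digamma_recurrence(self):
        # psi(1) - psi(3) = -(1 + 1/2)
        _, elog = dirichlet_expectations(np.array([1.0, 1.0, 1.0]))
        assert np.allclose(elog, -1.5)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            dirichlet_expectations(np.array([1.0, 0.0, 1.0]))


class TestEFETerms:
    def test_expected_utility_known_context_pair3(self):
        # all-option-1 in 3:EV-: P(red>=4) + P(blue>=4) under (0.8, 0.1)
        ps = enumerate_policies(4, 5)
        q_c = np.eye(6)[4]
        terms = lower_efe_terms(ps, known_counts(), q_c, executed=[])
        assert terms.exp_utility[0, 4] == pytest.approx(0.73774, abs=1e-9)

    def test_exp_utility_matches_sequence_enumeration(self):
        # independent oracle: enumerate all 3^5 outcome sequences explicitly
        ps = enumerate_policies(4, 5)
        a = 0.5 + 2.0 * default_context_tables().probs
        mean = a / a.sum(-1, keepdims=True)
        q_c = np.array([0.3, 0.1, 0.2, 0.1, 0.2, 0.1])
        terms = lower_efe_terms(ps, a, q_c, executed=[])
        rng = np.random.default_rng(0)
        for idx in rng.choice(len(ps.policies), 5, replace=False):
            pol = ps.policies[idx]
            expected = 0.0
            for c in range(6):
                for seq in itertools.product(range(3), repeat=5):
                    p = np.prod([mean[c, pol[t], seq[t]] for t in range(5)])
                    w_b = sum(1 for j in seq if j == 1)
                    w_r = sum(1 for j in seq if j == 2)
                    expected += q_c[c] * p * (w_b >= 4 or w_r >= 4)
            assert terms.exp_utility[idx, 4] == pytest.approx(expected, abs=1e-10)

    def test_informative_option_dominates_under_variant_uncertainty(self):
        ps = enumerate_policies(4, 5)
        q_c = np.zeros(6)
        q_c[4] = q_c[5] = 0.5  # pair 3 known, variant unknown
        terms = lower_efe_terms(ps, known_counts(), q_c, executed=[])
        ig = terms.info_gain.sum(axis=1)
        all_ones = 0
        all_fours = len(ps.policies) - 1
        assert ig[all_fours] > ig[all_ones]

    def test_no_uncertainty_no_info_gain(self):
        ps = enumerate_policies(4, 5)
        terms = lower_efe_terms(ps, known_counts(1e9), np.eye(6)[4], executed=[])
        assert np.all(terms.info_gain <= 1e-6)

    def test_info_gain_nonnegative_for_default_setup(self, rng):
        ps = enumerate_policies(4, 5)
        for _ in range(5):
            a = rng.gamma(1.0, 2.0, size=(6, 4, 3)) + 0.05
            q_c = rng.dirichlet(np.ones(6))
            terms = lower_efe_terms(ps, a, q_c, executed=[])
            assert np.all(terms.info_gain >= -1e-9)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_option_info_terms_nonnegative(seed):
    """Information gain (context MI + Dirichlet novelty) is never negative."""
    rng = np.random.default_rng(seed)
    a = rng.gamma(0.8, 3.0, size=(3, 2, 3)) + 0.02
    q_c = rng.dirichlet(np.ones(3))
    assert np.all(option_info_terms(a, q_c) >= -1e-9)


class TestPolicyPriorAndPosterior:
    def test_equal_efe_gives_uniform_prior(self):
        ps = enumerate_policies(2, 2)
        q_c = np.array([1.0, 0.0])
        a = np.full((2, 2, 3), 2.0)  # symmetric: all options equivalent
        terms = lower_efe_terms(ps, a, q_c, executed=[], threshold=2)
        prior = lower_policy_prior(terms, 0)
        assert np.allclose(prior, 0.25, atol=1e-12)

    def test_gamma_zero_gives_uniform(self):
        ps = enumerate_policies(4, 5)
        terms = lower_efe_terms(ps, known_counts(), np.eye(6)[4], executed=[],
                                gamma=0.0)
        assert np.allclose(lower_policy_prior(terms, 0), 1 / 1024, atol=1e-15)

    def test_alpha_zero_ranks_by_utility(self):
        ps = enumerate_policies(4, 5)
        q_c = np.zeros(6); q_c[4] = q_c[5] = 0.5
        terms = lower_efe_terms(ps, known_counts(), q_c, executed=[])
        prior = lower_policy_prior(terms, 1)  # meta state 2: alpha = 0
        eu = terms.exp_utility.sum(axis=1)
        order_prior = np.argsort(prior)
        order_eu = np.argsort(eu)
        assert np.allclose(prior[order_eu], np.sort(prior))
        assert eu[order_prior[-1]] == pytest.approx(eu.max())

    def test_posterior_matches_bruteforce_softmax(self, rng):
        # 3-policy toy evaluated by hand in log space
        ps = enumerate_policies(3, 1)
        a = rng.gamma(1.0, 1.0, size=(2, 3, 3)) + 0.1
        q_c = rng.dirichlet(np.ones(2))
        terms = lower_efe_terms(ps, a, q_c, executed=[], threshold=1)
        q_i = np.array([0.7, 0.3])
        F = np.array([0.3, 0.1, 0.9])
        post = lower_policy_posterior(terms, F, q_i)
        alpha_bar = 0.7 * 1.0 + 0.3 * 0.0
        logits = terms.gamma * (alpha_bar * terms.info_gain.sum(1)
                                + terms.exp_utility.sum(1)) - F
        brute = np.exp(logits) / np.exp(logits).sum()
        assert np.allclose(post, brute, atol=1e-12)

    def test_clamped_alpha_reduces_to_prior(self):
        ps = enumerate_policies(4, 5)
        q_c = np.zeros(6); q_c[4] = q_c[5] = 0.5
        terms = lower_efe_terms(ps, known_counts(), q_c, executed=[])
        F = np.full(1024, 0.42)
        for i, q_i in ((0, np.array([1.0, 0.0])), (1, np.array([0.0, 1.0]))):
            post = lower_policy_posterior(terms, F, q_i)
            assert np.allclose(post, lower_policy_prior(terms, i), atol=1e-12)


class TestPastFreeEnergy:
    def test_no_observations_equal_for_consistent(self):
        ps = enumerate_policies(4, 5)
        a = known_counts()
        q_c = np.full(6, 1 / 6)
        F = past_free_energy(ps, [], [], q_c, a, q_c)
        assert np.allclose(F, F[0])

    def test_inconsistent_policies_infinite(self):
        ps = enumerate_policies(4, 5)
        a = known_counts()
        q_c = np.full(6, 1 / 6)
        F = past_free_energy(ps, [2], [2], q_c, a, q_c)
        mask = ps.consistency_mask([2])
        assert np.all(np.isfinite(F[mask]))
        assert np.all(np.isinf(F[~mask]))

    def test_observation_term_matches_direct_summation(self):
        # 2-context toy: Delta F equals the belief-weighted expected-log gap
        ps = enumerate_policies(2, 2)
        a = np.array([[[4.0, 1.0, 1.0], [1.0, 4.0, 1.0]],
                      [[1.0, 1.0, 4.0], [2.0, 2.0, 2.0]]])
        q_c = np.array([0.6, 0.4])
        p_down = np.array([0.5, 0.5])
        F0 = past_free_energy(ps, [], [], q_c, a, p_down)
        F1 = past_free_energy(ps, [0], [2], q_c, a, p_down)
        _, elog = dirichlet_expectations(a)
        expected_drop = q_c @ elog[:, 0, 1]
        mask = ps.consistency_mask([0])
        assert F1[mask][0] - F0[0] == pytest.approx(-expected_drop, abs=1e-12)


class TestStateBeliefUpdates:
    def test_no_observations_returns_messages(self):
        ps = enumerate_policies(4, 5)
        a = known_counts()
        p_c = np.array([0.3, 0.1, 0.1, 0.1, 0.2, 0.2])
        p_i = np.array([0.5, 0.5])
        terms = lower_efe_terms(ps, a, p_c, executed=[])
        q_pi = lower_policy_prior(terms, 0)
        q_c, _ = update_lower_state_beliefs([], [], q_pi, terms, a, p_c, p_i)
        assert np.allclose(q_c, p_c, atol=1e-12)

    def test_five_sure_red_points_identify_ev_plus(self):
        # five red points from option 4 pin down context 3:EV+
        ps = enumerate_policies(4, 5)
        a = 1 / 3 + 10.0 * default_context_tables().probs
        p_c = np.full(6, 1 / 6)
        p_i = np.array([0.5, 0.5])
        terms = lower_efe_terms(ps, a, p_c, executed=[3] * 5)
        q_pi = lower_policy_prior(terms, 0)
        q_c, _ = update_lower_state_beliefs([3] * 5, [3] * 5, q_pi, terms, a,
                                            p_c, p_i)
        assert q_c[5] > 0.95

    def test_meta_state_tracks_policy_prior_agreement(self):
        # q_pi exactly one of the two priors -> q_i favours that meta state
        ps = enumerate_policies(4, 5)
        a = known_counts()
        q_c = np.zeros(6); q_c[4] = q_c[5] = 0.5
        p_c = q_c.copy()
        p_i = np.array([0.5, 0.5])
        terms = lower_efe_terms(ps, a, q_c, executed=[])
        for i in (0, 1):
            q_pi = lower_policy_prior(terms, i)
            _, q_i = update_lower_state_beliefs([], [], q_pi, terms, a, p_c, p_i)
            assert q_i[i] > 0.5


class TestDirichletLearning:
    def test_point_mass_update(self):
        a = np.ones((6, 4, 3))
        q_l = np.eye(4)[1]
        q_c = np.eye(6)[3]
        out = update_lower_dirichlet(a, 2, q_l, q_c)
        assert out[3, 1, 1] == 2.0
        assert out.sum() == pytest.approx(a.sum() + 1.0)

    def test_uniform_context_spreads_sixths(self):
        a = np.ones((6, 4, 3))
        out = update_lower_dirichlet(a, 1, np.eye(4)[0], np.full(6, 1 / 6))
        assert np.allclose(out[:, 0, 0], 1 + 1 / 6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_mass_conservation_random_beliefs(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.gamma(1.0, 1.0, size=(6, 4, 3)) + 0.01
        q_l = rng.dirichlet(np.ones(4))
        q_c = rng.dirichlet(np.ones(6))
        out = update_lower_dirichlet(a, int(rng.integers(1, 4)), q_l, q_c)
        assert out.sum() - a.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(out >= a)

    def test_parameter_recovery_under_forced_uniform_actions(self):
        # oracle context labels + uniform actions: visited rows converge
        rng = np.random.default_rng(99)
        table = default_context_tables()
        a = 1 / 3 + table.probs
        from metabandit.task import sample_point, encode_point_type
        for c in range(6):
            q_c = np.eye(6)[c]
            for _ in range(100 * 5):
                l = int(rng.integers(4))
                h = encode_point_type(sample_point(table, c + 1, l + 1, rng))
                a = update_lower_dirichlet(a, h, np.eye(4)[l], q_c)
        mean = a / a.sum(-1, keepdims=True)
        visits = a.sum(-1) - (1.0 + 3 / 3)
        l1 = np.abs(mean - table.probs).sum(-1)
        # ~125 visits per row: per-row multinomial L1 noise is ~0.07, so
        # check the average closely and each row loosely
        assert l1[visits >= 50].mean() < 0.1
        assert np.all(l1[visits >= 50] < 0.2)


class TestReducedTaskOracle:
    """Exhaustive evaluation of the variational updates on a 2-context,
    2-option, T=2 task, written as explicit loops over the full joint."""

    def setup_method(self):
        rng = np.random.default_rng(7)
        self.a = rng.gamma(2.0, 1.5, size=(2, 2, 3)) + 0.2
        self.q_c = np.array([0.65, 0.35])
        self.p_i = np.array([0.5, 0.5])
        self.gamma = 8.0
        self.ps = enumerate_policies(2, 2)
        self.mean = self.a / self.a.sum(-1, keepdims=True)

    def brute_terms(self):
        mean = self.mean
        a = self.a
        a0 = a.sum(-1, keepdims=True)
        kl_unit = np.log(a0 / a) + digamma(a + 1) - digamma(a0 + 1)
        eu = np.zeros(4)
        ig = np.zeros(4)
        for p_idx, pol in enumerate(self.ps.policies):
            for tau in range(2):
                l = pol[tau]
                pbar = self.q_c @ mean[:, l, :]
                for c in range(2):
                    for j in range(3):
                        ig[p_idx] += self.q_c[c] * mean[c, l, j] * (
                            np.log(mean[c, l, j]) - np.log(pbar[j])
                            + kl_unit[c, l, j])
            for c in range(2):
                for j1 in range(3):
                    for j2 in range(3):
                        p = mean[c, pol[0], j1] * mean[c, pol[1], j2]
                        blue = (j1 == 1) + (j2 == 1)
                        red = (j1 == 2) + (j2 == 2)
                        eu[p_idx] += self.q_c[c] * p * (blue >= 2 or red >= 2)
        return ig, eu

    def test_policy_posterior_matches_full_joint(self):
        terms = lower_efe_terms(self.ps, self.a, self.q_c, executed=[],
                                threshold=2, gamma=self.gamma)
        ig, eu = self.brute_terms()
        assert np.allclose(terms.info_gain.sum(1), ig, atol=1e-8)
        assert np.allclose(terms.exp_utility.sum(1), eu, atol=1e-8)
        q_i = np.array([0.4, 0.6])
        post = lower_policy_posterior(terms, np.zeros(4), q_i)
        logits = self.gamma * (0.4 * ig + eu)
        brute = np.exp(logits - logits.max())
        brute /= brute.sum()
        assert np.allclose(post, brute, atol=1e-8)

    def test_context_posterior_matches_full_joint(self):
        executed, outcomes = [1, 0], [2, 1]
        terms = lower_efe_terms(self.ps, self.a, self.q_c, executed=executed,
                                threshold=2, gamma=self.gamma)
        q_pi = lower_policy_posterior(
            terms, past_free_energy(self.ps, executed, outcomes, self.q_c,
                                    self.a, np.array([0.5, 0.5])),
            np.array([0.5, 0.5]))
        q_c, _ = update_lower_state_beliefs(executed, outcomes, q_pi, terms,
                                            self.a, np.array([0.5, 0.5]),
                                            self.p_i)
        _, elog = dirichlet_expectations(self.a)
        log_post = np.log(np.array([0.5, 0.5]))
        for l, h in zip(executed, outcomes):
            log_post += elog[:, l, h - 1]
        brute = np.exp(log_post - log_post.max())
        brute /= brute.sum()
        assert np.allclose(q_c, brute, atol=1e-8)


class TestEngineEquivalence:
    """The multiset fast path must agree with the per-policy operations."""

    @pytest.mark.parametrize("executed,outcomes,w", [
        ([], [], (0, 0)),
        ([3], [3], (0, 1)),
        ([0, 1], [2, 1], (1, 0)),
    ])
    def test_action_marginal_matches_per_policy_computation(self, executed,
                                                            outcomes, w):
        a = 1 / 3 + 5.0 * default_context_tables().probs
        q_c = np.array([0.1, 0.1, 0.15, 0.15, 0.3, 0.2])
        p_i = np.array([0.6, 0.4])
        eng = LowerLevel(a.copy(), alpha_map=(1.0, 0.0))
        eng.start_segment(q_c, p_i)
        for l, h in zip(executed, outcomes):
            eng.observe(l, h, w)
        state = eng.plan()
        # per-policy reference path with the same beliefs
        ps = enumerate_policies(4, 5)
        terms = lower_efe_terms(ps, a, eng.q_c, executed=executed, w=w)
        F = past_free_energy(ps, executed, outcomes, eng.q_c, a, q_c)
        F = np.where(np.isfinite(F), 0.0, np.inf)  # constant on consistent set
        q_pi = lower_policy_posterior(terms, F, eng.q_i)
        t0 = len(executed)
        marginal = np.zeros(4)
        for idx, pol in enumerate(ps.policies):
            marginal[pol[t0]] += q_pi[idx]
        assert np.allclose(state.action_marginal, marginal, atol=1e-9)
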