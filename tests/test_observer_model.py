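import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import restlessbandit as rb
from restlessbandit.observer_model import beta_dominance, _forward_arrays

from conftest import make_session


def state(g0, e0, g1, e1):
    return rb.BeliefState(gamma=np.array([g0, g1], float),
                          epsilon=np.array([e0, e1], float))


class TestBeliefBasics:
    def test_initial_beliefs_are_uniform(self):
        s = rb.init_beliefs()
        assert np.array_equal(s.gamma, [1.0, 1.0])
        assert np.array_equal(s.epsilon, [1.0, 1.0])
        assert np.array_equal(rb.posterior_mean(s), [0.5, 0.5])
        assert np.allclose(rb.posterior_variance(s), 1.0 / 12.0, atol=1e-15)

    @pytest.mark.parametrize(
        "g,e,q", [(1, 1, 0.5), (3, 1, 0.75), (2.5, 7.5, 0.25)]
    )
    def test_posterior_mean_formula(self, g, e, q):
        assert rb.posterior_mean(state(g, e, 1, 1))[0] == pytest.approx(q, abs=1e-15)

    def test_posterior_variance_formula_and_concentration(self):
        assert rb.posterior_variance(state(2, 2, 1, 1))[0] == pytest.approx(0.05, abs=1e-15)
        wide = rb.posterior_variance(state(1, 1, 1, 1))[0]
        narrow = rb.posterior_variance(state(10, 10, 1, 1))[0]
        assert narrow < wide

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            state(0.0, 1, 1, 1)


class TestUpdates:
    def test_pure_increment_limit(self):
        s = rb.update_chosen(state(2, 3, 1, 1), choice=0, reward=1, omega=0.0)
        assert s.gamma[0] == 3 and s.epsilon[0] == 3

    def test_full_relaxation_then_increment(self):
        s = rb.update_chosen(state(7.7, 3.3, 1, 1), choice=0, reward=1, omega=1.0)
        assert s.gamma[0] == 2 and s.epsilon[0] == 1

    def test_omission_update(self):
        s = rb.update_chosen(state(2, 2, 1, 1), choice=0, reward=0, omega=0.5)
        assert s.gamma[0] == pytest.approx(1.5) and s.epsilon[0] == pytest.approx(2.5)

    def test_update_leaves_other_bandit_untouched(self):
        s = rb.update_chosen(state(2, 3, 4, 5), choice=0, reward=1, omega=0.3)
        assert s.gamma[1] == 4 and s.epsilon[1] == 5

    @pytest.mark.parametrize(
        "lam,expected", [(0.0, (3.0, 2.0)), (1.0, (1.0, 1.0)), (0.5, (2.0, 1.5))]
    )
    def test_forgetting_relaxes_toward_one(self, lam, expected):
        s = rb.update_unchosen(state(3, 2, 1, 1), unchosen=0, lambda_forget=lam)
        assert (s.gamma[0], s.epsilon[0]) == pytest.approx(expected)

    def test_invalid_reward_rejected(self):
        with pytest.raises(ValueError):
            rb.update_chosen(state(1, 1, 1, 1), choice=0, reward=2, omega=0.5)


class TestBetaDominance:
    @pytest.mark.parametrize(
        "params,exact",
        [
            ((1, 1, 1, 1), 0.5),
            ((2, 1, 1, 1), 2.0 / 3.0),
            ((1, 2, 2, 1), 1.0 / 6.0),
        ],
    )
    def test_closed_forms(self, params, exact):
        assert rb.prob_first_beta_greater(*params) == pytest.approx(exact, abs=1e-9)

    def test_monte_carlo_agreement(self):
        rng = np.random.default_rng(0)
        vals = [0.5, 1.5, 4.0, 9.0, 18.0]
        n = 200_000
        for v1 in vals[:3]:
            for v0 in vals[2:]:
                p = rb.prob_first_beta_greater(v1, v0, v0, v1)
                draws1 = rng.beta(v1, v0, n)
                draws0 = rng.beta(v0, v1, n)
                mc = np.mean(draws1 > draws0)
                se = np.sqrt(p * (1 - p) / n)
                assert abs(p - mc) <= 3 * se + 3.0 / n

    @given(
        st.floats(0.5, 20), st.floats(0.5, 20), st.floats(0.5, 20), st.floats(0.5, 20)
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_complement_identity(self, g1, e1, g0, e0):
        p = rb.prob_first_beta_greater(g1, e1, g0, e0)
        q = rb.prob_first_beta_greater(g0, e0, g1, e1)
        assert abs(p + q - 1.0) < 1e-9

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            rb.prob_first_beta_greater(0.0, 1, 1, 1)


class TestRelativeConfidence:
    def test_identical_beliefs_give_zero(self):
        assert rb.relative_confidence(state(2, 3, 2, 3), chosen=0) == pytest.approx(0.0, abs=1e-9)

    def test_known_value(self):
        # chosen Beta(2,1) vs unchosen Beta(1,1): 2*(2/3)-1 = 1/3
        s = state(2, 1, 1, 1)
        assert rb.relative_confidence(s, chosen=0) == pytest.approx(1.0 / 3.0, abs=1e-9)

    def test_antisymmetry_under_role_swap(self):
        s = state(2.5, 1.5, 1.2, 3.4)
        assert rb.relative_confidence(s, 0) == pytest.approx(
            -rb.relative_confidence(s, 1), abs=1e-9
        )


class TestPropensities:
    def test_collapses_to_posterior_means_without_bonus_terms(self):
        params = rb.ObserverParams(1.0, 0.5, 0.5, 0.0, 0.0)
        prev = state(2, 1, 1, 1)   # chosen bandit 0 already updated
        new = state(2, 1, 1, 1)
        m = rb.propensities(prev, new, chosen_prev=0, params=params).m
        assert m[0] == pytest.approx(2.0 / 3.0, abs=1e-12)
        assert m[1] == pytest.approx(0.5, abs=1e-12)

    def test_exploration_bonus_weighting(self):
        # unchosen Beta(2,2): Q=0.5, V=0.05; upsilon=2 adds 0.1
        params = rb.ObserverParams(1.0, 0.5, 0.5, 2.0, 0.0)
        prev = state(2, 2, 2, 2)
        new = state(2, 2, 2, 2)
        m = rb.propensities(prev, new, chosen_prev=0, params=params).m
        assert m[1] == pytest.approx(0.6, abs=1e-12)

    def test_confidence_weighting(self):
        # chosen Beta(2,1) vs unchosen Beta(1,1): C_rel = 1/3; kappa=1
        params = rb.ObserverParams(1.0, 0.5, 0.5, 0.0, 1.0)
        prev = state(2, 1, 1, 1)
        new = state(2, 1, 1, 1)
        m = rb.propensities(prev, new, chosen_prev=0, params=params).m
        assert m[1] == pytest.approx(0.5 + 1.0 / 12.0 * 0 + 1.0 / 3.0, abs=1e-9)


class TestChoiceProbabilities:
    def test_symmetry_and_uniform_limit(self):
        assert np.allclose(rb.choice_probabilities(np.array([0.7, 0.7]), 5.0), 0.5)
        assert np.allclose(rb.choice_probabilities(np.array([0.9, 0.1]), 0.0), 0.5)

    def test_logistic_value(self):
        p = rb.choice_probabilities(np.array([0.8, 0.2]), 2.0)
        assert p[0] == pytest.approx(1.0 / (1.0 + np.exp(-1.2)), abs=1e-12)

    def test_greedy_limit(self):
        p = rb.choice_probabilities(np.array([0.51, 0.5]), 1e3)
        assert p[0] > 1.0 - 1e-6 or p[0] == pytest.approx(1 / (1 + np.exp(-10)), abs=1e-9)
        # propensity gap 0.01 at beta 10^3 concentrates all mass
        assert p[0] >= 1.0 / (1.0 + np.exp(-10.0)) - 1e-12

    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(0, 50))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_normalization(self, m0, m1, beta):
        p = rb.choice_probabilities(np.array([m0, m1]), beta)
        assert abs(p.sum() - 1.0) < 1e-12
        assert (p >= 0).all()

    def test_nonfinite_propensities_rejected(self):
        with pytest.raises(ValueError):
            rb.choice_probabilities(np.array([np.inf, 0.0]), 1.0)


# closed-form latents of the 3-trial session (choices 0,0,1; rewards 1,0,1)
# at omega=lambda=0.5, upsilon=kappa=1, beta=3, literal timing — worked out
# step by step from the update equations before the implementation was built
HANDWORKED = [
    dict(t=1, Q=(0.5, 0.5), V=(1 / 12, 1 / 12), m=(0.5, 0.5),
         p0=0.5, C_rel=1 / 3),
    dict(t=2, Q=(2 / 3, 0.5), V=(1 / 18, 1 / 12), m=(2 / 3, 0.5 + 1 / 12 + 1 / 3),
         p0=1 / (1 + np.exp(3 * 0.25)), C_rel=-1 / 7),
    # margin m1 - m0 = (0.5 + 1/12 - 1/7) - 3/7 = 1/84, scaled by beta = 3
    dict(t=3, Q=(3 / 7, 0.5), V=(8 / 147, 1 / 12), m=(3 / 7, 0.5 + 1 / 12 - 1 / 7),
         p0=1 / (1 + np.exp(3 / 84)), C_rel=11 / 21),
]


class TestRunObserver:
    def test_first_trial_is_uniform_for_any_parameters(self, session):
        for params in [rb.ObserverParams(9.0, 0.9, 0.1, -2.0, 3.0),
                       rb.ObserverParams(0.0, 0.2, 0.8, 0.0, 0.0)]:
            lat = rb.run_observer(session, params)
            assert np.array_equal(lat[0].choice_prob, [0.5, 0.5])
            assert np.array_equal(lat[0].Q, [0.5, 0.5])

    def test_three_trial_recursion_matches_hand_computation(self, toy_session):
        params = rb.ObserverParams(3.0, 0.5, 0.5, 1.0, 1.0)
        lat = rb.run_observer(toy_session, params, value_timing="literal")
        for row, la in zip(HANDWORKED, lat):
            assert la.t == row["t"]
            assert la.Q == pytest.approx(row["Q"], abs=1e-10)
            assert la.V == pytest.approx(row["V"], abs=1e-10)
            assert la.m.m == pytest.approx(row["m"], abs=1e-10)
            assert la.choice_prob[0] == pytest.approx(row["p0"], abs=1e-10)
            assert la.C_rel == pytest.approx(row["C_rel"], abs=1e-10)

    def test_conjugate_counting_limit(self):
        # omega=lambda=0: gamma counts rewards+1, epsilon counts omissions+1
        rng = np.random.default_rng(4)
        choices = [0] * 30
        rewards = rng.integers(0, 2, 30).tolist()
        sess = make_session(choices, rewards)
        params = rb.ObserverParams(2.0, 0.0, 0.0, 0.0, 0.0)
        lat = rb.run_observer(sess, params)
        for t in range(30):
            wins = sum(rewards[:t])
            expect = (1 + wins) / (2 + t)
            assert lat[t].Q[0] == pytest.approx(expect, abs=1e-12)

    def test_online_agent_matches_offline_recursion(self, schedule, observer_params):
        agent = rb.ObserverAgent(observer_params, rng=3)
        probs = []
        orig_choose = agent.choose

        def spy(t):
            probs.append(rb.choice_probabilities(agent._m, observer_params.beta_temp))
            return orig_choose(t)

        agent.choose = spy
        sess = rb.simulate_session(schedule, agent, rng=4)
        lat = rb.run_observer(sess, observer_params)
        offline = np.array([la.choice_prob for la in lat])
        assert np.allclose(np.array(probs), offline, atol=1e-9)

    def test_latents_invariants(self, session, observer_params):
        lat = rb.run_observer(session, observer_params)
        for la in lat:
            assert abs(la.choice_prob.sum() - 1.0) < 1e-12
            assert np.all((la.Q > 0) & (la.Q < 1))
            assert -1.0 <= la.C_rel <= 1.0

    def test_missed_trials_freeze_beliefs_and_propensities(self):
        sess = make_session([0, None, 1], [1, None, 0])
        params = rb.ObserverParams(3.0, 0.5, 0.5, 1.0, 1.0)
        lat = rb.run_observer(sess, params)
        assert np.isnan(lat[1].C_rel)
        assert np.array_equal(lat[1].m.m, lat[2].m.m)
        assert np.array_equal(lat[1].Q, lat[2].Q)

    def test_value_timing_modes_differ_when_forgetting_is_active(self):
        # the unchosen bandit must hold a non-prior belief for relaxation
        # timing to matter: choose 1 first, then 0 twice
        sess = make_session([1, 0, 0], [1, 1, 0])
        params = rb.ObserverParams(3.0, 0.5, 0.5, 1.0, 1.0)
        lit = rb.run_observer(sess, params, value_timing="literal")
        post = rb.run_observer(sess, params, value_timing="post_update")
        assert lit[2].m.m[1] != pytest.approx(post[2].m.m[1], abs=1e-12)

    def test_beliefs_stay_positive_and_finite_over_long_sessions(self):
        rng = np.random.default_rng(9)
        n = 10_000
        choices = rng.integers(0, 2, n)
        rewards = rng.integers(0, 2, n)
        fw = _forward_arrays(choices, rewards, omega=0.37, lam=0.11)
        for key in ("gamma", "epsilon"):
            assert np.all(np.isfinite(fw[key]))
            assert np.all(fw[key] > 0)
        # bounded by the update fixed points
        assert fw["gamma"].max() <= 1 + 1 / 0.37 + 1e-9

    def test_forgetting_fixed_point_is_geometric(self):
        # bandit 1 chosen early then never again: its parameters decay to 1
        lam = 0.3
        choices = [1] * 5 + [0] * 40
        rewards = [1] * 5 + [0] * 40
        fw = _forward_arrays(np.array(choices), np.array(rewards), omega=0.5, lam=lam)
        g1 = fw["gamma"][:, 1]
        dev = g1[6:] - 1.0
        ratios = dev[1:] / dev[:-1]
        assert np.allclose(ratios, 1 - lam, atol=1e-9)
        assert fw["gamma"][-1, 1] == pytest.approx(1.0, abs=1e-4)


class TestFastDominanceMode:
    def test_fast_mode_tracks_accurate_mode(self):
        rng = np.random.default_rng(2)
        g1, e1, g0, e0 = (rng.uniform(1, 25, 300) for _ in range(4))
        fast = beta_dominance(g1, e1, g0, e0, fast=True)
        slow = beta_dominance(g1, e1, g0, e0, fast=False)
        assert np.max(np.abs(fast - slow)) < 1e-4
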