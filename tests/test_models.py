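import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_params
from coopdyn._kernels import NLL_KERNELS
from coopdyn.models import (
    MODELS,
    baseline_prob,
    expectation_update_asymmetric,
    expectation_update_basic,
    expectation_update_influence,
    fehr_schmidt_utilities,
    expected_payoffs,
    get_model,
    replay,
    rl_update,
    simulate_agent,
    social_reward_utilities,
    softmax_coop_prob,
    trial_coop_prob,
    wsls_prob,
)
from coopdyn.task import generate_partner_schedule

# ----------------------------------------------------------- primitives


def test_softmax_closed_form_and_limits():
    assert softmax_coop_prob(1.0, 1.0, 5.0) == 0.5
    assert softmax_coop_prob(0.0, 1.0, 1.0) == pytest.approx(1 / (1 + math.e), abs=1e-9)
    assert softmax_coop_prob(2.0, 1.0, 1000.0) == pytest.approx(1.0)
    with pytest.raises(ValueError, match="finite"):
        softmax_coop_prob(np.inf, 0.0, 1.0)
    with pytest.raises(ValueError, match="beta"):
        softmax_coop_prob(0.0, 0.0, 0.0)


@given(
    u1=st.floats(-50, 50), u2=st.floats(-50, 50),
    beta=st.floats(1e-3, 20.0),
)
@settings(deadline=None, derandomize=True)
def test_softmax_exact_complement(u1, u2, beta):
    q1 = softmax_coop_prob(u1, u2, beta)
    q2 = softmax_coop_prob(u2, u1, beta)
    assert 0.0 <= q1 <= 1.0
    assert q1 + q2 == 1.0  # exact complement by construction


def test_baseline_prob():
    assert baseline_prob(0.7) == 0.7
    assert baseline_prob(0.0) == 0.0 and baseline_prob(1.0) == 1.0
    assert 1 - baseline_prob(0.7) == pytest.approx(0.3)
    with pytest.raises(ValueError):
        baseline_prob(1.2)


def test_wsls_prob():
    assert wsls_prob(0.2, "C", 6) == pytest.approx(0.9)  # won, stay on C
    assert wsls_prob(0.2, "C", 0) == pytest.approx(0.1)  # lost, shift
    assert wsls_prob(1.0, "C", 6) == 0.5  # fully random
    assert wsls_prob(1.0, "D", 0) == 0.5
    assert wsls_prob(0.2, None, None) == 0.5  # first trial
    assert wsls_prob(0.2, "D", 2) == pytest.approx(0.9)  # lost on D, shift to C
    with pytest.raises(ValueError, match="payoff"):
        wsls_prob(0.2, "C", 3)


def test_rl_update():
    assert rl_update(3.0, 6, 0.5) == pytest.approx(4.5)
    assert rl_update(3.0, 6, 0.0) == 3.0
    assert rl_update(3.0, 6, 1.0) == 6.0


def test_expected_payoffs_and_fehr_schmidt():
    assert expected_payoffs(0.5) == (2.0, 5.0, 4.0, 1.0)
    u_c, u_d = fehr_schmidt_utilities(0.5, 0.5, 0.25)
    assert u_c == pytest.approx(2 - 0.5 * 3)  # 0.5
    assert u_d == pytest.approx(4 - 0.25 * 3)  # 3.25
    assert fehr_schmidt_utilities(0.5, 0.0, 0.0) == (2.0, 4.0)


def test_social_reward_utilities():
    assert social_reward_utilities(0.5, 0.0) == (2.0, 4.0)
    u_c, u_d = social_reward_utilities(0.5, 4.0)
    assert u_c == u_d == 4.0  # indifference at omega = 2/p
    assert softmax_coop_prob(u_c, u_d, 7.3) == 0.5
    assert social_reward_utilities(0.0, 3.0) == (0.0, 2.0)


def test_expectation_updates():
    assert expectation_update_basic(0.5, 1, 0.3) == pytest.approx(0.65)
    assert expectation_update_basic(0.5, 1, 0.0) == 0.5
    assert expectation_update_basic(0.5, 0, 1.0) == 0.0
    assert expectation_update_asymmetric(0.5, 1, 0.4, 0.9) == pytest.approx(0.7)
    assert expectation_update_asymmetric(0.5, 0, 0.9, 0.2) == pytest.approx(0.4)


@given(p=st.floats(0.0, 1.0), partner=st.integers(0, 1), alpha=st.floats(0.0, 1.0))
@settings(deadline=None, derandomize=True)
def test_asymmetric_reduces_to_basic_when_rates_equal(p, partner, alpha):
    assert expectation_update_asymmetric(p, partner, alpha, alpha) == \
        expectation_update_basic(p, partner, alpha)


def test_influence_update_composition():
    # q' from the softmax at U_c=3, U_d=4, beta=1
    q_prime = softmax_coop_prob(3.0, 4.0, 1.0)
    assert q_prime == pytest.approx(0.26894, abs=1e-5)
    p_new = expectation_update_influence(0.5, 1, 1, q_prime, 0.3, 0.2)
    assert p_new == pytest.approx(0.79621, abs=1e-5)
    # kappa = 0 reduces to the basic update
    assert expectation_update_influence(0.5, 1, 1, 0.3, 0.3, 0.0) == \
        pytest.approx(expectation_update_basic(0.5, 1, 0.3))
    # Q = q' exactly: second-order term vanishes
    assert expectation_update_influence(0.5, 1, 1, 1.0, 0.3, 0.5) == \
        pytest.approx(expectation_update_basic(0.5, 1, 0.3))
    # clipped into [1e-3, 1 - 1e-3]
    assert expectation_update_influence(0.99, 1, 1, 0.0, 1.0, 1.0) == 1 - 1e-3


# ----------------------------------------------------------- dispatch


def test_trial_coop_prob_dispatch():
    assert trial_coop_prob("M1", {"b": 0.3}, {"anything": 1}) == 0.3
    assert trial_coop_prob("M5", {"omega": 4.0, "beta": 2.0}, {"p": 0.5}) == 0.5
    m8 = get_model("M8")
    params = dict(alpha_pos=0.3, alpha_neg=0.3, omega=0.0, beta=1.7)
    state = m8.init_state(params)
    assert trial_coop_prob("M8", params, state) == \
        pytest.approx(softmax_coop_prob(2.0, 4.0, 1.7))
    with pytest.raises(ValueError, match="expects parameters"):
        trial_coop_prob("M8", {"b": 0.5}, {})
    with pytest.raises(KeyError, match="unknown model"):
        get_model("M9")


# ----------------------------------------------------------- simulation


def test_simulate_agent_no_learning_and_determinism(default_cfg):
    schedule = generate_partner_schedule(default_cfg)
    params = dict(alpha_pos=0.0, alpha_neg=0.0, omega=1.5, beta=2.0)
    s1, t1 = simulate_agent("M8", params, schedule, rng=5)
    s2, t2 = simulate_agent("M8", params, schedule, rng=5)
    assert np.all(t1["p"] == 0.5), "zero learning rates freeze the belief"
    assert np.array_equal(s1.own, s2.own), "fixed seed, identical choices"
    assert np.allclose(t1["intrinsic"], t1["p"] * params["omega"])


def test_simulate_agent_near_deterministic_limit(default_cfg):
    schedule = np.ones(120, dtype=np.int8)  # partner always cooperates
    params = dict(alpha_pos=1.0, alpha_neg=1.0, omega=10.0, beta=20.0)
    session, trace = simulate_agent("M8", params, schedule, rng=0)
    # after the first trial p=1, U_c=14 >> U_d=6: cooperation assured
    assert np.all(session.own[1:] == 1)


@pytest.mark.parametrize("partner_action, expect", [(1, 1.0), (0, 0.0)])
def test_belief_monotone_under_consistent_partner(partner_action, expect):
    schedule = np.full(120, partner_action, dtype=np.int8)
    for model_id, params in [
        ("M6", dict(alpha=0.3, omega=2.0, beta=2.0)),
        ("M8", dict(alpha_pos=0.3, alpha_neg=0.2, omega=2.0, beta=2.0)),
    ]:
        _, trace = simulate_agent(model_id, params, schedule, rng=1)
        p = trace["p"].to_numpy()
        diffs = np.diff(p)
        assert np.all(diffs >= 0) if partner_action == 1 else np.all(diffs <= 0)
        assert abs(p[-1] - expect) < 1e-5


def test_m6_equals_m8_with_equal_rates(default_cfg):
    """M6 and the asymmetric rule with alpha+ = alpha- give identical traces."""
    schedule = generate_partner_schedule(default_cfg)
    p6 = dict(alpha=0.37, omega=2.2, beta=1.9)
    p8 = dict(alpha_pos=0.37, alpha_neg=0.37, omega=2.2, beta=1.9)
    s6, t6 = simulate_agent("M6", p6, schedule, rng=11)
    s8, t8 = simulate_agent("M8", p8, schedule, rng=11)
    assert np.array_equal(s6.own, s8.own)
    assert np.array_equal(t6["p"].to_numpy(), t8["p"].to_numpy())
    assert np.array_equal(t6["q"].to_numpy(), t8["q"].to_numpy())


@pytest.mark.parametrize("model_id", list(MODELS))
def test_probabilities_and_beliefs_stay_in_range(model_id, default_cfg):
    rng = np.random.default_rng(42)
    schedule = generate_partner_schedule(default_cfg)
    model = get_model(model_id)
    for _ in range(5):
        params = random_params(model, rng)
        _, trace = simulate_agent(model_id, params, schedule, rng=rng)
        q = trace["q"].to_numpy()
        assert np.all((q >= 0) & (q <= 1))
        if model.has_belief:
            p = trace["p"].to_numpy(dtype=float)
            assert np.all((p >= 0) & (p <= 1))
            if "omega" in params:
                assert np.allclose(trace["intrinsic"], p * params["omega"])


@pytest.mark.parametrize("model_id", list(MODELS))
def test_kernel_matches_class_replay(model_id, m8_session):
    """The compiled likelihood agrees with the per-trial class loop to 1e-10."""
    session, _ = m8_session
    model = get_model(model_id)
    rng = np.random.default_rng(99)
    for _ in range(10):
        params = random_params(model, rng)
        q, _ = replay(model_id, params, session)
        prob = np.clip(np.where(session.own == 1, q, 1 - q), 1e-10, 1 - 1e-10)
        naive = float(np.sum(np.log(prob)))
        theta = np.array([params[n] for n in model.param_names])
        kernel = -float(
            NLL_KERNELS[model_id](theta, session.own, session.partner,
                                  session.own_payoff)
        )
        assert kernel == pytest.approx(naive, abs=1e-10)
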