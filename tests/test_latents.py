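import numpy as np
import pandas as pd
import pytest

from coopdyn.fitting import session_loglik
from coopdyn.latents import (
    conditional_means,
    conditional_table,
    extract_latents,
    group_summary,
    normalize_ratings,
)
from coopdyn.models import replay, simulate_agent
from coopdyn.task import PayoffMatrix, Session


def _session(own, partner):
    own = np.asarray(own, dtype=np.int8)
    partner = np.asarray(partner, dtype=np.int8)
    m = PayoffMatrix()
    pays = np.array([m.payoff_codes(int(o), int(p)) for o, p in zip(own, partner)])
    return Session(own=own, partner=partner, own_payoff=pays[:, 0],
                   partner_payoff=pays[:, 1])


def test_hand_computed_m8_replay():
    """Five-trial asymmetric belief iteration, worked by hand.

    p0 = 0.5, alpha+ = 0.4, alpha- = 0.2, partner C,C,D,C,D gives pre-choice
    beliefs 0.5, 0.7, 0.82, 0.656, 0.7936 and final post-update 0.63488.
    """
    session = _session([1, 1, 1, 1, 1], [1, 1, 0, 1, 0])
    params = dict(alpha_pos=0.4, alpha_neg=0.2, omega=2.0, beta=1.0)
    trace = extract_latents("M8", params, session)
    assert np.allclose(trace["p"], [0.5, 0.7, 0.82, 0.656, 0.7936])
    assert trace["p_post"].iloc[-1] == pytest.approx(0.63488)
    assert np.allclose(trace["PE"], trace.index.map(
        lambda i: session.partner[i] - trace["p"].iloc[i]))
    assert np.allclose(trace["intrinsic"], trace["p"] * 2.0)


def test_extract_latents_degenerate_params(m8_session):
    session, _ = m8_session
    frozen = extract_latents(
        "M8", dict(alpha_pos=0.0, alpha_neg=0.0, omega=3.0, beta=1.0), session)
    assert np.all(frozen["p"] == 0.5)
    assert np.allclose(frozen["intrinsic"], 1.5)
    no_social = extract_latents(
        "M8", dict(alpha_pos=0.3, alpha_neg=0.3, omega=0.0, beta=1.0), session)
    assert np.all(no_social["intrinsic"] == 0.0)


def test_extract_latents_refuses_belief_free_models(m8_session):
    session, _ = m8_session
    for model_id, params in [("M1", {"b": 0.5}), ("M2", {"epsilon": 0.3}),
                             ("M3", {"alpha": 0.2, "beta": 1.0})]:
        with pytest.raises(ValueError, match="no partner-cooperation expectation"):
            extract_latents(model_id, params, session)


def test_replayed_q_matches_likelihood_probabilities(m8_session):
    """extract_latents and session_loglik use the same per-trial q to 1e-12."""
    session, _ = m8_session
    params = dict(alpha_pos=0.55, alpha_neg=0.18, omega=2.4, beta=1.3)
    q, _ = replay("M8", params, session)
    manual = float(np.sum(np.log(np.where(session.own == 1, q, 1 - q))))
    assert session_loglik("M8", params, session) == pytest.approx(manual, abs=1e-12)


def test_conditional_means_toy_examples():
    # partner C,C,D with choices C,D,C
    session = _session([1, 0, 1], [1, 1, 0])
    t1 = conditional_means([session], "choice", 1, "C")
    assert t1.loc[0, "mean"] == pytest.approx(0.5)  # trials 2,3 qualify
    assert t1.loc[0, "n_trials"] == 2
    t2 = conditional_means([session], "choice", 2, "C")
    assert t2.loc[0, "mean"] == 1.0 and t2.loc[0, "n_trials"] == 1
    # no qualifying trials: explicit missing marker
    t3 = conditional_means([session], "choice", 2, "D")
    assert np.isnan(t3.loc[0, "mean"]) and t3.loc[0, "n_trials"] == 0


def test_conditional_k1_partitions_trials(m8_session):
    session, _ = m8_session
    after_c = conditional_means([session], "choice", 1, "C")
    after_d = conditional_means([session], "choice", 1, "D")
    assert after_c.loc[0, "n_trials"] + after_d.loc[0, "n_trials"] == \
        session.n_trials - 1


def test_exact_mode_requires_run_break():
    # partner C,C,C,D: 'at least 1' after-C bins trials 2,3,4; 'exactly 1' only 2
    session = _session([1, 1, 1, 1], [1, 1, 1, 0])
    at_least = conditional_means([session], "choice", 1, "C")
    exact = conditional_means([session], "choice", 1, "C", mode="exact")
    assert at_least.loc[0, "n_trials"] == 3
    assert exact.loc[0, "n_trials"] == 1


def test_conditional_p_monotone_under_cooperation():
    schedule = np.ones(60, dtype=np.int8)
    params = dict(alpha_pos=0.3, alpha_neg=0.2, omega=2.0, beta=2.0)
    session, _ = simulate_agent("M8", params, schedule, rng=3)
    lat = extract_latents("M8", params, session)
    means = [
        conditional_means([session], "p", k, "C", latents=lat).loc[0, "mean"]
        for k in (1, 2, 3)
    ]
    assert means[0] <= means[1] <= means[2]


def test_conditional_table_and_group_summary(m8_session):
    session, _ = m8_session
    session.group = "adult"
    lat = extract_latents(
        "M8", dict(alpha_pos=0.4, alpha_neg=0.2, omega=2.0, beta=2.0), session)
    table = conditional_table([session], variables=("choice", "p", "intrinsic"),
                              latents=lat)
    assert len(table) == 3 * 3 * 2  # variables x k x partner action
    summary = group_summary(table)
    assert {"mean", "se", "n_participants", "n_excluded"} <= set(summary.columns)


def test_conditional_means_input_validation(m8_session):
    session, _ = m8_session
    with pytest.raises(ValueError, match="variable"):
        conditional_means([session], "banana", 1, "C")
    with pytest.raises(ValueError, match="latents"):
        conditional_means([session], "p", 1, "C")
    with pytest.raises(ValueError, match="k must"):
        conditional_means([session], "choice", 0, "C")


def test_normalize_ratings():
    out = normalize_ratings(np.array([0, 5, 9]))
    assert out[0] == 0.0 and out[2] == 1.0
    assert out[1] == pytest.approx(0.5556, abs=1e-4)
    with pytest.raises(ValueError):
        normalize_ratings(np.array([10]))
    with pytest.raises(ValueError):
        normalize_ratings(np.array([-1]))
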