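"""Eight generative models of trial-by-trial cooperation in the rPDG.

Each candidate model maps a (possibly history-dependent) internal state to a
per-trial cooperation probability, and updates that state from the observed
outcome.  The same code path serves likelihood evaluation (state driven by
the participant's observed actions) and agent simulation (actions sampled
from the model).

Model family
------------
M1  baseline            constant cooperation probability b
M2  win-stay/lose-shift repeat after a win (payoff 4 or 6) with prob 1-eps/2,
                        after a loss (0 or 2) with prob eps/2
M3  reward learning     Rescorla-Wagner value of the chosen option, softmax
M4  inequality aversion Fehr-Schmidt utilities at fixed expectation p = 0.5
M5  social reward       mutual cooperation carries a subjective bonus omega:
                        U_c = p(4 + omega), U_d = 4p + 2, fixed p
M6  social reward + RL  p updated by p <- p + alpha (P - p)
M7  + influence         second-order term kappa (Q - q') added to the update
M8  + asymmetric RL     separate rates alpha+ / alpha- for positive/negative
                        prediction errors P - p

Parameter bounds: learning rates and b, eps, kappa in [0, 1]; inverse
temperature beta in [1e-3, 20]; social reward omega in [0, 10]; inequality
aversion phi, nu in [0, 5].
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .task import PayoffMatrix, Session, run_session

#: initial partner-cooperation expectation for belief-based models (M6-M8)
#: and the fixed expectation of M4/M5 — uninformative midpoint.
P_INIT = 0.5
#: initial option values for M3: grand mean of the payoff entries (0+2+4+6)/4.
V_INIT = 3.0
#: belief clip bounds for the influence model (its update is not convex).
P_CLIP = 1e-3

BOUNDS: Mapping[str, tuple[float, float]] = {
    "b": (0.0, 1.0),
    "epsilon": (0.0, 1.0),
    "alpha": (0.0, 1.0),
    "alpha_pos": (0.0, 1.0),
    "alpha_neg": (0.0, 1.0),
    "kappa": (0.0, 1.0),
    "beta": (1e-3, 20.0),
    "omega": (0.0, 10.0),
    "phi": (0.0, 5.0),
    "nu": (0.0, 5.0),
}


# ---------------------------------------------------------------------------
# shared primitives
# ---------------------------------------------------------------------------

def softmax_coop_prob(u_c: float, u_d: float, beta: float) -> float:
    """q(cooperate) = 1 / (1 + exp(beta (U_d - U_c))).

    Larger beta makes choice more deterministic in the utility difference.
    Computed so that swapping the utilities gives an exact complement:
    softmax(a, b, beta) + softmax(b, a, beta) == 1.0 in floating point.
    """
    if not (math.isfinite(u_c) and math.isfinite(u_d)):
        raise ValueError("utilities must be finite")
    if beta <= 0:
        raise ValueError("inverse temperature beta must be positive")
    z = beta * (u_d - u_c)
    if z == 0.0:
        return 0.5
    e = math.exp(-abs(z))
    small = e / (1.0 + e)
    return small if z > 0 else 1.0 - small


def baseline_prob(b: float) -> float:
    """M1: cooperation probability is the parameter itself."""
    if not 0.0 <= b <= 1.0:
        raise ValueError("b must lie in [0, 1]")
    return b


def wsls_prob(epsilon: float, prev_own: int | str | None, prev_payoff: int | None) -> float:
    """M2 cooperation probability from the previous round.

    Repeat the previous choice with probability 1 - eps/2 after a win
    (payoff 4 or 6) and eps/2 after a loss (payoff 0 or 2); with no history
    (first trial) both options are equally likely.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    if prev_own is None:
        return 0.5
    if prev_payoff not in (0, 2, 4, 6):
        raise ValueError(f"payoff {prev_payoff!r} is not a matrix outcome")
    from .task import encode_action

    repeat = 1.0 - epsilon / 2.0 if prev_payoff >= 4 else epsilon / 2.0
    return repeat if encode_action(prev_own) == 1 else 1.0 - repeat


def rl_update(v: float, reward: float, alpha: float) -> float:
    """Rescorla-Wagner update V' = V + alpha (R - V), chosen option only."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return v + alpha * (reward - v)


def expected_payoffs(p: float) -> tuple[float, float, float, float]:
    """Expected tokens (c_self, c_other, d_self, d_other) at expectation p.

    Linear in p under the default 4/2/0/6 matrix: cooperating yields 4p to
    self and 6 - 2p to the partner; defecting 4p + 2 and 2 - 2p.
    """
    return 4.0 * p, 6.0 - 2.0 * p, 4.0 * p + 2.0, 2.0 - 2.0 * p


def fehr_schmidt_utilities(p: float, phi: float, nu: float) -> tuple[float, float]:
    """M4 utilities: expected payoff minus inequality penalties.

    phi weights disadvantageous inequality (partner ahead), nu advantageous
    inequality (self ahead).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if phi < 0 or nu < 0:
        raise ValueError("inequality aversion weights must be non-negative")
    c_self, c_other, d_self, d_other = expected_payoffs(p)
    u_c = c_self - phi * max(c_other - c_self, 0.0) - nu * max(c_self - c_other, 0.0)
    u_d = d_self - phi * max(d_other - d_self, 0.0) - nu * max(d_self - d_other, 0.0)
    return u_c, u_d


def social_reward_utilities(p: float, omega: float) -> tuple[float, float]:
    """M5-M8 utilities: U_c = p (4 + omega), U_d = 4p + 2.

    omega is the additional subjective reward of mutual cooperation; the
    expectation p is fixed for M5 and the trial's belief for M6-M8.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if omega < 0:
        raise ValueError("omega must be non-negative")
    return p * (4.0 + omega), 4.0 * p + 2.0


def expectation_update_basic(p: float, partner: int, alpha: float) -> float:
    """p' = p + alpha (P - p): convex step toward the observed action."""
    return p + alpha * (partner - p)


def expectation_update_asymmetric(
    p: float, partner: int, alpha_pos: float, alpha_neg: float
) -> float:
    """Asymmetric step: rate alpha+ for positive PE, alpha- for negative.

    PE = P - p; the belief is unchanged when PE = 0, and stays in [0, 1]
    without clipping because each branch is a convex combination.
    """
    pe = partner - p
    if pe > 0:
        return p + alpha_pos * pe
    if pe < 0:
        return p + alpha_neg * pe
    return p


def expectation_update_influence(
    p: float, partner: int, own: int, q_prime: float, alpha: float, kappa: float
) -> float:
    """M7 update: first-order step plus kappa (Q - q') second-order step.

    q' is the participant's own cooperation probability as the partner would
    infer it.  The sum can leave [0, 1], so the result is clipped to
    [1e-3, 1 - 1e-3].
    """
    p_new = p + alpha * (partner - p) + kappa * (own - q_prime)
    return min(max(p_new, P_CLIP), 1.0 - P_CLIP)


# ---------------------------------------------------------------------------
# model classes
# ---------------------------------------------------------------------------

class ChoiceModel:
    """Base class: parameter signature plus the state-machine interface."""

    id: str = ""
    label: str = ""
    param_names: tuple[str, ...] = ()
    has_belief: bool = False  # carries a partner-cooperation expectation p

    @property
    def k(self) -> int:
        """Number of free parameters (for AICc)."""
        return len(self.param_names)

    @property
    def bounds(self) -> list[tuple[float, float]]:
        return [BOUNDS[name] for name in self.param_names]

    def validate_params(self, params: Mapping[str, float]) -> None:
        if set(params) != set(self.param_names):
            raise ValueError(
                f"{self.id} expects parameters {self.param_names}, got {tuple(params)}"
            )
        for name in self.param_names:
            lo, hi = BOUNDS[name]
            if not lo <= params[name] <= hi:
                raise ValueError(f"{name}={params[name]} outside [{lo}, {hi}]")

    def params_from_array(self, theta: Sequence[float]) -> dict[str, float]:
        return dict(zip(self.param_names, map(float, theta)))

    def init_state(self, params: Mapping[str, float]) -> dict:
        raise NotImplementedError

    def coop_prob(self, params: Mapping[str, float], state: dict) -> float:
        raise NotImplementedError

    def update(self, params, state: dict, own: int, partner: int, payoff: int) -> None:
        """Advance the state after one round (default: no learning)."""

    def latents(self, params, state: dict) -> dict:
        """Pre-choice latent variables for the trace (model-specific keys)."""
        return {}


class Baseline(ChoiceModel):
    id = "M1"
    label = "baseline"
    param_names = ("b",)

    def init_state(self, params):
        return {}

    def coop_prob(self, params, state):
        return baseline_prob(params["b"])


class WinStayLoseShift(ChoiceModel):
    id = "M2"
    label = "win-stay/lose-shift"
    param_names = ("epsilon",)

    def init_state(self, params):
        return {"prev_own": None, "prev_payoff": None}

    def coop_prob(self, params, state):
        return wsls_prob(params["epsilon"], state["prev_own"], state["prev_payoff"])

    def update(self, params, state, own, partner, payoff):
        state["prev_own"] = own
        state["prev_payoff"] = payoff


class RewardLearning(ChoiceModel):
    id = "M3"
    label = "reward learning"
    param_names = ("alpha", "beta")

    def init_state(self, params):
        return {"V_c": V_INIT, "V_d": V_INIT}

    def coop_prob(self, params, state):
        return softmax_coop_prob(state["V_c"], state["V_d"], params["beta"])

    def update(self, params, state, own, partner, payoff):
        key = "V_c" if own == 1 else "V_d"
        state[key] = rl_update(state[key], payoff, params["alpha"])

    def latents(self, params, state):
        return {"V_c": state["V_c"], "V_d": state["V_d"]}


class InequalityAversion(ChoiceModel):
    id = "M4"
    label = "inequality aversion"
    param_names = ("phi", "nu", "beta")
    has_belief = True  # static expectation, fixed at 0.5

    def init_state(self, params):
        return {"p": P_INIT}

    def coop_prob(self, params, state):
        u_c, u_d = fehr_schmidt_utilities(state["p"], params["phi"], params["nu"])
        return softmax_coop_prob(u_c, u_d, params["beta"])

    def latents(self, params, state):
        u_c, u_d = fehr_schmidt_utilities(state["p"], params["phi"], params["nu"])
        return {"p": state["p"], "U_c": u_c, "U_d": u_d}


class SocialReward(ChoiceModel):
    id = "M5"
    label = "social reward"
    param_names = ("omega", "beta")
    has_belief = True  # static expectation, fixed at 0.5

    def init_state(self, params):
        return {"p": P_INIT}

    def coop_prob(self, params, state):
        u_c, u_d = social_reward_utilities(state["p"], params["omega"])
        return softmax_coop_prob(u_c, u_d, params["beta"])

    def latents(self, params, state):
        u_c, u_d = social_reward_utilities(state["p"], params["omega"])
        return {"p": state["p"], "U_c": u_c, "U_d": u_d,
                "intrinsic": state["p"] * params["omega"]}


class SocialRewardRL(SocialReward):
    id = "M6"
    label = "social reward + RL"
    param_names = ("alpha", "omega", "beta")

    def update(self, params, state, own, partner, payoff):
        state["p"] = expectation_update_basic(state["p"], partner, params["alpha"])


class SocialRewardInfluence(SocialReward):
    id = "M7"
    label = "social reward + influence"
    param_names = ("alpha", "kappa", "omega", "beta")

    def update(self, params, state, own, partner, payoff):
        q_prime = self.coop_prob(params, state)  # own prob as the partner infers it
        state["p"] = expectation_update_influence(
            state["p"], partner, own, q_prime, params["alpha"], params["kappa"]
        )

    def latents(self, params, state):
        out = super().latents(params, state)
        out["q_prime"] = self.coop_prob(params, state)
        return out


class SocialRewardAsymmetricRL(SocialReward):
    id = "M8"
    label = "social reward + asymmetric RL"
    param_names = ("alpha_pos", "alpha_neg", "omega", "beta")

    def update(self, params, state, own, partner, payoff):
        state["p"] = expectation_update_asymmetric(
            state["p"], partner, params["alpha_pos"], params["alpha_neg"]
        )


MODELS: dict[str, ChoiceModel] = {
    m.id: m
    for m in (
        Baseline(),
        WinStayLoseShift(),
        RewardLearning(),
        InequalityAversion(),
        SocialReward(),
        SocialRewardRL(),
        SocialRewardInfluence(),
        SocialRewardAsymmetricRL(),
    )
}

MODEL_IDS = tuple(MODELS)


def get_model(model_id: str) -> ChoiceModel:
    if model_id not in MODELS:
        raise KeyError(f"unknown model {model_id!r}; known: {MODEL_IDS}")
    return MODELS[model_id]


def trial_coop_prob(model_id: str, params: Mapping[str, float], state: dict) -> float:
    """Dispatch: cooperation probability of ``model_id`` in ``state``."""
    model = get_model(model_id)
    model.validate_params(params)
    return model.coop_prob(params, state)


# ---------------------------------------------------------------------------
# replay and simulation
# ---------------------------------------------------------------------------

TRACE_COLUMNS = [
    "trial", "q", "p", "U_c", "U_d", "V_c", "V_d", "q_prime",
    "PE", "intrinsic", "p_post",
]


class ModelAgent:
    """Adapter exposing a ChoiceModel as a policy for task.run_session.

    Records the pre-choice latent row at every ``coop_prob`` call and the
    post-update belief at every ``update``, so a single pass yields both the
    behavior and the latent trace.
    """

    def __init__(self, model: ChoiceModel, params: Mapping[str, float]):
        model.validate_params(params)
        self.model = model
        self.params = dict(params)
        self.state = model.init_state(self.params)
        self.rows: list[dict] = []

    def coop_prob(self) -> float:
        row = {"trial": len(self.rows) + 1}
        row.update(self.model.latents(self.params, self.state))
        row["q"] = self.model.coop_prob(self.params, self.state)
        self.rows.append(row)
        return row["q"]

    def update(self, own: int, partner: int, payoff: int) -> None:
        row = self.rows[-1]
        if "p" in row:
            row["PE"] = partner - row["p"]
        self.model.update(self.params, self.state, own, partner, payoff)
        if self.model.has_belief:
            row["p_post"] = self.state["p"]

    def trace(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows).reindex(columns=TRACE_COLUMNS)


def replay(
    model_id: str, params: Mapping[str, float], session: Session
) -> tuple[np.ndarray, pd.DataFrame]:
    """Drive the model with a participant's observed actions.

    Returns the per-trial probability the model assigns to *cooperation*
    (not to the observed choice) and the latent trace.  This deterministic
    pass underlies both the likelihood and latent-variable extraction.
    """
    agent = ModelAgent(get_model(model_id), params)
    for t in range(session.n_trials):
        agent.coop_prob()
        agent.update(int(session.own[t]), int(session.partner[t]),
                     int(session.own_payoff[t]))
    trace = agent.trace()
    return trace["q"].to_numpy(), trace


def simulate_agent(
    model_id: str,
    params: Mapping[str, float],
    schedule: np.ndarray,
    rng: np.random.Generator | int | None = None,
    matrix: PayoffMatrix | None = None,
    participant_id: str = "p0",
    group: str = "",
) -> tuple[Session, pd.DataFrame]:
    """Simulate a model agent against a scheduled partner.

    Each choice is sampled from the model's cooperation probability, then the
    model is updated with the realized outcome.  The trace records the
    pre-choice state (and post-update belief as ``p_post``).
    """
    agent = ModelAgent(get_model(model_id), params)
    session = run_session(
        agent, schedule, rng=rng, matrix=matrix,
        participant_id=participant_id, group=group,
    )
    return session, agent.trace()
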