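"""Trial-by-trial hidden variables and conditional-cooperation analyses.

From a fitted belief-based model the observed session is replayed
deterministically to recover the partner-cooperation expectation p_t, the
option utilities, the model's choice probability q_t and the intrinsic
reward for reciprocity p_t * omega.  The binning analysis then asks how a
variable (the cooperation indicator, p, or p * omega) behaves after the
partner acted consistently — cooperated or defected on each of the last
k = 1, 2, 3 trials.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import get_model, replay
from .task import Session, encode_action

VARIABLES = ("choice", "p", "intrinsic")
BELIEF_MODELS = ("M4", "M5", "M6", "M7", "M8")


def extract_latents(
    model_id: str, params: Mapping[str, float], session: Session
) -> pd.DataFrame:
    """Replay a session through a fitted model; return its latent trace.

    Only models that carry a partner-cooperation expectation (M4-M8) have
    p-based latents; for the others this raises.  The returned q_t equals
    the per-trial probability the likelihood uses for the same inputs.
    """
    model = get_model(model_id)
    if not model.has_belief:
        raise ValueError(
            f"{model_id} has no partner-cooperation expectation; "
            "latent extraction requires one of " + ", ".join(BELIEF_MODELS)
        )
    _, trace = replay(model_id, params, session)
    trace = trace.copy()
    trace.insert(0, "participant_id", session.participant_id)
    trace.insert(1, "group", session.group)
    return trace


def extract_cohort_latents(
    fits: pd.DataFrame, sessions: Sequence[Session], model_id: str
) -> pd.DataFrame:
    """Latent traces for every session, using each participant's MLE fit."""
    model = get_model(model_id)
    by_id = fits[fits["model"] == model_id].set_index("participant_id")
    traces = []
    for session in sessions:
        row = by_id.loc[session.participant_id]
        params = {name: float(row[name]) for name in model.param_names}
        traces.append(extract_latents(model_id, params, session))
    return pd.concat(traces, ignore_index=True)


def normalize_ratings(ratings) -> np.ndarray:
    """Map 0-9 probe ratings onto [0, 1] by dividing by 9."""
    arr = np.asarray(ratings)
    if arr.size and (np.any(arr < 0) or np.any(arr > 9) or
                     not np.issubdtype(arr.dtype, np.integer)):
        raise ValueError("ratings must be integers in 0..9")
    return arr / 9.0


def _qualifying_mask(partner: np.ndarray, k: int, a_code: int, mode: str) -> np.ndarray:
    """Boolean mask over trials whose last k partner actions all equal a."""
    n = partner.size
    mask = np.zeros(n, dtype=bool)
    for i in range(k, n):
        if np.all(partner[i - k:i] == a_code):
            if mode == "exact" and i - k - 1 >= 0 and partner[i - k - 1] == a_code:
                continue
            mask[i] = True
    return mask


def conditional_means(
    sessions: Sequence[Session],
    variable: str,
    k: int,
    action: str,
    latents: pd.DataFrame | None = None,
    mode: str = "at_least",
) -> pd.DataFrame:
    """Per-participant mean of ``variable`` after k consistent partner actions.

    A trial t qualifies when the partner's actions at t-1..t-k all equal
    ``action`` (so t > k).  ``mode='at_least'`` (default) places a trial in
    every run length it satisfies; ``mode='exact'`` additionally requires
    the action at t-k-1 (when it exists) to differ.  Participants with no
    qualifying trial get mean = NaN and n_trials = 0.

    For ``variable`` in {'p', 'intrinsic'} a latents table aligned on
    (participant_id, trial) must be supplied.
    """
    if variable not in VARIABLES:
        raise ValueError(f"variable must be one of {VARIABLES}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode not in ("at_least", "exact"):
        raise ValueError("mode must be 'at_least' or 'exact'")
    a_code = encode_action(action)
    if variable != "choice":
        if latents is None:
            raise ValueError(f"variable {variable!r} needs a latents table")
        lat_by_id = dict(tuple(latents.groupby("participant_id")))

    rows = []
    for session in sessions:
        mask = _qualifying_mask(session.partner, k, a_code, mode)
        if variable == "choice":
            values = session.own.astype(float)
        else:
            tr = lat_by_id[session.participant_id].sort_values("trial")
            if len(tr) != session.n_trials:
                raise ValueError(
                    f"latents misaligned for {session.participant_id}"
                )
            values = tr[variable].to_numpy(dtype=float)
        n_q = int(mask.sum())
        rows.append(
            {
                "participant_id": session.participant_id,
                "group": session.group,
                "variable": variable,
                "k": k,
                "partner_action": action,
                "mean": float(values[mask].mean()) if n_q else np.nan,
                "n_trials": n_q,
            }
        )
    return pd.DataFrame(rows)


def conditional_table(
    sessions: Sequence[Session],
    variables: Sequence[str] = ("choice",),
    ks: Sequence[int] = (1, 2, 3),
    actions: Sequence[str] = ("C", "D"),
    latents: pd.DataFrame | None = None,
    mode: str = "at_least",
) -> pd.DataFrame:
    """Long-format table over all (variable, k, partner action) conditions."""
    parts = [
        conditional_means(sessions, v, k, a, latents=latents, mode=mode)
        for v in variables
        for k in ks
        for a in actions
    ]
    return pd.concat(parts, ignore_index=True)


def group_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Across-participant group mean and standard error per condition.

    Participants without qualifying trials (NaN means) are excluded; the
    surviving count is reported so exclusions are visible.
    """
    def agg(g: pd.DataFrame) -> pd.Series:
        m = g["mean"].dropna()
        return pd.Series(
            {
                "mean": m.mean(),
                "se": m.std(ddof=1) / np.sqrt(len(m)) if len(m) > 1 else np.nan,
                "n_participants": len(m),
                "n_excluded": int(g["mean"].isna().sum()),
            }
        )

    keys = ["group", "variable", "k", "partner_action"]
    return table.groupby(keys, sort=True).apply(agg, include_groups=False).reset_index()
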