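"""Random-effects group Bayesian model selection (BMS).

Treats the model identity of each participant as a random effect: model
frequencies r in the population get a Dirichlet prior, each participant's
model assignment a categorical draw from r, and the per-participant model
log-evidence (approximated here as -AICc/2) enters the likelihood.  A
variational scheme yields the Dirichlet posterior, from which come

* expected model frequencies  alpha / sum(alpha),
* exceedance probability (XP): P(r_m is the largest frequency),
* Bayesian omnibus risk (BOR): posterior probability that observed
  differences in model frequencies arose by chance (all equal), and
* protected exceedance probability  PEP = XP (1 - BOR) + BOR / K,

the chance-corrected group-level measure used for model selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betainc, digamma, gammaln, logsumexp


@dataclass
class BMSResult:
    models: tuple[str, ...]
    alpha: np.ndarray  # Dirichlet concentration per model
    expected_freq: np.ndarray
    xp: np.ndarray
    bor: float
    pep: np.ndarray
    n_subjects: int

    def to_dict(self) -> dict:
        out = {"bor": self.bor, "n_subjects": self.n_subjects}
        for i, m in enumerate(self.models):
            out[f"alpha_{m}"] = float(self.alpha[i])
            out[f"expected_freq_{m}"] = float(self.expected_freq[i])
            out[f"xp_{m}"] = float(self.xp[i])
            out[f"pep_{m}"] = float(self.pep[i])
        return out


def evidence_from_fits(fits: pd.DataFrame) -> pd.DataFrame:
    """Participant x model log-evidence grid from a fits table, as -AICc/2."""
    wide = fits.pivot(index="participant_id", columns="model", values="aicc")
    return -wide / 2.0


def _variational_dirichlet(log_ev: np.ndarray, prior_alpha: float, tol: float,
                           max_iter: int) -> tuple[np.ndarray, np.ndarray]:
    n, k = log_ev.shape
    alpha0 = np.full(k, prior_alpha)
    alpha = alpha0.copy()
    for _ in range(max_iter):
        log_u = log_ev + (digamma(alpha) - digamma(alpha.sum()))
        log_g = log_u - logsumexp(log_u, axis=1, keepdims=True)
        g = np.exp(log_g)
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    return alpha, g


def _xp_exact_k2(alpha: np.ndarray) -> np.ndarray:
    """For K=2, P(r_1 > r_2) = P(r_1 > 1/2) via the regularized Beta CDF."""
    xp1 = 1.0 - betainc(alpha[0], alpha[1], 0.5)
    return np.array([xp1, 1.0 - xp1])


def _xp_sampling(alpha: np.ndarray, n_samples: int, rng: np.random.Generator,
                 batch: int = 200_000) -> np.ndarray:
    """Monte-Carlo exceedance probability from seeded Dirichlet draws."""
    k = alpha.size
    counts = np.zeros(k, dtype=np.int64)
    remaining = n_samples
    while remaining > 0:
        m = min(batch, remaining)
        draws = rng.dirichlet(alpha, size=m)
        counts += np.bincount(np.argmax(draws, axis=1), minlength=k)
        remaining -= m
    return counts / n_samples


def _dirichlet_free_energy(log_ev, alpha0, alpha, g) -> float:
    """Variational free energy of the random-effects model at (alpha, g)."""
    e_ln_r = digamma(alpha) - digamma(alpha.sum())
    f = float(np.sum(g * log_ev))
    f += float(np.sum(g * e_ln_r))
    # E[log p(r)] - E[log q(r)]  (Dirichlet prior vs posterior)
    f += float(
        gammaln(alpha0.sum()) - gammaln(alpha0).sum()
        + np.sum((alpha0 - 1.0) * e_ln_r)
    )
    f -= float(
        gammaln(alpha.sum()) - gammaln(alpha).sum()
        + np.sum((alpha - 1.0) * e_ln_r)
    )
    # entropy of the assignment posterior
    with np.errstate(divide="ignore", invalid="ignore"):
        f -= float(np.sum(np.where(g > 0, g * np.log(g), 0.0)))
    return f


def _null_free_energy(log_ev: np.ndarray) -> float:
    """Evidence of the null model: every frequency fixed at 1/K."""
    n, k = log_ev.shape
    return float(np.sum(logsumexp(log_ev, axis=1) - np.log(k)))


def group_bms(
    evidence: pd.DataFrame | np.ndarray,
    prior_alpha: float = 1.0,
    seed: int | None = None,
    n_samples: int = 1_000_000,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> BMSResult:
    """Group BMS from a participants x models log-evidence grid.

    The exceedance probability uses the exact Beta-CDF form when K = 2 and
    seeded Dirichlet sampling (``n_samples`` draws) otherwise.
    """
    if isinstance(evidence, pd.DataFrame):
        models = tuple(str(c) for c in evidence.columns)
        log_ev = evidence.to_numpy(dtype=float)
    else:
        log_ev = np.asarray(evidence, dtype=float)
        models = tuple(f"M{i + 1}" for i in range(log_ev.shape[1]))
    if log_ev.ndim != 2 or log_ev.shape[0] < 2 or log_ev.shape[1] < 2:
        raise ValueError("group BMS needs >= 2 participants and >= 2 models")
    if not np.all(np.isfinite(log_ev)):
        raise ValueError("log-evidence grid contains non-finite entries")
    if prior_alpha <= 0:
        raise ValueError("prior_alpha must be positive")

    # subtracting the per-subject max is a likelihood rescaling (no effect
    # on the posterior) that keeps the exponentials in range
    log_ev = log_ev - log_ev.max(axis=1, keepdims=True)
    alpha0 = np.full(log_ev.shape[1], float(prior_alpha))
    alpha, g = _variational_dirichlet(log_ev, prior_alpha, tol, max_iter)

    if alpha.size == 2:
        xp = _xp_exact_k2(alpha)
    else:
        xp = _xp_sampling(alpha, n_samples, np.random.default_rng(seed))

    f1 = _dirichlet_free_energy(log_ev, alpha0, alpha, g)
    f0 = _null_free_energy(log_ev)
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    pep = xp * (1.0 - bor) + bor / alpha.size

    return BMSResult(
        models=models,
        alpha=alpha,
        expected_freq=alpha / alpha.sum(),
        xp=xp,
        bor=bor,
        pep=pep,
        n_subjects=log_ev.shape[0],
    )


def select_winning_model(result: BMSResult, deltas: pd.DataFrame) -> dict:
    """Group-level selection report.

    Combines the PEP argmax (ties listed, never silently broken) with the
    per-model mean AICc difference and the fraction of participants each
    model fits best.
    """
    pep = pd.Series(result.pep, index=list(result.models))
    winners = [m for m in result.models if np.isclose(pep[m], pep.max(), atol=1e-12)]
    best_counts = (deltas == 0).sum(axis=0)
    return {
        "winner": winners[0] if len(winners) == 1 else None,
        "tied_winners": winners,
        "pep": pep.to_dict(),
        "mean_delta_aicc": deltas.mean(axis=0).to_dict(),
        "fraction_best_fit": (best_counts / len(deltas)).to_dict(),
        "bor": result.bor,
    }
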