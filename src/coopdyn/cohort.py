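"""Synthetic two-group study cohort.

Generates adolescent and adult groups with the study's structure (127 + 134
participants, 120-trial sessions, probes every 15 rounds) from
group-specific distributions over the asymmetric social-reward model's (M8)
parameters.  Group means are chosen to produce the qualitative developmental
pattern of interest — adolescents with a higher positive and lower negative
learning rate, weaker cooperation preference omega, and higher inverse
temperature beta — and every distribution is configurable.

Self-report probes are modeled as a noisy readout of the agent's own belief:
rating = round(9 * clip(p_t + N(0, probe_noise_sd), 0, 1)) after the probe
trial's update.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .models import BOUNDS, simulate_agent
from .task import ScheduleConfig, Session, generate_partner_schedule, probe_trials

GENERATOR_MODEL = "M8"

ADOLESCENT_DIST: Mapping[str, tuple[float, float]] = {
    "alpha_pos": (0.50, 0.15),
    "alpha_neg": (0.20, 0.10),
    "omega": (1.2, 0.6),
    "beta": (2.0, 0.7),
}
ADULT_DIST: Mapping[str, tuple[float, float]] = {
    "alpha_pos": (0.35, 0.15),
    "alpha_neg": (0.32, 0.10),
    "omega": (2.0, 0.6),
    "beta": (1.4, 0.5),
}

PROBE_COLUMNS = ["participant_id", "trial", "rating"]
PARAM_COLUMNS = ["participant_id", "group", "alpha_pos", "alpha_neg", "omega", "beta"]


@dataclass(frozen=True)
class CohortConfig:
    n_adolescents: int = 127
    n_adults: int = 134
    adolescent_dist: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(ADOLESCENT_DIST)
    )
    adult_dist: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(ADULT_DIST)
    )
    probe_noise_sd: float = 0.1
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    shared_sequence: bool = False  # one realized partner sequence for everyone
    seed: int | None = None

    def __post_init__(self):
        if self.n_adolescents < 1 or self.n_adults < 1:
            raise ValueError("group sizes must be >= 1")
        if self.probe_noise_sd < 0:
            raise ValueError("probe_noise_sd must be >= 0")
        for dist in (self.adolescent_dist, self.adult_dist):
            for name, (mean, sd) in dist.items():
                if name not in BOUNDS:
                    raise ValueError(f"unknown parameter {name!r}")
                if sd <= 0:
                    raise ValueError(f"degenerate distribution for {name}: sd={sd}")

    @property
    def n_participants(self) -> int:
        return self.n_adolescents + self.n_adults


@dataclass
class Participant:
    id: str
    group: str
    true_params: dict[str, float]
    session: Session
    probes: pd.DataFrame
    trace: pd.DataFrame


@dataclass
class Cohort:
    config: CohortConfig
    participants: list[Participant]

    def sessions(self) -> list[Session]:
        return [p.session for p in self.participants]

    def sessions_frame(self) -> pd.DataFrame:
        return pd.concat([p.session.to_frame() for p in self.participants],
                         ignore_index=True)

    def probes_frame(self) -> pd.DataFrame:
        return pd.concat([p.probes for p in self.participants], ignore_index=True)

    def params_frame(self) -> pd.DataFrame:
        rows = [
            {"participant_id": p.id, "group": p.group, **p.true_params}
            for p in self.participants
        ]
        return pd.DataFrame(rows, columns=PARAM_COLUMNS)


def draw_truncated_normal(
    dist: Mapping[str, tuple[float, float]], rng: np.random.Generator
) -> dict[str, float]:
    """One parameter vector, each entry TN(mean, sd) truncated at its bounds."""
    out = {}
    for name, (mean, sd) in dist.items():
        lo, hi = BOUNDS[name]
        a, b = (lo - mean) / sd, (hi - mean) / sd
        out[name] = float(sp_stats.truncnorm.rvs(a, b, loc=mean, scale=sd,
                                                 random_state=rng))
    return out


def _probe_ratings(
    trace: pd.DataFrame, cfg: CohortConfig, rng: np.random.Generator,
    participant_id: str,
) -> pd.DataFrame:
    ts = probe_trials(cfg.schedule)
    p_post = trace.set_index("trial")["p_post"].loc[ts].to_numpy()
    noisy = np.clip(p_post + rng.normal(0.0, cfg.probe_noise_sd, size=ts.size)
                    if cfg.probe_noise_sd > 0 else p_post, 0.0, 1.0)
    ratings = np.rint(9.0 * noisy).astype(int)
    return pd.DataFrame(
        {"participant_id": participant_id, "trial": ts, "rating": ratings}
    )


def generate_cohort(cfg: CohortConfig) -> Cohort:
    """Simulate the full two-group cohort; bit-reproducible given cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    shared = generate_partner_schedule(cfg.schedule, rng) if cfg.shared_sequence else None

    participants: list[Participant] = []
    specs = [("adolescent", cfg.adolescent_dist)] * cfg.n_adolescents + [
        ("adult", cfg.adult_dist)
    ] * cfg.n_adults
    width = len(str(len(specs)))
    for i, (group, dist) in enumerate(specs):
        pid = f"{group[:3]}{i + 1:0{width}d}"
        params = draw_truncated_normal(dist, rng)
        schedule = shared if shared is not None else generate_partner_schedule(
            cfg.schedule, rng
        )
        session, trace = simulate_agent(
            GENERATOR_MODEL, params, schedule, rng=rng,
            participant_id=pid, group=group,
        )
        probes = _probe_ratings(trace, cfg, rng, pid)
        participants.append(
            Participant(id=pid, group=group, true_params=params,
                        session=session, probes=probes, trace=trace)
        )
    return Cohort(config=cfg, participants=participants)


def export_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write sessions, probes and ground-truth parameter tables as CSV.

    The ground truth goes to a separate file (true_params.csv) so that
    fitting runs consuming sessions.csv cannot see it by accident.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sessions": out / "sessions.csv",
        "probes": out / "probes.csv",
        "true_params": out / "true_params.csv",
    }
    cohort.sessions_frame().to_csv(paths["sessions"], index=False)
    cohort.probes_frame().to_csv(paths["probes"], index=False)
    cohort.params_frame().to_csv(paths["true_params"], index=False)
    return paths
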