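"""Task performance measures and the trial-by-trial value regressor.

Performance is summarized as wins (rewarded trials; 1 monetary unit each),
the fraction of non-missed trials on which the objectively better bandit was
chosen, and the fraction of switches that moved to the objectively better
bandit. A switch is any non-missed trial whose choice differs from the
previous non-missed choice; ties in the true probabilities count as optimal.

The value regressor is the expected value Q of the chosen option at choice
time, per trial — the quantity used as a parametric modulator of
choice-locked brain activity in model-based fMRI analyses. Missed trials are
absent from the regressor (no choice event exists for them).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .observer_model import TrialLatents
from .task_environment import SessionData

__all__ = ["PerformanceSummary", "summarize_performance", "extract_value_regressor"]


@dataclass(frozen=True)
class PerformanceSummary:
    """Session-level performance measures."""

    wins: int
    pct_optimal_choice: float
    pct_optimal_switch: float
    n_missed: int

    def to_dict(self) -> dict:
        return {
            "wins": self.wins,
            "pct_optimal_choice": self.pct_optimal_choice,
            "pct_optimal_switch": self.pct_optimal_switch,
            "n_missed": self.n_missed,
        }


def summarize_performance(session: SessionData) -> PerformanceSummary:
    """Wins, optimal-choice fraction and optimal-switch fraction for a session.

    The optimal-switch denominator is the number of switch trials; if no
    switches occurred the fraction is NaN.
    """
    wins = 0
    n_opt_choice = 0
    n_obs = 0
    n_switch = 0
    n_opt_switch = 0
    prev_choice: int | None = None
    for tr in session.trials:
        if np.any(~np.isfinite(tr.p_true)):
            raise ValueError(f"trial {tr.t}: true probabilities missing")
        if tr.missed:
            continue
        n_obs += 1
        wins += tr.reward
        p0, p1 = tr.p_true
        best_p = max(p0, p1)
        optimal = tr.p_true[tr.choice] >= best_p  # ties count as optimal
        n_opt_choice += optimal
        if prev_choice is not None and tr.choice != prev_choice:
            n_switch += 1
            n_opt_switch += optimal
        prev_choice = tr.choice
    return PerformanceSummary(
        wins=int(wins),
        pct_optimal_choice=n_opt_choice / n_obs if n_obs else float("nan"),
        pct_optimal_switch=n_opt_switch / n_switch if n_switch else float("nan"),
        n_missed=session.n_missed(),
    )


def extract_value_regressor(
    session: SessionData, latents: Sequence[TrialLatents]
) -> pd.DataFrame:
    """Q of the chosen option at choice time, one row per non-missed trial.

    Columns ``trial`` (1-based) and ``q_chosen``; values lie strictly inside
    (0, 1) and the first observed trial has value 0.5 (uniform prior belief).
    """
    if len(latents) != session.n_trials:
        raise ValueError(
            f"latents length {len(latents)} does not match session "
            f"({session.n_trials} trials)"
        )
    rows = []
    for tr, la in zip(session.trials, latents):
        if la.t != tr.t:
            raise ValueError(f"latents misaligned at trial {tr.t}")
        if tr.missed:
            continue
        rows.append((tr.t, float(la.Q[tr.choice])))
    return pd.DataFrame(rows, columns=["trial", "q_chosen"])
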