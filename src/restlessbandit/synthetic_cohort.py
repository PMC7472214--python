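"""Synthetic subject cohorts with the covariate structure the group analysis
assumes.

The generator draws from a linear-Gaussian structural model on standardized
variables: a binary age contrast (old vs. young) drives white-matter
integrity (FA in the accumbens-vmPFC tract) and dopamine D1 receptor
availability (BP_ND in accumbens) with independent residuals, both of which
drive the vmPFC value-signal strength (q_signal), which alone drives task
wins:

    fa_z   = b_age_fa   * age_z + e_fa
    bpnd_z = b_age_bpnd * age_z + e_bp     (e_fa, e_bp independent)
    q_z    = b_fa_q * fa_z + b_bpnd_q * bpnd_z + e_q
    wins_z = b_q_wins * q_z + e_w

Residual variances are set so every structural variable has unit variance
(generation fails when the paths alone imply variance >= 1). FA and
BP_ND correlate only through age, so their age-partialled correlation is
zero by construction. FA is mapped to its raw scale so that the configured
group means are honored exactly and the configured group sds in pooled form;
BP_ND and wins get plausible raw scales (affine maps leave every
standardized statistic unchanged).

Wins can instead be generated mechanistically: q_signal is mapped through a
logistic link to a softmax temperature and a full bandit session is simulated
per subject, linking the cohort to the task model end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .observer_model import ObserverAgent, ObserverParams
from .task_environment import generate_walk, simulate_session
from .behavior_metrics import summarize_performance

__all__ = ["CohortSpec", "generate_cohort", "default_paperlike_spec"]


class ConfigurationError(ValueError):
    """Infeasible or inconsistent cohort specification."""


# raw scales for variables whose generating model is standardized; affine
# maps do not affect standardized coefficients or correlations
_BPND_LOC, _BPND_SCALE = 2.0, 0.25
_WINS_LOC, _WINS_SCALE = 128.21, 10.0
_AGE_RANGE_YOUNG = (19, 32)
_AGE_RANGE_OLD = (66, 75)

# logistic link from q_signal to softmax temperature in mechanistic mode
_MECH_BETA_LO, _MECH_BETA_HI, _MECH_SLOPE = 0.2, 6.0, 1.0
_MECH_OBSERVER = dict(omega=0.4, lambda_forget=0.15, upsilon=0.3, kappa=0.3)


@dataclass(frozen=True)
class CohortSpec:
    """Group sizes, standardized path coefficients and raw FA scale.

    ``effects`` maps path names (``age_fa``, ``age_bpnd``, ``fa_q``,
    ``bpnd_q``, ``q_wins``) to standardized coefficients; age is coded so
    that positive values mean higher in the old group. Residual sds for the
    q_signal and wins equations are derived from the paths unless given.
    """

    n_young: int = 23
    n_old: int = 22
    effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    q_resid_sd: float | None = None
    wins_resid_sd: float | None = None
    fa_mean_young: float = 0.34
    fa_mean_old: float = 0.31
    fa_sd_young: float = 0.03
    fa_sd_old: float = 0.02
    wins_mode: Literal["linear", "mechanistic"] = "linear"
    n_trials: int = 220
    schedule_seed: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_young < 2 or self.n_old < 2:
            raise ConfigurationError("each group needs at least 2 subjects")
        missing = set(DEFAULT_EFFECTS) - set(self.effects)
        if missing:
            raise ConfigurationError(f"effect map misses paths: {sorted(missing)}")
        for name in ("age_fa", "age_bpnd"):
            if abs(self.effects[name]) >= 1:
                raise ConfigurationError(f"|{name}| must be < 1 for unit variance")
        for sd in (self.q_resid_sd, self.wins_resid_sd):
            if sd is not None and sd <= 0:
                raise ConfigurationError("residual sds must be positive")

    def resolved_residual_sds(self) -> tuple[float, float]:
        """(q_resid_sd, wins_resid_sd), deriving unit-variance defaults."""
        eff = self.effects
        rho = eff["age_fa"] * eff["age_bpnd"]  # corr(fa_z, bpnd_z)
        var_q_struct = (
            eff["fa_q"] ** 2
            + eff["bpnd_q"] ** 2
            + 2.0 * eff["fa_q"] * eff["bpnd_q"] * rho
        )
        if self.q_resid_sd is None:
            if var_q_struct >= 1.0:
                raise ConfigurationError(
                    "q_signal paths imply variance >= 1; no admissible residual sd"
                )
            q_sd = float(np.sqrt(1.0 - var_q_struct))
        else:
            q_sd = self.q_resid_sd
        if self.wins_resid_sd is None:
            if eff["q_wins"] ** 2 >= 1.0:
                raise ConfigurationError(
                    "q_wins path implies variance >= 1; no admissible residual sd"
                )
            w_sd = float(np.sqrt(1.0 - eff["q_wins"] ** 2))
        else:
            w_sd = self.wins_resid_sd
        return q_sd, w_sd


def _implied_age_fa_path(mean_young, mean_old, sd_young, sd_old) -> float:
    """Standardized age->FA path implied by the configured group means/sds
    (balanced-group population correlation between the age contrast and FA)."""
    half_gap = 0.5 * abs(mean_young - mean_old)
    within = 0.5 * (sd_young**2 + sd_old**2)
    total_sd = float(np.sqrt(half_gap**2 + within))
    sign = -1.0 if mean_old < mean_young else 1.0
    return sign * half_gap / total_sd


DEFAULT_EFFECTS: dict[str, float] = {
    # age -> FA derived from the published FA group means/sds
    "age_fa": _implied_age_fa_path(0.34, 0.31, 0.03, 0.02),
    "age_bpnd": -0.45,
    # multivariate standardized coefficients of the published regressions
    "fa_q": 0.49,
    "bpnd_q": 0.41,
    "q_wins": 0.54,
}


def default_paperlike_spec(seed: int = 0) -> CohortSpec:
    """The documented default cohort: 23 young + 22 old, FA group means
    0.34/0.31 (sd 0.03/0.02), path coefficients mirroring the published
    multivariate estimates."""
    return CohortSpec(seed=seed)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort; deterministic given ``spec.seed``.

    Returns a DataFrame with columns subject_id, age_group, age, fa, bpnd,
    q_signal, wins.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_young + spec.n_old
    old = np.r_[np.zeros(spec.n_young), np.ones(spec.n_old)]
    # standardized age contrast (exact population standardization)
    p_old = spec.n_old / n
    age_z = (old - p_old) / np.sqrt(p_old * (1.0 - p_old))

    eff = spec.effects
    q_sd, w_sd = spec.resolved_residual_sds()
    fa_z = eff["age_fa"] * age_z + np.sqrt(1.0 - eff["age_fa"] ** 2) * rng.standard_normal(n)
    bpnd_z = eff["age_bpnd"] * age_z + np.sqrt(1.0 - eff["age_bpnd"] ** 2) * rng.standard_normal(n)
    q_z = eff["fa_q"] * fa_z + eff["bpnd_q"] * bpnd_z + q_sd * rng.standard_normal(n)

    # raw FA scale honoring the configured group means exactly
    half_gap = 0.5 * abs(spec.fa_mean_young - spec.fa_mean_old)
    within = 0.5 * (spec.fa_sd_young**2 + spec.fa_sd_old**2)
    fa_scale = float(np.sqrt(half_gap**2 + within))
    fa = 0.5 * (spec.fa_mean_young + spec.fa_mean_old) + fa_scale * fa_z
    fa = np.clip(fa, 1e-3, 1.0 - 1e-3)

    bpnd = np.maximum(_BPND_LOC + _BPND_SCALE * bpnd_z, 1e-3)

    age = np.where(
        old == 0,
        rng.integers(_AGE_RANGE_YOUNG[0], _AGE_RANGE_YOUNG[1] + 1, size=n),
        rng.integers(_AGE_RANGE_OLD[0], _AGE_RANGE_OLD[1] + 1, size=n),
    )

    if spec.wins_mode == "linear":
        wins_z = eff["q_wins"] * q_z + w_sd * rng.standard_normal(n)
        wins = np.round(_WINS_LOC + _WINS_SCALE * wins_z).astype(int)
        wins = np.maximum(wins, 0)
    elif spec.wins_mode == "mechanistic":
        schedule = generate_walk(n_trials=spec.n_trials, seed=spec.schedule_seed)
        wins = np.empty(n, dtype=int)
        child = np.random.SeedSequence(spec.seed).spawn(n)
        for i in range(n):
            beta = _MECH_BETA_LO + (_MECH_BETA_HI - _MECH_BETA_LO) * (
                1.0 / (1.0 + np.exp(-_MECH_SLOPE * q_z[i]))
            )
            params = ObserverParams(beta_temp=float(beta), **_MECH_OBSERVER)
            agent = ObserverAgent(params, np.random.default_rng(child[i]))
            sess = simulate_session(
                schedule, agent, np.random.default_rng(child[i].spawn(1)[0])
            )
            wins[i] = summarize_performance(sess).wins
    else:
        raise ConfigurationError(f"unknown wins_mode {spec.wins_mode!r}")

    return pd.DataFrame(
        {
            "subject_id": [f"s{i + 1:03d}" for i in range(n)],
            "age_group": np.where(old == 0, "young", "old"),
            "age": age,
            "fa": fa,
            "bpnd": bpnd,
            "q_signal": q_z,
            "wins": wins,
        }
    )
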