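"""Restless two-armed bandit task environment.

The task presents two bandits whose reward probabilities drift over trials as
independent reflected Gaussian random walks. On each trial the agent picks a
bandit and receives a Bernoulli reward (1 monetary unit) with the bandit's
current true probability. The experiment runs 2 blocks x 110 trials = 220
trials; here a session is simply a flat sequence of trials.

Walk parameters (per-step sd, reflection bounds) are configurable; the
defaults (sigma=0.05, bounds=[0.1, 0.9]) produce walks with the visual range
and smoothness typical of this task family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Protocol

import numpy as np

__all__ = [
    "MISSED",
    "WalkSchedule",
    "TrialRecord",
    "SessionData",
    "Agent",
    "RandomAgent",
    "ConstantAgent",
    "generate_walk",
    "play_trial",
    "simulate_session",
]

#: Sentinel for a missed trial (no response within the response window).
MISSED: None = None

DEFAULT_N_TRIALS = 220
DEFAULT_SIGMA = 0.05
DEFAULT_BOUNDS = (0.1, 0.9)


class ConfigurationError(ValueError):
    """Invalid task configuration (bounds, sigma, counts)."""


class ProtocolError(RuntimeError):
    """An agent violated the choice protocol."""


@dataclass(frozen=True)
class WalkSchedule:
    """True reward probabilities for both bandits over a session.

    Attributes
    ----------
    n_trials : int
        Number of trials.
    p : ndarray, shape (n_trials, 2)
        Per-trial true reward probability of each bandit.
    seed : int
        RNG seed the walk was generated from.
    bounds : (float, float)
        Reflection limits; every value of ``p`` lies inside them.
    sigma : float
        Per-step Gaussian standard deviation, in probability units.
    """

    n_trials: int
    p: np.ndarray
    seed: int
    bounds: tuple[float, float]
    sigma: float

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (self.n_trials, 2):
            raise ConfigurationError(
                f"p has shape {p.shape}, expected ({self.n_trials}, 2)"
            )
        lo, hi = self.bounds
        if not 0.0 <= lo < hi <= 1.0:  # container admits closed [0, 1]; generation is stricter
            raise ConfigurationError(f"invalid bounds {self.bounds}")
        if not (p.min() >= lo and p.max() <= hi):
            raise ConfigurationError("probabilities exit the reflection bounds")
        object.__setattr__(self, "p", p)

    def swapped(self) -> "WalkSchedule":
        """Return the schedule with bandit labels exchanged.

        Supports counterbalancing the walk-to-stimulus assignment across
        subjects while reusing one fixed walk pair.
        """
        return WalkSchedule(
            n_trials=self.n_trials,
            p=self.p[:, ::-1].copy(),
            seed=self.seed,
            bounds=self.bounds,
            sigma=self.sigma,
        )


@dataclass(frozen=True)
class TrialRecord:
    """One trial: 1-based index, choice (or ``MISSED``), reward, true ps."""

    t: int
    choice: Optional[int]
    reward: Optional[int]
    p_true: tuple[float, float]

    def __post_init__(self) -> None:
        if self.choice is MISSED:
            if self.reward is not None:
                raise ValueError(f"trial {self.t}: missed trial cannot carry a reward")
        else:
            if self.choice not in (0, 1):
                raise ValueError(f"trial {self.t}: choice must be 0, 1 or MISSED")
            if self.reward not in (0, 1):
                raise ValueError(f"trial {self.t}: reward must be 0 or 1")

    @property
    def missed(self) -> bool:
        return self.choice is MISSED


@dataclass
class SessionData:
    """One subject's trial sequence plus the generating schedule."""

    trials: list[TrialRecord]
    schedule: WalkSchedule
    subject_id: str = "sim"

    def __post_init__(self) -> None:
        if len(self.trials) != self.schedule.n_trials:
            raise ValueError(
                f"{len(self.trials)} trials but schedule has {self.schedule.n_trials}"
            )
        for i, tr in enumerate(self.trials, start=1):
            if tr.t != i:
                raise ValueError(f"trial indices must run 1..T; found {tr.t} at row {i}")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def choices(self) -> np.ndarray:
        """Choice per trial as int array; -1 codes a missed trial."""
        return np.array(
            [-1 if tr.missed else tr.choice for tr in self.trials], dtype=np.int64
        )

    def rewards(self) -> np.ndarray:
        """Reward per trial as int array; -1 codes a missed trial."""
        return np.array(
            [-1 if tr.missed else tr.reward for tr in self.trials], dtype=np.int64
        )

    def n_missed(self) -> int:
        return sum(tr.missed for tr in self.trials)


class Agent(Protocol):
    """Choice policy run against a schedule by :func:`simulate_session`."""

    def choose(self, t: int) -> int:
        """Return the bandit index chosen on (1-based) trial ``t``."""
        ...

    def observe(self, choice: int, reward: int) -> None:
        """Receive the outcome of the trial just played."""
        ...


class RandomAgent:
    """Chooses uniformly at random; the beta_temp=0 limit of any softmax agent."""

    def __init__(self, rng: np.random.Generator | int):
        self.rng = np.random.default_rng(rng) if isinstance(rng, int) else rng

    def choose(self, t: int) -> int:
        return int(self.rng.integers(0, 2))

    def observe(self, choice: int, reward: int) -> None:
        pass


class ConstantAgent:
    """Always chooses one fixed bandit."""

    def __init__(self, bandit: int):
        if bandit not in (0, 1):
            raise ValueError("bandit must be 0 or 1")
        self.bandit = bandit

    def choose(self, t: int) -> int:
        return self.bandit

    def observe(self, choice: int, reward: int) -> None:
        pass


def generate_walk(
    n_trials: int = DEFAULT_N_TRIALS,
    seed: int = 0,
    sigma: float = DEFAULT_SIGMA,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> WalkSchedule:
    """Generate two independent reflected Gaussian random walks.

    Each walk starts at an independent uniform draw inside ``bounds`` and takes
    Gaussian steps of sd ``sigma``; steps that would exit the bounds are
    reflected back inside. The same seed reproduces the schedule bit-identically.
    """
    lo, hi = bounds
    if not (0.0 < lo < hi < 1.0):
        raise ConfigurationError(f"bounds must satisfy 0 < lower < upper < 1, got {bounds}")
    if sigma <= 0:
        raise ConfigurationError(f"sigma must be positive, got {sigma}")
    if n_trials < 1:
        raise ConfigurationError(f"n_trials must be >= 1, got {n_trials}")

    rng = np.random.default_rng(seed)
    p = np.empty((n_trials, 2))
    p[0] = rng.uniform(lo, hi, size=2)
    steps = rng.normal(0.0, sigma, size=(n_trials - 1, 2))
    for t in range(1, n_trials):
        p[t] = _reflect(p[t - 1] + steps[t - 1], lo, hi)
    return WalkSchedule(n_trials=n_trials, p=p, seed=seed, bounds=(lo, hi), sigma=sigma)


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    x = np.asarray(x, dtype=float).copy()
    # fold until inside; terminates because each fold shrinks distance to the interval
    while True:
        below = x < lo
        above = x > hi
        if not (below.any() or above.any()):
            return x
        x[below] = 2 * lo - x[below]
        x[above] = 2 * hi - x[above]


def play_trial(
    schedule: WalkSchedule,
    t: int,
    choice: int,
    rng: np.random.Generator,
) -> TrialRecord:
    """Play (1-based) trial ``t``: Bernoulli reward at the chosen bandit's p."""
    if not 1 <= t <= schedule.n_trials:
        raise IndexError(f"trial {t} outside 1..{schedule.n_trials}")
    if choice not in (0, 1):
        raise ProtocolError(f"choice must be 0 or 1, got {choice!r}")
    p_true = schedule.p[t - 1]
    reward = int(rng.random() < p_true[choice])
    return TrialRecord(t=t, choice=choice, reward=reward, p_true=(p_true[0], p_true[1]))


def simulate_session(
    schedule: WalkSchedule,
    agent: Agent,
    rng: np.random.Generator | int,
    subject_id: str = "sim",
    miss_rate: float = 0.0,
) -> SessionData:
    """Run an agent through a schedule, trial by trial.

    The agent is queried in trial order and informed of each outcome. With
    ``miss_rate > 0``, trials are independently declared missed (uniformly at
    random) before the agent is queried — the agent neither chooses nor
    observes on those trials, emulating responses outside the response window.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    trials: list[TrialRecord] = []
    for t in range(1, schedule.n_trials + 1):
        if miss_rate > 0.0 and rng.random() < miss_rate:
            p_true = schedule.p[t - 1]
            trials.append(TrialRecord(t=t, choice=MISSED, reward=None,
                                      p_true=(p_true[0], p_true[1])))
            continue
        choice = agent.choose(t)
        if choice not in (0, 1):
            raise ProtocolError(f"agent returned invalid choice {choice!r} on trial {t}")
        rec = play_trial(schedule, t, choice, rng)
        agent.observe(choice, rec.reward)
        trials.append(rec)
    return SessionData(trials=trials, schedule=schedule, subject_id=subject_id)
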