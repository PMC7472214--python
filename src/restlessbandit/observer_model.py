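"""Bayesian-observer learning model for the restless two-armed bandit.

The observer keeps a beta distribution Beta(gamma_a, epsilon_a) over each
bandit's reward probability. Beliefs start uniform (gamma = epsilon = 1).
After each trial the chosen bandit's parameters are incremented by the
outcome while relaxing toward 1 at rate omega, and the unchosen bandit's
parameters are relaxed toward 1 at rate lambda (forgetting):

    chosen,   reward:    gamma' = (1-omega) gamma + omega + 1
                         epsilon' = (1-omega) epsilon + omega
    chosen,   omission:  gamma' = (1-omega) gamma + omega
                         epsilon' = (1-omega) epsilon + omega + 1
    unchosen:            gamma' = (1-lambda) gamma + lambda
                         epsilon' = (1-lambda) epsilon + lambda

Choice is a softmax with temperature beta over action propensities m. The
bandit chosen on the previous trial enters with its posterior mean Q; the
bandit *not* chosen on the previous trial receives an exploration bonus
(upsilon times its posterior variance V) and a relative-confidence term
(kappa times C_rel, the signed probability that the previously chosen
bandit's reward rate exceeds the unchosen one's):

    m_unchosen(t+1) = Q_unchosen(t) + upsilon * V_unchosen(t) + kappa * C_rel(t)
    m_chosen(t+1)   = Q_chosen(t+1)

C_rel(t) = 2 P(theta_chosen > theta_unchosen) - 1 for independent beta
variables; P is computed by deterministic quadrature (see
:func:`prob_first_beta_greater`).

Two timing conventions for the unchosen-bandit terms are supported via
``value_timing``: "literal" evaluates Q_unchosen and V_unchosen before the
trial-t relaxation (the chosen bandit's belief entering C_rel is the
post-update one), while "post_update" evaluates everything from the fully
updated t+1 state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import integrate, special

from .task_environment import SessionData

__all__ = [
    "ObserverParams",
    "BeliefState",
    "PropensityPair",
    "TrialLatents",
    "ObserverAgent",
    "init_beliefs",
    "posterior_mean",
    "posterior_variance",
    "update_chosen",
    "update_unchosen",
    "prob_first_beta_greater",
    "relative_confidence",
    "propensities",
    "choice_probabilities",
    "run_observer",
    "latents_frame",
]

ValueTiming = Literal["literal", "post_update"]

# defensive floor for beta parameters; unreachable for rates in (0, 1)
_PARAM_FLOOR = 1e-8


@dataclass(frozen=True)
class ObserverParams:
    """Free parameters of the observer model.

    beta_temp >= 0 (softmax temperature; 0 is the uniform-choice limit,
    admitted for testing), omega and lambda_forget in [0, 1] (boundaries
    admitted for testing; fitting keeps them interior), upsilon and kappa
    unconstrained reals.
    """

    beta_temp: float
    omega: float
    lambda_forget: float
    upsilon: float
    kappa: float

    def __post_init__(self) -> None:
        for name in ("beta_temp", "omega", "lambda_forget", "upsilon", "kappa"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.beta_temp < 0:
            raise ValueError(f"beta_temp must be >= 0, got {self.beta_temp}")
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError(f"omega must lie in [0, 1], got {self.omega}")
        if not 0.0 <= self.lambda_forget <= 1.0:
            raise ValueError(f"lambda_forget must lie in [0, 1], got {self.lambda_forget}")

    def to_dict(self) -> dict[str, float]:
        return {
            "beta": self.beta_temp,
            "omega": self.omega,
            "lambda": self.lambda_forget,
            "upsilon": self.upsilon,
            "kappa": self.kappa,
        }

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ObserverParams":
        return cls(
            beta_temp=float(d["beta"]),
            omega=float(d["omega"]),
            lambda_forget=float(d["lambda"]),
            upsilon=float(d["upsilon"]),
            kappa=float(d["kappa"]),
        )


@dataclass(frozen=True)
class BeliefState:
    """Beta-distribution parameters (gamma, epsilon) for both bandits."""

    gamma: np.ndarray
    epsilon: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma, dtype=float)
        e = np.asarray(self.epsilon, dtype=float)
        if g.shape != (2,) or e.shape != (2,):
            raise ValueError("gamma and epsilon must each hold one value per bandit")
        if not (np.all(g > 0) and np.all(e > 0)):
            raise ValueError("beta parameters must be positive")
        object.__setattr__(self, "gamma", g)
        object.__setattr__(self, "epsilon", e)


@dataclass(frozen=True)
class PropensityPair:
    """Action propensities entering the softmax, one per bandit."""

    m: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.shape != (2,):
            raise ValueError("propensities must hold one value per bandit")
        if not np.all(np.isfinite(m)):
            raise ValueError("propensities must be finite")
        object.__setattr__(self, "m", m)


@dataclass(frozen=True)
class TrialLatents:
    """Model latents for one trial.

    ``Q``, ``V``, ``m`` and ``choice_prob`` describe the state at choice time.
    ``C_rel`` is the relative confidence computed after the trial's choice
    (it feeds the next trial's propensities); NaN on missed trials.
    """

    t: int
    Q: np.ndarray
    V: np.ndarray
    C_rel: float
    m: PropensityPair
    choice_prob: np.ndarray


# ---------------------------------------------------------------------------
# Belief updates
# ---------------------------------------------------------------------------

def init_beliefs() -> BeliefState:
    """Uniform prior beliefs: gamma = epsilon = 1 for both bandits."""
    return BeliefState(gamma=np.ones(2), epsilon=np.ones(2))


def posterior_mean(state: BeliefState) -> np.ndarray:
    """Expected reward probability Q_a = gamma_a / (gamma_a + epsilon_a)."""
    return state.gamma / (state.gamma + state.epsilon)


def posterior_variance(state: BeliefState) -> np.ndarray:
    """Belief variance V_a = gamma eps / ((gamma+eps)^2 (gamma+eps+1))."""
    s = state.gamma + state.epsilon
    return state.gamma * state.epsilon / (s * s * (s + 1.0))


def update_chosen(state: BeliefState, choice: int, reward: int, omega: float) -> BeliefState:
    """Update the chosen bandit: relax toward 1 at rate omega, then add the outcome."""
    if choice not in (0, 1):
        raise ValueError(f"choice must be 0 or 1, got {choice!r}")
    if reward not in (0, 1):
        raise ValueError(f"reward must be 0 or 1, got {reward!r}")
    if not 0.0 <= omega <= 1.0:
        raise ValueError(f"omega must lie in [0, 1], got {omega}")
    g = state.gamma.copy()
    e = state.epsilon.copy()
    g[choice] = max((1.0 - omega) * g[choice] + omega + reward, _PARAM_FLOOR)
    e[choice] = max((1.0 - omega) * e[choice] + omega + (1 - reward), _PARAM_FLOOR)
    return BeliefState(gamma=g, epsilon=e)


def update_unchosen(state: BeliefState, unchosen: int, lambda_forget: float) -> BeliefState:
    """Forget the unchosen bandit: relax both parameters toward 1 at rate lambda."""
    if unchosen not in (0, 1):
        raise ValueError(f"unchosen must be 0 or 1, got {unchosen!r}")
    if not 0.0 <= lambda_forget <= 1.0:
        raise ValueError(f"lambda_forget must lie in [0, 1], got {lambda_forget}")
    g = state.gamma.copy()
    e = state.epsilon.copy()
    g[unchosen] = max((1.0 - lambda_forget) * g[unchosen] + lambda_forget, _PARAM_FLOOR)
    e[unchosen] = max((1.0 - lambda_forget) * e[unchosen] + lambda_forget, _PARAM_FLOOR)
    return BeliefState(gamma=g, epsilon=e)


# ---------------------------------------------------------------------------
# Beta-dominance probability P(theta1 > theta0)
# ---------------------------------------------------------------------------
# Deterministic quadrature of pdf(theta1) * cdf(theta0) over the region where
# both factors vary. Integration windows come from moment bounds (mean +- 10 sd),
# tightened to exact tail quantiles whenever the discarded tail mass would
# exceed 1e-13 (beta tails are polynomial, not Gaussian). Rows whose window is
# interior use Gauss-Legendre (64 nodes; the window spans at most 20 sd of the
# narrower distribution, which 64 nodes resolve to near machine precision).
# Rows whose window reaches an endpoint may contain an algebraic singularity
# x^(gamma-1) or (1-x)^(epsilon-1); these use tanh-sinh nodes, which handle
# endpoint singularities spectrally. The rare sharp-peak-under-wide-window rows
# fall back to adaptive quadrature. Orientation is swapped when the first
# density is singular but the second is not, so the integrated density is the
# smooth one.

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)

def _tanh_sinh_rule(h: float = 0.045, tmax: float = 4.3):
    t = np.arange(-int(np.ceil(tmax / h)), int(np.ceil(tmax / h)) + 1) * h
    s = 0.5 * np.pi * np.sinh(t)
    u = 0.5 * (1.0 + np.tanh(s))
    um = 0.5 * (1.0 - np.tanh(s))          # 1-u without cancellation
    w = h * 0.25 * np.pi * np.cosh(t) / np.cosh(s) ** 2
    keep = (u > 1e-17) & (um > 1e-17) & (w > 1e-40)
    return u[keep], um[keep], w[keep]

_TS_U, _TS_UM, _TS_W = _tanh_sinh_rule()

# lighter rules for the fast (search-time) mode
_GL_NODES_FAST, _GL_WEIGHTS_FAST = np.polynomial.legendre.leggauss(32)
_TS_U_FAST, _TS_UM_FAST, _TS_W_FAST = _tanh_sinh_rule(h=0.08)

_WINDOW_SD = 10.0
_TAIL_Q = 1e-16
_TAIL_TOL = 1e-13


def _beta_window(g: np.ndarray, e: np.ndarray) -> tuple[np.ndarray, ...]:
    s = g + e
    mu = g / s
    sd = np.sqrt(g * e / (s * s * (s + 1.0)))
    lo = np.maximum(mu - _WINDOW_SD * sd, 0.0)
    hi = np.minimum(mu + _WINDOW_SD * sd, 1.0)
    bad = (lo <= 0.0) | (special.betainc(g, e, np.maximum(lo, 1e-300)) > _TAIL_TOL)
    if bad.any():
        q = special.betaincinv(g[bad], e[bad], _TAIL_Q)
        # betaincinv can fail near degenerate shapes; the endpoint is always safe
        lo[bad] = np.where(np.isfinite(q) & (q >= 0.0) & (q < 1.0), q, 0.0)
    bad = (hi >= 1.0) | (special.betaincc(g, e, np.minimum(hi, 1.0 - 1e-16)) > _TAIL_TOL)
    if bad.any():
        q = special.betaincinv(g[bad], e[bad], 1.0 - _TAIL_Q)
        hi[bad] = np.where(np.isfinite(q) & (q > 0.0) & (q <= 1.0), q, 1.0)
    return mu, sd, lo, hi


def _dominance_quad_rows(g1, e1, g0, e0) -> np.ndarray:
    out = np.empty(g1.shape)
    for j in range(g1.size):
        lb = special.betaln(g1[j], e1[j])

        def f(x):
            return np.exp(
                special.xlogy(g1[j] - 1.0, x)
                + special.xlog1py(e1[j] - 1.0, -x)
                - lb
            ) * special.betainc(g0[j], e0[j], x)

        out[j], _ = integrate.quad(f, 0.0, 1.0, limit=200, epsabs=1e-11, epsrel=1e-11)
    return out


def _beta_window_fast(g: np.ndarray, e: np.ndarray) -> tuple[np.ndarray, ...]:
    # moment windows only; clipped ends fall back to the full interval, where
    # the tanh-sinh rule absorbs the endpoint behavior
    s = g + e
    mu = g / s
    sd = np.sqrt(g * e / (s * s * (s + 1.0)))
    lo = np.maximum(mu - _WINDOW_SD * sd, 0.0)
    hi = np.minimum(mu + _WINDOW_SD * sd, 1.0)
    return mu, sd, lo, hi


def beta_dominance(g1, e1, g0, e0, fast: bool = False) -> np.ndarray:
    """Vectorized P(theta1 > theta0), theta_i ~ Beta(g_i, e_i) independent.

    With ``fast=True`` the tail-mass window verification and the adaptive
    fallback are skipped — adequate inside iterative optimization, where the
    final value is always recomputed accurately.
    """
    g1, e1, g0, e0 = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(a, dtype=float)) for a in (g1, e1, g0, e0))
    )
    if min(g1.min(initial=np.inf), e1.min(initial=np.inf),
           g0.min(initial=np.inf), e0.min(initial=np.inf)) <= 0:
        raise ValueError("beta parameters must be positive")
    g1, e1, g0, e0 = (a.copy() for a in (g1, e1, g0, e0))

    swap = ((g1 < 1) | (e1 < 1)) & (g0 >= 1) & (e0 >= 1)
    if swap.any():
        g1, e1, g0, e0 = (
            np.where(swap, g0, g1),
            np.where(swap, e0, e1),
            np.where(swap, g1, g0),
            np.where(swap, e1, e0),
        )

    window = _beta_window_fast if fast else _beta_window
    mu1, sd1, lo1, hi1 = window(g1, e1)
    mu0, _, lo0, hi0 = window(g0, e0)
    lo = np.maximum(lo1, lo0)
    hi = np.minimum(hi1, hi0)

    out = np.empty(g1.shape)
    empty = hi <= lo                       # essentially disjoint supports
    out[empty] = (mu0 < mu1)[empty]
    width = np.where(empty, 1.0, hi - lo)
    singular = (~empty) & ((lo < 0.05 * width) | (1.0 - hi < 0.05 * width))
    if fast:
        hard = np.zeros_like(singular)
    else:
        # sharp peak under a wide window, or a singular integrated density
        # (no smooth orientation available): leave these to adaptive quadrature
        hard = (singular & (width > 8.0 * sd1)) | (
            (~empty) & ((g1 < 1) | (e1 < 1))
        )
    singular &= ~hard
    smooth = ~(empty | singular | hard)

    def _core(i, x, one_minus_x, w, scale):
        logpdf = (
            special.xlogy(g1[i][:, None] - 1.0, x)
            + special.xlogy(e1[i][:, None] - 1.0, one_minus_x)
            - special.betaln(g1[i], e1[i])[:, None]
        )
        cdf = special.betainc(g0[i][:, None], e0[i][:, None], x)
        val = (w * np.exp(logpdf) * cdf).sum(axis=1) * scale
        # mass of theta1 above the window, where cdf(theta0) is 1 to tolerance
        return val + special.betaincc(g1[i], e1[i], hi[i])

    gl_nodes, gl_weights = (_GL_NODES_FAST, _GL_WEIGHTS_FAST) if fast else (_GL_NODES, _GL_WEIGHTS)
    ts_u, ts_um, ts_w = (_TS_U_FAST, _TS_UM_FAST, _TS_W_FAST) if fast else (_TS_U, _TS_UM, _TS_W)
    if smooth.any():
        i = smooth
        mid = 0.5 * (hi[i] + lo[i])
        half = 0.5 * (hi[i] - lo[i])
        x = mid[:, None] + half[:, None] * gl_nodes[None, :]
        out[i] = _core(i, x, 1.0 - x, gl_weights[None, :], half)
    if singular.any():
        i = singular
        length = hi[i] - lo[i]
        x = lo[i][:, None] + length[:, None] * ts_u[None, :]
        one_minus_x = (1.0 - hi[i])[:, None] + length[:, None] * ts_um[None, :]
        out[i] = _core(i, x, one_minus_x, ts_w[None, :], length)
    if hard.any():
        out[hard] = _dominance_quad_rows(g1[hard], e1[hard], g0[hard], e0[hard])

    rescue = ~np.isfinite(out)
    if rescue.any():
        out[rescue] = _dominance_quad_rows(g1[rescue], e1[rescue],
                                           g0[rescue], e0[rescue])

    out = np.clip(out, 0.0, 1.0)
    return np.where(swap, 1.0 - out, out)


def prob_first_beta_greater(gamma1: float, epsilon1: float,
                            gamma0: float, epsilon0: float) -> float:
    """P(theta1 > theta0) for independent theta1 ~ Beta(gamma1, epsilon1),
    theta0 ~ Beta(gamma0, epsilon0), by deterministic quadrature (absolute
    accuracy well below 1e-6 over the parameter ranges the model visits)."""
    return float(beta_dominance(gamma1, epsilon1, gamma0, epsilon0)[0])


def relative_confidence(state: BeliefState, chosen: int) -> float:
    """C_rel = 2 P(theta_chosen > theta_unchosen) - 1, in [-1, 1].

    Antisymmetric under exchanging the roles of chosen and unchosen bandit
    (the two dominance probabilities are complementary for continuous
    distributions)."""
    if chosen not in (0, 1):
        raise ValueError(f"chosen must be 0 or 1, got {chosen!r}")
    u = 1 - chosen
    p = prob_first_beta_greater(
        state.gamma[chosen], state.epsilon[chosen], state.gamma[u], state.epsilon[u]
    )
    return 2.0 * p - 1.0


# ---------------------------------------------------------------------------
# Propensities and choice
# ---------------------------------------------------------------------------

def propensities(
    state_prev: BeliefState,
    state_new: BeliefState,
    chosen_prev: int,
    params: ObserverParams,
    value_timing: ValueTiming = "literal",
) -> PropensityPair:
    """Action propensities for the trial after a choice of ``chosen_prev``.

    ``state_prev`` is the belief state with the chosen bandit already updated
    by the outcome but the unchosen bandit not yet relaxed; ``state_new`` is
    the fully updated next-trial state. The chosen bandit enters with its
    updated posterior mean; the unchosen bandit receives the exploration bonus
    and relative-confidence terms, evaluated per ``value_timing``.
    """
    if chosen_prev not in (0, 1):
        raise ValueError(f"chosen_prev must be 0 or 1, got {chosen_prev!r}")
    u = 1 - chosen_prev
    m = np.empty(2)
    m[chosen_prev] = posterior_mean(state_new)[chosen_prev]
    if value_timing == "literal":
        # chosen bandit already updated in state_prev; unchosen not yet relaxed
        q_u = posterior_mean(state_prev)[u]
        v_u = posterior_variance(state_prev)[u]
        conf_state = state_prev
    elif value_timing == "post_update":
        q_u = posterior_mean(state_new)[u]
        v_u = posterior_variance(state_new)[u]
        conf_state = state_new
    else:
        raise ValueError(f"unknown value_timing {value_timing!r}")
    c_rel = relative_confidence(conf_state, chosen_prev)
    m[u] = q_u + params.upsilon * v_u + params.kappa * c_rel
    return PropensityPair(m=m)


def choice_probabilities(m: PropensityPair | np.ndarray, beta_temp: float) -> np.ndarray:
    """Softmax over the two propensities; numerically stable; sums to 1."""
    mv = m.m if isinstance(m, PropensityPair) else np.asarray(m, dtype=float)
    if not np.all(np.isfinite(mv)):
        raise ValueError("propensities must be finite")
    if beta_temp < 0:
        raise ValueError(f"beta_temp must be >= 0, got {beta_temp}")
    z = beta_temp * mv
    z = z - z.max()
    ez = np.exp(z)
    return ez / ez.sum()


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------

def _forward_arrays(
    choices: np.ndarray,
    rewards: np.ndarray,
    omega: float,
    lam: float,
    value_timing: ValueTiming = "literal",
    fast: bool = False,
) -> dict[str, np.ndarray]:
    """Belief recursion over one session, vector-friendly.

    Returns the per-trial belief trajectory at choice time (``gamma``,
    ``epsilon``: (T, 2)), the relative confidence ``c_rel`` (T,), and the
    propensity decomposition m = base + upsilon*coef_v + kappa*coef_c
    ((T, 2) each) which is linear in (upsilon, kappa) — the property the
    profile-likelihood fit exploits. Missed trials leave beliefs and
    propensities unchanged and have NaN confidence.
    """
    if value_timing not in ("literal", "post_update"):
        raise ValueError(f"unknown value_timing {value_timing!r}")
    T = len(choices)
    g = np.empty((T + 1, 2))
    e = np.empty((T + 1, 2))
    dom = np.empty((T, 4))
    observed = choices >= 0
    q_term = np.empty(T)
    v_term = np.empty(T)
    literal = value_timing == "literal"
    cur = [1.0, 1.0, 1.0, 1.0]  # g0, g1, e0, e1 as plain floats
    one_m_om = 1.0 - omega
    one_m_lam = 1.0 - lam
    for t in range(T):
        g[t, 0], g[t, 1], e[t, 0], e[t, 1] = cur
        a = choices[t]
        if a < 0:
            continue
        r = rewards[t]
        u = 1 - a
        ga, ea, gu_old, eu_old = cur[a], cur[2 + a], cur[u], cur[2 + u]
        gc = one_m_om * ga + omega + r
        ec = one_m_om * ea + omega + (1 - r)
        gu = one_m_lam * gu_old + lam
        eu = one_m_lam * eu_old + lam
        cur[a], cur[2 + a], cur[u], cur[2 + u] = gc, ec, gu, eu
        if literal:
            dom[t, 0] = gc; dom[t, 1] = ec; dom[t, 2] = gu_old; dom[t, 3] = eu_old
            su = gu_old + eu_old
            q_term[t] = gu_old / su
            v_term[t] = gu_old * eu_old / (su * su * (su + 1.0))
        else:
            dom[t, 0] = gc; dom[t, 1] = ec; dom[t, 2] = gu; dom[t, 3] = eu
            su = gu + eu
            q_term[t] = gu / su
            v_term[t] = gu * eu / (su * su * (su + 1.0))
    g[T, 0], g[T, 1], e[T, 0], e[T, 1] = cur
    # defensive floor; unreachable for rates in [0, 1]
    np.maximum(g, _PARAM_FLOOR, out=g)
    np.maximum(e, _PARAM_FLOOR, out=e)

    c_rel = np.full(T, np.nan)
    if observed.any():
        d = dom[observed]
        c_rel[observed] = (
            2.0 * beta_dominance(d[:, 0], d[:, 1], d[:, 2], d[:, 3], fast=fast) - 1.0
        )

    base = np.empty((T, 2))
    coef_v = np.zeros((T, 2))
    coef_c = np.zeros((T, 2))
    base[0] = 0.5
    for t in range(T - 1):
        a = choices[t]
        if a < 0:
            base[t + 1] = base[t]
            coef_v[t + 1] = coef_v[t]
            coef_c[t + 1] = coef_c[t]
            continue
        u = 1 - a
        base[t + 1, a] = g[t + 1, a] / (g[t + 1, a] + e[t + 1, a])
        base[t + 1, u] = q_term[t]
        coef_v[t + 1, a] = 0.0
        coef_v[t + 1, u] = v_term[t]
        coef_c[t + 1, a] = 0.0
        coef_c[t + 1, u] = c_rel[t]
    return {
        "gamma": g[:-1],
        "epsilon": e[:-1],
        "gamma_next": g[1:],
        "epsilon_next": e[1:],
        "c_rel": c_rel,
        "base": base,
        "coef_v": coef_v,
        "coef_c": coef_c,
    }


def run_observer(
    session: SessionData,
    params: ObserverParams,
    value_timing: ValueTiming = "literal",
) -> list[TrialLatents]:
    """Forward pass of the observer over a session.

    Returns one :class:`TrialLatents` per trial: beliefs (Q, V) at choice
    time, the propensities and softmax choice probabilities, and the
    relative confidence computed after the trial's choice. Trial 1 always has
    m = Q = (0.5, 0.5) and uniform choice probabilities.
    """
    choices = session.choices()
    rewards = session.rewards()
    if len(choices) == 0:
        raise ValueError("session has no trials")
    fw = _forward_arrays(choices, rewards, params.omega, params.lambda_forget,
                         value_timing)
    m = fw["base"] + params.upsilon * fw["coef_v"] + params.kappa * fw["coef_c"]
    z = params.beta_temp * m
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    gam, eps = fw["gamma"], fw["epsilon"]
    s = gam + eps
    Q = gam / s
    V = gam * eps / (s * s * (s + 1.0))
    out = []
    for t in range(len(choices)):
        out.append(
            TrialLatents(
                t=t + 1,
                Q=Q[t].copy(),
                V=V[t].copy(),
                C_rel=float(fw["c_rel"][t]),
                m=PropensityPair(m=m[t].copy()),
                choice_prob=probs[t].copy(),
            )
        )
    return out


def latents_frame(latents: Sequence[TrialLatents]):
    """Latents as a tidy DataFrame (columns trial,Q0,Q1,V0,V1,Crel,m0,m1,
    p_choice0,p_choice1)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "trial": [la.t for la in latents],
            "Q0": [la.Q[0] for la in latents],
            "Q1": [la.Q[1] for la in latents],
            "V0": [la.V[0] for la in latents],
            "V1": [la.V[1] for la in latents],
            "Crel": [la.C_rel for la in latents],
            "m0": [la.m.m[0] for la in latents],
            "m1": [la.m.m[1] for la in latents],
            "p_choice0": [la.choice_prob[0] for la in latents],
            "p_choice1": [la.choice_prob[1] for la in latents],
        }
    )


class ObserverAgent:
    """Online observer policy for :func:`~restlessbandit.task_environment.simulate_session`.

    Maintains beliefs trial by trial and samples choices from the softmax.
    """

    def __init__(
        self,
        params: ObserverParams,
        rng: np.random.Generator | int,
        value_timing: ValueTiming = "literal",
    ):
        self.params = params
        self.value_timing: ValueTiming = value_timing
        self.rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
        self.state = init_beliefs()
        self._m = PropensityPair(m=np.array([0.5, 0.5]))

    def choose(self, t: int) -> int:
        p = choice_probabilities(self._m, self.params.beta_temp)
        return int(self.rng.random() < p[1])

    def observe(self, choice: int, reward: int) -> None:
        after_choice = update_chosen(self.state, choice, reward, self.params.omega)
        new_state = update_unchosen(after_choice, 1 - choice, self.params.lambda_forget)
        self._m = propensities(after_choice, new_state, choice, self.params,
                               self.value_timing)
        self.state = new_state
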