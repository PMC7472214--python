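import numpy as np
import pytest

import restlessbandit as rb


@pytest.fixture
def schedule():
    return rb.generate_walk(220, seed=7)


@pytest.fixture
def observer_params():
    return rb.ObserverParams(beta_temp=5.0, omega=0.3, lambda_forget=0.1,
                             upsilon=0.5, kappa=0.5)


@pytest.fixture
def session(schedule, observer_params):
    agent = rb.ObserverAgent(observer_params, rng=11)
    return rb.simulate_session(schedule, agent, rng=12)


def make_session(choices, rewards, p=None):
    """Hand-build a session from explicit choice/reward sequences.

    ``None`` entries are missed trials; ``p`` defaults to constant (0.5, 0.5).
    """
    n = len(choices)
    if p is None:
        p = [(0.5, 0.5)] * n
    trials = []
    for t, (c, r, pt) in enumerate(zip(choices, rewards, p), start=1):
        trials.append(rb.TrialRecord(t=t, choice=c, reward=r, p_true=tuple(pt)))
    sched = rb.WalkSchedule(
        n_trials=n,
        p=np.array(p, dtype=float),
        seed=-1,
        bounds=(0.0, 1.0),
        sigma=0.05,
    )
    return rb.SessionData(trials=trials, schedule=sched, subject_id="toy")


@pytest.fixture
def toy_session():
    # choices 0,0,1 with rewards 1,0,1 — the hand-worked recursion example
    return make_session([0, 0, 1], [1, 0, 1])
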