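"""Configuration, file formats and seeded end-to-end orchestration.

Every artifact written by the pipeline carries provenance metadata (config
hash, seed, package version) as ``# key=value`` comment lines before the CSV
header, or under a ``_meta`` key in JSON. A single global seed expands into
per-stage child seeds through ``numpy.random.SeedSequence(global_seed,
spawn_key=(stage_index,))``, so any stage can be re-run in isolation with
the identical stream.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior_metrics import extract_value_regressor, summarize_performance
from .group_stats import compare_models_bic, standardized_regression
from .model_fitting import fit_observer
from .observer_model import ObserverAgent, ObserverParams, run_observer
from .synthetic_cohort import (
    CohortSpec,
    _MECH_BETA_HI,
    _MECH_BETA_LO,
    _MECH_OBSERVER,
    _MECH_SLOPE,
    generate_cohort,
)
from .task_environment import (
    MISSED,
    SessionData,
    TrialRecord,
    WalkSchedule,
    generate_walk,
    simulate_session,
)

__all__ = [
    "PipelineConfig",
    "stage_seed",
    "read_session",
    "write_session",
    "read_cohort",
    "write_cohort",
    "write_schedule",
    "read_schedule",
    "run_end_to_end",
]

log = logging.getLogger("restlessbandit")

STAGES = ("cohort", "schedule", "sessions", "fits", "stats")


class ParseError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for one end-to-end run."""

    seed: int = 0
    out_dir: str = "bandit_out"
    n_trials: int = 220
    sigma: float = 0.05
    bounds: tuple[float, float] = (0.1, 0.9)
    fixed_schedule: bool = True
    fit_starts: int = 10
    value_timing: Literal["literal", "post_update"] = "literal"
    cohort: CohortSpec = field(default_factory=CohortSpec)

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir")  # where results land does not change what they are
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["bounds"] = list(self.bounds)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        cohort = d.pop("cohort", None)
        cfg = cls(
            **{**d, "bounds": tuple(d.get("bounds", (0.1, 0.9)))},
        ) if cohort is None else cls(
            **{**d, "bounds": tuple(d.get("bounds", (0.1, 0.9))),
               "cohort": CohortSpec(**cohort)},
        )
        return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Child seed for a named pipeline stage (documented splitting scheme)."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(global_seed, spawn_key=(idx,))
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# CSV round-trips
# ---------------------------------------------------------------------------

def _meta_lines(meta: dict) -> str:
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def _read_csv(path: str | Path, expected_columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    text = path.read_text()
    body = "".join(ln for ln in text.splitlines(keepends=True) if not ln.startswith("#"))
    if not body.strip():
        raise ParseError(f"{path}: empty input")
    df = pd.read_csv(io.StringIO(body), float_precision="round_trip")
    if list(df.columns) != expected_columns:
        raise ParseError(
            f"{path}: header {list(df.columns)} does not match {expected_columns}"
        )
    return df


def write_session(path: str | Path, session: SessionData, meta: dict | None = None) -> None:
    """Session CSV: ``trial,choice,reward,p0,p1``; empty choice/reward = miss."""
    rows = []
    for tr in session.trials:
        rows.append(
            {
                "trial": tr.t,
                "choice": "" if tr.missed else tr.choice,
                "reward": "" if tr.missed else tr.reward,
                "p0": repr(float(tr.p_true[0])),
                "p1": repr(float(tr.p_true[1])),
            }
        )
    df = pd.DataFrame(rows, columns=["trial", "choice", "reward", "p0", "p1"])
    with open(path, "w") as fh:
        fh.write(_meta_lines({"subject_id": session.subject_id, **(meta or {})}))
        df.to_csv(fh, index=False)


def read_session(path: str | Path, subject_id: str = "loaded") -> SessionData:
    """Read a session CSV, validating choices and rewards row by row."""
    df = _read_csv(path, ["trial", "choice", "reward", "p0", "p1"])
    trials = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        missed = pd.isna(row.choice)
        if missed != pd.isna(row.reward):
            raise ParseError(f"row {i}: choice and reward must be both present or both empty")
        if missed:
            choice, reward = MISSED, None
        else:
            choice = int(row.choice)
            reward = int(row.reward)
            if choice not in (0, 1):
                raise ParseError(f"row {i}: choice must be 0 or 1, got {row.choice!r}")
            if reward not in (0, 1):
                raise ParseError(f"row {i}: reward must be 0 or 1, got {row.reward!r}")
        p0, p1 = float(row.p0), float(row.p1)
        if not (0.0 <= p0 <= 1.0 and 0.0 <= p1 <= 1.0):
            raise ParseError(f"row {i}: probabilities outside [0, 1]")
        trials.append(TrialRecord(t=int(row.trial), choice=choice, reward=reward,
                                  p_true=(p0, p1)))
    p = np.array([tr.p_true for tr in trials])
    schedule = WalkSchedule(
        n_trials=len(trials), p=p, seed=-1, bounds=(0.0, 1.0), sigma=float("nan")
    )
    return SessionData(trials=trials, schedule=schedule, subject_id=subject_id)


def write_schedule(path: str | Path, schedule: WalkSchedule, meta: dict | None = None) -> None:
    """Schedule CSV: ``trial,p0,p1``."""
    df = pd.DataFrame(
        {
            "trial": np.arange(1, schedule.n_trials + 1),
            "p0": [repr(float(v)) for v in schedule.p[:, 0]],
            "p1": [repr(float(v)) for v in schedule.p[:, 1]],
        }
    )
    with open(path, "w") as fh:
        fh.write(_meta_lines({"seed": schedule.seed, "sigma": schedule.sigma,
                              "bounds": schedule.bounds, **(meta or {})}))
        df.to_csv(fh, index=False)


def read_schedule(path: str | Path) -> np.ndarray:
    df = _read_csv(path, ["trial", "p0", "p1"])
    return df[["p0", "p1"]].to_numpy(dtype=float)


_COHORT_COLUMNS = ["subject_id", "age_group", "age", "fa", "bpnd", "q_signal", "wins"]


def write_cohort(path: str | Path, cohort: pd.DataFrame, meta: dict | None = None) -> None:
    """Cohort CSV with the standard column set."""
    missing = set(_COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort misses columns: {sorted(missing)}")
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta or {}))
        out = cohort[_COHORT_COLUMNS].copy()
        for col in ("fa", "bpnd", "q_signal"):
            out[col] = out[col].map(lambda v: repr(float(v)))
        out.to_csv(fh, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, _COHORT_COLUMNS)
    bad = ~df["age_group"].isin(["young", "old"])
    if bad.any():
        raise ParseError(f"row {int(np.flatnonzero(bad)[0]) + 1}: age_group must be young/old")
    if (df["wins"] < 0).any():
        raise ParseError("wins must be non-negative")
    return df


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def _beta_from_q(q: float) -> float:
    return _MECH_BETA_LO + (_MECH_BETA_HI - _MECH_BETA_LO) / (
        1.0 + float(np.exp(-_MECH_SLOPE * q))
    )


def run_end_to_end(config: PipelineConfig) -> dict:
    """Cohort -> sessions -> observer fits -> metrics/regressors -> group stats.

    Subjects' value-signal strengths map to softmax temperatures through the
    cohort module's logistic link; wins are taken from the simulated sessions
    so that behavior, fits and group statistics refer to the same data.
    Returns a dict of in-memory results; all artifacts are also written under
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "seed": config.seed,
            "version": __version__}

    def stage(name):
        log.info("stage %s", name)
        return stage_seed(config.seed, name)

    # cohort ----------------------------------------------------------------
    cohort_seed = stage("cohort")
    spec = replace(config.cohort, seed=cohort_seed, wins_mode="linear",
                   n_trials=config.n_trials)
    cohort = generate_cohort(spec)

    # schedule(s) -----------------------------------------------------------
    sched_seed = stage("schedule")
    schedule = generate_walk(config.n_trials, seed=sched_seed, sigma=config.sigma,
                             bounds=config.bounds)
    write_schedule(out / "schedule.csv", schedule, meta)

    # sessions --------------------------------------------------------------
    sess_root = np.random.SeedSequence(config.seed, spawn_key=(STAGES.index("sessions"),))
    children = sess_root.spawn(len(cohort))
    sessions: list[SessionData] = []
    for i, row in enumerate(cohort.itertuples(index=False)):
        params = ObserverParams(beta_temp=_beta_from_q(row.q_signal), **_MECH_OBSERVER)
        sched_i = schedule if config.fixed_schedule else generate_walk(
            config.n_trials, seed=int(children[i].generate_state(1)[0] & 0x7FFFFFFF),
            sigma=config.sigma, bounds=config.bounds,
        )
        if config.fixed_schedule and i % 2 == 1:
            sched_i = schedule.swapped()  # counterbalanced bandit assignment
        agent = ObserverAgent(params, np.random.default_rng(children[i]))
        sess = simulate_session(sched_i, agent, np.random.default_rng(children[i].spawn(1)[0]),
                                subject_id=row.subject_id)
        sessions.append(sess)
        write_session(out / f"session_{row.subject_id}.csv", sess, meta)

    # wins from the simulated behavior
    perf = [summarize_performance(s) for s in sessions]
    cohort = cohort.assign(wins=[p.wins for p in perf])
    write_cohort(out / "cohort.csv", cohort, meta)
    perf_df = pd.DataFrame(
        {
            "subject_id": cohort["subject_id"],
            "wins": [p.wins for p in perf],
            "pct_optimal_choice": [p.pct_optimal_choice for p in perf],
            "pct_optimal_switch": [p.pct_optimal_switch for p in perf],
            "n_missed": [p.n_missed for p in perf],
        }
    )
    with open(out / "performance.csv", "w") as fh:
        fh.write(_meta_lines(meta))
        perf_df.to_csv(fh, index=False)

    # fits and value regressors --------------------------------------------
    fit_seed = stage("fits")
    fits = []
    for sess in sessions:
        fit = fit_observer(sess, n_starts=config.fit_starts, seed=fit_seed,
                           value_timing=config.value_timing)
        fits.append(fit)
        latents = run_observer(sess, fit.params_hat, config.value_timing)
        reg = extract_value_regressor(sess, latents)
        with open(out / f"regressor_{sess.subject_id}.csv", "w") as fh:
            fh.write(_meta_lines(meta))
            reg.to_csv(fh, index=False)
        payload = {
            "_meta": meta,
            "model": fit.model,
            "params": fit.params_hat.to_dict(),
            "nll": fit.nll,
            "n_obs": fit.n_obs,
            "k": fit.k,
            "bic": fit.bic,
            "converged": fit.converged,
            "boundary_flags": fit.boundary_flags,
        }
        (out / f"fit_{sess.subject_id}.json").write_text(json.dumps(payload, indent=1))

    # group statistics ------------------------------------------------------
    stage("stats")
    dfc = cohort.assign(age_old=(cohort["age_group"] == "old").astype(float))
    q_report = standardized_regression(
        dfc["q_signal"], dfc[["age_old", "bpnd", "fa"]]
    )
    wins_report = standardized_regression(
        dfc["wins"], dfc[["age_old", "bpnd", "fa", "q_signal"]]
    )
    bic_table = compare_models_bic(
        [
            standardized_regression(dfc["q_signal"], dfc[["age_old", "bpnd"]]),
            standardized_regression(dfc["q_signal"], dfc[["age_old", "fa"]]),
            q_report,
        ]
    )
    for name, rep in (("q_signal", q_report), ("wins", wins_report)):
        payload = {
            "_meta": meta,
            "outcome": rep.outcome,
            "coefficients": rep.coefficients.to_dict(orient="records"),
            "bic": rep.bic,
            "adj_r2": rep.adj_r2,
            "shapiro_p": rep.shapiro_p,
            "normality_ok": rep.normality_ok,
        }
        (out / f"stats_{name}.json").write_text(json.dumps(payload, indent=1))
    with open(out / "model_comparison.csv", "w") as fh:
        fh.write(_meta_lines(meta))
        bic_table.to_csv(fh, index=False)

    return {
        "cohort": cohort,
        "sessions": sessions,
        "fits": fits,
        "performance": perf_df,
        "q_report": q_report,
        "wins_report": wins_report,
        "bic_table": bic_table,
    }
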