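"""Synthetic trial-level reaction times and outcomes.

The generator draws reaction times around the linear dissociation model

    RT = b0 + b1*SZ + (b2 + b3*SZ)*EX + b4*TG

with additive trial noise (Gaussian by default, optionally ex-Gaussian to
emulate the right skew of empirical RT distributions), an optional
between-subject intercept spread, a 1 s response window (draws beyond it
become omissions with no recorded RT), a physiological floor, and an
RT-independent Bernoulli error process.  Defaults place the regression
coefficients at the study's fitted estimates so that the full pipeline —
schedule, simulate, refit — can be exercised end to end.

Also provides a subject-profile generator (age, body-mass index, health and
habit ratings) used purely to exercise group-homogeneity comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import scheduler
from .scheduler import CohortPlan, SymbolPools, Trial

RT_COLUMNS = [
    "subject_id",
    "exposed",
    "block_sz",
    "is_target",
    "trial_index",
    "rt_ms",
    "outcome",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Reaction-time generator settings.

    Coefficients are in ms (slopes in ms per memory item) and default to the
    study's fitted values: intercept 428.0, set-size slope 19.4, exposure
    offset −15.0, exposure × set-size interaction 6.3, target offset −29.0.
    ``resid_sd`` (80 ms) is a typical trial-level RT dispersion and
    ``rt_floor`` (150 ms) a physiological lower bound; neither is an
    empirical estimate from the study.  ``subject_sd`` defaults to 0 so the
    generator matches the pooled-regression analysis model exactly;
    ``practice_drift`` (ms per trial, usually ≤ 0) adds a linear learning
    trend for robustness experiments.
    """

    beta0: float = 428.0
    beta1: float = 19.4
    beta2: float = -15.0
    beta3: float = 6.3
    beta4: float = -29.0
    resid_sd: float = 80.0
    subject_sd: float = 0.0
    practice_drift: float = 0.0
    p_error: float = 0.15
    rt_floor: float = 150.0
    censor_ms: float = 1000.0
    noise: str = "gaussian"  # or "exgaussian"
    exgauss_tau: float = 60.0  # mean of the exponential component, ms

    def __post_init__(self) -> None:
        if self.resid_sd < 0 or self.subject_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0.0 <= self.p_error <= 1.0:
            raise ValueError("p_error must be a probability")
        if self.rt_floor >= self.censor_ms:
            raise ValueError("rt_floor must lie below the censoring window")
        if self.noise not in ("gaussian", "exgaussian"):
            raise ValueError(f"unknown noise law {self.noise!r}")

    def as_coefficients(self) -> dict[str, float]:
        return {
            "beta0": self.beta0,
            "beta1": self.beta1,
            "beta2": self.beta2,
            "beta3": self.beta3,
            "beta4": self.beta4,
        }


@dataclass(frozen=True)
class RTRecord:
    """Outcome of one probe: a reaction time (absent for omissions) and a label."""

    trial: Trial
    exposed: int
    rt_ms: float | None
    outcome: str  # correct | error | omission

    def __post_init__(self) -> None:
        if (self.outcome == "omission") != (self.rt_ms is None):
            raise ValueError("rt_ms must be absent exactly for omissions")


def expected_rt(sz: int, tg: int, ex: int, params: GeneratorParams) -> float:
    """Noise-free model RT: b0 + b1*SZ + (b2 + b3*SZ)*EX + b4*TG."""
    return (
        params.beta0
        + params.beta1 * sz
        + (params.beta2 + params.beta3 * sz) * ex
        + params.beta4 * tg
    )


def _draw_noise(rng: np.random.Generator, n: int, params: GeneratorParams):
    eps = rng.normal(0.0, params.resid_sd, size=n) if params.resid_sd > 0 else np.zeros(n)
    if params.noise == "exgaussian":
        # centred exponential component: keeps the mean at expected_rt
        eps = eps + rng.exponential(params.exgauss_tau, size=n) - params.exgauss_tau
    return eps


def generate_record(
    trial: Trial,
    ex: int,
    params: GeneratorParams,
    subject_offset: float,
    rng: np.random.Generator,
    trial_index: int = 0,
) -> RTRecord:
    """Draw one trial outcome around the model mean.

    The latent RT is the model mean plus the subject offset, practice drift
    and trial noise; draws beyond the 1 s window are omissions (no RT),
    remaining trials are errors with probability ``p_error`` independently of
    their RT, and RTs are clamped below at ``rt_floor``.
    """
    latent = (
        expected_rt(trial.block_sz, trial.is_target, ex, params)
        + subject_offset
        + params.practice_drift * trial_index
        + _draw_noise(rng, 1, params)[0]
    )
    if latent > params.censor_ms:
        return RTRecord(trial=trial, exposed=ex, rt_ms=None, outcome="omission")
    rt = max(latent, params.rt_floor)
    outcome = "error" if rng.random() < params.p_error else "correct"
    return RTRecord(trial=trial, exposed=ex, rt_ms=float(rt), outcome=outcome)


def _simulate_session_frame(
    session: scheduler.Session,
    params: GeneratorParams,
    subject_offset: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    trials = session.test_trials
    n = len(trials)
    sz = np.array([t.block_sz for t in trials], dtype=float)
    tg = np.array([t.is_target for t in trials], dtype=float)
    ex = float(session.exposed)
    mean = (
        params.beta0
        + params.beta1 * sz
        + (params.beta2 + params.beta3 * sz) * ex
        + params.beta4 * tg
    )
    idx = np.arange(n)
    latent = mean + subject_offset + params.practice_drift * idx + _draw_noise(rng, n, params)
    omitted = latent > params.censor_ms
    rt = np.maximum(latent, params.rt_floor)
    err_draw = rng.random(n) < params.p_error
    outcome = np.where(omitted, "omission", np.where(err_draw, "error", "correct"))
    rt = np.where(omitted, np.nan, rt)
    return pd.DataFrame(
        {
            "subject_id": session.subject_id,
            "exposed": session.exposed,
            "block_sz": sz.astype(int),
            "is_target": tg.astype(int),
            "trial_index": idx,
            "rt_ms": rt,
            "outcome": outcome,
        }
    )


def simulate_cohort(
    plan: CohortPlan,
    params: GeneratorParams = GeneratorParams(),
    seed: int = 0,
    pools: SymbolPools | None = None,
    return_sessions: bool = False,
):
    """Simulate every subject's test session and trial outcomes.

    One session per subject is scheduled (seeded independently per subject
    from ``seed``), then trial RTs and outcomes are drawn.  Returns a tidy
    RT-record table; with ``return_sessions`` also the Session objects.
    """
    root = np.random.SeedSequence(seed)
    pool_seed, *subject_seeds = root.spawn(1 + len(plan.assignment))
    if pools is None:
        pools = scheduler.make_symbol_pools(pool_seed.generate_state(1)[0] % 2**31)
    frames, sessions = [], []
    for (sid, ex), ss in zip(plan.assignment.items(), subject_seeds):
        sched_seed = int(ss.generate_state(1)[0] % 2**31)
        session = scheduler.build_session(sid, ex, pools, sched_seed)
        rng = np.random.default_rng(ss.spawn(1)[0])
        offset = rng.normal(0.0, params.subject_sd) if params.subject_sd > 0 else 0.0
        frames.append(_simulate_session_frame(session, params, offset, rng))
        sessions.append(session)
    table = pd.concat(frames, ignore_index=True)
    if return_sessions:
        return table, sessions
    return table


#: Sham-group summary statistics (mean, SD, decimals of the printed precision)
#: used as default profile distributions for both groups, so that the cohort
#: is homogeneous by construction and homogeneity tests behave as null tests.
DEFAULT_PROFILE_VARS: dict[str, tuple[float, float, int]] = {
    "age": (22.8, 2.5, 1),
    "body_mass_index": (25.1, 3.7, 1),
    "headache": (1.2, 0.7, 1),
    "sleep_problems": (1.2, 0.8, 1),
    "tiredness": (1.4, 0.7, 1),
    "restlessness": (1.0, 0.9, 1),
    "difficulty_concentration": (1.4, 0.9, 1),
    "joint_pain": (0.9, 0.8, 1),
    "nervousness": (1.4, 1.2, 1),
    "nauseas": (0.2, 0.5, 1),
    "lack_appetite": (0.4, 0.5, 1),
    "feeling_sad": (0.4, 0.8, 1),
    "loss_memory": (0.6, 0.8, 1),
    "skin_problems": (0.5, 0.8, 1),
    "visual_problems": (0.4, 0.7, 1),
    "hearing_problems": (0.3, 0.6, 1),
    "dizziness": (0.2, 0.5, 1),
    "cardiovascular_problems": (0.0, 0.2, 1),
    "health_status": (2.7, 0.7, 1),
    "pc_hours_per_day": (4.8, 2.5, 1),
    "video_games": (0.7, 0.5, 1),
    "phone_minutes_per_day": (7.1, 0.6, 1),
}


def generate_profiles(
    plan: CohortPlan,
    seed: int = 0,
    variables: dict[str, tuple[float, float, int]] | None = None,
) -> pd.DataFrame:
    """Per-subject demographic / health / habit values from Gaussian draws.

    Both groups share the same distributions, so differences between groups
    are pure sampling noise; values are rounded to the given precision.
    """
    if variables is None:
        variables = DEFAULT_PROFILE_VARS
    rng = np.random.default_rng(seed)
    n = len(plan.assignment)
    data = {
        "subject_id": list(plan.assignment),
        "exposed": list(plan.assignment.values()),
    }
    for name, (mean, sd, decimals) in variables.items():
        draws = rng.normal(mean, sd, size=n) if sd > 0 else np.full(n, float(mean))
        data[name] = np.round(draws, decimals)
    return pd.DataFrame(data)


def write_records_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_records_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"RT-record CSV missing columns: {sorted(missing)}")
    return df
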