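"""Simulated observers for the sequential numerosity comparison task.

An observer chooses the *second* of two pulse trains with probability

    p = lapse/2 + (1 - lapse) * Phi(b0 + bN*xN + bD*xD + bT*xT)

where x are the second/first log2 ratios of numerosity, duration and
temporal spacing, Phi the standard normal CDF, and lapse the rate of
stimulus-independent guesses (split symmetrically over the two responses).
This is the generative inverse of the probit GLM used for analysis, so
simulated cohorts serve both as parameter-recovery testbeds and as the
engine of the Monte Carlo power analysis.

Single-feature observers read out exactly one temporal feature; their
coefficient vectors follow the log-linear feature geometry, e.g. a pure
total-event-duration (TED) reader has equal numerosity and duration
weights (gain * (1/2, 1/2, 0)).

Response times are cosmetic (they only exercise the screening rules) and
are drawn from a lognormal with a ~900 ms median by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dataset_builder import StimulusSet, subsample_balanced

__all__ = [
    "ObserverParams",
    "SessionData",
    "SESSION_COLUMNS",
    "choice_probability",
    "single_feature_observer",
    "simulate_session",
    "simulate_group",
    "sessions_to_csv",
    "read_sessions",
]

#: Direction of each feature readout in cardinal log2 space (num, dur, tmsp).
FEATURE_DIRECTIONS: Dict[str, Tuple[float, float, float]] = {
    "numerosity": (1.0, 0.0, 0.0),
    "ted": (0.5, 0.5, 0.0),
    "med": (-0.5, 0.5, 0.0),
    "tsd": (0.5, 0.0, 0.5),
    "mep": (-0.5, 0.0, 0.5),
    "cov": (0.0, 0.5, -0.5),
}

SESSION_COLUMNS = [
    "subject_id",
    "modality",
    "refresh_rate_hz",
    "phase",
    "trial_index",
    "pair_id",
    "log2_r_num",
    "log2_r_dur",
    "log2_r_tmsp",
    "response",
    "rt_ms",
    "correct",
]


@dataclass(frozen=True)
class ObserverParams:
    """Probit-observer parameters (coefficients per log2-ratio)."""

    beta_num: float
    beta_dur: float = 0.0
    beta_tmsp: float = 0.0
    beta0: float = 0.0
    lapse: float = 0.0
    rt_median_ms: float = 900.0
    rt_sigma: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError(f"lapse must lie in [0, 1], got {self.lapse}")
        for name in ("beta0", "beta_num", "beta_dur", "beta_tmsp"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def betas(self) -> Tuple[float, float, float]:
        return (self.beta_num, self.beta_dur, self.beta_tmsp)


@dataclass
class SessionData:
    """One participant's simulated (or imported) session.

    ``trials`` carries practice and test trials in the session CSV schema
    (see :data:`SESSION_COLUMNS`); response is coded 1 = chose first,
    2 = chose second.
    """

    subject_id: str
    modality: str
    refresh_rate_hz: float
    trials: pd.DataFrame
    #: generating parameters, kept for simulated sessions only (not in CSV)
    observer: ObserverParams | None = None

    def __post_init__(self) -> None:
        missing = set(SESSION_COLUMNS) - set(self.trials.columns)
        if missing:
            raise ValueError(f"trials missing columns: {sorted(missing)}")

    @property
    def test_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["phase"] == "test"]

    @property
    def practice_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["phase"] == "practice"]


def choice_probability(params: ObserverParams, x: Sequence[float]) -> float:
    """Probability of choosing the second sequence given log2-ratio triple x."""
    xn, xd, xt = x
    eta = (
        params.beta0
        + params.beta_num * xn
        + params.beta_dur * xd
        + params.beta_tmsp * xt
    )
    return params.lapse / 2.0 + (1.0 - params.lapse) * norm.cdf(eta)


def single_feature_observer(feature: str, gain: float, **kwargs) -> ObserverParams:
    """Observer reading out a single feature at the given gain.

    A TED reader at gain 2 has coefficients (1, 1, 0): equal positive
    weights on numerosity and duration.
    """
    if feature not in FEATURE_DIRECTIONS:
        raise ValueError(
            f"unknown feature {feature!r}; expected one of {sorted(FEATURE_DIRECTIONS)}"
        )
    if gain <= 0:
        raise ValueError("gain must be positive")
    d = FEATURE_DIRECTIONS[feature]
    return ObserverParams(
        beta_num=gain * d[0], beta_dur=gain * d[1], beta_tmsp=gain * d[2], **kwargs
    )


def _simulate_block(
    sset: StimulusSet,
    params: ObserverParams,
    rng: np.random.Generator,
    phase: str,
    shuffle: bool = True,
) -> List[dict]:
    order = np.arange(len(sset.pairs))
    if shuffle:
        rng.shuffle(order)
    rows = []
    for t, idx in enumerate(order):
        pair = sset.pairs[idx]
        r = pair.log2_ratios()
        x = (r["n"], r["dur"], r["tmsp"])
        p2 = choice_probability(params, x)
        response = 2 if rng.random() < p2 else 1
        larger = 2 if pair.second.n > pair.first.n else 1
        rt = float(
            np.exp(np.log(params.rt_median_ms) + params.rt_sigma * rng.standard_normal())
        )
        rows.append(
            {
                "phase": phase,
                "trial_index": t,
                "pair_id": pair.pair_id,
                "log2_r_num": x[0],
                "log2_r_dur": x[1],
                "log2_r_tmsp": x[2],
                "response": response,
                "rt_ms": rt,
                "correct": int(response == larger),
            }
        )
    return rows


def simulate_session(
    sset: StimulusSet,
    params: ObserverParams,
    rng: np.random.Generator,
    subject_id: str = "sim-000",
    modality: str = "visual",
    refresh_rate_hz: float = 60.0,
    practice_pool: StimulusSet | None = None,
    n_practice: int = 5,
) -> SessionData:
    """Simulate one session: optional practice block plus all pairs of ``sset``.

    Each pair yields one Bernoulli response at :func:`choice_probability`;
    trial order is shuffled.  Deterministic given the generator state.
    """
    rows: List[dict] = []
    if practice_pool is not None and n_practice > 0:
        pick = rng.choice(len(practice_pool.pairs), size=n_practice, replace=False)
        block = replace(
            practice_pool, pairs=[practice_pool.pairs[i] for i in pick]
        )
        rows.extend(_simulate_block(block, params, rng, "practice"))
    rows.extend(_simulate_block(sset, params, rng, "test"))
    df = pd.DataFrame(rows)
    df.insert(0, "subject_id", subject_id)
    df.insert(1, "modality", modality)
    df.insert(2, "refresh_rate_hz", refresh_rate_hz)
    return SessionData(
        subject_id=subject_id,
        modality=modality,
        refresh_rate_hz=refresh_rate_hz,
        trials=df[SESSION_COLUMNS],
        observer=params,
    )


def simulate_group(
    pop_mean: Sequence[float],
    pop_sd: Sequence[float],
    n_subjects: int,
    full_set: StimulusSet,
    seed: int | np.random.SeedSequence = 0,
    m_trials: int = 120,
    modality: str = "visual",
    lapse: float = 0.0,
    practice_pool: StimulusSet | None = None,
    intercept_mean: float = 0.0,
    intercept_sd: float = 0.0,
) -> List[SessionData]:
    """Simulate a cohort with normally distributed coefficients.

    Each subject gets independent normal draws of (beta_num, beta_dur,
    beta_tmsp), a fresh balanced ``m_trials``-pair subsample of ``full_set``
    and a fresh child RNG stream, all derived from the master seed.
    """
    if len(pop_mean) != 3 or len(pop_sd) != 3:
        raise ValueError("pop_mean and pop_sd must be length-3 (num, dur, tmsp)")
    if any(s < 0 for s in pop_sd) or intercept_sd < 0:
        raise ValueError("population SDs must be >= 0")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    sessions = []
    for k, child in enumerate(ss.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        betas = [m + s * rng.standard_normal() for m, s in zip(pop_mean, pop_sd)]
        b0 = intercept_mean + intercept_sd * rng.standard_normal()
        params = ObserverParams(
            beta_num=betas[0],
            beta_dur=betas[1],
            beta_tmsp=betas[2],
            beta0=b0,
            lapse=lapse,
        )
        subset = (
            subsample_balanced(full_set, m_trials, rng)
            if m_trials < len(full_set.pairs)
            else full_set
        )
        sessions.append(
            simulate_session(
                subset,
                params,
                rng,
                subject_id=f"sim-{k:03d}",
                modality=modality,
                practice_pool=practice_pool,
            )
        )
    return sessions


def sessions_to_csv(sessions: Sequence[SessionData], path: str | Path) -> None:
    """Write sessions to one CSV in the session schema."""
    pd.concat([s.trials for s in sessions], ignore_index=True).to_csv(
        path, index=False
    )


def read_sessions(path: str | Path) -> List[SessionData]:
    """Load sessions from a session-schema CSV (one per subject_id)."""
    df = pd.read_csv(path)
    missing = set(SESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"session CSV missing columns: {sorted(missing)}")
    out = []
    for sid, sub in df.groupby("subject_id", sort=True):
        out.append(
            SessionData(
                subject_id=str(sid),
                modality=str(sub["modality"].iloc[0]),
                refresh_rate_hz=float(sub["refresh_rate_hz"].iloc[0]),
                trials=sub.reset_index(drop=True),
            )
        )
    return out
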