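"""Trial- and participant-level exclusion pipeline.

Mirrors the pre-registered screening ladder of the comparison task:

* sessions recorded at a refresh rate other than 60 Hz are dropped;
* practice accuracy below 50% flags poor task comprehension;
* pairs at the maximal (2:1) numerosity ratio act as catch trials —
  accuracy below 75% on them flags inattention;
* responses before 200 ms (anticipations) or after 4 s are discarded at
  the trial level, and a participant loses more than 20% of test trials
  this way is excluded;
* an adjusted pseudo-R² below 0.2 flags a model fit too poor to interpret.

All thresholds use the printed "below"/"more than" semantics: values
exactly at a threshold are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from .observer_sim import SessionData
from .response_model import GlmFit

__all__ = [
    "ScreeningThresholds",
    "SubjectScreen",
    "ExclusionReport",
    "filter_trials",
    "is_catch_trial",
    "screen_participant",
    "screen_dataset",
]

#: |log2 numerosity ratio| at or above this marks a catch trial (ratio 2:1,
#: the design's largest; integer rounding can push it slightly above 2).
CATCH_LOG2_MIN = 1.0 - 1e-9


@dataclass(frozen=True)
class ScreeningThresholds:
    refresh_rate_hz: float = 60.0
    practice_min_accuracy: float = 0.50
    catch_min_accuracy: float = 0.75
    max_discard_fraction: float = 0.20
    min_r2_adj: float = 0.20
    rt_min_ms: float = 200.0
    rt_max_ms: float = 4000.0


@dataclass(frozen=True)
class SubjectScreen:
    """Screening outcome for one participant.

    ``flags`` maps criterion name -> (measured value, threshold); retained
    iff no flag was raised.
    """

    subject_id: str
    flags: Dict[str, Tuple[float | None, float]]
    retained: bool


@dataclass
class ExclusionReport:
    """Cohort-level screening summary."""

    subjects: List[SubjectScreen]
    counts: Dict[str, int]
    n_input: int
    n_retained: int

    @property
    def retained_ids(self) -> List[str]:
        return [s.subject_id for s in self.subjects if s.retained]

    def to_frame(self) -> pd.DataFrame:
        crits = sorted({c for s in self.subjects for c in s.flags})
        rows = []
        for s in self.subjects:
            row: dict = {"subject_id": s.subject_id, "retained": s.retained}
            for c in crits:
                row[f"flag_{c}"] = c in s.flags
                row[f"{c}_value"] = s.flags[c][0] if c in s.flags else None
            rows.append(row)
        return pd.DataFrame(rows)


def filter_trials(
    session: SessionData, rt_min_ms: float = 200.0, rt_max_ms: float = 4000.0
) -> Tuple[SessionData, float]:
    """Remove anticipations (rt < rt_min) and late responses (rt > rt_max)
    from the test block; returns the filtered session and the discarded
    fraction of test trials.  Boundary values are kept."""
    test = session.test_trials
    keep = (test["rt_ms"] >= rt_min_ms) & (test["rt_ms"] <= rt_max_ms)
    fraction = float((~keep).sum() / len(test)) if len(test) else 0.0
    filtered = pd.concat([session.practice_trials, test[keep]], ignore_index=True)
    return replace(session, trials=filtered), fraction


def is_catch_trial(trials: pd.DataFrame) -> pd.Series:
    """Mark trials at the maximal (2:1) numerosity ratio."""
    return trials["log2_r_num"].abs() >= CATCH_LOG2_MIN


def screen_participant(
    session: SessionData,
    fit: GlmFit | None,
    thresholds: ScreeningThresholds = ScreeningThresholds(),
) -> SubjectScreen:
    """Apply every participant-level rule to one session.

    ``fit`` must have been computed on the RT-filtered test trials; pass
    ``None`` when the model could not be fit (counts as a model-fit flag).
    A missing practice block raises a flag rather than silently passing.
    """
    th = thresholds
    flags: Dict[str, Tuple[float | None, float]] = {}

    if session.refresh_rate_hz != th.refresh_rate_hz:
        flags["refresh_rate"] = (session.refresh_rate_hz, th.refresh_rate_hz)

    practice = session.practice_trials
    if len(practice) == 0:
        flags["practice_missing"] = (None, th.practice_min_accuracy)
    else:
        acc = float(practice["correct"].mean())
        if acc < th.practice_min_accuracy:
            flags["practice_accuracy"] = (acc, th.practice_min_accuracy)

    _, fraction = filter_trials(session, th.rt_min_ms, th.rt_max_ms)
    if fraction > th.max_discard_fraction:
        flags["rt_discard_fraction"] = (fraction, th.max_discard_fraction)

    test = session.test_trials
    catch = test[is_catch_trial(test)]
    if len(catch) == 0:
        flags["catch_missing"] = (None, th.catch_min_accuracy)
    else:
        acc = float(catch["correct"].mean())
        if acc < th.catch_min_accuracy:
            flags["catch_accuracy"] = (acc, th.catch_min_accuracy)

    if fit is None:
        flags["model_fit"] = (None, th.min_r2_adj)
    else:
        r2 = fit.r2_adj
        if r2 < th.min_r2_adj:
            flags["model_fit"] = (r2, th.min_r2_adj)

    return SubjectScreen(
        subject_id=session.subject_id, flags=flags, retained=not flags
    )


def screen_dataset(
    sessions: Sequence[SessionData],
    fits: Dict[str, GlmFit | None],
    thresholds: ScreeningThresholds = ScreeningThresholds(),
) -> ExclusionReport:
    """Screen a cohort; ``fits`` maps subject_id -> GlmFit (or None).

    Screening is idempotent: re-screening the retained subjects changes
    nothing, since every rule is a pure function of a subject's own data.
    """
    subjects = [
        screen_participant(s, fits.get(s.subject_id), thresholds) for s in sessions
    ]
    counts: Dict[str, int] = {}
    for s in subjects:
        for crit in s.flags:
            counts[crit] = counts.get(crit, 0) + 1
    return ExclusionReport(
        subjects=subjects,
        counts=counts,
        n_input=len(subjects),
        n_retained=sum(s.retained for s in subjects),
    )
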