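"""Realize cardinal points as integer-frame pulse trains.

A stimulus is a sequence of ``n`` pulses ("events") separated by empty
intervals ("gaps"), described by 0-based integer frame timestamps so that
the same train can drive either a visual (flashing disc) or an auditory
(tone pip) presentation.  Event durations are constrained to 2–16 frames
and gaps to 3–30 frames by default (33–267 ms and 50–500 ms at 60 Hz),
keeping both above visual/auditory temporal-resolution thresholds.

Generation targets a :class:`~seqnum.feature_space.CardinalPoint`: the total
event duration TED is split into ``n`` bounded integer parts and the total
gap time TSD−TED into ``n−1`` bounded parts.  TED and TSD−TED are rounded
to whole frames first, so achieved log2 features can differ from the target
by a small quantization error (bounded by ~0.02 in log2 units for the
default grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .feature_space import CardinalPoint, FeatureSet, features_from_cardinal

__all__ = [
    "GenerationConstraints",
    "EventSequence",
    "Feasibility",
    "InfeasiblePointError",
    "feasible",
    "compose_bounded",
    "realize_sequence",
    "sequence_features",
    "validate_sequence",
]


@dataclass(frozen=True)
class GenerationConstraints:
    """Per-event and per-gap bounds (frames) plus presentation metadata."""

    dmin: int = 2
    dmax: int = 16
    gmin: int = 3
    gmax: int = 30
    regular: bool = False
    frame_rate: float = 60.0

    def __post_init__(self) -> None:
        if not (0 < self.dmin <= self.dmax):
            raise ValueError(f"need 0 < dmin <= dmax, got {self.dmin}, {self.dmax}")
        if not (0 < self.gmin <= self.gmax):
            raise ValueError(f"need 0 < gmin <= gmax, got {self.gmin}, {self.gmax}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")


@dataclass(frozen=True)
class EventSequence:
    """Integer-frame onsets/offsets of one pulse train (0-based, onset 0)."""

    onsets: Tuple[int, ...]
    offsets: Tuple[int, ...]
    frame_rate: float = 60.0

    def __post_init__(self) -> None:
        on, off = self.onsets, self.offsets
        if len(on) != len(off) or len(on) < 2:
            raise ValueError("need >= 2 events with matching onsets/offsets")
        if on[0] != 0:
            raise ValueError(f"first onset must be frame 0, got {on[0]}")
        for i in range(len(on)):
            if off[i] <= on[i]:
                raise ValueError(f"event {i}: offset {off[i]} <= onset {on[i]}")
            if i and on[i] < off[i - 1]:
                raise ValueError(f"event {i} overlaps previous event")

    @property
    def n(self) -> int:
        return len(self.onsets)

    @property
    def durations(self) -> Tuple[int, ...]:
        return tuple(b - a for a, b in zip(self.onsets, self.offsets))

    @property
    def gaps(self) -> Tuple[int, ...]:
        return tuple(a - b for a, b in zip(self.onsets[1:], self.offsets[:-1]))

    @property
    def span(self) -> int:
        """Realized TSD in frames: last offset minus first onset."""
        return self.offsets[-1] - self.onsets[0]


@dataclass(frozen=True)
class Feasibility:
    """Verdict of the bound check for realizing a point."""

    ok: bool
    violations: Tuple[str, ...] = field(default_factory=tuple)

    def __bool__(self) -> bool:
        return self.ok


class InfeasiblePointError(ValueError):
    """Raised when a cardinal point cannot be realized under the constraints."""

    def __init__(self, verdict: Feasibility):
        self.verdict = verdict
        super().__init__("; ".join(verdict.violations) or "infeasible point")


def feasible(p: CardinalPoint, c: GenerationConstraints) -> Feasibility:
    """Check whether ``p`` admits an integer realization under ``c``.

    The rounded TED must be splittable into ``n`` events of dmin..dmax frames
    and the rounded gap total TSD−TED into ``n−1`` gaps of gmin..gmax frames.
    """
    f = features_from_cardinal(p)
    ted = round(f.ted)
    gap_total = round(f.tsd - f.ted)
    n = p.n
    violations: List[str] = []
    if ted < n * c.dmin:
        violations.append(f"TED below n*dmin ({ted} < {n * c.dmin})")
    if ted > n * c.dmax:
        violations.append(f"TED above n*dmax ({ted} > {n * c.dmax})")
    if gap_total < (n - 1) * c.gmin:
        violations.append(
            f"gap total below (n-1)*gmin ({gap_total} < {(n - 1) * c.gmin})"
        )
    if gap_total > (n - 1) * c.gmax:
        violations.append(
            f"gap total above (n-1)*gmax ({gap_total} > {(n - 1) * c.gmax})"
        )
    return Feasibility(ok=not violations, violations=tuple(violations))


def compose_bounded(
    total: int,
    parts: int,
    lo: int,
    hi: int,
    rng: np.random.Generator | None = None,
    regular: bool = False,
) -> List[int]:
    """Split ``total`` into ``parts`` integers, each in [lo, hi].

    With ``regular=True`` the split is maximally equal (values differ by at
    most 1).  Otherwise each part is drawn uniformly on the sub-interval that
    keeps the remainder feasible, and the list is shuffled afterwards; the
    induced distribution over compositions is not uniform, only the bounds
    and the sum are guaranteed.

    Raises
    ------
    ValueError
        Naming the violated inequality when ``total`` cannot be split.
    """
    if parts < 1:
        raise ValueError(f"parts must be >= 1, got {parts}")
    if total < parts * lo:
        raise ValueError(f"infeasible: total {total} < parts*lo = {parts * lo}")
    if total > parts * hi:
        raise ValueError(f"infeasible: total {total} > parts*hi = {parts * hi}")

    if regular:
        base, extra = divmod(total, parts)
        values = [base + 1] * extra + [base] * (parts - extra)
        return values

    if rng is None:
        rng = np.random.default_rng()
    values = []
    rem = total
    for k in range(parts, 0, -1):
        lo_k = max(lo, rem - (k - 1) * hi)
        hi_k = min(hi, rem - (k - 1) * lo)
        v = int(rng.integers(lo_k, hi_k + 1))
        values.append(v)
        rem -= v
    rng.shuffle(values)
    return values


def realize_sequence(
    p: CardinalPoint,
    c: GenerationConstraints,
    rng: np.random.Generator | None = None,
) -> EventSequence:
    """Assemble an :class:`EventSequence` matching ``p`` under ``c``.

    Event durations come from splitting round(TED) into ``n`` parts and gaps
    from splitting round(TSD−TED) into ``n−1`` parts; ``c.regular`` selects
    maximally equal splits (fixed IED / fixed inter-event interval trains).
    """
    verdict = feasible(p, c)
    if not verdict:
        raise InfeasiblePointError(verdict)
    f = features_from_cardinal(p)
    durations = compose_bounded(
        round(f.ted), p.n, c.dmin, c.dmax, rng=rng, regular=c.regular
    )
    gaps = compose_bounded(
        round(f.tsd - f.ted), p.n - 1, c.gmin, c.gmax, rng=rng, regular=c.regular
    )
    onsets, offsets = [0], [durations[0]]
    for dur, gap in zip(durations[1:], gaps):
        onsets.append(offsets[-1] + gap)
        offsets.append(onsets[-1] + dur)
    return EventSequence(
        onsets=tuple(onsets), offsets=tuple(offsets), frame_rate=c.frame_rate
    )


def sequence_features(s: EventSequence) -> FeatureSet:
    """Measure the temporal features of a realized sequence.

    ted = sum of event durations, tsd = first-onset→last-offset span,
    med = ted/n, mep = tsd/n, cov = ted/tsd.
    """
    if s.n < 2:
        raise ValueError("need at least 2 events to measure features")
    ted = float(sum(s.durations))
    tsd = float(s.span)
    return FeatureSet(ted=ted, med=ted / s.n, tsd=tsd, mep=tsd / s.n, cov=ted / tsd)


def validate_sequence(s: EventSequence, c: GenerationConstraints) -> List[str]:
    """List every bound violation of ``s`` under ``c`` (empty list = valid)."""
    problems = []
    for i, d in enumerate(s.durations):
        if not (c.dmin <= d <= c.dmax):
            problems.append(f"event {i} duration {d} outside [{c.dmin}, {c.dmax}]")
    for i, g in enumerate(s.gaps):
        if not (c.gmin <= g <= c.gmax):
            problems.append(f"gap {i} of {g} frames outside [{c.gmin}, {c.gmax}]")
    return problems
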