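"""Algebra of the orthogonal stimulus space for sequential numerosity.

A sequence of pulses is located by three cardinal coordinates — numerosity
``n``, duration ``Dur`` and temporal spacing ``TmSp`` — chosen so that the
familiar temporal features of the pulse train are log-linear combinations
of the cardinal axes:

    TED = sqrt(Dur * n)     total event duration (sum of pulse lengths)
    MED = sqrt(Dur / n)     mean event duration (= IED for regular trains)
    TSD = sqrt(TmSp * n)    total stimulus duration (first onset - last offset)
    MEP = sqrt(TmSp / n)    mean event period
    Cov = sqrt(Dur / TmSp)  coverage, TED / TSD

so ``Dur = TED * MED`` and ``TmSp = TSD * MEP``.  ``Dur`` and ``TmSp`` carry
units of frames² at a configurable frame rate; millisecond values are views
computed on demand, never stored.

All logarithms here are base 2: a one-unit step in any log coordinate is a
doubling, and GLM coefficients downstream are per-log2-ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Tuple

__all__ = [
    "CardinalPoint",
    "FeatureSet",
    "FEATURE_NAMES",
    "features_from_cardinal",
    "cardinal_from_features",
    "log2_feature_ratios",
    "frames_to_ms",
]

#: Feature names accepted by observer / projection helpers, in canonical order.
FEATURE_NAMES: Tuple[str, ...] = ("numerosity", "ted", "med", "tsd", "mep", "cov")


@dataclass(frozen=True)
class CardinalPoint:
    """A stimulus location (n, Dur, TmSp) in the orthogonal parameter space.

    Parameters
    ----------
    n : int
        Number of events, >= 2.
    dur : float
        Duration product TED*MED in frames².
    tmsp : float
        Temporal-spacing product TSD*MEP in frames².  Must be >= ``dur``
        (equivalently TSD >= TED: the pulses fit inside the sequence).
    """

    n: int
    dur: float
    tmsp: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"numerosity must be >= 2, got {self.n}")
        if not (self.dur > 0 and math.isfinite(self.dur)):
            raise ValueError(f"dur must be positive and finite, got {self.dur}")
        if not (self.tmsp > 0 and math.isfinite(self.tmsp)):
            raise ValueError(f"tmsp must be positive and finite, got {self.tmsp}")
        if self.tmsp < self.dur:
            raise ValueError(
                f"tmsp ({self.tmsp}) < dur ({self.dur}): implies TSD < TED, "
                "i.e. pulses longer than the sequence"
            )


@dataclass(frozen=True)
class FeatureSet:
    """The five derived temporal features of one sequence (frames / unitless).

    For regular sequences MED coincides with the individual event duration
    (IED); no separate IED field is carried.
    """

    ted: float
    med: float
    tsd: float
    mep: float
    cov: float

    def __post_init__(self) -> None:
        for name in ("ted", "med", "tsd", "mep"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if not (0 < self.cov <= 1 + 1e-12):
            raise ValueError(f"coverage must lie in (0, 1], got {self.cov}")


def features_from_cardinal(p: CardinalPoint) -> FeatureSet:
    """Map a cardinal point to its derived temporal features.

    Implements the square-root feature formulas: ted = sqrt(dur*n),
    med = sqrt(dur/n), tsd = sqrt(tmsp*n), mep = sqrt(tmsp/n),
    cov = sqrt(dur/tmsp).
    """
    return FeatureSet(
        ted=math.sqrt(p.dur * p.n),
        med=math.sqrt(p.dur / p.n),
        tsd=math.sqrt(p.tmsp * p.n),
        mep=math.sqrt(p.tmsp / p.n),
        cov=math.sqrt(p.dur / p.tmsp),
    )


def cardinal_from_features(ted: float, tsd: float, n: int) -> CardinalPoint:
    """Invert the feature map: (TED, TSD, n) -> (n, Dur, TmSp).

    Raises
    ------
    ValueError
        If ``tsd < ted`` (the pulses cannot exceed the sequence span) or the
        inputs are non-positive.
    """
    if ted <= 0 or tsd <= 0:
        raise ValueError(f"ted and tsd must be positive, got ted={ted}, tsd={tsd}")
    if tsd < ted:
        raise ValueError(
            f"infeasible geometry: tsd ({tsd}) < ted ({ted})"
        )
    return CardinalPoint(n=n, dur=ted * ted / n, tmsp=tsd * tsd / n)


def log2_feature_ratios(a: CardinalPoint, b: CardinalPoint) -> Dict[str, float]:
    """Log2 ratios of cardinal and derived features of ``b`` relative to ``a``.

    Uses the log-linear relations: each derived-feature log-ratio is a
    half-weight combination of the cardinal log-ratios, e.g.
    ``log r_TED = 1/2 log r_Dur + 1/2 log r_n`` and
    ``log r_Cov = 1/2 log r_Dur - 1/2 log r_TmSp``.

    Returns a dict with keys ``n, dur, tmsp, ted, med, tsd, mep, cov``.
    """
    rn = math.log2(b.n / a.n)
    rd = math.log2(b.dur / a.dur)
    rt = math.log2(b.tmsp / a.tmsp)
    return {
        "n": rn,
        "dur": rd,
        "tmsp": rt,
        "ted": 0.5 * rd + 0.5 * rn,
        "med": 0.5 * rd - 0.5 * rn,
        "tsd": 0.5 * rt + 0.5 * rn,
        "mep": 0.5 * rt - 0.5 * rn,
        "cov": 0.5 * rd - 0.5 * rt,
    }


def frames_to_ms(frames: float | Iterable[float], frame_rate: float = 60.0):
    """Convert frame counts to milliseconds at the given refresh rate.

    A view helper: stored quantities stay in frames; 2 frames at 60 Hz is
    33.33 ms.
    """
    import numpy as np

    return np.asarray(frames, dtype=float) * (1000.0 / frame_rate)
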