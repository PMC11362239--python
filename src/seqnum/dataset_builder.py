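"""Build stimulus datasets: the 13-level log grid, ratio-constrained pairs,
the 500-pair dataset and balanced 120-trial subsamples.

Each of the three cardinal dimensions takes 13 levels evenly spaced on a log
scale over a 1:4 range (numerosity 7–28, rounded to distinct integers; the
duration and temporal-spacing anchors are calibrated so that realized
sequence durations at 60 Hz span roughly 1.7–6.8 s).  A comparison pair
picks, independently per dimension, two grid levels whose index distance is
1–6, i.e. an ideal ratio between 4^(1/12) ≈ 1.12 and 2.  Pairs whose gap
bounds cannot be met are rejected and resampled.

The per-participant subsample balances the signed index distance (−6..−1,
1..6) of every dimension simultaneously; this three-way balance is found
by a randomized best-swap local search (with an exact binary integer
program as fallback), followed by a profile-preserving swap repair that
guarantees each dimension's extreme levels appear.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .feature_space import CardinalPoint
from .sequence_gen import (
    EventSequence,
    GenerationConstraints,
    feasible,
    realize_sequence,
    sequence_features,
    validate_sequence,
)

__all__ = [
    "LevelGrid",
    "PairSpec",
    "StimulusPair",
    "StimulusSet",
    "make_levels",
    "default_grid",
    "sample_pair_spec",
    "build_dataset",
    "build_practice_pool",
    "subsample_balanced",
    "write_stimulus_set",
    "read_stimulus_set",
    "pair_manifest",
]

SCHEMA_TAG = "seqnum-stimulus-set/1"

#: Default anchors (frames²). MED spans 3–12 frames and TSD spans ~102–408
#: frames (1.70–6.80 s at 60 Hz) over the numerosity range 7–28.
DEFAULT_DUR_ANCHOR = 252.0
DEFAULT_TMSP_ANCHOR = 1487.0


def make_levels(
    vmin: float, max_ratio: float = 4.0, k: int = 13, integer: bool = False
) -> List[float] | List[int]:
    """Geometric ladder of ``k`` levels from ``vmin`` to ``vmin*max_ratio``.

    Level i is ``vmin * max_ratio**(i/(k-1))``.  With ``integer=True`` levels
    are rounded to the nearest integer and must remain distinct.
    """
    if vmin <= 0:
        raise ValueError("vmin must be positive")
    if k < 2:
        raise ValueError(f"need at least 2 levels, got k={k}")
    if max_ratio <= 1:
        raise ValueError("max_ratio must exceed 1")
    levels = [vmin * max_ratio ** (i / (k - 1)) for i in range(k)]
    if integer:
        rounded = [int(round(v)) for v in levels]
        if len(set(rounded)) != k:
            raise ValueError(
                "integer rounding collapses grid levels (grid too dense)"
            )
        return rounded
    return levels


@dataclass(frozen=True)
class LevelGrid:
    """13-level log grids for numerosity (integer), Dur and TmSp (frames²)."""

    num_levels: Tuple[int, ...]
    dur_levels: Tuple[float, ...]
    tmsp_levels: Tuple[float, ...]

    def __post_init__(self) -> None:
        for name in ("num_levels", "dur_levels", "tmsp_levels"):
            lv = getattr(self, name)
            if len(lv) < 2 or any(b <= a for a, b in zip(lv, lv[1:])):
                raise ValueError(f"{name} must be strictly increasing, length >= 2")

    @property
    def k(self) -> int:
        return len(self.num_levels)

    def point(self, i_num: int, i_dur: int, i_tmsp: int) -> CardinalPoint:
        return CardinalPoint(
            n=self.num_levels[i_num],
            dur=self.dur_levels[i_dur],
            tmsp=self.tmsp_levels[i_tmsp],
        )


def default_grid(
    num_anchor: int = 7,
    dur_anchor: float = DEFAULT_DUR_ANCHOR,
    tmsp_anchor: float = DEFAULT_TMSP_ANCHOR,
    max_ratio: float = 4.0,
    k: int = 13,
) -> LevelGrid:
    """The study grid: integer numerosity 7..28 plus calibrated Dur/TmSp."""
    return LevelGrid(
        num_levels=tuple(make_levels(num_anchor, max_ratio, k, integer=True)),
        dur_levels=tuple(make_levels(dur_anchor, max_ratio, k)),
        tmsp_levels=tuple(make_levels(tmsp_anchor, max_ratio, k)),
    )


@dataclass(frozen=True)
class PairSpec:
    """Grid placement of one comparison pair (indices into a LevelGrid)."""

    idx_first: Tuple[int, int, int]
    idx_second: Tuple[int, int, int]

    def signed_distances(self) -> Tuple[int, int, int]:
        """Second-minus-first index distance per dimension (−6..−1, 1..6)."""
        return tuple(b - a for a, b in zip(self.idx_first, self.idx_second))


@dataclass(frozen=True)
class StimulusPair:
    """A realized pair: spec, cardinal points and the two pulse trains."""

    pair_id: int
    spec: PairSpec
    first: CardinalPoint
    second: CardinalPoint
    seq_first: EventSequence
    seq_second: EventSequence

    def log2_ratios(self) -> Dict[str, float]:
        """Second/first log2 ratios of the three cardinal dimensions."""
        return {
            "n": math.log2(self.second.n / self.first.n),
            "dur": math.log2(self.second.dur / self.first.dur),
            "tmsp": math.log2(self.second.tmsp / self.first.tmsp),
        }

    @property
    def numerosity_ratio(self) -> float:
        """Realized larger/smaller numerosity ratio (>= 1)."""
        hi, lo = max(self.first.n, self.second.n), min(self.first.n, self.second.n)
        return hi / lo


@dataclass
class StimulusSet:
    """A collection of realized pairs with its grid, constraints and seed."""

    pairs: List[StimulusPair]
    grid: LevelGrid
    constraints: GenerationConstraints
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.pairs)

    def sequences(self):
        for p in self.pairs:
            yield p.seq_first
            yield p.seq_second


def sample_pair_spec(
    grid: LevelGrid,
    c: GenerationConstraints,
    rng: np.random.Generator,
    max_tries: int = 10_000,
) -> Tuple[PairSpec, CardinalPoint, CardinalPoint]:
    """Draw one ratio-constrained pair of grid placements.

    Per dimension the index distance is uniform on {1..6} with random sign
    and random placement; draws whose endpoints violate the gap/event bounds
    are rejected and resampled.
    """
    k = grid.k
    for _ in range(max_tries):
        lo_idx, hi_idx = [], []
        for _dim in range(3):
            d = int(rng.integers(1, 7))
            start = int(rng.integers(0, k - d))
            sign = 1 if rng.random() < 0.5 else -1
            if sign > 0:
                lo_idx.append(start)
                hi_idx.append(start + d)
            else:
                lo_idx.append(start + d)
                hi_idx.append(start)
        spec = PairSpec(idx_first=tuple(lo_idx), idx_second=tuple(hi_idx))
        first = grid.point(*spec.idx_first)
        second = grid.point(*spec.idx_second)
        if feasible(first, c) and feasible(second, c):
            return spec, first, second
    raise RuntimeError(f"no feasible pair found in {max_tries} draws")


def build_dataset(
    n_pairs: int = 500,
    grid: LevelGrid | None = None,
    constraints: GenerationConstraints | None = None,
    seed: int | None = 0,
) -> StimulusSet:
    """Generate the initial dataset of ratio-constrained pairs (default 500)."""
    grid = grid or default_grid()
    constraints = constraints or GenerationConstraints()
    rng = np.random.default_rng(seed)
    pairs = []
    for pid in range(n_pairs):
        spec, first, second = sample_pair_spec(grid, constraints, rng)
        pairs.append(
            StimulusPair(
                pair_id=pid,
                spec=spec,
                first=first,
                second=second,
                seq_first=realize_sequence(first, constraints, rng),
                seq_second=realize_sequence(second, constraints, rng),
            )
        )
    return StimulusSet(pairs=pairs, grid=grid, constraints=constraints, seed=seed)


def build_practice_pool(
    grid: LevelGrid | None = None,
    constraints: GenerationConstraints | None = None,
    rng: np.random.Generator | None = None,
    n_pairs: int = 30,
    max_tries: int = 10_000,
) -> StimulusSet:
    """Easy practice pairs: numerosity ratio 1:4 (grid extremes, e.g. 7 vs 28),
    non-numerical ratios 1.1–2 as in the test set."""
    grid = grid or default_grid()
    constraints = constraints or GenerationConstraints()
    rng = rng if rng is not None else np.random.default_rng()
    k = grid.k
    pairs = []
    for pid in range(n_pairs):
        for _ in range(max_tries):
            flip = rng.random() < 0.5
            i_first, i_second = (k - 1, 0) if flip else (0, k - 1)
            idx_first, idx_second = [i_first], [i_second]
            for _dim in range(2):
                d = int(rng.integers(1, 7))
                start = int(rng.integers(0, k - d))
                sign = 1 if rng.random() < 0.5 else -1
                a, b = (start, start + d) if sign > 0 else (start + d, start)
                idx_first.append(a)
                idx_second.append(b)
            spec = PairSpec(idx_first=tuple(idx_first), idx_second=tuple(idx_second))
            first = grid.point(*spec.idx_first)
            second = grid.point(*spec.idx_second)
            if feasible(first, constraints) and feasible(second, constraints):
                pairs.append(
                    StimulusPair(
                        pair_id=pid,
                        spec=spec,
                        first=first,
                        second=second,
                        seq_first=realize_sequence(first, constraints, rng),
                        seq_second=realize_sequence(second, constraints, rng),
                    )
                )
                break
        else:
            raise RuntimeError("no feasible practice pair found")
    return StimulusSet(pairs=pairs, grid=grid, constraints=constraints, seed=None)


def _bin_index(d: int) -> int:
    """Map a signed distance −6..−1, 1..6 to a bin 0..11."""
    return d + 6 if d < 0 else d + 5


def subsample_balanced(
    sset: StimulusSet,
    m: int = 120,
    rng: np.random.Generator | None = None,
    method: str = "auto",
) -> StimulusSet:
    """Random subsample of ``m`` pairs balanced on all three dimensions.

    Per dimension, the 12 signed-index-distance bins receive counts that
    differ by at most 1 (exactly m/12 each when m is divisible by 12), and
    each dimension's extreme grid levels are represented.  Balance across
    the three coupled dimensions is found by a randomized best-swap local
    search (fast; the usual path) falling back to a binary integer program
    (HiGHS via scipy) if the search stalls; ``method`` may force ``"local"``
    or ``"milp"``.
    """
    npairs = len(sset.pairs)
    if m > npairs:
        raise ValueError(f"cannot subsample {m} from {npairs} pairs")
    if m == npairs:
        return replace(sset, pairs=list(sset.pairs))
    rng = rng if rng is not None else np.random.default_rng()

    lo, hi = m // 12, -(-m // 12)
    bins = np.empty((npairs, 3), dtype=int)
    for i, p in enumerate(sset.pairs):
        bins[i] = [_bin_index(d) for d in p.spec.signed_distances()]

    # source deficit check: every bin needs at least `lo` candidate pairs
    deficient = []
    for dim in range(3):
        counts = np.bincount(bins[:, dim], minlength=12)
        for b in range(12):
            if counts[b] < lo:
                deficient.append((["num", "dur", "tmsp"][dim], b, int(counts[b])))
    if deficient:
        raise ValueError(f"source set cannot satisfy balance; deficient bins: {deficient}")

    # a draw can balance perfectly yet miss an extreme level that no
    # profile-preserving swap can restore; retry with fresh costs first
    last_error: Exception | None = None
    for _attempt in range(5):
        chosen = None
        if method in ("auto", "local"):
            chosen = _balance_local_search(bins, m, lo, hi, rng)
            if chosen is None and method == "local":
                raise ValueError("local-search balancing stalled")
        if chosen is None:
            chosen = _balance_milp(bins, m, lo, hi, rng)
        try:
            chosen = _repair_range_coverage(sset, chosen, bins)
        except ValueError as e:
            last_error = e
            continue
        return replace(sset, pairs=[sset.pairs[i] for i in sorted(chosen)])
    raise ValueError(f"balanced subsample failed range coverage: {last_error}")


def _balance_local_search(bins, m, lo, hi, rng, cap: int = 5000):
    """Best-swap local search on the bin-deviation objective; None if stalled."""
    npairs = len(bins)
    dims = np.arange(3)

    def cost(c):
        return np.maximum(0, lo - c) + np.maximum(0, c - hi)

    chosen = list(rng.choice(npairs, m, replace=False))
    inset = np.zeros(npairs, dtype=bool)
    inset[chosen] = True
    counts = np.zeros((3, 12), dtype=int)
    for i in chosen:
        counts[dims, bins[i]] += 1
    total = int(cost(counts).sum())
    it = 0
    while total > 0 and it < cap:
        it += 1
        ii = int(rng.integers(m))
        i = chosen[ii]
        bi = bins[i]
        rem = cost(counts[dims, bi] - 1) - cost(counts[dims, bi])
        add = cost(counts + 1) - cost(counts)
        per_pair = add[dims[None, :], bins]
        same = bins == bi[None, :]
        delta = np.where(same, 0, rem[None, :] + per_pair).sum(axis=1)
        delta[inset] = np.iinfo(np.int64).max
        dmin = int(delta.min())
        if dmin < 0 or (dmin == 0 and rng.random() < 0.05):
            cands = np.flatnonzero(delta == dmin)
            j = int(cands[rng.integers(len(cands))])
            chosen[ii] = j
            inset[i] = False
            inset[j] = True
            counts[dims, bi] -= 1
            counts[dims, bins[j]] += 1
            total += dmin
    return np.array(chosen) if total == 0 else None


def _balance_milp(bins, m, lo, hi, rng):
    """Exact balanced selection as a binary integer program (HiGHS)."""
    from scipy.optimize import LinearConstraint, milp
    from scipy.sparse import lil_matrix

    npairs = len(bins)
    A = lil_matrix((1 + 36, npairs))
    A[0, :] = 1.0
    lower = np.empty(37)
    upper = np.empty(37)
    lower[0] = upper[0] = m
    for dim in range(3):
        for b in range(12):
            r = 1 + dim * 12 + b
            A[r, bins[:, dim] == b] = 1.0
            lower[r], upper[r] = lo, hi
    res = milp(
        c=rng.random(npairs),
        constraints=LinearConstraint(A.tocsr(), lower, upper),
        integrality=np.ones(npairs),
        bounds=(0, 1),
    )
    if not res.success:
        raise ValueError(f"balanced subsample infeasible: {res.message}")
    return np.flatnonzero(res.x > 0.5)


def _levels_covered(sset: StimulusSet, chosen, dim: int) -> set:
    out = set()
    for i in chosen:
        out.add(sset.pairs[i].spec.idx_first[dim])
        out.add(sset.pairs[i].spec.idx_second[dim])
    return out


def _repair_range_coverage(sset: StimulusSet, chosen, bins) -> np.ndarray:
    """Swap in pairs so each dimension's min and max grid level appear.

    Swaps exchange pairs with identical bin profiles, so balance is kept.
    """
    chosen = set(int(i) for i in chosen)
    k = sset.grid.k
    targets = [(dim, e) for dim in range(3) for e in (0, k - 1)]

    def all_covered(upto: int) -> bool:
        return all(
            e in _levels_covered(sset, chosen, d) for d, e in targets[: upto + 1]
        )

    for t, (dim, extreme) in enumerate(targets):
        if extreme in _levels_covered(sset, chosen, dim):
            continue
        done = False
        for j in range(len(sset.pairs)):
            if j in chosen:
                continue
            pj = sset.pairs[j].spec
            if extreme not in (pj.idx_first[dim], pj.idx_second[dim]):
                continue
            for i in list(chosen):
                if not np.array_equal(bins[i], bins[j]):
                    continue
                chosen.discard(i)
                chosen.add(j)
                if all_covered(t):
                    done = True
                    break
                chosen.add(i)  # undo: the swap broke an earlier repair
                chosen.discard(j)
            if done:
                break
        if not done:
            raise ValueError(
                f"cannot cover extreme level {extreme} of dimension {dim} "
                "in balanced subsample"
            )
    return np.array(sorted(chosen))


# ---------------------------------------------------------------------------
# serialization

def _seq_to_json(s: EventSequence) -> dict:
    return {"onsets": list(s.onsets), "offsets": list(s.offsets)}


def write_stimulus_set(sset: StimulusSet, path: str | Path) -> None:
    """Serialize a stimulus set to versioned JSON (timestamps in frames)."""
    c = sset.constraints
    doc = {
        "schema": SCHEMA_TAG,
        "seed": sset.seed,
        "grid": {
            "num_levels": list(sset.grid.num_levels),
            "dur_levels": list(sset.grid.dur_levels),
            "tmsp_levels": list(sset.grid.tmsp_levels),
        },
        "constraints": {
            "dmin": c.dmin,
            "dmax": c.dmax,
            "gmin": c.gmin,
            "gmax": c.gmax,
            "regular": c.regular,
            "frame_rate": c.frame_rate,
        },
        "pairs": [
            {
                "pair_id": p.pair_id,
                "idx_first": list(p.spec.idx_first),
                "idx_second": list(p.spec.idx_second),
                "first": {"n": p.first.n, "dur": p.first.dur, "tmsp": p.first.tmsp},
                "second": {"n": p.second.n, "dur": p.second.dur, "tmsp": p.second.tmsp},
                "seq_first": _seq_to_json(p.seq_first),
                "seq_second": _seq_to_json(p.seq_second),
            }
            for p in sset.pairs
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_stimulus_set(path: str | Path) -> StimulusSet:
    """Parse and validate a stimulus-set JSON file.

    Every realized sequence is re-validated against the stored constraints;
    bound violations (e.g. a 17-frame event under a 16-frame cap) are parse
    errors naming the offending pair.
    """
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != SCHEMA_TAG:
        raise ValueError(f"unknown schema tag: {doc.get('schema')!r}")
    for key in ("grid", "constraints", "pairs"):
        if key not in doc:
            raise ValueError(f"missing field: {key}")
    g = doc["grid"]
    grid = LevelGrid(
        num_levels=tuple(int(v) for v in g["num_levels"]),
        dur_levels=tuple(float(v) for v in g["dur_levels"]),
        tmsp_levels=tuple(float(v) for v in g["tmsp_levels"]),
    )
    c = GenerationConstraints(**doc["constraints"])
    pairs = []
    for rec in doc["pairs"]:
        try:
            spec = PairSpec(
                idx_first=tuple(rec["idx_first"]), idx_second=tuple(rec["idx_second"])
            )
            first = CardinalPoint(**rec["first"])
            second = CardinalPoint(**rec["second"])
            sf = EventSequence(
                onsets=tuple(rec["seq_first"]["onsets"]),
                offsets=tuple(rec["seq_first"]["offsets"]),
                frame_rate=c.frame_rate,
            )
            ss = EventSequence(
                onsets=tuple(rec["seq_second"]["onsets"]),
                offsets=tuple(rec["seq_second"]["offsets"]),
                frame_rate=c.frame_rate,
            )
        except KeyError as e:
            raise ValueError(f"pair {rec.get('pair_id')}: missing field {e}") from e
        for label, seq in (("seq_first", sf), ("seq_second", ss)):
            problems = validate_sequence(seq, c)
            if problems:
                raise ValueError(
                    f"pair {rec['pair_id']} {label}: {'; '.join(problems)}"
                )
        pairs.append(
            StimulusPair(
                pair_id=int(rec["pair_id"]),
                spec=spec,
                first=first,
                second=second,
                seq_first=sf,
                seq_second=ss,
            )
        )
    return StimulusSet(pairs=pairs, grid=grid, constraints=c, seed=doc.get("seed"))


def pair_manifest(sset: StimulusSet) -> pd.DataFrame:
    """One row per pair: grid levels, log2 ratios, realized features."""
    rows = []
    for p in sset.pairs:
        r = p.log2_ratios()
        f1 = sequence_features(p.seq_first)
        f2 = sequence_features(p.seq_second)
        rows.append(
            {
                "pair_id": p.pair_id,
                "n_first": p.first.n,
                "n_second": p.second.n,
                "dur_first": p.first.dur,
                "dur_second": p.second.dur,
                "tmsp_first": p.first.tmsp,
                "tmsp_second": p.second.tmsp,
                "log2_r_num": r["n"],
                "log2_r_dur": r["dur"],
                "log2_r_tmsp": r["tmsp"],
                "ted_first": f1.ted,
                "ted_second": f2.ted,
                "tsd_first": f1.tsd,
                "tsd_second": f2.tsd,
                "cov_first": f1.cov,
                "cov_second": f2.cov,
            }
        )
    return pd.DataFrame(rows)
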