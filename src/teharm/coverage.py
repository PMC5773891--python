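"""Coverage of functional annotations by harmful regions, against a
random-placement null.

Coverage of a target (functional) interval set by a query (harmful) set is
the number of target positions overlapped by the query divided by the total
number of target positions.  The null model redraws the harmful regions at
random: intervals with exactly the observed lengths are placed on the
consensus without mutual overlap, and the coverage of each random
configuration is scored.  The reported probability is

    prob_less = P(cov_harm < cov_rand) = #{i : cov_rand_i > cov_harm} / n,

with ties counting toward "not less".  A small prob_less means random
placements rarely cover the annotation as well as the detected regions do.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import GenomicInterval

__all__ = [
    "CoverageSimResult",
    "coverage",
    "random_regions",
    "coverage_null_probability",
]


@dataclass(frozen=True)
class CoverageSimResult:
    """Observed coverage, the simulated null coverages, and their comparison."""

    cov_harm: float
    null_coverages: np.ndarray
    prob_less: float
    n: int
    seed: int | None


def _positions(intervals: Sequence[GenomicInterval]) -> set[int]:
    out: set[int] = set()
    for iv in intervals:
        out.update(iv.positions())
    return out


def coverage(
    query: Sequence[GenomicInterval], target: Sequence[GenomicInterval]
) -> float:
    """|positions(query) ∩ positions(target)| / |positions(target)|."""
    tpos = _positions(target)
    if not tpos:
        raise ValueError("target interval set is empty")
    qpos = _positions(query)
    return len(qpos & tpos) / len(tpos)


def random_regions(
    lengths: Sequence[int],
    L: int,
    seed=None,
    max_retries: int = 1000,
) -> list[GenomicInterval]:
    """Place non-overlapping intervals of exactly the given lengths on [1, L].

    Placement is sequential rejection sampling: the length list is shuffled,
    each interval start is drawn uniformly among the starts currently
    feasible given earlier placements, and the whole configuration is
    retried from scratch when a dead end is reached.  Touching (adjacent)
    intervals are allowed; only overlap is forbidden.  For a single interval
    this is exactly uniform over all placements.
    """
    lengths = [int(l) for l in lengths]
    if not lengths or any(l < 1 for l in lengths):
        raise ValueError("lengths must be positive integers")
    if sum(lengths) > L:
        raise ValueError(f"total length {sum(lengths)} exceeds consensus length {L}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    for _ in range(max_retries):
        order = rng.permutation(len(lengths))
        placed: list[tuple[int, int]] = []  # sorted disjoint (start, end)
        ok = True
        for idx in order:
            length = lengths[idx]
            # free gaps between already-placed intervals
            feasible: list[tuple[int, int]] = []  # ranges of feasible starts
            prev_end = 0
            for s, e in placed + [(L + 1, L + 1)]:
                gap_start, gap_end = prev_end + 1, s - 1
                last_start = gap_end - length + 1
                if last_start >= gap_start:
                    feasible.append((gap_start, last_start))
                prev_end = e
            total = sum(b - a + 1 for a, b in feasible)
            if total == 0:
                ok = False
                break
            pick = int(rng.integers(total))
            for a, b in feasible:
                span = b - a + 1
                if pick < span:
                    start = a + pick
                    break
                pick -= span
            placed.append((start, start + length - 1))
            placed.sort()
        if ok:
            return [GenomicInterval(s, e, label="random") for s, e in placed]
    raise RuntimeError(
        f"failed to place intervals of lengths {lengths} on [1, {L}] "
        f"after {max_retries} attempts"
    )


def coverage_null_probability(
    harmful: Sequence[GenomicInterval],
    functional: Sequence[GenomicInterval],
    L: int,
    n: int,
    seed: int | None = None,
) -> CoverageSimResult:
    """Score the observed coverage against n random placements."""
    if n < 1:
        raise ValueError("need at least one trial")
    for iv in list(harmful) + list(functional):
        if iv.end > L:
            raise ValueError(f"interval [{iv.start},{iv.end}] exceeds L={L}")
    cov_harm = coverage(harmful, functional)
    lengths = [iv.length for iv in harmful]
    rng = np.random.default_rng(seed)
    tpos = _positions(functional)
    null = np.empty(n)
    for i in range(n):
        rand = random_regions(lengths, L, seed=rng)
        null[i] = len(_positions(rand) & tpos) / len(tpos)
    prob_less = float(np.sum(null > cov_harm) / n)
    return CoverageSimResult(
        cov_harm=cov_harm, null_coverages=null, prob_less=prob_less, n=n, seed=seed
    )
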