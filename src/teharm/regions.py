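"""Harmful-region formation: filter significant windows and merge them.

A window starting at consensus position j spans [j, j + wsize - 1].  A
window is called harmful when its q-value falls below the confidence
threshold lambda (strictly, by default).  Harmful windows whose spans share
at least one consensus position are merged transitively into harmful
regions; windows that merely touch end-to-start are kept separate.  Each
region reports the unweighted mean q-value of its contributing windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import GenomicInterval
from .stats import WindowStatistics
from .windows import WindowGrid

__all__ = [
    "HarmfulRegion",
    "significant_windows",
    "merge_windows",
    "consensus_coverage_fraction",
    "detect_regions",
]


@dataclass(frozen=True)
class HarmfulRegion:
    """A merged run of significant windows on the consensus."""

    interval: GenomicInterval
    avg_q: float
    window_ids: tuple[int, ...]  # start indices of contributing windows


def significant_windows(
    stats: WindowStatistics, lam: float = 0.05, strict: bool = True
) -> list[int]:
    """Window start indices (1-based) whose q-value beats the threshold.

    ``strict`` compares q < lambda; with ``strict=False`` ties at exactly
    lambda are also called.  Undefined windows are never significant.
    """
    if not (0 < lam < 1):
        raise ValueError(f"lambda must be in (0, 1), got {lam}")
    q = stats.q_values
    with np.errstate(invalid="ignore"):
        mask = (q < lam) if strict else (q <= lam)
    mask &= ~np.isnan(q)
    return [int(j) + 1 for j in np.nonzero(mask)[0]]


def merge_windows(
    indices: Sequence[int],
    grid: WindowGrid,
    q_values=None,
) -> list[HarmfulRegion]:
    """Merge overlapping significant windows into harmful regions.

    ``indices`` are sorted, unique 1-based window start positions; window j
    covers [j, j + wsize - 1].  Two windows merge when their spans overlap
    by at least one position, i.e. when their starts differ by < wsize;
    merging is transitive.  ``q_values`` is the full per-window q vector
    (0-based by window index) used for the per-region average.
    """
    if list(indices) != sorted(set(indices)):
        raise ValueError("window indices must be sorted and unique")
    regions: list[HarmfulRegion] = []
    group: list[int] = []

    def flush(group: list[int]) -> None:
        if not group:
            return
        start, end = group[0], group[-1] + grid.wsize - 1
        if q_values is not None:
            qs = [q_values[j - 1] for j in group]
            avg_q = float(np.mean(qs))
        else:
            avg_q = float("nan")
        regions.append(
            HarmfulRegion(
                interval=GenomicInterval(start, end, label="harmful"),
                avg_q=avg_q,
                window_ids=tuple(group),
            )
        )

    for j in indices:
        if not (1 <= j <= grid.nw):
            raise ValueError(f"window start {j} outside [1, {grid.nw}]")
        if group and j - group[-1] < grid.wsize:
            group.append(j)
        else:
            flush(group)
            group = [j]
    flush(group)
    return regions


def consensus_coverage_fraction(regions: Sequence, L: int) -> float:
    """Fraction of the consensus covered by (disjoint) regions."""
    intervals = sorted(getattr(r, "interval", r) for r in regions)
    for a, b in zip(intervals, intervals[1:]):
        if b.start <= a.end:
            raise ValueError(
                f"regions overlap: [{a.start},{a.end}] and [{b.start},{b.end}]"
            )
    total = sum(iv.length for iv in intervals)
    if intervals and intervals[-1].end > L:
        raise ValueError(f"region end {intervals[-1].end} exceeds L={L}")
    return total / L


def detect_regions(
    stats: WindowStatistics,
    grid: WindowGrid,
    lam: float = 0.05,
    strict: bool = True,
) -> list[HarmfulRegion]:
    """Steps 5-6 of the method: threshold q-values and merge windows."""
    idx = significant_windows(stats, lam=lam, strict=strict)
    return merge_windows(idx, grid, q_values=stats.q_values)


def region_positions(regions: Sequence) -> set[int]:
    """Union of all consensus positions covered by the regions."""
    out: set[int] = set()
    for r in regions:
        iv = getattr(r, "interval", r)
        out.update(iv.positions())
    return out
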