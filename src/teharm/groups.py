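"""Activity-group classification and the harmful-vs-neutral mutation
partition used to verify detected regions.

Elements are grouped by their activity fraction (percent of the reference
element's activity): inactive [0, 5), low [5, 40), moderate [40, 66.6) and
high [66.6, inf).  Mutations carried by high-activity elements evidently did
not abolish transposition, so the union of their mutated positions is the
set of "neutral sites".

The partition report bins elements by percent identity to the consensus and
tabulates, per (bin, activity group) cell, what percentage of the cell's
mutations fall inside the detected harmful regions and inside the neutral
sites.  A mutation can count in both categories when a neutral site lies
inside a harmful region, so the two percentages need not sum to 100.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .alignment import MutationProfile
from .io import GenomicInterval

__all__ = [
    "ACTIVITY_GROUPS",
    "classify_activity",
    "neutral_sites",
    "partition_mutations",
]

ACTIVITY_GROUPS = ("inactive", "low", "moderate", "high")


def classify_activity(activity: float) -> str:
    """Assign an activity fraction (percent) to its activity group.

    Boundaries are half-open; the boundary value 66.6 itself belongs to the
    high group so that the four groups partition [0, inf).
    """
    if not (activity >= 0):
        raise ValueError(f"activity fraction must be >= 0, got {activity}")
    if activity < 5:
        return "inactive"
    if activity < 40:
        return "low"
    if activity < 66.6:
        return "moderate"
    return "high"


def neutral_sites(
    profiles: Sequence[MutationProfile], activities: Sequence[float]
) -> set[int]:
    """Union of mutation positions over all high-activity elements."""
    if len(profiles) != len(activities):
        raise ValueError("profiles and activities differ in length")
    sites: set[int] = set()
    for prof, act in zip(profiles, activities):
        if classify_activity(act) == "high":
            sites.update(prof.positions)
    return sites


def partition_mutations(
    profiles: Sequence[MutationProfile],
    activities: Sequence[float],
    bins: Sequence[tuple[float, float]],
    harmful: Sequence[GenomicInterval],
    neutral: set[int],
) -> pd.DataFrame:
    """Tabulate mutation placement per (percent-identity bin, activity group).

    ``bins`` are half-open percent-identity intervals [lo, hi) on the [0, 1]
    scale and must be disjoint; elements outside every bin are excluded.
    Each cell reports the percentage of its mutations (counted with
    multiplicity across elements) that fall inside harmful regions and
    inside neutral sites; zero-mutation cells report 0 by convention.
    """
    if len(profiles) != len(activities):
        raise ValueError("profiles and activities differ in length")
    bins = [(float(lo), float(hi)) for lo, hi in bins]
    for i, (lo, hi) in enumerate(bins):
        if not lo < hi:
            raise ValueError(f"bin {i}: need lo < hi, got [{lo}, {hi})")
        for lo2, hi2 in bins[i + 1 :]:
            if lo < hi2 and lo2 < hi:
                raise ValueError("percent-identity bins must be disjoint")
    harm_pos: set[int] = set()
    for iv in harmful:
        harm_pos.update((getattr(iv, "interval", iv)).positions())

    rows = []
    for b, (lo, hi) in enumerate(bins, start=1):
        for group in ACTIVITY_GROUPS:
            total = n_harm = n_neut = 0
            for prof, act in zip(profiles, activities):
                if prof.percent_identity is None:
                    raise ValueError(
                        f"element {prof.element_id!r} has no percent identity"
                    )
                if not (lo <= prof.percent_identity < hi):
                    continue
                if classify_activity(act) != group:
                    continue
                total += len(prof.positions)
                n_harm += sum(1 for p in prof.positions if p in harm_pos)
                n_neut += sum(1 for p in prof.positions if p in neutral)
            pct_h = 100.0 * n_harm / total if total else 0.0
            pct_n = 100.0 * n_neut / total if total else 0.0
            rows.append(
                {
                    "bin": b,
                    "group": group,
                    "n_mutations": total,
                    "pct_in_harmful": pct_h,
                    "pct_in_neutral": pct_n,
                }
            )
    return pd.DataFrame(rows)
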