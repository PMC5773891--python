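"""Synthetic element sets with planted harmful regions.

The generator emulates the structure of an activity-assayed TE family: a
random consensus, N element copies that each carry a Poisson number of
mutations at uniform consensus positions, and an activity fraction that
starts at a base level and drops by a fixed penalty for every mutation
landing inside one of the planted harmful regions, plus Gaussian noise,
floored at zero.  Activities live on the percent scale and, because noise
is unbounded above, can exceed 100 — as assayed activity fractions do.

Defaults mirror the AluY regime in which the method is known to operate:
52 elements on a 282 bp consensus with wsize 10, two planted 20 bp regions,
about 12 mutations per element (~4% divergence, within the range where
elements remain assayable), a 30-percentage-point penalty per harmful
mutation and 5 points of noise.

Mutations are substitutions by default; ``indel_fraction`` realises a
fraction of them as 1 bp indels to exercise the alignment module's
attribution rules.  The ground-truth profile records the drawn consensus
positions, matching the mutation-calling convention (a deletion is charged
to the deleted position, an insertion to its left flank).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import MutationProfile
from .io import ElementRecord, GenomicInterval, write_activity_table, write_fasta, write_mutation_table, write_regions

__all__ = ["SyntheticSpec", "SyntheticDataset", "simulate", "recovery_score", "write_dataset"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic family.

    mutation_rate is the Poisson mean number of mutations per element;
    effect_size and noise_sd are in activity percentage points.
    """

    N: int = 52
    L: int = 282
    wsize: int = 10
    planted_regions: tuple[GenomicInterval, ...] = (
        GenomicInterval(40, 59, "planted"),
        GenomicInterval(160, 179, "planted"),
    )
    mutation_rate: float = 12.0
    effect_size: float = 30.0
    base_activity: float = 100.0
    noise_sd: float = 5.0
    indel_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N < 4:
            raise ValueError("need at least 4 elements")
        if not (1 <= self.wsize <= self.L):
            raise ValueError("need 1 <= wsize <= L")
        if self.mutation_rate < 0 or self.noise_sd < 0 or self.effect_size < 0:
            raise ValueError("rates, noise and effect size must be non-negative")
        if not (0 <= self.indel_fraction <= 1):
            raise ValueError("indel_fraction must be in [0, 1]")
        ivs = sorted(self.planted_regions)
        for iv in ivs:
            if iv.end > self.L:
                raise ValueError(f"planted region [{iv.start},{iv.end}] exceeds L={self.L}")
        for a, b in zip(ivs, ivs[1:]):
            if b.start <= a.end:
                raise ValueError("planted regions must be pairwise disjoint")


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated family: consensus, elements with activities, and the
    ground-truth mutation profiles and planted regions."""

    consensus: str
    elements: tuple[ElementRecord, ...]
    profiles: tuple[MutationProfile, ...]
    planted_regions: tuple[GenomicInterval, ...]
    spec: SyntheticSpec

    @property
    def activities(self) -> np.ndarray:
        return np.array([e.activity_fraction for e in self.elements])


def _mutate(
    consensus: str, positions: np.ndarray, kinds: np.ndarray, rng: np.random.Generator
) -> str:
    """Apply mutations (kind 0 substitution, 1 deletion, 2 insertion) at the
    given 1-based consensus positions."""
    bykind = dict(zip(positions.tolist(), kinds.tolist()))
    out: list[str] = []
    for i, base in enumerate(consensus, start=1):
        kind = bykind.get(i)
        if kind == 1:  # deletion
            continue
        if kind == 0:  # substitution to a different base
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[int(rng.integers(3))])
        else:
            out.append(base)
        if kind == 2:  # insertion attributed to this (left-flank) position
            out.append(str(_BASES[int(rng.integers(4))]))
    return "".join(out)


def simulate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one synthetic family; byte-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    consensus = "".join(_BASES[rng.integers(0, 4, spec.L)])
    planted: set[int] = set()
    for iv in spec.planted_regions:
        planted.update(iv.positions())

    elements: list[ElementRecord] = []
    profiles: list[MutationProfile] = []
    width = len(str(spec.N))
    for k in range(spec.N):
        name = f"elem_{k + 1:0{width}d}"
        nmut = min(int(rng.poisson(spec.mutation_rate)), spec.L)
        positions = np.sort(rng.choice(spec.L, size=nmut, replace=False) + 1)
        if spec.indel_fraction > 0:
            is_indel = rng.random(nmut) < spec.indel_fraction
            # split indels evenly between deletions and insertions
            kinds = np.where(is_indel, 1 + (rng.random(nmut) < 0.5), 0)
        else:
            kinds = np.zeros(nmut, dtype=int)
        seq = _mutate(consensus, positions, kinds, rng)
        n_harm = int(np.sum(np.isin(positions, list(planted))))
        noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
        activity = max(0.0, spec.base_activity - spec.effect_size * n_harm + noise)
        elements.append(ElementRecord(name, seq, activity))
        profiles.append(
            MutationProfile(
                element_id=name,
                positions=tuple(int(p) for p in positions),
                # exact for substitution-only elements (gap-free alignment of
                # length L); approximate when indels are enabled
                percent_identity=1.0 - nmut / spec.L,
            )
        )
    return SyntheticDataset(
        consensus=consensus,
        elements=tuple(elements),
        profiles=tuple(profiles),
        planted_regions=tuple(sorted(spec.planted_regions)),
        spec=spec,
    )


def recovery_score(planted, detected) -> float:
    """Jaccard index of the position sets covered by two interval lists."""
    ppos: set[int] = set()
    for iv in planted:
        ppos.update((getattr(iv, "interval", iv)).positions())
    dpos: set[int] = set()
    for iv in detected:
        dpos.update((getattr(iv, "interval", iv)).positions())
    union = ppos | dpos
    if not union:
        return 1.0
    return len(ppos & dpos) / len(union)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write consensus FASTA, elements FASTA, activity TSV, ground-truth
    regions BED and the mutation table into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "consensus": outdir / "consensus.fasta",
        "elements": outdir / "elements.fasta",
        "activity": outdir / "activity.tsv",
        "planted": outdir / "planted.bed",
        "mutations": outdir / "mutations.tsv",
    }
    write_fasta([("consensus", dataset.consensus)], paths["consensus"])
    write_fasta([(e.element_id, e.sequence) for e in dataset.elements], paths["elements"])
    write_activity_table(
        {e.element_id: e.activity_fraction for e in dataset.elements}, paths["activity"]
    )
    write_regions(dataset.planted_regions, paths["planted"], dialect="bed")
    write_mutation_table(dataset.profiles, paths["mutations"])
    return paths
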