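"""Pairwise alignment of elements against the family consensus and mutation
calling in consensus coordinates.

Each element is aligned end-to-end (global Needleman-Wunsch with affine gap
penalties) against the consensus, and every difference is projected onto the
consensus coordinate system:

* a substitution contributes the consensus position of its column;
* a deletion contributes every deleted consensus position;
* an insertion run in the element contributes a single mutation attributed
  to the consensus position immediately to the left of the run (position 1
  when the run sits at the left end).

This keeps all mutation positions on the consensus, which is what the
sliding-window counting downstream requires, and prevents a single long
insertion from inflating the mutation count of one window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import Align

__all__ = [
    "AlignmentScoring",
    "PairwiseAlignment",
    "MutationProfile",
    "global_align",
    "percent_identity",
    "call_mutations",
    "profiles_from_sequences",
]


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine scoring scheme.  A gap of length k scores
    ``gap_open + (k - 1) * gap_extend`` (the opening score covers the first
    gapped column)."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0


DEFAULT_SCORING = AlignmentScoring()


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of the consensus (top row) and an element."""

    aligned_consensus: str
    aligned_element: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_consensus) != len(self.aligned_element):
            raise ValueError("gapped rows differ in length")
        for a, b in zip(self.aligned_consensus, self.aligned_element):
            if a == "-" and b == "-":
                raise ValueError("alignment column with gaps in both rows")


@dataclass(frozen=True)
class MutationProfile:
    """The set of consensus positions where an element differs from the
    consensus, plus its percent identity (fraction of identical columns over
    the gapped alignment length)."""

    element_id: str
    positions: tuple[int, ...]
    percent_identity: float | None = None

    def __post_init__(self) -> None:
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError(
                f"element {self.element_id!r}: positions must be sorted and unique"
            )
        if self.positions and self.positions[0] < 1:
            raise ValueError(f"element {self.element_id!r}: positions must be >= 1")


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def global_align(
    consensus: str, element: str, scoring: AlignmentScoring = DEFAULT_SCORING
) -> PairwiseAlignment:
    """Optimal global alignment of ``element`` against ``consensus``.

    When several alignments are co-optimal the first alignment in the
    aligner's deterministic enumeration order is taken, so repeated runs give
    identical tracebacks.
    """
    if not consensus or not element:
        raise ValueError("cannot align an empty sequence")
    aln = _make_aligner(scoring).align(consensus, element)[0]
    return PairwiseAlignment(str(aln[0]), str(aln[1]), float(aln.score))


def percent_identity(aln: PairwiseAlignment) -> float:
    """Identical columns divided by the gapped alignment length; in [0, 1]."""
    ncol = len(aln.aligned_consensus)
    matches = sum(
        1
        for a, b in zip(aln.aligned_consensus, aln.aligned_element)
        if a == b and a != "-"
    )
    return matches / ncol


def call_mutations(aln: PairwiseAlignment, element_id: str = "") -> MutationProfile:
    """Project the alignment's differences onto consensus positions."""
    positions: set[int] = set()
    cons_pos = 0  # last consumed consensus position
    in_insertion = False
    for a, b in zip(aln.aligned_consensus, aln.aligned_element):
        if a == "-":
            # insertion in the element: one mutation per run, at the left flank
            if not in_insertion:
                positions.add(max(cons_pos, 1))
                in_insertion = True
            continue
        in_insertion = False
        cons_pos += 1
        if b == "-" or b != a:
            positions.add(cons_pos)
    return MutationProfile(
        element_id=element_id,
        positions=tuple(sorted(positions)),
        percent_identity=percent_identity(aln),
    )


def profiles_from_sequences(
    consensus: str,
    elements: Sequence[tuple[str, str]] | Iterable,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> list[MutationProfile]:
    """Align every element against the consensus and call its mutations.

    ``elements`` are ``(id, sequence)`` pairs or objects with ``element_id``
    and ``sequence`` attributes.
    """
    profiles = []
    for elem in elements:
        if isinstance(elem, tuple):
            name, seq = elem
        else:
            name, seq = elem.element_id, elem.sequence
        aln = global_align(consensus, seq, scoring)
        profiles.append(call_mutations(aln, element_id=name))
    return profiles
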