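"""Sliding-window mutation counting: build the N x nw mutation matrix.

A window of size ``wsize`` starting at consensus position ``i`` spans
positions ``[i, i + wsize - 1]`` (1-based, inclusive), so a consensus of
length L carries ``nw = L - wsize + 1`` windows.  Entry (k, i) of the
mutation matrix is the number of mutated positions of element k falling in
window i.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alignment import MutationProfile

__all__ = ["WindowGrid", "MutationMatrix", "count_window_mutations", "build_mutation_matrix"]


@dataclass(frozen=True)
class WindowGrid:
    """The sliding-window layout on a consensus of length ``L``."""

    L: int
    wsize: int = 10

    def __post_init__(self) -> None:
        if not (1 <= self.wsize <= self.L):
            raise ValueError(f"need 1 <= wsize <= L, got wsize={self.wsize}, L={self.L}")

    @property
    def nw(self) -> int:
        return self.L - self.wsize + 1

    def window_span(self, i: int) -> tuple[int, int]:
        """Consensus span [start, end] of the window starting at position i."""
        if not (1 <= i <= self.nw):
            raise ValueError(f"window start {i} outside [1, {self.nw}]")
        return i, i + self.wsize - 1


@dataclass(frozen=True)
class MutationMatrix:
    """Per-window mutation counts, one row per element.

    Row order matches the activity vector order used downstream.
    """

    values: np.ndarray  # (N, nw) non-negative integers
    row_ids: tuple[str, ...]
    grid: WindowGrid

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("mutation matrix must be 2-dimensional")
        if self.values.shape != (len(self.row_ids), self.grid.nw):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.row_ids)} elements and nw={self.grid.nw}"
            )
        if np.any(self.values < 0):
            raise ValueError("mutation counts must be non-negative")

    @property
    def n_elements(self) -> int:
        return self.values.shape[0]


def count_window_mutations(profile: MutationProfile, grid: WindowGrid) -> np.ndarray:
    """Vector of per-window mutation counts for one element.

    Computed from the cumulative sum of the per-position mutation indicator,
    which is the vectorised form of the sliding-window telescoping recurrence
    m_{i+1} = m_i - [i mutated] + [i + wsize mutated].
    """
    if profile.positions and profile.positions[-1] > grid.L:
        raise ValueError(
            f"element {profile.element_id!r}: mutation position "
            f"{profile.positions[-1]} exceeds consensus length {grid.L}"
        )
    indicator = np.zeros(grid.L + 1, dtype=np.int64)
    if profile.positions:
        indicator[np.asarray(profile.positions)] = 1
    csum = np.cumsum(indicator)
    starts = np.arange(1, grid.nw + 1)
    return csum[starts + grid.wsize - 1] - csum[starts - 1]


def build_mutation_matrix(
    profiles: Sequence[MutationProfile], grid: WindowGrid
) -> MutationMatrix:
    """Stack per-element window counts into the N x nw mutation matrix."""
    if not profiles:
        raise ValueError("no mutation profiles provided")
    rows = [count_window_mutations(p, grid) for p in profiles]
    return MutationMatrix(
        values=np.vstack(rows),
        row_ids=tuple(p.element_id for p in profiles),
        grid=grid,
    )


def write_matrix_tsv(matrix: MutationMatrix, path) -> None:
    """Dump the mutation matrix as TSV (heat-map source data)."""
    with open(path, "w") as fh:
        header = "\t".join(f"w{j}" for j in range(1, matrix.grid.nw + 1))
        fh.write("element_id\t" + header + "\n")
        for name, row in zip(matrix.row_ids, matrix.values):
            fh.write(name + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
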