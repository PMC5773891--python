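"""End-to-end orchestration: sequences + activities -> harmful regions.

The pipeline runs alignment -> mutation matrix -> observed correlations ->
permutation null -> empirical p -> q -> significance filter -> region
merging, logging the problem dimensions and per-stage timings.  A
precomputed mutation table can stand in for the alignment stage when the
mutation calls come from curated data.

All randomness flows from one master seed: each randomized stage draws its
own child seed from a seed sequence, so adding a stage never perturbs the
random stream of an earlier one.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .alignment import AlignmentScoring, MutationProfile, profiles_from_sequences
from .io import ElementRecord, match_elements
from .regions import HarmfulRegion, detect_regions
from .stats import WindowStatistics, compute_window_statistics
from .windows import MutationMatrix, WindowGrid, build_mutation_matrix

__all__ = ["RunConfig", "DetectResult", "detect"]

logger = logging.getLogger("teharm")


@dataclass(frozen=True)
class RunConfig:
    """Tunable parameters of a detection run; echoed into output headers."""

    wsize: int = 10
    n_perm: int = 10_000
    lam: float = 0.05
    seed: int | None = None
    pi0: float | None = 1.0  # 1 = Benjamini-Hochberg; None = Storey smoother
    p_mode: str = "add_one"
    strict: bool = True
    scoring: AlignmentScoring = field(default_factory=AlignmentScoring)

    def header(self) -> dict:
        return {
            "wsize": self.wsize,
            "n_perm": self.n_perm,
            "lambda": self.lam,
            "seed": self.seed,
            "pi0": "storey" if self.pi0 is None else self.pi0,
            "p_mode": self.p_mode,
        }


@dataclass(frozen=True)
class DetectResult:
    grid: WindowGrid
    profiles: tuple[MutationProfile, ...]
    matrix: MutationMatrix
    stats: WindowStatistics
    regions: tuple[HarmfulRegion, ...]
    config: RunConfig


def _subseed(seed: int | None, stage: int) -> int | None:
    """Derive an independent, stable per-stage seed below 2**31."""
    if seed is None:
        return None
    child = np.random.SeedSequence(seed).spawn(stage + 1)[stage]
    return int(child.generate_state(1, np.uint32)[0] % (2**31))


def detect(
    consensus: str,
    elements: list[tuple[str, str]] | None,
    activity: dict[str, float],
    config: RunConfig = RunConfig(),
    profiles: list[MutationProfile] | None = None,
) -> DetectResult:
    """Run the full harmful-region detection.

    Either ``elements`` (sequences, to be aligned) or ``profiles``
    (precomputed mutation calls) must be given.  Activity IDs must match the
    element IDs exactly.
    """
    t0 = time.perf_counter()
    if profiles is None:
        if elements is None:
            raise ValueError("need element sequences or precomputed mutation profiles")
        records = match_elements(elements, activity)
        profiles = profiles_from_sequences(consensus, records, config.scoring)
        logger.info(
            "aligned %d elements in %.2fs", len(profiles), time.perf_counter() - t0
        )
        act_vector = np.array([r.activity_fraction for r in records])
    else:
        ids = [p.element_id for p in profiles]
        missing = [i for i in ids if i not in activity]
        extra = sorted(set(activity) - set(ids))
        if missing or extra:
            raise ValueError(
                "element IDs do not match between mutation table and activity "
                f"table: missing activity for {missing[:5]}; unmatched activity "
                f"entries {extra[:5]}"
            )
        act_vector = np.array([activity[i] for i in ids])

    grid = WindowGrid(L=len(consensus), wsize=config.wsize)
    t1 = time.perf_counter()
    matrix = build_mutation_matrix(profiles, grid)
    logger.info(
        "N=%d elements, L=%d, nw=%d windows (matrix in %.2fs)",
        matrix.n_elements,
        grid.L,
        grid.nw,
        time.perf_counter() - t1,
    )

    t2 = time.perf_counter()
    stats = compute_window_statistics(
        matrix,
        act_vector,
        n_perm=config.n_perm,
        seed=_subseed(config.seed, 0),
        pi0=config.pi0,
        p_mode=config.p_mode,
    )
    logger.info(
        "permutation null (n=%d) and q-values in %.2fs",
        config.n_perm,
        time.perf_counter() - t2,
    )

    regions = detect_regions(stats, grid, lam=config.lam, strict=config.strict)
    logger.info(
        "%d harmful regions at lambda=%g (total %.2fs)",
        len(regions),
        config.lam,
        time.perf_counter() - t0,
    )
    return DetectResult(
        grid=grid,
        profiles=tuple(profiles),
        matrix=matrix,
        stats=stats,
        regions=tuple(regions),
        config=config,
    )
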