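"""Readers and writers for the external representations used by the pipeline.

All coordinates are 1-based and inclusive on the consensus sequence, the
convention used throughout the package; only BED export/import converts to
(from) 0-based half-open coordinates.

Activity fractions are stored on the percent scale on which they are
measured (106 means 106% of the reference element's activity) and are never
rescaled to [0, 1].
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "ElementRecord",
    "GenomicInterval",
    "read_fasta",
    "write_fasta",
    "read_activity_table",
    "write_activity_table",
    "match_elements",
    "read_mutation_table",
    "write_mutation_table",
    "read_bed",
    "read_interval_table",
    "write_regions",
    "read_regions",
    "write_window_stats",
]


@dataclass(frozen=True)
class ElementRecord:
    """One transposable-element copy with its assayed activity.

    ``activity_fraction`` is a percentage of the reference element's
    transposition rate (AluYa5 for Alu, L1-RP for L1) and may exceed 100.
    """

    element_id: str
    sequence: str
    activity_fraction: float

    def __post_init__(self) -> None:
        if not self.element_id:
            raise ValueError("element_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"element {self.element_id!r}: sequence is empty")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(
                f"element {self.element_id!r}: invalid characters {sorted(bad)}"
            )
        if not (self.activity_fraction >= 0):
            raise ValueError(
                f"element {self.element_id!r}: activity_fraction must be >= 0, "
                f"got {self.activity_fraction}"
            )


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive interval on the consensus sequence."""

    start: int
    end: int
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}]: need 1 <= start <= end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def positions(self) -> range:
        """All consensus positions covered by the interval."""
        return range(self.start, self.end + 1)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.start <= other.end and other.start <= self.end


def _normalize_sequence(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, sequence)`` pairs in file order.

    Sequences are uppercased and RNA ``U`` is mapped to ``T``. An empty file
    or a duplicated record ID is an error.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate ID {rec.id} in {path}")
        seen.add(rec.id)
        records.append((rec.id, _normalize_sequence(str(rec.seq))))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_activity_table(path: str | Path) -> dict[str, float]:
    """Read a two-column (element ID, activity percent) table.

    The delimiter is tab or whitespace; a single header line is tolerated.
    Values must parse as non-negative reals; errors carry the line number.
    """
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            name, value = parts[0], parts[1]
            try:
                act = float(value)
            except ValueError:
                if lineno == 1 and not out:
                    continue  # header line
                raise ValueError(
                    f"{path}:{lineno}: non-numeric activity value {value!r}"
                ) from None
            if math.isnan(act) or act < 0:
                raise ValueError(
                    f"{path}:{lineno}: activity fraction must be >= 0, got {value}"
                )
            if name in out:
                raise ValueError(f"{path}:{lineno}: duplicate element ID {name!r}")
            out[name] = act
    if not out:
        raise ValueError(f"no activity entries found in {path}")
    return out


def write_activity_table(activity: dict[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("element_id\tactivity_fraction\n")
        for name, value in activity.items():
            fh.write(f"{name}\t{value!r}\n")


def match_elements(
    fasta_records: Sequence[tuple[str, str]], activity: dict[str, float]
) -> list[ElementRecord]:
    """Join sequences with activity fractions, requiring a perfect ID match.

    Elements present in only one of the two inputs are a hard error rather
    than a silent drop: the mutation matrix rows and the activity vector must
    stay aligned element-for-element.
    """
    fasta_ids = [name for name, _ in fasta_records]
    missing_act = [i for i in fasta_ids if i not in activity]
    missing_seq = sorted(set(activity) - set(fasta_ids))
    if missing_act or missing_seq:
        raise ValueError(
            "element IDs do not match between FASTA and activity table: "
            f"missing from activity table: {missing_act[:5]}; "
            f"missing from FASTA: {missing_seq[:5]}"
        )
    return [
        ElementRecord(name, seq, activity[name]) for name, seq in fasta_records
    ]


# ---------------------------------------------------------------------------
# mutation tables


def read_mutation_table(path: str | Path) -> list[tuple[str, tuple[int, ...], float | None]]:
    """Read a mutation table: element_id, comma-separated 1-based positions,
    optional percent identity.  An empty position field means no mutations."""
    rows: list[tuple[str, tuple[int, ...], float | None]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "element_id":
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 columns")
            name = parts[0]
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate element ID {name!r}")
            seen.add(name)
            posfield = parts[1].strip()
            try:
                positions = tuple(
                    sorted({int(tok) for tok in posfield.split(",") if tok})
                )
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: malformed position list {posfield!r}"
                ) from None
            if positions and positions[0] < 1:
                raise ValueError(f"{path}:{lineno}: positions must be >= 1")
            pid = None
            if len(parts) > 2 and parts[2].strip():
                pid = float(parts[2])
            rows.append((name, positions, pid))
    if not rows:
        raise ValueError(f"no mutation entries found in {path}")
    return rows


def write_mutation_table(
    profiles: Iterable, path: str | Path
) -> None:
    """Write MutationProfile-like objects (element_id, positions,
    percent_identity) as TSV."""
    with open(path, "w") as fh:
        fh.write("element_id\tpositions\tpercent_identity\n")
        for prof in profiles:
            pos = ",".join(str(p) for p in prof.positions)
            pid = "" if prof.percent_identity is None else f"{prof.percent_identity:.6f}"
            fh.write(f"{prof.element_id}\t{pos}\t{pid}\n")


# ---------------------------------------------------------------------------
# intervals / regions


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED intervals (0-based half-open) into 1-based inclusive form."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 3 fields")
            start0, end0 = int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else ""
            out.append(GenomicInterval(start0 + 1, end0, label))
    if not out:
        raise ValueError(f"no intervals found in {path}")
    return out


def read_interval_table(path: str | Path) -> list[GenomicInterval]:
    """Read a 1-based inclusive interval table: start, end, optional label."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            try:
                start, end = int(parts[0]), int(parts[1])
            except (ValueError, IndexError):
                if not out:
                    continue  # header line(s)
                raise ValueError(f"{path}:{lineno}: malformed interval line") from None
            label = parts[2] if len(parts) > 2 else ""
            out.append(GenomicInterval(start, end, label))
    if not out:
        raise ValueError(f"no intervals found in {path}")
    return out


def _check_sorted_disjoint(intervals: Sequence[GenomicInterval]) -> None:
    for a, b in zip(intervals, intervals[1:]):
        if b.start <= a.end:
            raise ValueError(
                f"regions overlap or are unsorted: [{a.start},{a.end}] and "
                f"[{b.start},{b.end}]"
            )


def write_regions(
    regions: Sequence,
    path: str | Path,
    dialect: str = "table",
    header: dict | None = None,
) -> None:
    """Write harmful regions as a 1-based table or a BED file.

    ``regions`` are HarmfulRegion objects (``interval``, ``avg_q``) or bare
    GenomicIntervals. The table dialect mirrors the report layout
    (region id, start, end, average q-value); BED converts to 0-based
    half-open coordinates.
    """
    if dialect not in ("table", "bed"):
        raise ValueError(f"unknown dialect {dialect!r}")
    intervals = [getattr(r, "interval", r) for r in regions]
    _check_sorted_disjoint(intervals)
    with open(path, "w") as fh:
        if header:
            fh.write("# " + " ".join(f"{k}={v}" for k, v in header.items()) + "\n")
        if dialect == "table":
            fh.write("region_id\tstart\tend\tavg_q\n")
            for i, reg in enumerate(regions, start=1):
                iv = getattr(reg, "interval", reg)
                q = getattr(reg, "avg_q", float("nan"))
                qtxt = "NA" if q is None or math.isnan(q) else f"{q:.6g}"
                fh.write(f"{i}\t{iv.start}\t{iv.end}\t{qtxt}\n")
        else:
            for i, reg in enumerate(regions, start=1):
                iv = getattr(reg, "interval", reg)
                q = getattr(reg, "avg_q", float("nan"))
                qtxt = "." if q is None or math.isnan(q) else f"{q:.6g}"
                name = iv.label or f"region_{i}"
                fh.write(f"consensus\t{iv.start - 1}\t{iv.end}\t{name}\t{qtxt}\n")


def read_regions(path: str | Path, dialect: str = "table") -> list[GenomicInterval]:
    """Read back a region file written by :func:`write_regions`."""
    if dialect == "bed":
        return read_bed(path)
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("region_id"):
                continue
            parts = line.split("\t")
            out.append(GenomicInterval(int(parts[1]), int(parts[2]), parts[0]))
    if not out:
        raise ValueError(f"no regions found in {path}")
    return out


def write_window_stats(stats, grid, path: str | Path, header: dict | None = None) -> None:
    """Write the per-window statistics report: window index, consensus span,
    observed correlation, empirical p, q. Undefined windows print NA; in raw
    p-value mode a zero count prints as ``<1/n``."""
    with open(path, "w") as fh:
        if header:
            fh.write("# " + " ".join(f"{k}={v}" for k, v in header.items()) + "\n")
        fh.write("window\tstart\tend\trho_obs\tp\tq\n")
        for j in range(grid.nw):
            start, end = j + 1, j + grid.wsize
            rho, p, q = stats.rho_obs[j], stats.p_values[j], stats.q_values[j]
            rtxt = "NA" if math.isnan(rho) else f"{rho:.6g}"
            if math.isnan(p):
                ptxt = "NA"
            elif stats.p_mode == "raw" and p == 0:
                ptxt = f"<{1.0 / stats.n_perm:g}"
            else:
                ptxt = f"{p:.6g}"
            qtxt = "NA" if math.isnan(q) else f"{q:.6g}"
            fh.write(f"{start}\t{start}\t{end}\t{rtxt}\t{ptxt}\t{qtxt}\n")
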