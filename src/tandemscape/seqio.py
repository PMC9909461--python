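"""Sequence records, coordinate conventions, and plain-text I/O.

All coordinates are 0-based half-open internally; report writers convert to
1-based inclusive where a table mimics published coordinates.  The DNA
alphabet is {A, C, G, T, N}: N is tolerated in input sequences but repeat
units containing N are excluded from unique-sequence catalogs downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

TECHNOLOGIES = ("CLR", "CCS", "synthetic")


class SeqIOError(ValueError):
    """Raised on malformed sequence input."""


def _validate_dna(seq: str, name: str = "sequence") -> None:
    if not seq:
        raise SeqIOError(f"{name}: empty sequence")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise SeqIOError(
            f"{name}: non-DNA characters {sorted(bad)} (alphabet is A/C/G/T/N)"
        )


@dataclass(frozen=True)
class GeneInterval:
    """A half-open [start, end) interval on a named contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_1based(self) -> tuple[int, int]:
        """Convert to 1-based inclusive coordinates (for published-style tables)."""
        return self.start + 1, self.end

    @classmethod
    def from_1based(cls, contig: str, start1: int, end1: int, strand: str = "+") -> "GeneInterval":
        return cls(contig, start1 - 1, end1, strand)

    def overlaps(self, other: "GeneInterval") -> bool:
        return self.contig == other.contig and self.start < other.end and other.start < self.end

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class HaplotypeRecord:
    """One haplotype's gene sequence plus sample metadata."""

    sample_id: str
    haplotype_index: int
    technology: str
    sequence: str
    ancestry: str | None = None
    source_path: str = ""

    def __post_init__(self) -> None:
        if self.haplotype_index not in (1, 2):
            raise ValueError(f"haplotype_index must be 1 or 2, got {self.haplotype_index}")
        if self.technology not in TECHNOLOGIES:
            raise ValueError(f"technology must be one of {TECHNOLOGIES}")
        _validate_dna(self.sequence, f"{self.sample_id} h{self.haplotype_index}")

    @property
    def label(self) -> str:
        return f"{self.sample_id}_h{self.haplotype_index}"

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.sample_id, self.haplotype_index, self.technology)


def check_cohort_keys(records: Sequence[HaplotypeRecord]) -> None:
    """Enforce uniqueness of (sample_id, haplotype_index, technology) in a cohort."""
    seen: set[tuple[str, int, str]] = set()
    for rec in records:
        if rec.key in seen:
            raise SeqIOError(f"duplicate haplotype key {rec.key} in cohort")
        seen.add(rec.key)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (header, sequence) pairs, order preserved.

    Sequences are uppercased and validated against {A,C,G,T,N}; RNA (U) and
    other characters are rejected with the offending record named.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        _validate_dna(seq, f"record {rec.id!r} in {path.name}")
        records.append((rec.description, seq))
    if not records:
        raise SeqIOError(f"{path}: empty or headerless FASTA")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=header.split()[0], description=header)
        for header, seq in records
    ]
    # SeqIO writes "id description"; keep header verbatim by clearing the echo.
    for sr in seq_records:
        sr.description = sr.description[len(sr.id):].strip() if sr.description.startswith(sr.id) else sr.description
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# Elementary sequence operations
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    _validate_dna(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """(G + C) / length.  The reporting layer rounds x100 half-up to integer percent."""
    _validate_dna(seq)
    return (seq.count("G") + seq.count("C")) / len(seq)


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero at the given decimal (published-table convention)."""
    factor = 10 ** decimals
    import math

    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def gc_percent(seq: str) -> int:
    return int(round_half_up(gc_fraction(seq) * 100))


# ---------------------------------------------------------------------------
# BED / TSV
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[tuple[GeneInterval, str]], path: str | Path) -> None:
    """Write BED6 lines (0-based half-open), position-sorted."""
    rows = sorted(intervals, key=lambda t: (t[0].contig, t[0].start, t[0].end))
    with open(path, "w") as fh:
        for iv, name in rows:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bed(path: str | Path) -> list[tuple[GeneInterval, str]]:
    out: list[tuple[GeneInterval, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 else "+"
            out.append((GeneInterval(contig, start, end, strand), name))
    return out


def write_table(rows: pd.DataFrame | list[dict], path: str | Path, sort_by: str | None = None) -> None:
    """Write a TSV with a header row; deterministic row order."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    if sort_by is not None and not df.empty:
        df = df.sort_values(sort_by, kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
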