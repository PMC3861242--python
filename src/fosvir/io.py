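"""Readers/writers and interval arithmetic shared by the whole pipeline.

Coordinates are 0-based half-open everywhere in memory.  Files meant for
human eyes (annotation tables, reports) use 1-based inclusive coordinates;
conversion happens at the file boundary and nowhere else.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

VALID_BASES = set("ACGTN")

#: gene flags recognised throughout the pipeline
KNOWN_FLAGS = {"integrase", "terminase", "psbA", "psbD", "tRNA", "capsid",
               "tape_measure", "other"}


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (contig, genome, read or vector)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        return replace(self, seq=str(Seq(self.seq).reverse_complement()))


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open interval [start, end)."""

    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"malformed interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class GeneAnnotation:
    """One predicted gene on a contig with its functional metadata.

    ``vq`` is the virus quotient of the gene's orthologous group: a score in
    [0, 1] where 1 means the family occurs only in phages.  ``None`` means
    the gene matched no phage orthologous group.
    """

    contig_id: str
    interval: Interval
    strand: str = "+"
    product: str = ""
    vq: float | None = None
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.vq is not None and not (0.0 <= self.vq <= 1.0):
            raise ValueError(f"VQ {self.vq} outside [0, 1]")
        object.__setattr__(self, "flags", frozenset(self.flags))


# ---------------------------------------------------------------------------
# interval arithmetic


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping/adjacent-overlapping intervals into a disjoint set.

    The returned list is sorted and covers exactly the union of input
    positions.  Intervals that merely abut (end == start) are kept separate:
    no position is shared, so the union is unchanged either way; we merge
    only genuine overlaps.
    """
    ivs = sorted(intervals)
    if not ivs:
        return []
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.start < last.end:  # genuine overlap
            if iv.end > last.end:
                merged[-1] = Interval(last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def merged_length(intervals: Iterable[Interval]) -> int:
    return sum(len(iv) for iv in merge_intervals(intervals))


def coverage_fraction(hits_on_contig: Sequence[Interval], contig_length: int) -> float:
    """Fraction of a contig covered by the union of hit intervals."""
    if contig_length <= 0:
        raise ValueError("contig_length must be positive")
    for iv in hits_on_contig:
        if iv.start < 0 or iv.end > contig_length:
            raise ValueError(
                f"interval [{iv.start}, {iv.end}) out of bounds for length {contig_length}"
            )
    return merged_length(hits_on_contig) / contig_length


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-FASTA file; sequences are uppercased on input.

    Raises :class:`ParseError` on duplicate ids or characters outside
    {A, C, G, T, N}.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ParseError(
                f"{path}: record {rec.id!r} contains illegal characters {sorted(bad)}"
            )
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, seq, desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_fastx(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA or FASTQ (by extension); qualities are discarded."""
    p = str(path)
    fmt = "fastq" if p.endswith((".fastq", ".fq")) else "fasta"
    if fmt == "fastq":
        return [
            SequenceRecord(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(p, "fastq")
        ]
    return read_fasta(path)


# ---------------------------------------------------------------------------
# annotation tables

_ANN_COLUMNS = ["contig_id", "start", "end", "strand", "product", "vq", "flags"]


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read a gene annotation table (TSV, 1-based inclusive coordinates).

    Columns: contig_id, start, end, strand, product, vq, flags.  ``vq`` may
    be empty (gene outside any phage orthologous group); ``flags`` is a
    comma-separated list.
    """
    out: list[GeneAnnotation] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for ln, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if row[:3] == _ANN_COLUMNS[:3]:  # header line
                continue
            if len(row) != len(_ANN_COLUMNS):
                raise ParseError(f"{path}:{ln}: expected {len(_ANN_COLUMNS)} columns, got {len(row)}")
            try:
                start1, end1 = int(row[1]), int(row[2])
                vq = float(row[5]) if row[5] != "" else None
                flags = frozenset(f for f in row[6].split(",") if f)
                out.append(
                    GeneAnnotation(
                        contig_id=row[0],
                        interval=Interval(start1 - 1, end1),
                        strand=row[3],
                        product=row[4],
                        vq=vq,
                        flags=flags,
                    )
                )
            except (ValueError, TypeError) as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from exc
    return out


def write_annotations(annotations: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_ANN_COLUMNS)
        for a in annotations:
            w.writerow(
                [
                    a.contig_id,
                    a.interval.start + 1,
                    a.interval.end,
                    a.strand,
                    a.product,
                    "" if a.vq is None else f"{a.vq:g}",
                    ",".join(sorted(a.flags)),
                ]
            )


# ---------------------------------------------------------------------------
# newick


def write_newick(newick: str, path: str | Path) -> None:
    """Write a newick string (with branch lengths) to file."""
    text = newick.strip()
    if not text.endswith(";"):
        text += ";"
    with open(path, "w") as fh:
        fh.write(text + "\n")


def read_newick(path: str | Path) -> str:
    with open(path) as fh:
        return fh.read().strip()
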