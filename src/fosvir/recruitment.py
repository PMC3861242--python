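"""Fragment recruitment of metavirome/metagenome reads against contigs.

Each read is assigned to at most one contig: its best-scoring hit that
passes the filter thresholds (ties broken to the lexicographically
smallest contig id), preventing double counting.  Counts are normalised
as RPKG — reads recruited per kb of contig per Gb of dataset — so
recruitment is comparable across contigs of different length and across
datasets of different size.

Two filter modes mirror the two questions asked of a dataset:

* strict  (>95% identity, >=50 bp, e<=1e-5): abundance profiling of a
  specific contig/genome;
* relaxed (any identity, >=50 bp, e<=0.01): what fraction of the dataset
  is related to the contig set at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .align import AlignmentHit, NucleotideIndex, filter_hits
from .io import SequenceRecord

#: (min_identity %, min_length, max_evalue)
FILTER_MODES: dict[str, tuple[float, int, float]] = {
    "strict": (95.0, 50, 1e-5),
    "relaxed": (0.0, 50, 0.01),
}


@dataclass(frozen=True)
class RecruitmentResult:
    contig_id: str
    dataset_id: str
    read_count: int
    contig_len: int
    dataset_size: int  # total bp in the read dataset
    rpkg: float


def rpkg(read_count: int, contig_len: int, dataset_size: int) -> float:
    """Reads per kb of contig per Gb of dataset."""
    if contig_len <= 0 or dataset_size <= 0:
        raise ValueError("contig_len and dataset_size must be positive")
    return read_count / (contig_len / 1e3) / (dataset_size / 1e9)


def recruit(
    reads: Sequence[SequenceRecord],
    contigs: Sequence[SequenceRecord],
    min_identity: float = 95.0,
    min_len: int = 50,
    max_evalue: float = 1e-5,
    index: NucleotideIndex | None = None,
) -> dict[str, int]:
    """Per-contig recruited read counts under the given filters.

    Filter semantics follow :func:`fosvir.align.filter_hits`: identity
    strictly above ``min_identity``, length at least ``min_len``, e-value
    at most ``max_evalue``.  Returns a count for every contig (zero
    included).
    """
    if not reads or not contigs:
        raise ValueError("reads and contigs must be non-empty")
    if index is None:
        index = NucleotideIndex(contigs)
    counts = {c.id: 0 for c in contigs}
    for read in reads:
        hits = filter_hits(
            index.search(read), min_identity, min_len, max_evalue
        )
        if not hits:
            continue
        best = max(hits, key=lambda h: (h.bitscore, h.subject_id))
        # ties on bitscore go to the lexicographically smallest contig id
        top = min(
            (h for h in hits if h.bitscore == best.bitscore),
            key=lambda h: h.subject_id,
        )
        counts[top.subject_id] += 1
    return counts


def recruit_dataset(
    reads: Sequence[SequenceRecord],
    contigs: Sequence[SequenceRecord],
    dataset_id: str = "dataset",
    mode: str = "strict",
    index: NucleotideIndex | None = None,
) -> list[RecruitmentResult]:
    """Recruit a whole dataset and express counts as RPKG per contig."""
    min_id, min_len, max_ev = FILTER_MODES[mode]
    counts = recruit(reads, contigs, min_id, min_len, max_ev, index=index)
    dataset_size = sum(len(r.seq) for r in reads)
    return [
        RecruitmentResult(
            c.id,
            dataset_id,
            counts[c.id],
            len(c.seq),
            dataset_size,
            rpkg(counts[c.id], len(c.seq), dataset_size),
        )
        for c in sorted(contigs, key=lambda c: c.id)
    ]


def fraction_recruited(
    counts: Mapping[str, int], total_reads: int, mode: str = "strict"
) -> float:
    """Percentage of the dataset recruited by the contig set.

    ``counts`` must come from :func:`recruit` run with the thresholds of
    the stated mode; this helper only does the normalisation.
    """
    if mode not in FILTER_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return 100.0 * sum(counts.values()) / total_reads
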