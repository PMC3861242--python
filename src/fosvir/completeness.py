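"""Complete-genome detection for concatamer-derived fosmid contigs.

Phages replicating through a concatamer intermediate yield fosmid inserts
that are circularly permuted windows of the genome.  A contig longer than
the genome carries an exact direct terminal repeat (the window wraps past
its own start); two contigs cut at different offsets jointly witness both
junctions of the circle.  Either observation demonstrates that a complete
genome is present, and fixes its length.

Statuses follow the CGR/CGF/GF scheme:

* CGR — complete genome representative: completeness evidence on the
  contig itself or on its subcluster's permutation layout;
* CGF — complete genome fragment: incomplete, but in a cluster that
  contains a CGR;
* GF — genomic fragment: no CGR anywhere in its cluster.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .align import AlignmentHit, all_vs_all_nuc
from .clustering import UNCLUSTERED, ClusterAssignment
from .io import Interval, SequenceRecord, merged_length

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompletenessCall:
    contig_id: str
    status: str  # CGR | CGF | GF
    evidence: frozenset[str] = field(default_factory=frozenset)
    inferred_genome_length: int | None = None
    terminal_repeat_len: int | None = None
    vector_flanks: tuple[int | None, int | None] = (None, None)


# ---------------------------------------------------------------------------
# terminal redundancy


def find_terminal_repeat(seq: str, min_repeat_len: int = 20) -> int | None:
    """Length of the longest exact direct terminal repeat, or None.

    The repeat is the longest proper prefix that recurs as the suffix of
    the sequence (capped at half the length: a concatamer window of a
    genome of length L has repeat r = window - L < L).  Exact matching
    only; a single mismatch voids the repeat.
    """
    n = len(seq)
    if n <= 2 * min_repeat_len:
        return None
    # KMP failure function: borders of the whole string are exactly the
    # prefix==suffix lengths.
    fail = [0] * n
    j = 0
    for i in range(1, n):
        while j and seq[i] != seq[j]:
            j = fail[j - 1]
        if seq[i] == seq[j]:
            j += 1
        fail[i] = j
    r = fail[n - 1]
    while r > n // 2:
        r = fail[r - 1]
    return r if r >= min_repeat_len else None


# ---------------------------------------------------------------------------
# vector flanks


def _longest_terminal_match(end_seq: str, vector_text: str, min_len: int) -> int | None:
    """Longest prefix of ``end_seq`` occurring in ``vector_text``."""
    lo, hi = 0, len(end_seq)  # invariant: prefix of length lo always found
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if end_seq[:mid] in vector_text:
            lo = mid
        else:
            hi = mid - 1
    return lo if lo >= min_len else None


def detect_vector_flanks(
    seq: str,
    vector: SequenceRecord,
    min_flank: int = 16,
    max_flank: int = 200,
) -> tuple[int | None, int | None, str]:
    """Exact vector sequence at the contig termini.

    Returns (left flank bp, right flank bp, trimmed sequence).  Both
    strands of the vector are searched; flanks shorter than ``min_flank``
    are ignored.  Both-sided detection marks the insert as a complete
    fosmid.
    """
    vec_text = vector.seq + "#" + vector.reverse_complement().seq
    cap = min(max_flank, len(seq) // 2)
    left = _longest_terminal_match(seq[:cap], vec_text, min_flank)
    right = _longest_terminal_match(seq[::-1][:cap], vec_text[::-1], min_flank)
    trimmed = seq[(left or 0): len(seq) - (right or 0)]
    return left, right, trimmed


# ---------------------------------------------------------------------------
# circular permutation layout


def _hit_orientation_and_diagonal(
    h: AlignmentHit, len_a: int, len_b: int
) -> tuple[str, int]:
    """Diagonal of a hit in A-coordinates; minus-strand hits are projected
    through the reverse complement of B."""
    if h.strand == "+":
        return "+", h.q_interval.start - h.s_interval.start
    flipped = len_b - h.s_interval.end
    return "-", h.q_interval.start - flipped


def _circle_cover(len_a: int, len_b: int, offset_b: int, circ: int) -> int:
    """Positions of a circle of length ``circ`` covered by contig A at
    offset 0 and contig B at ``offset_b`` (both linear windows)."""
    covered = [False] * circ
    for start, length in ((0, len_a), (offset_b % circ, len_b)):
        for p in range(min(length, circ)):
            covered[(start + p) % circ] = True
    return sum(covered)


def circular_permutation_complete(
    cluster_contigs: Sequence[SequenceRecord],
    within_cluster_hits: Iterable[AlignmentHit],
    offset_tolerance: int = 50,
    min_hit_len: int = 100,
    min_identity: float = 99.5,
) -> tuple[set[str], int | None]:
    """Detect a closed circular layout among differently permuted contigs.

    The contigs are members of one cluster of highly related sequences;
    the identity guard (default 99.5%) restricts pairing to contigs of the
    same clone lineage, whose overlaps are essentially exact.  For every
    such pair, hits are grouped by alignment diagonal.  Two diagonal
    groups whose separation equals the circle length mean the pair
    witnesses both junctions; if the two windows then jointly cover the
    whole circle, a complete genome is present.  Returns the contigs
    participating in any closed layout and the inferred genome length
    (median over witnessing pairs).  Pairs whose extra diagonals are not
    multiples of the circle length (beyond tolerance) are dropped with a
    warning.
    """
    lengths = {c.id: len(c.seq) for c in cluster_contigs}
    by_pair: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in within_cluster_hits:
        if h.query_id == h.subject_id or h.length < min_hit_len:
            continue
        if h.pct_identity < min_identity:
            continue
        if h.query_id in lengths and h.subject_id in lengths:
            key = (h.query_id, h.subject_id)
            by_pair.setdefault(key, []).append(h)

    complete: set[str] = set()
    inferred: list[int] = []
    for (a, b), hits in sorted(by_pair.items()):
        len_a, len_b = lengths[a], lengths[b]
        diags: list[int] = []
        for h in hits:
            _, d = _hit_orientation_and_diagonal(h, len_a, len_b)
            diags.append(d)
        # group diagonals within tolerance
        groups: list[list[int]] = []
        for d in sorted(diags):
            if groups and d - groups[-1][-1] <= offset_tolerance:
                groups[-1].append(d)
            else:
                groups.append([d])
        if len(groups) < 2:
            continue
        reps = [int(statistics.median(g)) for g in groups]
        circ = reps[1] - reps[0]
        if circ <= 0:
            continue
        consistent = all(
            min(abs((r - reps[0]) % circ), circ - abs((r - reps[0]) % circ))
            <= offset_tolerance
            for r in reps
        )
        if not consistent:
            logger.warning(
                "inconsistent circular layout for pair (%s, %s): diagonals %s",
                a, b, reps,
            )
            continue
        # B's start maps to circle coordinate reps[0] in A's frame
        # (A_pos = B_pos + d; both diagonals are congruent mod circ)
        if _circle_cover(len_a, len_b, reps[0] % circ, circ) >= circ:
            complete.update((a, b))
            inferred.append(circ)
    genome_len = int(statistics.median(inferred)) if inferred else None
    return complete, genome_len


# ---------------------------------------------------------------------------
# orchestration and naming


def call_completeness(
    assignments: Sequence[ClusterAssignment],
    contigs: Sequence[SequenceRecord],
    vector: SequenceRecord | None = None,
    hits: Iterable[AlignmentHit] | None = None,
    min_repeat_len: int = 20,
    min_flank: int = 16,
) -> list[CompletenessCall]:
    """One completeness status per contig.

    Vector flanks are trimmed before repeat detection.  Permutation
    layouts are evaluated within round-1 clusters (permuted fragments of
    one genome share their overlap at near-100% identity, but cannot
    reach the 95% mutual coverage that defines subclusters); the identity
    guard inside :func:`circular_permutation_complete` keeps cross-variant
    pairs out.  ``hits`` may be precomputed all-vs-all nucleotide hits,
    otherwise they are computed here.
    """
    by_id = {c.id: c for c in contigs}
    assign = {a.contig_id: a for a in assignments}

    flanks: dict[str, tuple[int | None, int | None]] = {}
    trimmed: dict[str, str] = {}
    for c in contigs:
        if vector is not None:
            left, right, t = detect_vector_flanks(c.seq, vector, min_flank)
            flanks[c.id] = (left, right)
            trimmed[c.id] = t
        else:
            flanks[c.id] = (None, None)
            trimmed[c.id] = c.seq

    repeat_len: dict[str, int | None] = {
        cid: find_terminal_repeat(trimmed[cid], min_repeat_len) for cid in by_id
    }

    # permutation layouts per round-1 cluster
    clusters: dict[str, list[str]] = {}
    for a in assignments:
        if a.cluster_id != UNCLUSTERED:
            clusters.setdefault(a.cluster_id, []).append(a.contig_id)
    perm_complete: set[str] = set()
    perm_len: dict[str, int] = {}
    for sub_id in sorted(clusters):
        members = sorted(clusters[sub_id])
        if len(members) < 2:
            continue
        sub_contigs = [by_id[m] for m in members]
        if hits is None:
            sub_hits = all_vs_all_nuc(sub_contigs)
        else:
            mset = set(members)
            sub_hits = [
                h for h in hits if h.query_id in mset and h.subject_id in mset
            ]
        ids, glen = circular_permutation_complete(sub_contigs, sub_hits)
        perm_complete.update(ids)
        if glen is not None:
            for cid in ids:
                perm_len[cid] = glen

    calls: dict[str, CompletenessCall] = {}
    cgr_clusters: set[str] = set()
    for cid in sorted(by_id):
        evidence = set()
        glen = None
        if repeat_len[cid] is not None:
            evidence.add("terminal_repeat")
            glen = len(trimmed[cid]) - repeat_len[cid]
        if cid in perm_complete:
            evidence.add("circular_permutation")
            glen = glen if glen is not None else perm_len.get(cid)
        if flanks[cid][0] is not None and flanks[cid][1] is not None:
            evidence.add("vector_flanks")
        complete = bool(evidence - {"vector_flanks"})
        calls[cid] = CompletenessCall(
            contig_id=cid,
            status="CGR" if complete else "GF",
            evidence=frozenset(evidence) if complete else frozenset(
                evidence & {"vector_flanks"}),
            inferred_genome_length=glen if complete else None,
            terminal_repeat_len=repeat_len[cid] if complete else None,
            vector_flanks=flanks[cid],
        )
        if complete:
            a = assign.get(cid)
            if a and a.cluster_id != UNCLUSTERED:
                cgr_clusters.add(a.cluster_id)

    # upgrade GF -> CGF in clusters containing a CGR
    out = []
    for cid in sorted(by_id):
        call = calls[cid]
        a = assign.get(cid)
        if (
            call.status == "GF"
            and a is not None
            and a.cluster_id in cgr_clusters
        ):
            call = CompletenessCall(
                cid, "CGF", call.evidence, None, None, call.vector_flanks
            )
        out.append(call)
    return out


@dataclass(frozen=True)
class UvName:
    """Structured uncultured-virus identifier, e.g.
    uvMED-CGR-C1-MedDCM-OCT-S17-C19."""

    site_code: str  # e.g. MED
    status: str  # CGR | CGF | GF
    cluster_tag: str  # C1 / C1A / U
    contig_id: str

    def render(self) -> str:
        return f"uv{self.site_code}-{self.status}-{self.cluster_tag}-{self.contig_id}"


def parse_uv_name(name: str) -> UvName:
    parts = name.split("-", 3)
    if len(parts) != 4 or not parts[0].startswith("uv"):
        raise ValueError(f"not a valid uv identifier: {name!r}")
    return UvName(parts[0][2:], parts[1], parts[2], parts[3])


def assign_names(
    calls: Sequence[CompletenessCall],
    assignments: Sequence[ClusterAssignment],
    site_code: str = "MED",
) -> list[UvName]:
    """Render the uv nomenclature for every contig.

    The cluster tag is the subcluster id when assigned, else the cluster
    id, else U for unclustered contigs.
    """
    assign = {a.contig_id: a for a in assignments}
    names = []
    for call in calls:
        a = assign.get(call.contig_id)
        if a is None or a.cluster_id == UNCLUSTERED:
            tag = "U"
        else:
            tag = a.subcluster_id or a.cluster_id
        names.append(UvName(site_code, call.status, tag, call.contig_id))
    return names
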