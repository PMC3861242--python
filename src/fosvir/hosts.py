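"""Host prediction for phage contigs from three evidence streams.

SS  — high nucleotide similarity to a reference phage with a known host
      (likely only when the phages share a host species);
AMG — auxiliary metabolic genes: photosystem genes psbA/psbD link a phage
      unequivocally to Cyanobacteria;
INT — an integrase-carrying contig whose putative attP site is an exact
      match (tens of bp) to a host tRNA gene (the attB site).

Because tRNA genes are conserved among close relatives, INT evidence alone
supports only a broad assignment (phylum or class); a genus/species-level
call requires two concordant evidence kinds or strong SS evidence alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import NucleotideIndex, _encode_nt
from .io import GeneAnnotation, Interval, SequenceRecord, coverage_fraction

logger = logging.getLogger(__name__)

RANK_BROAD = "phylum_or_class"
RANK_FINE = "genus_or_species"

AMG_FLAGS = {"psbA", "psbD"}
AMG_BROAD = "Cyanobacteria"


@dataclass(frozen=True)
class HostTaxon:
    """A host with its specific name and its broad (phylum/class) group."""

    name: str
    broad: str


@dataclass(frozen=True)
class HostEvidence:
    kind: str  # SS | AMG | INT
    taxon: str | None  # specific taxon, when known
    broad: str
    detail: dict = field(default_factory=dict)


@dataclass(frozen=True)
class HostPrediction:
    contig_id: str
    predicted_taxon: str
    rank: str  # RANK_BROAD | RANK_FINE
    evidences: tuple[HostEvidence, ...]


@dataclass(frozen=True)
class AttMatch:
    trna_id: str
    length: int
    contig_interval: Interval
    trna_interval: Interval
    strand: str  # strand of the contig carrying the match


# ---------------------------------------------------------------------------
# gene-level evidence


def find_integrase(annotations: Iterable[GeneAnnotation]) -> list[GeneAnnotation]:
    """Genes flagged or annotated as integrases."""
    return [
        a
        for a in annotations
        if "integrase" in a.flags or "integrase" in a.product.lower()
    ]


def amg_flags(annotations: Iterable[GeneAnnotation]) -> set[str]:
    """Auxiliary metabolic gene flags present on the contig (psbA/psbD)."""
    found = set()
    for a in annotations:
        found.update(a.flags & AMG_FLAGS)
        for f in AMG_FLAGS:
            if f.lower() in a.product.lower():
                found.add(f)
    return found


# ---------------------------------------------------------------------------
# attP / attB matching


def _lcs_one_strand(contig_codes: np.ndarray, trna_codes: np.ndarray):
    """Longest exact common substring via column-vectorised suffix DP.

    Returns (length, contig_end, trna_end), ends exclusive.  O(|tRNA|)
    numpy passes over the contig.
    """
    n = len(contig_codes)
    prev = np.zeros(n, dtype=np.int32)
    best = (0, 0, 0)
    for j, cj in enumerate(trna_codes):
        match = (contig_codes == cj) & (contig_codes < 4)
        shifted = np.empty(n, dtype=np.int32)
        shifted[0] = 0
        shifted[1:] = prev[:-1]
        cur = np.where(match, shifted + 1, 0).astype(np.int32)
        m = int(cur.max()) if n else 0
        if m > best[0]:
            i = int(np.argmax(cur))
            best = (m, i + 1, j + 1)
        prev = cur
    return best


def find_att_match(
    contig: SequenceRecord,
    host_trnas: Sequence[SequenceRecord],
    min_len: int = 30,
) -> list[AttMatch]:
    """Longest exact shared substring between the contig and each tRNA.

    Both strands of the contig are searched; matches of at least
    ``min_len`` bp are returned sorted by decreasing length (ties by tRNA
    id).  Exact matching: this is the attP == attB identity signature of
    site-specific integration.
    """
    if not host_trnas:
        raise ValueError("tRNA set is empty")
    fwd = _encode_nt(contig.seq)
    rev = _encode_nt(contig.reverse_complement().seq)
    n = len(contig.seq)
    out: list[AttMatch] = []
    for trna in host_trnas:
        t_codes = _encode_nt(trna.seq)
        best = None
        for strand, codes in (("+", fwd), ("-", rev)):
            length, c_end, t_end = _lcs_one_strand(codes, t_codes)
            if length >= min_len:
                c_lo, c_hi = c_end - length, c_end
                if strand == "-":  # map back to forward contig coordinates
                    c_lo, c_hi = n - c_hi, n - c_lo
                m = AttMatch(
                    trna.id,
                    length,
                    Interval(c_lo, c_hi),
                    Interval(t_end - length, t_end),
                    strand,
                )
                if best is None or m.length > best.length:
                    best = m
        if best is not None:
            out.append(best)
    out.sort(key=lambda m: (-m.length, m.trna_id))
    return out


def int_evidence(
    contig: SequenceRecord,
    annotations: Sequence[GeneAnnotation],
    host_trnas: Sequence[SequenceRecord],
    trna_hosts: Mapping[str, HostTaxon],
    min_len: int = 30,
) -> list[HostEvidence]:
    """INT evidence: integrase on the contig plus an att match to a host
    tRNA.  Without an integrase, att matches yield no evidence.  When the
    longest matches tie across hosts of different broad taxa the signal is
    ambiguous and discarded."""
    integrases = find_integrase(annotations)
    if not integrases:
        return []
    matches = [m for m in find_att_match(contig, host_trnas, min_len)
               if m.trna_id in trna_hosts]
    if not matches:
        return []
    top = matches[0]
    tied = [m for m in matches if m.length == top.length]
    broads = {trna_hosts[m.trna_id].broad for m in tied}
    if len(broads) > 1:
        logger.warning(
            "contig %s: att match length %d ties across broad taxa %s; "
            "INT evidence discarded as ambiguous",
            contig.id, top.length, sorted(broads),
        )
        return []
    host = trna_hosts[top.trna_id]
    int_starts = [a.interval.start for a in integrases]
    dist = min(abs(s - top.contig_interval.start) for s in int_starts)
    return [
        HostEvidence(
            "INT",
            host.name,
            host.broad,
            detail={
                "trna_id": top.trna_id,
                "match_len": top.length,
                "contig_interval": (top.contig_interval.start, top.contig_interval.end),
                "trna_interval": (top.trna_interval.start, top.trna_interval.end),
                "strand": top.strand,
                "integrase_distance": dist,
            },
        )
    ]


def amg_evidence(annotations: Sequence[GeneAnnotation]) -> list[HostEvidence]:
    flags = amg_flags(annotations)
    if not flags:
        return []
    return [
        HostEvidence("AMG", None, AMG_BROAD, detail={"genes": sorted(flags)})
    ]


def ss_evidence(
    contig: SequenceRecord,
    reference_phages: Sequence[SequenceRecord],
    ref_hosts: Mapping[str, HostTaxon],
    strong_identity: float = 75.0,
    strong_cov: float = 0.5,
    index: NucleotideIndex | None = None,
) -> list[HostEvidence]:
    """SS evidence: the contig resembles a reference phage of known host.

    Nucleotide hits at >= ``strong_identity`` are aggregated per
    reference; evidence is emitted when their merged projection covers at
    least ``strong_cov`` of the contig.  References without host metadata
    are skipped with a warning.
    """
    if index is None:
        index = NucleotideIndex(reference_phages)
    hits = index.search(contig)
    per_ref: dict[str, list] = {}
    for h in hits:
        if h.pct_identity >= strong_identity:
            per_ref.setdefault(h.subject_id, []).append(h)
    out = []
    for ref_id in sorted(per_ref):
        if ref_id not in ref_hosts:
            logger.warning("reference phage %s has no host metadata; skipped", ref_id)
            continue
        ref_hits = per_ref[ref_id]
        cov = coverage_fraction([h.q_interval for h in ref_hits], len(contig.seq))
        if cov < strong_cov:
            continue
        total = sum(h.length for h in ref_hits)
        mean_id = sum(h.pct_identity * h.length for h in ref_hits) / total
        host = ref_hosts[ref_id]
        out.append(
            HostEvidence(
                "SS",
                host.name,
                host.broad,
                detail={
                    "reference": ref_id,
                    "pct_identity": round(mean_id, 2),
                    "covered_fraction": round(cov, 4),
                },
            )
        )
    out.sort(key=lambda e: (-e.detail["covered_fraction"], e.detail["reference"]))
    return out


# ---------------------------------------------------------------------------
# prediction


def predict_host(
    contig_id: str, evidences: Sequence[HostEvidence]
) -> HostPrediction | None:
    """Combine evidence into one prediction under the rank rules.

    INT or AMG alone -> broad rank; two concordant kinds, or SS alone
    -> genus/species rank.  Evidence pointing at different broad taxa is
    a conflict: no prediction.
    """
    evs = list(evidences)
    if not evs:
        return None
    broads = {e.broad for e in evs}
    if len(broads) > 1:
        logger.warning(
            "contig %s: conflicting host evidence %s; no prediction",
            contig_id, sorted(broads),
        )
        return None
    broad = broads.pop()
    kinds = {e.kind for e in evs}
    fine = "SS" in kinds or len(kinds) >= 2
    if fine:
        specific = next(
            (e.taxon for k in ("SS", "INT") for e in evs if e.kind == k and e.taxon),
            None,
        )
        if specific is not None:
            return HostPrediction(contig_id, specific, RANK_FINE, tuple(evs))
    return HostPrediction(contig_id, broad, RANK_BROAD, tuple(evs))


def assign_hosts(
    contigs: Sequence[SequenceRecord],
    annotations_by_contig: Mapping[str, Sequence[GeneAnnotation]],
    host_trnas: Sequence[SequenceRecord],
    trna_hosts: Mapping[str, HostTaxon],
    reference_phages: Sequence[SequenceRecord] = (),
    ref_hosts: Mapping[str, HostTaxon] | None = None,
    min_att_len: int = 30,
) -> list[HostPrediction]:
    """Run all three evidence streams over a contig set."""
    ref_hosts = ref_hosts or {}
    ref_index = NucleotideIndex(reference_phages) if reference_phages else None
    predictions = []
    for contig in sorted(contigs, key=lambda c: c.id):
        anns = annotations_by_contig.get(contig.id, [])
        evs: list[HostEvidence] = []
        if host_trnas:
            evs.extend(
                int_evidence(contig, anns, host_trnas, trna_hosts, min_att_len)
            )
        evs.extend(amg_evidence(anns))
        if ref_index is not None:
            evs.extend(ss_evidence(contig, reference_phages, ref_hosts, index=ref_index))
        pred = predict_host(contig.id, evs)
        if pred is not None:
            predictions.append(pred)
    return predictions
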