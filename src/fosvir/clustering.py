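"""Two-round lineage clustering of contigs.

Round 1 groups contigs of the same or highly related phage lineage:
>95% nucleotide identity over at least 20% coverage.  Round 2 splits each
cluster into subclusters of nearly identical contigs at >95% coverage.
Clusters are connected components of the pairwise similarity graph.

Coverage is computed on the SHORTER contig of the pair: concatamer-derived
fosmid fragments of one lineage differ in length, and a short fragment
wholly contained in a long one should join its lineage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .align import AlignmentHit
from .io import Interval, SequenceRecord, coverage_fraction

UNCLUSTERED = "UNCLUSTERED"


@dataclass(frozen=True)
class ClusterAssignment:
    contig_id: str
    cluster_id: str  # "C1", ... or UNCLUSTERED
    subcluster_id: str | None = None  # "C1A", ... or None


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def build_edges(
    contigs: Sequence[SequenceRecord],
    all_vs_all_hits: Iterable[AlignmentHit],
    min_identity: float = 95.0,
    min_hit_len: int = 50,
    min_cov: float = 0.20,
) -> list[tuple[str, str]]:
    """Edges of the similarity graph.

    For each contig pair, hits above the identity/length thresholds are
    projected onto both contigs (strand-independently), overlapping
    projections merged, and an undirected edge emitted when the merged
    coverage of the shorter contig reaches ``min_cov``.
    """
    lengths = {c.id: len(c.seq) for c in contigs}
    by_pair: dict[tuple[str, str], dict[str, list[Interval]]] = {}
    for h in all_vs_all_hits:
        if h.query_id not in lengths or h.subject_id not in lengths:
            raise ValueError(
                f"hit references unknown contig: {h.query_id!r}/{h.subject_id!r}"
            )
        if h.query_id == h.subject_id:
            continue
        if h.pct_identity <= min_identity or h.length < min_hit_len:
            continue
        key = _pair_key(h.query_id, h.subject_id)
        proj = by_pair.setdefault(key, {key[0]: [], key[1]: []})
        proj[h.query_id].append(h.q_interval)
        proj[h.subject_id].append(h.s_interval)

    edges = []
    for (a, b), proj in sorted(by_pair.items()):
        shorter = a if lengths[a] <= lengths[b] else b
        cov = coverage_fraction(proj[shorter], lengths[shorter])
        if cov >= min_cov:
            edges.append((a, b))
    return edges


def connected_components(
    edges: Iterable[tuple[str, str]], nodes: Iterable[str]
) -> list[list[str]]:
    """Connected components, each sorted; components ordered by
    decreasing size then smallest member."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def _subcluster_letters(i: int) -> str:
    """0 -> A, 25 -> Z, 26 -> AA ..."""
    letters = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        letters = chr(ord("A") + rem) + letters
    return letters


def two_round_cluster(
    contigs: Sequence[SequenceRecord],
    hits: Iterable[AlignmentHit],
    min_identity: float = 95.0,
    min_hit_len: int = 50,
    cov_round1: float = 0.20,
    cov_round2: float = 0.95,
) -> list[ClusterAssignment]:
    """Cluster contigs in two rounds and name the groups.

    Round-1 components of size >= 2 become C1, C2, ... (decreasing size,
    ties by smallest member id); singletons are UNCLUSTERED.  Within each
    cluster, round-2 components of size >= 2 become letter-suffixed
    subclusters (C1A, C1B, ...); round-2 singletons keep no subcluster.
    The result is independent of contig and hit input order.
    """
    hits = list(hits)
    node_ids = [c.id for c in contigs]
    edges1 = build_edges(contigs, hits, min_identity, min_hit_len, cov_round1)
    comps1 = connected_components(edges1, node_ids)

    by_id = {c.id: c for c in contigs}
    assignments: dict[str, ClusterAssignment] = {}
    cluster_no = 0
    for comp in comps1:
        if len(comp) == 1:
            assignments[comp[0]] = ClusterAssignment(comp[0], UNCLUSTERED)
            continue
        cluster_no += 1
        cname = f"C{cluster_no}"
        members = set(comp)
        sub_hits = [
            h for h in hits if h.query_id in members and h.subject_id in members
        ]
        edges2 = build_edges(
            [by_id[i] for i in comp], sub_hits, min_identity, min_hit_len, cov_round2
        )
        comps2 = connected_components(edges2, comp)
        sub_no = 0
        for sub in comps2:
            if len(sub) == 1:
                assignments[sub[0]] = ClusterAssignment(sub[0], cname)
                continue
            sub_name = cname + _subcluster_letters(sub_no)
            sub_no += 1
            for cid in sub:
                assignments[cid] = ClusterAssignment(cid, cname, sub_name)
    return [assignments[cid] for cid in sorted(assignments)]
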