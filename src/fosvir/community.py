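"""Ground-truthed synthetic phage communities.

Generates the statistical structure the pipeline assumes to find in real
fosmid metagenomes:

* lineages of near-identical genomes (independent substitutions from a
  hidden ancestor, so every within-lineage pair sits at the configured
  identity) carrying divergent islands at much lower identity;
* hybrid mosaic genomes that swap a large segment between two lineages
  sharing a host;
* fosmid-sized contigs cut from the rolled-out replication concatamer at
  random offsets — terminally redundant when the insert exceeds the
  genome, circularly permuted otherwise — optionally flanked by vector
  sequence on both sides;
* host genomes with tRNA genes, and planted integrase + attP sites copied
  exactly from a host tRNA;
* metavirome reads drawn from the genome mixture with per-base errors.

Every generated record has exactly one truth row, so recovery can be
scored exactly.  All randomness flows through one integer-seeded
generator; a fixed seed reproduces the community byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hosts import HostTaxon
from .io import GeneAnnotation, Interval, SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_BROAD_CYCLE = [
    "Cyanobacteria",
    "Alphaproteobacteria",
    "Verrucomicrobia",
    "Gammaproteobacteria",
]
_HOST_GENUS = {
    "Cyanobacteria": "Prochlorococcus",
    "Alphaproteobacteria": "Ca. Pelagibacter",
    "Verrucomicrobia": "Verrucomicrobium",
    "Gammaproteobacteria": "SAR86 cluster bacterium",
}


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of the synthetic community.

    Defaults follow the regime of fosmid-scale marine viral metagenomics:
    genomes of 30-45 kb (fosmid inserts of 30-40 kb cap what is
    recoverable), GC between 27 and 57%, lineage variants at 97%
    nucleotide identity with ~10% of the genome in islands diverged to
    75-80%, vector flanks of 16-67 bp, and attP sites of 36-46 bp.
    """

    seed: int = 0
    n_lineages: int = 5
    lineage_size: int = 4
    genome_len_range: tuple[int, int] = (30_000, 45_000)
    gc_range: tuple[float, float] = (0.27, 0.57)
    within_identity: float = 0.97
    island_fraction: float = 0.10
    island_identity_range: tuple[float, float] = (0.75, 0.80)
    n_islands: int = 2
    n_hybrids: int = 0
    hybrid_swap_fraction: float = 0.3
    fragments_per_genome: int = 2
    insert_range: tuple[int, int] = (30_000, 40_000)
    vector_flank_range: tuple[int, int] = (16, 67)
    flank_prob: float = 0.12
    att_len_range: tuple[int, int] = (36, 46)
    n_hosts: int = 3
    host_genome_len: int = 20_000
    trnas_per_host: int = 4
    trna_len: int = 85
    n_decoys: int = 5
    decoy_len_range: tuple[int, int] = (5_000, 15_000)
    read_len: int = 100
    n_reads: int = 10_000
    read_error_rate: float = 0.02
    gene_len: int = 900
    gene_spacing: int = 1_000

    def validate(self) -> None:
        if not (0.0 <= self.island_fraction <= 1.0):
            raise ValueError("island_fraction must be in [0, 1]")
        if not (0.0 < self.within_identity <= 1.0):
            raise ValueError("within_identity must be in (0, 1]")
        for lo, hi, what in [
            (*self.genome_len_range, "genome_len_range"),
            (*self.gc_range, "gc_range"),
            (*self.island_identity_range, "island_identity_range"),
            (*self.insert_range, "insert_range"),
            (*self.vector_flank_range, "vector_flank_range"),
            (*self.att_len_range, "att_len_range"),
        ]:
            if lo > hi:
                raise ValueError(f"{what} is not ordered: ({lo}, {hi})")
        if not (0.0 <= self.hybrid_swap_fraction <= 1.0):
            raise ValueError("hybrid_swap_fraction must be in [0, 1]")


@dataclass
class Community:
    spec: CommunitySpec
    genomes: list[SequenceRecord]
    genome_annotations: dict[str, list[GeneAnnotation]]
    contigs: list[SequenceRecord]
    contig_annotations: dict[str, list[GeneAnnotation]]
    decoy_contigs: list[SequenceRecord]
    decoy_annotations: dict[str, list[GeneAnnotation]]
    vector: SequenceRecord
    host_genomes: list[SequenceRecord]
    host_taxa: dict[str, HostTaxon]
    trnas: list[SequenceRecord]
    trna_hosts: dict[str, HostTaxon]
    reads: list[SequenceRecord]
    truth_genomes: pd.DataFrame = field(default_factory=pd.DataFrame)
    truth_contigs: pd.DataFrame = field(default_factory=pd.DataFrame)
    truth_reads: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# sequence-level primitives


def random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def mutate(
    rng: np.random.Generator, seq: str, rate: float, region: Interval | None = None
) -> str:
    """Substitute bases at the given per-site rate (no indels), optionally
    only inside ``region``.  Substitutions always change the base."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    lo, hi = (region.start, region.end) if region else (0, len(arr))
    n = hi - lo
    hit = np.nonzero(rng.random(n) < rate)[0] + lo
    if hit.size:
        # shift each hit base by 1..3 positions in the ACGT cycle
        code = np.searchsorted(_BASES, arr[hit])  # ACGT are sorted ASCII
        code = (code + rng.integers(1, 4, size=hit.size)) % 4
        arr[hit] = _BASES[code]
    return arr.tobytes().decode()


def _orf_grid(contig_id: str, length: int, gene_len: int, spacing: int,
              vq: float | None) -> list[GeneAnnotation]:
    """A regular gene grid (~1 gene/kb) so annotation-driven modules have
    something to consume."""
    out = []
    pos = 50
    strand_toggle = 0
    while pos + gene_len <= length:
        out.append(
            GeneAnnotation(
                contig_id,
                Interval(pos, pos + gene_len),
                "+" if strand_toggle % 2 == 0 else "-",
                "hypothetical protein",
                vq,
                frozenset(),
            )
        )
        strand_toggle += 1
        pos += spacing
    return out


def _set_gene(
    anns: list[GeneAnnotation], idx: int, product: str, flags: set[str]
) -> list[GeneAnnotation]:
    anns = list(anns)
    anns[idx] = replace(anns[idx], product=product, flags=frozenset(flags))
    return anns


# ---------------------------------------------------------------------------
# att planting


def plant_att(
    genome: SequenceRecord,
    annotations: list[GeneAnnotation],
    host_trna: SequenceRecord,
    att_len: int,
    rng: np.random.Generator,
    with_integrase: bool = True,
) -> tuple[SequenceRecord, list[GeneAnnotation], dict]:
    """Copy an exact ``att_len`` bp tRNA substring into the genome and
    (optionally) mark a nearby gene as the integrase.

    Returns (modified genome, modified annotations, truth record).  The
    att site overwrites sequence just downstream of the chosen gene, in
    the intergenic gap, so the gene grid is untouched.
    """
    if att_len > len(host_trna.seq):
        raise ValueError("att_len exceeds tRNA length")
    t0 = int(rng.integers(0, len(host_trna.seq) - att_len + 1))
    att = host_trna.seq[t0 : t0 + att_len]
    gene_idx = int(rng.integers(1, max(2, len(annotations) - 1)))
    gene = annotations[gene_idx]
    pos = gene.interval.end + 10
    if pos + att_len > len(genome.seq):
        pos = gene.interval.start - 10 - att_len
    seq = genome.seq[:pos] + att + genome.seq[pos + att_len :]
    if with_integrase:
        annotations = _set_gene(
            annotations, gene_idx, "site-specific integrase", {"integrase"}
        )
    truth = {
        "genome_id": genome.id,
        "att_trna": host_trna.id,
        "att_len": att_len,
        "att_pos": pos,
        "att_trna_start": t0,
        "integrase_pos": gene.interval.start if with_integrase else None,
    }
    return replace(genome, seq=seq), annotations, truth


# ---------------------------------------------------------------------------
# fosmid contigs


def make_fosmid_contigs(
    genome: SequenceRecord,
    annotations: list[GeneAnnotation],
    n_fragments: int,
    insert_range: tuple[int, int],
    vector: SequenceRecord,
    flank_prob: float,
    flank_range: tuple[int, int],
    rng: np.random.Generator,
) -> tuple[list[SequenceRecord], dict[str, list[GeneAnnotation]], list[dict]]:
    """Cut fosmid inserts from the rolled-out replication concatamer.

    Each contig is a window at a random offset; terminal redundancy arises
    naturally when the insert exceeds the genome length.  With probability
    ``flank_prob`` the insert keeps vector flanks (16-67 bp) on both
    sides, marking it as a completely sequenced fosmid.
    """
    glen = len(genome.seq)
    concat = genome.seq * (max(insert_range) // glen + 2)
    contigs, anns_out, truth = [], {}, []
    for i in range(n_fragments):
        offset = int(rng.integers(0, glen))
        insert_len = int(rng.integers(insert_range[0], insert_range[1] + 1))
        window = concat[offset : offset + insert_len]
        left = right = 0
        if rng.random() < flank_prob:
            left = int(rng.integers(flank_range[0], flank_range[1] + 1))
            right = int(rng.integers(flank_range[0], flank_range[1] + 1))
            v0 = int(rng.integers(0, len(vector.seq) - max(left, right)))
            window = (
                vector.seq[v0 : v0 + left]
                + window
                + vector.seq[v0 : v0 + right]
            )
        cid = f"{genome.id}-F{i + 1}"
        contigs.append(SequenceRecord(cid, window))
        mapped = []
        for a in annotations:
            for copy in range(len(concat) // glen):
                gs = copy * glen + a.interval.start
                ge = copy * glen + a.interval.end
                if gs >= offset and ge <= offset + insert_len:
                    mapped.append(
                        replace(
                            a,
                            contig_id=cid,
                            interval=Interval(gs - offset + left, ge - offset + left),
                        )
                    )
        anns_out[cid] = mapped
        truth.append(
            {
                "contig_id": cid,
                "genome_id": genome.id,
                "cut_offset": offset,
                "insert_len": insert_len,
                "left_flank": left,
                "right_flank": right,
                "complete_genome_present": insert_len >= glen,
            }
        )
    return contigs, anns_out, truth


# ---------------------------------------------------------------------------
# reads


def simulate_metavirome(
    genomes: list[SequenceRecord],
    abundances: np.ndarray,
    n_reads: int,
    read_len: int,
    err_rate: float,
    rng: np.random.Generator,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Reads drawn multinomially by abundance x genome length, uniform
    start on the circular genome, independent per-base errors."""
    abundances = np.asarray(abundances, dtype=float)
    if abs(abundances.sum() - 1.0) > 1e-9:
        raise ValueError("abundances must sum to 1")
    w = abundances * np.array([len(g.seq) for g in genomes])
    w = w / w.sum()
    counts = rng.multinomial(n_reads, w)
    reads, rows = [], []
    r = 0
    for g, c in zip(genomes, counts):
        circ = g.seq + g.seq[:read_len]
        for _ in range(int(c)):
            start = int(rng.integers(0, len(g.seq)))
            frag = circ[start : start + read_len]
            if err_rate > 0:
                frag = mutate(rng, frag, err_rate)
            if rng.random() < 0.5:
                frag = SequenceRecord("t", frag).reverse_complement().seq
            rid = f"read_{r:06d}"
            r += 1
            reads.append(SequenceRecord(rid, frag))
            rows.append({"read_id": rid, "genome_id": g.id, "start": start})
    return reads, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole community


def generate_community(spec: CommunitySpec) -> Community:
    """Generate genomes, hosts, contigs, decoys, reads and truth tables.

    Deterministic given ``spec.seed``.  One variant per lineage carries a
    planted integrase + attP site matching a tRNA of the lineage's host;
    genomes hosted by Cyanobacteria additionally carry a psbA gene (AMG).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    # hosts and tRNAs
    host_genomes, trnas = [], []
    host_taxa: dict[str, HostTaxon] = {}
    trna_hosts: dict[str, HostTaxon] = {}
    for h in range(spec.n_hosts):
        broad = _BROAD_CYCLE[h % len(_BROAD_CYCLE)]
        taxon = HostTaxon(f"{_HOST_GENUS[broad]} H{h + 1}", broad)
        hid = f"host{h + 1}"
        seq = random_sequence(rng, spec.host_genome_len, 0.45)
        for t in range(spec.trnas_per_host):
            t_seq = random_sequence(rng, spec.trna_len, 0.55)
            pos = 1_000 + t * 2_000
            seq = seq[:pos] + t_seq + seq[pos + spec.trna_len :]
            tid = f"{hid}_tRNA{t + 1}"
            trnas.append(SequenceRecord(tid, t_seq))
            trna_hosts[tid] = taxon
        host_genomes.append(SequenceRecord(hid, seq))
        host_taxa[hid] = taxon

    # lineages of phage genomes
    genomes: list[SequenceRecord] = []
    genome_annotations: dict[str, list[GeneAnnotation]] = {}
    genome_rows: list[dict] = []
    ancestors: dict[int, str] = {}
    host_of_lineage: dict[int, int] = {}
    half_rate = (1.0 - spec.within_identity) / 2.0
    for li in range(spec.n_lineages):
        glen = int(rng.integers(spec.genome_len_range[0], spec.genome_len_range[1] + 1))
        gc = float(rng.uniform(*spec.gc_range))
        ancestor = random_sequence(rng, glen, gc)
        ancestors[li] = ancestor
        host_idx = li % spec.n_hosts
        host_of_lineage[li] = host_idx
        taxon = host_taxa[f"host{host_idx + 1}"]
        for vi in range(spec.lineage_size):
            gid = f"L{li + 1}V{vi + 1}"
            seq = mutate(rng, ancestor, half_rate)
            islands = []
            if spec.island_fraction > 0 and spec.n_islands > 0:
                island_len = int(glen * spec.island_fraction / spec.n_islands)
                for _ in range(spec.n_islands):
                    start = int(rng.integers(0, glen - island_len))
                    ident = float(rng.uniform(*spec.island_identity_range))
                    seq = mutate(rng, seq, 1.0 - ident,
                                 Interval(start, start + island_len))
                    islands.append((start, start + island_len))
            genome = SequenceRecord(gid, seq)
            anns = _orf_grid(gid, glen, spec.gene_len, spec.gene_spacing, vq=1.0)
            anns = _set_gene(anns, 0, "terminase large subunit", {"terminase"})
            if taxon.broad == "Cyanobacteria" and len(anns) > 2:
                anns = _set_gene(anns, 2, "photosystem II protein D1", {"psbA"})
            att_row = {}
            if vi == 0:  # one integrase+att variant per lineage
                trna = trnas[host_idx * spec.trnas_per_host]
                att_len = int(rng.integers(spec.att_len_range[0],
                                           spec.att_len_range[1] + 1))
                genome, anns, att_row = plant_att(genome, anns, trna, att_len, rng)
            genomes.append(genome)
            genome_annotations[gid] = anns
            genome_rows.append(
                {
                    "genome_id": gid,
                    "lineage": li + 1,
                    "variant": vi + 1,
                    "genome_len": glen,
                    "gc": gc,
                    "host_taxon": taxon.name,
                    "host_broad": taxon.broad,
                    "islands": ";".join(f"{a}-{b}" for a, b in islands),
                    "att_trna": att_row.get("att_trna", ""),
                    "att_len": att_row.get("att_len", 0),
                    "att_pos": att_row.get("att_pos", -1),
                    "is_hybrid": False,
                }
            )

    # hybrid mosaics: swap a segment between two lineages sharing a host
    by_host: dict[int, list[int]] = {}
    for li, hi in host_of_lineage.items():
        by_host.setdefault(hi, []).append(li)
    for hy in range(spec.n_hybrids):
        pairs = [v for v in by_host.values() if len(v) >= 2]
        if not pairs:
            break
        la, lb = pairs[hy % len(pairs)][:2]
        rec = ancestors[la]
        don = ancestors[lb]
        seg_len = int(min(len(rec), len(don)) * spec.hybrid_swap_fraction)
        start = int(rng.integers(0, min(len(rec), len(don)) - seg_len + 1))
        seq = rec[:start] + don[start : start + seg_len] + rec[start + seg_len :]
        gid = f"HYB{hy + 1}"
        genomes.append(SequenceRecord(gid, seq))
        anns = _orf_grid(gid, len(seq), spec.gene_len, spec.gene_spacing, vq=1.0)
        genome_annotations[gid] = _set_gene(
            anns, 0, "terminase large subunit", {"terminase"})
        genome_rows.append(
            {
                "genome_id": gid,
                "lineage": la + 1,
                "variant": 0,
                "genome_len": len(seq),
                "gc": float("nan"),
                "host_taxon": host_taxa[f"host{host_of_lineage[la] + 1}"].name,
                "host_broad": host_taxa[f"host{host_of_lineage[la] + 1}"].broad,
                "islands": "",
                "att_trna": "",
                "att_len": 0,
                "att_pos": -1,
                "is_hybrid": True,
                "donor_lineage": lb + 1,
                "swap_start": start,
                "swap_len": seg_len,
            }
        )

    vector = SequenceRecord("pCC1FOS-like", random_sequence(rng, 8_000, 0.50))

    # fosmid contigs
    contigs: list[SequenceRecord] = []
    contig_annotations: dict[str, list[GeneAnnotation]] = {}
    contig_rows: list[dict] = []
    for genome in genomes:
        cs, ca, rows = make_fosmid_contigs(
            genome,
            genome_annotations[genome.id],
            spec.fragments_per_genome,
            spec.insert_range,
            vector,
            spec.flank_prob,
            spec.vector_flank_range,
            rng,
        )
        contigs.extend(cs)
        contig_annotations.update(ca)
        lineage = next(r for r in genome_rows if r["genome_id"] == genome.id)
        for row in rows:
            row["lineage"] = lineage["lineage"]
            contig_rows.append(row)

    # decoy (cellular) contigs from host genomes: no VQ, no hallmark genes
    decoys: list[SequenceRecord] = []
    decoy_annotations: dict[str, list[GeneAnnotation]] = {}
    for d in range(spec.n_decoys):
        host = host_genomes[d % len(host_genomes)]
        dlen = int(rng.integers(spec.decoy_len_range[0], spec.decoy_len_range[1] + 1))
        start = int(rng.integers(0, max(1, len(host.seq) - dlen)))
        did = f"decoy{d + 1}"
        decoys.append(SequenceRecord(did, host.seq[start : start + dlen]))
        decoy_annotations[did] = _orf_grid(
            did, dlen, spec.gene_len, spec.gene_spacing, vq=None
        )

    # metavirome reads from the genome mixture
    reads: list[SequenceRecord] = []
    truth_reads = pd.DataFrame()
    if spec.n_reads > 0:
        abund = rng.dirichlet(np.ones(len(genomes)))
        reads, truth_reads = simulate_metavirome(
            genomes, abund, spec.n_reads, spec.read_len, spec.read_error_rate, rng
        )

    return Community(
        spec=spec,
        genomes=genomes,
        genome_annotations=genome_annotations,
        contigs=contigs,
        contig_annotations=contig_annotations,
        decoy_contigs=decoys,
        decoy_annotations=decoy_annotations,
        vector=vector,
        host_genomes=host_genomes,
        host_taxa=host_taxa,
        trnas=trnas,
        trna_hosts=trna_hosts,
        reads=reads,
        truth_genomes=pd.DataFrame(genome_rows),
        truth_contigs=pd.DataFrame(contig_rows),
        truth_reads=truth_reads,
    )
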