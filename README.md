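# fosvir

Recovery and analysis of **complete uncultured phage genomes** from
fosmid-scale metagenomic contigs.

Most marine phages have never been cultured. Cloning environmental DNA into
fosmids (~30–40 kb inserts) captures phage genomes that are actively
replicating through a concatamer intermediate: each insert is a circularly
permuted window of a genome, often terminally redundant. `fosvir`
implements the full downstream analysis for such data, for microbial
ecologists and phage genomicists working with fosmid libraries, viral
metagenomes, or any contig set suspected to contain complete phage genomes:

1. **Viral screening** (`fosvir.screen`) — classify contigs from their
   per-gene virus quotient (VQ) profile and hallmark genes (terminase,
   capsid, tape measure protein).
2. **Lineage clustering** (`fosvir.clustering`) — two rounds of
   connected-component clustering of the similarity graph: >95% nucleotide
   identity over ≥20% coverage (clusters C1, C2, …), then ≥95% coverage
   within clusters (subclusters C1A, C1B, …). Coverage is measured on the
   shorter contig of each pair.
3. **Completeness calling** (`fosvir.completeness`) — a contig carries a
   complete genome when (a) it has an exact direct terminal repeat
   (contig length − repeat = genome length), or (b) two differently
   permuted contigs of one cluster jointly witness both junctions of the
   circle. Vector flanks (≥16 bp, both sides = completely sequenced
   fosmid) are detected and trimmed first. Contigs are named
   `uv<SITE>-<CGR|CGF|GF>-<C1A|U>-<contig id>`.
4. **Genome taxonomy** (`fosvir.taxonomy`) — six-frame translated
   comparison of genome pairs (BLOSUM45); the bit scores of significant
   hits (>30% identity, ≥30 aa, e ≤ 0.01) are summed to a comparison score
   *AB*, normalised by the self scores:

       Dice = 2·AB / (AA + BB),   d = 1 − Dice

   A neighbor-joining tree is built from the distance matrix and sequence
   groups (G1, G2, …) are cut at a path-distance threshold.
5. **Host assignment** (`fosvir.hosts`) — three evidence streams: SS
   (high nucleotide identity to a reference phage of known host), AMG
   (psbA/psbD link a phage to Cyanobacteria), INT (an integrase-carrying
   contig whose putative *attP* site matches a host tRNA gene — the *attB*
   site — exactly over ≥30 bp). INT or AMG alone give a phylum/class-level
   call; two concordant kinds, or strong SS alone, allow genus/species.
6. **Read recruitment** (`fosvir.recruitment`) — fragment recruitment of
   metavirome/metagenome reads with strict (>95% identity, ≥50 bp,
   e ≤ 1e-5) or relaxed (≥50 bp, e ≤ 0.01) filters, one best hit per read,
   normalised as RPKG = reads / (contig kb) / (dataset Gb).

A built-in seed-and-extend aligner (`fosvir.align`) runs all of this
without external binaries; an adapter ingests 12-column tabular output of
any external search tool for replication runs. `fosvir.community`
generates ground-truthed synthetic communities (diverged lineages with
divergent islands, hybrid mosaics, concatamer-cut fosmid contigs with
vector flanks, planted integrase + att sites, metavirome reads) so every
stage can be scored against known truth.

## Worked example

```bash
$ fosvir simulate --seed 5 --out demo --lineages 3 --variants 2 --reads 500
community: 6 genomes, 12 contigs, 500 reads -> demo

$ fosvir screen demo/contigs.fasta demo/annotations.tsv --out demo/screen.tsv
12/17 contigs classified viral

$ fosvir cluster demo/contigs.fasta --out demo/clusters.tsv
12/12 contigs clustered

$ fosvir complete demo/contigs.fasta demo/clusters.tsv \
    --vector demo/vector.fasta --out demo/complete.tsv
12 CGR / 12 contigs

$ fosvir host demo/contigs.fasta demo/annotations.tsv \
    --trnas demo/trnas.fasta --trna-taxa demo/trna_taxa.tsv --out demo/hosts.tsv
8 host predictions for 12 contigs

$ fosvir recruit demo/reads.fasta demo/contigs.fasta --out demo/recruit.tsv
483/500 reads recruited (96.60%, mode=strict)

$ fosvir taxonomy demo/genomes.fasta --out-prefix demo/tax
6 genomes -> 3 groups
```

The 17 screened contigs are the 12 phage contigs (all classified viral:
VQ-1.0 gene profiles plus terminase genes) and 5 cellular decoys (all
rejected). The two fosmid contigs cut from genome L1V1 land in one
cluster; `demo/complete.tsv` shows why both are complete:

```
contig_id  status  evidence                              inferred_genome_length  terminal_repeat_len
L1V1-F1    CGR     circular_permutation                  33137
L1V1-F2    CGR     circular_permutation,terminal_repeat  33137                   2563
```

F2's insert exceeded the 33,137 bp genome, leaving a 2,563 bp terminal
repeat (35,700 − 2,563 = 33,137); F1 and F2 were cut at different
concatamer offsets, so together they close the circle — two independent
lines of evidence agreeing on the same genome length. Recruitment reports
483 of 500 simulated reads (96.6%) passing the strict filter: reads carry
2% simulated sequencing error, so a minority fall below 95% identity.
The taxonomy step groups the 6 genomes into their 3 source lineages.

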