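# Methods

## The analysis model

`fosvir` assumes its input contigs derive from fosmid cloning of phage
replication concatamers. This has three consequences the pipeline
exploits:

* a fosmid insert longer than the phage genome wraps past its own start,
  producing an **exact direct terminal repeat** whose length fixes the
  genome length (genome = contig − repeat);
* two inserts cut from the concatamer at different offsets are
  **circularly permuted**: aligned against each other they produce two
  alignment diagonals whose separation equals the genome length, and if
  their windows jointly cover the circle, both circle junctions are
  witnessed;
* contigs of one phage lineage form tight **identity clusters**, since the
  library samples the same replicating population repeatedly.

All coordinates are 0-based half-open in memory and 1-based inclusive in
written tables. N bases are legal input and never count as matches.

## Alignment backend

The built-in aligner is a seed-and-extend local aligner tuned for the
high-identity regime the pipeline operates in (clustering at >95%,
recruitment at >95%, att matching exact).

* Nucleotide mode: exact 12-mer seeds (both query strands against forward
  subjects), grouped by (subject, diagonal), one ungapped X-drop extension
  per diagonal region (X = 20, chunked over 256-column blocks). Scoring is
  match +1 / mismatch −2; bit scores and e-values use the Karlin–Altschul
  transform with fixed ungapped parameters (λ = 1.33, K = 0.62).
* Extended segments are **split at low-identity valleys**: wherever a
  100-column window inside a segment falls below 86% identity the segment
  is split there, recursively, and each piece trimmed to matching end
  columns. A long alignment crossing a divergent island is therefore
  reported as high-identity flanking hits plus the island itself, the way
  a finer-grained local search would report it. Without this, an
  alignment blending a 97%-identity backbone with a 77%-identity island
  averages ~95% — exactly at the clustering threshold, where chance decides
  the outcome. The 86% midpoint separates the two regimes; a window of
  100 at 97% identity essentially never dips below it
  (P[≥14 mismatches in 100 at p=0.03] ≈ 1e-7).
* Translated mode: all 36 frame pairs of the six-frame conceptual
  translations, exact 4-mer amino-acid seeds, BLOSUM45 scoring with its
  native stop-codon entries, X-drop 22, λ = 0.2291, K = 0.0924 (the
  published BLOSUM45 ungapped parameters). Hit lengths and identities are
  in amino acids; intervals map back to forward-strand nucleotides.
* The aligner is ungapped. The synthetic communities diverge by
  substitution, so this is exact there; on real data with indels the
  backend is the replaceable part — `read_tabular_hits` ingests standard
  12-column tabular output from any external aligner, and every downstream
  module consumes plain `AlignmentHit` lists.

Threshold semantics everywhere: identity is compared strictly
(`> min_identity`, so "more than 95% identical" excludes 95.0), length and
e-value bounds are inclusive (`length ≥ min`, `e ≤ max`); "significant at
e-value 0.01" is read as e ≤ 0.01, the only reading consistent with a
significance filter.

## Viral screening

A gene's virus quotient (VQ ∈ [0,1]) measures how phage-specific its
orthologous group is. A contig is called viral when at least τ = 0.6 of
its VQ-bearing genes have VQ ≥ 0.8 and it has at least m = 3 such genes,
or when it carries any hallmark structural gene (terminase, tape measure,
capsid). The original selection of this kind involved manual curation;
the declared thresholds replace that with a reproducible rule, and the
rationale string records which rules fired so a curator can review calls.

## Clustering

Round 1 links contigs sharing >95%-identity hits (≥50 bp) whose merged
projections cover ≥20% of the **shorter** contig; round 2 relinks within
each cluster at ≥95% coverage. The shorter-contig denominator is a
deliberate choice: concatamer fragments of one lineage differ in length,
and a short fragment contained in a long one belongs with it. Components
are named C1, C2, … by decreasing size (ties by smallest member id),
subclusters by letter suffix — naming is deterministic under input
permutation.

## Completeness

* Terminal repeats: the longest proper prefix recurring as the suffix
  (KMP border chain, capped at half the contig), minimum 20 bp — far above
  chance for 10⁴–10⁵ bp sequences (expected chance border ≥20 bp ≈
  n/4²⁰ ≈ 10⁻⁷). Matching is exact; one mismatch voids the repeat.
* Vector flanks ≥16 bp at the termini (either vector strand) are trimmed
  before repeat detection; both-sided flanks mark a completely sequenced
  fosmid. Detection is maximal-exact-match, so a reported flank can
  exceed the cloned flank by a couple of chance bases; the inferred genome
  length is unaffected (the repeat shortens by the same amount).
* Circular permutation: evaluated per round-1 cluster, pairing only
  contigs that share ≥99.5%-identity hits (≥100 bp) — permuted fragments
  of one clone are essentially exact in their overlap but mathematically
  cannot reach the 95% mutual coverage that defines subclusters, so the
  subcluster is the wrong scope for this evidence. Hit diagonals are
  grouped with ±50 bp tolerance (assembly-edge noise); two groups whose
  separation is the circle length, plus full joint coverage of the
  circle, declare a complete genome. Additional diagonals must be
  congruent modulo the circle length or the pair is dropped with a
  warning (conflicting layout). The genome length reported is the median
  over witnessing pairs.
* Statuses: CGR (completeness evidence), CGF (no evidence, but the
  round-1 cluster contains a CGR), GF (neither); unclustered contigs take
  the U tag in the uv name.

## Genome taxonomy

Comparison score AB = Σ bit scores of significant translated hits
(>30% aa identity, ≥30 aa, e ≤ 0.01). Overlapping hits are **not**
merged before summation — the score is a sum over all selected hits.
Since the A→B and B→A sums differ slightly (extension asymmetry), AB is
their arithmetic mean, making Dice = 2AB/(AA+BB) symmetric by
construction; it is clamped into [0,1]. Distance = 1 − Dice.

Neighbor joining is the classical O(n³) Q-criterion algorithm; Q-ties are
broken to the lexicographically smallest label pair, negative branch
lengths are clamped to zero with the deficit moved to the sister branch.
On additive matrices the implementation recovers the generating tree
exactly (topology and all path lengths), verified against an independent
least-squares topology oracle at n=4 and random additive matrices up to
n=10.

Sequence groups are cut by complete-linkage agglomeration of the
leaf–leaf path-distance matrix at a threshold (default 0.9): a group is a
set of genomes all within the threshold of each other along the tree.
This is rooting-independent — the arbitrary trifurcation NJ ends on
cannot split a tight family, which a naive rooted-subtree recursion does.
The original grouping of this kind was done by inspection; the threshold
makes it reproducible.

## Host assignment

* INT: requires an annotated integrase on the same contig; the att signal
  is the longest exact common substring (vectorised suffix DP, both
  contig strands) between contig and each host tRNA, minimum 30 bp.
  Observed att sites run 36–46 bp; 30 leaves margin while staying above
  chance for ~40 kb contigs against tens of tRNAs (expected chance LCS
  ≈ log₄(n·m) ≈ 12 bp). If the longest matches tie across hosts of
  different phyla the evidence is discarded as ambiguous. The
  integrase–att distance is reported for review but not used as a filter.
* AMG: psbA/psbD photosystem genes tie a phage to Cyanobacteria.
* SS: hits at ≥75% identity aggregated per reference phage; evidence when
  they cover ≥50% of the contig.
* Rank rules: INT or AMG alone → phylum/class; two concordant kinds or SS
  alone → genus/species (taking the most specific taxon available, SS
  preferred). Evidence pointing at different phyla is a conflict: no
  prediction, logged.

## Recruitment

Each read is assigned to at most one contig — its best-scoring passing
hit, ties to the lexicographically smallest contig id — so dataset
fractions never double-count. RPKG = reads / (contig length/10³) /
(dataset size/10⁹) compares differently sized contigs across differently
sized datasets. Strict mode (>95%, ≥50 bp, e ≤ 1e-5) measures abundance;
relaxed mode (any identity, ≥50 bp, e ≤ 0.01) measures how much of a
dataset is related to the contig set at all. Read qualities are ignored.

## Synthetic communities

The generator emulates the statistical structure the analysis assumes,
with defaults chosen for the fosmid-scale marine regime: genomes 30–45 kb
at GC 27–57%; lineages of 4 variants, each mutated independently from a
hidden ancestor at half the divergence rate so **every** within-lineage
pair sits at the configured identity (default 97% ± 0.5%); two islands
per variant totalling 10% of the genome, diverged to 75–80%; fosmid
inserts of 30–40 kb cut at uniform concatamer offsets; vector flanks of
16–67 bp on both sides with probability 0.12; one variant per lineage
carries a planted integrase + attP site (36–46 bp, copied exactly from a
host tRNA); genomes on cyanobacterial hosts carry a psbA gene; reads are
drawn multinomially by abundance × genome length with uniform starts on
the circular genome, random strand and independent per-base errors
(default 2%, 100 bp). Hybrid mosaics (off by default) swap a large
ancestor segment between two lineages sharing a host. Cellular decoy
contigs are cut from the host genomes, annotated without VQ values or
hallmark flags. All randomness flows through one PCG64 generator seeded
from the spec; a fixed seed reproduces every byte.

Genes are laid out on a regular grid (~1 per kb) with VQ 1.0 on phage
genes — enough to exercise screening and host assignment, but it means
the generator does not emulate: real codon structure or gene-density
variation, indels or rearrangements within lineages, MDA chimeras,
repeat families, or ssDNA/RNA phages. Tests passing on these communities
therefore demonstrate the recovery logic under the model's assumptions
(substitution-driven divergence, faithful cloning), not robustness to
assembly artefacts; the external-aligner adapter is the intended path for
real data with indels.

## Problem sizes in tests and acceptance

The shipped checks run at desk scale, chosen to exercise every code path
with comfortable statistical power: communities of 5 lineages × 4
variants (40 contigs) for clustering; 100 seeded genomes of 20–28 kb for
completeness; 50 planted att contigs + 100 decoys for host assignment;
10⁴ reads for mixture recovery; 100 random additive matrices (n = 4–10)
for neighbor joining; genome families of 6–9 × 4–6 kb for the translated
Dice/tree stage.

## Known limitations

* The aligner is ungapped; indel-rich comparisons need an external
  aligner through the adapter.
* Permutation completeness needs two fragments at distinct offsets; a
  genome sampled by identically permuted fragments only is recoverable
  solely through terminal redundancy.
* Group cutting and viral screening expose tunable thresholds where the
  original analyses were curated by hand; defaults are documented above
  and should be revisited for habitats very unlike the mid-photic marine
  water column.
* pac/cos packaging mechanisms are not distinguished; CRISPR-spacer and
  abundance-correlation host inference are out of scope.
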