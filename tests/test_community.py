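"""The synthetic community generator against its own declared statistics."""

import numpy as np
import pytest

from fosvir.community import (Community, CommunitySpec, generate_community,
                              make_fosmid_contigs, mutate, plant_att,
                              random_sequence, simulate_metavirome)
from fosvir.hosts import assign_hosts
from fosvir.io import GeneAnnotation, Interval, SequenceRecord
from fosvir.screen import group_annotations

SMALL = CommunitySpec(
    seed=11, n_lineages=3, lineage_size=3, genome_len_range=(8_000, 10_000),
    insert_range=(6_000, 9_000), n_reads=0, fragments_per_genome=2,
    n_hosts=2, n_decoys=2,
)


@pytest.fixture(scope="module")
def small_community():
    return generate_community(SMALL)


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        a = generate_community(SMALL)
        b = generate_community(SMALL)
        assert [g.seq for g in a.genomes] == [g.seq for g in b.genomes]
        assert [c.seq for c in a.contigs] == [c.seq for c in b.contigs]
        assert a.truth_contigs.equals(b.truth_contigs)
        assert a.truth_genomes.equals(b.truth_genomes)

    def test_different_seed_differs(self):
        a = generate_community(SMALL)
        b = generate_community(
            CommunitySpec(**{**SMALL.__dict__, "seed": 12})
        )
        assert a.genomes[0].seq != b.genomes[0].seq


class TestGenomeStatistics:
    def test_gc_within_one_percent_of_spec(self, small_community):
        for row in small_community.truth_genomes.itertuples():
            if row.is_hybrid:
                continue
            g = next(x for x in small_community.genomes if x.id == row.genome_id)
            gc = (g.seq.count("G") + g.seq.count("C")) / len(g.seq)
            assert abs(gc - row.gc) < 0.01

    def test_within_lineage_identity_outside_islands(self, small_community):
        """Pairwise identity outside both variants' islands lies within
        +/-0.5% of the configured value."""
        truth = small_community.truth_genomes
        by_id = {g.id: g for g in small_community.genomes}
        for lineage, grp in truth[~truth.is_hybrid].groupby("lineage"):
            rows = list(grp.itertuples())
            for i in range(len(rows)):
                for j in range(i + 1, len(rows)):
                    a = np.frombuffer(by_id[rows[i].genome_id].seq.encode(), np.uint8)
                    b = np.frombuffer(by_id[rows[j].genome_id].seq.encode(), np.uint8)
                    mask = np.ones(len(a), bool)
                    for r in (rows[i], rows[j]):
                        for span in filter(None, r.islands.split(";")):
                            lo, hi = map(int, span.split("-"))
                            mask[lo:hi] = False
                        if r.att_len > 0:  # planted att replaces sequence
                            mask[r.att_pos : r.att_pos + r.att_len] = False
                    ident = float((a[mask] == b[mask]).mean())
                    assert abs(ident - SMALL.within_identity) < 0.005

    def test_island_regions_markedly_diverged(self, small_community):
        truth = small_community.truth_genomes
        by_id = {g.id: g for g in small_community.genomes}
        grp = truth[truth.lineage == 1]
        r1, r2 = list(grp.itertuples())[:2]
        a = np.frombuffer(by_id[r1.genome_id].seq.encode(), np.uint8)
        b = np.frombuffer(by_id[r2.genome_id].seq.encode(), np.uint8)
        for span in filter(None, r1.islands.split(";")):
            lo, hi = map(int, span.split("-"))
            island_ident = float((a[lo:hi] == b[lo:hi]).mean())
            assert island_ident < 0.90  # well below the backbone identity

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            CommunitySpec(island_fraction=1.5).validate()
        with pytest.raises(ValueError):
            CommunitySpec(gc_range=(0.6, 0.3)).validate()


class TestHybrids:
    def test_hybrid_mosaic_structure(self):
        spec = CommunitySpec(**{**SMALL.__dict__, "n_hybrids": 1})
        com = generate_community(spec)
        truth = com.truth_genomes
        hyb_row = truth[truth.is_hybrid].iloc[0]
        hyb = next(g for g in com.genomes if g.id == hyb_row.genome_id)
        s, ln = int(hyb_row.swap_start), int(hyb_row.swap_len)
        # compare against the lineage consensus: variants are ~1.5% from
        # their ancestor, the donor segment should match the donor lineage
        # far better than the recipient lineage
        idx = truth.set_index("genome_id")
        rec_row = next(
            r for r in truth.itertuples()
            if r.lineage == hyb_row.lineage and not r.is_hybrid
        )
        rec_variant = next(g for g in com.genomes if g.id == rec_row.genome_id)
        a = np.frombuffer(hyb.seq.encode(), np.uint8)
        r = np.frombuffer(rec_variant.seq.encode(), np.uint8)
        n = min(len(a), len(r))
        mask = np.ones(n, bool)  # exclude the variant's own islands and att
        for span in filter(None, rec_row.islands.split(";")):
            lo, hi = map(int, span.split("-"))
            mask[lo:min(hi, n)] = False
        if rec_row.att_len > 0:
            mask[rec_row.att_pos : rec_row.att_pos + rec_row.att_len] = False
        back = mask.copy()
        back[s : s + ln] = False
        seg = mask.copy()
        seg[:s] = False
        seg[s + ln :] = False
        backbone_ident = (a[:n][back] == r[:n][back]).mean()
        segment_ident = (a[:n][seg] == r[:n][seg]).mean()
        assert backbone_ident > 0.97  # recipient lineage backbone
        assert segment_ident < 0.5  # swapped-in donor material is unrelated


class TestFosmidContigs:
    def test_terminal_redundancy_when_insert_exceeds_genome(self, rng):
        genome = SequenceRecord("g", random_sequence(rng, 5_000, 0.5))
        vector = SequenceRecord("v", random_sequence(rng, 2_000, 0.5))
        contigs, _, truth = make_fosmid_contigs(
            genome, [], 5, (5_500, 6_500), vector, 0.0, (16, 67), rng
        )
        for c, row in zip(contigs, truth):
            assert row["complete_genome_present"]
            assert len(c.seq) == row["insert_len"]
            # the window wraps: its first insert_len-5000 bases recur at the end
            r = row["insert_len"] - 5_000
            assert c.seq[:r] == c.seq[-r:]

    def test_vector_flanks_recorded_and_applied(self, rng):
        genome = SequenceRecord("g", random_sequence(rng, 5_000, 0.5))
        vector = SequenceRecord("v", random_sequence(rng, 2_000, 0.5))
        contigs, _, truth = make_fosmid_contigs(
            genome, [], 10, (4_000, 4_500), vector, 1.0, (16, 67), rng
        )
        for c, row in zip(contigs, truth):
            assert 16 <= row["left_flank"] <= 67
            assert 16 <= row["right_flank"] <= 67
            assert len(c.seq) == row["insert_len"] + row["left_flank"] + row["right_flank"]

    def test_annotations_mapped_into_contig_bounds(self, small_community):
        for cid, anns in small_community.contig_annotations.items():
            contig = next(c for c in small_community.contigs if c.id == cid)
            for a in anns:
                assert a.contig_id == cid
                assert 0 <= a.interval.start < a.interval.end <= len(contig.seq)


class TestPlantAtt:
    def _genome_with_grid(self, rng, n_genes=6):
        seq = random_sequence(rng, 7_000, 0.45)
        anns = [
            GeneAnnotation("g", Interval(50 + i * 1_000, 950 + i * 1_000), "+",
                           "hypothetical protein", 1.0)
            for i in range(n_genes)
        ]
        return SequenceRecord("g", seq), anns

    def test_att_recovered_end_to_end(self, rng):
        genome, anns = self._genome_with_grid(rng)
        trna = SequenceRecord("host1_tRNA1", random_sequence(rng, 85, 0.55))
        from fosvir.hosts import HostTaxon

        taxon = HostTaxon("Prochlorococcus H1", "Cyanobacteria")
        g2, a2, truth = plant_att(genome, anns, trna, 43, rng)
        preds = assign_hosts([g2], {"g": a2}, [trna], {"host1_tRNA1": taxon})
        assert len(preds) == 1
        ev = preds[0].evidences[0]
        assert ev.kind == "INT"
        # neighbouring genome bases may extend the exact match by chance
        assert 43 <= ev.detail["match_len"] <= 45
        lo, hi = ev.detail["contig_interval"]
        assert lo <= truth["att_pos"] and hi >= truth["att_pos"] + 43

    def test_without_integrase_no_prediction(self, rng):
        genome, anns = self._genome_with_grid(rng)
        trna = SequenceRecord("t", random_sequence(rng, 85, 0.55))
        from fosvir.hosts import HostTaxon

        g2, a2, _ = plant_att(genome, anns, trna, 43, rng, with_integrase=False)
        preds = assign_hosts([g2], {"g": a2}, [trna],
                             {"t": HostTaxon("X", "Cyanobacteria")})
        assert preds == []

    def test_att_below_min_len_gives_no_evidence(self, rng):
        genome, anns = self._genome_with_grid(rng)
        trna = SequenceRecord("t", random_sequence(rng, 85, 0.55))
        from fosvir.hosts import HostTaxon

        g2, a2, _ = plant_att(genome, anns, trna, 25, rng)
        preds = assign_hosts([g2], {"g": a2}, [trna],
                             {"t": HostTaxon("X", "Cyanobacteria")})
        assert preds == []

    def test_att_longer_than_trna_rejected(self, rng):
        genome, anns = self._genome_with_grid(rng)
        trna = SequenceRecord("t", random_sequence(rng, 40, 0.55))
        with pytest.raises(ValueError):
            plant_att(genome, anns, trna, 60, rng)


class TestMetavirome:
    def test_read_counts_within_multinomial_3sigma(self, rng):
        genomes = [SequenceRecord(f"g{i}", random_sequence(rng, 5_000, 0.5))
                   for i in range(4)]
        abund = np.array([0.4, 0.3, 0.2, 0.1])
        n = 4_000
        reads, truth = simulate_metavirome(genomes, abund, n, 100, 0.0, rng)
        assert len(reads) == n
        w = abund * 5_000
        w = w / w.sum()
        counts = truth.groupby("genome_id").size()
        for i, g in enumerate(genomes):
            exp = n * w[i]
            sigma = np.sqrt(n * w[i] * (1 - w[i]))
            assert abs(counts[g.id] - exp) <= 3 * sigma

    def test_abundances_must_sum_to_one(self, rng):
        g = SequenceRecord("g", random_sequence(rng, 1_000, 0.5))
        with pytest.raises(ValueError):
            simulate_metavirome([g], np.array([0.5]), 10, 50, 0.0, rng)

    def test_reads_have_uniform_truth_rows(self, small_community):
        com = generate_community(
            CommunitySpec(**{**SMALL.__dict__, "n_reads": 200})
        )
        assert len(com.reads) == 200
        assert len(com.truth_reads) == 200
        assert set(com.truth_reads.read_id) == {r.id for r in com.reads}
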