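"""Dice similarity, distance matrices, neighbor joining, group cutting."""

import itertools

import numpy as np
import pytest

from fosvir.community import mutate, random_sequence
from fosvir.io import SequenceRecord
from fosvir.taxonomy import (DistanceMatrix, TreeNode, build_distance_matrix,
                             comparison_score, cut_groups, dice_similarity,
                             leaf_distances, nj_tree)


class TestDice:
    def test_self_case(self):
        assert dice_similarity(100, 100, 100) == 1.0

    def test_zero_overlap(self):
        assert dice_similarity(0, 100, 140) == 0.0

    def test_mixed(self):
        assert dice_similarity(60, 100, 140) == pytest.approx(0.5)

    def test_clamped_to_one(self):
        assert dice_similarity(500, 100, 100) == 1.0

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            dice_similarity(10, 0, 100)

    def test_comparison_score_sums_bitscores(self):
        from fosvir.align import AlignmentHit
        from fosvir.io import Interval

        def hit(bit):
            return AlignmentHit("a", "b", Interval(0, 90), Interval(0, 90),
                                50.0, 30, bit, 1e-9)

        assert comparison_score([hit(50.2), hit(30.1)]) == pytest.approx(80.3)
        assert comparison_score([]) == 0.0


class TestDistanceMatrix:
    def test_identical_genomes_distance_zero(self, rng):
        seq = random_sequence(rng, 3_000, 0.5)
        dm, scores = build_distance_matrix(
            [SequenceRecord("a", seq), SequenceRecord("b", seq)]
        )
        assert dm[("a", "b")] == pytest.approx(0.0, abs=1e-9)
        assert scores[0].dice == pytest.approx(1.0)

    def test_unrelated_genomes_distance_near_one(self, rng):
        dm, _ = build_distance_matrix(
            [SequenceRecord("a", random_sequence(rng, 6_000, 0.5)),
             SequenceRecord("b", random_sequence(rng, 6_000, 0.5))]
        )
        assert dm[("a", "b")] > 0.97

    def test_symmetry_and_zero_diagonal(self, rng):
        base = random_sequence(rng, 3_000, 0.5)
        genomes = [SequenceRecord(f"g{i}", mutate(rng, base, 0.05 * i))
                   for i in range(3)]
        dm, _ = build_distance_matrix(genomes)
        assert np.allclose(dm.matrix, dm.matrix.T)
        assert np.all(np.diag(dm.matrix) == 0)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 0.1], [0.2, 0.0]]))

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0.0, np.nan], [np.nan, 0.0]]))


def random_additive_matrix(rng, n):
    """Distances generated by random subtree joins: additive by
    construction.  Returns (ids, matrix, splits of the generating tree)."""
    active = [({f"t{i}"}, {f"t{i}": 0.0}) for i in range(n)]
    dist = {}
    splits = []
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        (sa, da), (sb, db) = active[i], active[j]
        bi, bj = rng.uniform(0.05, 1.0, 2)
        for la, va in da.items():
            for lb, vb in db.items():
                dist[frozenset((la, lb))] = va + bi + vb + bj
        merged_set = sa | sb
        merged = {k: v + bi for k, v in da.items()} | {k: v + bj for k, v in db.items()}
        if 1 < len(merged_set) < n - 1:
            splits.append(frozenset(merged_set))
        if 1 < len(sa) < n - 1:
            splits.append(frozenset(sa))
        if 1 < len(sb) < n - 1:
            splits.append(frozenset(sb))
        active = [x for k, x in enumerate(active) if k not in (i, j)] + [
            (merged_set, merged)
        ]
    ids = [f"t{i}" for i in range(n)]
    m = np.zeros((n, n))
    for x, y in itertools.combinations(range(n), 2):
        m[x, y] = m[y, x] = dist[frozenset((ids[x], ids[y]))]
    return ids, m, set(splits)


def tree_splits(tree: TreeNode):
    """Non-trivial bipartitions of the (unrooted) tree, each as the leaf
    set of one side."""
    all_leaves = frozenset(tree.leaves())
    out = set()

    def walk(node):
        for child, _ in node.children:
            clade = frozenset(child.leaves())
            if 1 < len(clade) < len(all_leaves) - 1:
                side = min(clade, other := all_leaves - clade,
                           key=lambda s: sorted(s))
                out.add(frozenset(side))
            walk(child)

    walk(tree)
    return out


def _normalise_splits(splits, all_leaves):
    return {
        frozenset(min(s, all_leaves - s, key=lambda x: sorted(x))) for s in splits
    }


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        m = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(DistanceMatrix(("a", "b", "c"), m))
        leaves, d = leaf_distances(tree)
        # three-point formulas: la = (dab+dac-dbc)/2 etc.
        bl = {node.name: l for node, l in tree.children}
        assert bl["a"] == pytest.approx(0.1)
        assert bl["b"] == pytest.approx(0.2)
        assert bl["c"] == pytest.approx(0.4)

    def test_four_taxon_additive_exact_vs_least_squares_oracle(self, rng):
        """NJ recovers the generating 4-taxon topology; a least-squares fit
        over all three topologies confirms it is the best (zero residual)."""
        for _ in range(20):
            ids, m, true_splits = random_additive_matrix(rng, 4)
            tree = nj_tree(DistanceMatrix(tuple(ids), m))
            # oracle: LS branch fit for each of the 3 unrooted topologies
            pairs = list(itertools.combinations(range(4), 2))
            y = np.array([m[i, j] for i, j in pairs])
            best_topo, best_resid = None, np.inf
            for split in [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]:
                (a, b), (c, d) = split
                # params: la, lb, lc, ld, internal
                design = []
                for i, j in pairs:
                    row = np.zeros(5)
                    row[i] = row[j] = 1.0
                    same_side = {i, j} in ({a, b}, {c, d})
                    if not same_side:
                        row[4] = 1.0
                    design.append(row)
                sol, *_ = np.linalg.lstsq(np.array(design), y, rcond=None)
                resid = np.linalg.norm(np.array(design) @ sol - y)
                if resid < best_resid:
                    best_resid, best_topo = resid, split
            oracle_split = frozenset(f"t{i}" for i in best_topo[0])
            assert best_resid < 1e-9
            all_leaves = frozenset(ids)
            assert tree_splits(tree) == _normalise_splits({oracle_split}, all_leaves)

    def test_random_additive_matrices_recovered_exactly(self, rng):
        """Topology and all path lengths match the generating tree."""
        for _ in range(30):
            n = int(rng.integers(4, 11))
            ids, m, true_splits = random_additive_matrix(rng, n)
            tree = nj_tree(DistanceMatrix(tuple(ids), m))
            leaves, d = leaf_distances(tree)
            order = [leaves.index(i) for i in ids]
            assert np.allclose(d[np.ix_(order, order)], m, atol=1e-9)
            all_leaves = frozenset(ids)
            assert tree_splits(tree) == _normalise_splits(true_splits, all_leaves)

    def test_ultrametric_matches_average_linkage_oracle(self, rng):
        """On an 8-taxon ultrametric matrix, NJ splits contain every
        cluster found by average-linkage hierarchical clustering."""
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        n = 8
        # build ultrametric distances from a random nested hierarchy
        ids = [f"t{i}" for i in range(n)]
        heights = {}
        active = [{i} for i in range(n)]
        level = 0.1
        while len(active) > 1:
            i, j = sorted(rng.choice(len(active), 2, replace=False))
            for a in active[i]:
                for b in active[j]:
                    heights[frozenset((a, b))] = level
            active = [x for k, x in enumerate(active) if k not in (i, j)] + [
                active[i] | active[j]
            ]
            level += float(rng.uniform(0.05, 0.3))
        m = np.zeros((n, n))
        for x, y in itertools.combinations(range(n), 2):
            m[x, y] = m[y, x] = 2 * heights[frozenset((x, y))]
        tree = nj_tree(DistanceMatrix(tuple(ids), m))
        got = tree_splits(tree)
        z = linkage(squareform(m, checks=False), method="average")
        members = {i: {i} for i in range(n)}
        all_leaves = frozenset(ids)
        for k, (a, b, _, _) in enumerate(z):
            clust = members[int(a)] | members[int(b)]
            members[n + k] = clust
            if 1 < len(clust) < n - 1:
                split = frozenset(f"t{i}" for i in clust)
                assert _normalise_splits({split}, all_leaves) <= got

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [1.0, 0.0]])))

    def test_no_negative_branch_lengths(self, rng):
        for _ in range(10):
            n = 6
            m = rng.uniform(0.2, 1.0, (n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0.0)
            tree = nj_tree(DistanceMatrix(tuple(f"t{i}" for i in range(n)), m))

            def check(node):
                for child, bl in node.children:
                    assert bl >= 0.0
                    check(child)

            check(tree)


class TestCutGroups:
    def _family_tree(self, rng):
        genomes = []
        for f in range(3):
            base = random_sequence(rng, 4_000, 0.45)
            for m in range(3):
                genomes.append(SequenceRecord(f"F{f}M{m}", mutate(rng, base, 0.04)))
        dm, _ = build_distance_matrix(genomes)
        return nj_tree(dm)

    def test_planted_families_recovered(self, rng):
        tree = self._family_tree(rng)
        groups = cut_groups(tree, 0.6)
        assert len(groups) == 3
        for members in groups.values():
            assert len({m[:2] for m in members}) == 1

    def test_threshold_above_diameter_single_group(self, rng):
        tree = self._family_tree(rng)
        groups = cut_groups(tree, 100.0)
        assert len(groups) == 1 and len(groups["G1"]) == 9

    def test_threshold_zero_singletons(self, rng):
        tree = self._family_tree(rng)
        groups = cut_groups(tree, 0.0)
        assert len(groups) == 9
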