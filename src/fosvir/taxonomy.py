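"""Whole-genome phage comparison and sequence-group extraction.

Genomes are compared by six-frame translated local alignment; the bit
scores of significant hits (>30% identity, >=30 aa, e <= 0.01) are summed
into a comparison score AB.  Self scores AA and BB normalise for genome
size through the Dice coefficient

    Dice = 2 AB / (AA + BB)            (similarity, 0..1)
    d    = 1 - Dice                    (distance)

A neighbor-joining tree is built from the complete distance matrix, and
sequence groups are cut from the tree as maximal subtrees whose leaves are
all within a path-distance threshold of each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .align import AlignmentHit, filter_hits, translated_compare
from .io import SequenceRecord

# significance thresholds for translated hits
SIG_MIN_IDENTITY = 30.0
SIG_MIN_LENGTH = 30
SIG_MAX_EVALUE = 0.01


@dataclass(frozen=True)
class GenomeComparisonScore:
    """Summed-bitscore comparison of one genome pair, with the Dice
    similarity derived from it."""

    id_a: str
    id_b: str
    ab: float  # symmetrised summed bitscore A<->B
    aa: float
    bb: float
    dice: float
    distance: float


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray  # square, symmetric, zero diagonal

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if np.any(np.isnan(m)):
            raise ValueError("distance matrix contains NaN")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        object.__setattr__(self, "matrix", m)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.ids.index(pair[0]), self.ids.index(pair[1])
        return float(self.matrix[i, j])


def comparison_score(hits: Iterable[AlignmentHit]) -> float:
    """Sum of bitscores of (already filtered) translated hits."""
    return float(sum(h.bitscore for h in hits))


def dice_similarity(ab: float, aa: float, bb: float) -> float:
    """Dice = 2 AB / (AA + BB), clamped into [0, 1]."""
    if aa <= 0 or bb <= 0:
        raise ValueError("self comparison scores must be positive (empty genome?)")
    if ab < 0:
        raise ValueError("comparison score must be non-negative")
    return min(1.0, 2.0 * ab / (aa + bb))


def _significant_score(a: SequenceRecord, b: SequenceRecord, **params) -> float:
    hits = translated_compare(a, b, **params)
    return comparison_score(
        filter_hits(hits, SIG_MIN_IDENTITY, SIG_MIN_LENGTH, SIG_MAX_EVALUE)
    )


def build_distance_matrix(
    genomes: Sequence[SequenceRecord],
    score_fn: Callable[[SequenceRecord, SequenceRecord], float] | None = None,
) -> tuple[DistanceMatrix, list[GenomeComparisonScore]]:
    """All-pairs Dice distances.

    AB asymmetry (the A->B and B->A hit sums differ slightly) is resolved
    by the arithmetic mean, guaranteeing a symmetric matrix.  ``score_fn``
    may replace the built-in translated comparison (e.g. to ingest
    external-aligner scores).
    """
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    score = score_fn or _significant_score
    ids = tuple(g.id for g in genomes)
    n = len(genomes)
    self_scores = [score(g, g) for g in genomes]
    mat = np.zeros((n, n))
    scores: list[GenomeComparisonScore] = []
    for i in range(n):
        for j in range(i + 1, n):
            ab = 0.5 * (score(genomes[i], genomes[j]) + score(genomes[j], genomes[i]))
            dice = dice_similarity(ab, self_scores[i], self_scores[j])
            dist = 1.0 - dice
            mat[i, j] = mat[j, i] = dist
            scores.append(
                GenomeComparisonScore(
                    ids[i], ids[j], ab, self_scores[i], self_scores[j], dice, dist
                )
            )
    return DistanceMatrix(ids, mat), scores


# ---------------------------------------------------------------------------
# neighbor joining


@dataclass
class TreeNode:
    """Rooted view of the (unrooted) NJ tree; the top node is the final
    trifurcation."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf:
            return self.name
        parts = [
            f"{child._newick_inner()}:{bl:.12g}" for child, bl in self.children
        ]
        return "(" + ",".join(parts) + ")"


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, moving the deficit to the sister."""
    if la < 0:
        lb = max(0.0, lb + la)
        la = 0.0
    elif lb < 0:
        la = max(0.0, la + lb)
        lb = 0.0
    return la, lb


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Classical neighbor joining (Q-criterion agglomeration).

    Ties on Q are broken to the lexicographically smallest label pair, so
    the result is deterministic.  Negative branch lengths are clamped to 0
    with the deficit transferred to the sister branch.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.matrix.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    # sort key per node for tie-breaking: smallest leaf label underneath
    keys: list[str] = list(dm.ids)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best: tuple[str, str] | None = None
        bi = bj = -1
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] <= qmin + 1e-12:
                    pair = tuple(sorted((keys[i], keys[j])))
                    if best is None or pair < best:
                        best, bi, bj = pair, i, j
        i, j = bi, bj
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_key = min(keys[i], keys[j])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d2 = np.zeros((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        nodes = [nodes[x] for x in keep] + [new]
        keys = [keys[x] for x in keep] + [new_key]

    # final trifurcation (three-point closed form)
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    order = sorted(range(3), key=lambda x: keys[x])
    lens = [max(0.0, x) for x in (la, lb, lc)]
    return TreeNode(
        children=[(nodes[x], lens[x]) for x in order]
    )


def leaf_distances(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    """Path distances between all leaf pairs of the tree."""
    leaves = sorted(tree.leaves())
    idx = {name: i for i, name in enumerate(leaves)}
    n = len(leaves)
    mat = np.zeros((n, n))

    def walk(node: TreeNode) -> dict[int, float]:
        if node.is_leaf:
            return {idx[node.name]: 0.0}
        below: dict[int, float] = {}
        child_maps = []
        for child, bl in node.children:
            cm = {k: v + bl for k, v in walk(child).items()}
            child_maps.append(cm)
        for a_map_i in range(len(child_maps)):
            for b_map_i in range(a_map_i + 1, len(child_maps)):
                for ia, da in child_maps[a_map_i].items():
                    for ib, db in child_maps[b_map_i].items():
                        mat[ia, ib] = mat[ib, ia] = da + db
        for cm in child_maps:
            below.update(cm)
        return below

    walk(tree)
    return leaves, mat


def cut_groups(tree: TreeNode, distance_threshold: float = 0.9) -> dict[str, list[str]]:
    """Partition leaves into sequence groups G1, G2, ...

    Groups are sets of leaves whose pairwise path distances along the tree
    are all <= the threshold, agglomerated by complete linkage on the path
    distance matrix (rooting-independent: the arbitrary trifurcation the
    NJ construction ends on cannot split a tight family).  Numbering is by
    decreasing size then by smallest leaf name.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    leaves, mat = leaf_distances(tree)
    if len(leaves) == 1:
        return {"G1": leaves}
    labels = fcluster(
        linkage(squareform(mat, checks=False), method="complete"),
        t=distance_threshold,
        criterion="distance",
    )
    by_label: dict[int, list[str]] = {}
    for name, lab in zip(leaves, labels):
        by_label.setdefault(int(lab), []).append(name)
    groups = sorted((sorted(g) for g in by_label.values()),
                    key=lambda g: (-len(g), g[0]))
    return {f"G{i + 1}": g for i, g in enumerate(groups)}
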