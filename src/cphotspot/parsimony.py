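"""Small-scale phylogenetic evaluation of candidate loci.

Fitch maximum parsimony over exhaustively enumerated unrooted binary
topologies (exact for up to 9 taxa, covering the 7-taxon case-study
design), neighbor joining on uncorrected p-distances, bootstrap
majority-rule consensus with NJ or MP per-replicate trees, and a
species-resolution metric: a consensus over n taxa is fully resolved when
all n - 3 possible internal edges are present.

Gaps and ambiguity codes are treated as missing data (wildcard state) in
both parsimony and distances.  Tree shapes are represented as nested pairs
over taxon indices 1..n-1, rooted at the edge leading to taxon 0; every
unrooted binary topology corresponds to exactly one such shape, and Fitch
counts are invariant to the rooting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np

from .io_formats import GenusAlignment

log = logging.getLogger(__name__)

Shape = Union[int, tuple]  # nested pairs of taxon indices 1..n-1

MAX_EXHAUSTIVE_TAXA = 9

# state masks: A=1 C=2 G=4 T=8; gap / ambiguity -> all four (missing)
_MASK = np.full(256, 15, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _MASK[ord(_b)] = 1 << _i


@dataclass(frozen=True)
class CharacterMatrix:
    """Aligned locus sequences for tree building."""

    taxa: tuple[str, ...]
    rows: tuple[str, ...]
    outgroup: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows must have equal length")
        if len(self.taxa) != len(set(self.taxa)):
            raise ValueError("duplicate taxon labels")
        L = len(self.rows[0])
        for t, r in zip(self.taxa, self.rows):
            if len(r) != L:
                raise ValueError(f"row for {t!r} has length {len(r)} != {L}")
        if self.outgroup is not None and self.outgroup not in self.taxa:
            raise ValueError(f"outgroup {self.outgroup!r} not among taxa")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def masks(self) -> np.ndarray:
        """(n_taxa, n_columns) uint8 state-mask matrix."""
        raw = np.vstack(
            [
                np.frombuffer(r.upper().encode("ascii"), dtype=np.uint8)
                for r in self.rows
            ]
        )
        return _MASK[raw]

    @classmethod
    def from_alignment(
        cls, aln: GenusAlignment, outgroup: Optional[str] = None
    ) -> "CharacterMatrix":
        return cls(taxa=aln.ids, rows=aln.seqs, outgroup=outgroup)

    @classmethod
    def concatenate(cls, matrices: Sequence["CharacterMatrix"]) -> "CharacterMatrix":
        """Concatenate loci sharing the same taxon set (order of the first)."""
        taxa = matrices[0].taxa
        rows = []
        for t in taxa:
            parts = []
            for m in matrices:
                if set(m.taxa) != set(taxa):
                    raise ValueError("matrices must share one taxon set")
                parts.append(m.rows[m.taxa.index(t)])
            rows.append("".join(parts))
        return cls(taxa=taxa, rows=tuple(rows), outgroup=matrices[0].outgroup)


Split = frozenset  # of taxon labels; stored as the side NOT containing taxa[0]


@dataclass(frozen=True)
class Topology:
    """An unrooted tree over a fixed taxon set, represented by its
    non-trivial bipartitions (each stored as the side not containing the
    first taxon), optionally with bootstrap support percentages."""

    taxa: tuple[str, ...]
    splits: frozenset
    supports: Optional[dict] = None
    shape: Optional[Shape] = None

    @property
    def n_internal_edges(self) -> int:
        return len(self.splits)

    def normalized_split(self, members: Iterable[str]) -> Split:
        s = frozenset(members)
        if self.taxa[0] in s:
            s = frozenset(self.taxa) - s
        return s

    def newick(self) -> str:
        """Deterministic Newick string; internal node labels carry bootstrap
        supports when present.  Branch lengths are not tracked (zero-length
        edges of degenerate inputs are simply collapsed or arbitrary)."""
        anchor = self.taxa[0]
        clusters = sorted(self.splits, key=lambda s: (len(s), sorted(s)))
        parent: dict[Split, Optional[Split]] = {}
        for cl in clusters:
            best = None
            for other in clusters:
                if other is not cl and cl < other:
                    if best is None or len(other) < len(best):
                        best = other
            parent[cl] = best
        children: dict[Optional[Split], list[Split]] = {}
        for cl, p in parent.items():
            children.setdefault(p, []).append(cl)

        def render(members: frozenset, child_clusters: list[Split]) -> str:
            covered = set().union(*child_clusters) if child_clusters else set()
            items = []
            for cl in sorted(child_clusters, key=min):
                label = ""
                if self.supports and cl in self.supports:
                    label = f"{self.supports[cl]:g}"
                items.append(f"{render(cl, children.get(cl, []))}{label}")
            for leaf in sorted(members - covered):
                items.append(leaf)
            items.sort()
            return "(" + ",".join(items) + ")"

        top = children.get(None, [])
        rest = frozenset(self.taxa) - {anchor}
        body = render(rest, top)
        return f"({anchor},{body[1:-1]});" if len(body) > 2 else f"({anchor});"


# ---------------------------------------------------------------------------
# Shapes: enumeration and splits


def enumerate_shapes(n_taxa: int) -> Iterator[Shape]:
    """Yield every unrooted binary topology over n taxa exactly once, in a
    deterministic order, as shapes over taxa 1..n-1 rooted at taxon 0's edge.

    Counts follow (2n-5)!!: 3 shapes for 4 taxa, 945 for 7.
    """
    if n_taxa < 4:
        raise ValueError("tree enumeration needs >=4 taxa")
    if n_taxa > MAX_EXHAUSTIVE_TAXA:
        raise ValueError(
            f"exhaustive enumeration supports at most {MAX_EXHAUSTIVE_TAXA} "
            f"taxa ((2n-5)!! growth); {n_taxa} requested — reduce the taxon "
            "set or analyze loci separately"
        )

    def grow(shape: Shape, leaf: int) -> Iterator[Shape]:
        yield (shape, leaf)
        if isinstance(shape, tuple):
            left, right = shape
            for s in grow(left, leaf):
                yield (s, right)
            for s in grow(right, leaf):
                yield (left, s)

    shapes: list[Shape] = [1]
    for leaf in range(2, n_taxa):
        shapes = [g for s in shapes for g in grow(s, leaf)]
    yield from shapes


def shape_splits(shape: Shape, taxa: Sequence[str]) -> frozenset:
    """Non-trivial bipartitions of the unrooted tree the shape encodes,
    each as the frozenset of labels on the side away from taxa[0]."""
    n = len(taxa)
    splits = []

    def rec(node: Shape) -> set:
        if isinstance(node, int):
            return {node}
        leaves = rec(node[0]) | rec(node[1])
        if 2 <= len(leaves) <= n - 2:
            splits.append(frozenset(taxa[i] for i in leaves))
        return leaves

    rec(shape)
    return frozenset(splits)


def topology_from_shape(shape: Shape, taxa: Sequence[str]) -> Topology:
    return Topology(
        taxa=tuple(taxa), splits=shape_splits(shape, taxa), shape=shape
    )


# ---------------------------------------------------------------------------
# Fitch parsimony


def _fitch_changes(shape: Shape, leaf_masks: np.ndarray) -> np.ndarray:
    """Per-column Fitch change counts for one shape; leaf_masks is
    (n_taxa, n_patterns) uint8."""
    changes = np.zeros(leaf_masks.shape[1], dtype=np.int64)

    def rec(node: Shape) -> np.ndarray:
        if isinstance(node, int):
            return leaf_masks[node]
        a = rec(node[0])
        b = rec(node[1])
        inter = a & b
        empty = inter == 0
        changes[empty] += 1
        return np.where(empty, a | b, inter)

    top = rec(shape)
    changes[(top & leaf_masks[0]) == 0] += 1
    return changes


def _resolve_tree(matrix: CharacterMatrix, tree) -> Shape:
    if isinstance(tree, Topology):
        if tree.shape is None:
            raise ValueError("Topology carries no explicit shape")
        if tuple(tree.taxa) != tuple(matrix.taxa):
            raise ValueError("tree taxa do not match the matrix taxa")
        return tree.shape
    return tree


def fitch_score(matrix: CharacterMatrix, tree) -> int:
    """Minimum number of state changes the tree requires for the matrix
    (sum of per-column Fitch counts; gaps/ambiguity are wildcards)."""
    shape = _resolve_tree(matrix, tree)
    masks = matrix.masks()
    _check_shape_taxa(shape, matrix.n_taxa)
    return int(_fitch_changes(shape, masks).sum())


def _check_shape_taxa(shape: Shape, n_taxa: int) -> None:
    leaves: set[int] = set()

    def rec(node: Shape) -> None:
        if isinstance(node, int):
            leaves.add(node)
        else:
            rec(node[0])
            rec(node[1])

    rec(shape)
    if leaves != set(range(1, n_taxa)):
        raise ValueError(
            f"tree leaves {sorted(leaves)} do not match taxa 1..{n_taxa - 1}"
        )


def _site_patterns(
    matrix: CharacterMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse alignment columns into unique site patterns.

    Returns (pattern_masks (n_taxa, P), counts (P,), pattern_id (L,))."""
    masks = matrix.masks()
    patterns, pattern_id, counts = np.unique(
        masks.T, axis=0, return_inverse=True, return_counts=True
    )
    return patterns.T.copy(), counts.astype(np.int64), pattern_id.ravel()


def exhaustive_mp(
    matrix: CharacterMatrix,
) -> tuple[int, list[Topology]]:
    """Best Fitch score over every unrooted binary topology, with all ties.

    Deterministic enumeration; refuses more than 9 taxa (the case-study
    scale is 7; heuristic search is out of scope).
    """
    n = matrix.n_taxa
    pattern_masks, counts, _ = _site_patterns(matrix)
    best_score: Optional[int] = None
    best_shapes: list[Shape] = []
    for shape in enumerate_shapes(n):
        score = int(_fitch_changes(shape, pattern_masks) @ counts)
        if best_score is None or score < best_score:
            best_score = score
            best_shapes = [shape]
        elif score == best_score:
            best_shapes.append(shape)
    assert best_score is not None
    return best_score, [topology_from_shape(s, matrix.taxa) for s in best_shapes]


# ---------------------------------------------------------------------------
# Distances and neighbor joining


def p_distance_matrix(matrix: CharacterMatrix) -> np.ndarray:
    """Uncorrected pairwise p-distances with pairwise deletion of
    gaps/missing; errors if a pair shares no comparable site."""
    masks = matrix.masks()
    valid = masks != 15
    n = matrix.n_taxa
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        both = valid[i] & valid[j]
        L = int(both.sum())
        if L == 0:
            raise ValueError(
                f"taxa {matrix.taxa[i]!r} and {matrix.taxa[j]!r} share no "
                "comparable sites"
            )
        diff = int(((masks[i] != masks[j]) & both).sum())
        d[i, j] = d[j, i] = diff / L
    return d


def _nj_merge_order(
    dist: np.ndarray, taxa: Sequence[str]
) -> list[tuple[frozenset, frozenset]]:
    """Run neighbor joining, returning the merged cluster pairs in order.

    Tie-breaking is deterministic: candidate pairs are scanned in
    lexicographic order of their clusters' smallest taxon labels, and a new
    minimum must be strictly smaller (beyond a 1e-12 tolerance) to displace
    the incumbent.
    """
    clusters: list[frozenset] = [frozenset([t]) for t in taxa]
    d = dist.astype(float).copy()
    merges: list[tuple[frozenset, frozenset]] = []
    while len(clusters) > 3:
        m = len(clusters)
        r = d.sum(axis=1)
        order = sorted(
            combinations(range(m), 2),
            key=lambda ij: (min(clusters[ij[0]]), min(clusters[ij[1]])),
        )
        best = None
        best_q = np.inf
        for i, j in order:
            q = (m - 2) * d[i, j] - r[i] - r[j]
            if q < best_q - 1e-12:
                best_q = q
                best = (i, j)
        assert best is not None
        i, j = best
        merges.append((clusters[i], clusters[j]))
        new_cluster = clusters[i] | clusters[j]
        nd = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d_new = np.zeros((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = nd[keep]
        clusters = [clusters[x] for x in keep] + [new_cluster]
        d = d_new
    return merges


def nj_from_distance(dist: np.ndarray, taxa: Sequence[str]) -> Topology:
    merges = _nj_merge_order(dist, taxa)
    taxa = tuple(taxa)
    all_taxa = frozenset(taxa)
    splits = set()
    for a, b in merges:
        cl = a | b
        if 2 <= len(cl) <= len(taxa) - 2:
            s = cl if taxa[0] not in cl else all_taxa - cl
            splits.add(frozenset(s))
    return Topology(taxa=taxa, splits=frozenset(splits))


def nj_tree(matrix: CharacterMatrix) -> Topology:
    """Neighbor-joining tree on uncorrected p-distances."""
    if matrix.n_taxa < 4:
        raise ValueError("tree building needs >=4 taxa")
    return nj_from_distance(p_distance_matrix(matrix), matrix.taxa)


# ---------------------------------------------------------------------------
# Bootstrap and consensus


def bootstrap_consensus(
    matrix: CharacterMatrix,
    method: str = "mp",
    replicates: int = 1000,
    seed: int = 0,
) -> Topology:
    """Majority-rule (>50%) consensus of per-replicate trees built from
    column-resampled matrices, with support percentages on retained splits.

    MP replicates enumerate all topologies; co-optimal trees contribute
    fractionally (1/#ties) to each of their splits, keeping the procedure
    deterministic and unbiased.  Fixed seed gives identical output.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if method not in ("mp", "nj"):
        raise ValueError(f"method must be mp|nj, got {method!r}")
    rng = np.random.default_rng(seed)
    pattern_masks, _counts, pattern_id = _site_patterns(matrix)
    P = pattern_masks.shape[1]
    L = matrix.n_columns
    n = matrix.n_taxa
    taxa = matrix.taxa

    if method == "mp":
        shapes = list(enumerate_shapes(n))
        score_matrix = np.vstack(
            [_fitch_changes(s, pattern_masks) for s in shapes]
        )
        split_sets = [shape_splits(s, taxa) for s in shapes]
    else:
        valid = pattern_masks != 15
        pair_idx = list(combinations(range(n), 2))
        diff_pat = np.vstack(
            [
                ((pattern_masks[i] != pattern_masks[j]) & valid[i] & valid[j])
                for i, j in pair_idx
            ]
        ).astype(np.int64)
        comp_pat = np.vstack(
            [(valid[i] & valid[j]) for i, j in pair_idx]
        ).astype(np.int64)

    credit: dict[frozenset, float] = {}
    for _rep in range(replicates):
        cols = rng.integers(0, L, size=L)
        weights = np.bincount(pattern_id[cols], minlength=P).astype(np.int64)
        if method == "mp":
            scores = score_matrix @ weights
            best = scores.min()
            tied = np.nonzero(scores == best)[0]
            w = 1.0 / len(tied)
            for t in tied:
                for sp in split_sets[t]:
                    credit[sp] = credit.get(sp, 0.0) + w
        else:
            diffs = diff_pat @ weights
            comps = comp_pat @ weights
            if (comps == 0).any():
                raise ValueError(
                    "a bootstrap replicate left a taxon pair with no "
                    "comparable sites"
                )
            d = np.zeros((n, n))
            for (i, j), df, cp in zip(pair_idx, diffs, comps):
                d[i, j] = d[j, i] = df / cp
            for sp in nj_from_distance(d, taxa).splits:
                credit[sp] = credit.get(sp, 0.0) + 1.0

    majority = {
        sp: 100.0 * c / replicates
        for sp, c in credit.items()
        if c > replicates / 2
    }
    return Topology(
        taxa=taxa,
        splits=frozenset(majority),
        supports={sp: round(pct, 1) for sp, pct in majority.items()},
    )


def resolution(
    consensus: Topology, outgroup: Optional[str] = None
) -> tuple[int, int, bool]:
    """(resolved internal edges, maximum possible n-3, fully_resolved).

    "Solving all species" in a 7-taxon design (6 ingroup species plus the
    outgroup) means 4 of 4 internal edges present."""
    n = len(consensus.taxa)
    max_edges = n - 3
    resolved = consensus.n_internal_edges
    return resolved, max_edges, resolved == max_edges
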