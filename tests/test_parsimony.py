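import numpy as np
import pytest

from cphotspot.parsimony import (
    CharacterMatrix,
    Topology,
    bootstrap_consensus,
    enumerate_shapes,
    exhaustive_mp,
    fitch_score,
    nj_from_distance,
    nj_tree,
    p_distance_matrix,
    resolution,
    shape_splits,
    topology_from_shape,
    _nj_merge_order,
)
import oracles


def random_matrix(rng, n_taxa, n_cols, gap_frac=0.05):
    alphabet = np.array(list("ACGT"))
    rows = []
    for _ in range(n_taxa):
        chars = alphabet[rng.integers(0, 4, size=n_cols)]
        gaps = rng.random(n_cols) < gap_frac
        chars = np.where(gaps, "-", chars)
        rows.append("".join(chars))
    return CharacterMatrix(
        taxa=tuple(f"t{i}" for i in range(n_taxa)), rows=tuple(rows))


def signal_matrix(taxa, splits, per_split=25, constant=100):
    """Columns supporting each split, plus constant columns: ample clean
    signal for the tree whose non-trivial bipartitions are ``splits``."""
    cols = []
    for sp in splits:
        cols.extend(
            ["".join("T" if t in sp else "A" for t in taxa)] * per_split)
    cols.extend(["C" * len(taxa)] * constant)
    rows = tuple("".join(c[i] for c in cols) for i in range(len(taxa)))
    return CharacterMatrix(taxa=tuple(taxa), rows=rows)


TRUE_SPLITS_7 = [
    frozenset({"A", "B"}),
    frozenset({"A", "B", "C"}),
    frozenset({"E", "F"}),
    frozenset({"E", "F", "G"}),
]


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(4, 3), (5, 15), (7, 945)])
    def test_double_factorial_counts(self, n, count):
        shapes = list(enumerate_shapes(n))
        assert len(shapes) == count
        # all distinct as unrooted trees
        taxa = tuple(f"t{i}" for i in range(n))
        assert len({shape_splits(s, taxa) for s in shapes}) == count

    def test_too_many_taxa_refused(self):
        with pytest.raises(ValueError, match="at most"):
            list(enumerate_shapes(10))


class TestFitch:
    def test_invariant_matrix_scores_zero(self):
        m = CharacterMatrix(taxa=("a", "b", "c", "d"),
                            rows=("ACGT", "ACGT", "ACGT", "ACGT"))
        for shape in enumerate_shapes(4):
            assert fitch_score(m, shape) == 0

    def test_four_taxon_single_column(self):
        """Column A,A,T,T scores 1 on the matching split and 2 otherwise."""
        m = CharacterMatrix(taxa=("t1", "t2", "t3", "t4"),
                            rows=("A", "A", "T", "T"))
        assert fitch_score(m, (1, (2, 3))) == 1   # ((t1,t2),(t3,t4))
        assert fitch_score(m, (2, (1, 3))) == 2   # ((t1,t3),(t2,t4))
        assert fitch_score(m, (3, (1, 2))) == 2   # ((t1,t4),(t2,t3))

    def test_matches_exhaustive_labeling_oracle(self, rng):
        for n in (4, 5, 6):
            m = random_matrix(rng, n, 30)
            for shape in list(enumerate_shapes(n))[:12]:
                assert fitch_score(m, shape) == oracles.fitch_bruteforce(
                    shape, m.rows)

    def test_invariant_under_leaf_permutation(self, rng):
        """The score of a fixed unrooted tree does not depend on which leaf
        anchors the internal rooted representation."""
        m = random_matrix(rng, 6, 40)
        shape = next(enumerate_shapes(6))
        base = fitch_score(m, shape)
        want_splits = {
            s for s in shape_splits(shape, m.taxa)
        }
        perm = rng.permutation(6)
        m2 = CharacterMatrix(
            taxa=tuple(m.taxa[i] for i in perm),
            rows=tuple(m.rows[i] for i in perm))

        def normalize(splits, taxa):
            full = frozenset(taxa)
            return {s if taxa[0] not in s else full - s for s in splits}

        target = normalize(want_splits, m2.taxa)
        for shape2 in enumerate_shapes(6):
            if normalize(shape_splits(shape2, m2.taxa), m2.taxa) == target:
                assert fitch_score(m2, shape2) == base
                break
        else:  # pragma: no cover
            pytest.fail("permuted tree not found in enumeration")

    def test_taxon_mismatch_rejected(self):
        m = CharacterMatrix(taxa=("a", "b", "c", "d"), rows=("A",) * 4)
        with pytest.raises(ValueError):
            fitch_score(m, (1, (2, 4)))


class TestExhaustiveMP:
    def test_best_score_bounds_every_tree(self, rng):
        m = random_matrix(rng, 6, 25)
        best, _trees = exhaustive_mp(m)
        for shape in enumerate_shapes(6):
            assert best <= fitch_score(m, shape)

    def test_strong_signal_recovers_unique_true_tree(self):
        m = signal_matrix("ABCDEFG", TRUE_SPLITS_7)
        best, trees = exhaustive_mp(m)
        assert len(trees) == 1
        assert set(trees[0].splits) == {
            frozenset(m.taxa) - s if m.taxa[0] in s else s
            for s in TRUE_SPLITS_7}


class TestNeighborJoining:
    def test_additive_distances_recover_topology(self):
        # quartet ((a,b),(c,d)) with internal edge 3 and leaf edges 1,2,4,5
        taxa = ("a", "b", "c", "d")
        d = np.array([
            [0, 3, 8, 9],
            [3, 0, 9, 10],
            [8, 9, 0, 9],
            [9, 10, 9, 0],
        ], dtype=float)
        topo = nj_from_distance(d, taxa)
        assert topo.splits == frozenset({frozenset({"c", "d"})})

    def test_identical_sequences_degenerate_but_deterministic(self):
        m = CharacterMatrix(taxa=("a", "b", "c", "d"),
                            rows=("ACGT",) * 4)
        t1 = nj_tree(m)
        t2 = nj_tree(m)
        assert t1.splits == t2.splits  # arbitrary but reproducible

    def test_q_criterion_argmin_matches_bruteforce_scan(self, rng):
        from itertools import combinations

        for _ in range(5):
            n = 6
            d = rng.random((n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            taxa = tuple(f"t{i}" for i in range(n))
            merges = _nj_merge_order(d, taxa)
            # replay: at the first step the chosen pair must minimize Q
            m0 = n
            r = d.sum(axis=1)
            q = {(i, j): (m0 - 2) * d[i, j] - r[i] - r[j]
                 for i, j in combinations(range(n), 2)}
            qmin = min(q.values())
            first = merges[0]
            i = taxa.index(min(first[0]))
            j = taxa.index(min(first[1]))
            assert q[tuple(sorted((i, j)))] == pytest.approx(qmin)

    def test_agrees_with_dendropy_on_clean_signal(self):
        dendropy = pytest.importorskip("dendropy")
        m = signal_matrix("ABCDEFG", TRUE_SPLITS_7)
        mine = nj_tree(m)
        # dendropy NJ from the same p-distance matrix
        dist = p_distance_matrix(m)
        csv_rows = [",".join([""] + list(m.taxa))]
        for i, t in enumerate(m.taxa):
            csv_rows.append(",".join([t] + [f"{x:.10f}" for x in dist[i]]))
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO("\n".join(csv_rows)),
            delimiter=",")
        dtree = pdm.nj_tree()
        full = frozenset(m.taxa)
        theirs = set()
        for node in dtree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if m.taxa[0] in side:
                side = full - side
            if 2 <= len(side) <= len(full) - 2:
                theirs.add(side)
        assert set(mine.splits) == theirs


class TestBootstrap:
    def test_unanimous_split_gets_full_support(self):
        taxa = ("a", "b", "c", "d")
        m = CharacterMatrix(
            taxa=taxa, rows=("A" * 30, "A" * 30, "T" * 30, "T" * 30))
        cons = bootstrap_consensus(m, method="mp", replicates=100, seed=1)
        assert cons.splits == frozenset({frozenset({"c", "d"})})
        (support,) = cons.supports.values()
        assert support == 100.0

    def test_zero_variation_gives_star(self):
        m = CharacterMatrix(taxa=("a", "b", "c", "d"), rows=("ACGT",) * 4)
        cons = bootstrap_consensus(m, method="mp", replicates=50, seed=2)
        assert cons.splits == frozenset()
        assert resolution(cons) == (0, 1, False)

    @pytest.mark.parametrize("method", ["mp", "nj"])
    def test_fixed_seed_reproducible_newick(self, method):
        m = signal_matrix("ABCDEFG", TRUE_SPLITS_7, per_split=5, constant=20)
        n1 = bootstrap_consensus(m, method=method, replicates=50, seed=9).newick()
        n2 = bootstrap_consensus(m, method=method, replicates=50, seed=9).newick()
        assert n1 == n2

    def test_invalid_replicates(self):
        m = CharacterMatrix(taxa=("a", "b", "c", "d"), rows=("ACGT",) * 4)
        with pytest.raises(ValueError):
            bootstrap_consensus(m, replicates=0)


class TestResolution:
    def test_fully_bifurcating_seven_taxa(self):
        shape = next(enumerate_shapes(7))
        topo = topology_from_shape(shape, tuple("ABCDEFG"))
        assert resolution(topo) == (4, 4, True)

    def test_star_consensus(self):
        topo = Topology(taxa=tuple("ABCDEFG"), splits=frozenset())
        assert resolution(topo) == (0, 4, False)

    def test_combining_loci_resolves_what_neither_does_alone(self):
        """Each locus carries signal for only half the internal edges; the
        concatenation resolves the full tree (the combination effect)."""
        taxa = tuple("ABCDEFG")
        locus1 = signal_matrix(taxa, TRUE_SPLITS_7[:2], per_split=20)
        locus2 = signal_matrix(taxa, TRUE_SPLITS_7[2:], per_split=20)
        both = CharacterMatrix.concatenate([locus1, locus2])
        r1 = resolution(bootstrap_consensus(locus1, "mp", 100, seed=3))
        r2 = resolution(bootstrap_consensus(locus2, "mp", 100, seed=3))
        rb = resolution(bootstrap_consensus(both, "mp", 100, seed=3))
        assert not r1[2] and not r2[2]
        assert rb == (4, 4, True)
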