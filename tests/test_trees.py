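"""Newick I/O, pruning, rooting enumeration, distances, NJ and bootstrap."""

import io

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from phylorigins.alignment import Alignment
from phylorigins.errors import NewickError, ValidationError
from phylorigins.synthetic import simulate_yule_tree
from phylorigins.trees import (
    DistanceMatrix,
    bootstrap_columns,
    enumerate_rootings,
    evolutionary_distance,
    leaf_labels,
    nj_tree,
    prune_to_taxa,
    read_newick,
    write_newick,
)


def path_lengths(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return {
        frozenset((a, b)): pdm.patristic_distance(taxa[a], taxa[b])
        for a in taxa
        for b in taxa
        if a < b
    }


class TestNewickIO:
    def test_basal_bifurcation_collapsed_on_unrooted_input(self):
        tree = read_newick("((A,B),(C,D));")
        assert len(tree.seed_node.child_nodes()) == 3

    def test_lengths_survive_round_trip(self):
        text = "((A:1,B:2):0.5,C:3);"
        tree = read_newick(text)
        again = read_newick(write_newick(tree))
        assert path_lengths(tree) == path_lengths(again)

    def test_round_trip_idempotent(self):
        text = write_newick(read_newick("((A:1,B:2):0.5,C:3,(D:1,E:1):2);"))
        assert write_newick(read_newick(text)) == text

    def test_duplicate_leaf_rejected(self):
        with pytest.raises(NewickError, match="duplicate"):
            read_newick("((A,B),(A,C));")

    def test_malformed_text_rejected(self):
        with pytest.raises(NewickError):
            read_newick("((A,B),(C,D);")

    def test_underscores_preserved(self):
        tree = read_newick("(taxon_a,taxon_b,taxon_c);")
        assert "taxon_a" in leaf_labels(tree)


class TestPrune:
    def test_induced_topology(self):
        tree = read_newick("((A,B),(C,D));")
        pruned = prune_to_taxa(tree, ["A", "B", "C"])
        assert leaf_labels(pruned) == {"A", "B", "C"}
        assert len(pruned.seed_node.child_nodes()) == 3  # single internal node

    def test_prune_to_all_leaves_is_identity(self):
        tree = read_newick("((A:1,B:2):0.5,C:3,D:4);")
        pruned = prune_to_taxa(tree, ["A", "B", "C", "D"])
        assert path_lengths(pruned) == path_lengths(tree)

    def test_suppressed_node_lengths_summed(self):
        tree = read_newick("(A:1,(B:1,C:2):3);")
        pruned = prune_to_taxa(tree, ["A", "C"])
        (pair_length,) = path_lengths(pruned).values()
        assert pair_length == pytest.approx(1 + 3 + 2)

    def test_unknown_taxon_listed(self):
        tree = read_newick("((A,B),(C,D));")
        with pytest.raises(ValidationError, match="X"):
            prune_to_taxa(tree, ["A", "X"])

    def test_path_lengths_preserved_on_random_trees(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            tree = simulate_yule_tree(12, 1.0, int(rng.integers(1 << 30)))
            keep = sorted(leaf_labels(tree))[:6]
            full = path_lengths(tree)
            pruned = path_lengths(prune_to_taxa(tree, keep))
            for pair, value in pruned.items():
                assert value == pytest.approx(full[pair], rel=1e-9)


class TestEnumerateRootings:
    def test_binary_quartet_yields_five(self):
        views = list(enumerate_rootings(read_newick("((A,B),(C,D));")))
        assert len(views) == 5

    def test_three_leaf_star_yields_three(self):
        assert len(list(enumerate_rootings(read_newick("(A,B,C);")))) == 3

    def test_views_are_rooted_and_conserve_leaves(self):
        tree = read_newick("((A,B),(C,D),E);")
        for index, view in enumerate_rootings(tree):
            assert view.is_rooted is True
            assert leaf_labels(view) == {"A", "B", "C", "D", "E"}
            assert len(view.seed_node.child_nodes()) == 2

    def test_rooted_input_rejected(self):
        tree = read_newick("((A,B),(C,D));")
        tree.is_rooted = True
        with pytest.raises(ValidationError):
            list(enumerate_rootings(tree))


class TestDistances:
    def test_identical_sequences_zero(self):
        aln = Alignment.from_records([("a", "ACGT"), ("b", "ACGT")])
        for model in ("p", "jc69"):
            assert evolutionary_distance(aln, model).values[0, 1] == 0.0

    def test_p_distance_direct_count(self):
        aln = Alignment.from_records([("a", "AAAA"), ("b", "AAAT")])
        assert evolutionary_distance(aln, "p").values[0, 1] == pytest.approx(0.25)

    def test_jc_closed_form(self):
        aln = Alignment.from_records([("a", "AAAA"), ("b", "AAAT")])
        d = evolutionary_distance(aln, "jc69").values[0, 1]
        assert d == pytest.approx(-0.75 * np.log(1 - 1 / 3), abs=1e-6)
        assert d == pytest.approx(0.304099, abs=1e-6)

    def test_saturated_pair_hits_ceiling(self):
        aln = Alignment.from_records([("a", "AAAA"), ("b", "TTTT")])
        assert evolutionary_distance(aln, "jc69").values[0, 1] == 5.0

    def test_no_comparable_columns_warns_and_uses_ceiling(self):
        aln = Alignment.from_records([("a", "AC--"), ("b", "--GT")])
        with pytest.warns(RuntimeWarning, match="no comparable columns"):
            d = evolutionary_distance(aln, "jc69")
        assert d.values[0, 1] == 5.0


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = np.array([[0.0, 2, 3], [2, 0, 3], [3, 3, 0]])
        tree = nj_tree(DistanceMatrix(("A", "B", "C"), D))
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 2.0})

    def test_forced_join_of_identical_pairs(self):
        D = np.array(
            [
                [0.0, 0.0, 1, 1],
                [0.0, 0, 1, 1],
                [1, 1, 0, 0.0],
                [1, 1, 0.0, 0],
            ]
        )
        tree = nj_tree(DistanceMatrix(("a1", "a2", "b1", "b2"), D))
        for leaf in tree.leaf_node_iter():
            if leaf.taxon.label == "a1":
                siblings = {
                    n.taxon.label
                    for n in leaf.parent_node.leaf_iter()
                }
                assert siblings == {"a1", "a2"}

    def test_fewer_than_three_taxa_rejected(self):
        D = np.zeros((2, 2))
        with pytest.raises(ValidationError):
            nj_tree(DistanceMatrix(("a", "b"), D))

    @pytest.mark.parametrize("n,seed", [(8, 3), (30, 4)])
    def test_exact_recovery_from_additive_distances(self, n, seed):
        true = simulate_yule_tree(n, 1.0, seed)
        lengths = path_lengths(true)
        ids = tuple(sorted(leaf_labels(true)))
        D = np.zeros((n, n))
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j:
                    D[i, j] = D[j, i] = lengths[frozenset((a, b))]
        mine = nj_tree(DistanceMatrix(ids, D))
        joined = dendropy.Tree.get(
            data=write_newick(mine) + "\n",
            schema="newick",
            taxon_namespace=true.taxon_namespace,
            preserve_underscores=True,
        )
        joined.encode_bipartitions()
        true.encode_bipartitions()
        assert treecompare.symmetric_difference(true, joined) == 0

    def test_agrees_with_dendropy_reference_on_noisy_matrix(self):
        rng = np.random.default_rng(9)
        n = 10
        true = simulate_yule_tree(n, 1.0, 123)
        lengths = path_lengths(true)
        ids = tuple(sorted(leaf_labels(true)))
        D = np.zeros((n, n))
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j:
                    noise = 1.0 + rng.normal(scale=0.02)
                    D[i, j] = D[j, i] = lengths[frozenset((a, b))] * noise
        mine = nj_tree(DistanceMatrix(ids, D))
        csv = "," + ",".join(ids) + "\n"
        for i, a in enumerate(ids):
            csv += a + "," + ",".join(f"{D[i, j]:.10f}" for j in range(n)) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO(csv), delimiter=","
        )
        reference = pdm.nj_tree()
        joined = dendropy.Tree.get(
            data=write_newick(mine) + "\n",
            schema="newick",
            taxon_namespace=reference.taxon_namespace,
            preserve_underscores=True,
        )
        joined.encode_bipartitions()
        reference.encode_bipartitions()
        reference.collapse_basal_bifurcation()
        assert treecompare.symmetric_difference(reference, joined) == 0


class TestBootstrap:
    def test_single_column_identity(self):
        aln = Alignment.from_records([("a", "A"), ("b", "C")])
        out = bootstrap_columns(aln, 0)
        assert out.sequence("a") == "A" and out.sequence("b") == "C"

    def test_dimensions_preserved_and_reproducible(self, toy_alignment):
        one = bootstrap_columns(toy_alignment, 42)
        two = bootstrap_columns(toy_alignment, 42)
        other = bootstrap_columns(toy_alignment, 43)
        assert one.n_columns == toy_alignment.n_columns
        assert one.ids == toy_alignment.ids
        assert np.array_equal(one.matrix, two.matrix)
        assert not np.array_equal(one.matrix, other.matrix)

    def test_distinct_column_fraction_near_632(self):
        # with all original columns distinct, the fraction of them present in
        # a bootstrap replicate converges to 1 - 1/e
        length = 4000
        rng = np.random.default_rng(1)
        # 12 rows give 4^12 possible columns, so all columns are distinct
        rows = rng.integers(0, 4, size=(12, length))
        assert np.unique(rows, axis=1).shape[1] == length
        aln = Alignment.from_records(
            [
                (f"s{i}", "".join("ACGT"[b] for b in rows[i]))
                for i in range(rows.shape[0])
            ]
        )
        fractions = []
        for seed in range(5):
            out = bootstrap_columns(aln, seed)
            fractions.append(np.unique(out.matrix, axis=1).shape[1] / length)
        assert np.mean(fractions) == pytest.approx(1 - 1 / np.e, abs=0.02)
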