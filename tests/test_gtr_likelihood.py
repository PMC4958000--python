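"""GTR+I+G model machinery, pruning likelihood and estimation."""

import itertools

import numpy as np
import pytest

from phylorigins.alignment import Alignment
from phylorigins.errors import ValidationError
from phylorigins.gtr import GTRModel
from phylorigins.likelihood import (
    PruningEngine,
    empirical_frequencies,
    estimate_gtr,
    fit_branch_lengths,
)
from phylorigins.simulate import simulate_alignment
from phylorigins.synthetic import simulate_yule_tree
from phylorigins.trees import read_newick


@pytest.fixture(scope="module")
def gtr_model():
    return GTRModel(
        exchangeabilities=(1, 2, 1, 1, 2, 1),
        stationary_freqs=(0.3, 0.2, 0.3, 0.2),
        p_inv=0.15,
        gamma_shape=0.8,
    )


class TestModel:
    def test_frequency_normalization(self):
        m = GTRModel(stationary_freqs=(2, 1, 1, 1))
        assert sum(m.stationary_freqs) == pytest.approx(1.0)

    def test_rate_matrix_mean_rate_one(self, gtr_model):
        Q = gtr_model.rate_matrix()
        assert -(gtr_model.freqs * np.diag(Q)).sum() == pytest.approx(1.0)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    @pytest.mark.parametrize("t", [0.0, 1e-6, 0.1, 1.0, 10.0, 100.0])
    def test_kernels_are_stochastic(self, gtr_model, t):
        P = gtr_model.transition_matrix(t)
        assert (P >= 0).all()
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)

    def test_kernel_limits(self, gtr_model):
        assert np.allclose(gtr_model.transition_matrix(0.0), np.eye(4), atol=1e-9)
        P_inf = gtr_model.transition_matrix(500.0)
        assert np.allclose(P_inf, np.tile(gtr_model.freqs, (4, 1)), atol=1e-8)

    def test_jc_kernel_closed_form(self):
        # under Jukes-Cantor, P_ii(t) = 1/4 + 3/4 exp(-4t/3)
        jc = GTRModel.jc()
        for t in (0.05, 0.3, 1.2):
            expected = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
            assert np.diag(jc.transition_matrix(t)) == pytest.approx(
                [expected] * 4, abs=1e-12
            )

    def test_gamma_category_rates_mean_one(self):
        for alpha in (0.2, 0.8, 2.0, 20.0):
            rates = GTRModel.jc(gamma_shape=alpha).gamma_category_rates()
            assert rates.mean() == pytest.approx(1.0)
            assert (np.diff(rates) > 0).all()

    def test_json_round_trip(self, gtr_model, tmp_path):
        path = tmp_path / "model.json"
        gtr_model.to_json(path)
        assert GTRModel.from_json(path) == gtr_model

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            GTRModel(p_inv=1.5)
        with pytest.raises(ValidationError):
            GTRModel(gamma_shape=0.0)
        with pytest.raises(ValidationError):
            GTRModel(exchangeabilities=(1, 1, 1, 1, 1))


def brute_force_loglik(tree, aln, model):
    """Likelihood by explicit summation over internal-node states."""
    rates = model.gamma_category_rates()
    pi = model.freqs
    nodes = list(tree.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    leaves = [n for n in nodes if n.is_leaf()]
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    total = 0.0
    for col in range(aln.n_columns):
        observed = {
            n.taxon.label: code[aln.sequence(n.taxon.label)[col]] for n in leaves
        }
        var_like = 0.0
        for r in rates:
            kernels = {
                id(n): model.transition_matrix(n.edge.length, rate=r)
                for n in nodes
                if n.parent_node is not None
            }
            s = 0.0
            for assignment in itertools.product(range(4), repeat=len(internal)):
                state = {id(n): a for n, a in zip(internal, assignment)}
                for n in leaves:
                    state[id(n)] = observed[n.taxon.label]
                p = pi[state[id(tree.seed_node)]]
                for n in nodes:
                    if n.parent_node is not None:
                        p *= kernels[id(n)][state[id(n.parent_node)], state[id(n)]]
                s += p
            var_like += s / len(rates)
        inv_like = pi[next(iter(observed.values()))] if len(set(observed.values())) == 1 else 0.0
        total += np.log(model.p_inv * inv_like + (1 - model.p_inv) * var_like)
    return total


class TestPruningLikelihood:
    def test_matches_brute_force_enumeration(self, gtr_model):
        tree = read_newick("((A:0.1,B:0.2):0.05,C:0.3,D:0.15);")
        aln = Alignment.from_records(
            [("A", "ACGTA"), ("B", "ACGAA"), ("C", "AGGTC"), ("D", "ACTTA")]
        )
        engine = PruningEngine(tree, aln)
        assert engine.loglik(gtr_model) == pytest.approx(
            brute_force_loglik(tree, aln, gtr_model), abs=1e-9
        )

    def test_branch_closure_consistent_with_full_likelihood(self, gtr_model):
        tree = read_newick("((A:0.1,B:0.2):0.05,C:0.3,(D:0.15,E:0.2):0.1);")
        aln = Alignment.from_records(
            [
                ("A", "ACGTACGG"),
                ("B", "ACGAACGG"),
                ("C", "AGGTCCGG"),
                ("D", "ACTTACGT"),
                ("E", "ACTTACTT"),
            ]
        )
        engine = PruningEngine(tree, aln)
        full = engine.loglik(gtr_model)
        for i in range(1, len(engine.nodes)):
            fn = engine.branch_loglik_fn(gtr_model, i)
            assert fn(engine.lengths[i]) == pytest.approx(full, abs=1e-9)

    def test_ambiguity_and_gap_are_missing_data(self, gtr_model):
        tree = read_newick("(A:0.1,B:0.2,C:0.3);")
        with_n = Alignment.from_records([("A", "AN"), ("B", "A-"), ("C", "AN")])
        informative = Alignment.from_records([("A", "A"), ("B", "A"), ("C", "A")])
        # the all-missing second column contributes log(1) = 0
        assert PruningEngine(tree, with_n).loglik(gtr_model) == pytest.approx(
            PruningEngine(tree, informative).loglik(gtr_model)
        )

    def test_tree_alignment_mismatch_reported(self, gtr_model):
        tree = read_newick("(A:0.1,B:0.2,X:0.3);")
        aln = Alignment.from_records([("A", "AC"), ("B", "AC")])
        with pytest.raises(ValidationError, match="X"):
            PruningEngine(tree, aln)


class TestEstimation:
    def test_empirical_frequencies(self):
        # bases: A,A,C,G from the first row, A and U (counted as T) from the
        # second; gap and N excluded -> 6 unambiguous bases
        aln = Alignment.from_records([("a", "AACG"), ("b", "AU-N")])
        freqs = empirical_frequencies(aln)
        assert freqs == pytest.approx([3 / 6, 1 / 6, 1 / 6, 1 / 6])

    def test_degenerate_composition_warns(self):
        tree = read_newick("(a:0.1,b:0.1,c:0.1);")
        aln = Alignment.from_records([("a", "AAAA"), ("b", "AAAA"), ("c", "AAAA")])
        with pytest.warns(RuntimeWarning, match="degenerate"):
            model = estimate_gtr(aln, tree)
        assert model.stationary_freqs[0] == pytest.approx(1.0, abs=1e-6)

    def test_jc_frequency_recovery(self):
        tree = simulate_yule_tree(12, 2.0, 5)
        aln = simulate_alignment(tree, GTRModel.jc(), 10_000, seed=6)
        model = estimate_gtr(aln, tree, optimize=False)
        assert np.allclose(model.stationary_freqs, 0.25, atol=0.02)

    def test_pinv_and_shape_recovery(self):
        truth = GTRModel.jc(p_inv=0.3, gamma_shape=1.0)
        tree = simulate_yule_tree(20, 2.0, 15)
        aln = simulate_alignment(tree, truth, 5_000, seed=16)
        model = estimate_gtr(aln, tree, maxiter=40)
        assert model.p_inv == pytest.approx(0.3, abs=0.1)
        assert 0.5 <= model.gamma_shape <= 2.0  # within a factor of 2


class TestBranchLengths:
    def test_identical_sequences_hit_lower_bound(self):
        tree = read_newick("(A:0.5,B:0.5,C:0.5);")
        aln = Alignment.from_records(
            [("A", "ACGT" * 30), ("B", "ACGT" * 30), ("C", "ACGT" * 30)]
        )
        fitted = fit_branch_lengths(tree, aln, GTRModel.jc())
        for node in fitted.preorder_node_iter():
            if node is not fitted.seed_node:
                assert node.edge.length <= 1e-6

    def test_recovers_simulated_lengths(self):
        # moderate depth: branches beyond ~1.5 substitutions/site saturate
        # and their estimates are unstable regardless of the optimizer
        tree = simulate_yule_tree(10, 2.0, 31)
        truth = GTRModel.jc()
        aln = simulate_alignment(tree, truth, 5_000, seed=32)
        start = tree.clone(depth=1)
        for node in start.preorder_node_iter():
            if node is not start.seed_node:
                node.edge.length = 0.05
        fitted = fit_branch_lengths(start, aln, truth)
        true_lengths, fitted_lengths = [], []
        fit_nodes = list(fitted.preorder_node_iter())
        for a, b in zip(tree.preorder_node_iter(), fit_nodes):
            if a.edge.length is not None:
                true_lengths.append(a.edge.length)
                fitted_lengths.append(b.edge.length)
        r = np.corrcoef(true_lengths, fitted_lengths)[0, 1]
        assert r > 0.95

    def test_loglik_never_decreases(self):
        tree = simulate_yule_tree(8, 1.0, 41)
        model = GTRModel.jc(p_inv=0.1, gamma_shape=1.0)
        aln = simulate_alignment(tree, model, 800, seed=42)
        engine = PruningEngine(tree, aln)
        before = engine.loglik(model)
        fitted = fit_branch_lengths(tree, aln, model)
        after = PruningEngine(fitted, aln).loglik(model)
        assert after >= before - 1e-6
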