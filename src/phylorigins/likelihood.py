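"""Felsenstein-pruning likelihood on a fixed topology, with profile-style
GTR+I+G parameter estimation and per-branch length optimization.

The estimation strategy is deliberately modest and documented as such:
stationary frequencies are fixed at their empirical values; the five free
exchangeabilities (GT = 1), the invariant-sites proportion and the gamma
shape are optimized jointly with a bounded quasi-Newton search; branch
lengths are then optimized one at a time with Brent-style bounded searches.
Full joint maximum likelihood is not attempted.  Ambiguity codes and gaps
are treated as missing data (partial likelihoods of all ones).

Implementation notes: site patterns are compressed once; partial likelihoods
are batched over the discrete-gamma categories; per-branch optimization uses
"outside" partials so that re-evaluating the likelihood as a function of one
branch length costs O(patterns) rather than a full tree traversal.
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np
from scipy.optimize import minimize, minimize_scalar

from phylorigins.alignment import Alignment
from phylorigins.errors import ValidationError
from phylorigins.gtr import GTRModel
from phylorigins.trees import leaf_labels

# IUPAC code -> compatibility mask over (A, C, G, T); gap and N are missing
_MASKS = {
    "A": (1, 0, 0, 0), "C": (0, 1, 0, 0), "G": (0, 0, 1, 0), "T": (0, 0, 0, 1),
    "U": (0, 0, 0, 1),
    "R": (1, 0, 1, 0), "Y": (0, 1, 0, 1), "S": (0, 1, 1, 0), "W": (1, 0, 0, 1),
    "K": (0, 0, 1, 1), "M": (1, 1, 0, 0),
    "B": (0, 1, 1, 1), "D": (1, 0, 1, 1), "H": (1, 1, 0, 1), "V": (1, 1, 1, 0),
    "N": (1, 1, 1, 1), "-": (1, 1, 1, 1),
}

MIN_BRANCH = 1e-8
MAX_BRANCH = 20.0


def empirical_frequencies(aln: Alignment) -> np.ndarray:
    """Base frequencies over unambiguous characters ('U' counts as 'T')."""
    mat = aln.comp_matrix()
    counts = np.array([(mat == ord(b)).sum() for b in "ACGT"], dtype=float)
    if counts.sum() == 0:
        raise ValidationError("alignment has no unambiguous bases")
    return counts / counts.sum()


class PruningEngine:
    """Likelihood of an alignment on a fixed tree topology.

    Branch lengths live in a flat array (one entry per non-seed node, in
    preorder) so per-branch optimization can mutate one entry at a time.
    """

    def __init__(self, tree: dendropy.Tree, aln: Alignment):
        tree_leaves = leaf_labels(tree)
        missing = tree_leaves - set(aln.ids)
        if missing:
            raise ValidationError(
                f"tree leaves absent from alignment: {sorted(missing)}"
            )
        self.tree = tree
        nodes = list(tree.preorder_node_iter())
        self.nodes = nodes
        self._node_index = {id(n): i for i, n in enumerate(nodes)}
        self.parent = np.full(len(nodes), -1)
        self.children: list[list[int]] = [[] for _ in nodes]
        for i, node in enumerate(nodes):
            for child in node.child_nodes():
                j = self._node_index[id(child)]
                self.parent[j] = i
                self.children[i].append(j)
        self.postorder_idx = [
            self._node_index[id(n)] for n in tree.postorder_node_iter()
        ]
        self.lengths = np.empty(len(nodes))
        for i, node in enumerate(nodes):
            if node is tree.seed_node:
                self.lengths[i] = 0.0
            else:
                length = node.edge.length
                self.lengths[i] = (
                    MIN_BRANCH if length is None else max(length, MIN_BRANCH)
                )

        # pattern compression
        leaf_ids = [n.taxon.label for n in nodes if n.is_leaf()]
        sub = aln.subset_taxa(leaf_ids)
        order = {t: i for i, t in enumerate(sub.ids)}
        code_of = np.zeros(256, dtype=np.uint8)
        mask_table = np.ones((len(_MASKS), 4))
        for k, (char, mask) in enumerate(_MASKS.items()):
            code_of[ord(char)] = k
            mask_table[k] = mask
        codes = code_of[sub.matrix]  # (n_leaves, L)
        patterns, weights = np.unique(codes, axis=1, return_counts=True)
        self.weights = weights.astype(float)
        self.n_patterns = patterns.shape[1]
        self.leaf_partials: dict[int, np.ndarray] = {}
        for i, node in enumerate(nodes):
            if node.is_leaf():
                row = patterns[order[node.taxon.label]]
                self.leaf_partials[i] = mask_table[row]  # (n_patterns, 4)
        # invariant-component compatibility product over leaves, (patterns, 4)
        prod = np.ones((self.n_patterns, 4))
        for part in self.leaf_partials.values():
            prod = prod * part
        self._invariant_compat = prod

    # -- transition kernels -----------------------------------------------

    def _kernels(self, model: GTRModel, t: float, rates: np.ndarray) -> np.ndarray:
        """Stacked P(t·r) over gamma categories, shape (k, 4, 4)."""
        eigval, right, left = model._eigen()
        expo = np.exp(eigval[None, :] * rates[:, None] * t)  # (k, 4)
        P = (right[None, :, :] * expo[:, None, :]) @ left[None, :, :]
        P = np.clip(P, 0.0, None)
        P /= P.sum(axis=2, keepdims=True)
        return P

    # -- likelihood --------------------------------------------------------

    def _contribs_and_down(
        self, model: GTRModel, rates: np.ndarray
    ) -> tuple[list, list]:
        """Per-node down partials and per-edge contributions.

        down[i]: (k, patterns, 4) conditional likelihood of the subtree below
        node i given the state at i; contrib[i] = down[i] @ P_i^T, indexed by
        the state at i's parent.
        """
        k = len(rates)
        down: list = [None] * len(self.nodes)
        contrib: list = [None] * len(self.nodes)
        for i in self.postorder_idx:
            if not self.children[i]:
                down[i] = np.broadcast_to(
                    self.leaf_partials[i], (k, self.n_patterns, 4)
                )
            else:
                part = None
                for j in self.children[i]:
                    part = contrib[j] if part is None else part * contrib[j]
                down[i] = part
            if self.parent[i] >= 0:
                P = self._kernels(model, self.lengths[i], rates)
                contrib[i] = down[i] @ np.transpose(P, (0, 2, 1))
        return down, contrib

    def _site_mix(self, model: GTRModel, variable_site: np.ndarray) -> np.ndarray:
        """Combine the variable-rate mixture with the invariant component."""
        site = variable_site.mean(axis=0)
        if model.p_inv > 0:
            inv = self._invariant_compat @ model.freqs
            site = model.p_inv * inv + (1.0 - model.p_inv) * site
        return np.maximum(site, 1e-300)

    def loglik(self, model: GTRModel) -> float:
        rates = model.gamma_category_rates()
        down, _ = self._contribs_and_down(model, rates)
        root = down[0]  # seed node is preorder index 0
        site = self._site_mix(model, root @ model.freqs)
        total = float(self.weights @ np.log(site))
        if not np.isfinite(total):
            bad = int(np.argmin(site))
            raise ValidationError(f"non-finite likelihood at site pattern {bad}")
        return total

    def _outside(self, model: GTRModel, rates: np.ndarray) -> tuple[list, list]:
        """Outside partials: out[i] is the likelihood of everything outside
        the subtree of node i, as a function of the state at i's parent."""
        down, contrib = self._contribs_and_down(model, rates)
        k = len(rates)
        out: list = [None] * len(self.nodes)
        out[0] = np.broadcast_to(
            model.freqs[None, None, :], (k, self.n_patterns, 4)
        )
        for i in range(len(self.nodes)):  # preorder: parents first
            kids = self.children[i]
            if not kids:
                continue
            if i == 0:
                base = out[0]
            else:
                P = self._kernels(model, self.lengths[i], rates)
                base = out[i] @ P
            for j in kids:
                sib_prod = base
                for s in kids:
                    if s != j:
                        sib_prod = sib_prod * contrib[s]
                out[j] = sib_prod
        return down, out

    def branch_loglik_fn(self, model: GTRModel, i: int):
        """Closure computing the log-likelihood as a function of the length
        of the edge above node ``i`` alone (all other branches fixed)."""
        rates = model.gamma_category_rates()
        down, out = self._outside(model, rates)
        down_i, out_i = down[i], out[i]

        def fn(t: float) -> float:
            P = self._kernels(model, t, rates)
            contrib = down_i @ np.transpose(P, (0, 2, 1))
            site = self._site_mix(model, (out_i * contrib).sum(axis=2))
            return float(self.weights @ np.log(site))

        return fn

    def write_lengths(self, tree: dendropy.Tree | None = None) -> dendropy.Tree:
        """Copy the current branch-length vector back onto tree edges."""
        target = tree if tree is not None else self.tree
        for node, length in zip(target.preorder_node_iter(), self.lengths):
            if node is not target.seed_node:
                node.edge.length = float(length)
        return target


# -- model estimation -----------------------------------------------------


def estimate_gtr(
    aln: Alignment,
    tree: dendropy.Tree,
    n_rate_categories: int = 4,
    optimize: bool = True,
    maxiter: int = 50,
) -> GTRModel:
    """Estimate GTR+I+G parameters on a fixed tree with branch lengths.

    Frequencies are empirical; exchangeabilities (GT = 1), ``p_inv`` and the
    gamma shape maximize the pruning log-likelihood under a bounded L-BFGS-B
    search.  With degenerate composition (any base absent) estimation of the
    exchangeabilities is skipped with a warning.
    """
    freqs = empirical_frequencies(aln)
    if (freqs == 0).any() or not optimize:
        if (freqs == 0).any():
            warnings.warn(
                "degenerate base composition: exchangeability estimation skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            freqs = np.maximum(freqs, 1e-9)
            freqs /= freqs.sum()
        return GTRModel(
            stationary_freqs=tuple(freqs),
            n_rate_categories=n_rate_categories,
        )
    engine = PruningEngine(tree, aln)

    def build(x: np.ndarray) -> GTRModel:
        ex = np.exp(np.append(x[:5], 0.0))
        return GTRModel(
            exchangeabilities=tuple(ex),
            stationary_freqs=tuple(freqs),
            p_inv=float(x[5]),
            gamma_shape=float(np.exp(x[6])),
            n_rate_categories=n_rate_categories,
        )

    def objective(x: np.ndarray) -> float:
        return -engine.loglik(build(x))

    x0 = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.1, 0.0])
    bounds = [(-7.0, 7.0)] * 5 + [(0.0, 0.95), (np.log(0.02), np.log(100.0))]
    result = minimize(
        objective, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter},
    )
    return build(result.x)


def fit_branch_lengths(
    tree: dendropy.Tree,
    aln: Alignment,
    model: GTRModel,
    min_passes: int = 2,
    max_passes: int = 6,
    tol: float = 1e-3,
) -> dendropy.Tree:
    """Optimize branch lengths one at a time on a fixed topology.

    Brent-style bounded searches per branch, at least two full passes,
    stopping when a pass improves the total log-likelihood by less than
    ``tol``.  Lengths are bounded to [1e-8, 20].  The input tree is not
    mutated; a fitted clone is returned.
    """
    fitted = tree.clone(depth=1)
    engine = PruningEngine(fitted, aln)
    branch_ids = [i for i in range(len(engine.nodes)) if engine.parent[i] >= 0]
    current = engine.loglik(model)
    for pass_no in range(max_passes):
        for i in branch_ids:
            fn = engine.branch_loglik_fn(model, i)
            original = engine.lengths[i]
            best_ll = fn(original)
            res = minimize_scalar(
                lambda t: -fn(t),
                bounds=(MIN_BRANCH, MAX_BRANCH),
                method="bounded",
                options={"xatol": 1e-5, "maxiter": 25},
            )
            # bounded search cannot land exactly on the boundary; snap to the
            # lower bound when it is at least as good (zero-length branches)
            candidates = [(best_ll, original), (-res.fun, float(res.x))]
            candidates.append((fn(MIN_BRANCH), MIN_BRANCH))
            engine.lengths[i] = max(candidates, key=lambda c: (c[0], -c[1]))[1]
        new = engine.loglik(model)
        if new + 1e-6 < current:
            raise AssertionError("branch-length pass decreased the log-likelihood")
        improvement = new - current
        current = new
        if pass_no + 1 >= min_passes and improvement < tol:
            break
    return engine.write_lengths()
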