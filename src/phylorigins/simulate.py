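"""Sequence simulation under GTR+I+G, single-origin constraint trees, and
the parametric-bootstrap single-origin null.

The null experiment asks: if endosymbiosis arose exactly once, how many
origins would this pipeline infer?  A constraint tree with all endosymbiont
leaves in one clade is built from the empirical tree, GTR+I+G parameters
and branch lengths are fitted to the observed alignment on that topology,
replicate alignments of the same dimensions are simulated, and each
replicate is pushed through the same inference engine and origin count as
the empirical data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import dendropy
import numpy as np

from phylorigins.alignment import Alignment
from phylorigins.errors import LabelError, ValidationError
from phylorigins.gtr import BASES, GTRModel
from phylorigins.likelihood import estimate_gtr, fit_branch_lengths
from phylorigins.origins import LabelMap, min_origins
from phylorigins.trees import leaf_labels, nj_from_alignment, read_newick, write_newick

BRANCH_MODEL_ATTR = "sim_model"  # per-node attribute overriding the model


@dataclass(frozen=True)
class SimulationConfig:
    """Replicate count, alignment width and master seed for the null."""

    n_replicates: int = 100
    alignment_length: int = 1476
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.alignment_length < 1:
            raise ValidationError("replicates and alignment length must be positive")


# -- simulation -----------------------------------------------------------


def _sample_states(P: np.ndarray, parents: np.ndarray, rng) -> np.ndarray:
    cum = P.cumsum(axis=1)
    u = rng.random(parents.size)
    return (u[:, None] > cum[parents]).sum(axis=1).astype(np.int8)


def simulate_alignment(
    tree: dendropy.Tree,
    model: GTRModel,
    length: int,
    seed: int,
) -> Alignment:
    """Simulate a gap-free alignment along a tree with branch lengths.

    Per column: with probability ``p_inv`` the column is invariant (a single
    stationary root draw copied to every leaf); otherwise a discrete-gamma
    category is drawn and the column evolves by P(t) = exp(Q·r·t) along each
    branch from a stationary root draw.  A node attribute named by
    ``BRANCH_MODEL_ATTR`` substitutes a different :class:`GTRModel` on the
    edge above that node (used for compositional regime shifts inside
    endosymbiont clades).
    """
    if length < 1:
        raise ValidationError("alignment length must be >= 1")
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node and node.edge.length is None:
            name = node.taxon.label if node.is_leaf() else "internal node"
            raise ValidationError(f"missing branch length on edge above {name}")
    rng = np.random.default_rng(seed)
    rates = model.gamma_category_rates()
    k = len(rates)
    invariant = rng.random(length) < model.p_inv
    category = rng.integers(0, k, size=length)
    root_states = rng.choice(4, size=length, p=model.freqs)
    var = ~invariant
    var_cat = category[var]

    states: dict[int, np.ndarray] = {id(tree.seed_node): root_states[var]}
    leaf_states: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            parent_states = states[id(node)]
        else:
            parent_states = states[id(node.parent_node)]
            branch_model = getattr(node, BRANCH_MODEL_ATTR, None) or model
            t = node.edge.length
            child = np.empty_like(parent_states)
            for c in range(k):
                idx = np.nonzero(var_cat == c)[0]
                if idx.size == 0:
                    continue
                P = branch_model.transition_matrix(t, rate=rates[c])
                child[idx] = _sample_states(P, parent_states[idx], rng)
            states[id(node)] = child
            parent_states = child
        if node.is_leaf():
            full = root_states.copy()
            full[var] = parent_states
            leaf_states[node.taxon.label] = full
    base = np.frombuffer(BASES.encode(), dtype=np.uint8)
    records = [
        (taxon, base[leaf_states[taxon]].tobytes().decode())
        for taxon in sorted(leaf_states)
    ]
    return Alignment.from_records(records)


# -- single-origin constraint tree ----------------------------------------

_PLACEHOLDER = "ENDOGRAFTPLACEHOLDER"


def _mean_branch_length(tree: dendropy.Tree) -> float | None:
    lengths = [
        n.edge.length
        for n in tree.preorder_node_iter()
        if n is not tree.seed_node and n.edge.length is not None
    ]
    return float(np.mean(lengths)) if lengths else None


def build_single_origin_tree(tree: dendropy.Tree, labels: LabelMap) -> dendropy.Tree:
    """Rearrange a tree so every endosymbiont leaf sits in one pure clade.

    The induced endosymbiont subtree is grafted where the largest
    endosymbiont clade of the input attached; non-endosymbiont structure is
    otherwise untouched.  New edges get the mean input branch length.  The
    output satisfies ``min_origins == 1`` (asserted).
    """
    leaves = leaf_labels(tree)
    missing = sorted(leaves - set(labels))
    if missing:
        raise LabelError(f"leaves missing from label map: {missing}")
    endo = sorted(t for t in leaves if labels[t])
    non_endo = sorted(t for t in leaves if not labels[t])
    if len(endo) < 1 or len(non_endo) < 2:
        raise ValidationError(
            "need at least 1 endosymbiont and 2 non-endosymbiont leaves"
        )
    if min_origins(tree, labels).min_origins == 1:
        return tree.clone(depth=1)
    mean_len = _mean_branch_length(tree)

    # rooted view at the pendant edge of the smallest non-endosymbiont leaf;
    # round-trip through Newick gives the working copy its own taxon namespace
    rooted = read_newick(write_newick(tree))
    anchor = non_endo[0]
    anchor_edge = next(
        leaf.edge for leaf in rooted.leaf_node_iter() if leaf.taxon.label == anchor
    )
    half = None if anchor_edge.length is None else anchor_edge.length / 2.0
    rooted.reroot_at_edge(anchor_edge, length1=half, length2=half)
    rooted.is_rooted = True

    # purity scan; collect maximal pure clades
    pure: dict[int, bool] = {}
    clade_leaves: dict[int, list[str]] = {}
    for node in rooted.postorder_node_iter():
        if node.is_leaf():
            pure[id(node)] = bool(labels[node.taxon.label])
            clade_leaves[id(node)] = [node.taxon.label]
        else:
            kids = node.child_nodes()
            pure[id(node)] = all(pure[id(c)] for c in kids)
            clade_leaves[id(node)] = [
                t for c in kids for t in clade_leaves[id(c)]
            ]
    maximal = [
        node
        for node in rooted.preorder_node_iter()
        if pure[id(node)]
        and (node.parent_node is None or not pure[id(node.parent_node)])
    ]
    largest = max(
        maximal, key=lambda n: (len(clade_leaves[id(n)]), sorted(clade_leaves[id(n)]))
    )
    attach_parent = largest.parent_node

    # induced rooted subtree over all endosymbiont leaves
    if len(endo) == 1:
        endo_fragment = endo[0]
    else:
        endo_sub = rooted.clone(depth=1)
        endo_sub.retain_taxa_with_labels(endo)
        endo_fragment = write_newick(endo_sub).rstrip(";").strip()

    # delete every maximal pure clade; plant a placeholder leaf at the
    # attachment point of the largest one
    for node in maximal:
        node.parent_node.remove_child(node)
    placeholder_taxon = dendropy.Taxon(label=_PLACEHOLDER)
    rooted.taxon_namespace.add_taxon(placeholder_taxon)
    new_leaf = dendropy.Node(taxon=placeholder_taxon)
    attach_parent.add_child(new_leaf)
    new_leaf.edge.length = mean_len
    rooted.suppress_unifurcations()
    rooted.is_rooted = False
    if len(rooted.seed_node.child_nodes()) == 2:
        rooted.collapse_basal_bifurcation()

    text = write_newick(rooted).replace(_PLACEHOLDER, f"({endo_fragment})")
    constrained = read_newick(text)
    result = min_origins(constrained, labels)
    assert result.min_origins == 1, "constraint tree failed the single-origin check"
    assert leaf_labels(constrained) == leaves
    return constrained


# -- parametric bootstrap -------------------------------------------------


def fit_gtr_on_tree(
    aln: Alignment,
    tree: dendropy.Tree,
    outer_rounds: int = 2,
    estimate_maxiter: int = 60,
) -> tuple[GTRModel, dendropy.Tree]:
    """Alternate model estimation and branch-length fitting on a fixed
    topology (frequencies empirical throughout)."""
    fitted = tree
    model = None
    for _ in range(outer_rounds):
        model = estimate_gtr(aln, fitted, maxiter=estimate_maxiter)
        fitted = fit_branch_lengths(fitted, aln, model)
    assert model is not None
    return model, fitted


def parametric_bootstrap_single_origin(
    aln: Alignment,
    labels: LabelMap,
    config: SimulationConfig,
    infer: Callable[[Alignment], dendropy.Tree] | None = None,
    tree: dendropy.Tree | None = None,
    evaluate_on_true_trees: bool = False,
    outer_rounds: int = 2,
) -> tuple[list[int], dict]:
    """Single-origin null distribution of inferred origin counts.

    Pipeline: infer (or accept) a tree from the data, constrain it to a
    single endosymbiont origin, fit GTR+I+G and branch lengths on the
    constraint topology, simulate ``n_replicates`` alignments of the input's
    dimensions, re-infer a tree per replicate with the same engine, and
    count minimum origins.  Returns the counts plus a provenance record
    (per-replicate seeds, fitted model, engine).
    """
    engine = infer if infer is not None else nj_from_alignment
    missing = sorted(set(aln.ids) - set(labels))
    if missing:
        raise LabelError(f"alignment taxa missing from label map: {missing}")
    empirical_tree = tree if tree is not None else engine(aln)
    constraint = build_single_origin_tree(empirical_tree, labels)
    model, constraint = fit_gtr_on_tree(aln, constraint, outer_rounds=outer_rounds)
    rng = np.random.default_rng(config.seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=config.n_replicates)
    counts: list[int] = []
    for r, rep_seed in enumerate(rep_seeds):
        try:
            sim = simulate_alignment(
                constraint, model, config.alignment_length, seed=int(rep_seed)
            )
            if evaluate_on_true_trees:
                counts.append(min_origins(constraint, labels).min_origins)
            else:
                counts.append(min_origins(engine(sim), labels).min_origins)
        except Exception as exc:
            raise RuntimeError(f"replicate {r} failed: {exc}") from exc
    provenance = {
        "seed": config.seed,
        "replicate_seeds": [int(s) for s in rep_seeds],
        "n_replicates": config.n_replicates,
        "alignment_length": config.alignment_length,
        "model": model.to_dict(),
        "constraint_tree": write_newick(constraint),
        "inference": getattr(engine, "__name__", repr(engine)),
        "evaluate_on_true_trees": evaluate_on_true_trees,
    }
    return counts, provenance
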