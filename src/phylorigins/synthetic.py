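"""Synthetic Gammaproteobacteria-like datasets with known truth.

A pure-birth (Yule) tree supplies the backbone; ``k`` leaf-disjoint clades
are planted as endosymbiont lineages; sequences are simulated under a
16S-like GTR+I+G model, with endosymbiont clades evolving faster (branch
scaling) and under an A+T-enriched stationary composition — the two
signatures of endosymbiont genome degradation that matter for this
pipeline.  Every emitted dataset is validated so that the minimum-origins
statistic on the generating tree equals the planted ``k`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from phylorigins.alignment import Alignment
from phylorigins.errors import ValidationError
from phylorigins.gtr import GTRModel
from phylorigins.origins import min_origins, oracle_min_origins
from phylorigins.simulate import BRANCH_MODEL_ATTR, simulate_alignment

#: Mildly transition-biased, GC-leaning base model loosely shaped like
#: bacterial 16S data; conventional defaults, not fitted to any dataset.
DEFAULT_BASE_MODEL = GTRModel(
    exchangeabilities=(1.0, 3.0, 1.0, 1.0, 3.0, 1.0),
    stationary_freqs=(0.25, 0.23, 0.32, 0.20),
    p_inv=0.1,
    gamma_shape=1.0,
)


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    ``birth_rate`` is in substitutions-per-site time units: at the default
    10.0 a 300-leaf Yule tree has expected root height ≈ 0.53, giving
    pairwise divergences up to ≈ 1 substitution/site — deep enough that the
    70–95% identity clustering thresholds are all informative.
    ``endo_branch_scale`` (default 2.0) and ``endo_at_shift`` (default 0.2
    added A+T stationary mass) encode the endosymbiont rate acceleration and
    compositional bias.
    """

    n_taxa: int
    k_origins: int
    endo_clade_size_range: tuple[int, int] = (2, 6)
    alignment_length: int = 1476
    birth_rate: float = 10.0
    endo_branch_scale: float = 2.0
    endo_at_shift: float = 0.2
    base_model: GTRModel = field(default_factory=lambda: DEFAULT_BASE_MODEL)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.endo_clade_size_range
        if self.k_origins < 1:
            raise ValidationError("k_origins must be >= 1")
        if not (1 <= lo <= hi):
            raise ValidationError("invalid endosymbiont clade size range")
        if self.k_origins * hi >= self.n_taxa:
            raise ValidationError(
                "k_origins × max clade size must be smaller than n_taxa"
            )
        if self.alignment_length < 1:
            raise ValidationError("alignment_length must be >= 1")
        if self.birth_rate <= 0:
            raise ValidationError("birth_rate must be positive")
        if self.endo_branch_scale < 1.0:
            raise ValidationError("endo_branch_scale must be >= 1")
        if not (0.0 <= self.endo_at_shift <= 0.4):
            raise ValidationError("endo_at_shift must lie in [0, 0.4]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth accompanying a generated dataset."""

    tree: dendropy.Tree
    labels: dict[str, bool]
    k_true: int
    config: SynthConfig


def simulate_yule_tree(n_taxa: int, birth_rate: float, seed: int) -> dendropy.Tree:
    """Pure-birth tree with exponential waiting times, returned unrooted
    with strictly positive branch lengths.

    The seed node sits at the original root, so seed-to-leaf path lengths
    are tree heights; expected height is (H_n − 1) / birth_rate.
    """
    if n_taxa < 3:
        raise ValidationError("need at least 3 taxa")
    if birth_rate <= 0:
        raise ValidationError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    tree = dendropy.Tree()
    tree.seed_node.edge.length = None
    active: list[dendropy.Node] = []
    for _ in range(2):
        child = dendropy.Node()
        child.edge.length = 0.0
        tree.seed_node.add_child(child)
        active.append(child)
    while len(active) < n_taxa:
        m = len(active)
        dt = rng.exponential(1.0 / (birth_rate * m))
        for node in active:
            node.edge.length += dt
        idx = int(rng.integers(m))
        parent = active.pop(idx)
        for _ in range(2):
            child = dendropy.Node()
            child.edge.length = 0.0
            parent.add_child(child)
            active.append(child)
    # final stretch to the next (unrealized) speciation keeps pendant edges
    # strictly positive
    dt = rng.exponential(1.0 / (birth_rate * n_taxa))
    for node in active:
        node.edge.length += dt
    width = len(str(n_taxa))
    for i, node in enumerate(active, start=1):
        taxon = dendropy.Taxon(label=f"t{i:0{width}d}")
        tree.taxon_namespace.add_taxon(taxon)
        node.taxon = taxon
    tree.is_rooted = False
    # collapsing the basal bifurcation keeps the seed at the original root
    # point (the removed child's length is added onto its children)
    tree.collapse_basal_bifurcation()
    return tree


def _clade_leafsets(tree: dendropy.Tree) -> dict[int, frozenset[str]]:
    """Leaf set below each non-seed node (viewed from the seed)."""
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
        else:
            below[id(node)] = frozenset().union(
                *(below[id(c)] for c in node.child_nodes())
            )
    below.pop(id(tree.seed_node))
    return below


def plant_origins(
    tree: dendropy.Tree,
    k: int,
    size_range: tuple[int, int],
    seed: int,
    max_retries: int = 1000,
) -> dict[str, bool]:
    """Label ``k`` leaf-disjoint clades as endosymbiont lineages.

    Candidate clades are edges whose leaf sets have a size in
    ``size_range``; a uniform random disjoint selection is validated with
    the minimum-origins statistic (the planted clades must not be mergeable
    under any rooting) and re-drawn on failure, up to ``max_retries``.
    """
    lo, hi = size_range
    leaves = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    candidates = sorted(
        (ls for ls in _clade_leafsets(tree).values() if lo <= len(ls) <= hi),
        key=sorted,
    )
    if len(candidates) < k:
        raise ValidationError(
            f"only {len(candidates)} candidate clades of size {lo}..{hi}; "
            "grow the tree or widen the size range"
        )
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        chosen: list[frozenset[str]] = []
        order = rng.permutation(len(candidates))
        for i in order:
            cand = candidates[i]
            if all(not (cand & c) for c in chosen):
                chosen.append(cand)
                if len(chosen) == k:
                    break
        if len(chosen) < k:
            continue
        endo = frozenset().union(*chosen)
        if len(endo) >= len(leaves):
            continue
        labels = {t: (t in endo) for t in leaves}
        if min_origins(tree, labels).min_origins == k:
            return labels
    raise ValidationError(
        f"could not plant {k} disjoint origins after {max_retries} tries; "
        "adjust k or the clade size range"
    )


def generate_redundant_pool(
    config: SynthConfig,
    n_hubs: int = 50,
    copies_per_hub: int = 20,
    copy_divergence: float = 0.01,
) -> tuple[Alignment, dict[str, bool], SyntheticTruth]:
    """A pool emulating 16S database redundancy.

    Public 16S pools are dominated by near-duplicate sequences of
    well-sampled taxa; random taxon sampling therefore wastes most picks on
    redundancy, while diversity-maximizing sampling (one representative per
    identity cluster) spans the breadth of the pool.  This generator plants
    ``k`` endosymbiont origins on a ``n_taxa``-leaf backbone exactly as
    :func:`generate_dataset`, then expands ``n_hubs`` random non-endosymbiont
    leaves into crowds of ``copies_per_hub`` near-duplicates (pendant edges
    of order ``copy_divergence`` substitutions/site).  All copies are
    non-endosymbiont; the planted origin count is revalidated after
    expansion.
    """
    if n_hubs < 1 or copies_per_hub < 1 or copy_divergence <= 0:
        raise ValidationError("redundancy parameters must be positive")
    rng = np.random.default_rng(config.seed)
    tree_seed, label_seed, sim_seed = (int(s) for s in rng.integers(0, 2**31 - 1, 3))
    tree = simulate_yule_tree(config.n_taxa, config.birth_rate, tree_seed)
    labels = plant_origins(
        tree, config.k_origins, config.endo_clade_size_range, label_seed
    )
    non_endo = sorted(t for t in labels if not labels[t])
    if n_hubs > len(non_endo):
        raise ValidationError("more redundancy hubs than non-endosymbiont leaves")
    hub_ids = list(rng.choice(non_endo, size=n_hubs, replace=False))
    leaf_of = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    for hub in hub_ids:
        node = leaf_of[hub]
        taxon = node.taxon
        node.taxon = None
        original = dendropy.Node(taxon=taxon)
        original.edge.length = copy_divergence / 2.0
        node.add_child(original)
        for j in range(copies_per_hub):
            copy_taxon = dendropy.Taxon(label=f"{hub}x{j}")
            tree.taxon_namespace.add_taxon(copy_taxon)
            copy = dendropy.Node(taxon=copy_taxon)
            copy.edge.length = copy_divergence / 2.0 + copy_divergence * rng.random()
            node.add_child(copy)
            labels[copy_taxon.label] = False
    endo = frozenset(t for t, is_endo in labels.items() if is_endo)
    endo_model = (
        _at_shifted(config.base_model, config.endo_at_shift)
        if config.endo_at_shift > 0
        else config.base_model
    )
    below = _clade_leafsets(tree)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if below[id(node)] <= endo:
            node.edge.length *= config.endo_branch_scale
            setattr(node, BRANCH_MODEL_ATTR, endo_model)
    aln = simulate_alignment(
        tree, config.base_model, config.alignment_length, sim_seed
    )
    k_check = min_origins(tree, labels).min_origins
    if k_check != config.k_origins:
        raise AssertionError(
            f"redundant pool has {k_check} origins, expected {config.k_origins}"
        )
    truth = SyntheticTruth(tree=tree, labels=dict(labels), k_true=config.k_origins,
                           config=config)
    return aln, labels, truth


def _at_shifted(model: GTRModel, shift: float) -> GTRModel:
    """Move ``shift`` stationary mass from C+G to A+T, pro rata."""
    a, c, g, t = model.stationary_freqs
    cg = c + g
    at = a + t
    if shift >= cg:
        raise ValidationError("AT shift exceeds available C+G mass")
    return replace(
        model,
        stationary_freqs=(
            a + shift * a / at,
            c - shift * c / cg,
            g - shift * g / cg,
            t + shift * t / at,
        ),
    )


def generate_dataset(
    config: SynthConfig,
) -> tuple[Alignment, dict[str, bool], SyntheticTruth]:
    """Tree + labels + simulated alignment with validated planted truth.

    Endosymbiont-clade branches are scaled by ``endo_branch_scale`` and
    evolve under the A+T-shifted model; everything else follows the base
    model.  The alignment is gap-free.  Identical config (including seed)
    reproduces the dataset byte-for-byte.
    """
    rng = np.random.default_rng(config.seed)
    tree_seed, label_seed, sim_seed = (int(s) for s in rng.integers(0, 2**31 - 1, 3))
    tree = simulate_yule_tree(config.n_taxa, config.birth_rate, tree_seed)
    labels = plant_origins(
        tree, config.k_origins, config.endo_clade_size_range, label_seed
    )
    endo = frozenset(t for t, is_endo in labels.items() if is_endo)
    endo_model = (
        _at_shifted(config.base_model, config.endo_at_shift)
        if config.endo_at_shift > 0
        else config.base_model
    )
    below = _clade_leafsets(tree)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if below[id(node)] <= endo:
            node.edge.length *= config.endo_branch_scale
            setattr(node, BRANCH_MODEL_ATTR, endo_model)
    aln = simulate_alignment(
        tree, config.base_model, config.alignment_length, sim_seed
    )
    k_check = (
        oracle_min_origins(tree, labels)
        if config.n_taxa <= 30
        else min_origins(tree, labels).min_origins
    )
    if k_check != config.k_origins:
        raise AssertionError(
            f"generated truth has {k_check} origins, expected {config.k_origins}"
        )
    truth = SyntheticTruth(tree=tree, labels=labels, k_true=config.k_origins,
                           config=config)
    return aln, labels, truth
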