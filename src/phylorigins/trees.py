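"""Phylogenetic trees: Newick I/O, pruning, rooting enumeration, distances,
neighbor-joining inference and nonparametric column bootstrap.

Trees are ``dendropy.Tree`` objects throughout.  Unrooted trees are
normalized to have no degree-2 vertices (a basal bifurcation read from
Newick is collapsed into a trifurcation); rooted views produced by
:func:`enumerate_rootings` carry ``is_rooted=True`` and a bifurcating root
bisecting one edge.

Neighbor joining is implemented here in vectorized numpy (the Saitou–Nei
Q-criterion with negative branch-length estimates clamped to zero) because
the pipeline re-infers trees for hundreds of bootstrap replicates; tests
cross-check it against dendropy's independent implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import dendropy
import numpy as np

from phylorigins.alignment import Alignment
from phylorigins.errors import NewickError, ValidationError

__all__ = [
    "DistanceMatrix",
    "read_newick",
    "read_newick_file",
    "write_newick",
    "leaf_labels",
    "prune_to_taxa",
    "enumerate_rootings",
    "evolutionary_distance",
    "nj_tree",
    "bootstrap_columns",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative taxon distances with zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValidationError("distance matrix diagonal must be 0")
        if v.min() < -1e-12:
            raise ValidationError("distances must be non-negative")


# -- Newick I/O -----------------------------------------------------------


def _validate_leaves(tree: dendropy.Tree) -> None:
    labels = [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]
    if any(label is None for label in labels):
        raise NewickError("tree has an unlabeled leaf")
    dupes = sorted({x for x in labels if labels.count(x) > 1})
    if dupes:
        raise NewickError(f"duplicate leaf names: {dupes}")


def read_newick(text: str) -> dendropy.Tree:
    """Parse one Newick tree.  Branch lengths are optional; internal labels
    (e.g. support values) are preserved as opaque strings; a basal
    bifurcation on an unrooted tree is collapsed to a trifurcation."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"Newick parse failure: {exc}") from exc
    _validate_leaves(tree)
    if tree.is_rooted is not True:
        tree.is_rooted = False
        if len(tree.seed_node.child_nodes()) == 2:
            tree.collapse_basal_bifurcation()
    return tree


def read_newick_file(path: str | Path) -> list[dendropy.Tree]:
    """Read one tree per line from a Newick file."""
    trees = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            trees.append(read_newick(line))
    if not trees:
        raise NewickError(f"no trees in {path}")
    return trees


def write_newick(tree: dendropy.Tree) -> str:
    """Single-line Newick string (branch lengths kept if present)."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


# -- topology operations --------------------------------------------------


def prune_to_taxa(tree: dendropy.Tree, keep: Sequence[str]) -> dendropy.Tree:
    """Induced subtree on ``keep``: degree-2 vertices suppressed with branch
    lengths summed; the leaf set of the result is exactly ``keep``."""
    keep = frozenset(keep)
    present = leaf_labels(tree)
    missing = keep - present
    if missing:
        raise ValidationError(f"taxa not in tree: {sorted(missing)}")
    if len(keep) < 2:
        raise ValidationError("need at least 2 taxa to prune to")
    if keep == present:
        return tree.clone(depth=1)
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(sorted(keep))
    pruned.purge_taxon_namespace()
    if pruned.is_rooted is not True:
        pruned.is_rooted = False
        if len(pruned.seed_node.child_nodes()) == 2:
            pruned.collapse_basal_bifurcation()
    return pruned


def _preorder_edges(tree: dendropy.Tree) -> list[dendropy.Edge]:
    return [
        node.edge
        for node in tree.preorder_node_iter()
        if node is not tree.seed_node
    ]


def enumerate_rootings(
    tree: dendropy.Tree,
) -> Iterator[tuple[int, dendropy.Tree]]:
    """Yield ``(edge_index, rooted view)`` for every edge of an unrooted tree.

    The root bisects the edge (lengths halved when present).  Edge indices
    follow a deterministic preorder; a binary unrooted tree with n leaves
    yields 2n-3 rootings.  The input tree is never mutated."""
    if tree.is_rooted is True:
        raise ValidationError("tree is rooted; unroot it before enumerating rootings")
    n_edges = len(_preorder_edges(tree))
    for index in range(n_edges):
        view = tree.clone(depth=1)
        edge = _preorder_edges(view)[index]
        length = edge.length
        half = None if length is None else length / 2.0
        view.reroot_at_edge(edge, length1=half, length2=half)
        view.is_rooted = True
        yield index, view


# -- distances and inference ----------------------------------------------

JC_CEILING = 5.0


def evolutionary_distance(
    aln: Alignment, model: str = "jc69", ceiling: float = JC_CEILING
) -> DistanceMatrix:
    """Pairwise distances from the alignment.

    ``p``: mismatch fraction over comparable columns (both non-gap, exact
    character equality with 'U' as 'T').  ``jc69``: -(3/4)·ln(1 - 4p/3),
    with saturated pairs (p >= 0.75) and pairs with no comparable columns
    mapped to ``ceiling``.
    """
    if model not in {"p", "jc69"}:
        raise ValidationError(f"unknown distance model {model!r}")
    mat = aln.comp_matrix()
    nongap = aln.nongap_mask().astype(np.float64)
    n = aln.n_sequences
    p = np.zeros((n, n))
    empty_pairs = 0
    for i in range(n):
        comparable = nongap[i] * nongap
        total = comparable.sum(axis=1)
        mismatch = (comparable * (mat != mat[i])).sum(axis=1)
        with np.errstate(invalid="ignore"):
            row = np.where(total > 0, mismatch / np.maximum(total, 1), np.nan)
        empty_pairs += int(np.isnan(row).sum())
        p[i] = row
    p = (p + np.transpose(p)) / 2.0
    np.fill_diagonal(p, 0.0)
    if empty_pairs:
        warnings.warn(
            f"{empty_pairs // 2} sequence pairs share no comparable columns; "
            "assigned ceiling distance",
            RuntimeWarning,
            stacklevel=2,
        )
    if model == "p":
        d = np.where(np.isnan(p), 1.0, p)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            d = -0.75 * np.log1p(-4.0 * p / 3.0)
        d = np.where(np.isnan(d) | (p >= 0.75), ceiling, d)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tuple(aln.ids), d)


def _quote(label: str) -> str:
    if any(c in label for c in "()[]{}:;,= \t'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def nj_tree(matrix: DistanceMatrix) -> dendropy.Tree:
    """Neighbor joining (Saitou–Nei) on a distance matrix.

    Negative branch-length estimates are clamped to 0; the returned tree is
    unrooted with a basal trifurcation.  Requires at least 3 taxa.
    """
    n = len(matrix.ids)
    if n < 3:
        raise ValidationError("neighbor joining requires at least 3 taxa")
    D = matrix.values.astype(np.float64).copy()
    frags = [_quote(t) for t in matrix.ids]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # deterministic first-minimum tie-break
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new_row = 0.5 * (D[i, np.array(active)] + D[j, np.array(active)] - dij)
        new_row = np.maximum(new_row, 0.0)
        # reuse slot i for the merged node
        D[i, np.array(active)] = new_row
        D[np.array(active), i] = new_row
        D[i, i] = 0.0
        frags[i] = f"({frags[i]}:{li:.10g},{frags[j]}:{lj:.10g})"
        active.remove(j)
    ai, aj, ak = active
    dij, dik, djk = D[ai, aj], D[ai, ak], D[aj, ak]
    la = max(0.5 * (dij + dik - djk), 0.0)
    lb = max(0.5 * (dij + djk - dik), 0.0)
    lc = max(0.5 * (dik + djk - dij), 0.0)
    newick = (
        f"({frags[ai]}:{la:.10g},{frags[aj]}:{lb:.10g},{frags[ak]}:{lc:.10g});"
    )
    return read_newick(newick)


def nj_from_alignment(aln: Alignment, model: str = "jc69") -> dendropy.Tree:
    """Convenience inference engine: JC distances + neighbor joining."""
    return nj_tree(evolutionary_distance(aln, model=model))


# -- bootstrap ------------------------------------------------------------


def bootstrap_columns(aln: Alignment, seed: int) -> Alignment:
    """Nonparametric bootstrap: resample alignment columns uniformly with
    replacement; same dimensions, reproducible per seed."""
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, aln.n_columns, size=aln.n_columns)
    return aln.take_columns(idx)
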