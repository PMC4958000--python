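"""Minimum number of independent origins of an irreversible binary character.

Endosymbiosis is modeled as a gain-only trait: free-living lineages can
become endosymbionts, endosymbionts never revert.  On a rooted tree the
number of origins is then simply the number of maximal clades whose leaves
are all endosymbionts.  Because the root of the bacterial tree is uncertain,
the statistic reported for an unrooted tree is the minimum of that count
over every possible rooting (one per edge).

``min_origins`` computes this in linear time with a two-pass dynamic program
over directed edges: for each directed edge u→v it computes whether the
subtree on the v side is purely endosymbiont and how many maximal pure
clades it contains; rooting on an edge combines the two directions.
``oracle_min_origins`` is a deliberately naive reference that materializes
every rooting (edges and internal vertices) and counts maximal pure clades
by a direct leaf-set scan; it exists to validate the fast path on small
instances.

The statistic depends only on the topology and the labels, never on branch
lengths.  Multifurcations are handled natively: purity is a property of leaf
sets, not of resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import dendropy

from phylorigins.errors import LabelError, ValidationError

LabelMap = Mapping[str, bool]


@dataclass(frozen=True)
class OriginsResult:
    """Minimum origins over all edge rootings of an unrooted tree.

    ``best_root_edges`` holds preorder edge indices achieving the minimum;
    ``per_rooting_counts`` (edge index → count) is kept only on request.
    """

    min_origins: int
    best_root_edges: frozenset[int]
    per_rooting_counts: dict[int, int] | None = None


def _check_labels(leaves: list[str], labels: LabelMap) -> None:
    missing = sorted(set(leaves) - set(labels))
    if missing:
        raise LabelError(f"leaves missing from label map: {missing}")


# -- adjacency conversion -------------------------------------------------


def _adjacency(tree: dendropy.Tree) -> tuple[list[list[int]], dict[int, str]]:
    """Convert to neighbor lists with deterministic preorder node indices.

    Node 0 is the seed node; the edge above preorder node i (i >= 1) carries
    edge index i - 1, matching :func:`phylorigins.trees.enumerate_rootings`.
    """
    nodes = list(tree.preorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    adj: list[list[int]] = [[] for _ in nodes]
    leaf_of: dict[int, str] = {}
    for i, node in enumerate(nodes):
        for child in node.child_nodes():
            j = index[id(child)]
            adj[i].append(j)
            adj[j].append(i)
        if node.is_leaf():
            leaf_of[i] = node.taxon.label
    return adj, leaf_of


# -- rooted count ---------------------------------------------------------


def count_origins_rooted(tree: dendropy.Tree, labels: LabelMap) -> int:
    """Number of maximal endosymbiont-pure clades on a rooted tree.

    A node is pure when every leaf below it is an endosymbiont; a maximal
    pure clade is a pure node whose parent is not pure (the root counts when
    it is itself pure).  All-endosymbiont trees therefore score 1, trees
    without endosymbionts score 0.
    """
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    _check_labels(leaves, labels)
    pure: dict[int, bool] = {}
    count = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            pure[id(node)] = bool(labels[node.taxon.label])
        else:
            pure[id(node)] = all(pure[id(c)] for c in node.child_nodes())
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if pure[id(node)] and (parent is None or not pure[id(parent)]):
            count += 1
    return count


# -- fast minimum over rootings -------------------------------------------


def min_origins(
    tree: dendropy.Tree,
    labels: LabelMap,
    keep_per_rooting: bool = False,
) -> OriginsResult:
    """Minimum origin count over every edge rooting of an unrooted tree.

    Runs the two-pass directed-edge dynamic program (no rooted copies are
    materialized).  All minimizing edges are reported.
    """
    if tree.is_rooted is True:
        raise ValidationError("min_origins expects an unrooted tree")
    adj, leaf_of = _adjacency(tree)
    _check_labels(list(leaf_of.values()), labels)
    n = len(adj)
    if n == 1:
        # single leaf: no edges to root on
        state = bool(labels[leaf_of[0]])
        return OriginsResult(1 if state else 0, frozenset(), {} if keep_per_rooting else None)

    # iterative DFS from node 0 establishing parent order
    parent = [-1] * n
    order: list[int] = []
    stack = [0]
    seen = [False] * n
    while stack:
        u = stack.pop()
        seen[u] = True
        order.append(u)
        for w in adj[u]:
            if not seen[w]:
                parent[w] = u
                stack.append(w)

    down_pure = [False] * n
    down_f = [0] * n
    for v in reversed(order):  # post-order
        children = [w for w in adj[v] if parent[w] == v]
        if not children:
            endo = bool(labels[leaf_of[v]])
            down_pure[v] = endo
            down_f[v] = 1 if endo else 0
        else:
            down_pure[v] = all(down_pure[c] for c in children)
            down_f[v] = 1 if down_pure[v] else sum(down_f[c] for c in children)

    # up values: the complement subtree seen from v across the edge (parent, v)
    up_pure = [False] * n
    up_f = [0] * n
    for v in order:  # pre-order: parent values ready before children
        if parent[v] == -1:
            continue
        u = parent[v]
        sibs = [w for w in adj[u] if parent[w] == u and w != v]
        parts_pure = [down_pure[s] for s in sibs]
        parts_f = [down_f[s] for s in sibs]
        if parent[u] != -1:
            parts_pure.append(up_pure[u])
            parts_f.append(up_f[u])
        up_pure[v] = all(parts_pure) if parts_pure else False
        up_f[v] = 1 if up_pure[v] else sum(parts_f)

    # preorder edge index i-1 belongs to preorder node i; DFS order here is
    # not dendropy's preorder, so map via node order of _adjacency
    counts: dict[int, int] = {}
    for v in range(1, n):
        if down_pure[v] and up_pure[v]:
            c = 1
        else:
            c = down_f[v] + up_f[v]
        counts[v - 1] = c
    best = min(counts.values())
    best_edges = frozenset(e for e, c in counts.items() if c == best)
    return OriginsResult(
        min_origins=best,
        best_root_edges=best_edges,
        per_rooting_counts=counts if keep_per_rooting else None,
    )


# -- naive oracle ---------------------------------------------------------


def _naive_rooted_count(
    adj: list[list[int]], leaf_of: dict[int, str], labels: LabelMap,
    root: int, first: int | None = None,
) -> int:
    """Count maximal pure clades with root at a vertex (or, when ``first``
    is given, at a virtual root bisecting the edge root—first).

    Computes every node's leaf set from scratch — intentionally naive.
    """
    # parent structure by BFS; -1 marks the vertex root, -2 the virtual root
    if first is None:
        parent: dict[int, int] = {root: -1}
        queue = [root]
    else:
        parent = {root: -2, first: -2}
        queue = [root, first]
    visited = set(queue)
    order = []
    while queue:
        u = queue.pop(0)
        order.append(u)
        for w in adj[u]:
            if w not in visited:
                visited.add(w)
                parent[w] = u
                queue.append(w)

    def leafset(u: int) -> frozenset[str]:
        acc = set()
        stack = [u]
        while stack:
            x = stack.pop()
            if x in leaf_of:
                acc.add(leaf_of[x])
            for w in adj[x]:
                if parent.get(w) == x:
                    stack.append(w)
        return frozenset(acc)

    def pure(u: int) -> bool:
        ls = leafset(u)
        return bool(ls) and all(labels[t] for t in ls)

    count = 0
    for u in order:
        p = parent[u]
        if pure(u):
            if p == -2:
                # parent is the virtual root: other side decides maximality
                other = first if u == root else root
                if not pure(other):
                    count += 1
            elif p == -1 or not pure(p):
                count += 1
    # both halves pure across a virtual root: one clade, counted zero times above
    if first is not None and pure(root) and pure(first):
        count = 1
    return count


def oracle_min_origins(tree: dendropy.Tree, labels: LabelMap) -> int:
    """Brute-force reference: minimum origin count over every edge rooting
    and every internal-vertex rooting, each counted by a naive scan.

    Intended for small trees (n ≲ 50); also asserts the working assumption
    that no internal-vertex rooting beats the best edge rooting.
    """
    if tree.is_rooted is True:
        raise ValidationError("oracle expects an unrooted tree")
    adj, leaf_of = _adjacency(tree)
    _check_labels(list(leaf_of.values()), labels)
    n = len(adj)
    edge_counts = []
    # edges: (parent, child) pairs reconstructed by DFS from node 0
    parent = [-1] * n
    stack = [0]
    seen = [False] * n
    seen[0] = True
    while stack:
        u = stack.pop()
        for w in adj[u]:
            if not seen[w]:
                seen[w] = True
                parent[w] = u
                stack.append(w)
    for v in range(1, n):
        edge_counts.append(
            _naive_rooted_count(adj, leaf_of, labels, root=parent[v], first=v)
        )
    best_edge = min(edge_counts)
    vertex_counts = [
        _naive_rooted_count(adj, leaf_of, labels, root=u)
        for u in range(n)
        if u not in leaf_of
    ]
    if vertex_counts and min(vertex_counts) < best_edge:
        raise AssertionError(
            "internal-vertex rooting beat the best edge rooting; "
            "edge-only enumeration assumption violated"
        )
    return best_edge


def read_labels_tsv(path) -> dict[str, bool]:
    """Read a two-column TSV ``taxon_id <TAB> 0|1`` into a label map."""
    labels: dict[str, bool] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            taxon, _, state = line.partition("\t")
            if state not in {"0", "1"}:
                raise ValidationError(f"bad state {state!r} for taxon {taxon!r}")
            labels[taxon] = state == "1"
    if not labels:
        raise ValidationError(f"no labels in {path}")
    return labels


def write_labels_tsv(labels: LabelMap, path) -> None:
    with open(path, "w") as handle:
        for taxon in sorted(labels):
            handle.write(f"{taxon}\t{1 if labels[taxon] else 0}\n")
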