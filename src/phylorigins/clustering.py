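"""Identity-threshold (QT) clustering and taxon subsampling.

The clustering follows the classic quality-threshold procedure: every
remaining taxon seeds a candidate cluster that is grown greedily under the
constraint that the minimum pairwise identity inside the cluster stays at or
above the threshold; the largest candidate is committed and removed, and the
procedure repeats.  "Quality" is the cluster diameter in similarity space
(minimum within-cluster pairwise identity).  Tie-breaks are fully
deterministic: among equally good candidate additions the lexicographically
smallest id wins, and among equally large candidate clusters the one seeded
by the lexicographically smallest taxon wins.

Subsampling supports the two strategies compared in taxon-sampling studies:
nested diversity-maximizing subsamples (at least one representative per
cluster at each threshold, each set containing the set for every lower
threshold) and random subsamples of fixed size.  Both always retain a
mandatory taxon set (the endosymbionts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from phylorigins.alignment import Alignment
from phylorigins.errors import ValidationError


@dataclass(frozen=True)
class IdentityMatrix:
    """Symmetric pairwise identity fractions in [0, 1] with unit diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValidationError("identity matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValidationError("identity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValidationError("identity matrix diagonal must be 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValidationError("identity values must lie in [0, 1]")

    def index(self, taxon: str) -> int:
        return self.ids.index(taxon)


@dataclass(frozen=True)
class ClusterPartition:
    """Disjoint cover of the taxon set; every within-cluster pair has
    identity >= threshold.  Clusters are in commit order, members sorted."""

    threshold: float
    clusters: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise ValidationError("threshold must be in (0, 1]")
        flat = [t for c in self.clusters for t in c]
        if len(flat) != len(set(flat)):
            raise ValidationError("clusters are not disjoint")
        if any(not c for c in self.clusters):
            raise ValidationError("empty cluster")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def universe(self) -> frozenset[str]:
        return frozenset(t for c in self.clusters for t in c)


@dataclass(frozen=True)
class SubsampleSeries:
    """Strictly nested taxon sets along ascending identity thresholds, every
    set containing the mandatory taxa."""

    thresholds: tuple[float, ...]
    taxon_sets: tuple[frozenset[str], ...]
    mandatory: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.taxon_sets):
            raise ValidationError("thresholds/taxon_sets length mismatch")
        for lower, higher in zip(self.taxon_sets, self.taxon_sets[1:]):
            if not lower <= higher:
                raise ValidationError("taxon sets are not nested")
        for s in self.taxon_sets:
            if not self.mandatory <= s:
                raise ValidationError("mandatory taxa missing from a subsample")


def pairwise_identity(aln: Alignment) -> IdentityMatrix:
    """Fraction of matching characters over pairwise comparable columns.

    Comparable columns have non-gap characters in both sequences; matches are
    exact character equality ('U' compares as 'T').  Pairs with no comparable
    columns get identity 0, which forces separation rather than spurious
    merging downstream.
    """
    mat = aln.comp_matrix()
    nongap = aln.nongap_mask().astype(np.float64)
    n = aln.n_sequences
    values = np.empty((n, n))
    for i in range(n):
        comparable = nongap[i] * nongap  # (n, L)
        matches = (comparable * (mat == mat[i])).sum(axis=1)
        total = comparable.sum(axis=1)
        with np.errstate(invalid="ignore"):
            row = np.where(total > 0, matches / np.maximum(total, 1), 0.0)
        values[i] = row
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return IdentityMatrix(tuple(aln.ids), values)


def qt_cluster(matrix: IdentityMatrix, threshold: float) -> ClusterPartition:
    """Greedy quality-threshold clustering at an identity threshold."""
    if not (0.0 < threshold <= 1.0):
        raise ValidationError("threshold must be in (0, 1]")
    ids = list(matrix.ids)
    # lexicographic rank for deterministic tie-breaking
    order = np.array(sorted(range(len(ids)), key=lambda i: ids[i]))
    rank = np.empty(len(ids), dtype=np.int64)
    rank[order] = np.arange(len(ids))
    values = matrix.values
    remaining = np.ones(len(ids), dtype=bool)
    clusters: list[tuple[str, ...]] = []
    while remaining.any():
        best_members: list[int] | None = None
        # seeds in lexicographic order so the first largest candidate wins
        for seed in order:
            if not remaining[seed]:
                continue
            members = [seed]
            # min identity of each remaining taxon to current members
            minid = np.where(remaining, values[seed], -np.inf)
            minid[seed] = -np.inf
            while True:
                admissible = minid >= threshold
                if not admissible.any():
                    break
                # argmax of minid, ties by lexicographic rank
                cand = np.nonzero(admissible)[0]
                top = minid[cand].max()
                tied = cand[minid[cand] == top]
                pick = tied[np.argmin(rank[tied])]
                members.append(int(pick))
                minid = np.minimum(minid, values[pick])
                minid[pick] = -np.inf
            if best_members is None or len(members) > len(best_members):
                best_members = members
        assert best_members is not None
        clusters.append(tuple(sorted(ids[i] for i in best_members)))
        remaining[best_members] = False
    return ClusterPartition(threshold=threshold, clusters=tuple(clusters))


def _representative(
    cluster: Sequence[str], already: set[str], nongap: dict[str, int]
) -> str | None:
    """Representative choice: an already-selected member stands for the
    cluster; otherwise the member with the most non-gap characters, ties by
    lexicographic id.  Returns None if the cluster is already represented."""
    if any(t in already for t in cluster):
        return None
    return max(cluster, key=lambda t: (nongap[t], _NegStr(t)))


class _NegStr:
    """Reverses string comparison so max() prefers the smallest id."""

    __slots__ = ("s",)

    def __init__(self, s: str):
        self.s = s

    def __lt__(self, other: "_NegStr") -> bool:
        return self.s > other.s


def build_nested_subsamples(
    partitions: Sequence[ClusterPartition],
    mandatory: Iterable[str],
    aln: Alignment,
    seed: int = 0,
) -> SubsampleSeries:
    """Diversity-maximizing nested subsamples along ascending thresholds.

    The lowest threshold contributes one representative per cluster plus the
    mandatory taxa; each higher threshold keeps everything selected so far
    and adds one representative from every cluster not yet represented.  The
    representative rule is deterministic, so ``seed`` only fixes the
    signature shared with :func:`random_subsample`.
    """
    del seed  # representative choice is deterministic
    if not partitions:
        raise ValidationError("no cluster partitions supplied")
    thresholds = [p.threshold for p in partitions]
    if thresholds != sorted(thresholds):
        raise ValidationError("partitions must be in ascending threshold order")
    universe = partitions[0].universe()
    for p in partitions[1:]:
        if p.universe() != universe:
            raise ValidationError("partitions do not share one taxon universe")
    mandatory = frozenset(mandatory)
    if not mandatory <= universe:
        raise ValidationError(
            f"mandatory taxa outside universe: {sorted(mandatory - universe)}"
        )
    nongap = {
        taxon: int(count)
        for taxon, count in zip(aln.ids, aln.nongap_mask().sum(axis=1))
    }
    selected: set[str] = set(mandatory)
    sets: list[frozenset[str]] = []
    for partition in partitions:
        for cluster in partition.clusters:
            rep = _representative(cluster, selected, nongap)
            if rep is not None:
                selected.add(rep)
        sets.append(frozenset(selected))
    return SubsampleSeries(tuple(thresholds), tuple(sets), mandatory)


def random_subsample(
    universe: Iterable[str], size: int, mandatory: Iterable[str], seed: int
) -> frozenset[str]:
    """Mandatory taxa plus a uniform without-replacement draw up to ``size``."""
    universe = frozenset(universe)
    mandatory = frozenset(mandatory)
    if not mandatory <= universe:
        raise ValidationError("mandatory taxa must be a subset of the universe")
    if not (len(mandatory) <= size <= len(universe)):
        raise ValidationError(
            f"size must be in [{len(mandatory)}, {len(universe)}], got {size}"
        )
    pool = sorted(universe - mandatory)
    rng = np.random.default_rng(seed)
    extra = rng.choice(len(pool), size=size - len(mandatory), replace=False)
    return mandatory | {pool[i] for i in extra}
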