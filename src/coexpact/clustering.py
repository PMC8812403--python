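"""Hierarchical clustering with correlation distance and cut-height modules.

Distance is sign-sensitive, ``d = 1 - r`` (range [0, 2]): strongly
negatively correlated gene blocks land in separate top-level clusters,
which sign-blind distances would merge.  Agglomeration is complete
linkage with a documented deterministic tie rule (ties broken by the
lexicographically smallest leaf names of the candidate pair), so trees are
identical across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError


@dataclass
class Merge:
    left: frozenset
    right: frozenset
    height: float

    @property
    def members(self) -> frozenset:
        return self.left | self.right


@dataclass
class Dendrogram:
    """An agglomerative tree: ordered merges over named leaves."""

    leaves: list[str]
    merges: list[Merge]

    def __post_init__(self):
        if len(self.merges) != max(len(self.leaves) - 1, 0):
            raise DataError("a dendrogram over n leaves needs n-1 merges")

    @property
    def max_height(self) -> float:
        return self.merges[-1].height if self.merges else 0.0

    def cophenetic(self, a: str, b: str) -> float:
        """Height of the first merge joining leaves ``a`` and ``b``."""
        if a == b:
            return 0.0
        for m in self.merges:
            if ({a, b} <= m.members) and not (
                    {a, b} <= m.left or {a, b} <= m.right):
                return m.height
        raise DataError(f"leaves {a!r}/{b!r} never merged")

    def to_newick(self) -> str:
        """Newick text with branch lengths = height differences."""
        node_repr: dict[frozenset, tuple[str, float]] = {
            frozenset([leaf]): (leaf, 0.0) for leaf in self.leaves}
        for m in self.merges:
            lrep, lh = node_repr.pop(m.left)
            rrep, rh = node_repr.pop(m.right)
            rep = (f"({lrep}:{m.height - lh:.17g},{rrep}:{m.height - rh:.17g})")
            node_repr[m.members] = (rep, m.height)
        (rep, _), = node_repr.values()
        return rep + ";"


def correlation_distance(data: pd.DataFrame | None = None,
                         method: str = "pearson",
                         correlations: pd.DataFrame | None = None
                         ) -> pd.DataFrame:
    """Distance matrix ``d = 1 - r`` between the rows of ``data``.

    Alternatively accepts a precomputed square correlation matrix via
    ``correlations``.  NA correlations are rejected with the offending
    pairs named.
    """
    if correlations is None:
        if method == "spearman":
            ranked = data.rank(axis=1)
            corr = ranked.T.corr(method="pearson")
        else:
            corr = data.T.corr(method=method)
    else:
        corr = correlations
    d = 1.0 - corr
    nan_pairs = [(a, b) for a in d.index for b in d.columns
                 if a < b and np.isnan(d.loc[a, b])]
    if nan_pairs:
        raise DataError(f"undefined correlation for pairs: {nan_pairs[:10]}")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d.values, 0.0)
    return d


def hierarchical_cluster(distance: pd.DataFrame,
                         linkage: str = "complete") -> Dendrogram:
    """Agglomerative complete-linkage clustering of a distance matrix.

    Naive O(n^3) agglomeration; ties on merge distance are broken by the
    lexicographically smallest leaf names of the two candidate clusters.
    """
    if linkage != "complete":
        raise DataError("only complete linkage is supported")
    if not np.allclose(distance.values, distance.values.T, equal_nan=False):
        raise DataError("distance matrix not symmetric")
    leaves = list(distance.index)
    if len(leaves) < 2:
        raise DataError("need >= 2 leaves")

    dmat = distance.to_numpy(dtype=float)
    clusters: list[list[int]] = [[i] for i in range(len(leaves))]
    merges: list[Merge] = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = float(dmat[np.ix_(clusters[i], clusters[j])].max())
                names = sorted((min(leaves[k] for k in clusters[i]),
                                min(leaves[k] for k in clusters[j])))
                key = (d, names[0], names[1])
                if best is None or key < best[0]:
                    best = (key, i, j)
        (d, *_), i, j = best
        sets = sorted((frozenset(leaves[k] for k in clusters[i]),
                       frozenset(leaves[k] for k in clusters[j])), key=min)
        merges.append(Merge(left=sets[0], right=sets[1], height=float(d)))
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return Dendrogram(leaves=leaves, merges=merges)


@dataclass
class ClusterAssignment:
    assignment: dict[str, int]
    cut_height: float

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, cluster_id: int) -> list[str]:
        return sorted(k for k, v in self.assignment.items()
                      if v == cluster_id)

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for v in self.assignment.values():
            out[v] = out.get(v, 0) + 1
        return out


def cut_tree(dendrogram: Dendrogram, height: float) -> ClusterAssignment:
    """Clusters = connected components after removing merges above ``height``.

    Cluster ids are 1..k in order of each cluster's first leaf in the
    dendrogram's leaf list.
    """
    if height < 0:
        raise DataError("cut height must be >= 0")
    parent = {leaf: leaf for leaf in dendrogram.leaves}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m in dendrogram.merges:
        if m.height <= height:
            ra, rb = find(min(m.left)), find(min(m.right))
            if ra != rb:
                parent[rb] = ra
    roots: dict[str, int] = {}
    assignment: dict[str, int] = {}
    for leaf in dendrogram.leaves:
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots) + 1
        assignment[leaf] = roots[r]
    return ClusterAssignment(assignment=assignment, cut_height=height)


def sample_separation(expr: pd.DataFrame, labels: pd.Series,
                      target_class: str | None = None) -> float:
    """Fraction of one class isolated in a pure subtree.

    Samples (columns of ``expr``) are clustered with correlation distance
    and complete linkage.  The score is the size of the largest subtree
    containing only target-class samples, divided by the class size; with
    a single class present the fraction is 1.0 by convention.
    """
    labels = pd.Series(labels.values, index=expr.columns) \
        if len(labels) == len(expr.columns) else labels
    classes = labels.unique().tolist()
    if len(classes) == 1:
        return 1.0
    if len(classes) != 2:
        raise DataError("sample_separation expects exactly two classes")
    if target_class is None:
        target_class = classes[0]
    n_target = int((labels == target_class).sum())
    if n_target < 2 or (len(labels) - n_target) < 2:
        raise DataError("each class needs >= 2 samples")

    dist = correlation_distance(expr.T)
    tree = hierarchical_cluster(dist)
    best = 1  # every target leaf is itself a pure singleton subtree
    for m in tree.merges:
        for subtree in (m.left, m.right, m.members):
            sub_labels = labels.loc[list(subtree)]
            if (sub_labels == target_class).all():
                best = max(best, len(subtree))
    return best / n_target


def write_assignment_tsv(assignment: ClusterAssignment, path) -> None:
    with open(path, "w") as fh:
        fh.write("leaf\tcluster\n")
        for leaf, cid in sorted(assignment.assignment.items()):
            fh.write(f"{leaf}\t{cid}\n")


def cluster_size(genes: list[str]) -> int:
    """Size of an enumerated cluster membership list (duplicates rejected)."""
    if len(set(genes)) != len(genes):
        raise DataError("duplicate genes in cluster membership list")
    return len(genes)
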