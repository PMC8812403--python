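"""Three-metric closeness of each gene to a probe gene set.

For a probe set T (by default the panel's five TLR genes) and a gene g,
three counts are summed one point per gene:

1. members of T adjacent to g in the co-expression network;
2. shared neighbors between g and T treated as one merged node
   (excluding g itself and all of T);
3. members of T in g's cut-height cluster.

The network metric uses the loose (p < alpha) network rather than the
high-correlation network, so that weak but significant probe-set edges
count.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .clustering import ClusterAssignment
from .errors import DataError

DEFAULT_TLR_SET = frozenset({"TLR1", "TLR2", "TLR4", "TLR6", "TLR8"})


@dataclass
class ClosenessScore:
    gene: str
    metric_coexpr: int
    metric_common: int
    metric_cluster: int

    def __post_init__(self):
        if min(self.metric_coexpr, self.metric_common,
               self.metric_cluster) < 0:
            raise DataError("closeness metric counts must be >= 0")

    @property
    def total(self) -> int:
        return self.metric_coexpr + self.metric_common + self.metric_cluster


def metric_coexpressed_tlrs(network: nx.Graph, gene: str,
                            tlr_set: frozenset | set) -> int:
    """Number of probe-set genes adjacent to ``gene``."""
    if gene not in network:
        raise DataError(f"gene {gene!r} not a network node")
    if not set(tlr_set) <= set(network.nodes):
        raise DataError("probe set not contained in network nodes")
    return len(set(network.neighbors(gene)) & set(tlr_set))


def metric_common_neighbors(network: nx.Graph, gene: str,
                            tlr_set: frozenset | set) -> int:
    """Shared neighbors of ``gene`` and the merged probe-set node.

    Both neighbor sets exclude the probe gene itself and every probe-set
    member.
    """
    if gene not in network:
        raise DataError(f"gene {gene!r} not a network node")
    if not set(tlr_set) <= set(network.nodes):
        raise DataError("probe set not contained in network nodes")
    excluded = set(tlr_set) | {gene}
    mine = set(network.neighbors(gene)) - excluded
    theirs = set()
    for t in tlr_set:
        theirs |= set(network.neighbors(t))
    theirs -= excluded
    return len(mine & theirs)


def metric_tlrs_in_cluster(assignment: ClusterAssignment, gene: str,
                           tlr_set: frozenset | set) -> int:
    """Probe-set genes sharing ``gene``'s cut-height cluster."""
    if gene not in assignment.assignment:
        raise DataError(f"gene {gene!r} unassigned")
    cid = assignment.assignment[gene]
    return sum(1 for t in tlr_set
               if t != gene and assignment.assignment.get(t) == cid)


def closeness_table(network: nx.Graph, assignment: ClusterAssignment,
                    tlr_set: frozenset | set = DEFAULT_TLR_SET,
                    genes: list[str] | None = None) -> list[ClosenessScore]:
    """Per-gene closeness scores, sorted by total desc then gene name.

    ``genes`` defaults to all network nodes outside the probe set.
    """
    if genes is None:
        genes = sorted(set(network.nodes) - set(tlr_set))
    scores = [
        ClosenessScore(
            gene=g,
            metric_coexpr=metric_coexpressed_tlrs(network, g, tlr_set),
            metric_common=metric_common_neighbors(network, g, tlr_set),
            metric_cluster=metric_tlrs_in_cluster(assignment, g, tlr_set),
        )
        for g in genes
    ]
    scores.sort(key=lambda s: (-s.total, s.gene))
    return scores


def closeness_to_rows(scores: list[ClosenessScore]) -> list[dict]:
    return [{
        "gene": s.gene,
        "coexpressed_tlrs": s.metric_coexpr,
        "common_neighbors": s.metric_common,
        "tlrs_in_cluster": s.metric_cluster,
        "total": s.total,
    } for s in scores]
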