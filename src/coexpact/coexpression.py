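"""Condition-wise gene co-expression networks and topology metrics.

Pairwise Pearson/Spearman correlation over all gene pairs, undirected
network construction at conjunctive (r, p) thresholds with isolated nodes
retained, topology statistics using the finite-pairs convention for
disconnected graphs, and cross-condition edge comparison (gained/lost
edges and multi-network overlap regions).

Edge identity ignores the correlation sign: a "relation" is a gene pair,
whether the correlation is positive or negative; the sign is recorded as
an edge attribute.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

P_FLOOR_NOTE = "perfect correlation; p below machine floor reported as 0"


@dataclass
class CorrelationResult:
    """One gene pair's correlation under one method.

    ``gene_a < gene_b`` canonically; ``n`` is the sample count after
    pairwise NA removal; r/p are NaN when undefined (zero variance or
    n < 3).
    """

    gene_a: str
    gene_b: str
    method: str
    r: float
    p: float
    n: int
    note: str = ""

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def _corr_and_p(x: np.ndarray, y: np.ndarray, method: str,
                exact_spearman: bool = False) -> tuple[float, float, str]:
    n = len(x)
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan, "undefined (n<3 or zero variance)"
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-14:
        return float(np.sign(r)), 0.0, P_FLOOR_NOTE
    if method == "spearman" and exact_spearman:
        if n > 8:
            raise DataError("exact Spearman p only supported for n <= 8")
        obs = abs(r)
        count = 0
        total = 0
        for perm in itertools.permutations(y):
            rp = np.corrcoef(x, perm)[0, 1]
            count += abs(rp) >= obs - 1e-12
            total += 1
        return r, count / total, "exact permutation p"
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, p, ""


def pairwise_correlation(expr: pd.DataFrame, method: str = "pearson",
                         condition_samples: list[str] | None = None,
                         exact_spearman: bool = False) -> list[CorrelationResult]:
    """Correlation of every gene pair within one sample set.

    Pearson p comes from the t distribution with n-2 df; Spearman p from
    the same t approximation applied to the rank correlation (average
    ranks for ties), with an exact-permutation option for n <= 8.
    Pairs are emitted in canonical (sorted-name) order.
    """
    if method not in ("pearson", "spearman"):
        raise DataError(f"unknown method {method!r}")
    sub = expr[condition_samples] if condition_samples is not None else expr
    genes = sorted(sub.index)
    x = sub.loc[genes].to_numpy(dtype=float)
    results: list[CorrelationResult] = []

    if not np.isnan(x).any() and not exact_spearman:
        # fast path: matrix correlation on complete data
        data = x
        if method == "spearman":
            data = np.apply_along_axis(stats.rankdata, 1, x)
        sd = data.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rmat = np.corrcoef(data)
        n = data.shape[1]
        for i, j in itertools.combinations(range(len(genes)), 2):
            if n < 3 or sd[i] == 0 or sd[j] == 0:
                r, p, note = np.nan, np.nan, "undefined (n<3 or zero variance)"
            else:
                r = float(rmat[i, j])
                if abs(r) >= 1.0 - 1e-14:
                    r, p, note = float(np.sign(r)), 0.0, P_FLOOR_NOTE
                else:
                    t = r * np.sqrt((n - 2) / (1.0 - r * r))
                    p, note = float(2.0 * stats.t.sf(abs(t), n - 2)), ""
            results.append(CorrelationResult(genes[i], genes[j], method, r, p,
                                             n, note))
        return results

    for i, j in itertools.combinations(range(len(genes)), 2):
        xi, xj = x[i], x[j]
        ok = ~(np.isnan(xi) | np.isnan(xj))
        r, p, note = _corr_and_p(xi[ok], xj[ok], method, exact_spearman)
        results.append(CorrelationResult(genes[i], genes[j], method, r, p,
                                         int(ok.sum()), note))
    return results


def correlations_frame(correlations: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_a": c.gene_a, "gene_b": c.gene_b, "method": c.method,
        "r": c.r, "p": c.p, "n": c.n, "note": c.note,
    } for c in correlations])


# ---------------------------------------------------------------------------
# network construction


def build_network(correlations: list[CorrelationResult], alpha: float = 0.05,
                  r_min: float | None = None,
                  nodes: list[str] | None = None,
                  condition: str | None = None) -> nx.Graph:
    """Undirected network of pairs meeting the conjunctive threshold.

    An edge requires ``p < alpha`` and, when ``r_min`` is given,
    ``|r| > r_min``.  Isolated genes are retained as nodes.  All input
    correlations must share one method.
    """
    methods = {c.method for c in correlations}
    if len(methods) > 1:
        raise DataError(f"mixed-method correlation input: {sorted(methods)}")
    g = nx.Graph(threshold_alpha=alpha, threshold_r_min=r_min,
                 condition=condition,
                 method=methods.pop() if methods else None)
    if nodes is None:
        node_set = sorted({n for c in correlations for n in c.pair})
    else:
        node_set = list(nodes)
    g.add_nodes_from(node_set)
    for c in correlations:
        if np.isnan(c.p) or np.isnan(c.r):
            continue
        if c.p < alpha and (r_min is None or abs(c.r) > r_min):
            g.add_edge(c.gene_a, c.gene_b, r=c.r, p=c.p,
                       sign=1 if c.r >= 0 else -1)
    return g


# ---------------------------------------------------------------------------
# topology


@dataclass
class TopologyMetrics:
    nodes: int
    edges: int
    average_neighbors: float
    diameter: float
    clustering_coefficient: float
    characteristic_path_length: float


def topology(g: nx.Graph) -> TopologyMetrics:
    """Topology statistics with the finite-pairs convention.

    Characteristic path length is the mean shortest-path length over
    connected (finite) unordered pairs; the diameter is the max such
    length.  The clustering coefficient averages local coefficients over
    all nodes, degree<2 nodes contributing 0.  Both path metrics are NaN
    on edgeless graphs.
    """
    if g.number_of_nodes() < 1:
        raise DataError("empty graph")
    n = g.number_of_nodes()
    e = g.number_of_edges()
    lengths = []
    for source, dist in nx.all_pairs_shortest_path_length(g):
        lengths.extend(d for target, d in dist.items() if target != source)
    cpl = float(np.mean(lengths)) if lengths else float("nan")
    diam = float(max(lengths)) if lengths else float("nan")
    cc = nx.average_clustering(g, count_zeros=True) if n else float("nan")
    return TopologyMetrics(
        nodes=n, edges=e, average_neighbors=2.0 * e / n if n else 0.0,
        diameter=diam, clustering_coefficient=float(cc),
        characteristic_path_length=cpl)


# ---------------------------------------------------------------------------
# cross-condition comparison


def _check_universe(networks: list[nx.Graph]) -> None:
    base = set(networks[0].nodes)
    for other in networks[1:]:
        diff = base.symmetric_difference(other.nodes)
        if diff:
            raise DataError(f"node-set mismatch: {sorted(diff)}")


def differential_edges(net_a: nx.Graph,
                       net_b: nx.Graph) -> tuple[list, list]:
    """Edges gained (in B only) and lost (in A only), by pair identity."""
    _check_universe([net_a, net_b])
    ea = {tuple(sorted(e)) for e in net_a.edges}
    eb = {tuple(sorted(e)) for e in net_b.edges}
    return sorted(eb - ea), sorted(ea - eb)


def edge_overlap(networks: list[nx.Graph],
                 labels: list[str] | None = None) -> pd.DataFrame:
    """Presence/absence of every edge across conditions.

    Returns a boolean frame indexed by canonical edge tuple with one
    column per network.
    """
    if len(networks) < 2:
        raise DataError("need >= 2 networks")
    _check_universe(networks)
    if labels is None:
        labels = [g.graph.get("condition") or f"net{i}"
                  for i, g in enumerate(networks)]
    edge_sets = [{tuple(sorted(e)) for e in g.edges} for g in networks]
    universe = sorted(set().union(*edge_sets))
    data = {lab: [e in es for e in universe]
            for lab, es in zip(labels, edge_sets)}
    index = pd.Index(universe, name="edge", tupleize_cols=False)
    return pd.DataFrame(data, index=index)


def overlap_region_counts(membership: pd.DataFrame) -> dict[tuple, int]:
    """Count edges per presence/absence region (Venn-style)."""
    counts: dict[tuple, int] = {}
    for _, row in membership.iterrows():
        key = tuple(bool(v) for v in row)
        counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# serialization


def write_sif(g: nx.Graph, path, relation: str = "co") -> None:
    """Cytoscape SIF: one ``GENE1 <relation> GENE2`` line per edge."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")
        connected = {n for e in g.edges for n in e}
        for node in sorted(set(g.nodes) - connected):
            fh.write(f"{node}\n")


def write_edges_tsv(g: nx.Graph, path) -> None:
    rows = [{"gene_a": a, "gene_b": b, **g.edges[a, b]}
            for a, b in sorted(tuple(sorted(e)) for e in g.edges)]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "p", "sign"]).to_csv(
        path, sep="\t", index=False)


def network_to_json(g: nx.Graph) -> str:
    payload = {
        "graph": g.graph,
        "nodes": sorted(g.nodes),
        "edges": [{"a": a, "b": b, **g.edges[a, b]}
                  for a, b in sorted(tuple(sorted(e)) for e in g.edges)],
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def network_from_json(text: str) -> nx.Graph:
    payload = json.loads(text)
    g = nx.Graph(**payload["graph"])
    g.add_nodes_from(payload["nodes"])
    for e in payload["edges"]:
        attrs = {k: v for k, v in e.items() if k not in ("a", "b")}
        g.add_edge(e["a"], e["b"], **attrs)
    return g
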