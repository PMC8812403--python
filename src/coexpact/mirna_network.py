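"""miRNA-target network construction.

Consumes per-gene miRNA target lists (two-column TSV or GMT-like files),
filters to multi-target miRNAs, pools miRNA families, ranks nodes by target
count, and emits a degree-filtered bipartite network, optionally annotated
with differential-expression calls.  Target maps are file inputs — no live
database queries (database versions drift).

The fold-change helper for count tables is an explicitly simplified
stand-in (library-size normalized mean ratio + Mann-Whitney p), not a
replication of any particular sequencing DE method.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

_FAMILY_RE = re.compile(r"^(?:hsa-)?((?:let|miR|mir)-\d+)", re.IGNORECASE)


@dataclass
class MirnaTargetMap:
    """A miRNA (or family) -> target-gene-set mapping.

    ``families`` maps each miRNA id to its family id; ids absent from the
    mapping are treated as their own singleton family.
    """

    targets: dict[str, set[str]]
    families: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for mirna, genes in self.targets.items():
            if not genes:
                raise DataError(f"empty target set for {mirna!r}")

    def family_of(self, mirna: str) -> str:
        return self.families.get(mirna, mirna)

    def degree(self, mirna: str) -> int:
        return len(self.targets[mirna])

    def __len__(self) -> int:
        return len(self.targets)


def infer_family(mirna: str) -> str:
    """Family id from the seed-family naming stem (miR-548ad-5p -> miR-548)."""
    m = _FAMILY_RE.match(mirna)
    return m.group(1) if m else mirna


# ---------------------------------------------------------------------------
# operations


def filter_multi_target(target_map: MirnaTargetMap,
                        gene_panel: set[str] | None = None) -> MirnaTargetMap:
    """Retain exactly the miRNAs targeting >= 2 genes.

    If ``gene_panel`` is given, target sets are first restricted to the
    panel and the >= 2 rule applies to the restricted sets.
    """
    out: dict[str, set[str]] = {}
    for mirna, genes in target_map.targets.items():
        kept = genes & gene_panel if gene_panel is not None else set(genes)
        if len(kept) >= 2:
            out[mirna] = kept
    fams = {m: target_map.family_of(m) for m in out}
    return MirnaTargetMap(targets=out, families=fams)


def pool_families(target_map: MirnaTargetMap) -> MirnaTargetMap:
    """Collapse families with >= 2 members into one node (union of targets).

    Singleton-family miRNAs pass through unchanged.
    """
    members: dict[str, list[str]] = {}
    for mirna in target_map.targets:
        members.setdefault(target_map.family_of(mirna), []).append(mirna)
    out: dict[str, set[str]] = {}
    fams: dict[str, str] = {}
    for fam, mirnas in members.items():
        if len(mirnas) >= 2:
            out[fam] = set().union(*(target_map.targets[m] for m in mirnas))
            fams[fam] = fam
        else:
            (m,) = mirnas
            out[m] = set(target_map.targets[m])
            fams[m] = fam
    return MirnaTargetMap(targets=out, families=fams)


def rank_by_target_count(target_map: MirnaTargetMap) -> list[tuple[str, int]]:
    """Rank nodes by target count, descending; ties alphabetical."""
    return sorted(
        ((m, len(g)) for m, g in target_map.targets.items()),
        key=lambda item: (-item[1], item[0]),
    )


def build_network(target_map: MirnaTargetMap, min_degree: int = 3,
                  de_table: pd.DataFrame | None = None,
                  include_de_below_min: bool = True) -> nx.Graph:
    """Bipartite miRNA-gene network keeping high-degree or DE nodes.

    A miRNA/family node is retained when its degree >= ``min_degree``, or —
    if ``include_de_below_min`` — when it appears in ``de_table`` (a frame
    indexed by miRNA with ``fold``, ``direction`` columns).  Node attributes:
    ``kind`` ("mirna"|"gene"), and for DE miRNAs ``fold`` / ``direction``.
    """
    if min_degree < 1:
        raise ConfigError("min_degree must be >= 1")
    de_index = set(de_table.index) if de_table is not None else set()
    unknown = de_index - set(target_map.targets)
    if unknown:
        warnings.warn(
            f"DE table references unknown miRNA(s): {sorted(unknown)}",
            stacklevel=2)
    g = nx.Graph()
    for mirna, genes in target_map.targets.items():
        keep = len(genes) >= min_degree or (
            include_de_below_min and mirna in de_index)
        if not keep:
            continue
        g.add_node(mirna, kind="mirna")
        if mirna in de_index:
            g.nodes[mirna]["fold"] = float(de_table.loc[mirna, "fold"])
            g.nodes[mirna]["direction"] = str(de_table.loc[mirna, "direction"])
        for gene in sorted(genes):
            g.add_node(gene, kind="gene")
            g.add_edge(mirna, gene)
    return g


def fold_change(case_counts: pd.DataFrame,
                control_counts: pd.DataFrame) -> pd.DataFrame:
    """Per-miRNA fold change (case/control) on library-size-normalized counts.

    Returns a frame indexed by miRNA with ``fold`` (ratio, > 0; inf flagged
    via ``zero_denominator``), ``direction`` ("up"|"down"), and a two-sided
    Mann-Whitney ``p_value``.  A labeled stand-in for a proper count model.
    """
    from .group_stats import mann_whitney

    if not case_counts.index.equals(control_counts.index):
        raise DataError("case and control count tables must share miRNA index")
    case = case_counts / case_counts.sum(axis=0)
    control = control_counts / control_counts.sum(axis=0)
    rows = []
    for mirna in case.index:
        a = case.loc[mirna].to_numpy(dtype=float)
        b = control.loc[mirna].to_numpy(dtype=float)
        mean_case, mean_control = a.mean(), b.mean()
        zero_den = mean_control == 0
        fold = np.inf if zero_den else mean_case / mean_control
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0
        else:
            p = mann_whitney(a, b).p_value
        rows.append({
            "mirna": mirna, "fold": fold,
            "direction": "up" if fold >= 1 else "down",
            "p_value": p, "zero_denominator": zero_den,
        })
    return pd.DataFrame(rows).set_index("mirna")


# ---------------------------------------------------------------------------
# file formats


def read_target_map(path, family_column: bool = False) -> MirnaTargetMap:
    """Read a target map from a two-column (or three-column) TSV.

    Columns: miRNA, gene[, family].  Without an explicit family column,
    families are inferred from the name stem.  Conflicting explicit family
    annotations for one miRNA raise DataError.
    """
    targets: dict[str, set[str]] = {}
    families: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataError(f"malformed target-map line: {line!r}")
            mirna, gene = parts[0], parts[1]
            fam = parts[2] if family_column and len(parts) > 2 else infer_family(mirna)
            if mirna in families and families[mirna] != fam:
                raise DataError(f"conflicting family annotations for {mirna!r}")
            targets.setdefault(mirna, set()).add(gene)
            families[mirna] = fam
    return MirnaTargetMap(targets=targets, families=families)


def read_target_map_gmt(path) -> MirnaTargetMap:
    """Read GMT-like lines: miRNA <tab> description <tab> gene1 <tab> ..."""
    targets: dict[str, set[str]] = {}
    families: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            mirna = parts[0]
            targets[mirna] = set(p for p in parts[2:] if p)
            families[mirna] = infer_family(mirna)
    return MirnaTargetMap(targets=targets, families=families)


def write_network_sif(g: nx.Graph, path, relation: str = "targets") -> None:
    with open(path, "w") as fh:
        for a, b in sorted(g.edges()):
            if g.nodes[a].get("kind") == "gene":
                a, b = b, a
            fh.write(f"{a}\t{relation}\t{b}\n")
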