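"""MCODE-style complex detection on protein-protein interaction networks.

Implements the molecular-complex detection procedure of Bader & Hogue on an
undirected simple graph: k-core-based vertex weighting, greedy seeded
expansion from the highest-weight vertices, and k-core/haircut
post-processing; plus Fisher's-exact functional-category enrichment of the
resulting clusters against an annotated gene universe.

Graphs are :class:`networkx.Graph` instances; self-loops and duplicate
edges are rejected at load.  All tie-breaks are lexicographic on the gene
symbol so results are invariant to node/edge input order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .gene_db import GeneSet, GeneTable, _scheme_column, UNTAGGED

__all__ = [
    "MCODEParams",
    "Cluster",
    "EnrichmentCell",
    "build_graph",
    "read_edge_list",
    "write_edge_list",
    "k_core",
    "vertex_weights",
    "find_complexes",
    "fisher_enrichment",
    "overlay_de",
]


@dataclass(frozen=True)
class MCODEParams:
    """MCODE tuning parameters (published defaults)."""

    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ValueError("node_score_cutoff must lie in [0, 1]")
        if self.degree_cutoff < 0 or self.k_core < 0 or self.max_depth < 0:
            raise ValueError("cutoffs must be non-negative")


@dataclass(frozen=True)
class Cluster:
    """A detected complex: member set, density x size score, and its seed."""

    id: int
    members: frozenset[str]
    score: float
    seed_node: str
    flagged: bool = False  # singleton clusters: reported but excluded downstream

    def __len__(self) -> int:
        return len(self.members)

    def as_gene_set(self) -> GeneSet:
        return GeneSet.from_symbols(f"cluster_{self.id}", self.members)


@dataclass(frozen=True)
class EnrichmentCell:
    """One cluster x category Fisher's-exact enrichment entry."""

    cluster_id: int
    category: str
    a: int  # in cluster, in category
    b: int  # in cluster, not in category
    c: int  # not in cluster, in category
    d: int  # neither
    odds_ratio: float
    p: float
    neg_log_p: float


# ---------------------------------------------------------------------------
# Graph construction and IO


def build_graph(edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()) -> nx.Graph:
    """Undirected simple graph from symbol pairs; self-loops rejected."""
    g = nx.Graph()
    g.add_nodes_from(str(n) for n in nodes)
    for u, v in edges:
        u, v = str(u), str(v)
        if u == v:
            raise ValueError(f"self-loop on {u!r}")
        g.add_edge(u, v)
    return g


def read_edge_list(path: str | Path) -> nx.Graph:
    """Two-column TSV edge list, or SIF (node<TAB>relation<TAB>partners)."""
    edges: list[tuple[str, str]] = []
    singletons: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) == 1:
            singletons.append(fields[0])
        elif len(fields) == 2:
            edges.append((fields[0], fields[1]))
        else:  # SIF: source, interaction type, one or more targets
            src = fields[0]
            edges.extend((src, tgt) for tgt in fields[2:] if tgt)
    return build_graph(edges, nodes=singletons)


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    lines = [f"{min(u, v)}\t{max(u, v)}" for u, v in graph.edges()]
    Path(path).write_text("\n".join(sorted(lines)) + "\n")


# ---------------------------------------------------------------------------
# MCODE


def k_core(graph: nx.Graph, k: int) -> nx.Graph:
    """Maximal subgraph in which every node has degree >= k (may be empty)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    return nx.k_core(graph, k)


def _density(graph: nx.Graph) -> float:
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def vertex_weights(graph: nx.Graph, params: MCODEParams = MCODEParams()) -> dict[str, float]:
    """MCODE vertex weighting.

    weight(v) = (highest k-core number within v's closed neighborhood)
                x (edge density of that highest k-core subgraph),
    with weight 0 for vertices of degree < ``degree_cutoff`` and for
    neighborhoods whose highest core falls below 2 (no dense local region).
    """
    weights: dict[str, float] = {}
    for v in graph.nodes:
        if graph.degree(v) < params.degree_cutoff:
            weights[v] = 0.0
            continue
        neighborhood = graph.subgraph([v, *graph.neighbors(v)])
        core_numbers = nx.core_number(neighborhood)
        k_max = max(core_numbers.values())
        if k_max < 2:
            weights[v] = 0.0
            continue
        core_sub = neighborhood.subgraph(
            [n for n, c in core_numbers.items() if c >= k_max]
        )
        weights[v] = k_max * _density(core_sub)
    return weights


def find_complexes(graph: nx.Graph, params: MCODEParams = MCODEParams()) -> list[Cluster]:
    """Detect complexes by seeded expansion in decreasing vertex-weight order.

    From each unvisited seed (ties broken lexicographically), breadth-first
    expansion admits unvisited neighbors whose weight is at least
    ``seed_weight * (1 - node_score_cutoff)``, up to ``max_depth`` hops.
    Post-processing: haircut trims degree-1 members; multi-node candidates
    whose induced subgraph has no ``k_core``-core are dropped; singleton
    candidates are emitted with ``flagged=True``.  Clusters are ranked by
    score = density x size.
    """
    weights = vertex_weights(graph, params)
    order = sorted(weights, key=lambda v: (-weights[v], v))
    visited: set[str] = set()
    raw: list[tuple[str, set[str]]] = []
    for seed in order:
        if seed in visited or weights[seed] <= 0.0:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        visited.add(seed)
        frontier = [seed]
        depth = 0
        while frontier and depth < params.max_depth:
            next_frontier: list[str] = []
            for node in frontier:
                for nbr in sorted(graph.neighbors(node)):
                    if nbr in visited:
                        continue
                    if weights[nbr] >= threshold:
                        visited.add(nbr)
                        members.add(nbr)
                        next_frontier.append(nbr)
            frontier = next_frontier
            depth += 1
        raw.append((seed, members))

    clusters: list[Cluster] = []
    for seed, members in raw:
        sub = graph.subgraph(members).copy()
        if params.haircut and sub.number_of_nodes() > 1:
            # iterative trim of degree-1 members
            changed = True
            while changed:
                leaves = [n for n in sub.nodes if sub.degree(n) == 1]
                changed = bool(leaves)
                sub.remove_nodes_from(leaves)
        if sub.number_of_nodes() == 0:
            continue
        if sub.number_of_nodes() == 1:
            node = next(iter(sub.nodes))
            clusters.append(
                Cluster(id=0, members=frozenset({node}), score=0.0,
                        seed_node=seed, flagged=True)
            )
            continue
        if k_core(sub, params.k_core).number_of_nodes() == 0:
            continue
        score = _density(sub) * sub.number_of_nodes()
        clusters.append(
            Cluster(id=0, members=frozenset(sub.nodes), score=score, seed_node=seed)
        )
    clusters.sort(key=lambda c: (-c.score, min(c.members)))
    return [
        Cluster(id=i + 1, members=c.members, score=c.score,
                seed_node=c.seed_node, flagged=c.flagged)
        for i, c in enumerate(clusters)
    ]


# ---------------------------------------------------------------------------
# Cluster enrichment and DE overlay


def fisher_enrichment(
    cluster: Cluster,
    annotation: GeneTable,
    universe: GeneSet,
    scheme: str = "functional",
) -> list[EnrichmentCell]:
    """Fisher's-exact category enrichment of a cluster over a universe.

    For each category the 2x2 table is (in-cluster & in-category) vs the
    complements over the universe; two-sided p sums hypergeometric table
    probabilities <= the observed table's; the sample odds ratio gets the
    Haldane 0.5 correction only when a zero cell exists.
    """
    labels = annotation.category_of(scheme).reindex(sorted(universe.symbols))
    labels = labels.fillna(UNTAGGED).replace("", UNTAGGED)
    categories = sorted(set(labels) - {UNTAGGED})
    if not categories:
        raise ValueError("no category labels available in the universe")
    members = cluster.members & universe.symbols
    if members != cluster.members:
        missing = cluster.members - universe.symbols
        raise ValueError(f"cluster members outside universe: {sorted(missing)}")
    in_cluster = labels.index.isin(members)
    cells = []
    for cat in categories:
        in_cat = (labels == cat).to_numpy()
        a = int((in_cluster & in_cat).sum())
        b = int((in_cluster & ~in_cat).sum())
        c = int((~in_cluster & in_cat).sum())
        d = int((~in_cluster & ~in_cat).sum())
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if min(a, b, c, d) == 0:
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orr = (a * d) / (b * c)
        cells.append(
            EnrichmentCell(
                cluster_id=cluster.id, category=cat, a=a, b=b, c=c, d=d,
                odds_ratio=float(orr), p=float(p),
                neg_log_p=float(-np.log10(p)) if p > 0 else float("inf"),
            )
        )
    return cells


def enrichment_table(cells: Iterable[EnrichmentCell]) -> pd.DataFrame:
    """Tabular form of enrichment cells (the bubble-plot equivalent)."""
    rows = [
        {
            "cluster": c.cluster_id,
            "category": c.category,
            "a": c.a, "b": c.b, "c": c.c, "d": c.d,
            "odds_ratio": c.odds_ratio,
            "p": c.p,
            "neg_log_p": c.neg_log_p,
        }
        for c in cells
    ]
    return pd.DataFrame(rows)


def overlay_de(
    graph: nx.Graph,
    de_values: Mapping[str, tuple[float, bool]],
    clusters: Iterable[Cluster] = (),
) -> pd.DataFrame:
    """Annotate network nodes with DE log-fold-changes and significance.

    ``de_values`` maps gene -> (log_fc, significant); genes absent from the
    map get null logFC.  When clusters are given, the table joins cluster
    membership so per-cluster up/down/non-significant fractions can be
    summarized directly.
    """
    membership: dict[str, int] = {}
    for cl in clusters:
        for m in cl.members:
            membership[m] = cl.id
    rows = []
    for node in sorted(graph.nodes):
        if node in de_values:
            log_fc, sig = de_values[node]
        else:
            log_fc, sig = float("nan"), False
        rows.append(
            {
                "symbol": node,
                "log_fc": log_fc,
                "significant": bool(sig),
                "cluster": membership.get(node, pd.NA),
            }
        )
    return pd.DataFrame(rows)


def cluster_de_summary(node_table: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster fractions of up-, down- and non-significantly DE nodes."""
    tbl = node_table.dropna(subset=["cluster"])
    out = []
    for cid, grp in tbl.groupby("cluster"):
        n = len(grp)
        sig = grp["significant"] & grp["log_fc"].notna()
        out.append(
            {
                "cluster": cid,
                "n": n,
                "frac_up": float((sig & (grp["log_fc"] > 0)).sum() / n),
                "frac_down": float((sig & (grp["log_fc"] < 0)).sum() / n),
                "frac_nonsig": float((~sig).sum() / n),
            }
        )
    return pd.DataFrame(out)
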