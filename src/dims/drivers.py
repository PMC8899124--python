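"""Driver-gene identification by structural network controllability.

A condition-specific differential co-expression network is built on a
module's genes (edges where the correlation changes strongly between two
conditions), oriented hub -> periphery, and its minimum driver-node set is
obtained from a maximum matching on the bipartite out-copy/in-copy
representation: a directed network is structurally controllable from its
unmatched nodes, and the minimum number of driver nodes is
``N_D = max(N - |M*|, 1)``. Drivers shared by the combination-vs-monoA and
combination-vs-monoB analyses are the synergistic drivers. Five standard
centrality indicators on the undirected view validate that drivers occupy
topologically important positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .network import correlation_matrix
from .study import ExpressionStudy

__all__ = [
    "DirectedInteractionNetwork",
    "DriverSet",
    "DriverValidation",
    "build_condition_network",
    "orient_edges",
    "minimum_driver_set",
    "synergistic_drivers",
    "node_importance",
    "validate_drivers",
]

IMPORTANCE_METRICS = (
    "degree_centrality",
    "eigenvector",
    "betweenness",
    "pagerank",
    "closeness",
)


@dataclass
class DirectedInteractionNetwork:
    """Directed network over a module's genes."""

    nodes: list[str]
    arcs: list[tuple[str, str]]
    provenance: str = ""
    orientation: str = "degree"

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        seen = set()
        for tail, head in self.arcs:
            if tail == head:
                raise ValueError(f"self-loop on {tail!r}")
            if tail not in node_set or head not in node_set:
                raise ValueError(f"arc ({tail}, {head}) uses unknown node")
            if (tail, head) in seen:
                raise ValueError(f"duplicate arc ({tail}, {head})")
            seen.add((tail, head))
        self.nodes = sorted(self.nodes)
        self.arcs = sorted(self.arcs)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs)
        return g

    def undirected(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs)
        return g


def orient_edges(
    edges: list[tuple[str, str]], degrees: dict[str, int]
) -> list[tuple[str, str]]:
    """Orient undirected edges from the higher-degree endpoint to the lower.

    Ties go lexicographically: the smaller node id is the tail. Deterministic
    (output sorted).
    """
    arcs = []
    for u, v in edges:
        du, dv = degrees.get(u, 0), degrees.get(v, 0)
        if du > dv or (du == dv and u < v):
            arcs.append((u, v))
        else:
            arcs.append((v, u))
    return sorted(arcs)


def build_condition_network(
    module_genes,
    study: ExpressionStudy,
    condition_groups: tuple[str, str],
    corr_threshold: float = 0.5,
    orientation: str = "degree",
    provenance: str | None = None,
) -> DirectedInteractionNetwork:
    """Differential co-expression network between two conditions.

    An undirected edge (i, j) is kept when
    ``|corr_A(i, j) - corr_B(i, j)| >= corr_threshold``; edges are then
    oriented hub -> periphery (``orientation='degree'``) or duplicated as two
    opposite arcs (``orientation='bidirectional'``).
    """
    group_a, group_b = condition_groups
    genes = sorted(set(module_genes))
    corr_a = correlation_matrix(study, group_a, genes).to_numpy()
    corr_b = correlation_matrix(study, group_b, genes).to_numpy()
    delta = np.abs(corr_a - corr_b)
    np.fill_diagonal(delta, 0.0)
    ii, jj = np.where(np.triu(delta >= corr_threshold, k=1))
    edges = [(genes[i], genes[j]) for i, j in zip(ii, jj)]
    if provenance is None:
        provenance = f"{group_a}_vs_{group_b}"
    if not edges:
        warnings.warn(
            f"differential network {provenance}: no edge passes "
            f"threshold {corr_threshold}"
        )
        return DirectedInteractionNetwork(genes, [], provenance, orientation)
    if orientation == "bidirectional":
        arcs = sorted([(u, v) for u, v in edges] + [(v, u) for u, v in edges])
    elif orientation == "degree":
        deg: dict[str, int] = {g: 0 for g in genes}
        for u, v in edges:
            deg[u] += 1
            deg[v] += 1
        arcs = orient_edges(edges, deg)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return DirectedInteractionNetwork(genes, arcs, provenance, orientation)


@dataclass
class DriverSet:
    """Minimum driver-node set of a directed network."""

    drivers: list[str]
    matching: list[tuple[str, str]]  # matched arcs (tail, head)
    n_nodes: int

    @property
    def matching_size(self) -> int:
        return len(self.matching)

    @property
    def n_d(self) -> int:
        return max(self.n_nodes - self.matching_size, 1)


def minimum_driver_set(net: DirectedInteractionNetwork) -> DriverSet:
    """Minimum driver set via maximum bipartite matching.

    Each node is split into an out-copy and an in-copy; every arc (u, v)
    becomes a bipartite edge out(u) - in(v). Nodes whose in-copy is unmatched
    in a maximum matching are the drivers; when the matching is perfect one
    arbitrary node (the smallest id) is the single driver. Arc ordering is
    canonical, so the result is reproducible.
    """
    if net.n_nodes == 0:
        raise ValueError("empty node set")
    g = nx.Graph()
    outs = [("out", u) for u in net.nodes]
    ins = [("in", u) for u in net.nodes]
    g.add_nodes_from(outs, bipartite=0)
    g.add_nodes_from(ins, bipartite=1)
    for tail, head in net.arcs:
        g.add_edge(("out", tail), ("in", head))
    matching = nx.bipartite.hopcroft_karp_matching(g, top_nodes=outs)
    matched_arcs = sorted(
        (u[1], v[1]) for u, v in matching.items() if u[0] == "out"
    )
    matched_heads = {head for _, head in matched_arcs}
    drivers = [u for u in net.nodes if u not in matched_heads]
    if not drivers:  # perfect matching: one driver still needed
        drivers = [net.nodes[0]]
    return DriverSet(drivers=drivers, matching=matched_arcs, n_nodes=net.n_nodes)


def possible_drivers(net: DirectedInteractionNetwork) -> list[str]:
    """All nodes that belong to at least one minimum driver set.

    Maximum matchings are not unique, so the minimum driver set is not
    either. A node is a *possible* driver iff some maximum matching leaves
    its in-copy unmatched; these are found exactly by alternating-path
    reachability from the unmatched in-copies of one maximum matching
    (an in-copy v is avoidable iff an even alternating path connects an
    unmatched in-copy to v). When the matching is perfect every node can
    serve as the single required driver.
    """
    base = minimum_driver_set(net)
    if base.matching_size == net.n_nodes:
        return list(net.nodes)
    matched_head_of = {tail: head for tail, head in base.matching}
    in_arcs: dict[str, list[str]] = {u: [] for u in net.nodes}
    for tail, head in net.arcs:
        in_arcs[head].append(tail)
    unmatched = [u for u in net.nodes if u not in {h for _, h in base.matching}]
    # BFS over in-copies: from head u step to head v when some tail t has a
    # non-matching arc t->u and its matching arc is t->v
    avoidable = set(unmatched)
    frontier = list(unmatched)
    while frontier:
        u = frontier.pop()
        for t in in_arcs[u]:
            if matched_head_of.get(t) == u:
                continue  # matching arc, not usable as the free step
            v = matched_head_of.get(t)
            if v is not None and v not in avoidable:
                avoidable.add(v)
                frontier.append(v)
    return sorted(avoidable)


def synergistic_drivers(
    combo_vs_mono_a: DriverSet | set[str], combo_vs_mono_b: DriverSet | set[str]
) -> list[str]:
    """Drivers common to both combination-vs-monotherapy analyses."""
    a = set(combo_vs_mono_a.drivers if isinstance(combo_vs_mono_a, DriverSet) else combo_vs_mono_a)
    b = set(combo_vs_mono_b.drivers if isinstance(combo_vs_mono_b, DriverSet) else combo_vs_mono_b)
    inter = sorted(a & b)
    if not inter:
        warnings.warn("driver sets are disjoint: no synergistic drivers")
    return inter


def node_importance(net: DirectedInteractionNetwork) -> pd.DataFrame:
    """Five centrality indicators on the undirected view of the network.

    Degree centrality (degree / (N-1)), eigenvector centrality (power
    iteration, tol 1e-8), betweenness (normalized by pair count), PageRank
    (damping 0.85, sums to 1) and closeness (reachable-set scaling for
    disconnected graphs). Edgeless graphs get uniform eigenvector/PageRank
    by convention.
    """
    if net.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    g = net.undirected()
    n = g.number_of_nodes()
    deg = nx.degree_centrality(g)
    btw = nx.betweenness_centrality(g, normalized=True)
    clo = nx.closeness_centrality(g)
    if g.number_of_edges() == 0:
        eig = {u: 1.0 / np.sqrt(n) for u in g}
        pr = {u: 1.0 / n for u in g}
    else:
        pr = nx.pagerank(g, alpha=0.85)
        try:
            eig = nx.eigenvector_centrality(g, max_iter=5000, tol=1e-8)
        except nx.PowerIterationFailedConvergence:
            eig = nx.eigenvector_centrality_numpy(g)
    table = pd.DataFrame(
        {
            "degree_centrality": deg,
            "eigenvector": eig,
            "betweenness": btw,
            "pagerank": pr,
            "closeness": clo,
        }
    ).loc[net.nodes]
    table.index.name = "gene_id"
    return table


@dataclass
class DriverValidation:
    """Rank-sum comparison of drivers vs non-drivers per centrality metric."""

    p_values: dict[str, float]
    stars: dict[str, str]
    deciles: pd.DataFrame = field(repr=False)  # per node x metric, 1..10 (10 = top)
    n_drivers: int = 0
    n_non_drivers: int = 0


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def rank_sum_greater(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided Mann-Whitney p for x stochastically greater than y.

    Exact for small tie-free samples, normal approximation with tie
    correction otherwise; identical constant samples give p = 1.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if np.all(x == x[0]) and np.all(y == x[0]):
        return 1.0
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="greater", method=method).pvalue)


def validate_drivers(table: pd.DataFrame, drivers) -> DriverValidation:
    """Compare drivers against non-drivers on every importance metric.

    Per metric: one-sided rank-sum p (drivers > non-drivers) with
    significance stars, plus each node's decile of the metric (decile 10 =
    top of the distribution).
    """
    drivers = set(drivers)
    is_driver = table.index.to_series().isin(drivers)
    if is_driver.all() or not is_driver.any():
        raise ValueError(
            "degenerate split: drivers and non-drivers must both be nonempty"
        )
    p_values, stars = {}, {}
    deciles = pd.DataFrame(index=table.index)
    for metric in IMPORTANCE_METRICS:
        vals = table[metric]
        p = rank_sum_greater(vals[is_driver].to_numpy(), vals[~is_driver].to_numpy())
        p_values[metric] = p
        stars[metric] = _stars(p)
        pct = vals.rank(method="average", pct=True)
        deciles[metric] = np.ceil(pct * 10).clip(1, 10).astype(int)
    deciles["is_driver"] = is_driver
    return DriverValidation(
        p_values=p_values,
        stars=stars,
        deciles=deciles,
        n_drivers=int(is_driver.sum()),
        n_non_drivers=int((~is_driver).sum()),
    )
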