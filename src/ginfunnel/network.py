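"""Thresholded Pearson correlation networks between candidate genes and a
key-enzyme panel, final/key candidate calling, and trait-group network
comparison.

An edge joins two genes when the two-sided t-transform p of their Pearson
correlation is at or below the threshold.  "Tight interaction with the
enzyme panel" is operationalized as at least one surviving direct edge to
an enzyme-panel gene; a stricter minimum edge count is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix
from .wgcna import correlation_pvalue

log = logging.getLogger(__name__)


@dataclass
class NetworkGraph:
    graph: nx.Graph  # nodes carry role=candidate|enzyme; edges carry r, p
    threshold: float
    excluded: list[str] = field(default_factory=list)  # constant-expression genes

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def connected_nodes(self) -> list[str]:
        return [n for n in self.graph.nodes if self.graph.degree(n) > 0]

    def edge_table(self) -> pd.DataFrame:
        rows = [(a, b, d["r"], d["p"]) for a, b, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "p"]).sort_values(
            ["gene_a", "gene_b"]
        ).reset_index(drop=True)


def build_network(
    expr: ExpressionMatrix,
    node_set: list[str],
    p_max: float,
    roles: dict[str, str] | None = None,
) -> NetworkGraph:
    """Pairwise Pearson network over ``node_set`` with edges at p <= p_max.

    Isolated nodes stay in the node list (flagged by zero degree); genes
    with constant expression have undefined correlations and are excluded
    from edges but kept as flagged nodes.
    """
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples for a correlation network")
    sub = expr.subset_genes(node_set)
    missing = set(node_set) - set(sub.genes)
    if missing:
        log.warning("node set genes absent from expression matrix: %s", sorted(missing)[:5])
    x = sub.values
    n = sub.n_samples
    sd = x.std(axis=1)
    constant = [g for g, s in zip(sub.genes, sd) if s == 0]
    G = nx.Graph()
    for g in sub.genes:
        role = (roles or {}).get(g, "candidate")
        G.add_node(g, role=role, constant=g in set(constant))
    r = np.corrcoef(x)
    for i in range(len(sub.genes)):
        for j in range(i + 1, len(sub.genes)):
            if sd[i] == 0 or sd[j] == 0:
                continue
            rij = float(r[i, j])
            p = correlation_pvalue(rij, n)
            if p <= p_max:
                G.add_edge(sub.genes[i], sub.genes[j], r=rij, p=p)
    return NetworkGraph(graph=G, threshold=p_max, excluded=constant)


def call_candidates(
    expr: ExpressionMatrix,
    candidate_ids: list[str],
    enzyme_ids: list[str],
    p_confirm: float = 0.05,
    p_key: float = 1e-6,
    min_edges: int = 1,
) -> tuple[list[str], list[str], dict[float, NetworkGraph]]:
    """Confirmed and key candidates by edge-connectivity to the enzyme panel.

    A candidate is confirmed when it keeps >= min_edges direct edges to
    enzyme genes at p <= p_confirm, and key when it still does at
    p <= p_key.  Returns (confirmed, key, networks-by-threshold).
    """
    if not enzyme_ids:
        raise ValueError("enzyme panel is empty")
    roles = {g: "candidate" for g in candidate_ids}
    roles.update({g: "enzyme" for g in enzyme_ids})
    node_set = list(dict.fromkeys(list(candidate_ids) + list(enzyme_ids)))
    networks: dict[float, NetworkGraph] = {}
    called: dict[float, list[str]] = {}
    for p_max in (p_confirm, p_key):
        net = build_network(expr, node_set, p_max, roles)
        networks[p_max] = net
        enz = set(enzyme_ids)
        keep = []
        for g in candidate_ids:
            if g not in net.graph:
                continue
            n_enz_edges = sum(1 for nb in net.graph.neighbors(g) if nb in enz)
            if n_enz_edges >= min_edges:
                keep.append(g)
        called[p_max] = keep
    return called[p_confirm], called[p_key], networks


def group_network_comparison(
    expr: ExpressionMatrix,
    trait: pd.Series,
    node_set: list[str],
    n_groups: int = 3,
    group_size: int = 14,
    p_max: float = 0.05,
) -> tuple[dict[str, NetworkGraph], pd.DataFrame]:
    """High/Mid/Low trait-group networks and a node/edge summary.

    Samples are ranked by trait (ties resolve deterministically by sample
    id); the bottom, centered-middle and top ``group_size`` samples form
    the Low/Mid/High groups.  The summary counts nodes with >= 1 edge,
    total nodes, edges, and each group's unique connected genes and edges.
    """
    if n_groups != 3:
        raise ValueError("comparison is defined for the three-group design")
    samples = [s for s in trait.index if s in set(expr.samples)]
    if len(samples) < n_groups * group_size:
        raise ValueError(
            f"need at least {n_groups * group_size} samples, got {len(samples)}"
        )
    ranked = sorted(samples, key=lambda s: (trait[s], s))
    low = ranked[:group_size]
    high = ranked[-group_size:]
    mid_start = (len(ranked) - group_size) // 2
    mid = ranked[mid_start : mid_start + group_size]

    nets: dict[str, NetworkGraph] = {}
    for name, members in (("Low", low), ("Mid", mid), ("High", high)):
        nets[name] = build_network(expr.subset_samples(members), node_set, p_max)

    edge_sets = {
        name: {tuple(sorted(e)) for e in net.graph.edges()} for name, net in nets.items()
    }
    node_sets = {name: set(net.connected_nodes()) for name, net in nets.items()}
    rows = []
    for name, net in nets.items():
        others_nodes = set().union(*(node_sets[o] for o in nets if o != name))
        others_edges = set().union(*(edge_sets[o] for o in nets if o != name))
        rows.append(
            (
                name,
                len(node_sets[name]),
                net.n_nodes,
                net.n_edges,
                len(node_sets[name] - others_nodes),
                len(edge_sets[name] - others_edges),
            )
        )
    summary = pd.DataFrame(
        rows,
        columns=["group", "nodes_connected", "nodes_total", "edges", "unique_genes", "unique_edges"],
    )
    return nets, summary


def write_graphml(net: NetworkGraph, path: str) -> None:
    nx.write_graphml(net.graph, path)
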