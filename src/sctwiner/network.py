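"""Signed gene co-expression networks over a selected signature.

Nodes are the signature genes; an edge joins two genes whose expression
correlation within one cell population exceeds the display threshold in
magnitude (|r| > 0.2 by default). Edge sign and strength record the
correlation's direction and magnitude, so the networks of different
populations can be compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSignature
from .weights import correlation_matrix


@dataclass
class GeneNetwork:
    """Thresholded signed correlation network of one population."""

    graph: nx.Graph
    population_label: str
    threshold: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [
            (u, v, d["correlation"]) for u, v, d in self.graph.edges(data=True)
        ]

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return {tuple(sorted((u, v))) for u, v in self.graph.edges}

    def to_edge_list(self) -> pd.DataFrame:
        rows = [
            {
                "gene_i": u,
                "gene_j": v,
                "correlation": d["correlation"],
                "sign": d["sign"],
                "strength": d["strength"],
            }
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(
            rows, columns=["gene_i", "gene_j", "correlation", "sign", "strength"]
        )


def build_network(
    expr: ExpressionMatrix,
    genes: GeneSignature | list[str],
    threshold: float = 0.2,
    *,
    population_label: str = "",
    selected_by: dict[str, str] | None = None,
) -> GeneNetwork:
    """Correlation network of the signature genes within one population.

    Edges are kept iff |r| > threshold (strict); isolated signature genes
    remain as nodes. ``selected_by`` optionally annotates nodes with the
    regularizer(s) that picked them (both / twiner_only / en_only).
    """
    gene_ids = genes.gene_ids if isinstance(genes, GeneSignature) else list(genes)
    present = [g for g in gene_ids if g in set(expr.gene_ids)]
    if len(present) < 2:
        raise ValueError("need at least 2 signature genes present in the matrix")
    if expr.n_cells < 3:
        raise ValueError("need at least 3 cells to build a network")
    sub = expr.subset_genes(present)
    corr = correlation_matrix(sub, population_label=population_label).matrix

    g = nx.Graph()
    for gene in present:
        attrs = {"selected_by": selected_by.get(gene, "")} if selected_by else {}
        g.add_node(gene, **attrs)
    for a, b in combinations(range(len(present)), 2):
        r = float(corr[a, b])
        if abs(r) > threshold:
            u, v = sorted((present[a], present[b]))
            g.add_edge(
                u, v, correlation=r, sign="+" if r > 0 else "-", strength=abs(r)
            )
    return GeneNetwork(g, population_label, threshold)


def compare_networks(networks: list[GeneNetwork]) -> pd.DataFrame:
    """Pairwise edge-set Jaccard indices and sign agreement on shared edges."""
    if len(networks) < 2:
        raise ValueError("need at least two networks to compare")
    node_sets = [set(n.nodes) for n in networks]
    if any(s != node_sets[0] for s in node_sets[1:]):
        raise ValueError("networks must share an identical node set")
    rows = []
    for i, j in combinations(range(len(networks)), 2):
        ei, ej = networks[i].edge_set, networks[j].edge_set
        union = ei | ej
        inter = ei & ej
        jac = len(inter) / len(union) if union else 1.0
        if inter:
            agree = sum(
                networks[i].graph.edges[e]["sign"] == networks[j].graph.edges[e]["sign"]
                for e in inter
            ) / len(inter)
        else:
            agree = float("nan")
        rows.append(
            {
                "network_a": networks[i].population_label or str(i),
                "network_b": networks[j].population_label or str(j),
                "jaccard": jac,
                "sign_agreement": agree,
                "n_edges_a": len(ei),
                "n_edges_b": len(ej),
                "n_shared": len(inter),
            }
        )
    return pd.DataFrame(rows)


def write_edge_list(net: GeneNetwork, path: str | Path) -> None:
    net.to_edge_list().to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_graphml(net: GeneNetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph, path)
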