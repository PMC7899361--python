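"""Signed differential correlation networks and core-metabolite detection.

Nodes are metabolites incident to at least one significantly differentially
correlated pair; edges carry the sign of r_diff (positive: the pair is more
strongly correlated in plasma; negative: in joint fluid). Node importance is
scored by degree, normalized shortest-path betweenness and within-component
closeness, and "core metabolites" (hubs) are nodes jointly high in degree
and at least one centrality.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .diffcorr import DiffCorrResult

logger = logging.getLogger(__name__)

EXPORT_FORMATS = ("graphml", "sif", "edge-table")


def build_network(
    result: DiffCorrResult, alpha: float | None = None, tier: str = "nominal"
) -> nx.Graph:
    """Graph over the pairs significant at the chosen tier.

    ``tier="nominal"`` uses the per-pair permutation flags (optionally
    re-thresholded at ``alpha``); ``tier="adjusted"`` uses the
    multiple-testing-corrected flags. Only metabolites incident to at least
    one edge become nodes, so isolated metabolites never appear.
    """
    table = result.table
    if "p_perm" not in table:
        raise ValueError("p-values not computed; run permutation_pvalues first")
    if tier == "nominal":
        mask = table["p_perm"] < (alpha if alpha is not None else result.alpha)
    elif tier == "adjusted":
        if "sig_adjusted" not in table:
            raise ValueError("adjusted flags missing; run adjust_significance first")
        mask = table["sig_adjusted"].to_numpy(bool)
    else:
        raise ValueError(f"unknown tier {tier!r}; use 'nominal' or 'adjusted'")

    G = nx.Graph(tier=tier, stratum=result.stratum)
    sig = table[mask]
    if sig.empty:
        logger.warning("no significant pairs at tier %r; returning empty network", tier)
        return G
    for row in sig.itertuples(index=False):
        G.add_edge(
            row.metabolite_i,
            row.metabolite_j,
            r_diff=float(row.r_diff),
            sign="positive" if row.r_diff >= 0 else "negative",
            p_perm=float(row.p_perm),
        )
    return G


def mean_degree(G: nx.Graph) -> float:
    """2|E| / |N|; zero for the empty graph."""
    n = G.number_of_nodes()
    return 0.0 if n == 0 else 2.0 * G.number_of_edges() / n


def centralities(G: nx.Graph) -> nx.Graph:
    """Attach degree, betweenness and closeness to every node (in place).

    All edges count as unit length and signs are ignored for paths.
    Betweenness is normalized by (n-1)(n-2)/2; closeness uses the
    within-component definition scaled by (component size - 1)/(n - 1), the
    usual convention for disconnected graphs.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("cannot compute centralities of an empty network")
    betweenness = nx.betweenness_centrality(G, normalized=True)
    closeness = nx.closeness_centrality(G, wf_improved=True)
    for node in G.nodes:
        G.nodes[node]["degree"] = int(G.degree[node])
        G.nodes[node]["betweenness"] = float(betweenness[node])
        G.nodes[node]["closeness"] = float(closeness[node])
    return G


def identify_hubs(
    G: nx.Graph,
    degree_quantile: float = 0.9,
    centrality_quantile: float = 0.9,
    combine: str = "or",
    ties: str = "include",
) -> nx.Graph:
    """Flag core metabolites: high degree AND high centrality (in place).

    A node is a hub iff its degree reaches the ``degree_quantile`` of all
    node degrees and its betweenness/closeness reach the
    ``centrality_quantile`` in at least one (``combine="or"``) or both
    (``combine="and"``) of the two centralities. With ``ties="include"``
    values equal to the quantile qualify; ``ties="strict"`` requires strict
    exceedance (so a perfectly regular graph has no hubs).
    """
    if G.number_of_nodes() == 0:
        raise ValueError("cannot identify hubs in an empty network")
    if combine not in ("or", "and"):
        raise ValueError(f"combine must be 'or' or 'and', got {combine!r}")
    if ties not in ("include", "strict"):
        raise ValueError(f"ties must be 'include' or 'strict', got {ties!r}")
    if "degree" not in next(iter(G.nodes.values())):
        centralities(G)
    nodes = list(G.nodes)
    deg = np.array([G.nodes[v]["degree"] for v in nodes], dtype=float)
    bet = np.array([G.nodes[v]["betweenness"] for v in nodes])
    clo = np.array([G.nodes[v]["closeness"] for v in nodes])
    cmp_ = np.greater_equal if ties == "include" else np.greater
    # exclusive-type (Weibull) quantiles keep the cutoff above the bulk on
    # heavy-tailed degree/centrality distributions, so "high" means the tail
    high_deg = cmp_(deg, np.quantile(deg, degree_quantile, method="weibull"))
    high_bet = cmp_(bet, np.quantile(bet, centrality_quantile, method="weibull"))
    high_clo = cmp_(clo, np.quantile(clo, centrality_quantile, method="weibull"))
    high_cen = (high_bet | high_clo) if combine == "or" else (high_bet & high_clo)
    for v, flag in zip(nodes, high_deg & high_cen):
        G.nodes[v]["is_hub"] = bool(flag)
    return G


def hub_list(G: nx.Graph) -> list[str]:
    return sorted(v for v, d in G.nodes(data=True) if d.get("is_hub"))


def node_table(G: nx.Graph) -> pd.DataFrame:
    """Per-node centrality table (sorted by id) for reporting/export."""
    rows = [
        {
            "metabolite": v,
            "degree": d.get("degree", np.nan),
            "betweenness": d.get("betweenness", np.nan),
            "closeness": d.get("closeness", np.nan),
            "is_hub": bool(d.get("is_hub", False)),
        }
        for v, d in sorted(G.nodes(data=True))
    ]
    return pd.DataFrame(
        rows, columns=["metabolite", "degree", "betweenness", "closeness", "is_hub"]
    )


def _canonical(G: nx.Graph) -> nx.Graph:
    """Copy with lexicographically sorted nodes/edges for diffable output."""
    H = nx.Graph(**G.graph)
    for v in sorted(G.nodes, key=str):
        H.add_node(v, **G.nodes[v])
    for u, v in sorted((tuple(sorted((str(a), str(b)))) for a, b in G.edges)):
        H.add_edge(u, v, **G.edges[u, v])
    return H


def export_network(G: nx.Graph, path: str | Path, fmt: str = "graphml") -> Path:
    """Write the network as GraphML, SIF (+ node attributes) or an edge table.

    SIF edges use the interaction types ``pos_dc`` / ``neg_dc``; a companion
    ``<stem>.nodes.tsv`` carries the node attributes. GraphML written here
    round-trips through :func:`read_graphml` exactly.
    """
    if fmt not in EXPORT_FORMATS:
        raise ValueError(f"unknown format {fmt!r}; use one of {EXPORT_FORMATS}")
    path = Path(path)
    H = _canonical(G)
    if fmt == "graphml":
        nx.write_graphml(H, path, named_key_ids=True)
    elif fmt == "sif":
        with path.open("w") as fh:
            for u, v, d in H.edges(data=True):
                kind = "pos_dc" if d.get("sign") == "positive" else "neg_dc"
                fh.write(f"{u}\t{kind}\t{v}\n")
        node_table(H).to_csv(path.with_suffix(".nodes.tsv"), sep="\t", index=False)
    else:  # edge-table
        rows = [
            {"metabolite_i": u, "metabolite_j": v, **d}
            for u, v, d in H.edges(data=True)
        ]
        cols = ["metabolite_i", "metabolite_j", "r_diff", "sign", "p_perm"]
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    return path


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)
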