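"""Spearman correlation network over monthly-aggregated variables.

Monthly means of bacterial abundance, particulate matter, meteorology and
air-mass pathway frequencies are correlated pairwise (Spearman rank
correlation, pairwise-complete observations); edges significant at the
chosen alpha form an undirected network whose communities and focal
subnetworks summarise which environmental factors travel together with
the airborne bacterial population.  Near-duplicate variables are pruned
greedily before network construction so a cluster of interchangeable
measurements does not dominate the graph.  Exports are Cytoscape
compatible (SIF and GraphML).
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "spearman_matrix",
    "prune_collinear",
    "build_network",
    "find_modules",
    "ego_subnetwork",
    "write_sif",
    "write_graphml",
    "write_edge_csv",
]

MIN_PAIRS = 4


def spearman_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Spearman correlations with two-sided p-values.

    Ties receive average ranks; p-values come from the t approximation.
    Pairs with fewer than four complete observations, or with a constant
    variable, are reported as NaN.  The diagonal is 1 with p = 0.
    """
    cols = list(table.columns)
    k = len(cols)
    rho = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    data = table.to_numpy(dtype=float)
    for i in range(k):
        rho[i, i] = 1.0
        pval[i, i] = 0.0
        for j in range(i + 1, k):
            ok = ~(np.isnan(data[:, i]) | np.isnan(data[:, j]))
            if ok.sum() < MIN_PAIRS:
                continue
            x, y = data[ok, i], data[ok, j]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r, p = scipy.stats.spearmanr(x, y)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    return (pd.DataFrame(rho, index=cols, columns=cols),
            pd.DataFrame(pval, index=cols, columns=cols))


def prune_collinear(table: pd.DataFrame,
                    threshold: float = 0.8) -> tuple[list[str], dict[str, str]]:
    """Greedy collinearity pruning at |rho| > threshold.

    Variables are scanned in column order; a variable whose absolute
    Spearman correlation with an already-kept variable exceeds the
    threshold is dropped.  Returns the kept column list and a mapping from
    each dropped variable to the keeper that excluded it.
    """
    rho, _ = spearman_matrix(table)
    kept: list[str] = []
    dropped: dict[str, str] = {}
    for col in table.columns:
        keeper = None
        for other in kept:
            r = rho.loc[col, other]
            if np.isfinite(r) and abs(r) > threshold:
                keeper = other
                break
        if keeper is None:
            kept.append(col)
        else:
            dropped[col] = keeper
    return kept, dropped


def build_network(rho: pd.DataFrame, p: pd.DataFrame, alpha: float = 0.05,
                  node_classes: dict[str, str] | None = None) -> nx.Graph:
    """Keep edges with p < alpha; sign and weight come from rho.

    Node attribute ``cls`` carries a variable-class tag (population, PM,
    meteorology, pathway, ...) for downstream styling; edge attributes are
    ``rho``, ``p`` and ``sign`` ("+"/"-").
    """
    if list(rho.columns) != list(p.columns):
        raise ValueError("rho and p matrices are not conformable")
    node_classes = node_classes or {}
    g = nx.Graph()
    for col in rho.columns:
        g.add_node(col, cls=node_classes.get(col, "other"))
    cols = list(rho.columns)
    for i, u in enumerate(cols):
        for v in cols[i + 1:]:
            r, pv = rho.loc[u, v], p.loc[u, v]
            if np.isfinite(r) and np.isfinite(pv) and pv < alpha:
                g.add_edge(u, v, rho=float(r), p=float(pv),
                           sign="+" if r >= 0 else "-")
    return g


def find_modules(net: nx.Graph) -> dict[str, int]:
    """Deterministic greedy-modularity community assignment.

    Communities are found on the positive-correlation subgraph weighted by
    |rho| (negative edges are kept in the network for display but do not
    define cohesion).  Modules are numbered by their lexicographically
    smallest member so the labelling is invariant to node insertion order.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    pos = nx.Graph()
    pos.add_nodes_from(sorted(net.nodes))
    for u, v, d in net.edges(data=True):
        if d.get("rho", 0) > 0:
            pos.add_edge(u, v, weight=abs(d["rho"]))
    communities = nx.community.greedy_modularity_communities(pos, weight="weight")
    ordered = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    return {node: idx for idx, members in enumerate(ordered) for node in members}


def ego_subnetwork(net: nx.Graph, focal: list[str]) -> nx.Graph:
    """Focal nodes plus their direct neighbours.

    Edges between two non-focal nodes are removed: the subnetwork shows how
    the environment connects to the focal variables, not how environmental
    attributes inter-correlate.
    """
    for node in focal:
        if node not in net:
            raise KeyError(f"unknown focal node {node!r}")
    keep = set(focal)
    for node in focal:
        keep.update(net.neighbors(node))
    sub = net.subgraph(keep).copy()
    focal_set = set(focal)
    for u, v in list(sub.edges):
        if u not in focal_set and v not in focal_set:
            sub.remove_edge(u, v)
    return sub


def write_sif(net: nx.Graph, path) -> None:
    """Simple interaction format: ``source <sign-tag> target`` per edge."""
    with open(path, "w") as fh:
        for u, v, d in sorted(net.edges(data=True)):
            tag = "pos" if d.get("sign", "+") == "+" else "neg"
            fh.write(f"{u}\t{tag}\t{v}\n")
        for node in sorted(nx.isolates(net)):
            fh.write(f"{node}\n")


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path)


def write_edge_csv(net: nx.Graph, path) -> None:
    rows = [{"source": u, "target": v, **d}
            for u, v, d in sorted(net.edges(data=True))]
    pd.DataFrame(rows).to_csv(path, index=False)
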