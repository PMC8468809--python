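"""Pathway-merged functional networks: hubs, betweenness, degree statistics.

Pathways are consumed as generic named edge lists.  Every pathway containing
at least one differentially expressed gene is merged into a single undirected
network whose nodes are gene products; hubs are nodes with degree above a
threshold (default > 20) and betweenness centrality is normalized to [0, 1]
by the number of node pairs.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

HUB_DEGREE = 20


def merge_pathway_graphs(
    pathways: Mapping[str, Sequence[tuple[str, str]]],
    de_genes: Iterable[str],
) -> nx.Graph:
    """Union of all pathways whose node set contains a DE gene.

    Shared nodes are merged by identifier; duplicate edges collapse and
    self-loops are dropped.  Empty pathway edge lists are skipped.
    """
    de = set(de_genes)
    graph = nx.Graph()
    for name, edges in pathways.items():
        if not edges:
            continue
        nodes = {n for e in edges for n in e[:2]}
        if not nodes & de:
            continue
        for a, b in ((e[0], e[1]) for e in edges):
            if a != b:
                graph.add_edge(a, b)
    return graph


def node_metrics(graph: nx.Graph, hub_degree: int = HUB_DEGREE) -> pd.DataFrame:
    """Degree, normalized betweenness and hub flag for every node.

    Betweenness is shortest-path betweenness divided by (n-1)(n-2)/2 with the
    global node count n, so values lie in [0, 1]; hubs have degree strictly
    above ``hub_degree``.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    betweenness = nx.betweenness_centrality(graph, normalized=True)
    rows = [
        {
            "node": n,
            "degree": graph.degree(n),
            "betweenness": betweenness[n],
            "is_hub": graph.degree(n) > hub_degree,
        }
        for n in graph.nodes
    ]
    return pd.DataFrame(rows).set_index("node")


def first_neighbor_subnetwork(graph: nx.Graph, seeds: Iterable[str]) -> nx.Graph:
    """Induced subgraph on the seeds plus their direct neighbors.

    Seeds absent from the graph are ignored.  The induced subgraph keeps all
    edges internal to the node set, including neighbor-neighbor edges.
    """
    present = [s for s in seeds if s in graph]
    nodes = set(present)
    for s in present:
        nodes.update(graph.neighbors(s))
    return graph.subgraph(nodes).copy()


def powerlaw_check(degrees: Sequence[int]) -> tuple[float, float]:
    """Log-log least-squares fit of the degree distribution.

    Returns ``(exponent, r_squared)`` where the exponent is the slope of
    log(frequency) vs log(degree) over degrees with nonzero frequency.
    Requires at least 3 distinct positive degree values.
    """
    deg = np.asarray(degrees, dtype=int)
    deg = deg[deg > 0]
    values, counts = np.unique(deg, return_counts=True)
    if values.size < 3:
        raise ValueError(
            "power-law fit needs >= 3 distinct positive degree values"
        )
    x = np.log(values.astype(float))
    y = np.log(counts.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), r2


def degree_permutation_test(
    graph: nx.Graph,
    set_a: Sequence[str],
    set_b: Sequence[str],
    iterations: int = 1000,
    seed: int = 0,
    statistic: str = "mean_difference",
) -> tuple[float, float]:
    """Two-sided permutation test comparing degrees of two node sets.

    The observed statistic is the difference in mean degree (A - B); the null
    shuffles the combined label vector.  ``statistic='rank_sum'`` uses the
    rank-sum of set A instead.  Returns ``(observed_statistic, p_value)``
    with the add-one permutation p-value.
    """
    a = list(set_a)
    b = list(set_b)
    if not a or not b:
        raise ValueError("both node sets must be nonempty")
    if set(a) & set(b):
        raise ValueError("node sets must be disjoint")
    missing = [n for n in a + b if n not in graph]
    if missing:
        raise ValueError(f"nodes absent from graph: {missing[:5]}")
    deg = np.array([graph.degree(n) for n in a + b], dtype=float)
    n_a = len(a)

    if statistic == "mean_difference":
        def stat(d: np.ndarray) -> float:
            return float(d[:n_a].mean() - d[n_a:].mean())
    elif statistic == "rank_sum":
        def stat(d: np.ndarray) -> float:
            ranks = pd.Series(d).rank().to_numpy()
            return float(ranks[:n_a].sum())
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    obs = stat(deg)
    center = 0.0
    if statistic == "rank_sum":
        center = n_a * (len(deg) + 1) / 2.0
    rng = np.random.default_rng(seed)
    exceed = 0
    d = deg.copy()
    for _ in range(iterations):
        rng.shuffle(d)
        if abs(stat(d) - center) >= abs(obs - center):
            exceed += 1
    p = (1 + exceed) / (1 + iterations)
    return obs, p


def degree_quantile(graph: nx.Graph, nodes: Sequence[str], q: float = 0.9) -> float:
    """Inclusive empirical quantile of the degrees of a node set."""
    deg = np.array([graph.degree(n) for n in nodes if n in graph], dtype=float)
    if deg.size == 0:
        raise ValueError("no listed nodes are present in the graph")
    return float(np.quantile(deg, q, method="inverted_cdf"))
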