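"""Node metrics on the population graph and their edge-permutation nulls.

Edge weights on a population graph are genetic *distances*, so shortest-path
metrics (closeness, betweenness) use them directly, while eigenvector
centrality — which rewards strong connections — uses similarity weights
``1/w``.  Higher closeness therefore means higher genetic distance from the
rest of the network; higher degree/betweenness/eigenvector centrality mark
gene-flow hubs.

Null models randomize topology while holding the node set fixed and
re-dealing the observed edge-weight multiset onto the rewired edges, so the
metric scale stays comparable between observed and null graphs:

``edge_permutation``
    a uniformly random simple graph with the same node set and edge count;
``degree_preserving``
    double-edge swaps preserving every node's degree exactly.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.sparse.csgraph import shortest_path

from .core import DegenerateInputError, PermutationResult, spawn_rng

__all__ = [
    "node_metrics",
    "metric_permutation_test",
    "edge_permutation_null",
    "degree_preserving_null",
]

METRICS = ("degree", "closeness", "betweenness", "eigenvector")


def _distance_matrix(graph: nx.Graph, weighted: bool) -> tuple[list, np.ndarray]:
    nodes = list(graph.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    for u, v, d in graph.edges(data=True):
        w = float(d.get("weight", 1.0)) if weighted else 1.0
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = w
    return nodes, shortest_path(A, method="D", directed=False, unweighted=False)


def _closeness(graph: nx.Graph, weighted: bool) -> dict:
    nodes, D = _distance_matrix(graph, weighted)
    out: dict = {}
    for i, v in enumerate(nodes):
        d = D[i]
        reach = np.isfinite(d) & (np.arange(d.size) != i)
        if not reach.any() or d[reach].sum() == 0:
            out[v] = np.nan
        else:
            out[v] = float(1.0 / d[reach].mean())
    return out


def _eigenvector(graph: nx.Graph, weighted: bool) -> dict:
    """Leading-eigenvector score on similarity (1/w) weights, unit-norm per
    connected component; isolated nodes are undefined (NaN)."""
    out = {v: np.nan for v in graph.nodes}
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        if len(nodes) < 2:
            continue
        sub = graph.subgraph(nodes)
        A = np.zeros((len(nodes), len(nodes)))
        idx = {v: i for i, v in enumerate(nodes)}
        for u, v, d in sub.edges(data=True):
            sim = 1.0 / d["weight"] if weighted and d.get("weight", 0) > 0 else 1.0
            A[idx[u], idx[v]] = A[idx[v], idx[u]] = sim
        vals, vecs = eigh(A)
        lead = vecs[:, -1]
        # Perron vector: fix sign so entries are nonnegative
        if lead[np.argmax(np.abs(lead))] < 0:
            lead = -lead
        lead = lead / np.linalg.norm(lead)
        for v, s in zip(nodes, lead):
            out[v] = float(s)
    return out


def node_metrics(graph: nx.Graph, weighted: bool = True) -> pd.DataFrame:
    """Degree, closeness, betweenness and eigenvector centrality per locale.

    Closeness and betweenness use weighted shortest paths (closeness is the
    reciprocal of the mean distance to reachable nodes, restricted to the
    node's connected component); betweenness is normalized to the fraction
    of shortest paths through the node.  Isolated nodes carry NaN closeness
    and eigenvector scores.
    """
    if graph.number_of_nodes() == 0:
        raise DegenerateInputError("empty graph")
    w = "weight" if weighted else None
    btw = nx.betweenness_centrality(graph, weight=w, normalized=True)
    return pd.DataFrame(
        {
            "degree": dict(graph.degree()),
            "closeness": _closeness(graph, weighted),
            "betweenness": btw,
            "eigenvector": _eigenvector(graph, weighted),
        }
    ).loc[list(graph.nodes)]


# ---------------------------------------------------------------------------
# null models
# ---------------------------------------------------------------------------


def edge_permutation_null(
    graph: nx.Graph, rng: np.random.Generator
) -> nx.Graph:
    """Uniformly random simple graph on the same nodes with the same edge count."""
    nodes = list(graph.nodes)
    k = len(nodes)
    m = graph.number_of_edges()
    iu = np.triu_indices(k, 1)
    pick = rng.choice(iu[0].size, size=m, replace=False)
    G = nx.Graph()
    G.add_nodes_from(nodes)
    G.add_edges_from((nodes[iu[0][p]], nodes[iu[1][p]]) for p in pick)
    return G


def degree_preserving_null(
    graph: nx.Graph, rng: np.random.Generator, swaps_per_edge: int = 10
) -> nx.Graph:
    """Rewire by double-edge swaps: every node keeps its exact degree.

    Requires ≥ ``swaps_per_edge·|E|`` successful swaps; raises if the graph
    admits no swap (e.g. a star, where any swap would create a multi-edge).
    """
    m = graph.number_of_edges()
    if m < 2:
        raise DegenerateInputError("degree-preserving rewiring needs ≥2 edges")
    nodes = list(graph.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    edges = [(idx[u], idx[v]) for u, v in graph.edges()]
    present = {frozenset(e) for e in edges}
    target = swaps_per_edge * m
    max_tries = 200 * target
    done = tries = 0
    # draw randomness in batches; a tight loop dominates runtime otherwise
    batch = max(256, 4 * m)
    picks = rng.integers(0, m, size=(batch, 2))
    flips = rng.integers(0, 2, size=batch)
    cursor = 0
    while done < target:
        if tries >= max_tries:
            raise DegenerateInputError(
                "graph admits too few degree-preserving swaps"
            )
        if cursor >= batch:
            picks = rng.integers(0, m, size=(batch, 2))
            flips = rng.integers(0, 2, size=batch)
            cursor = 0
        i, j = picks[cursor]
        a, b = edges[i]
        c, d = edges[j]
        if flips[cursor]:
            c, d = d, c
        cursor += 1
        tries += 1
        if len({a, b, c, d}) < 4:
            continue
        e1, e2 = frozenset((a, d)), frozenset((c, b))
        if e1 in present or e2 in present:
            continue
        present.discard(frozenset((a, b)))
        present.discard(frozenset((c, d)))
        present.add(e1)
        present.add(e2)
        edges[i] = (a, d)
        edges[j] = (c, b)
        done += 1
    G = nx.Graph()
    G.add_nodes_from(nodes)
    G.add_edges_from((nodes[a], nodes[b]) for a, b in edges)
    return G


def _reassign_weights(
    template: nx.Graph, weights: np.ndarray, rng: np.random.Generator
) -> None:
    perm = rng.permutation(weights)
    for (u, v), w in zip(sorted(template.edges()), perm):
        template[u][v]["weight"] = float(w)


def _metric_values(graph: nx.Graph, metric: str, weighted: bool) -> dict:
    if metric == "degree":
        return dict(graph.degree())
    if metric == "closeness":
        return _closeness(graph, weighted)
    if metric == "betweenness":
        return nx.betweenness_centrality(
            graph, weight="weight" if weighted else None, normalized=True
        )
    if metric == "eigenvector":
        return _eigenvector(graph, weighted)
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def _focus_mean(values: dict, focus) -> float:
    vals = np.asarray([values[v] for v in focus], dtype=float)
    if np.isnan(vals).any():
        warnings.warn("undefined metric for some focus nodes; excluded from mean")
        vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def metric_permutation_test(
    graph: nx.Graph,
    metric: str,
    focus=None,
    n_perm: int = 1000,
    seed: int = 0,
    null_model: str = "edge_permutation",
    tail: str = "two-sided",
    weighted: bool = True,
) -> PermutationResult:
    """Is the mean metric over ``focus`` nodes extreme under rewired graphs?

    The observed statistic is the mean of ``metric`` over the focus subset
    (all nodes when ``focus`` is None).  Each replicate rewires the topology
    under ``null_model`` and permutes the observed edge-weight multiset onto
    the new edges before recomputing the metric.  p-value by the add-one
    rule; ``tail`` defaults to two-sided.
    """
    focus = list(graph.nodes) if focus is None else list(focus)
    if not focus:
        raise ValueError("focus subset is empty")
    if n_perm < 1:
        raise ValueError("n_perm must be ≥ 1")
    missing = [v for v in focus if v not in graph]
    if missing:
        raise KeyError(f"focus nodes not in graph: {missing}")
    observed = _focus_mean(_metric_values(graph, metric, weighted), focus)
    weights = np.asarray(
        [d.get("weight", 1.0) for _, _, d in graph.edges(data=True)], dtype=float
    )
    rng = spawn_rng(seed, 1)
    nulls = np.empty(n_perm)
    for r in range(n_perm):
        if null_model == "edge_permutation":
            g0 = edge_permutation_null(graph, rng)
        elif null_model == "degree_preserving":
            g0 = degree_preserving_null(graph, rng)
        else:
            raise ValueError(f"unknown null model {null_model!r}")
        _reassign_weights(g0, weights, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nulls[r] = _focus_mean(_metric_values(g0, metric, weighted), focus)
    return PermutationResult.from_null(
        observed, nulls, tail=tail, seed=seed, null_model=null_model
    )
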