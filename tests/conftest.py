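"""Shared fixtures and independent oracle helpers.

The oracles here are deliberately naive (pair enumeration, brute-force path
search, closed forms) and independent of the library code paths they check.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from landgraph.core import SNPDataset


def make_dataset(genotypes, locales, ploidy=1, L=None) -> SNPDataset:
    """Small-dataset builder: genotypes (n×m) with per-sample locale labels."""
    g = np.asarray(genotypes)
    n, m = g.shape
    return SNPDataset(
        genotypes=g,
        sample_ids=np.asarray([f"s{i}" for i in range(n)], dtype=object),
        locale_ids=np.asarray(list(locales), dtype=object),
        ploidy=ploidy,
        locus_ids=np.asarray([f"l{j}" for j in range(m)], dtype=object),
        n_sites_surveyed=L if L is not None else m,
    )


# ---------------------------------------------------------------------------
# pair-enumeration FST oracle
# ---------------------------------------------------------------------------


def _allele_copies(dosages, ploidy):
    """Expand sample dosages into individual allele copies (0/1 list)."""
    copies = []
    for d in dosages:
        if d < 0:
            continue
        copies.extend([1] * int(d) + [0] * (ploidy - int(d)))
    return copies


def enumeration_fst(gen_a, gen_b, ploidy=1) -> float:
    """Hudson FST by exhaustive enumeration of allele pairs.

    Hw per locale is the mean difference over all unordered within-locale
    allele pairs (which carries the n/(n−1) correction implicitly); Hb the
    mean over all cross-locale pairs.  Loci combine as a ratio of summed
    numerators over summed denominators.
    """
    gen_a, gen_b = np.atleast_2d(gen_a), np.atleast_2d(gen_b)
    num = den = 0.0
    for l in range(gen_a.shape[1]):
        a = _allele_copies(gen_a[:, l], ploidy)
        b = _allele_copies(gen_b[:, l], ploidy)
        if len(a) < 2 or len(b) < 2:
            continue
        hw_a = np.mean([x != y for x, y in itertools.combinations(a, 2)])
        hw_b = np.mean([x != y for x, y in itertools.combinations(b, 2)])
        hb = np.mean([x != y for x in a for y in b])
        num += hb - 0.5 * (hw_a + hw_b)
        den += hb
    return num / den


# ---------------------------------------------------------------------------
# brute-force path metrics for tiny graphs
# ---------------------------------------------------------------------------


def brute_shortest(graph: nx.Graph, s, t):
    """(min length, list of minimal paths) by enumerating all simple paths."""
    best, paths = np.inf, []
    for path in nx.all_simple_paths(graph, s, t):
        length = sum(
            graph[u][v].get("weight", 1.0) for u, v in zip(path, path[1:])
        )
        if length < best - 1e-12:
            best, paths = length, [path]
        elif abs(length - best) <= 1e-12:
            paths.append(path)
    return best, paths


def brute_closeness(graph: nx.Graph) -> dict:
    out = {}
    for v in graph.nodes:
        dists = []
        for u in graph.nodes:
            if u == v:
                continue
            d, _ = brute_shortest(graph, v, u)
            if np.isfinite(d):
                dists.append(d)
        out[v] = 1.0 / np.mean(dists) if dists else np.nan
    return out


def brute_betweenness(graph: nx.Graph) -> dict:
    """Fraction of shortest paths through each node, pair-normalized."""
    nodes = list(graph.nodes)
    n = len(nodes)
    acc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        d, paths = brute_shortest(graph, s, t)
        if not np.isfinite(d) or not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p[1:-1])
            acc[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    return {v: acc[v] / norm for v in nodes}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
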