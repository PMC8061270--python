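"""Population graphs from among-locale genetic covariance.

The procedure starts from individual allele dosages, forms locale centroids
in allele space, Gower double-centres the squared centroid distances into a
covariance matrix, and prunes the saturated locale graph by
conditional-independence testing: the partial correlation ρ_ij implied by
the precision matrix is tested with the edge-exclusion deviance
``−n·ln(1 − ρ²)`` against χ² with one degree of freedom.  Edges whose
exclusion is rejected are retained, weighted by the centroid distance
``√(c_ii + c_jj − 2 c_ij)``.  Conditional genetic distance (cGD) between two
locales is then the shortest-path length through the retained graph,
summarizing connectivity through the whole network rather than a single
pairwise dissimilarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, DegenerateInputError, PairwiseMatrix, SNPDataset

__all__ = [
    "EncodedGenotypes",
    "LocaleCovariance",
    "encode_alleles",
    "locale_covariance",
    "prune_edges",
    "cgd_matrix",
    "CGDMatrix",
    "isolated_nodes",
    "write_graphml",
    "read_graphml",
    "write_edges_csv",
]


@dataclass
class EncodedGenotypes:
    """Grand-mean-centred allele-dosage design matrix (samples × columns).

    One column per non-reference allele per polymorphic locus; monomorphic
    loci contribute no columns.  Missing calls are mean-imputed per column
    before centring.
    """

    matrix: np.ndarray
    sample_ids: np.ndarray
    locale_ids: np.ndarray
    column_loci: np.ndarray


@dataclass
class LocaleCovariance:
    """Gower-centred covariance among locale centroids.

    ``C = −½ J D2 J`` where ``D2`` holds squared Euclidean distances among
    locale centroids and ``J`` is the centring projector.  ``shrinkage``
    records the diagonal ridge applied for inversion (0 until
    :func:`prune_edges` needs one).
    """

    ids: list[str]
    C: np.ndarray
    D2: np.ndarray
    shrinkage: float = 0.0


def encode_alleles(dataset: SNPDataset) -> EncodedGenotypes:
    """Centred dosage encoding of all polymorphic loci.

    For biallelic SNPs this is one column per locus carrying the alternate
    allele dosage (0/1 haploid, 0/1/2 diploid), with the reference allele's
    column dropped to avoid exact collinearity.
    """
    poly = dataset.polymorphic_mask
    if not poly.any():
        raise DegenerateInputError("no polymorphic loci to encode")
    g = dataset.genotypes[:, poly].astype(float)
    g[dataset.genotypes[:, poly] == MISSING] = np.nan
    col_mean = np.nanmean(g, axis=0)
    inds = np.where(np.isnan(g))
    g[inds] = np.take(col_mean, inds[1])
    g -= g.mean(axis=0)
    return EncodedGenotypes(
        matrix=g,
        sample_ids=dataset.sample_ids,
        locale_ids=dataset.locale_ids,
        column_loci=dataset.locus_ids[poly],
    )


def gower_center(D2: np.ndarray) -> np.ndarray:
    """−½ J D2 J with J = I − 11ᵀ/k (classical MDS double-centring)."""
    k = D2.shape[0]
    J = np.eye(k) - np.ones((k, k)) / k
    return -0.5 * (J @ D2 @ J)


def locale_covariance(encoded: EncodedGenotypes) -> LocaleCovariance:
    """Covariance among locale centroids in allele space."""
    locs = list(pd.unique(encoded.locale_ids))
    if len(locs) < 3:
        raise DegenerateInputError("population graph needs at least three locales")
    cent = np.stack(
        [encoded.matrix[encoded.locale_ids == loc].mean(axis=0) for loc in locs]
    )
    sq = (cent**2).sum(axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (cent @ cent.T)
    np.fill_diagonal(D2, 0.0)
    D2 = np.maximum(D2, 0.0)
    D2 = 0.5 * (D2 + D2.T)
    return LocaleCovariance(ids=locs, C=gower_center(D2), D2=D2)


MAX_SHRINKAGE = 1e-2
COND_LIMIT = 1e10
NULLSPACE_RTOL = 1e-12


def _shrunk_inverse(C: np.ndarray):
    """Precision matrix of C on its row space, with diagonal shrinkage.

    Gower centring leaves an *exact* null direction (the ones vector), so C
    is inverted via its eigendecomposition restricted to eigenvalues above
    ``NULLSPACE_RTOL·λmax``; a full-rank covariance is simply inverted.
    If the retained spectrum is still ill-conditioned, shrinkage δ doubles
    from 1e−8 up to 1e−2 until the condition number drops below 1e10.
    """
    lam, Q = np.linalg.eigh(C)
    lam_max = float(lam.max())
    if lam_max <= 0:
        raise np.linalg.LinAlgError("covariance has no positive eigenvalue")
    keep = lam > NULLSPACE_RTOL * lam_max
    delta = 0.0
    while True:
        cond = lam_max / (lam[keep].min() + delta)
        if cond < COND_LIMIT:
            inv_lam = np.where(keep, 1.0 / (lam + delta), 0.0)
            return (Q * inv_lam) @ Q.T, delta
        if delta == 0.0:
            delta = 1e-8
        elif delta >= MAX_SHRINKAGE:
            raise np.linalg.LinAlgError(
                f"covariance not invertible: condition number {cond:.3g} "
                f"at maximum shrinkage {MAX_SHRINKAGE:g}"
            )
        else:
            delta *= 2.0


def prune_edges(
    cov: LocaleCovariance,
    alpha: float = 0.05,
    n: int | None = None,
    bonferroni: bool = False,
) -> nx.Graph:
    """Prune the saturated locale graph by edge-exclusion deviance.

    Parameters
    ----------
    cov
        Locale covariance (Gower-centred or a plain covariance matrix).
    alpha
        Significance level: an edge is retained iff the test rejects its
        exclusion (deviance p ≤ alpha).  ``alpha=1`` keeps the complete
        graph; ``alpha→0`` empties it.
    n
        Sample size used in the deviance, by default the number of encoded
        individuals is unknown here so it must be supplied; conventionally
        the total number of sampled individuals.
    bonferroni
        Divide alpha by the number of candidate edges.

    Returns
    -------
    networkx.Graph
        Nodes are locale ids.  Edge attributes: ``weight`` (centroid genetic
        distance), ``partial_correlation``, ``deviance``, ``p``.  Graph
        attributes record alpha, n, and the shrinkage actually applied.
    """
    if n is None:
        raise ValueError("n (deviance sample size) must be given")
    k = len(cov.ids)
    if n < k + 1:
        raise DegenerateInputError("deviance sample size must exceed locale count")
    omega, delta = _shrunk_inverse(cov.C)
    cov.shrinkage = delta
    d = np.sqrt(np.diag(omega))
    rho = -omega / np.outer(d, d)
    np.fill_diagonal(rho, 0.0)
    rho = np.clip(rho, -0.999999999, 0.999999999)
    dev = -n * np.log1p(-(rho**2))
    pval = stats.chi2.sf(dev, df=1)
    thresh = alpha / (k * (k - 1) / 2) if bonferroni else alpha
    G = nx.Graph(alpha=alpha, n=int(n), shrinkage=delta)
    G.add_nodes_from(cov.ids)
    C = cov.C
    for i in range(k):
        for j in range(i + 1, k):
            if pval[i, j] <= thresh:
                w = float(np.sqrt(max(C[i, i] + C[j, j] - 2 * C[i, j], 0.0)))
                G.add_edge(
                    cov.ids[i],
                    cov.ids[j],
                    weight=w,
                    partial_correlation=float(rho[i, j]),
                    deviance=float(dev[i, j]),
                    p=float(pval[i, j]),
                )
    return G


def build_popgraph(
    dataset: SNPDataset, alpha: float = 0.05, n: int | None = None
) -> nx.Graph:
    """Convenience: encode → covariance → prune in one call.

    ``n`` defaults to the number of sampled individuals in the dataset.
    """
    enc = encode_alleles(dataset)
    cov = locale_covariance(enc)
    return prune_edges(cov, alpha=alpha, n=n if n is not None else dataset.n_samples)


@dataclass
class CGDMatrix:
    """Conditional genetic distances (shortest paths over retained edges).

    ``values[i, j]`` is NaN and ``reachable[i, j]`` False for pairs with no
    connecting path; exports write such pairs as ``NA``, never as infinity.
    """

    ids: list[str]
    values: np.ndarray
    reachable: np.ndarray

    def to_pairwise(self) -> PairwiseMatrix:
        return PairwiseMatrix(self.ids, self.values, "cGD")

    def write_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, na_rep="NA"
        )


def cgd_matrix(graph: nx.Graph) -> CGDMatrix:
    """All-pairs conditional genetic distance over the population graph."""
    if graph.number_of_nodes() == 0:
        raise DegenerateInputError("empty graph")
    ids = list(graph.nodes)
    k = len(ids)
    vals = np.full((k, k), np.nan)
    reach = np.zeros((k, k), dtype=bool)
    np.fill_diagonal(vals, 0.0)
    np.fill_diagonal(reach, True)
    index = {v: i for i, v in enumerate(ids)}
    for src, dists in nx.all_pairs_dijkstra_path_length(graph, weight="weight"):
        i = index[src]
        for dst, d in dists.items():
            j = index[dst]
            vals[i, j] = d
            reach[i, j] = True
    return CGDMatrix(ids=ids, values=vals, reachable=reach)


def isolated_nodes(graph: nx.Graph) -> list[str]:
    """Locales retaining no conditional-covariance connection at all."""
    return [v for v, deg in graph.degree() if deg == 0]


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def write_edges_csv(graph: nx.Graph, path) -> None:
    rows = [
        {
            "locale_a": u,
            "locale_b": v,
            "weight": d.get("weight"),
            "partial_correlation": d.get("partial_correlation"),
            "deviance": d.get("deviance"),
            "p": d.get("p"),
        }
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
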