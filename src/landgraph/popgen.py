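"""Diversity statistics, Hudson's FST, and the pooled-resampling panmixia test.

All statistics operate on allele counts derived from an :class:`~landgraph.core.SNPDataset`.
Sites are treated as biallelic SNPs ascertained over ``n_sites_surveyed``
nucleotide sites, so θπ and θS are reported *per site*.

Hudson's FST is computed as ``1 − Hw/Hb``, where ``Hw`` is the mean
within-locale pairwise difference (averaged over the two locales, each with
the ``n/(n−1)`` small-sample correction) and ``Hb`` the mean between-locale
pairwise difference.  Multi-locus values combine loci as a ratio of averages
(sum of numerators over sum of denominators), the standard rule for
Hudson-type estimators; per-locus ratios are never averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    MISSING,
    DegenerateInputError,
    PairwiseMatrix,
    PermutationResult,
    SNPDataset,
    spawn_rng,
)

__all__ = [
    "DiversityStats",
    "nucleotide_diversity",
    "watterson_theta",
    "tajimas_d",
    "diversity_stats",
    "hudson_fst",
    "pairwise_fst_matrix",
    "global_fst",
    "panmixia_permutation",
    "PanmixiaResult",
]


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


@dataclass
class DiversityStats:
    """Per-site diversity summaries for one group of allele sequences.

    ``tajimas_d`` is ``nan`` when the group has no segregating sites (the
    statistic is undefined there, never silently zero).
    """

    theta_pi: float
    theta_s: float
    S: int
    tajimas_d: float
    n: int


def _group_rows(dataset: SNPDataset, group: str | None) -> np.ndarray:
    if group is None or group == "all":
        return np.arange(dataset.n_samples)
    return dataset.sample_indices(group)


def _pairwise_diff_sums(alt: np.ndarray, n: np.ndarray):
    """Per-locus mean pairwise difference k(n−k)/C(n,2) over callable alleles."""
    usable = n >= 2
    pi = np.zeros_like(alt)
    nn = n[usable]
    pi[usable] = alt[usable] * (nn - alt[usable]) / (nn * (nn - 1) / 2.0)
    return pi, usable


def nucleotide_diversity(dataset: SNPDataset, group: str | None = "all") -> float:
    """θπ: mean pairwise nucleotide difference per surveyed site.

    Missing calls are handled by pairwise deletion per locus.  Raises
    :class:`DegenerateInputError` for groups with fewer than two alleles.
    """
    rows = _group_rows(dataset, group)
    alt, n = dataset.allele_counts(rows)
    if rows.size * dataset.ploidy < 2 or (n >= 2).sum() == 0:
        raise DegenerateInputError("need at least two alleles to estimate θπ")
    pi, _ = _pairwise_diff_sums(alt, n)
    return float(pi.sum() / dataset.n_sites_surveyed)


def _harmonic(k: int) -> float:
    return float(np.sum(1.0 / np.arange(1, k + 1)))


def watterson_theta(dataset: SNPDataset, group: str | None = "all") -> float:
    """θS: segregating sites scaled by the harmonic number, per surveyed site."""
    rows = _group_rows(dataset, group)
    n_alleles = rows.size * dataset.ploidy
    if n_alleles < 2:
        raise DegenerateInputError("need at least two alleles to estimate θS")
    alt, n = dataset.allele_counts(rows)
    S = int(np.count_nonzero((alt > 0) & (alt < n)))
    a1 = _harmonic(n_alleles - 1)
    return S / (a1 * dataset.n_sites_surveyed)


def _tajima_constants(n: int):
    # Tajima (1989) normalizing constants as functions of allele count n
    a1 = _harmonic(n - 1)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_d(dataset: SNPDataset, group: str | None = "all") -> float:
    """Tajima's D on the group's concatenated SNP set.

    Returns ``nan`` (with a warning) when there are no segregating sites;
    the statistic is undefined there.
    """
    rows = _group_rows(dataset, group)
    n_alleles = rows.size * dataset.ploidy
    if n_alleles < 3:
        raise DegenerateInputError("Tajima's D needs at least three alleles")
    alt, n = dataset.allele_counts(rows)
    seg = (alt > 0) & (alt < n)
    S = int(np.count_nonzero(seg))
    if S == 0:
        warnings.warn("Tajima's D undefined: no segregating sites")
        return float("nan")
    pi, _ = _pairwise_diff_sums(alt, n)
    pi_total = float(pi.sum())  # total (not per-site) mean pairwise differences
    a1, e1, e2 = _tajima_constants(n_alleles)
    var = e1 * S + e2 * S * (S - 1)
    return (pi_total - S / a1) / np.sqrt(var)


def diversity_stats(dataset: SNPDataset, group: str | None = "all") -> DiversityStats:
    rows = _group_rows(dataset, group)
    alt, n = dataset.allele_counts(rows)
    S = int(np.count_nonzero((alt > 0) & (alt < n)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d = tajimas_d(dataset, group) if S > 0 else float("nan")
    return DiversityStats(
        theta_pi=nucleotide_diversity(dataset, group),
        theta_s=watterson_theta(dataset, group),
        S=S,
        tajimas_d=d,
        n=rows.size * dataset.ploidy,
    )


# ---------------------------------------------------------------------------
# Hudson FST
# ---------------------------------------------------------------------------


def _dose_called(dataset: SNPDataset):
    g = dataset.genotypes
    called = (g != MISSING).astype(float)
    dose = np.where(g != MISSING, g, 0).astype(float)
    return dose, called


def _freq_tables(dataset: SNPDataset, membership: np.ndarray, _pre=None):
    """Per-locale allele frequencies from a (k, n_samples) membership matrix.

    Returns ``(P, Hw, V)``: frequencies, corrected within-locale mean pairwise
    differences ``2p(1−p)·n/(n−1)``, and a validity mask (≥2 callable
    alleles), all of shape (k, n_loci).
    """
    dose, called = _dose_called(dataset) if _pre is None else _pre
    alt = membership @ dose  # (k, L) alt-allele counts
    n = (membership @ called) * dataset.ploidy
    V = n >= 2
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(V, alt / np.maximum(n, 1), np.nan)
        Hw = np.where(V, 2.0 * P * (1.0 - P) * n / np.maximum(n - 1.0, 1), np.nan)
    return P, Hw, V


def _pair_sums(P: np.ndarray, Hw: np.ndarray, V: np.ndarray):
    """Locus-summed within (SHw) and between (SHb) heterozygosity per pair."""
    PV = np.where(V, P, 0.0)
    HwV = np.where(V, Hw, 0.0)
    Vf = V.astype(float)
    # Σ_l V_i V_j (p_i + p_j − 2 p_i p_j)
    SHb = PV @ Vf.T + Vf @ PV.T - 2.0 * (PV @ PV.T)
    SHw = 0.5 * (HwV @ Vf.T + Vf @ HwV.T)
    return SHw, SHb


def hudson_fst(dataset: SNPDataset, locale_a: str, locale_b: str) -> float:
    """Multi-locus Hudson FST between two locales (ratio of averages).

    Negative values are reported as computed, never clamped.  Returns an
    error if no locus is usable in both locales.
    """
    k_ids = [locale_a, locale_b]
    memb = np.stack(
        [np.isin(dataset.locale_ids, [loc]).astype(float) for loc in k_ids]
    )
    P, Hw, V = _freq_tables(dataset, memb)
    SHw, SHb = _pair_sums(P, Hw, V)
    if SHb[0, 1] == 0.0:
        raise DegenerateInputError(
            f"no usable polymorphic loci shared by {locale_a!r} and {locale_b!r}"
        )
    return float(1.0 - SHw[0, 1] / SHb[0, 1])


def _membership_matrix(dataset: SNPDataset, order: np.ndarray | None = None):
    """(k, n_samples) 0/1 matrix; ``order`` permutes samples into locale slots."""
    locs = dataset.locales
    # permuting the label vector re-deals individuals into locales while
    # preserving every locale's sample size
    lab = dataset.locale_ids if order is None else dataset.locale_ids[order]
    M = np.stack([(lab == loc).astype(float) for loc in locs])
    return locs, M


def pairwise_fst_matrix(dataset: SNPDataset) -> tuple[PairwiseMatrix, float]:
    """All-pairs Hudson FST plus the global multi-locus value.

    The global value pools every between-locale comparison with the same
    ratio-of-averages rule.  Pairs with no usable loci propagate as NaN with
    a warning.  The matrix diagonal is NaN (FST of a locale with itself is
    not a distance).
    """
    locs, M = _membership_matrix(dataset)
    if len(locs) < 2:
        raise DegenerateInputError("need at least two locales")
    P, Hw, V = _freq_tables(dataset, M)
    SHw, SHb = _pair_sums(P, Hw, V)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = 1.0 - SHw / SHb
    np.fill_diagonal(F, np.nan)
    iu = np.triu_indices(len(locs), k=1)
    bad = SHb[iu] == 0.0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} locale pair(s) have no usable loci; NaN FST")
        F[iu[0][bad], iu[1][bad]] = np.nan
        F[iu[1][bad], iu[0][bad]] = np.nan
    gnum = float((SHb[iu] - SHw[iu]).sum())
    gden = float(SHb[iu].sum())
    g = gnum / gden if gden > 0 else float("nan")
    return PairwiseMatrix(locs, F, "hudson_fst"), g


def global_fst(dataset: SNPDataset) -> float:
    """Global multi-locus Hudson FST pooled over all locale pairs."""
    return pairwise_fst_matrix(dataset)[1]


# ---------------------------------------------------------------------------
# panmixia permutation test
# ---------------------------------------------------------------------------


@dataclass
class PanmixiaResult:
    """Per-pair permutation tests of panmixia.

    ``p_matrix`` holds the upper-tail add-one p-value for each locale pair;
    ``results`` maps ``(locale_a, locale_b)`` (a < b in dataset order) to a
    full :class:`PermutationResult`.
    """

    p_matrix: PairwiseMatrix
    observed: PairwiseMatrix
    results: dict[tuple[str, str], PermutationResult]
    n_perm: int
    seed: int


def panmixia_permutation(
    dataset: SNPDataset,
    n_perm: int = 1000,
    seed: int = 0,
    bootstrap: bool = False,
) -> PanmixiaResult:
    """Test every locale pair against the pooled panmixia null.

    Each replicate pools all individuals and re-deals them to locales
    preserving the observed per-locale sample sizes (a permutation of
    individuals without replacement; set ``bootstrap=True`` to resample
    individuals with replacement instead).  Pairwise FST is recomputed for
    every replicate; the upper-tail p-value per pair uses the add-one rule,
    so identical inputs and seed give bit-identical results.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be ≥ 1")
    locs, M = _membership_matrix(dataset)
    k = len(locs)
    if k < 2:
        raise DegenerateInputError("need at least two locales")
    pre = _dose_called(dataset)
    P, Hw, V = _freq_tables(dataset, M, pre)
    SHw, SHb = _pair_sums(P, Hw, V)
    iu = np.triu_indices(k, k=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        obs = 1.0 - SHw[iu] / np.where(SHb[iu] > 0, SHb[iu], np.nan)

    rng = spawn_rng(seed, 0)
    nulls = np.empty((n_perm, obs.size))
    n_samp = dataset.n_samples
    for r in range(n_perm):
        if bootstrap:
            # each locale slot refilled by an individual drawn with replacement
            order = rng.integers(0, n_samp, size=n_samp)
            Pp, Hwp, Vp = _freq_tables(
                dataset, M, (pre[0][order], pre[1][order])
            )
        else:
            # permuted membership is a column gather of the observed one
            order = rng.permutation(n_samp)
            Pp, Hwp, Vp = _freq_tables(dataset, M[:, order], pre)
        SHwp, SHbp = _pair_sums(Pp, Hwp, Vp)
        with np.errstate(divide="ignore", invalid="ignore"):
            nulls[r] = 1.0 - SHwp[iu] / np.where(SHbp[iu] > 0, SHbp[iu], np.nan)

    null_model = "pooled_bootstrap" if bootstrap else "pooled_permutation"
    results: dict[tuple[str, str], PermutationResult] = {}
    pvals = np.full((k, k), np.nan)
    for idx, (i, j) in enumerate(zip(*iu)):
        res = PermutationResult.from_null(
            obs[idx], nulls[:, idx], tail="upper", seed=seed, null_model=null_model
        )
        results[(locs[i], locs[j])] = res
        pvals[i, j] = pvals[j, i] = res.p_value
    fobs = np.full((k, k), np.nan)
    fobs[iu] = obs
    fobs[(iu[1], iu[0])] = obs
    return PanmixiaResult(
        p_matrix=PairwiseMatrix(locs, pvals, "panmixia_p"),
        observed=PairwiseMatrix(locs, fobs, "hudson_fst"),
        results=results,
        n_perm=n_perm,
        seed=seed,
    )
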