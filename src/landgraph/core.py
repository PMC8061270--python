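"""Shared data containers for locale-based population genetics.

A *locale* is a sampled site treated as a population unit.  All genetic
computation operates on :class:`SNPDataset` (a locale-labelled allele-dosage
matrix), and most pairwise results are carried in :class:`PairwiseMatrix`.
Permutation tests of any flavour return :class:`PermutationResult`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: sentinel for a missing genotype call in dosage matrices
MISSING: int = -1


class LandgraphError(Exception):
    """Base class for errors raised by this package."""


class DegenerateInputError(LandgraphError):
    """Raised when an operation's preconditions on the data are not met."""


@dataclass
class SNPDataset:
    """Locale-labelled SNP allele-dosage matrix.

    Parameters
    ----------
    genotypes
        ``(n_samples, n_loci)`` integer array of alternate-allele dosages in
        ``{0..ploidy}``, with :data:`MISSING` (−1) marking missing calls.
    sample_ids, locale_ids
        Per-sample identifiers; each sample belongs to exactly one locale.
    ploidy
        1 for haploid (chloroplast-like) data, 2 for diploid (nuclear-like).
    locus_ids
        Per-locus identifiers.
    n_sites_surveyed
        Total sequence length L over which the SNPs were ascertained; used to
        express diversity per nucleotide site.  Must be ≥ the number of loci.
    """

    genotypes: np.ndarray
    sample_ids: np.ndarray
    locale_ids: np.ndarray
    ploidy: int
    locus_ids: np.ndarray
    n_sites_surveyed: int

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.locale_ids = np.asarray(self.locale_ids, dtype=object)
        self.locus_ids = np.asarray(self.locus_ids, dtype=object)
        n, m = self.genotypes.shape
        if self.ploidy not in (1, 2):
            raise ValueError(f"ploidy must be 1 or 2, got {self.ploidy}")
        if len(self.sample_ids) != n or len(self.locale_ids) != n:
            raise ValueError("sample/locale id length does not match genotypes")
        if len(self.locus_ids) != m:
            raise ValueError("locus id length does not match genotypes")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids are not unique")
        bad = (self.genotypes != MISSING) & (
            (self.genotypes < 0) | (self.genotypes > self.ploidy)
        )
        if bad.any():
            raise ValueError("genotype dosages outside {0..ploidy} / missing")
        if self.n_sites_surveyed < m:
            raise ValueError(
                f"n_sites_surveyed ({self.n_sites_surveyed}) < number of loci ({m})"
            )

    # -- basic structure ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def locales(self) -> list[str]:
        """Locale ids in first-appearance order."""
        return list(pd.unique(self.locale_ids))

    def sample_indices(self, locale: str) -> np.ndarray:
        idx = np.flatnonzero(self.locale_ids == locale)
        if idx.size == 0:
            raise KeyError(f"unknown locale {locale!r}")
        return idx

    def allele_counts(self, rows: np.ndarray | None = None):
        """Alternate-allele count and total allele count per locus.

        Missing calls contribute to neither count (pairwise deletion per
        locus).  Returns ``(alt, n)`` as float arrays of length ``n_loci``.
        """
        g = self.genotypes if rows is None else self.genotypes[rows]
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=0).astype(float)
        n = called.sum(axis=0).astype(float) * self.ploidy
        return alt, n

    @property
    def polymorphic_mask(self) -> np.ndarray:
        """Boolean mask of loci segregating in the full dataset."""
        alt, n = self.allele_counts()
        return (alt > 0) & (alt < n)

    # -- I/O ---------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.genotypes, columns=self.locus_ids)
        df.insert(0, "locale_id", self.locale_ids)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def write_csv(self, path: str | Path) -> None:
        """Write as a locale-labelled CSV (missing dosages left blank)."""
        df = self.to_dataframe()
        loci = list(self.locus_ids)
        df[loci] = df[loci].astype(object).where(df[loci] != MISSING, "")
        df.to_csv(path, index=False)

    @classmethod
    def read_csv(
        cls, path: str | Path, ploidy: int, n_sites_surveyed: int | None = None
    ) -> "SNPDataset":
        df = pd.read_csv(path, dtype={"sample_id": str, "locale_id": str})
        loci = [c for c in df.columns if c not in ("sample_id", "locale_id")]
        g = df[loci].to_numpy(dtype=float)
        g = np.where(np.isnan(g), MISSING, g).astype(np.int16)
        return cls(
            genotypes=g,
            sample_ids=df["sample_id"].to_numpy(),
            locale_ids=df["locale_id"].to_numpy(),
            ploidy=ploidy,
            locus_ids=np.asarray(loci, dtype=object),
            n_sites_surveyed=n_sites_surveyed or len(loci),
        )

    def write_vcf(self, path: str | Path) -> None:
        """Write a minimal VCF 4.2 with GT calls (haploid or diploid)."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=landgraph\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("##contig=<ID=1>\n")
            cols = "\t".join(str(s) for s in self.sample_ids)
            fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
            for j in range(self.n_loci):
                calls = []
                for d in self.genotypes[:, j]:
                    if d == MISSING:
                        calls.append("." if self.ploidy == 1 else "./.")
                    elif self.ploidy == 1:
                        calls.append(str(int(d)))
                    else:
                        calls.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(d)])
                row = "\t".join(
                    ["1", str(j + 1), str(self.locus_ids[j]), "A", "T", ".", "PASS", ".", "GT"]
                    + calls
                )
                fh.write(row + "\n")

    @classmethod
    def read_vcf(
        cls,
        vcf_path: str | Path,
        locale_map: str | Path | dict,
        ploidy: int,
        n_sites_surveyed: int | None = None,
    ) -> "SNPDataset":
        """Read genotypes from a VCF plus a sample→locale mapping.

        ``locale_map`` is a CSV with columns ``sample_id,locale_id`` (or an
        equivalent dict).  Only biallelic sites are accepted.
        """
        from cyvcf2 import VCF

        if not isinstance(locale_map, dict):
            mdf = pd.read_csv(locale_map, dtype=str)
            locale_map = dict(zip(mdf["sample_id"], mdf["locale_id"]))
        vcf = VCF(str(vcf_path))
        samples = list(vcf.samples)
        missing_samples = [s for s in samples if s not in locale_map]
        if missing_samples:
            raise ValueError(f"samples without a locale: {missing_samples[:5]} ...")
        rows: list[np.ndarray] = []
        ids: list[str] = []
        for var in vcf:
            if len(var.ALT) != 1:
                warnings.warn(f"skipping non-biallelic site {var.ID or var.POS}")
                continue
            dosage = np.full(len(samples), MISSING, dtype=np.int16)
            for i, gt in enumerate(var.genotypes):
                alleles = [a for a in gt[:-1] if a >= 0]
                if alleles:
                    dosage[i] = int(sum(alleles))
            rows.append(dosage)
            ids.append(var.ID if var.ID not in (None, ".") else f"site{var.POS}")
        g = np.stack(rows, axis=1) if rows else np.zeros((len(samples), 0), np.int16)
        return cls(
            genotypes=g,
            sample_ids=np.asarray(samples, dtype=object),
            locale_ids=np.asarray([locale_map[s] for s in samples], dtype=object),
            ploidy=ploidy,
            locus_ids=np.asarray(ids, dtype=object),
            n_sites_surveyed=n_sites_surveyed or len(ids),
        )


@dataclass
class PairwiseMatrix:
    """Symmetric locale × locale matrix (FST, geographic distance, cGD ...)."""

    ids: list[str]
    values: np.ndarray
    statistic_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.ids)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match id list")
        if not np.allclose(
            self.values, self.values.T, equal_nan=True, atol=1e-10, rtol=0
        ):
            raise ValueError("matrix is not symmetric")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in (i<j) row-major order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def pairs(self) -> list[tuple[str, str]]:
        k = len(self.ids)
        return [(self.ids[i], self.ids[j]) for i in range(k) for j in range(i + 1, k)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, na_rep="NA")

    @classmethod
    def read_csv(cls, path: str | Path, statistic_name: str = "") -> "PairwiseMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(float), statistic_name)


def permutation_pvalue(observed: float, null: np.ndarray, tail: str) -> float:
    """Add-one permutation p-value; never exactly zero.

    ``tail`` is one of ``upper``, ``lower``, ``two-sided``.  The two-sided
    value doubles the smaller one-sided value (capped at 1).
    """
    null = np.asarray(null, dtype=float)
    n = null.size
    upper = (1.0 + np.count_nonzero(null >= observed)) / (1.0 + n)
    lower = (1.0 + np.count_nonzero(null <= observed)) / (1.0 + n)
    if tail == "upper":
        return upper
    if tail == "lower":
        return lower
    if tail == "two-sided":
        return min(1.0, 2.0 * min(upper, lower))
    raise ValueError(f"unknown tail {tail!r}")


@dataclass
class PermutationResult:
    """Observed statistic, its permutation null sample, and the p-value."""

    observed: float
    null_values: np.ndarray
    p_value: float
    n_perm: int
    tail: str
    seed: int
    null_model: str

    def __post_init__(self) -> None:
        self.null_values = np.asarray(self.null_values, dtype=float)
        if self.null_values.size != self.n_perm:
            raise ValueError("null sample length does not match n_perm")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value outside (0, 1]")

    @classmethod
    def from_null(
        cls,
        observed: float,
        null_values: Sequence[float],
        tail: str,
        seed: int,
        null_model: str,
    ) -> "PermutationResult":
        null = np.asarray(null_values, dtype=float)
        return cls(
            observed=float(observed),
            null_values=null,
            p_value=permutation_pvalue(observed, null, tail),
            n_perm=null.size,
            tail=tail,
            seed=seed,
            null_model=null_model,
        )

    def to_dict(self, include_null: bool = False) -> dict:
        d = {
            "observed": self.observed,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "tail": self.tail,
            "seed": self.seed,
            "null_model": self.null_model,
        }
        if include_null:
            d["null_values"] = self.null_values.tolist()
        return d


def spawn_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child RNG for a named sub-stream of a global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))
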