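"""Synthetic landscapes, locale coordinates, and structured SNP datasets.

The generator emulates the sampling design the rest of the package is built
for: ~51 locales across a heterogeneous landscape, a haploid
"chloroplast-like" marker set with few loci and strong structure, and a
diploid "nuclear-like" set with many loci and weak structure.  Allele
frequencies follow the Balding–Nichols model: per locus an ancestral
frequency ``p`` is drawn uniformly, and each locale's frequency comes from
``Beta(p(1−F)/F, (1−p)(1−F)/F)`` with ``F = fst_target``, whose expected
multi-locus Hudson FST is F itself — giving every downstream stage a
quantitative ground truth.  All generators are pure functions of
(scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import SNPDataset, spawn_rng
from .landscape import RasterLayer

__all__ = [
    "SyntheticScenario",
    "chloroplast_like",
    "nuclear_like",
    "make_landscape",
    "make_locales",
    "simulate_snp_dataset",
    "simulate_barrier_scenario",
]


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic study.

    ``fst_target`` is the Balding–Nichols F: the expected multi-locus Hudson
    FST among locales.  ``sites_per_locus`` scales the implied surveyed
    sequence length (``n_sites_surveyed = sites_per_locus · n_loci``) so that
    per-site diversity statistics are on a realistic SNP-density scale.
    """

    n_locales: int = 51
    samples_per_locale: int = 6
    ploidy: int = 1
    n_loci: int = 500
    fst_target: float = 0.3
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    raster_extent: tuple[int, int] = (60, 100)
    seed: int = 0
    sites_per_locus: int = 50

    def __post_init__(self) -> None:
        lo, hi = self.ancestral_freq_range
        if self.n_locales < 2:
            raise ValueError("need at least two locales")
        if self.samples_per_locale < 2:
            raise ValueError("need at least two samples per locale")
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        if not (0.0 <= self.fst_target < 1.0):
            raise ValueError("fst_target must lie in [0, 1)")
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral frequency range must satisfy 0 < lo ≤ hi < 1")
        if min(self.raster_extent) < 1:
            raise ValueError("raster extent must be positive")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["ancestral_freq_range"] = list(d["ancestral_freq_range"])
        d["raster_extent"] = list(d["raster_extent"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticScenario":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["ancestral_freq_range"] = tuple(d["ancestral_freq_range"])
        d["raster_extent"] = tuple(d["raster_extent"])
        return cls(**d)


def chloroplast_like(seed: int = 0, **overrides) -> SyntheticScenario:
    """Haploid, few loci, strong structure (51 locales × 6 sequences)."""
    kw = dict(
        n_locales=51, samples_per_locale=6, ploidy=1, n_loci=120,
        fst_target=0.8, seed=seed,
    )
    kw.update(overrides)
    return SyntheticScenario(**kw)


def nuclear_like(seed: int = 0, **overrides) -> SyntheticScenario:
    """Diploid, many loci, weak structure (51 locales × 4 diploids = 408 alleles)."""
    kw = dict(
        n_locales=51, samples_per_locale=4, ploidy=2, n_loci=850,
        fst_target=0.1, seed=seed,
    )
    kw.update(overrides)
    return SyntheticScenario(**kw)


# ---------------------------------------------------------------------------
# landscapes
# ---------------------------------------------------------------------------


def make_landscape(
    scenario: SyntheticScenario, kind: str, **params
) -> RasterLayer:
    """Deterministic raster of the scenario's extent.

    Kinds
    -----
    ``constant``
        every pixel equals ``value`` (default 0).
    ``gradient``
        linear ramp from ``low`` to ``high`` along ``direction``
        (``east``/``west``/``north``/``south``); column c of an eastward
        ramp over ``ncols`` columns is ``low + (high−low)·c/(ncols−1)``.
    ``ridge``
        ``low`` background with a ``high`` band of fractional width
        ``width`` centred at fractional position ``center`` along ``axis``
        (``x`` or ``y``).
    ``categorical_patches``
        ``n_classes`` integer classes from quantile-binned smoothed noise;
        carries a class code table.
    """
    nr, nc = scenario.raster_extent
    if kind == "constant":
        grid = np.full((nr, nc), float(params.get("value", 0.0)))
        rkind = "continuous"
        table: dict[int, str] = {}
    elif kind == "gradient":
        low = float(params.get("low", 0.0))
        high = float(params.get("high", 100.0))
        direction = params.get("direction", "east")
        if direction in ("east", "west"):
            ramp = np.linspace(low, high, nc) if nc > 1 else np.array([low])
            if direction == "west":
                ramp = ramp[::-1]
            grid = np.tile(ramp, (nr, 1))
        elif direction in ("south", "north"):
            ramp = np.linspace(low, high, nr) if nr > 1 else np.array([low])
            if direction == "north":
                ramp = ramp[::-1]
            grid = np.tile(ramp[:, None], (1, nc))
        else:
            raise ValueError(f"unknown gradient direction {direction!r}")
        rkind = "continuous"
        table = {}
    elif kind == "ridge":
        low = float(params.get("low", 0.0))
        high = float(params.get("high", 100.0))
        center = float(params.get("center", 0.5))
        width = float(params.get("width", 0.2))
        axis = params.get("axis", "x")
        n = nc if axis == "x" else nr
        frac = (np.arange(n) + 0.5) / n
        band = np.where(np.abs(frac - center) <= width / 2, high, low)
        grid = np.tile(band, (nr, 1)) if axis == "x" else np.tile(band[:, None], (1, nc))
        rkind = "continuous"
        table = {}
    elif kind == "categorical_patches":
        n_classes = int(params.get("n_classes", 4))
        smooth = int(params.get("smooth", 6))
        rng = spawn_rng(scenario.seed, 10)
        noise = rng.normal(size=(nr, nc))
        # box-smooth the noise field to create spatially coherent patches
        kernel = np.ones(2 * smooth + 1) / (2 * smooth + 1)
        for ax in (0, 1):
            noise = np.apply_along_axis(
                lambda m: np.convolve(m, kernel, mode="same"), ax, noise
            )
        qs = np.quantile(noise, np.linspace(0, 1, n_classes + 1)[1:-1])
        grid = np.digitize(noise, qs).astype(float)
        rkind = "categorical"
        table = {i: f"class_{i}" for i in range(n_classes)}
    else:
        raise ValueError(f"unknown landscape kind {kind!r}")
    return RasterLayer(
        grid=grid,
        x_origin=0.0,
        y_origin=float(nr),
        pixel_size=1.0,
        kind=rkind,
        class_table=table,
    )


# ---------------------------------------------------------------------------
# locales and SNP data
# ---------------------------------------------------------------------------


def make_locales(
    scenario: SyntheticScenario, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Uniformly scattered locale coordinates inside the raster extent."""
    rng = rng or spawn_rng(scenario.seed, 11)
    nr, nc = scenario.raster_extent
    x = rng.uniform(0.5, nc - 0.5, size=scenario.n_locales)
    y = rng.uniform(0.5, nr - 0.5, size=scenario.n_locales)
    return pd.DataFrame(
        {
            "locale_id": [f"L{i:02d}" for i in range(scenario.n_locales)],
            "x": x,
            "y": y,
            "n_samples": scenario.samples_per_locale,
        }
    )


def _balding_nichols_freqs(
    p: np.ndarray, F: float, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-locale frequencies (k, L) around ancestral p with differentiation F."""
    if F == 0.0:
        return np.tile(p, (k, 1))
    ratio = (1.0 - F) / F
    a = np.clip(p * ratio, 1e-12, None)
    b = np.clip((1.0 - p) * ratio, 1e-12, None)
    return rng.beta(a[None, :], b[None, :], size=(k, p.size))


def _sample_genotypes(
    freqs: np.ndarray, scenario: SyntheticScenario, rng: np.random.Generator
):
    """Binomial dosage draws: (k·samples_per_locale, L) ints in {0..ploidy}."""
    k, L = freqs.shape
    reps = np.repeat(freqs, scenario.samples_per_locale, axis=0)
    return rng.binomial(scenario.ploidy, reps).astype(np.int16)


def _assemble(
    scenario: SyntheticScenario, geno: np.ndarray, locale_ids: list[str]
) -> SNPDataset:
    n = geno.shape[0]
    samples = [
        f"{loc}_s{j}"
        for loc in locale_ids
        for j in range(scenario.samples_per_locale)
    ]
    per_sample_locale = np.repeat(locale_ids, scenario.samples_per_locale)
    return SNPDataset(
        genotypes=geno,
        sample_ids=np.asarray(samples, dtype=object),
        locale_ids=np.asarray(per_sample_locale, dtype=object),
        ploidy=scenario.ploidy,
        locus_ids=np.asarray(
            [f"snp{j:05d}" for j in range(scenario.n_loci)], dtype=object
        ),
        n_sites_surveyed=scenario.sites_per_locus * scenario.n_loci,
    )


def simulate_snp_dataset(
    scenario: SyntheticScenario,
) -> tuple[SNPDataset, pd.DataFrame]:
    """Balding–Nichols SNP dataset plus its locale coordinate table.

    Monomorphic loci (possible at extreme frequencies) are retained in the
    dataset but flagged by ``SNPDataset.polymorphic_mask`` and excluded from
    statistics downstream.
    """
    rng = spawn_rng(scenario.seed, 12)
    lo, hi = scenario.ancestral_freq_range
    p = rng.uniform(lo, hi, size=scenario.n_loci)
    freqs = _balding_nichols_freqs(p, scenario.fst_target, scenario.n_locales, rng)
    geno = _sample_genotypes(freqs, scenario, rng)
    locales = make_locales(scenario)
    return _assemble(scenario, geno, list(locales["locale_id"])), locales


def simulate_barrier_scenario(
    scenario: SyntheticScenario,
    barrier_strength: float,
    barrier_raster: RasterLayer | None = None,
) -> tuple[SNPDataset, pd.DataFrame, RasterLayer]:
    """Two locale clusters separated by a high-value raster band.

    Locales are placed on both sides of a central vertical barrier (a
    ``ridge`` raster by default).  Allele frequencies follow a hierarchical
    Balding–Nichols model: ancestral → two cluster frequencies with
    ``F = barrier_strength`` → locale frequencies with
    ``F = scenario.fst_target`` inside each cluster, so cross-barrier
    genetic covariance is depressed relative to within-side covariance.
    ``barrier_strength = 0`` collapses to the single-population model.
    """
    if not (0.0 <= barrier_strength < 1.0):
        raise ValueError("barrier_strength must lie in [0, 1)")
    nr, nc = scenario.raster_extent
    if barrier_raster is None:
        barrier_raster = make_landscape(
            scenario, "ridge", axis="x", center=0.5, width=0.2, low=0.0, high=100.0
        )
    rng = spawn_rng(scenario.seed, 13)
    k = scenario.n_locales
    n_left = k // 2
    n_right = k - n_left
    if n_left == 0 or n_right == 0:
        raise ValueError("locales must be placed on both sides of the barrier")
    # keep clear of the central band (fractional width 0.2 around 0.5)
    xl = rng.uniform(0.02 * nc, 0.35 * nc, size=n_left)
    xr = rng.uniform(0.65 * nc, 0.98 * nc, size=n_right)
    y = rng.uniform(0.5, nr - 0.5, size=k)
    locales = pd.DataFrame(
        {
            "locale_id": [f"L{i:02d}" for i in range(k)],
            "x": np.concatenate([xl, xr]),
            "y": y,
            "n_samples": scenario.samples_per_locale,
            "side": ["west"] * n_left + ["east"] * n_right,
        }
    )
    lo, hi = scenario.ancestral_freq_range
    p = rng.uniform(lo, hi, size=scenario.n_loci)
    cluster = _balding_nichols_freqs(p, barrier_strength, 2, rng)
    freqs = np.empty((k, scenario.n_loci))
    freqs[:n_left] = _balding_nichols_freqs(
        cluster[0], scenario.fst_target, n_left, rng
    )
    freqs[n_left:] = _balding_nichols_freqs(
        cluster[1], scenario.fst_target, n_right, rng
    )
    geno = _sample_genotypes(freqs, scenario, rng)
    dataset = _assemble(scenario, geno, list(locales["locale_id"]))
    return dataset, locales, barrier_raster


def write_locales_csv(locales: pd.DataFrame, path: str | Path) -> None:
    locales.to_csv(path, index=False)


def write_sample_locale_map(dataset: SNPDataset, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": dataset.sample_ids, "locale_id": dataset.locale_ids}
    ).to_csv(path, index=False)
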