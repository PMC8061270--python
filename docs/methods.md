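# Methods

This note documents the models, estimators, null models, and numerical
choices implemented in `landgraph`, and what the synthetic generator does
and does not emulate.

## Data model

All genetic computation operates on a locale-labelled allele-dosage matrix
(`SNPDataset`): samples × biallelic SNP loci, dosages in {0..ploidy} with a
missing sentinel, each sample assigned to exactly one locale. A surveyed
sequence length L (≥ number of loci) scales diversity to per-nucleotide
units; it defaults to 50 sites per SNP locus in synthetic data, a
SNP-density typical of amplicon panels. Missing genotypes are handled by
pairwise deletion per locus throughout.

## Diversity statistics

- θ<sub>π</sub> = Σ<sub>l</sub> k<sub>l</sub>(n<sub>l</sub>−k<sub>l</sub>) / C(n<sub>l</sub>,2) / L,
  with k the alternate-allele count and n the callable allele count per
  locus.
- θ<sub>S</sub> = S/(a₁L), a₁ = Σ<sub>i=1</sub><sup>n−1</sup> 1/i, with n
  the group's allele count.
- Tajima's D uses the 1989 constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂)
  computed from n, on the concatenated SNP set of the group; one D per
  dataset. D is undefined when S = 0 and is returned as NaN with a warning,
  never silently 0.

## Hudson's F<sub>ST</sub>

Per locus, H<sub>w</sub> per locale is the mean pairwise difference among
its alleles (equivalently 2p(1−p)·n/(n−1)), averaged over the two locales;
H<sub>b</sub> = p₁(1−p₂) + p₂(1−p₁). Multi-locus and global values combine
loci (and, for the global value, all locale pairs) as a ratio of averages —
Σ(H<sub>b</sub>−H̄<sub>w</sub>) / ΣH<sub>b</sub> — never an average of
per-locus ratios, which is unstable for low-diversity loci. Negative
estimates are reported as computed; clamping would bias permutation nulls.
The pairwise matrix is computed with a masked matrix-product formulation so
the panmixia permutation (below) can recompute all 1275 pairs per replicate
cheaply.

**Panmixia test.** All individuals are pooled and re-dealt to locales
preserving each locale's sample size — a permutation of whole individuals
without replacement (the exact null); a with-replacement bootstrap mode
exists behind a flag. p-values use the add-one rule, upper tail, so p is
never 0 and identical (data, n_perm, seed) gives bit-identical results.

## Population graph and cGD

1. **Encoding.** One centred column per polymorphic locus carrying the
   alternate-allele dosage (the reference column is dropped to avoid exact
   collinearity); monomorphic loci contribute nothing; missing dosages are
   mean-imputed per column before centring.
2. **Covariance.** Locale centroids give squared Euclidean distances D²,
   Gower-centred to C = −½JD²J. The Gower identity
   d²<sub>ij</sub> = c<sub>ii</sub>+c<sub>jj</sub>−2c<sub>ij</sub> is
   preserved to 1e−8 and tested.
3. **Precision.** Gower centring leaves an exact null direction (the ones
   vector), so C is inverted on its row space: eigenvalues below
   1e−12·λmax are excluded and the rest inverted. If the retained spectrum
   is ill-conditioned (condition number ≥ 1e10), diagonal shrinkage δ
   doubles from 1e−8 up to 1e−2; δ is recorded in graph attributes, and
   failure beyond δ = 1e−2 is an explicit error naming the condition
   number. Inverting the naively shrunk full matrix would let the null
   direction dominate and saturate the graph with spurious |ρ| ≈ 1 edges.
4. **Pruning.** Partial correlation ρ<sub>ij</sub> = −Ω<sub>ij</sub>/√(Ω<sub>ii</sub>Ω<sub>jj</sub>);
   edge-exclusion deviance −n·ln(1−ρ²) compared to χ²₁; an edge is retained
   iff its exclusion is rejected at α (default 0.05, no multiplicity
   correction by default, Bonferroni behind a flag). n defaults to the
   number of sampled individuals and is configurable — the literature is
   ambiguous between individuals and strata. Edge weight is the centroid
   distance √(c<sub>ii</sub>+c<sub>jj</sub>−2c<sub>ij</sub>).
5. **cGD.** All-pairs Dijkstra over retained edges; unreachable pairs are
   flagged and exported as "NA", never infinity. Isolated nodes (degree 0)
   are reported; in this framework they indicate a locale adds no
   conditional-covariance information, not biological isolation.

Planted-structure validation samples n = 200 draws from chain-structured
precision matrices (off-diagonal partial correlation 0.45) on 4–8 nodes and
requires exact recovery in ≥95 of 100 replicates. That check runs at
α = 10⁻³ rather than the 0.05 default: exact recovery requires all true
non-edges to stay excluded, and at α = 0.05 the false-edge rate alone caps
the exact-recovery probability at 0.95²¹ ≈ 0.81 for 8 nodes, so a test of
*exact* structure must spend less type-I error per candidate edge. At
ρ = 0.45 and n = 200 the per-edge power at α = 10⁻³ is ≈ 1 − 5·10⁻⁵, so the
stricter level costs essentially no power.

## Network metrics and their null

Degree (edge count), closeness (reciprocal of the mean weighted
shortest-path distance to reachable nodes; NaN for isolated nodes),
betweenness (weighted, normalized to a fraction of pairs), eigenvector
centrality (leading eigenvector per connected component, unit Euclidean
norm, on similarity weights 1/w — distance weights would invert its
meaning).

The permutation test statistic is the mean metric over a focus subset.
Null replicates randomize topology — `edge_permutation` draws a uniformly
random simple graph with the same node set and edge count;
`degree_preserving` performs ≥10·|E| successful double-edge swaps — and
re-deal the observed edge-weight multiset onto the new edges, keeping the
metric scale comparable between observed and null. Two-sided p by default
(doubled smaller tail, capped at 1). A graph admitting no swap (e.g. a
star) raises an explicit error.

## Landscape overlay and permutation

Edges are straight Euclidean segments between locale coordinates (the
method overlays graph connections directly; least-cost routing is a
non-goal). Pixel traversal is the *supercover* — every pixel the segment
touches, via Amanatides–Woo grid walking — so short diagonal edges are not
under-sampled; traversal is symmetric in its endpoints. Nodata pixels are
excluded from statistics and counted separately; an edge is flagged missing
only when fully nodata. Continuous rasters yield per-edge mean and
population variance; categorical rasters yield per-class proportions —
mean/variance of class codes is meaningless and never computed. No
reprojection is performed: coordinates must share the raster's CRS, and
points outside the extent fail fast.

The permutation test aggregates a per-edge statistic over the graph's edges
(mean of per-edge means/variances/class proportions) and compares it to
degree-preserving rewirings with node positions fixed. Per-pair transect
summaries are computed once and cached, so replicates only re-aggregate.

## MLPE regression

Rows of the pair table (one per unordered locale pair; predictors z-scored,
constant predictors dropped with a warning) are correlated whenever they
share a locale. With B the pair–locale incidence matrix, the sharing
indicator A = BBᵀ − 2I has smallest eigenvalue −2, so the covariance
V = σ²(I + ρA) is positive definite iff ρ < 0.5 — the same bound as the
random-locale-effect form ρ = σ²ᵤ/(2σ²ᵤ+σ²ₑ). The likelihood is maximized
by profiling β and σ² analytically in the eigenbasis of BBᵀ (an O(mk²) SVD
of B; no m×m decomposition) and optimizing the scalar ρ on [0, 0.5) by
bounded Brent search; the ρ = 0 boundary is checked explicitly and
reproduces OLS to 1e−6. ML rather than REML so AIC is comparable across
fixed-effect structures; AIC counts coefficients plus ρ and σ².
Pseudo-R² is the squared Pearson correlation of fitted vs observed — a
deliberate, documented choice, since "variance explained" is not uniquely
defined under correlated errors.

## Synthetic generator

`simulate_snp_dataset` draws, per locus, an ancestral frequency
p ~ Uniform(0.1, 0.9) (avoiding near-fixed loci dominating the variance),
then per-locale frequencies from the Balding–Nichols
Beta(p(1−F)/F, (1−p)(1−F)/F) with F the target differentiation, and
genotypes binomially. E[Hudson F<sub>ST</sub>] = F under this model, which
is what makes parameter recovery assertable (the package recovers
F ∈ {0.1, 0.3, 0.5, 0.8} within ±0.05 at 51 locales × 6 haploids × 500
loci). `simulate_barrier_scenario` adds a hierarchical layer: two clusters
at F = barrier_strength around the ancestral frequency, locales at the
scenario F within clusters, with coordinates placed on opposite sides of a
high-valued raster band. Landscapes are deterministic gradients, ridges,
constants, or quantile-binned smoothed-noise categorical patches; all
generators are pure functions of (scenario, seed), with sub-streams derived
from one global seed. Coordinates are planar map units so Euclidean
distances are exact.

What the generator does **not** emulate: coalescent genealogies (the site
frequency spectrum is governed by the uniform ancestral-frequency draw, so
Tajima's D on pooled structured data is strongly positive by construction
and carries no demographic signal), linkage between loci, mutation or
dispersal mechanisms, and missing-data patterns. Passing tests therefore
demonstrate estimator and test correctness and calibration — not that real
data meet these assumptions.

## Calibration and problem sizes

Permutation calibration uses 200 seeded runs per engine with 199 replicates
each (p-values then live on a fine enough grid for a Kolmogorov–Smirnov
check at the 0.01 level), small datasets (2–12 locales, 10–60 loci) for the
nulls, and 400 two-locale runs for the empirical size of the panmixia test
(0.05 ± 0.02 at α = 0.05). Planted-signal checks use 20 seeded runs each:
the barrier scenario at 40 locales × 300 loci (barrier F = 0.4 over
within-side F = 0.15) against a ridge raster, and a 40-node graph with a
10-node cluster at 3× the background edge retention of 0.15. MLPE recovery
uses 50 seeds at 40 locales (780 pairs). These sizes were chosen to give
each check clear statistical resolution while keeping the full suite fast
on a single CPU.

## Known limitations

- Only biallelic SNPs; multi-allelic sites are skipped on VCF import.
- Watterson's θ and Tajima's D use the group's nominal allele count;
  heavily missing data would bias them (π and F<sub>ST</sub> use per-locus
  callable counts).
- The edge-exclusion deviance is asymptotic in n and treats the centroid
  covariance as if estimated without error from individuals.
- Raster I/O is ESRI ASCII grid only, single-band, square pixels.
- The replication-mode quantities reported for the original field study
  (global F<sub>ST</sub>, D, isolated-node counts) require that study's
  deposited dataset; the pipeline accepts such data as VCF/CSV + locale
  coordinates, but exact reproduction additionally depends on encoding and
  deviance-sample-size conventions of the original graph software, which
  are not fully specified.
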