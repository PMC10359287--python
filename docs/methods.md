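# Methods

## Data model

The atomic record is one quadrat (0.25 m², 50 × 50 cm) with a taxon →
wet-weight biomass map and (year, region, reef, quadrat) labels; reefs are
nested in year × region and quadrats replicate reefs. The canonical exchange
format is a long (tidy) CSV; a wide sample × taxon matrix with explicit
zeros over the dataset's taxon union is derived for dissimilarities and
richness. Taxon names are opaque labels compared after whitespace trimming,
case-sensitively. The taxon catalog carries rank (species / genus / family),
morpho-functional group (encrusting, turf, subcanopy, canopy) and an
optional STI in °C (validated to [−5, 40]). Genus- and family-rank taxa are
kept in the descriptors (richness counts every identified taxon) but are
excluded from CTI, which is defined on species-level thermal indices; a
`species_only` switch restricts descriptors too.

## Species temperature index

The STI is the 0.50 quantile of SST over the species' area of occupancy.
The occupancy comes from binarizing a continuous suitability surface at the
max-SSS threshold: among the unique observed model scores, the one
maximizing sensitivity + specificity of classifying presence vs background
points, with rates (not raw counts) so unequal class sizes do not bias the
threshold, and ties broken toward the smallest threshold (the more inclusive
map). Quantiles use linear interpolation between order statistics, so
even-count medians are midpoints; this convention is stated because the STI
shifts under others. Cells are equal-weighted (no latitude-dependent area
correction — at the ~5-arcmin scale of typical SST layers the cell-area
differences across a species' range are second-order); missing-SST cells
inside the mask are dropped, not imputed. Rasters are exchanged as ESRI
ASCII grids (plain text, `NODATA_value` supported); model scores as
`point_id,kind,score` CSV.

## CTI and the four-process decomposition

`CTI = Σ wᵢ·STIᵢ / Σ wᵢ` with raw biomass weights — the square-root
transform used in the dissimilarity analyses is never applied to CTI
weights. Species lacking an STI are excluded from numerator and denominator;
the reported `coverage` is the biomass fraction they leave behind. Reef CTIs
pool the reef's quadrats; region and dataset CTIs are means (± SE) of reef
CTIs, treating reefs as the replicates (consistent with the ANOVA, which
also operates on reef-level variation).

For the change between two surveys within a region: species shares
`w_t` are each species' fraction of the region-time's total eligible
biomass (pooling removes total-biomass drift from the abundance-change
signal; per-reef sharing then averaging is a documented alternative not
used by default). The reference CTI is the mean of the region's reef CTIs
pooled over both times — one fixed vertical line per region — with a
`time1` alternative selectable. A species with STI above (below) the
reference is warm- (cold-) affinity; exact equality is neutral and excluded.
The sign table maps (affinity, sign of dw) to tropicalization /
borealization / detropicalization / deborealization; `dw = 0` contributes
nothing. Strengths are accumulated both as `Σ|dw|` and as
`Σ|dw|·|STI − ref|`; the dominant process uses the CTI-weighted metric.
The weighted metric is the discriminating one: because shares sum to 1,
the total `|dw|` of gainers always equals that of losers, so whenever all
gainers share one affinity class and all losers the other, the unweighted
sums tie exactly.

## Community descriptors

Richness counts taxa with biomass > 0 (explicit zeros excluded). Shannon H′
uses biomass shares in natural log — wet weight is the only abundance
measure collected — and Pielou J′ = H′/ln S is reported as undefined (NaN)
for S ≤ 1. Group biomass sums within the four morpho-functional classes and
errors on unclassified taxa; classified group totals conserve total biomass
exactly.

## Multivariate testing

Bray–Curtis dissimilarity `d = Σ|x−y| / Σ(x+y)` is computed (scipy) on
optionally square-root transformed biomass; a pair of all-zero samples gets
d = 0 with a warning. Sums of squares are partitioned directly from squared
dissimilarities: `W(G) = Σ_g (1/n_g) Σ_{i<j∈g} d²ᵢⱼ` within any grouping and
`SS_total = (1/N) Σ_{i<j} d²ᵢⱼ`, giving the standard balanced decomposition
(Time, Region, Time×Region, Reef(T×R), Residual); on Euclidean distances and
one factor this reduces exactly to classical ANOVA. Two denominator presets
are shipped: `ems` tests every fixed term over Reef(T×R), the
expected-mean-squares rule; `printed` (default) additionally tests Region
over Time×Region, reproducing the pseudo-F layout used in the reference
survey's published multivariate table, whose Region denominator differs
from its univariate one — the discrepancy cannot be resolved from the
published account, so both maps are named options.

Permutations act on exchangeable units per term: terms tested against
Reef(T×R) permute whole reef units (Time labels within region strata,
Region labels within time strata, free unit permutation for the
interaction), while the Reef term permutes quadrats among reefs within each
Time × Region cell. p-values use the +1 convention,
`p = (1 + #{F* ≥ F}) / (1 + n_perm)`, and are reproducible given (seed,
n_perm). Pairwise contrasts are one-way sample-level PERMANOVAs restricted
to two levels, reporting F, R² = SS_between/SS_total and p. Only balanced
designs are supported; unbalanced input raises.

PCoA Gower-centers `−½d²` and keeps negative eigenvalues as imaginary axes;
pairwise distances reconstruct as `√(Δreal² − Δimag²)`. PERMDISP computes
each sample's distance to its group centroid in that space via the
equivalent direct form `(1/n_g)Σ_j d²ᵢⱼ − (1/n_g²)Σ_{j<k} d²ⱼₖ` (clamped at
0), applies a one-way F to the distances, and permutes group labels over
the fixed distances for the p-value — centroids are not recomputed per
permutation, a deliberate simplification of the residual-permutation scheme.
Between-group sums below 10⁻¹² of the total are treated as 0 so congruent
configurations report F = 0 exactly. NMDS is deliberately not implemented:
it is visualization-only in this workflow and PCoA carries the testing
machinery.

## Univariate testing

The balanced mixed model has Time and Region fixed and Reef random, nested
in Time × Region. Sums of squares come from marginal means; with a time
levels, b regions, r reefs per cell and n quadrats per reef, the dfs are
(a−1), (b−1), (a−1)(b−1), ab(r−1), abr(n−1). The expected mean squares put
σ²_reef under every fixed effect, so Time, Region and Time×Region are tested
over MS_Reef(T×R) and Reef over the Residual; applying this rule to the
reference survey's published richness mean squares (1584.2, 946.12 over 61)
reproduces its published F ratios (25.970, 15.510) to three decimals, which
fixes the denominator choice.

Cochran's C = max s²ₖ / Σ s²ₖ over the ab·r cell variances. Its p-value uses
the Bonferroni × F-tail relation — `F = (k−1)C/(1−C)` referred to
F(ν, (k−1)ν) with ν = n−1 and multiplied by k — validated against a
Monte-Carlo null (k = 30, n = 6: empirical rejection at nominal 5% is
within ±0.01 over 10⁴ draws). Transforms (none / ln / √) are caller-declared
per response, as heteroscedasticity handling is a modeling choice, and
recorded in the table; heterogeneous-variance results are annotated, never
suppressed (balanced ANOVAs are robust, and conclusions should lean on
p ≪ 0.05 in that case).

SNK compares ordered means stepwise with the studentized-range quantile
q(α, span, df)·√(MS/n), freezing the interior of any non-significant span;
ties in the sorted means break by level label for determinism. On k = 2 the
procedure coincides with a single studentized-range test. Homogeneous
subsets are rendered as e.g. `VIA < PEN = SIN`.

## Synthetic communities

The simulator exists so every stage has a ground truth. Species have
Gaussian thermal responses — the minimal model under which "warm-affinity
species increase under warming" is literally true — with optima that are
the true STIs. Realized quadrat biomass multiplies the expected response by
lognormal noise (mean 1, cv default 0.35) and a Bernoulli absence
(p default 0.10): positive, right-skewed abundance with true zeros. Reefs
add an additive temperature offset (sd default 0.15 °C) drawn once per
(region, reef) and shared across surveys, inducing the reef-level variance
the nested design tests while keeping a no-change scenario exactly
reproducible at time 2. Default region SSTs (13.5, 15.0, 15.8 °C) mirror a
summer latitudinal gradient on an upwelling-moderated temperate coast, and
the default warming increment is +1 °C. All randomness flows from one
master seed through named `SeedSequence` substreams.

The default niche set is warm-skewed: two cold canopy/sub-canopy formers
near the community's thermal centre of mass and a tail of warm turf and
encrusting species. Under warming, share losses occur close to the reference
CTI while gains accumulate far above it, so the CTI-weighted decomposition
is dominated by tropicalization — the configuration in which tropicalization
recovery is well-posed. The cold-loss scenario instead uses a cold-dominated
set whose very cold species (optima ≳ 2.5 °C below the reference) lose
biomass while species near the reference absorb the share gain; analysis of
the weighted metric shows this separation is required for deborealization to
dominate, since the mirror-image share gains would otherwise tie or win.
Raster fixtures place a linear SST gradient along grid rows, define
suitability as the normalized Gaussian response, and sample presences with
probability proportional to suitability against a uniform background.

What the simulator does **not** emulate: real species pools or dispersal,
within-region SST structure beyond a scalar reef offset, inter-species
interactions (each species responds independently), observation error in
taxonomy, or unbalanced/missing sampling. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated generative
model, not robustness to these field realities.

## Problem sizes and numerical choices

Recovery and calibration runs use the full 2 × 3 × 5 × 6 design (180
quadrats) for decomposition (200 seeds per scenario) and a reduced balanced
2 × 3 × 3 × 4 layout (72 samples, 499 permutations, 500 seeds) for the
PERMANOVA type-I study, sizes at which the Monte-Carlo standard error of a
5% rate is well under the ±2-point acceptance band. Permutation p-values
can never be 0 (+1 convention); permutation counts default to 999 in the
library and 9999 in the CLI. Degenerate inputs are handled explicitly:
constant ANOVA responses flag the table rather than dividing by zero,
all-identical PERMDISP inputs report F = 0, p = 1, and a degenerate
(single-value) score set returns that value as threshold with a warning.

## Known limitations

- Balanced designs only, by construction; there is no Type-II/III
  partitioning for unbalanced data.
- Exactly two survey times for the decomposition; no CTI trend regression.
- PERMDISP's permutation fixes centroid distances (see above), which is
  slightly liberal relative to recomputing centroids per permutation.
- The package consumes suitability surfaces; it does not fit niche models,
  retrieve occurrences, or ensemble model replicates — one surface per
  species, ensembling left to the caller.
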