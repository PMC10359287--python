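# seatherm

Thermal-affinity analysis of subtidal seaweed communities.

Biodiversity resurvey programs on temperate rocky reefs ask whether
communities are *tropicalizing* — whether warm-affinity species are gaining
dominance as the sea warms. `seatherm` implements the full quantitative
chain such studies use, for ecologists who have (or want to simulate) a
balanced quadrat survey repeated across years, regions and reefs:

- **STI** — the species temperature index: the median (50th percentile) of
  sea-surface temperatures over a species' modeled area of occupancy. The
  package consumes a continuous habitat-suitability surface plus an aligned
  SST raster, binarizes the surface at the threshold that maximizes
  sensitivity + specificity on presence vs background model scores
  (max SSS), and extracts the SST quantiles over the occupied cells.
- **CTI** — the community temperature index,
  `CTI = Σᵢ wᵢ·STIᵢ / Σᵢ wᵢ`, the biomass-weighted mean STI of the species
  present. Reef CTIs are computed on quadrat-pooled biomass; region and
  dataset values are means (± SE) over reef CTIs.
- **Four-process decomposition** of CTI change between two surveys: each
  species' share change `dw = w₂ − w₁` is classed, relative to the region's
  reference CTI, as tropicalization (warm-affinity gain), borealization
  (cold-affinity gain), detropicalization (warm loss) or deborealization
  (cold loss), with process strengths `Σ|dw|` and `Σ|dw|·|STI − CTI_ref|`.
- **Community descriptors** — richness, Shannon H′ (nats, biomass shares),
  Pielou J′, standing biomass, and biomass per morpho-functional group
  (encrusting / turf / sub-canopy / canopy).
- **Multivariate tests** — Bray–Curtis dissimilarities on square-root
  transformed biomass; three-factor PERMANOVA with Time (fixed), Region
  (fixed, crossed) and Reef (random, nested in Time × Region); pairwise
  one-way contrasts; PCoA retaining negative eigenvalues; PERMDISP.
- **Univariate tests** — balanced mixed-model ANOVA with expected-mean-square
  denominators (fixed effects over MS_Reef(T×R)), Cochran's C homogeneity
  check, log/sqrt transforms, and Student–Newman–Keuls post-hoc grouping.
- **A synthetic-community simulator** in which species follow Gaussian
  thermal response curves `b(T) = b_max·exp(−(T − t_opt)²/2σ²)` with known
  optima (= true STIs), so every stage can be validated against closed-form
  truth: CTI recovery, decomposition recovery under warming or
  cold-species-loss scenarios, and permutation-test calibration.

## Worked example

```sh
python examples/04_cti_and_decomposition.py
```

simulates the default warming survey (2 surveys × 3 regions × 5 reefs ×
6 quadrats, +1 °C between surveys) and prints:

```
Dataset CTI (mean +/- SE over the 15 reef CTIs per survey):
year    cti  cti_se  n_reefs
2012 14.770   0.122       15
2018 15.286   0.159       15

Per-region decomposition (|dw| x |STI - reference| metric):

  PEN (reference CTI 15.04 degC)
    tropicalization    0.239  <- dominant
    borealization      0.000
    detropicalization  0.000
    deborealization    0.180
  ...
```

The dataset CTI rises by ≈0.5 °C between the surveys — biomass shares shift
toward species with optima above the ambient temperature — and in every
region the dominant process is tropicalization, matching the simulator's
ground truth. The other `examples/` scripts cover the simulator, STI
estimation from rasters, descriptors, the multivariate tests and the mixed
ANOVA with SNK grouping.

A thin CLI wraps the same functions (`seatherm simulate | sti | descriptors
| cti | decompose | permanova | permdisp | anova | run | report`); `seatherm
run --config cfg.yaml` executes the whole pipeline from a YAML config and
writes CSV tables plus a manifest.

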