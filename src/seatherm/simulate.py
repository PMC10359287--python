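"""Synthetic survey and raster generator with known thermal truth.

Species carry Gaussian thermal response curves whose optima are the true
STIs, so CTI and decomposition recovery can be checked against closed forms.
The default design mirrors a balanced 2 (time) x 3 (region) x 5 (reef) x
6 (quadrat) subtidal survey on a latitudinal SST gradient, with a warming
increment between the two campaigns.

All randomness flows from one master seed through named ``SeedSequence``
substreams, so each stage is reproducible in isolation.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import CommunitySample, StudyDesign, TaxonCatalog
from .errors import UndefinedValueError, ValidationError


@dataclass(frozen=True)
class NicheSpec:
    """Gaussian thermal response of one species.

    ``t_opt`` (deg C) is the thermal optimum and the species' true STI;
    ``sigma`` (deg C) the niche breadth; ``b_max`` (g / 0.25 m^2) the peak
    expected biomass; ``group`` the morpho-functional class.
    """

    taxon: str
    t_opt: float
    sigma: float
    b_max: float
    group: str = "turf"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError(f"{self.taxon}: sigma must be > 0")
        if self.b_max <= 0:
            raise ValidationError(f"{self.taxon}: b_max must be > 0")

    def response(self, temperature) -> np.ndarray:
        """Expected biomass at the given temperature(s)."""
        t = np.asarray(temperature, dtype=float)
        return self.b_max * np.exp(-((t - self.t_opt) ** 2) / (2.0 * self.sigma**2))


@dataclass(frozen=True)
class ScenarioSpec:
    """Environmental scenario for one simulated survey.

    ``region_sst`` maps region to its mean summer SST (deg C) at time 1;
    ``delta_t`` is the warming increment applied at time 2; ``noise_cv`` the
    coefficient of variation of the multiplicative lognormal biomass noise;
    ``p_absent`` the probability a taxon is absent from a quadrat;
    ``reef_sd`` the s.d. of the per-reef additive temperature offset;
    ``cold_loss`` an optional time-2 biomass reduction (fraction in [0, 1))
    applied to species whose optimum lies more than 1 deg C below their
    region's SST — a stylized loss of cold-affinity species.
    """

    region_sst: Mapping[str, float] = field(
        default_factory=lambda: {"VIA": 13.5, "PEN": 15.0, "SIN": 15.8}
    )
    delta_t: float = 1.0
    noise_cv: float = 0.35
    p_absent: float = 0.10
    reef_sd: float = 0.15
    cold_loss: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if not 0 <= self.p_absent < 1:
            raise ValidationError("p_absent must lie in [0, 1)")
        if not 0 <= self.cold_loss < 1:
            raise ValidationError("cold_loss must lie in [0, 1)")


def default_niches() -> list[NicheSpec]:
    """Warm-skewed reference community: two cold canopy formers near the
    community's thermal centre of mass and a long tail of warm turf and
    encrusting species. Under warming, share gains concentrate far above the
    reference CTI, so tropicalization is the dominant signed process."""
    return [
        NicheSpec("Frigidaria_borealis", 13.0, 2.5, 30.0, "canopy"),
        NicheSpec("Boreophyllum_crassum", 13.5, 2.5, 25.0, "subcanopy"),
        NicheSpec("Mediale_tepidum", 15.0, 2.5, 12.0, "subcanopy"),
        NicheSpec("Calidella_gracilis", 16.0, 2.5, 15.0, "turf"),
        NicheSpec("Calidella_minor", 17.0, 2.5, 12.0, "turf"),
        NicheSpec("Thermophyca_rubra", 18.0, 2.5, 10.0, "turf"),
        NicheSpec("Thermophyca_crustosa", 19.0, 2.5, 8.0, "encrusting"),
        NicheSpec("Australina_extrema", 20.0, 2.5, 6.0, "encrusting"),
    ]


def cold_loss_niches() -> list[NicheSpec]:
    """Cold-dominated community used for the cold-species-loss scenario:
    the very cold species sit far below the reference CTI while the species
    absorbing their share sit close to it, so the weighted decomposition is
    dominated by deborealization rather than by the mirror-image share gains."""
    return [
        NicheSpec("Glacialis_magna", 10.0, 2.5, 40.0, "canopy"),
        NicheSpec("Glacialis_minor", 11.0, 2.5, 40.0, "canopy"),
        NicheSpec("Mediale_densum", 12.5, 2.5, 20.0, "subcanopy"),
        NicheSpec("Mediale_tepidum", 13.0, 2.5, 20.0, "subcanopy"),
        NicheSpec("Calidella_gracilis", 14.5, 2.5, 8.0, "turf"),
        NicheSpec("Thermophyca_rubra", 15.5, 2.5, 6.0, "turf"),
    ]


def cold_loss_scenario(seed: int = 0) -> ScenarioSpec:
    """No warming; 60% time-2 biomass loss of species > 1 deg C below SST."""
    return ScenarioSpec(
        region_sst={"VIA": 13.2, "PEN": 13.5, "SIN": 13.8},
        delta_t=0.0,
        cold_loss=0.6,
        seed=seed,
    )


def catalog_from_niches(niches: Sequence[NicheSpec]) -> TaxonCatalog:
    """Catalog for a simulated community; STIs are the true optima."""
    return TaxonCatalog.from_records(
        [(n.taxon, "species", n.group, n.t_opt) for n in niches]
    )


@dataclass
class SimulationTruth:
    """Ground truth accompanying a simulated survey."""

    t_opt: dict[str, float]
    cell_temperature: pd.DataFrame  # one row per (year, region, reef) with temp_c
    expected_biomass: pd.DataFrame  # (year, region, reef) x taxon expected g/quadrat


def _streams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    names = ("reef_offsets", "noise", "zeros", "rasters")
    return {n: np.random.default_rng(s) for n, s in zip(names, root.spawn(len(names)))}


def simulate_community(
    niches: Sequence[NicheSpec],
    scenario: ScenarioSpec,
    design: StudyDesign | None = None,
) -> tuple[list[CommunitySample], SimulationTruth]:
    """Simulate a balanced survey under the scenario.

    Expected biomass of taxon i in a quadrat at site temperature T is
    ``b_max_i * exp(-(T - t_opt_i)^2 / (2 sigma_i^2))``; realized biomass
    multiplies lognormal noise with mean 1 and cv ``noise_cv`` and is zeroed
    with probability ``p_absent``. Reefs within a region share the region SST
    plus a per-reef offset drawn once. Identical inputs give identical output.
    """
    if not niches:
        raise ValidationError("at least one niche is required")
    design = design or StudyDesign()
    missing = [r for r in design.regions if r not in scenario.region_sst]
    if missing:
        raise ValidationError(f"scenario lacks SST for region(s) {missing}")
    rng = _streams(scenario.seed)

    # one additive offset per (region, reef), shared by both surveys, so a
    # no-change scenario with noise off reproduces time 1 exactly at time 2
    reef_keys = [
        (region, f"reef{j + 1}")
        for region in design.regions
        for j in range(design.reefs_per_cell)
    ]
    offset_of = dict(
        zip(reef_keys, rng["reef_offsets"].normal(0.0, scenario.reef_sd, len(reef_keys)))
    )
    units = [
        (year, region, f"reef{j + 1}")
        for year in design.times
        for region in design.regions
        for j in range(design.reefs_per_cell)
    ]

    if scenario.noise_cv > 0:
        sigma_ln = float(np.sqrt(np.log1p(scenario.noise_cv**2)))
    else:
        sigma_ln = 0.0

    samples: list[CommunitySample] = []
    temp_rows = []
    expected_rows = []
    taxa = [n.taxon for n in niches]
    for year, region, reef in units:
        warmed = year != design.times[0]
        temp = (scenario.region_sst[region]
                + (scenario.delta_t if warmed else 0.0)
                + offset_of[(region, reef)])
        mean_b = np.array([n.response(temp) for n in niches], dtype=float)
        if warmed and scenario.cold_loss > 0:
            cold = np.array(
                [n.t_opt < scenario.region_sst[region] - 1.0 for n in niches]
            )
            mean_b = np.where(cold, mean_b * (1.0 - scenario.cold_loss), mean_b)
        temp_rows.append((year, region, reef, temp))
        expected_rows.append((year, region, reef, *mean_b))
        for q in range(1, design.quadrats_per_reef + 1):
            if sigma_ln > 0:
                noise = rng["noise"].lognormal(-0.5 * sigma_ln**2, sigma_ln, len(niches))
            else:
                noise = np.ones(len(niches))
            if scenario.p_absent > 0:
                present = rng["zeros"].random(len(niches)) >= scenario.p_absent
            else:
                present = np.ones(len(niches), dtype=bool)
            biomass = mean_b * noise * present
            samples.append(
                CommunitySample(
                    sample_id=f"{year}-{region}-{reef}-q{q}",
                    year=year,
                    region=region,
                    reef=reef,
                    quadrat=q,
                    biomass=dict(zip(taxa, biomass.astype(float))),
                )
            )
    truth = SimulationTruth(
        t_opt={n.taxon: n.t_opt for n in niches},
        cell_temperature=pd.DataFrame(
            temp_rows, columns=["year", "region", "reef", "temp_c"]
        ),
        expected_biomass=pd.DataFrame(
            expected_rows, columns=["year", "region", "reef", *taxa]
        ),
    )
    return samples, truth


def expected_cti(niches: Sequence[NicheSpec], temperature: float) -> float:
    """Closed-form CTI of the noise-free community at the given temperature:
    sum b_i(T) t_opt_i / sum b_i(T)."""
    if not niches:
        raise ValidationError("at least one niche is required")
    responses = np.array([n.response(temperature) for n in niches], dtype=float)
    total = responses.sum()
    if total <= np.finfo(float).tiny:
        raise UndefinedValueError(
            f"all thermal responses vanish at T={temperature} deg C"
        )
    optima = np.array([n.t_opt for n in niches])
    return float(np.dot(responses, optima) / total)


@dataclass
class RasterFixture:
    """Aligned SST / suitability grids plus presence and background scores."""

    sst: np.ndarray  # deg C, gradient along axis 0
    suitability: np.ndarray  # in [0, 1], max 1
    presence_scores: np.ndarray
    background_scores: np.ndarray

    @property
    def sst_step(self) -> float:
        """SST difference between adjacent rows along the gradient axis."""
        return float(abs(self.sst[1, 0] - self.sst[0, 0]))


def simulate_rasters(
    grid_shape: tuple[int, int],
    sst_range: tuple[float, float],
    niche: NicheSpec,
    n_presence: int = 200,
    n_background: int = 500,
    seed: int = 0,
) -> RasterFixture:
    """SST raster with a linear gradient along rows, the niche's Gaussian
    suitability surface (normalized to max 1), and seeded presence /
    background score tables (score = suitability at the sampled cell).
    Presences are drawn with probability proportional to suitability;
    background points uniformly."""
    nrow, ncol = grid_shape
    if nrow < 2 or ncol < 1:
        raise ValidationError("grid must have >= 2 rows and >= 1 column")
    lo, hi = sst_range
    if lo == hi:
        raise ValidationError("SST gradient must be strictly monotone")
    rng = _streams(seed)["rasters"]
    sst_axis = np.linspace(lo, hi, nrow)
    sst = np.tile(sst_axis[:, None], (1, ncol))
    suit = niche.response(sst)
    suit = suit / suit.max()

    flat = suit.ravel()
    presence_cells = rng.choice(flat.size, size=n_presence, p=flat / flat.sum())
    background_cells = rng.integers(0, flat.size, size=n_background)
    return RasterFixture(
        sst=sst,
        suitability=suit,
        presence_scores=flat[presence_cells],
        background_scores=flat[background_cells],
    )
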