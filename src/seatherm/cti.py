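"""Community temperature index (CTI) and the four-process decomposition.

The CTI of a community is the abundance-weighted mean of the STIs of its
species: sum(w_i STI_i) / sum(w_i), with raw biomass weights — the
square-root transform used for the dissimilarity analyses is never applied
here. Species without an STI (genus/family records, unmodelled species) are
excluded from numerator and denominator; ``coverage`` reports the biomass
fraction they leave behind.

Change in CTI between two surveys is attributed to four processes defined by
the sign of each species' share change dw and its thermal affinity relative
to a reference CTI: tropicalization (warm-affinity gain), borealization
(cold-affinity gain), detropicalization (warm-affinity loss) and
deborealization (cold-affinity loss).
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CommunitySample, TaxonCatalog
from .errors import UndefinedValueError, ValidationError

PROCESSES = ("tropicalization", "borealization", "detropicalization", "deborealization")


def compute_cti(weights: Mapping[str, float], stis: Mapping[str, float]) -> float:
    """Abundance-weighted mean STI over species present in both maps.

    Invariant to rescaling all weights by a positive constant and bounded by
    the contributing STIs.
    """
    pairs = [(w, stis[t]) for t, w in weights.items() if t in stis and w > 0]
    if not pairs:
        raise UndefinedValueError("no species with both an STI and positive weight")
    w = np.array([p[0] for p in pairs], dtype=float)
    s = np.array([p[1] for p in pairs], dtype=float)
    return float(np.dot(w, s) / w.sum())


@dataclass
class CTIResult:
    """CTI of one reef unit (pooled over its quadrats)."""

    year: str
    region: str
    reef: str
    cti: float
    weight_total: float  # g of biomass carrying an STI
    n_species: int  # STI-bearing species with positive pooled weight
    coverage: float  # fraction of total biomass carried by STI-bearing species


def _pooled_biomass(samples: Sequence[CommunitySample]) -> dict[str, float]:
    pooled: dict[str, float] = {}
    for s in samples:
        for taxon, b in s.biomass.items():
            pooled[taxon] = pooled.get(taxon, 0.0) + b
    return pooled


def reef_cti(samples: Sequence[CommunitySample], catalog: TaxonCatalog) -> list[CTIResult]:
    """CTI per reef unit on biomass pooled over the reef's quadrats.

    Reefs with no eligible species are flagged with a warning and omitted.
    """
    stis = catalog.sti_map
    by_unit: dict[tuple[str, str, str], list[CommunitySample]] = {}
    for s in samples:
        by_unit.setdefault(s.unit, []).append(s)
    results: list[CTIResult] = []
    for (year, region, reef), group in sorted(by_unit.items()):
        pooled = _pooled_biomass(group)
        total = sum(pooled.values())
        eligible = {t: w for t, w in pooled.items() if t in stis and w > 0}
        if not eligible:
            warnings.warn(
                f"reef ({year}, {region}, {reef}) has no STI-bearing species; "
                "excluded from CTI summaries",
                stacklevel=2,
            )
            continue
        weight_total = sum(eligible.values())
        results.append(
            CTIResult(
                year=year,
                region=region,
                reef=reef,
                cti=compute_cti(eligible, stis),
                weight_total=weight_total,
                n_species=len(eligible),
                coverage=weight_total / total if total > 0 else 0.0,
            )
        )
    if not results:
        raise UndefinedValueError("no reef has any STI-bearing species")
    return results


def cti_by_unit(
    samples: Sequence[CommunitySample],
    catalog: TaxonCatalog,
    level: str = "reef",
) -> pd.DataFrame:
    """CTI table at reef, region, or dataset level.

    Reef CTIs are computed on quadrat-pooled biomass; region- and
    dataset-level values are the mean +/- SE of the reef CTIs within the unit
    (reefs are the replicates), one row per year.
    """
    reefs = pd.DataFrame([vars(r) for r in reef_cti(samples, catalog)])
    if level == "reef":
        return reefs
    if level == "region":
        keys = ["year", "region"]
    elif level == "dataset":
        keys = ["year"]
    else:
        raise ValidationError(f"unknown level {level!r}; use reef|region|dataset")
    grouped = reefs.groupby(keys)["cti"]
    out = grouped.agg(cti="mean", cti_se="sem", n_reefs="size").reset_index()
    return out


def classify_affinity(sti: float, reference_cti: float) -> str:
    """warm if STI > reference, cold if STI < reference, neutral if equal."""
    if not (np.isfinite(sti) and np.isfinite(reference_cti)):
        raise ValidationError("sti and reference_cti must be finite")
    if sti > reference_cti:
        return "warm"
    if sti < reference_cti:
        return "cold"
    return "neutral"


def classify_process(affinity: str, dw: float) -> str:
    """Sign table mapping (affinity, share change) to a process; 'none' for
    neutral species or unchanged shares."""
    if dw == 0 or affinity == "neutral":
        return "none"
    if affinity == "warm":
        return "tropicalization" if dw > 0 else "detropicalization"
    return "borealization" if dw > 0 else "deborealization"


@dataclass
class ShiftRecord:
    """One species' share change between the two surveys."""

    taxon: str
    sti: float
    w1: float
    w2: float
    dw: float
    affinity: str
    process: str


@dataclass
class DecompositionResult:
    """Per-region attribution of CTI change to the four processes.

    ``strengths_dw`` sums |dw| per process; ``strengths_weighted`` sums
    |dw| * |STI - reference|. ``dominant`` lists the process(es) maximizing
    the weighted metric (empty when all strengths are zero).
    """

    region: str
    reference_cti: float
    strengths_dw: dict[str, float]
    strengths_weighted: dict[str, float]
    dominant: list[str]
    records: list[ShiftRecord] = field(default_factory=list)

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


def decompose_cti_change(
    samples: Sequence[CommunitySample],
    catalog: TaxonCatalog,
    region: str | None = None,
    reference: str = "both",
) -> DecompositionResult:
    """Four-process decomposition of CTI change for one region.

    The reference CTI is the mean of the region's reef CTIs pooled over both
    times (``reference='both'``, the single vertical line per region in the
    shift plots) or the time-1 mean (``reference='time1'``). Species shares
    ``w_t`` are each species' fraction of the region-time's total eligible
    biomass pooled over reefs and quadrats, so total-biomass drift between
    surveys does not masquerade as abundance change.
    """
    if region is not None:
        samples = [s for s in samples if s.region == region]
    if not samples:
        raise ValidationError(f"no samples for region {region!r}")
    region_label = region if region is not None else "+".join(
        sorted({s.region for s in samples})
    )
    years = sorted({s.year for s in samples})
    if len(years) != 2:
        raise ValidationError(f"exactly two survey times required, found {years}")
    t1, t2 = years
    stis = catalog.sti_map

    reef_results = reef_cti(samples, catalog)
    if reference == "both":
        ref = float(np.mean([r.cti for r in reef_results]))
    elif reference == "time1":
        ref = float(np.mean([r.cti for r in reef_results if r.year == t1]))
    else:
        raise ValidationError(f"unknown reference rule {reference!r}; use both|time1")

    shares: dict[str, dict[str, float]] = {}
    for year in (t1, t2):
        pooled = _pooled_biomass([s for s in samples if s.year == year])
        eligible = {t: w for t, w in pooled.items() if t in stis and w > 0}
        total = sum(eligible.values())
        if total <= 0:
            raise UndefinedValueError(f"time {year!r} has no eligible species")
        shares[year] = {t: w / total for t, w in eligible.items()}

    taxa = sorted(set(shares[t1]) | set(shares[t2]))
    records: list[ShiftRecord] = []
    strengths_dw = {p: 0.0 for p in PROCESSES}
    strengths_weighted = {p: 0.0 for p in PROCESSES}
    for taxon in taxa:
        w1 = shares[t1].get(taxon, 0.0)
        w2 = shares[t2].get(taxon, 0.0)
        dw = w2 - w1
        sti = stis[taxon]
        affinity = classify_affinity(sti, ref)
        process = classify_process(affinity, dw)
        records.append(ShiftRecord(taxon, sti, w1, w2, dw, affinity, process))
        if process != "none":
            strengths_dw[process] += abs(dw)
            strengths_weighted[process] += abs(dw) * abs(sti - ref)

    peak = max(strengths_weighted.values())
    dominant = [] if peak == 0 else [
        p for p in PROCESSES if strengths_weighted[p] == peak
    ]
    return DecompositionResult(
        region=region_label,
        reference_cti=ref,
        strengths_dw=strengths_dw,
        strengths_weighted=strengths_weighted,
        dominant=dominant,
        records=records,
    )


def decompose_all_regions(
    samples: Sequence[CommunitySample],
    catalog: TaxonCatalog,
    reference: str = "both",
) -> dict[str, DecompositionResult]:
    """Decomposition per region, keyed by region label."""
    regions = sorted({s.region for s in samples})
    return {
        r: decompose_cti_change(samples, catalog, region=r, reference=reference)
        for r in regions
    }
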