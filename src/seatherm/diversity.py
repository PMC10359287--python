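"""Univariate community descriptors per quadrat.

Richness counts taxa with positive biomass; Shannon H' is computed on
biomass shares in natural log (nats) — the only abundance measure collected
is wet weight, and Pielou's J' = H'/ln S is base-invariant either way.
"""

from __future__ import annotations

import math
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import GROUPS, CommunitySample, TaxonCatalog
from .errors import TaxonLookupError, UndefinedValueError


def richness(sample: CommunitySample) -> int:
    """Number of taxa with biomass > 0 (explicit zeros do not count)."""
    return sum(1 for b in sample.biomass.values() if b > 0)


def shannon(sample: CommunitySample) -> float:
    """Shannon H' (nats) on biomass shares; zero-weight taxa contribute 0."""
    weights = np.array([b for b in sample.biomass.values() if b > 0], dtype=float)
    if weights.size == 0:
        raise UndefinedValueError(
            f"sample {sample.sample_id!r} has zero total biomass; H' undefined"
        )
    return float(stats.entropy(weights))  # normalizes and uses natural log


def pielou(sample: CommunitySample) -> float:
    """Pielou's evenness J' = H'/ln S; NaN when S <= 1 (undefined)."""
    s = richness(sample)
    if s == 0:
        raise UndefinedValueError(
            f"sample {sample.sample_id!r} has zero total biomass; J' undefined"
        )
    if s == 1:
        return math.nan
    return shannon(sample) / math.log(s)


def group_biomass(sample: CommunitySample, catalog: TaxonCatalog) -> dict[str, float]:
    """Biomass summed within the four morpho-functional groups; groups absent
    from the sample report 0. Raises for any unclassified taxon."""
    out = {g: 0.0 for g in GROUPS}
    for taxon, biomass in sample.biomass.items():
        group = catalog.group(taxon)  # raises TaxonLookupError if unclassified
        out[group] += biomass
    return out


def descriptor_table(
    samples: Sequence[CommunitySample],
    catalog: TaxonCatalog | None = None,
    species_only: bool = False,
) -> pd.DataFrame:
    """Per-quadrat descriptor table (one row per sample).

    By default richness/H'/J' count all ranks, matching field practice of
    reporting every identified taxon; ``species_only`` restricts them to
    species-rank taxa (requires a catalog). Group biomass always requires a
    catalog; without one the group columns are omitted.
    """
    rows = []
    for s in samples:
        if species_only:
            if catalog is None:
                raise TaxonLookupError("species_only filtering requires a catalog")
            biomass = {t: b for t, b in s.biomass.items() if catalog.rank(t) == "species"}
            s = CommunitySample(s.sample_id, s.year, s.region, s.reef, s.quadrat, biomass)
        row = {
            "sample_id": s.sample_id,
            "year": s.year,
            "region": s.region,
            "reef": s.reef,
            "quadrat": s.quadrat,
            "richness": richness(s),
            "shannon": shannon(s) if s.total_biomass > 0 else math.nan,
            "pielou": pielou(s) if s.total_biomass > 0 else math.nan,
            "biomass_g": s.total_biomass,
        }
        if catalog is not None:
            for g, b in group_biomass(s, catalog).items():
                row[f"biomass_{g}_g"] = b
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def descriptor_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SE of each descriptor per region x year (reef-pooled)."""
    value_cols = [c for c in table.columns if c not in ("year", "region", "reef", "quadrat")]
    grouped = table.groupby(["year", "region"])[value_cols]
    mean = grouped.mean().add_suffix("_mean")
    se = grouped.sem().add_suffix("_se")
    return pd.concat([mean, se], axis=1).sort_index(axis=1)
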