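"""Core survey data model: quadrat samples, taxon catalog, study design.

The exchange format is a long (tidy) CSV with one row per (sample, taxon)
pair; a wide sample x taxon matrix writer is provided for interop. Zeros are
explicit in the wide representation so that dissimilarities and richness see
the full taxon union of a dataset.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError, SchemaError, TaxonLookupError, ValidationError

RANKS = ("species", "genus", "family")
GROUPS = ("encrusting", "turf", "subcanopy", "canopy")

COMMUNITY_COLUMNS = ("sample_id", "year", "region", "reef", "quadrat", "taxon", "biomass_g")
CATALOG_COLUMNS = ("taxon", "rank", "group", "sti_c")


@dataclass
class CommunitySample:
    """One quadrat's taxon -> wet-weight biomass map (g per 0.25 m^2).

    ``(year, region, reef, quadrat)`` is jointly unique across a dataset;
    ``reef`` is nested in year x region.
    """

    sample_id: str
    year: str
    region: str
    reef: str
    quadrat: int
    biomass: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for taxon, value in self.biomass.items():
            if not math.isfinite(value) or value < 0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: biomass of {taxon!r} is {value!r}; "
                    "biomass must be finite and >= 0"
                )

    @property
    def unit(self) -> tuple[str, str, str]:
        """(year, region, reef) — the reef unit this quadrat replicates."""
        return (self.year, self.region, self.reef)

    @property
    def total_biomass(self) -> float:
        return float(sum(self.biomass.values()))


@dataclass
class TaxonCatalog:
    """Per-taxon rank, morpho-functional group, and optional STI (deg C).

    The catalog gates which taxa enter the CTI (species-level only) and which
    morpho-functional bucket each taxon contributes to.
    """

    table: pd.DataFrame  # indexed by taxon; columns rank, group, sti_c

    def __post_init__(self) -> None:
        bad_rank = set(self.table["rank"]) - set(RANKS)
        if bad_rank:
            raise ValidationError(f"unknown taxonomic rank(s): {sorted(bad_rank)}")
        bad_group = set(self.table["group"].dropna()) - set(GROUPS)
        if bad_group:
            raise ValidationError(f"unknown morpho-functional group(s): {sorted(bad_group)}")
        sti = self.table["sti_c"].dropna()
        if len(sti) and not ((sti >= -5.0) & (sti <= 40.0)).all():
            raise ValidationError("sti_c values must lie within [-5, 40] deg C")

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str | None, float | None]]
    ) -> "TaxonCatalog":
        """Build from (taxon, rank, group, sti) tuples; group/sti may be None."""
        frame = pd.DataFrame(records, columns=list(CATALOG_COLUMNS)).set_index("taxon")
        frame["sti_c"] = pd.to_numeric(frame["sti_c"])
        return cls(frame)

    @classmethod
    def read_csv(cls, path) -> "TaxonCatalog":
        frame = pd.read_csv(path, dtype={"taxon": str, "rank": str, "group": str})
        missing = set(CATALOG_COLUMNS) - set(frame.columns)
        if missing:
            raise SchemaError(f"catalog is missing column(s): {sorted(missing)}")
        frame["taxon"] = frame["taxon"].str.strip()
        frame = frame.set_index("taxon")
        frame["sti_c"] = pd.to_numeric(frame["sti_c"], errors="coerce")
        return cls(frame[["rank", "group", "sti_c"]])

    def write_csv(self, path) -> None:
        self.table.reset_index().to_csv(path, index=False)

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.table.index

    def _lookup(self, taxon: str) -> pd.Series:
        try:
            return self.table.loc[taxon]
        except KeyError:
            raise TaxonLookupError(f"taxon {taxon!r} is not in the catalog") from None

    def rank(self, taxon: str) -> str:
        return str(self._lookup(taxon)["rank"])

    def group(self, taxon: str) -> str:
        value = self._lookup(taxon)["group"]
        if pd.isna(value):
            raise TaxonLookupError(f"taxon {taxon!r} has no morpho-functional group")
        return str(value)

    def sti(self, taxon: str) -> float | None:
        value = self._lookup(taxon)["sti_c"]
        return None if pd.isna(value) else float(value)

    @property
    def sti_map(self) -> dict[str, float]:
        """Taxa with a finite STI, as a plain dict."""
        sti = self.table["sti_c"].dropna()
        return {str(t): float(v) for t, v in sti.items()}

    def with_sti(self, sti: Mapping[str, float]) -> "TaxonCatalog":
        """Return a copy with STIs filled in for the given taxa."""
        table = self.table.copy()
        for taxon, value in sti.items():
            table.loc[taxon, "sti_c"] = value
        return TaxonCatalog(table)


@dataclass(frozen=True)
class StudyDesign:
    """Balanced 3-factor sampling design.

    time: fixed; region: fixed, crossed with time; reef: random, nested in
    time x region; ``quadrats`` replicates per reef. The reference survey
    instance is 2 x 3 x 5 x 6 = 180 samples.
    """

    times: tuple[str, ...] = ("2012", "2018")
    regions: tuple[str, ...] = ("VIA", "PEN", "SIN")
    reefs_per_cell: int = 5
    quadrats_per_reef: int = 6

    @property
    def n_cells(self) -> int:
        return len(self.times) * len(self.regions) * self.reefs_per_cell

    @property
    def n_samples(self) -> int:
        return self.n_cells * self.quadrats_per_reef


@dataclass
class DesignReport:
    """Outcome of checking a dataset against a StudyDesign (report-only)."""

    passed: bool
    cell_counts: pd.DataFrame  # one row per (year, region, reef) with column n
    problems: list[str]

    def __bool__(self) -> bool:
        return self.passed


def read_community_table(path) -> list[CommunitySample]:
    """Read a long-format survey CSV into one sample per quadrat.

    Rows with zero biomass are retained as explicit zeros. Raises
    :class:`SchemaError` for missing columns and :class:`ValidationError` for
    negative biomass (with the offending row number) or duplicated
    (sample, taxon) pairs.
    """
    frame = pd.read_csv(
        path, dtype={c: str for c in COMMUNITY_COLUMNS if c not in ("quadrat", "biomass_g")}
    )
    missing = set(COMMUNITY_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"community table is missing column(s): {sorted(missing)}")
    frame["taxon"] = frame["taxon"].str.strip()
    frame["biomass_g"] = pd.to_numeric(frame["biomass_g"])
    negative = frame.index[frame["biomass_g"] < 0]
    if len(negative):
        # +2: header line and 1-based file numbering
        raise ValidationError(f"negative biomass_g at file row {int(negative[0]) + 2}")
    dup = frame.duplicated(subset=["sample_id", "taxon"])
    if dup.any():
        first = frame.loc[dup].iloc[0]
        raise ValidationError(
            f"duplicate (sample, taxon) pair: ({first['sample_id']!r}, {first['taxon']!r})"
        )
    samples: list[CommunitySample] = []
    if frame.empty:
        return samples
    keys = ["sample_id", "year", "region", "reef", "quadrat"]
    for (sample_id, year, region, reef, quadrat), chunk in frame.groupby(keys, sort=False):
        samples.append(
            CommunitySample(
                sample_id=str(sample_id),
                year=str(year),
                region=str(region),
                reef=str(reef),
                quadrat=int(quadrat),
                biomass=dict(zip(chunk["taxon"], chunk["biomass_g"].astype(float))),
            )
        )
    seen: dict[tuple, str] = {}
    for s in samples:
        key = (s.year, s.region, s.reef, s.quadrat)
        if key in seen:
            raise ValidationError(
                f"(year, region, reef, quadrat)={key} appears under two sample ids "
                f"({seen[key]!r}, {s.sample_id!r})"
            )
        seen[key] = s.sample_id
    return samples


def write_community_table(samples: Sequence[CommunitySample], path) -> None:
    rows = [
        (s.sample_id, s.year, s.region, s.reef, s.quadrat, taxon, biomass)
        for s in samples
        for taxon, biomass in sorted(s.biomass.items())
    ]
    pd.DataFrame(rows, columns=list(COMMUNITY_COLUMNS)).to_csv(path, index=False)


def to_wide(samples: Sequence[CommunitySample]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(meta, matrix): metadata and the dense sample x taxon biomass matrix.

    Both frames are indexed by ``sample_id`` in input order; the matrix
    columns are the sorted taxon union with explicit zeros.
    """
    meta = pd.DataFrame(
        {
            "year": [s.year for s in samples],
            "region": [s.region for s in samples],
            "reef": [s.reef for s in samples],
            "quadrat": [s.quadrat for s in samples],
        },
        index=pd.Index([s.sample_id for s in samples], name="sample_id"),
    )
    taxa = sorted({t for s in samples for t in s.biomass})
    matrix = pd.DataFrame(
        [[s.biomass.get(t, 0.0) for t in taxa] for s in samples],
        index=meta.index,
        columns=taxa,
        dtype=float,
    )
    return meta, matrix


def write_wide_matrix(samples: Sequence[CommunitySample], path) -> None:
    _, matrix = to_wide(samples)
    matrix.to_csv(path)


def validate_design(samples: Sequence[CommunitySample], design: StudyDesign) -> DesignReport:
    """Report per-cell replicate counts; passes iff every time x region x reef
    cell holds exactly ``design.quadrats_per_reef`` quadrats."""
    problems: list[str] = []
    counts: dict[tuple[str, str, str], int] = {}
    for s in samples:
        counts[s.unit] = counts.get(s.unit, 0) + 1
    rows = [(y, r, reef, n) for (y, r, reef), n in sorted(counts.items())]
    cell_counts = pd.DataFrame(rows, columns=["year", "region", "reef", "n"])
    if not samples:
        return DesignReport(False, cell_counts, ["no samples (0 cells)"])

    expected_cells = design.n_cells
    if len(counts) != expected_cells:
        problems.append(f"found {len(counts)} reef cells, expected {expected_cells}")
    for (y, r, reef), n in sorted(counts.items()):
        if y not in design.times:
            problems.append(f"unexpected time level {y!r}")
        if r not in design.regions:
            problems.append(f"unexpected region level {r!r}")
        if n != design.quadrats_per_reef:
            problems.append(
                f"cell (year={y}, region={r}, reef={reef}) has {n} quadrats, "
                f"expected {design.quadrats_per_reef}"
            )
    return DesignReport(not problems, cell_counts, problems)


def require_balanced(samples: Sequence[CommunitySample], design: StudyDesign) -> None:
    report = validate_design(samples, design)
    if not report.passed:
        raise DesignError("; ".join(report.problems[:5]))


def taxon_filter_species_level(
    samples: Sequence[CommunitySample], catalog: TaxonCatalog
) -> tuple[list[CommunitySample], dict[str, float]]:
    """Restrict every sample to species-rank taxa.

    Returns the filtered samples and, per sample id, the fraction of total
    biomass carried by the discarded (genus/family) taxa; 0 for empty samples.
    """
    filtered: list[CommunitySample] = []
    discarded: dict[str, float] = {}
    for s in samples:
        keep = {t: b for t, b in s.biomass.items() if catalog.rank(t) == "species"}
        total = s.total_biomass
        kept_total = sum(keep.values())
        discarded[s.sample_id] = 0.0 if total == 0 else (total - kept_total) / total
        filtered.append(
            CommunitySample(s.sample_id, s.year, s.region, s.reef, s.quadrat, keep)
        )
    return filtered, discarded
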