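"""End-to-end orchestration: config -> descriptor/CTI/decomposition/test tables.

A run consumes either a real survey table + catalog or a simulation spec
(exactly one of the two), executes every analysis stage, and writes CSV
tables plus a JSON manifest and a human-readable summary into the output
directory. Re-running a manifest's config reproduces every number exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .anova import mixed_anova, snk_for_factor
from .cti import cti_by_unit, decompose_all_regions
from .data import (
    StudyDesign,
    TaxonCatalog,
    read_community_table,
    require_balanced,
    taxon_filter_species_level,
    to_wide,
    write_community_table,
)
from .diversity import descriptor_table
from .errors import ValidationError
from .permanova import bray_curtis, pairwise_permanova, permanova, permdisp
from .simulate import (
    NicheSpec,
    ScenarioSpec,
    catalog_from_niches,
    default_niches,
    simulate_community,
)

log = logging.getLogger("seatherm")


@dataclass
class RunConfig:
    """One run's inputs and switches; exactly one of (community_csv,
    simulate) must be set."""

    out_dir: str = "seatherm_run"
    community_csv: str | None = None
    catalog_csv: str | None = None
    simulate: dict | None = None  # ScenarioSpec fields (+ optional "niches")
    transform: str = "sqrt"  # for Bray-Curtis
    anova_transforms: dict = field(default_factory=dict)  # response -> transform
    n_perm: int = 999
    seed: int = 0
    denominators: str = "printed"
    cti_reference: str = "both"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        real = self.community_csv is not None
        sim = self.simulate is not None
        if real == sim:
            raise ValidationError(
                "config must set exactly one of community_csv or simulate"
            )
        if real and self.catalog_csv is None:
            raise ValidationError("real-data runs require catalog_csv")


def _load_inputs(config: RunConfig):
    if config.simulate is not None:
        spec = dict(config.simulate)
        niche_rows = spec.pop("niches", None)
        niches = (
            [NicheSpec(**row) for row in niche_rows] if niche_rows else default_niches()
        )
        scenario = ScenarioSpec(**{**spec, "seed": spec.get("seed", config.seed)})
        samples, _ = simulate_community(niches, scenario)
        catalog = catalog_from_niches(niches)
        log.info("simulated %d samples, %d taxa", len(samples), len(niches))
    else:
        samples = read_community_table(config.community_csv)
        catalog = TaxonCatalog.read_csv(config.catalog_csv)
        log.info("read %d samples from %s", len(samples), config.community_csv)
    return samples, catalog


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every stage and write the report bundle; returns the table paths."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def save(name: str, frame: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
        log.info("stage %-14s wrote %4d rows -> %s", name, len(frame), path)

    samples, catalog = _load_inputs(config)
    if config.simulate is not None:
        write_community_table(samples, out / "community.csv")
        catalog.write_csv(out / "catalog.csv")

    # infer the balanced design from the data (reef count from the first cell)
    first_cell = (samples[0].year, samples[0].region)
    design = StudyDesign(
        times=tuple(sorted({s.year for s in samples})),
        regions=tuple(sorted({s.region for s in samples})),
        reefs_per_cell=len(
            {s.reef for s in samples if (s.year, s.region) == first_cell}
        ),
        quadrats_per_reef=max(s.quadrat for s in samples),
    )
    require_balanced(samples, design)

    descriptors = descriptor_table(samples, catalog).reset_index()
    save("descriptors", descriptors)

    species_samples, _ = taxon_filter_species_level(samples, catalog)
    save("cti_reef", cti_by_unit(species_samples, catalog, level="reef"))
    save("cti_region", cti_by_unit(species_samples, catalog, level="region"))
    save("cti_dataset", cti_by_unit(species_samples, catalog, level="dataset"))

    decomp = decompose_all_regions(species_samples, catalog, reference=config.cti_reference)
    shift_rows, strength_rows = [], []
    for region, res in decomp.items():
        frame = res.records_frame()
        frame.insert(0, "region", region)
        shift_rows.append(frame)
        for process in res.strengths_weighted:
            strength_rows.append(
                {
                    "region": region,
                    "reference_cti": res.reference_cti,
                    "process": process,
                    "strength_dw": res.strengths_dw[process],
                    "strength_weighted": res.strengths_weighted[process],
                    "dominant": process in res.dominant,
                }
            )
    save("decomposition_shifts", pd.concat(shift_rows, ignore_index=True))
    save("decomposition_strengths", pd.DataFrame(strength_rows))

    meta, matrix = to_wide(samples)
    dm = bray_curtis(matrix, transform=config.transform)
    dm.write_csv(out / "bray_curtis.csv")
    paths["bray_curtis"] = out / "bray_curtis.csv"
    perm = permanova(
        dm, meta, n_perm=config.n_perm, seed=config.seed, denominators=config.denominators
    )
    save("permanova", perm.table)
    pw = []
    for year in design.times:
        frame = pairwise_permanova(
            dm, meta, factor="region", within=("year", year),
            n_perm=config.n_perm, seed=config.seed,
        )
        frame.insert(0, "year", year)
        pw.append(frame)
    save("pairwise_permanova", pd.concat(pw, ignore_index=True))

    disp = permdisp(
        dm, meta["year"].tolist(), n_perm=config.n_perm, seed=config.seed
    )
    save(
        "permdisp",
        pd.DataFrame(
            [
                {
                    "F": disp.f,
                    "df_between": disp.df_between,
                    "df_within": disp.df_within,
                    "p_perm": disp.p_perm,
                    **{f"meandist_{k}": v for k, v in disp.group_mean_distance.items()},
                }
            ]
        ),
    )

    anova_rows, snk_rows = [], []
    responses = [c for c in descriptors.columns if c.startswith(("richness", "shannon", "pielou", "biomass"))]
    for response in responses:
        if descriptors[response].isna().any():
            log.info("stage anova: skipping %s (undefined for some quadrats)",
                     response)
            continue
        kind = config.anova_transforms.get(response, "none")
        table = mixed_anova(descriptors, response, transform=kind)
        frame = table.table.copy()
        frame.insert(0, "response", response)
        frame["transform"] = kind
        frame["cochran_c"] = table.cochran.c
        frame["cochran_p"] = table.cochran.p
        anova_rows.append(frame)
        for factor in ("year", "region"):
            snk = snk_for_factor(descriptors, response, factor, table)
            snk_rows.append(
                {"response": response, "factor": factor, "snk": snk.summary()}
            )
    save("anova", pd.concat(anova_rows, ignore_index=True))
    save("snk", pd.DataFrame(snk_rows))

    manifest = {
        "seatherm_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "n_samples": len(samples),
        "tables": {k: str(v) for k, v in paths.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    paths["manifest"] = out / "manifest.json"

    with open(out / "summary.txt", "w") as fh:
        fh.write(f"seatherm {__version__} run (seed {config.seed})\n")
        fh.write(f"samples: {len(samples)}  design: {design}\n\n")
        for name, path in paths.items():
            fh.write(f"{name}: {path}\n")
    paths["summary"] = out / "summary.txt"
    return paths
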