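"""Species thermal profiles from habitat-suitability and SST rasters.

A continuous suitability surface is binarized at the threshold maximizing
sensitivity + specificity on presence vs background model scores (max SSS);
the SST values over the occupied cells define the species' thermal profile,
whose median is the species temperature index (STI).

Rasters are exchanged as ESRI ASCII grids (plain text, ``nodata`` allowed);
score tables as CSV with columns ``point_id, kind, score``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError, UndefinedValueError, ValidationError

QUANTILE_PROBS = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))


@dataclass(frozen=True)
class ThresholdResult:
    """Max-SSS binarization threshold with its achieved rates."""

    tau: float
    sensitivity: float
    specificity: float
    degenerate: bool = False


def max_sss_threshold(presence_scores, absence_scores) -> ThresholdResult:
    """Threshold maximizing sensitivity + specificity.

    A score ``s`` classifies as presence iff ``s >= tau``. Candidates are the
    unique observed scores; among ties the smallest tau is returned, and the
    rate-based objective keeps unequal class sizes from biasing the choice.
    """
    pres = np.asarray(presence_scores, dtype=float)
    absc = np.asarray(absence_scores, dtype=float)
    if pres.size == 0 or absc.size == 0:
        raise ValidationError("presence and absence score lists must be non-empty")
    candidates = np.unique(np.concatenate([pres, absc]))
    if candidates.size == 1:
        warnings.warn("all scores identical; threshold is degenerate", stacklevel=2)
        return ThresholdResult(float(candidates[0]), 1.0, 0.0, degenerate=True)
    # vectorized rates at every candidate; ties resolved to the smallest tau
    sens = (pres[None, :] >= candidates[:, None]).mean(axis=1)
    spec = (absc[None, :] < candidates[:, None]).mean(axis=1)
    objective = sens + spec
    best = int(np.flatnonzero(objective == objective.max())[0])
    return ThresholdResult(float(candidates[best]), float(sens[best]), float(spec[best]))


def occupancy_mask(suitability: np.ndarray, tau: float) -> np.ndarray:
    """Binary area-of-occupancy grid: occupied iff suitability >= tau.
    Missing (NaN) suitability cells are unoccupied."""
    if not np.isfinite(tau):
        raise ValidationError("threshold must be finite")
    suit = np.asarray(suitability, dtype=float)
    with np.errstate(invalid="ignore"):
        return (suit >= tau) & np.isfinite(suit)


@dataclass
class ThermalProfile:
    """SST multiset over a species' occupied cells plus its quantiles.

    Quantiles use linear interpolation between order statistics, so the
    even-count median is the midpoint of the two central values; the STI is
    the 0.50 quantile. The convention matters: STIs shift under other
    quantile definitions.
    """

    temps: np.ndarray
    quantiles: dict[float, float]
    sti: float

    @classmethod
    def from_temps(cls, temps) -> "ThermalProfile":
        t = np.asarray(temps, dtype=float)
        t = t[np.isfinite(t)]
        if t.size == 0:
            raise UndefinedValueError("no occupied area: zero usable SST cells")
        qs = np.quantile(t, QUANTILE_PROBS, method="linear")
        quantiles = {float(p): float(q) for p, q in zip(QUANTILE_PROBS, qs)}
        return cls(temps=np.sort(t), quantiles=quantiles, sti=quantiles[0.5])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"quantile": list(self.quantiles), "temperature_c": list(self.quantiles.values())}
        )


def thermal_profile(mask: np.ndarray, sst: np.ndarray) -> ThermalProfile:
    """Thermal profile over occupied cells; missing-SST cells are dropped."""
    mask = np.asarray(mask, dtype=bool)
    sst = np.asarray(sst, dtype=float)
    if mask.shape != sst.shape:
        raise ValidationError(
            f"mask shape {mask.shape} does not match SST shape {sst.shape}"
        )
    return ThermalProfile.from_temps(sst[mask])


def compute_sti(profile: ThermalProfile) -> float:
    """The species temperature index: the profile's median (0.50 quantile)."""
    return profile.sti


def sti_from_surface(
    suitability: np.ndarray,
    sst: np.ndarray,
    presence_scores,
    absence_scores,
) -> tuple[float, ThresholdResult, ThermalProfile]:
    """Full ENM post-processing chain: threshold, binarize, profile, STI."""
    thr = max_sss_threshold(presence_scores, absence_scores)
    mask = occupancy_mask(suitability, thr.tau)
    profile = thermal_profile(mask, sst)
    return profile.sti, thr, profile


# ---------------------------------------------------------------- raster I/O

_ASC_NODATA = -9999.0


def write_ascii_grid(path, grid: np.ndarray, cellsize: float = 1.0,
                     xllcorner: float = 0.0, yllcorner: float = 0.0) -> None:
    """Write an ESRI ASCII grid (.asc). NaNs map to the nodata value."""
    grid = np.asarray(grid, dtype=float)
    out = np.where(np.isfinite(grid), grid, _ASC_NODATA)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.shape[1]}\n")
        fh.write(f"nrows {grid.shape[0]}\n")
        fh.write(f"xllcorner {xllcorner}\n")
        fh.write(f"yllcorner {yllcorner}\n")
        fh.write(f"cellsize {cellsize}\n")
        fh.write(f"NODATA_value {_ASC_NODATA}\n")
        np.savetxt(fh, out, fmt="%.6g")


def read_ascii_grid(path) -> np.ndarray:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows"):
        if key not in header:
            raise SchemaError(f"ASCII grid header is missing {key!r}")
    grid = np.loadtxt(lines[n_header:]).reshape(int(header["nrows"]), int(header["ncols"]))
    nodata = header.get("nodata_value")
    if nodata is not None:
        grid = np.where(grid == nodata, np.nan, grid)
    return grid


def read_scores_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a ``point_id,kind,score`` table into (presence, background) arrays."""
    frame = pd.read_csv(path)
    missing = {"point_id", "kind", "score"} - set(frame.columns)
    if missing:
        raise SchemaError(f"score table is missing column(s): {sorted(missing)}")
    kinds = set(frame["kind"]) - {"presence", "background"}
    if kinds:
        raise ValidationError(f"unknown score kind(s): {sorted(kinds)}")
    pres = frame.loc[frame["kind"] == "presence", "score"].to_numpy(float)
    back = frame.loc[frame["kind"] == "background", "score"].to_numpy(float)
    return pres, back


def write_scores_csv(path, presence_scores, background_scores) -> None:
    rows = [("p%d" % i, "presence", s) for i, s in enumerate(presence_scores, 1)]
    rows += [("b%d" % i, "background", s) for i, s in enumerate(background_scores, 1)]
    pd.DataFrame(rows, columns=["point_id", "kind", "score"]).to_csv(path, index=False)
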