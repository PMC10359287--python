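"""Distance-based multivariate testing for the balanced nested survey design.

Implements Bray-Curtis dissimilarities (optionally on square-root
transformed biomass), a three-factor PERMANOVA with Time (fixed), Region
(fixed, crossed) and Reef (random, nested in Time x Region), pairwise
one-way tests, principal-coordinates analysis retaining negative eigenvalues
as imaginary axes, and PERMDISP (homogeneity of multivariate dispersions).

Sums of squares are partitioned directly from squared dissimilarities:
for any grouping G, the within-group sum is
``W(G) = sum_g (1/n_g) sum_{i<j in g} d_ij^2`` and the total is
``SS_total = (1/N) sum_{i<j} d_ij^2``; term sums follow the standard
balanced decomposition. Because reefs are whole exchangeable units for the
terms tested against Reef(T x R), permutations act on reef units (restricted
to the strata of the other fixed factor); the Reef term permutes quadrats
among reefs within each Time x Region cell. The permutation p-value uses the
+1 convention, so p is never 0.

Two denominator presets are shipped: ``"ems"`` tests Time, Region and
Time x Region all over Reef(T x R) (the expected-mean-squares rule used by
the univariate ANOVA) while ``"printed"`` tests Region over Time x Region —
the pseudo-F layout of the reference survey's published multivariate table,
whose Region denominator differs from its univariate one.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import DesignError, UndefinedValueError, ValidationError

DENOMINATOR_PRESETS = {
    "ems": {
        "Time": "Reef(TxR)",
        "Region": "Reef(TxR)",
        "TimexRegion": "Reef(TxR)",
        "Reef(TxR)": "Residual",
    },
    "printed": {
        "Time": "Reef(TxR)",
        "Region": "TimexRegion",
        "TimexRegion": "Reef(TxR)",
        "Reef(TxR)": "Residual",
    },
}


@dataclass
class DissimilarityMatrix:
    """Square symmetric dissimilarity matrix with sample ids."""

    data: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = self.data.shape[0]
        if self.data.shape != (n, n) or n != len(self.ids):
            raise ValidationError("dissimilarity matrix must be square with matching ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValidationError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0.0, atol=1e-12):
            raise ValidationError("dissimilarity matrix must have a zero diagonal")

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)

    @classmethod
    def read_csv(cls, path) -> "DissimilarityMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(frame.to_numpy(float), [str(i) for i in frame.index])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def bray_curtis(matrix: pd.DataFrame, transform: str = "sqrt") -> DissimilarityMatrix:
    """Bray-Curtis dissimilarities between the rows of a sample x taxon
    biomass matrix, after an optional element-wise square root.

    Pairs of all-zero samples are set to 0 with a warning (the 0/0 case).
    """
    if transform not in ("none", "sqrt"):
        raise ValidationError(f"unknown transform {transform!r}; use none|sqrt")
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValidationError("biomass matrix contains negative values")
    if transform == "sqrt":
        values = np.sqrt(values)
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(values, metric="braycurtis"))
    if np.isnan(d).any():
        empty = values.sum(axis=1) == 0
        if empty.sum() >= 2:
            warnings.warn(
                f"{int(empty.sum())} all-zero samples; their mutual dissimilarity "
                "is set to 0",
                stacklevel=2,
            )
        d = np.nan_to_num(d, nan=0.0)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(d, [str(i) for i in matrix.index])


# --------------------------------------------------------------- PERMANOVA


def _within_groups(S: np.ndarray, codes: np.ndarray, n_per_unit: int) -> float:
    """W(G) from the unit-block sum matrix S for a grouping of units."""
    k = codes.max() + 1
    onehot = np.zeros((len(codes), k))
    onehot[np.arange(len(codes)), codes] = 1.0
    block = onehot.T @ S @ onehot
    counts = onehot.sum(axis=0)
    return float((np.diag(block) / (2.0 * n_per_unit * counts)).sum())


@dataclass
class _Layout:
    """Precomputed balanced-design bookkeeping for one dissimilarity matrix."""

    S: np.ndarray  # unit-block sums of squared dissimilarities
    time_codes: np.ndarray  # per unit
    region_codes: np.ndarray  # per unit
    unit_members: list[np.ndarray]  # sample indices per unit
    n_per_unit: int
    a: int  # time levels
    b: int  # region levels
    r: int  # reefs per cell
    ss_total: float
    w_units: float
    D2: np.ndarray


def _build_layout(dm: DissimilarityMatrix, meta: pd.DataFrame) -> _Layout:
    meta = meta.loc[dm.ids]
    units = meta[["year", "region", "reef"]].astype(str).agg("|".join, axis=1)
    unit_labels = list(dict.fromkeys(units))
    unit_index = {u: i for i, u in enumerate(unit_labels)}
    u_of_sample = units.map(unit_index).to_numpy()
    U = len(unit_labels)
    members = [np.flatnonzero(u_of_sample == u) for u in range(U)]
    sizes = {len(m) for m in members}
    if len(sizes) != 1:
        raise DesignError("unequal quadrat counts per reef; balanced design required")
    n_per_unit = sizes.pop()

    first = [m[0] for m in members]
    time_lv = sorted(meta["year"].astype(str).unique())
    region_lv = sorted(meta["region"].astype(str).unique())
    time_codes = np.array([time_lv.index(str(meta["year"].iloc[i])) for i in first])
    region_codes = np.array([region_lv.index(str(meta["region"].iloc[i])) for i in first])
    a, b = len(time_lv), len(region_lv)
    cells, counts = np.unique(time_codes * b + region_codes, return_counts=True)
    if len(cells) != a * b or len(set(counts)) != 1:
        raise DesignError("design must be a full Time x Region crossing with equal reefs")
    r = int(counts[0])

    D2 = dm.data**2
    onehot = np.zeros((len(dm), U))
    onehot[np.arange(len(dm)), u_of_sample] = 1.0
    S = onehot.T @ D2 @ onehot
    ss_total = float(D2.sum() / (2.0 * len(dm)))
    w_units = float(np.diag(S).sum() / (2.0 * n_per_unit))
    return _Layout(S, time_codes, region_codes, members, n_per_unit, a, b, r,
                   ss_total, w_units, D2)


def _terms_from_groupings(lay: _Layout, time_codes, region_codes, w_units=None):
    """SS for each term given (possibly permuted) unit labels."""
    w_units = lay.w_units if w_units is None else w_units
    n = lay.n_per_unit
    w_time = _within_groups(lay.S, time_codes, n)
    w_region = _within_groups(lay.S, region_codes, n)
    w_cell = _within_groups(lay.S, time_codes * lay.b + region_codes, n)
    ss_t = lay.ss_total - w_time
    ss_r = lay.ss_total - w_region
    ss_tr = (lay.ss_total - w_cell) - ss_t - ss_r
    ss_reef = w_cell - w_units
    ss_res = w_units
    return {"Time": ss_t, "Region": ss_r, "TimexRegion": ss_tr,
            "Reef(TxR)": ss_reef, "Residual": ss_res}


def _dfs(lay: _Layout) -> dict[str, int]:
    a, b, r, n = lay.a, lay.b, lay.r, lay.n_per_unit
    return {
        "Time": a - 1,
        "Region": b - 1,
        "TimexRegion": (a - 1) * (b - 1),
        "Reef(TxR)": a * b * (r - 1),
        "Residual": a * b * r * (n - 1),
    }


def _f_stats(ss: dict, df: dict, denom: dict) -> dict[str, float]:
    ms = {k: ss[k] / df[k] if df[k] > 0 else np.nan for k in ss}
    out = {}
    for term, d in denom.items():
        out[term] = ms[term] / ms[d] if ms.get(d, 0) > 0 else np.nan
    return out


def _permute_within_strata(rng, codes: np.ndarray, strata: np.ndarray) -> np.ndarray:
    permuted = codes.copy()
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        permuted[idx] = codes[idx[rng.permutation(len(idx))]]
    return permuted


@dataclass
class PermanovaTable:
    """PERMANOVA source table plus the permutation settings that made it."""

    table: pd.DataFrame
    n_perm: int
    seed: int
    denominators: dict[str, str]

    def __repr__(self) -> str:
        return self.table.to_string(index=False)


def permanova(
    dm: DissimilarityMatrix,
    meta: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    denominators: str | dict = "printed",
    terms: Sequence[str] | None = None,
) -> PermanovaTable:
    """Three-factor PERMANOVA for the balanced Time x Region x Reef design.

    ``meta`` must be indexed by the matrix's sample ids with columns
    ``year``, ``region``, ``reef``. ``denominators`` is a preset name
    (``"printed"`` or ``"ems"``) or an explicit term -> denominator map.
    ``terms`` restricts which terms get permutation p-values (all by
    default); the source table always reports every term's SS and pseudo-F.
    """
    lay = _build_layout(dm, meta)
    if lay.ss_total <= 0:
        raise UndefinedValueError("total sum of squares is zero")
    denom = (DENOMINATOR_PRESETS[denominators]
             if isinstance(denominators, str) else dict(denominators))
    df = _dfs(lay)
    ss = _terms_from_groupings(lay, lay.time_codes, lay.region_codes)
    f_obs = _f_stats(ss, df, denom)

    active = set(denom) if terms is None else set(terms)
    unknown = active - set(denom)
    if unknown:
        raise ValidationError(f"unknown term(s) {sorted(unknown)}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    exceed = {t: 0 for t in denom}
    for _ in range(n_perm):
        # terms above the reef level: permute whole reef units
        if "Time" in active:
            t_perm = _permute_within_strata(rng, lay.time_codes, lay.region_codes)
            ss_p = _terms_from_groupings(lay, t_perm, lay.region_codes)
            f_p = _f_stats(ss_p, df, denom)
            if f_p["Time"] >= f_obs["Time"]:
                exceed["Time"] += 1

        if "Region" in active:
            r_perm = _permute_within_strata(rng, lay.region_codes, lay.time_codes)
            ss_p = _terms_from_groupings(lay, lay.time_codes, r_perm)
            f_p = _f_stats(ss_p, df, denom)
            if f_p["Region"] >= f_obs["Region"]:
                exceed["Region"] += 1

        if "TimexRegion" in active:
            free = rng.permutation(len(lay.time_codes))
            ss_p = _terms_from_groupings(lay, lay.time_codes[free],
                                         lay.region_codes[free])
            f_p = _f_stats(ss_p, df, denom)
            if f_p["TimexRegion"] >= f_obs["TimexRegion"]:
                exceed["TimexRegion"] += 1

        if "Reef(TxR)" in active:
            # reef term: permute quadrats among reefs within each T x R cell
            w_units = 0.0
            cell_codes = lay.time_codes * lay.b + lay.region_codes
            for c in np.unique(cell_codes):
                cell_units = np.flatnonzero(cell_codes == c)
                pool = np.concatenate([lay.unit_members[u] for u in cell_units])
                pool = pool[rng.permutation(len(pool))].reshape(len(cell_units), -1)
                for row in pool:
                    w_units += lay.D2[np.ix_(row, row)].sum() / (2.0 * lay.n_per_unit)
            ss_p = _terms_from_groupings(lay, lay.time_codes, lay.region_codes,
                                         w_units=w_units)
            f_p = _f_stats(ss_p, df, denom)
            if f_p["Reef(TxR)"] >= f_obs["Reef(TxR)"]:
                exceed["Reef(TxR)"] += 1

    rows = []
    for term in ("Time", "Region", "TimexRegion", "Reef(TxR)", "Residual"):
        rows.append({
            "source": term,
            "df": df[term],
            "SS": ss[term],
            "MS": ss[term] / df[term],
            "pseudo_F": f_obs.get(term, np.nan),
            "p_perm": ((exceed[term] + 1) / (n_perm + 1)) if term in active else np.nan,
            "denominator": denom.get(term, ""),
        })
    rows.append({"source": "Total", "df": sum(df.values()), "SS": sum(ss.values()),
                 "MS": np.nan, "pseudo_F": np.nan, "p_perm": np.nan, "denominator": ""})
    return PermanovaTable(pd.DataFrame(rows), n_perm, seed, denom)


def oneway_permanova(
    dm: DissimilarityMatrix,
    grouping: Sequence,
    n_perm: int = 999,
    seed: int = 0,
) -> dict[str, float]:
    """One-way PERMANOVA at the sample level (the pairwise-test workhorse).

    Returns pseudo-F (equal to the classical ANOVA F for Euclidean distances
    on univariate data), R^2 = SS_between/SS_total and the permutation p.
    """
    groups = np.asarray([str(g) for g in grouping])
    if len(groups) != len(dm):
        raise ValidationError("grouping length must match the matrix")
    levels, codes = np.unique(groups, return_inverse=True)
    k = len(levels)
    if k < 2:
        raise ValidationError("at least two groups required")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValidationError("every group needs >= 2 samples")
    D2 = dm.data**2
    N = len(dm)
    ss_total = D2.sum() / (2.0 * N)
    if ss_total <= 0:
        raise UndefinedValueError("total sum of squares is zero")

    def f_of(codes_):
        within = 0.0
        for g in range(k):
            idx = np.flatnonzero(codes_ == g)
            within += D2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
        between = ss_total - within
        return (between / (k - 1)) / (within / (N - k)), between

    f_obs, ss_between = f_of(codes)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    exceed = sum(
        f_of(codes[rng.permutation(N)])[0] >= f_obs for _ in range(n_perm)
    )
    return {
        "F": float(f_obs),
        "R2": float(ss_between / ss_total),
        "p_perm": (exceed + 1) / (n_perm + 1),
        "df_between": k - 1,
        "df_within": N - k,
    }


def pairwise_permanova(
    dm: DissimilarityMatrix,
    meta: pd.DataFrame,
    factor: str,
    within: tuple[str, str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise one-way PERMANOVAs between the levels of ``factor``,
    optionally restricted to samples where ``within=(column, level)`` holds
    (e.g. each survey year separately)."""
    meta = meta.loc[dm.ids]
    keep = np.ones(len(dm), dtype=bool)
    if within is not None:
        column, level = within
        keep = (meta[column].astype(str) == str(level)).to_numpy()
    labels = meta[factor].astype(str).to_numpy()
    levels = sorted(set(labels[keep]))
    rows = []
    root = np.random.SeedSequence(seed)
    seeds = iter(root.generate_state(len(levels) * (len(levels) - 1) // 2))
    for i, lv1 in enumerate(levels):
        for lv2 in levels[i + 1:]:
            sel = keep & np.isin(labels, [lv1, lv2])
            idx = np.flatnonzero(sel)
            sub = DissimilarityMatrix(
                dm.data[np.ix_(idx, idx)], [dm.ids[j] for j in idx]
            )
            res = oneway_permanova(
                sub, labels[idx], n_perm=n_perm, seed=int(next(seeds) % 2**31)
            )
            rows.append({"level_1": lv1, "level_2": lv2, **res})
    return pd.DataFrame(rows)


# -------------------------------------------------------------------- PCoA


@dataclass
class PCoAResult:
    """Principal coordinates with negative eigenvalues kept as imaginary axes.

    ``coords_real`` spans the positive eigenvalues, ``coords_imag`` the
    negative ones; pairwise squared distances reconstruct as
    ``|dx_real|^2 - |dx_imag|^2``.
    """

    eigvals: np.ndarray  # descending, positive then negative
    coords_real: np.ndarray
    coords_imag: np.ndarray
    ids: list[str]

    def reconstructed_distances(self) -> np.ndarray:
        dr2 = squareform(pdist(self.coords_real)) ** 2 if self.coords_real.size else 0.0
        di2 = squareform(pdist(self.coords_imag)) ** 2 if self.coords_imag.size else 0.0
        d2 = dr2 - di2
        return np.sqrt(np.clip(d2, 0.0, None))


def pcoa(dm: DissimilarityMatrix) -> PCoAResult:
    """Gower-centered eigendecomposition of the dissimilarity matrix."""
    n = len(dm)
    A = -0.5 * dm.data**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    eigvals, eigvecs = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-8 * max(1.0, float(np.abs(eigvals).max()))
    pos = eigvals > tol
    neg = eigvals < -tol
    coords_real = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    coords_imag = eigvecs[:, neg] * np.sqrt(-eigvals[neg])
    return PCoAResult(eigvals, coords_real, coords_imag, list(dm.ids))


# ---------------------------------------------------------------- PERMDISP


@dataclass
class PermdispResult:
    """Homogeneity-of-dispersion test outcome."""

    f: float
    df_between: int
    df_within: int
    p_perm: float
    group_mean_distance: dict[str, float]
    distances: pd.Series


def _anova_f(values: np.ndarray, codes: np.ndarray, k: int) -> float:
    grand = values.mean()
    ss_between = sum(
        (values[codes == g].mean() - grand) ** 2 * (codes == g).sum() for g in range(k)
    )
    ss_within = sum(
        ((values[codes == g] - values[codes == g].mean()) ** 2).sum() for g in range(k)
    )
    # rounding-level between-group differences (congruent configurations)
    if ss_between <= 1e-12 * (ss_between + ss_within):
        ss_between = 0.0
    if ss_within <= 1e-30:
        return 0.0 if ss_between <= 1e-30 else np.inf
    n = len(values)
    return float((ss_between / (k - 1)) / (ss_within / (n - k)))


def permdisp(
    dm: DissimilarityMatrix,
    grouping: Sequence,
    n_perm: int = 999,
    seed: int = 0,
) -> PermdispResult:
    """PERMDISP: distances to group centroids in PCoA space, imaginary-part
    corrected, compared by a one-way F whose p-value comes from permuting
    samples across groups.

    The squared distance of sample i to its group centroid is computed
    directly from the squared dissimilarities,
    ``(1/n_g) sum_{j in g} d_ij^2 - (1/n_g^2) sum_{j<k in g} d_jk^2``,
    which equals the real-minus-imaginary PCoA form; small negative values
    are clamped to 0.
    """
    groups = np.asarray([str(g) for g in grouping])
    if len(groups) != len(dm):
        raise ValidationError("grouping length must match the matrix")
    levels, codes = np.unique(groups, return_inverse=True)
    k = len(levels)
    if k < 2:
        raise ValidationError("at least two groups required")
    if np.bincount(codes).min() < 2:
        raise ValidationError("every group needs >= 2 samples")

    D2 = dm.data**2
    z = np.empty(len(dm))
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        n_g = len(idx)
        row_mean = D2[np.ix_(idx, idx)].sum(axis=1) / n_g
        within = D2[np.ix_(idx, idx)].sum() / (2.0 * n_g**2)
        z[idx] = np.sqrt(np.clip(row_mean - within, 0.0, None))

    f_obs = _anova_f(z, codes, k)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if f_obs == 0.0:
        p = 1.0
    else:
        exceed = sum(
            _anova_f(z, codes[rng.permutation(len(z))], k) >= f_obs
            for _ in range(n_perm)
        )
        p = (exceed + 1) / (n_perm + 1)
    return PermdispResult(
        f=f_obs,
        df_between=k - 1,
        df_within=len(z) - k,
        p_perm=p,
        group_mean_distance={lv: float(z[codes == g].mean()) for g, lv in enumerate(levels)},
        distances=pd.Series(z, index=dm.ids, name="dist_to_centroid"),
    )
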