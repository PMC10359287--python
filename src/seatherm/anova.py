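"""Balanced mixed-model ANOVA for the Time x Region x Reef(T x R) design.

With Reef random, the expected mean squares put Reef(T x R) under every
fixed effect: Time, Region and Time x Region are all tested over
MS_Reef(T x R), and Reef over the Residual. Cochran's C checks variance
homogeneity across cells beforehand; Student-Newman-Keuls (SNK) stepwise
range tests compare level means a posteriori using the matching ANOVA
denominator.

Cochran's C p-value uses the Bonferroni x F-tail relation: with k cell
variances on nu = n - 1 df each, F = (k - 1) C / (1 - C) follows an
F(nu, (k - 1) nu) distribution for one fixed cell under the null, and the
maximum is Bonferroni-corrected, p = min(1, k * P[F_{nu,(k-1)nu} >= F]).
The tests validate this approximation against a Monte-Carlo null.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, UndefinedValueError, ValidationError

SOURCES = ("Time", "Region", "TimexRegion", "Reef(TxR)", "Residual")
EMS_DENOMINATORS = {
    "Time": "Reef(TxR)",
    "Region": "Reef(TxR)",
    "TimexRegion": "Reef(TxR)",
    "Reef(TxR)": "Residual",
}


@dataclass
class CochranResult:
    c: float
    p: float
    k: int
    df_per_cell: int


def cochran_c(variances: Sequence[float], n_per_cell: int) -> CochranResult:
    """Cochran's C = max(s^2) / sum(s^2) over cell variances with equal
    replicate counts, with the Bonferroni-F p-value described above."""
    s2 = np.asarray(variances, dtype=float)
    if s2.size < 2:
        raise ValidationError("Cochran's C needs at least two cell variances")
    if (s2 < 0).any() or not np.isfinite(s2).all():
        raise ValidationError("variances must be finite and >= 0")
    total = s2.sum()
    if total == 0:
        raise UndefinedValueError("all cell variances are zero")
    k = int(s2.size)
    nu = n_per_cell - 1
    if nu < 1:
        raise ValidationError("need at least two replicates per cell")
    c = float(s2.max() / total)
    if c >= 1.0:
        p = 0.0
    else:
        f = (k - 1) * c / (1.0 - c)
        p = float(min(1.0, k * stats.f.sf(f, nu, (k - 1) * nu)))
    return CochranResult(c=c, p=p, k=k, df_per_cell=nu)


def apply_transform(values, kind: str = "none") -> np.ndarray:
    """Element-wise variance-stabilizing transform: none | log | sqrt.
    ``log`` is the natural log and requires strictly positive data."""
    x = np.asarray(values, dtype=float)
    if kind == "none":
        return x.copy()
    if kind == "sqrt":
        if (x < 0).any():
            raise ValidationError("sqrt transform requires non-negative data")
        return np.sqrt(x)
    if kind == "log":
        if (x <= 0).any():
            raise ValidationError("log transform requires strictly positive data")
        return np.log(x)
    raise ValidationError(f"unknown transform {kind!r}; use none|log|sqrt")


@dataclass
class AnovaTable:
    """Mixed-ANOVA source table with the transform and Cochran test attached."""

    table: pd.DataFrame
    transform: str
    cochran: CochranResult

    def __repr__(self) -> str:
        head = f"transform={self.transform}  Cochran C={self.cochran.c:.4f} (p={self.cochran.p:.3f})"
        return head + "\n" + self.table.to_string(index=False)

    def ms(self, source: str) -> float:
        return float(self.table.set_index("source").loc[source, "MS"])

    def df(self, source: str) -> int:
        return int(self.table.set_index("source").loc[source, "df"])


def mixed_anova(
    data: pd.DataFrame,
    response: str,
    transform: str = "none",
) -> AnovaTable:
    """Balanced mixed-model ANOVA of ``response`` on columns ``year``,
    ``region``, ``reef`` (reef labels nested in year x region).

    Sums of squares come from the standard balanced-design marginal-mean
    formulas; F denominators follow the expected mean squares with Reef
    random. Raises :class:`DesignError` on unbalanced input.
    """
    needed = {"year", "region", "reef", response}
    missing = needed - set(data.columns)
    if missing:
        raise ValidationError(f"data is missing column(s): {sorted(missing)}")
    df = data[["year", "region", "reef"]].astype(str).copy()
    df["y"] = apply_transform(data[response].to_numpy(), transform)
    if df["y"].isna().any():
        raise ValidationError("response contains missing values")

    cell_sizes = df.groupby(["year", "region", "reef"])["y"].size()
    a = df["year"].nunique()
    b = df["region"].nunique()
    reefs_per_cell = df.groupby(["year", "region"])["reef"].nunique()
    if cell_sizes.nunique() != 1 or reefs_per_cell.nunique() != 1 \
            or len(reefs_per_cell) != a * b:
        raise DesignError("balanced design required (equal reefs and quadrats per cell)")
    r = int(reefs_per_cell.iloc[0])
    n = int(cell_sizes.iloc[0])
    if n < 2:
        raise DesignError("zero residual df: need >= 2 quadrats per reef")

    grand = df["y"].mean()
    m_t = df.groupby("year")["y"].mean()
    m_r = df.groupby("region")["y"].mean()
    m_tr = df.groupby(["year", "region"])["y"].mean()
    m_reef = df.groupby(["year", "region", "reef"])["y"].mean()

    ss_t = b * r * n * ((m_t - grand) ** 2).sum()
    ss_r = a * r * n * ((m_r - grand) ** 2).sum()
    inter = m_tr - m_t.reindex(m_tr.index.get_level_values(0)).to_numpy() \
        - m_r.reindex(m_tr.index.get_level_values(1)).to_numpy() + grand
    ss_tr = r * n * (inter**2).sum()
    reef_dev = m_reef - m_tr.reindex(
        m_reef.index.droplevel("reef")
    ).to_numpy()
    ss_reef = n * (reef_dev**2).sum()
    resid = df["y"] - df.set_index(["year", "region", "reef"]).index.map(m_reef).to_numpy()
    ss_res = (resid**2).sum()

    ss = {"Time": ss_t, "Region": ss_r, "TimexRegion": ss_tr,
          "Reef(TxR)": ss_reef, "Residual": ss_res}
    dfs = {"Time": a - 1, "Region": b - 1, "TimexRegion": (a - 1) * (b - 1),
           "Reef(TxR)": a * b * (r - 1), "Residual": a * b * r * (n - 1)}
    ms = {k: ss[k] / dfs[k] for k in ss}

    total_ss = sum(ss.values())
    degenerate = total_ss <= 1e-30
    rows = []
    for source in SOURCES:
        denom = EMS_DENOMINATORS.get(source, "")
        if denom and ms[denom] > 0 and not degenerate:
            f = ms[source] / ms[denom]
            p = float(stats.f.sf(f, dfs[source], dfs[denom]))
        else:
            f, p = np.nan, np.nan
        rows.append({"source": source, "df": dfs[source], "SS": float(ss[source]),
                     "MS": float(ms[source]), "F": f, "p": p, "denominator": denom})
    rows.append({"source": "Total", "df": sum(dfs.values()), "SS": float(total_ss),
                 "MS": np.nan, "F": np.nan, "p": np.nan, "denominator": ""})
    table = pd.DataFrame(rows)
    if degenerate:
        table.attrs["degenerate"] = "constant response: all sums of squares are zero"

    cell_var = df.groupby(["year", "region", "reef"])["y"].var(ddof=1)
    try:
        cochran = cochran_c(cell_var.to_numpy(), n)
    except UndefinedValueError:  # constant-within-cell response
        cochran = CochranResult(c=np.nan, p=np.nan, k=a * b * r, df_per_cell=n - 1)
    # heterogeneous variances are annotated, never suppressed: balanced
    # ANOVAs tolerate them when significant p-values are well below 0.05
    if np.isfinite(cochran.p) and cochran.p < 0.05:
        table.attrs["heteroscedastic"] = (
            f"Cochran C={cochran.c:.3f} (p={cochran.p:.3g}): variances "
            "heterogeneous; treat p-values near 0.05 with caution"
        )
    return AnovaTable(table=table, transform=transform, cochran=cochran)


@dataclass
class SnkResult:
    """SNK post-hoc outcome: ordered means, homogeneous subsets, decisions."""

    means: pd.Series  # ascending
    subsets: list[list[str]]
    pairwise: pd.DataFrame  # level_1, level_2, q, q_crit, significant
    alpha: float

    def summary(self) -> str:
        """'VIA < PEN = SIN'-style string (by ascending mean); overlapping
        subsets fall back to listing the subsets."""
        parts = []
        covered: set[str] = set()
        disjoint = True
        for sub in self.subsets:
            if covered & set(sub):
                disjoint = False
            covered |= set(sub)
        if not disjoint:
            return "; ".join("{" + " = ".join(sub) + "}" for sub in self.subsets)
        for sub in self.subsets:
            parts.append(" = ".join(sub))
        return " < ".join(parts)


def snk_test(
    means: Mapping[str, float],
    ms_denominator: float,
    df_denominator: int,
    n_per_mean: int,
    alpha: float = 0.05,
) -> SnkResult:
    """Student-Newman-Keuls stepwise studentized-range comparison.

    Means are sorted; a span of r ordered means differs when its range
    exceeds ``q(alpha, r, df) * sqrt(MS / n)``; non-significant spans freeze
    their interior. Ties in the sorted means break by level label.
    """
    if n_per_mean <= 0 or df_denominator <= 0:
        raise ValidationError("n_per_mean and df_denominator must be positive")
    if ms_denominator < 0:
        raise ValidationError("ms_denominator must be >= 0")
    ordered = pd.Series(dict(means), dtype=float).sort_values(kind="stable")
    ordered = ordered.loc[
        sorted(ordered.index, key=lambda lv: (ordered[lv], str(lv)))
    ]
    labels = list(ordered.index)
    values = ordered.to_numpy()
    k = len(labels)
    se = np.sqrt(ms_denominator / n_per_mean)

    sig = np.zeros((k, k), dtype=bool)  # sig[i, j]: means i..j differ (i < j)
    pairs = []

    def q_crit(span: int) -> float:
        return float(stats.studentized_range.ppf(1 - alpha, span, df_denominator))

    def test_span(i: int, j: int) -> None:
        if j <= i:
            return
        span = j - i + 1
        diff = values[j] - values[i]
        q_obs = np.inf if se == 0 and diff > 0 else (diff / se if se > 0 else 0.0)
        crit = q_crit(span)
        significant = q_obs > crit
        pairs.append({"level_1": labels[i], "level_2": labels[j], "span": span,
                      "q": q_obs, "q_crit": crit, "significant": significant})
        if significant:
            sig[i, j] = True
            test_span(i, j - 1)
            test_span(i + 1, j)
        # a non-significant span freezes its interior: no further testing

    test_span(0, k - 1)

    # homogeneous subsets: maximal runs [i..j] never declared different
    subsets: list[list[str]] = []
    i = 0
    while i < k:
        j = i
        while j + 1 < k and not any(
            sig[p, q] for p in range(i, j + 2) for q in range(p + 1, j + 2)
        ):
            j += 1
        subsets.append(labels[i:j + 1])
        i = j + 1
    return SnkResult(
        means=ordered,
        subsets=subsets,
        pairwise=pd.DataFrame(pairs),
        alpha=alpha,
    )


def snk_for_factor(
    data: pd.DataFrame,
    response: str,
    factor: str,
    anova: AnovaTable,
    alpha: float = 0.05,
) -> SnkResult:
    """SNK on the level means of a fixed factor using the factor's ANOVA
    denominator MS/df (Reef(T x R) under the EMS rule)."""
    source = {"year": "Time", "region": "Region"}.get(factor, factor)
    denom = EMS_DENOMINATORS[source]
    y = apply_transform(data[response].to_numpy(), anova.transform)
    df = data[[factor]].astype(str).assign(y=y)
    means = df.groupby(factor)["y"].mean()
    n_per_mean = len(df) // means.size
    return snk_test(
        means.to_dict(),
        ms_denominator=anova.ms(denom),
        df_denominator=anova.df(denom),
        n_per_mean=n_per_mean,
        alpha=alpha,
    )
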