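"""Mass-univariate group comparisons with Benjamini–Hochberg FDR control.

Per-feature two-sample Welch t tests (the unequal-variance default uniquely
reproduces the cohort table's age statistic from its printed summaries),
chi-square tests for categorical demographics, and the BH step-up procedure
applied within each modality's feature family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DataModelError, MultiModalDataset


@dataclass
class GroupStatsTable:
    """Tidy per-feature comparison for one contrast and one modality."""

    contrast: tuple[str, str]
    modality: str
    table: pd.DataFrame  # feature, mean_A, mean_B, t, df, p, q, rejected
    q_level: float


def welch_t(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float
) -> tuple[float, float, float]:
    """Welch's unequal-variance t test from group summaries.

    Returns (t, df, p) with t = (mean2 - mean1) / sqrt(sd1^2/n1 + sd2^2/n2),
    Welch–Satterthwaite degrees of freedom, and a two-sided p-value.
    """
    if n1 < 2 or n2 < 2:
        raise DataModelError("welch_t needs n >= 2 per group")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0):
        raise DataModelError("degenerate variances")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean2 - mean1) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_t_vectors(x1: np.ndarray, x2: np.ndarray) -> tuple[float, float, float]:
    """Welch t from raw vectors (summaries computed internally)."""
    x1, x2 = np.asarray(x1, float), np.asarray(x2, float)
    return welch_t(
        len(x1), x1.mean(), x1.std(ddof=1), len(x2), x2.mean(), x2.std(ddof=1)
    )


def pooled_t(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float
) -> tuple[float, float, float]:
    """Classic pooled-variance two-sample t (available by flag)."""
    if n1 < 2 or n2 < 2:
        raise DataModelError("pooled_t needs n >= 2 per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 == 0:
        raise DataModelError("degenerate variances")
    t = (mean2 - mean1) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def chi2_contingency(table: np.ndarray, yates: bool = True):
    """Pearson chi-square test of independence for a contingency table.

    ``yates`` applies the continuity correction (|O-E| reduced by 0.5,
    floored at 0) — the convention for 2x2 demographic tables.
    Returns (chi2, df, p).
    """
    table = np.asarray(table)
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.number):
        raise DataModelError("counts must be nonnegative numbers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DataModelError("zero row/column margin")
    res = stats.chi2_contingency(table, correction=yates)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def bh_fdr(pvals: np.ndarray, q_level: float = 0.05):
    """Benjamini–Hochberg step-up FDR control.

    q_i = min_{j : p_(j) >= p_(i)} m * p_(j) / j, capped at 1 (the standard
    adjusted p-value); a hypothesis is rejected iff its q < ``q_level``.
    Returns (qvals, rejected) in the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise DataModelError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q, q < q_level


def group_difference_table(
    ds: MultiModalDataset,
    contrast: tuple[str, str],
    modality: str,
    q_level: float = 0.05,
    equal_var: bool = False,
    global_mean_row: bool = False,
) -> GroupStatsTable:
    """Per-feature Welch t tests for one modality and one group contrast,
    BH-corrected within that modality's feature family.

    With ``global_mean_row`` a whole-modality aggregate (the mean across the
    modality's features per subject, e.g. global white-matter FA) is tested
    as an extra row, outside the FDR family.
    """
    ga, gb = contrast
    if ga == gb:
        raise DataModelError("contrast groups must differ")
    ia = ds.covariates.group_indices(ga)
    ib = ds.covariates.group_indices(gb)
    if len(ia) < 2 or len(ib) < 2:
        raise DataModelError("both groups need n >= 2")
    blk = ds.block(modality)
    Xa, Xb = blk.values[ia], blk.values[ib]
    tfun = pooled_t if equal_var else welch_t
    rows = []
    for j, name in enumerate(blk.feature_names):
        a, b = Xa[:, j], Xb[:, j]
        t, df, p = tfun(
            len(a), a.mean(), a.std(ddof=1), len(b), b.mean(), b.std(ddof=1)
        )
        rows.append(
            {"feature": name, "mean_A": a.mean(), "mean_B": b.mean(),
             "t": t, "df": df, "p": p}
        )
    df_out = pd.DataFrame(rows)
    q, rej = bh_fdr(df_out["p"].to_numpy(), q_level)
    df_out["q"] = q
    df_out["rejected"] = rej
    df_out = df_out.sort_values("p", kind="mergesort", ignore_index=True)
    if global_mean_row:
        ga_mean = Xa.mean(axis=1)
        gb_mean = Xb.mean(axis=1)
        t, dfree, p = welch_t_vectors(ga_mean, gb_mean)
        extra = pd.DataFrame(
            [{
                "feature": f"__global_{modality}__",
                "mean_A": ga_mean.mean(), "mean_B": gb_mean.mean(),
                "t": t, "df": dfree, "p": p, "q": np.nan,
                "rejected": p < q_level,
            }]
        )
        df_out = pd.concat([extra, df_out], ignore_index=True)
    return GroupStatsTable(contrast=contrast, modality=modality,
                           table=df_out, q_level=q_level)


def demographics_table(demo: pd.DataFrame, contrasts) -> pd.DataFrame:
    """Cohort-description tests: Welch t for age, Yates chi-square for sex,
    plain chi-square for race, per requested group contrast."""
    rows = []
    for ga, gb in contrasts:
        a = demo[demo["group"] == ga]
        b = demo[demo["group"] == gb]
        t, _, p_age = welch_t_vectors(a["age"], b["age"])
        sex_tab = np.array(
            [[(a["sex"] == "M").sum(), (a["sex"] == "F").sum()],
             [(b["sex"] == "M").sum(), (b["sex"] == "F").sum()]]
        )
        chi2_sex, _, p_sex = chi2_contingency(sex_tab, yates=True)
        levels = sorted(set(demo["race"]))
        race_tab = np.array(
            [[(a["race"] == lev).sum() for lev in levels],
             [(b["race"] == lev).sum() for lev in levels]]
        )
        keep = race_tab.sum(axis=0) > 0
        chi2_race, _, p_race = chi2_contingency(race_tab[:, keep], yates=False)
        rows.append(
            {"contrast": f"{ga} vs {gb}",
             "n_A": len(a), "n_B": len(b),
             "age_t": t, "age_p": p_age,
             "sex_chi2": chi2_sex, "sex_p": p_sex,
             "race_chi2": chi2_race, "race_p": p_race}
        )
    return pd.DataFrame(rows)
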