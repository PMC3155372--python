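"""Clinical chemistry analysis: one-way ANOVA, Tukey HSD, IQR outliers.

The seven study groups (vehicle + three doses of each drug) are compared
per analyte.  Both raw per-animal values and published-style group
summaries (mean, SE, n) are supported: with exact summaries the two
routes are algebraically identical, which lets printed tables be
re-analysed without the underlying raw data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GROUP_ORDER = ("V", "E1", "E2", "E3", "T1", "T2", "T3")


@dataclass(frozen=True)
class GroupSummary:
    group: str
    mean: float
    se: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"group {self.group!r}: n={self.n} < 2, variance unrecoverable")
        if self.se < 0:
            raise ValueError(f"group {self.group!r}: negative SE")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def group_label(drug: str, dose_code: int) -> str:
    return "V" if drug == "V" else f"{drug}{dose_code}"


def summaries_from_raw(values: pd.Series, groups: pd.Series) -> list[GroupSummary]:
    """Exact per-group mean/SE/n from raw per-animal values."""
    out = []
    for g, v in values.groupby(groups):
        v = v.to_numpy(float)
        out.append(GroupSummary(str(g), float(v.mean()),
                                float(v.std(ddof=1) / np.sqrt(len(v))), len(v)))
    return out


def anova_from_summary(groups: list[GroupSummary]) -> AnovaResult:
    """One-way ANOVA from group means, standard errors and sizes.

    The within-group mean square pools each group's variance
    (recovered as n * se^2), weighted by its degrees of freedom:
    MSW = sum (n_i - 1) n_i se_i^2 / sum (n_i - 1).
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    n = np.array([g.n for g in groups], float)
    m = np.array([g.mean for g in groups], float)
    se = np.array([g.se for g in groups], float)
    k = len(groups)
    df_w = int(np.sum(n - 1))
    df_b = k - 1
    msw = float(np.sum((n - 1) * n * se**2) / np.sum(n - 1))
    grand = float(np.sum(n * m) / np.sum(n))
    msb = float(np.sum(n * (m - grand) ** 2) / df_b)
    if msw == 0.0:
        # degenerate: no within-group variance
        f = np.inf if msb > 0 else 0.0
    else:
        f = msb / msw
    p = 1.0 if f == 0.0 else float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(F=float(f), df_between=df_b, df_within=df_w, p=p)


def anova_from_raw(values: pd.Series, groups: pd.Series) -> AnovaResult:
    return anova_from_summary(summaries_from_raw(values, groups))


def tukey_pairwise(groups: list[GroupSummary]) -> pd.DataFrame:
    """All-pairwise Tukey HSD p-values from group summaries.

    q = |mean_i - mean_j| / sqrt(MSW / n), with the harmonic mean of the
    pair's sizes when they are unequal (Tukey-Kramer; flagged in the
    ``unequal_n`` column).  p comes from the studentized-range
    distribution with k groups and the pooled within df.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("Tukey needs >= 2 groups")
    n = np.array([g.n for g in groups], float)
    df_w = int(np.sum(n - 1))
    msw = float(np.sum((n - 1) * n * np.array([g.se for g in groups]) ** 2)
                / np.sum(n - 1))
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[i], groups[j]
            nh = stats.hmean([gi.n, gj.n])
            delta = abs(gi.mean - gj.mean)
            if msw == 0.0:
                p = 1.0 if delta == 0 else 0.0
                q = np.inf if delta > 0 else 0.0
            else:
                q = delta / np.sqrt(msw / nh)
                p = 1.0 if q == 0 else float(stats.studentized_range.sf(q, k, df_w))
            rows.append({"group_i": gi.group, "group_j": gj.group,
                         "delta": gi.mean - gj.mean, "q": float(q), "p": p,
                         "unequal_n": gi.n != gj.n})
    return pd.DataFrame(rows)


def analyze_summary_table(table: pd.DataFrame) -> pd.DataFrame:
    """ANOVA per analyte from a long-form summary table (io.read_clinchem_summary)."""
    rows = []
    for analyte, sub in table.groupby("analyte", sort=False):
        gs = [GroupSummary(r.group, r.mean, r.se, int(r.n)) for r in sub.itertuples()]
        res = anova_from_summary(gs)
        rows.append({"analyte": analyte, "F": res.F, "df_between": res.df_between,
                     "df_within": res.df_within, "p": res.p})
    return pd.DataFrame(rows)


def iqr_fences(values: np.ndarray, k: float = 1.5) -> tuple[float, float]:
    """Tukey fences [Q1 - k*IQR, Q3 + k*IQR]; quartiles by linear interpolation."""
    q1, q3 = np.quantile(values, [0.25, 0.75], method="linear")
    iqr = q3 - q1
    return float(q1 - k * iqr), float(q3 + k * iqr)


def flag_outliers_iqr(values: pd.Series, groups: pd.Series, k: float = 1.5,
                      min_group: int = 4) -> pd.DataFrame:
    """Flag per-animal values outside their treatment group's IQR fences.

    With a constant group (IQR 0) the fences collapse to the common
    value, so exact ties are unflagged and any other value is flagged.
    """
    rows = []
    for g, v in values.groupby(groups):
        if len(v) < min_group:
            raise ValueError(f"group {g!r} has {len(v)} < {min_group} values")
        lo, hi = iqr_fences(v.to_numpy(float), k)
        for animal, x in v.items():
            if x > hi:
                rows.append({"animal_id": animal, "group": g, "value": float(x),
                             "direction": "high"})
            elif x < lo:
                rows.append({"animal_id": animal, "group": g, "value": float(x),
                             "direction": "low"})
    return pd.DataFrame(rows, columns=["animal_id", "group", "value", "direction"])
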