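"""Susceptible-animal analysis.

Idiosyncratic toxicity is carried by a small sensitive subpopulation, so
individual outlier animals are informative even when group means are
not.  This module flags animals whose clinical chemistry is extreme
within their treatment group, asks which marker genes (by default the
ideal drug-specific category) are elevated in those same animals, and
correlates marker expression with the flagging analytes across the
animal's treatment group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from pairtox import clinchem as cc


def find_susceptible_animals(clin: pd.DataFrame, groups: pd.Series,
                             analytes: list[str] | None = None,
                             k: float = 1.5) -> pd.DataFrame:
    """Animals flagged by the within-group IQR rule on >= 1 monitored analyte.

    ``groups`` maps animal id -> treatment group.  Returns one row per
    (animal, analyte) flag with the direction of the excursion.
    """
    analytes = list(analytes) if analytes is not None else list(clin.columns)
    rows = []
    for analyte in analytes:
        flags = cc.flag_outliers_iqr(clin[analyte], groups.loc[clin.index], k=k)
        for r in flags.itertuples():
            rows.append({"animal_id": r.animal_id, "analyte": analyte,
                         "group": r.group, "value": r.value,
                         "direction": r.direction})
    return pd.DataFrame(rows, columns=["animal_id", "analyte", "group",
                                       "value", "direction"])


def elevated_genes_for_animal(expr: pd.DataFrame, group_animals: list[str],
                              animal: str, genes: list[str],
                              k: float = 1.5, rule: str = "iqr",
                              z_threshold: float = 2.5) -> list[str]:
    """Genes whose expression in *animal* exceeds its group-mates' fences.

    The fence is computed leave-the-animal-out: Q3 + k*IQR of the other
    group members (rule="iqr", default), or mean + z_threshold*SD
    (rule="z").  Needs >= 4 comparator animals.
    """
    if animal not in group_animals:
        raise ValueError(f"{animal!r} is not in the supplied group")
    others = [a for a in group_animals if a != animal]
    if len(others) < 4:
        raise ValueError(f"only {len(others)} comparator animals; >= 4 required")
    genes = [g for g in genes if g in expr.index]
    rest = expr.loc[genes, others].to_numpy(float)
    own = expr.loc[genes, animal].to_numpy(float)
    if rule == "iqr":
        q1, q3 = np.quantile(rest, [0.25, 0.75], axis=1, method="linear")
        hi = q3 + k * (q3 - q1)
    elif rule == "z":
        hi = rest.mean(axis=1) + z_threshold * rest.std(axis=1, ddof=1)
    else:
        raise ValueError("rule must be 'iqr' or 'z'")
    return [g for g, v, h in zip(genes, own, hi) if v > h]


def shared_elevated_genes(per_animal: dict[str, list[str]]) -> list[str]:
    """Genes elevated in every listed animal (order-independent)."""
    if not per_animal:
        return []
    sets = [set(v) for v in per_animal.values()]
    return sorted(set.intersection(*sets))


def gene_analyte_correlation(expr: pd.DataFrame, clin: pd.DataFrame,
                             genes: list[str], analytes: list[str],
                             group_animals: list[str]) -> pd.DataFrame:
    """Pearson r per gene-analyte pair across one treatment group.

    A zero-variance gene or analyte has no defined correlation; the
    cell is reported as NaN.
    """
    animals = [a for a in group_animals if a in clin.index and a in expr.columns]
    if len(animals) < 3:
        raise ValueError("need >= 3 matched animals for a correlation")
    out = pd.DataFrame(index=pd.Index(genes, name="gene"),
                       columns=analytes, dtype=float)
    for g in genes:
        x = expr.loc[g, animals].to_numpy(float)
        for a in analytes:
            y = clin.loc[animals, a].to_numpy(float)
            if x.std() == 0 or y.std() == 0:
                out.loc[g, a] = np.nan
            else:
                out.loc[g, a] = float(np.corrcoef(x, y)[0, 1])
    return out


def analyze_susceptible(expr: pd.DataFrame, clin: pd.DataFrame,
                        groups: pd.Series, categories: pd.Series,
                        monitor_analytes: list[str] | None = None,
                        gene_category: str = "T", k: float = 1.5,
                        focus_group: str = "T3") -> dict:
    """Full stage: flag animals, list elevated category genes, correlate.

    Elevated genes are restricted to ``gene_category`` markers (default
    the ideal tolcapone-specific set, the class tied to the toxic drug);
    the cross-animal shared-gene report is computed over the flagged
    animals of ``focus_group`` (default the toxic drug's high dose,
    where the sensitive subpopulation is expected to surface).
    """
    flags = find_susceptible_animals(clin, groups, monitor_analytes, k=k)
    genes = categories.index[categories == gene_category].tolist()
    per_animal: dict[str, list[str]] = {}
    correlations: dict[str, pd.DataFrame] = {}
    # gene elevation is a high-side notion: only animals flagged high on
    # some analyte (the toxicity direction) enter the gene-level analysis
    high = flags[flags["direction"] == "high"]
    for animal in high["animal_id"].unique():
        grp = groups.loc[animal]
        mates = groups.index[groups == grp].tolist()
        if len(mates) < 5 or not genes:
            continue
        elevated = elevated_genes_for_animal(expr, mates, animal, genes, k=k)
        per_animal[animal] = elevated
        analytes = high.loc[high["animal_id"] == animal, "analyte"].tolist()
        if elevated and analytes:
            correlations[animal] = gene_analyte_correlation(
                expr, clin, elevated, analytes, mates)
    focus = {a: g for a, g in per_animal.items()
             if groups.get(a) == focus_group}
    return {"flags": flags, "elevated_genes": per_animal,
            "shared_genes": shared_elevated_genes(focus),
            "correlations": correlations}
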