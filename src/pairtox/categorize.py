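"""Marker categorization from the three significance calls + directions.

Categories (sig means q <= alpha for that comparison):

* t — tolcapone-specific: sig(T-V), not sig(E-V), both slopes same sign;
  T (ideal) additionally sig(T-E).
* e / E — the mirror image for entacapone.
* c — common: sig(T-V) and sig(E-V), same sign; C (ideal) additionally
  NOT sig(T-E).
* d — divergent: sig(T-E) with opposite slope signs; D (ideal)
  additionally sig(T-V) and sig(E-V).

Direction is decided first: genes whose two slopes have opposite signs
can only enter the d-branch.  Every ideal category is a subset of its
primary; genes matching no rule are 'none'.  The scheme deliberately
captures the ideal-marker patterns rather than partitioning all 2^3
significance outcomes.
"""

from __future__ import annotations

import warnings

import pandas as pd

PRIMARY = ("t", "e", "c", "d")
IDEAL = ("T", "E", "C", "D")
CATEGORIES = IDEAL + PRIMARY + ("none",)


def primary_letter(category: str) -> str:
    """Primary-category letter of any label ('T' -> 't'; 'none' -> 'none')."""
    return category if category == "none" else category.lower()


def is_ideal(category: str) -> bool:
    return category in IDEAL


def categorize_gene(sig_tv: bool, sig_ev: bool, sig_te: bool,
                    dir_t: str, dir_e: str,
                    strict_divergent: bool = False,
                    p_tv: float | None = None, p_ev: float | None = None,
                    alpha: float = 0.05) -> str:
    """Assign one of {T,E,C,D,t,e,c,d,none} from calls and directions.

    ``strict_divergent`` additionally requires nominal p < alpha in both
    drug-vs-vehicle comparisons for the d-branch (the divergent rule's
    "both drugs differ from the vehicle" read strictly).
    """
    if "flat" in (dir_t, dir_e):
        if sig_tv or sig_ev or sig_te:
            warnings.warn("flat slope with a significant call; gene left "
                          "uncategorized", stacklevel=2)
        return "none"
    same_sign = dir_t == dir_e

    if not same_sign:
        if not sig_te:
            return "none"
        if strict_divergent:
            if p_tv is None or p_ev is None:
                raise ValueError("strict_divergent needs nominal p_TV and p_EV")
            if not (p_tv < alpha and p_ev < alpha):
                return "none"
        return "D" if (sig_tv and sig_ev) else "d"

    if sig_tv and sig_ev:
        return "C" if not sig_te else "c"
    if sig_tv and not sig_ev:
        return "T" if sig_te else "t"
    if sig_ev and not sig_tv:
        return "E" if sig_te else "e"
    return "none"


def categorize_all(results: pd.DataFrame, alpha: float = 0.05,
                   strict_divergent: bool = False) -> pd.DataFrame:
    """Append a ``category`` column to an analyze_genes result table."""
    cats = []
    for row in results.itertuples():
        cats.append(categorize_gene(
            row.q_TV <= alpha, row.q_EV <= alpha, row.q_TE <= alpha,
            row.dir_T, row.dir_E, strict_divergent=strict_divergent,
            p_tv=getattr(row, "p_TV", None), p_ev=getattr(row, "p_EV", None),
            alpha=alpha))
    out = results.copy()
    out["category"] = cats
    return out


def category_counts(categories: pd.Series) -> dict:
    """Nested marker counts: primary totals with their ideal subsets.

    Mirrors the usual reporting convention "primary (ideal)", e.g. a
    't' count of 223 (120) means 223 tolcapone-specific markers of which
    120 meet the ideal criteria.  The grand total sums the four primary
    counts.
    """
    counts = categories.value_counts().to_dict()
    primary = {p: counts.get(p, 0) + counts.get(p.upper(), 0) for p in PRIMARY}
    ideal = {p: counts.get(p.upper(), 0) for p in PRIMARY}
    return {
        "primary": primary,
        "ideal": ideal,
        "total": sum(primary.values()),
        "total_ideal": sum(ideal.values()),
    }
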