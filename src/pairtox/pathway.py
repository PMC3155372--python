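"""MANOVA gene-set (pathway) analysis.

Over-representation tests discard every gene outside the significant
list regardless of how close its p-value was, ignore gene order, and
assume independence between genes.  The set-level test here avoids all
three: for each pathway it compares the mean expression vectors of the
vehicle, entacapone high-dose and tolcapone high-dose groups over the
set's genes with Wilks' lambda (Pillai's trace by config), taking the
gene-gene covariance into account, and computes the p-value by
permutation of group labels.

Small group sizes make the pooled covariance singular whenever a set
has at least as many genes as within-group degrees of freedom; in that
case the pooled estimate is shrunk toward its diagonal with the
analytic (Schafer-Strimmer) intensity before the statistic is formed.
A single-gene set reduces exactly to a one-way permutation ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pairtox.categorize import primary_letter


@dataclass
class PathwayConfig:
    n_permutations: int = 10_000
    alpha: float = 0.05
    statistic: str = "wilks"     # or "pillai"
    seed: int = 0

    def __post_init__(self):
        if self.statistic not in ("wilks", "pillai"):
            raise ValueError("statistic must be 'wilks' or 'pillai'")


def filter_candidate_sets(gene_sets: dict[str, list[str]],
                          markers: pd.DataFrame) -> pd.DataFrame:
    """Retain sets containing >= 1 categorized gene; annotate members.

    ``markers`` is a categorize_all output (indexed by gene, with a
    ``category`` column).  A set whose categorized members are all
    tolcapone-specific (T or t) is flagged ``tol_specific``.
    """
    categorized = markers.loc[markers["category"] != "none", "category"]
    on_array = set(markers.index)
    rows = []
    for name, members in gene_sets.items():
        present = [g for g in members if g in on_array]
        cat_members = [(g, categorized[g]) for g in present if g in categorized.index]
        if not cat_members:
            continue
        letters = {primary_letter(c) for _, c in cat_members}
        rows.append({
            "set": name,
            "size": len(present),
            "members": present,
            "categorized_members": cat_members,
            "tol_specific": letters == {"t"},
        })
    return pd.DataFrame(rows, columns=["set", "size", "members",
                                       "categorized_members", "tol_specific"])


def _shrinkage_intensity(resid: np.ndarray) -> float:
    """Schafer-Strimmer intensity for shrinking correlations to zero.

    ``resid`` holds group-centered residuals (rows = samples).  Returns
    lambda in [0, 1]; off-diagonal correlations are scaled by
    (1 - lambda), the diagonal is untouched.
    """
    n, p = resid.shape
    if p < 2:
        return 0.0
    sd = resid.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    X = (resid - resid.mean(axis=0)) / sd
    r = X.T @ X / (n - 1)
    w_bar = X.T @ X / n
    sq = (X**2).T @ (X**2)
    var_w = (sq / n - w_bar**2) * n / (n - 1) ** 3 * n
    off = ~np.eye(p, dtype=bool)
    denom = float((r[off] ** 2).sum())
    if denom == 0:
        return 1.0
    lam = float(var_w[off].sum()) / denom
    return float(np.clip(lam, 0.0, 1.0))


def _scatter(X: np.ndarray, groups: np.ndarray):
    """Within- and between-group scatter matrices and group-centered residuals."""
    grand = X.mean(axis=0)
    labels = np.unique(groups)
    p = X.shape[1]
    W = np.zeros((p, p))
    H = np.zeros((p, p))
    resid = np.empty_like(X)
    for g in labels:
        sel = groups == g
        Xg = X[sel]
        mg = Xg.mean(axis=0)
        C = Xg - mg
        resid[sel] = C
        W += C.T @ C
        d = (mg - grand)[:, None]
        H += Xg.shape[0] * (d @ d.T)
    return W, H, resid, len(labels)


def _statistic(X: np.ndarray, groups: np.ndarray, kind: str) -> float:
    """Wilks' lambda (small = strong effect) or negative Pillai trace.

    Returned on a scale where SMALLER means a stronger group effect, so
    a single exceedance rule serves both statistics.
    """
    n, p = X.shape
    W, H, resid, k = _scatter(X, groups)
    df_within = n - k
    if p >= df_within:
        lam = _shrinkage_intensity(resid)
        d = np.sqrt(np.diag(W))
        d[d == 0] = 1.0
        R = W / np.outer(d, d)
        off = ~np.eye(p, dtype=bool)
        R[off] *= (1.0 - lam)
        W = R * np.outer(d, d)
        if lam == 0.0:  # singular but nothing to shrink: minimal ridge
            W = W + 1e-10 * np.mean(np.diag(W)) * np.eye(p)
    if kind == "wilks":
        sW, ldW = np.linalg.slogdet(W)
        sT, ldT = np.linalg.slogdet(W + H)
        if sW <= 0 or sT <= 0:
            return 0.0  # degenerate: treat as maximal effect
        return float(np.exp(ldW - ldT))
    # Pillai: trace((W+H)^-1 H), larger = stronger; negate
    sol = np.linalg.solve(W + H, H)
    return float(-np.trace(sol))


def manova_gene_set(expr: pd.DataFrame, meta: pd.DataFrame,
                    set_genes: list[str],
                    config: PathwayConfig | None = None) -> dict | None:
    """Permutation MANOVA p-value for one gene set.

    Compares vehicle vs the two high-dose groups over the set's genes.
    Returns None when no set gene is on the array.
    """
    config = config or PathwayConfig()
    genes = [g for g in set_genes if g in expr.index]
    if not genes:
        return None
    high = meta["dose_code"].max()
    sel = (meta["drug"] == "V") | (meta["dose_code"] == high)
    sub = meta[sel]
    X = expr.loc[genes, sub["animal_id"].tolist()].to_numpy(float).T
    groups = np.where(sub["drug"] == "V", "V",
                      sub["drug"].astype(str) + str(high))
    obs = _statistic(X, groups, config.statistic)
    rng = np.random.default_rng(config.seed)
    B = config.n_permutations
    tol = 1e-12 * (1.0 + abs(obs))
    count = 0
    for _ in range(B):
        perm = rng.permutation(X.shape[0])
        if _statistic(X[perm], groups, config.statistic) <= obs + tol:
            count += 1
    return {"p": (count + 1) / (B + 1), "statistic": obs,
            "n_genes": len(genes), "n_permutations": B}


def analyze_sets(expr: pd.DataFrame, meta: pd.DataFrame,
                 candidates: pd.DataFrame,
                 config: PathwayConfig | None = None) -> pd.DataFrame:
    """MANOVA p for every candidate set (filter_candidate_sets output)."""
    config = config or PathwayConfig()
    rows = []
    for row in candidates.itertuples():
        res = manova_gene_set(expr, meta, row.members, config)
        if res is None:
            continue
        cat_str = ",".join(
            f"{g}*" if c == "t" else g for g, c in row.categorized_members)
        rows.append({"set": row.set, "size": res["n_genes"],
                     "categorized_genes": cat_str, "p": res["p"],
                     "tol_specific": bool(row.tol_specific),
                     "significant": res["p"] <= config.alpha})
    out = pd.DataFrame(rows, columns=["set", "size", "categorized_genes", "p",
                                      "tol_specific", "significant"])
    return out.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)


def rank_tolcapone_specific(results: pd.DataFrame) -> pd.DataFrame:
    """Tolcapone-specific sets ordered by p (set name breaks ties)."""
    sub = results[results["tol_specific"]]
    return sub.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)


def fisher_overrepresentation(set_genes: list[str], significant: set[str],
                              universe: list[str]) -> float:
    """Fisher's exact over-representation p; simulation-harness baseline only.

    Kept out of the pipeline output deliberately: it discards
    near-threshold genes and ignores the correlation structure the
    MANOVA test was chosen to respect.
    """
    in_set = set(set_genes) & set(universe)
    a = len(in_set & significant)
    b = len(in_set) - a
    c = len(significant - in_set)
    d = len(universe) - a - b - c
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])
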