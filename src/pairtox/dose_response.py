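"""Per-gene linear dose-response testing for a vehicle + two-drug design.

For each gene and each drug, expression is regressed on the ordinal dose
code (0 = vehicle, 1/2/3 = low/medium/high) over that drug's animals plus
the shared vehicle animals.  Three permutation tests are computed per
gene:

* drug T vs vehicle (``p_TV``) and drug E vs vehicle (``p_EV``): the
  slope t-ratio, with the null generated by permuting expression values
  among the vehicle + that drug's animals (equivalently, permuting their
  dose codes);
* drug T vs drug E (``p_TE``): the standardized slope difference
  (slope_T - slope_E) / sqrt(se_T^2 + se_E^2), with the null generated
  by permuting drug identity between dose-matched animals (dose codes
  preserved, vehicle fixed in both fits).

p-values are two-sided, computed as (exceedances + 1) / (B + 1) for B
random permutations, or by exhaustive enumeration of the distinct
assignments when ``method="exact"``.  Benjamini-Hochberg FDR is applied
separately within each comparison across genes.

Ordinal dose codes are shared by both drugs even though their mg/kg
scales differ: the middle doses sit at an approximate geometric mean of
the low and high, so the ordinal scale makes the two slopes directly
comparable in the T-E test.  Log-dose coding is available via the config
(with an additive offset so the vehicle is defined).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AnalysisConfig", "fit_slopes", "permutation_test", "adjust_fdr",
           "analyze_genes"]


@dataclass
class AnalysisConfig:
    """Tuning knobs for the per-gene dose-response analysis.

    alpha            FDR threshold used downstream for significance calls.
    n_permutations   random permutations per test (B); p >= 1/(B+1).
    dose_coding      "ordinal" (0..3, default) or "log" (log10 mg/kg with
                     an offset so the vehicle is finite).
    statistic        "t" (slope t-ratio, default) or "slope".
    method           "random" or "exact" (exhaustive enumeration; only
                     feasible for toy designs).
    share_vehicle    include vehicle animals in each drug's fit (default).
    seed             master seed; permutations come from a seeded
                     generator so runs are reproducible and independent
                     of thread count.
    """

    alpha: float = 0.05
    n_permutations: int = 10_000
    dose_coding: str = "ordinal"
    log_dose_offset: float | None = None
    statistic: str = "t"
    method: str = "random"
    share_vehicle: bool = True
    seed: int = 0
    chunk_size: int = 512

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.method == "random" and self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        if self.dose_coding not in ("ordinal", "log"):
            raise ValueError("dose_coding must be 'ordinal' or 'log'")
        if self.statistic not in ("t", "slope"):
            raise ValueError("statistic must be 't' or 'slope'")
        if 1 / (self.n_permutations + 1) > self.alpha / 10 and self.method == "random":
            warnings.warn(
                f"B={self.n_permutations} gives p-value granularity "
                f"{1/(self.n_permutations+1):.2g}, coarse for alpha={self.alpha}",
                stacklevel=2)


def _dose_values(meta: pd.DataFrame, config: AnalysisConfig) -> np.ndarray:
    """Numeric dose covariate for a metadata subset."""
    if config.dose_coding == "ordinal":
        return meta["dose_code"].to_numpy(float)
    if "dose_mgkg" not in meta.columns:
        raise ValueError("log dose coding requires a dose_mgkg metadata column")
    mg = meta["dose_mgkg"].to_numpy(float)
    offset = config.log_dose_offset
    if offset is None:
        pos = mg[mg > 0]
        if pos.size == 0:
            raise ValueError("no positive doses for log coding")
        offset = pos.min()
    return np.log10(mg + offset)


def _drug_subset(meta: pd.DataFrame, drug: str, config: AnalysisConfig) -> pd.DataFrame:
    drugs = [drug, "V"] if config.share_vehicle else [drug]
    sub = meta[meta["drug"].isin(drugs)]
    if sub["dose_code"].nunique() < 2:
        raise ValueError(f"degenerate design for drug {drug}: <2 dose levels")
    return sub


def _ols_slope(Y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-row OLS of Y (genes x n) on x; returns (slope, se)."""
    n = x.size
    xc = x - x.mean()
    sxx = float(xc @ xc)
    slope = Y @ xc / sxx
    yc = Y - Y.mean(axis=1, keepdims=True)
    syy = np.einsum("ij,ij->i", yc, yc)
    sse = np.maximum(syy - slope**2 * sxx, 0.0)
    df = n - 2
    se = np.sqrt(sse / df / sxx)
    return slope, se


def _t_ratio(slope: np.ndarray, se: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / se
    t[np.isnan(t)] = 0.0  # 0/0: constant gene, no evidence either way
    return t


def fit_slopes(expr: pd.DataFrame, meta: pd.DataFrame,
               config: AnalysisConfig | None = None) -> pd.DataFrame:
    """OLS slope and standard error per gene for each drug.

    Returns a DataFrame indexed by gene with columns slope_T, se_T,
    slope_E, se_E.
    """
    config = config or AnalysisConfig()
    out = {}
    for drug in ("T", "E"):
        sub = _drug_subset(meta, drug, config)
        x = _dose_values(sub, config)
        Y = expr[sub["animal_id"].tolist()].to_numpy(float)
        slope, se = _ols_slope(Y, x)
        out[f"slope_{drug}"] = slope
        out[f"se_{drug}"] = se
    return pd.DataFrame(out, index=expr.index)


# ---------------------------------------------------------------------------
# drug-vs-vehicle permutation test

def _count_exceed(count, abs_obs, abs_perm):
    # tolerant >= so enumerated ties (including the identity) count;
    # infinite statistics (perfect fits) compare against inf directly
    tol = 1e-12 * (1.0 + abs_obs)
    thresh = np.where(np.isfinite(abs_obs), abs_obs - tol, abs_obs)
    count += (abs_perm >= thresh[:, None]).sum(axis=1)


def _dv_statistic(Y, Xc, sxx, syy, df, statistic):
    """Statistic for each gene x permuted dose column. Xc centered, n x B."""
    slope = Y @ Xc / sxx
    if statistic == "slope":
        return slope
    sse = np.maximum(syy[:, None] - slope**2 * sxx, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / np.sqrt(sse / df / sxx)
    t[np.isnan(t)] = 0.0
    return t


def _perm_drug_vs_vehicle(Y, x, config, rng):
    """Two-sided permutation p per gene for one drug-vs-vehicle slope test."""
    n = x.size
    xc = x - x.mean()
    sxx = float(xc @ xc)
    yc = Y - Y.mean(axis=1, keepdims=True)
    syy = np.einsum("ij,ij->i", yc, yc)
    df = n - 2
    obs = _dv_statistic(yc, xc[:, None], sxx, syy, df, config.statistic)[:, 0]
    abs_obs = np.abs(obs)
    count = np.zeros(Y.shape[0])

    if config.method == "exact":
        perms = np.array(sorted(set(itertools.permutations(x))), float)
        total = perms.shape[0]
        for start in range(0, total, config.chunk_size):
            P = perms[start:start + config.chunk_size].T
            stat = _dv_statistic(yc, P - P.mean(axis=0), sxx, syy, df, config.statistic)
            _count_exceed(count, abs_obs, np.abs(stat))
        return count / total, obs

    B = config.n_permutations
    done = 0
    while done < B:
        c = min(config.chunk_size, B - done)
        P = np.empty((n, c))
        for b in range(c):
            P[:, b] = rng.permutation(x)
        stat = _dv_statistic(yc, P - P.mean(axis=0), sxx, syy, df, config.statistic)
        _count_exceed(count, abs_obs, np.abs(stat))
        done += c
    return (count + 1) / (B + 1), obs


# ---------------------------------------------------------------------------
# drug-vs-drug permutation test (dose-stratified label swap)

def _te_statistic(Y, Y2, x, IT, IE, sxx, xbar, n_fit, statistic):
    """Standardized slope difference per gene for each T/E assignment column.

    IT, IE: n x B indicators of membership in the T-fit and E-fit
    subsets (vehicle rows are 1 in both).  The subset composition per
    dose level is fixed by the stratified swap, so xbar and sxx are the
    observed-fit values.
    """
    w = (x - xbar) / sxx
    df = n_fit - 2
    res = {}
    for key, I in (("T", IT), ("E", IE)):
        slope = Y @ (w[:, None] * I)
        s1 = Y @ I
        s2 = Y2 @ I
        syy = s2 - s1**2 / n_fit
        sse = np.maximum(syy - slope**2 * sxx, 0.0)
        se2 = sse / df / sxx
        res[key] = (slope, se2)
    sT, vT = res["T"]
    sE, vE = res["E"]
    diff = sT - sE
    if statistic == "slope":
        return diff
    with np.errstate(divide="ignore", invalid="ignore"):
        d = diff / np.sqrt(vT + vE)
    # zero pooled SE: a slope difference at rounding-noise scale is no
    # evidence (constant gene), a real difference is a perfect fit
    zero_se = (vT + vE) == 0.0
    if zero_se.any():
        noise = 1e-8 * (np.abs(sT) + np.abs(sE)) + 1e-12
        d[zero_se] = np.where(np.abs(diff[zero_se]) <= noise[zero_se],
                              0.0, np.inf)
    d[np.isnan(d)] = 0.0
    return d


def _perm_drug_vs_drug(expr, meta, config, rng):
    """p_TE: permute drug identity within each dose stratum."""
    sub = meta[meta["drug"].isin(["T", "E", "V"])].reset_index(drop=True)
    Y = expr[sub["animal_id"].tolist()].to_numpy(float)
    Y2 = Y**2
    x = _dose_values(sub, config)
    n = len(sub)
    veh = (sub["drug"] == "V").to_numpy()
    if config.share_vehicle:
        base = veh.astype(float)
    else:
        base = np.zeros(n)
    strata = []
    for d in sorted(sub.loc[sub["drug"] != "V", "dose_code"].unique()):
        idx = np.flatnonzero((sub["dose_code"] == d).to_numpy() & ~veh)
        nT = int((sub.loc[idx, "drug"] == "T").sum())
        if nT == 0 or nT == len(idx):
            raise ValueError(f"dose level {d} is not shared by both drugs")
        strata.append((idx, nT))

    obs_T = (sub["drug"] == "T").to_numpy(float) + base * veh
    obs_T = np.clip(obs_T, 0, 1)
    obs_E = (sub["drug"] == "E").to_numpy(float) + base * veh
    obs_E = np.clip(obs_E, 0, 1)
    n_fit = int(obs_T.sum())
    x_fit = x[obs_T > 0]
    xbar = float(x_fit.mean())
    sxx = float(((x_fit - xbar) ** 2).sum())

    obs = _te_statistic(Y, Y2, x, obs_T[:, None], obs_E[:, None],
                        sxx, xbar, n_fit, config.statistic)[:, 0]
    abs_obs = np.abs(obs)
    count = np.zeros(Y.shape[0])

    def eval_chunk(IT):
        IE = np.zeros_like(IT)
        for idx, _ in strata:
            IE[idx] = 1.0 - IT[idx]
        IT = IT + base[:, None] * veh[:, None]
        IE = IE + base[:, None] * veh[:, None]
        stat = _te_statistic(Y, Y2, x, IT, IE, sxx, xbar, n_fit, config.statistic)
        _count_exceed(count, abs_obs, np.abs(stat))

    if config.method == "exact":
        choices = [list(itertools.combinations(range(len(idx)), nT))
                   for idx, nT in strata]
        combos = list(itertools.product(*choices))
        total = len(combos)
        for start in range(0, total, config.chunk_size):
            chunk = combos[start:start + config.chunk_size]
            IT = np.zeros((n, len(chunk)))
            for b, combo in enumerate(chunk):
                for (idx, _), picks in zip(strata, combo):
                    IT[idx[list(picks)], b] = 1.0
            eval_chunk(IT)
        return count / total, obs

    B = config.n_permutations
    done = 0
    while done < B:
        c = min(config.chunk_size, B - done)
        IT = np.zeros((n, c))
        for idx, nT in strata:
            keys = rng.random((c, len(idx)))
            order = np.argsort(keys, axis=1)
            for b in range(c):
                IT[idx[order[b, :nT]], b] = 1.0
        eval_chunk(IT)
        done += c
    return (count + 1) / (B + 1), obs


def permutation_test(expr: pd.DataFrame, meta: pd.DataFrame,
                     config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Raw permutation p-values p_TV, p_EV, p_TE for every gene."""
    config = config or AnalysisConfig()
    rng = np.random.default_rng(config.seed)
    out = pd.DataFrame(index=expr.index)
    for comp, drug in (("TV", "T"), ("EV", "E")):
        sub = _drug_subset(meta, drug, config)
        x = _dose_values(sub, config)
        Y = expr[sub["animal_id"].tolist()].to_numpy(float)
        p, _ = _perm_drug_vs_vehicle(Y, x, config, rng)
        out[f"p_{comp}"] = p
    p_te, _ = _perm_drug_vs_drug(expr, meta, config, rng)
    out["p_TE"] = p_te
    return out


def adjust_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p, capped at 1)."""
    p = np.asarray(p, float)
    if p.ndim != 1:
        raise ValueError("adjust_fdr expects a 1-d array")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _direction(slope: np.ndarray) -> np.ndarray:
    return np.where(slope > 0, "up", np.where(slope < 0, "down", "flat"))


def analyze_genes(expr: pd.DataFrame, meta: pd.DataFrame,
               config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Full per-gene test table: slopes, SEs, raw p, BH q, directions."""
    config = config or AnalysisConfig()
    slopes = fit_slopes(expr, meta, config)
    pvals = permutation_test(expr, meta, config)
    out = pd.concat([slopes, pvals], axis=1)
    for comp in ("TV", "EV", "TE"):
        out[f"q_{comp}"] = adjust_fdr(out[f"p_{comp}"].to_numpy())
    out["dir_T"] = _direction(out["slope_T"].to_numpy())
    out["dir_E"] = _direction(out["slope_E"].to_numpy())
    out.index.name = "gene"
    return out
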