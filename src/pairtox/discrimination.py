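"""Per-marker logistic discrimination with leave-one-out cross-validation.

Each marker gene is scored as a single-covariate logistic classifier for
the class pair its category is defined by (drug-specific markers:
that drug's high dose vs vehicle; common: pooled high doses vs vehicle;
divergent: high dose vs high dose).  Sensitivity is the recalled
fraction of the drug (positive) class, specificity of the negative
class; with n animals per class and leave-one-out prediction both lie
on a 1/n grid.

The fit carries a small ridge penalty on the (standardized) slope so it
remains defined under complete separation; a perfectly separating gene
then still predicts every held-out animal correctly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from pairtox.categorize import primary_letter

CONTRASTS = {  # category letter -> (positive group, negative group)
    "t": ("T3", "V"), "e": ("E3", "V"), "c": ("high", "V"), "d": ("T3", "E3"),
}


@dataclass
class DiscriminationConfig:
    ridge: float = 1e-2        # L2 penalty on the standardized slope
    pool_doses: bool = False   # use all dose groups of the drug, not high only
    max_iter: int = 200
    tol: float = 1e-10


def fit_logistic(x: np.ndarray, y: np.ndarray, ridge: float = 1e-2,
                 max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Ridge-penalized logistic fit (intercept unpenalized) by Newton steps.

    ``x`` must already be on a standardized scale; returns (b0, b1).
    """
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    P = np.diag([0.0, ridge])
    for _ in range(max_iter):
        mu = expit(X @ beta)
        w = mu * (1.0 - mu) + 1e-12
        grad = X.T @ (y - mu) - P @ beta
        H = (X * w[:, None]).T @ X + P
        step = np.linalg.solve(H, grad)
        beta += step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def loocv_predict(x: np.ndarray, y: np.ndarray,
                  config: DiscriminationConfig | None = None) -> np.ndarray:
    """Leave-one-out predicted class (probability >= 0.5) per sample."""
    config = config or DiscriminationConfig()
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mu, sd = x.mean(), x.std()
    z = (x - mu) / sd if sd > 0 else x - mu
    n = x.size
    pred = np.zeros(n, bool)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        beta = fit_logistic(z[keep], y[keep], config.ridge,
                            config.max_iter, config.tol)
        pred[i] = expit(beta[0] + beta[1] * z[i]) >= 0.5
    return pred


def evaluate_marker(values: np.ndarray, classes: np.ndarray,
                    config: DiscriminationConfig | None = None) -> dict:
    """Sensitivity/specificity of one gene by LOOCV logistic prediction.

    ``classes`` is boolean with True = positive (drug) class; each class
    needs >= 4 samples.
    """
    classes = np.asarray(classes, bool)
    n_pos, n_neg = int(classes.sum()), int((~classes).sum())
    if n_pos < 4 or n_neg < 4:
        raise ValueError("each class needs >= 4 samples")
    pred = loocv_predict(values, classes, config)
    sens = float((pred & classes).sum() / n_pos)
    spec = float((~pred & ~classes).sum() / n_neg)
    return {"sensitivity": sens, "specificity": spec,
            "n_pos": n_pos, "n_neg": n_neg}


def _contrast_samples(meta: pd.DataFrame, cat_letter: str, pool_doses: bool):
    """Sample ids and class labels for a category's defining contrast."""
    g = np.where(meta["drug"] == "V", "V",
                 meta["drug"].astype(str) + meta["dose_code"].astype(str))
    high = meta["dose_code"].max()
    pos_spec, neg_spec = CONTRASTS[cat_letter]

    def pick(spec):
        if spec == "V":
            return meta["drug"] == "V"
        if spec == "high":
            sel = meta["drug"].isin(["T", "E"])
            return sel if pool_doses else sel & (meta["dose_code"] == high)
        drug = spec[0]
        sel = meta["drug"] == drug
        return sel if pool_doses else sel & (meta["dose_code"] == high)

    pos, neg = pick(pos_spec).to_numpy(), pick(neg_spec).to_numpy()
    ids = meta.loc[pos | neg, "animal_id"].tolist()
    classes = pos[pos | neg]
    return ids, classes, f"{pos_spec}-vs-{neg_spec}"


def evaluate_all(expr: pd.DataFrame, meta: pd.DataFrame, categories: pd.Series,
                 config: DiscriminationConfig | None = None) -> pd.DataFrame:
    """Evaluate every categorized gene under its category's contrast."""
    config = config or DiscriminationConfig()
    rows = []
    for gene, cat in categories.items():
        if cat == "none":
            continue
        letter = primary_letter(cat)
        ids, classes, contrast = _contrast_samples(meta, letter, config.pool_doses)
        perf = evaluate_marker(expr.loc[gene, ids].to_numpy(float), classes, config)
        rows.append({"gene": gene, "category": cat, "contrast": contrast,
                     "sensitivity": perf["sensitivity"],
                     "specificity": perf["specificity"]})
    return pd.DataFrame(rows, columns=["gene", "category", "contrast",
                                       "sensitivity", "specificity"])


def summarize_performance(per_marker: pd.DataFrame) -> pd.DataFrame:
    """Mean and range of sensitivity/specificity per primary category + overall."""
    if per_marker.empty:
        return pd.DataFrame(columns=["category", "n", "sens_mean", "sens_min",
                                     "sens_max", "spec_mean", "spec_min", "spec_max"])
    df = per_marker.copy()
    df["letter"] = df["category"].map(primary_letter)
    rows = []
    for label, sub in [*df.groupby("letter"), ("overall", df)]:
        rows.append({
            "category": label, "n": len(sub),
            "sens_mean": sub["sensitivity"].mean(),
            "sens_min": sub["sensitivity"].min(),
            "sens_max": sub["sensitivity"].max(),
            "spec_mean": sub["specificity"].mean(),
            "spec_min": sub["specificity"].min(),
            "spec_max": sub["specificity"].max(),
        })
    return pd.DataFrame(rows)
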