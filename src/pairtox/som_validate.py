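"""Self-organizing map validation of the marker categories.

The categorization from the significance tests is supervised by the
three comparisons; the SOM provides an independent, unsupervised check.
Candidate genes are embedded as 8-feature dose-response profiles
(group means for vehicle + the three entacapone doses, then vehicle +
the three tolcapone doses, z-standardized per gene so shape rather than
magnitude drives the clustering), a k1 x k2 grid of codebook vectors is
trained online, each unit is labeled with the primary category most
improbably enriched in it under a binomial null, and concordance is the
fraction of genes whose unit label matches their own category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from pairtox.categorize import PRIMARY, primary_letter, is_ideal

PROFILE_GROUPS = ("V", "E1", "E2", "E3", "V", "T1", "T2", "T3")


@dataclass
class SomConfig:
    k1: int = 5
    k2: int = 5
    epochs: int = 50
    lr_start: float = 0.5
    lr_end: float = 0.01
    sigma_end: float = 1.0
    seed: int = 0
    topology: str = "rectangular"  # hexagonal: config stub, not implemented

    def __post_init__(self):
        if self.topology != "rectangular":
            raise NotImplementedError("only the rectangular topology is implemented")


@dataclass
class SomModel:
    codebook: np.ndarray               # (k1*k2) x n_features
    grid: np.ndarray                   # (k1*k2) x 2 unit coordinates
    unit_of_gene: pd.Series            # gene -> flat unit index
    label_of_unit: dict[int, str | None] = field(default_factory=dict)
    qe_trace: list[float] = field(default_factory=list)

    @property
    def quantization_error(self) -> float:
        return self.qe_trace[-1] if self.qe_trace else np.nan


def build_profiles(expr: pd.DataFrame, meta: pd.DataFrame,
                   genes: list[str]) -> pd.DataFrame:
    """Per-gene standardized dose-response profile over the 8 design groups.

    Constant genes (zero variance across group means) cannot be
    standardized; they are excluded with a warning.
    """
    group = np.where(meta["drug"] == "V", "V",
                     meta["drug"].astype(str) + meta["dose_code"].astype(str))
    sub = expr.loc[genes]
    means = {}
    for g in set(PROFILE_GROUPS):
        cols = meta.loc[group == g, "animal_id"].tolist()
        if not cols:
            raise ValueError(f"design group {g} has no samples")
        means[g] = sub[cols].mean(axis=1)
    prof = np.column_stack([means[g] for g in PROFILE_GROUPS])
    mu = prof.mean(axis=1, keepdims=True)
    sd = prof.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant gene(s) excluded from SOM "
                      "profiles", stacklevel=2)
    prof = (prof[~flat] - mu[~flat]) / sd[~flat]
    return pd.DataFrame(prof, index=sub.index[~flat], columns=PROFILE_GROUPS)


def train_som(profiles: pd.DataFrame, config: SomConfig | None = None) -> SomModel:
    """Online SOM training, deterministic for a fixed seed.

    Codebook vectors are initialized from randomly chosen input rows;
    the Gaussian neighborhood radius anneals linearly from
    max(k1,k2)/2 to ``sigma_end`` and the learning rate from
    ``lr_start`` to ``lr_end`` over epochs x n_genes updates.
    """
    config = config or SomConfig()
    if profiles.empty:
        raise ValueError("no profiles to train on")
    X = profiles.to_numpy(float)
    n, d = X.shape
    k1, k2 = config.k1, config.k2
    n_units = k1 * k2
    if n < n_units:
        warnings.warn(f"{n} genes < {n_units} SOM units; grid will be sparse",
                      stacklevel=2)
    rng = np.random.default_rng(config.seed)
    grid = np.array([(i, j) for i in range(k1) for j in range(k2)], float)
    grid_d2 = ((grid[:, None, :] - grid[None, :, :]) ** 2).sum(-1)
    codebook = X[rng.integers(0, n, size=n_units)].copy()

    total = config.epochs * n
    sigma0 = max(k1, k2) / 2.0
    step = 0
    qe_trace = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        sq_err = 0.0
        for i in order:
            frac = step / max(total - 1, 1)
            sigma = sigma0 + frac * (config.sigma_end - sigma0)
            lr = config.lr_start + frac * (config.lr_end - config.lr_start)
            diff = X[i] - codebook
            d2 = np.einsum("ij,ij->i", diff, diff)
            bmu = int(np.argmin(d2))
            sq_err += d2[bmu]
            h = np.exp(-grid_d2[bmu] / (2.0 * sigma**2))
            codebook += (lr * h)[:, None] * diff
            step += 1
        qe_trace.append(float(np.sqrt(sq_err / n)))

    d2 = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(-1)
    units = pd.Series(d2.argmin(axis=1), index=profiles.index, name="unit")
    return SomModel(codebook=codebook, grid=grid, unit_of_gene=units,
                    qe_trace=qe_trace)


def label_clusters(model: SomModel, categories: pd.Series) -> dict[int, str | None]:
    """Label each unit with the most binomially enriched primary category.

    For a unit with m genes and category k with within-unit count n_k
    and global prevalence pi_k, enrichment is scored by the upper-tail
    binomial probability P[X >= n_k | m, pi_k]; the smallest tail wins.
    Ties break toward the larger count, then the fixed category order.
    Empty units stay unlabeled (None).
    """
    prim = categories.loc[model.unit_of_gene.index].map(primary_letter)
    pi = {k: float((prim == k).mean()) for k in PRIMARY}
    labels: dict[int, str | None] = {}
    for unit in range(model.codebook.shape[0]):
        members = prim[model.unit_of_gene == unit]
        m = len(members)
        if m == 0:
            labels[unit] = None
            continue
        best = None
        for k in PRIMARY:
            n_k = int((members == k).sum())
            if n_k == 0 or pi[k] == 0:
                continue
            tail = float(stats.binom.sf(n_k - 1, m, pi[k]))
            key = (tail, -n_k, PRIMARY.index(k))
            if best is None or key < best[0]:
                best = (key, k)
        labels[unit] = best[1] if best else None
    model.label_of_unit = labels
    return labels


def concordance(categories: pd.Series, model: SomModel) -> dict:
    """Agreement between unit labels and per-gene categories.

    Overall: fraction of candidate genes whose unit's primary label
    equals their own primary letter.  Ideal: the same fraction
    restricted to ideal-category genes (an ideal gene matches a unit
    labeled with its primary letter).  Per-category rates included.
    """
    if not model.label_of_unit:
        raise ValueError("model units are unlabeled; run label_clusters first")
    genes = model.unit_of_gene.index
    prim = categories.loc[genes].map(primary_letter)
    unit_label = model.unit_of_gene.map(model.label_of_unit)
    match = (unit_label == prim).to_numpy()
    ideal_mask = categories.loc[genes].map(is_ideal).to_numpy()

    per_cat, per_cat_ideal = {}, {}
    for k in PRIMARY:
        sel = (prim == k).to_numpy()
        per_cat[k] = float(match[sel].mean()) if sel.any() else np.nan
        sel_i = sel & ideal_mask
        per_cat_ideal[k] = float(match[sel_i].mean()) if sel_i.any() else np.nan
    return {
        "overall": float(match.mean()) if len(genes) else np.nan,
        "ideal": float(match[ideal_mask].mean()) if ideal_mask.any() else np.nan,
        "n_match": int(match.sum()),
        "n_total": int(len(genes)),
        "n_match_ideal": int(match[ideal_mask].sum()),
        "n_total_ideal": int(ideal_mask.sum()),
        "per_category": per_cat,
        "per_category_ideal": per_cat_ideal,
    }


def rounded_pct(matches: int, total: int) -> int:
    """Percentage rounded half away from zero, the printed-table convention."""
    if total == 0:
        raise ValueError("empty denominator")
    return int(np.floor(100.0 * matches / total + 0.5))
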