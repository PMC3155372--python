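"""Synthetic paired-drug study generator with planted ground truth.

Emulates the 28-day rat design the pipeline targets: a vehicle group
plus three dose groups of each of two drugs (T = hepatotoxic, E = its
non-toxic comparator), 12 animals per group by default.  Expression is
gene-wise independent normal noise on the log2 scale around group means
that are linear in the ordinal dose code — exactly the structure the
linear-slope permutation test assumes — so planted slopes are
recoverable parameters.

Every marker category can be planted.  Per-category slope multipliers
(in units of ``slope_effect`` residual-SDs per dose step) default to:

    T (1, 0.1)      strong under tolcapone, trace same-direction response
                    under entacapone
    E (0.1, 1)      mirror of T
    C (1, 1)        equal slopes, both drugs
    c (1, 0.55)     same sign, unequal -> the T-E test fires
    D (1, -1)       strong opposite slopes
    d (0.1, -0.9)   opposite signs, T-V underpowered
    t (0.28, 0.14)  both drugs weakly up so T-V is significant but the
                    T-E separation is underpowered
    e (0.14, 0.28)  mirror of t

The categories are defined with both drugs sharing the directional
effect, so drug-specific genes carry a trace response of the comparator
drug as well; its size is set where the comparator's slope z-score sits
midway between losing its sign to noise and becoming significant
itself, the window the drug-specific pattern occupies.

The weak-category multipliers place those genes in the power window
where the primary-but-not-ideal patterns arise; they are inherently
borderline, which is what the primary/ideal split models.

Susceptible animals are injected by adding a fixed multiple (default 4x)
of the residual SD to chosen clinical analytes and chosen T-category
genes of chosen tolcapone high-dose animals, producing IQR-flaggable
outliers with positively correlated gene/analyte elevations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pairtox import io as ptio

DOSES_MGKG = {"E": (30.0, 110.0, 400.0), "T": (15.0, 55.0, 200.0)}

# (T-slope, E-slope) multipliers, in units of slope_effect * residual_sd
CATEGORY_SLOPES = {
    "T": (1.0, 0.1),
    "E": (0.1, 1.0),
    "C": (1.0, 1.0),
    "c": (1.0, 0.55),
    "D": (1.0, -1.0),
    "d": (0.1, -0.9),
    "t": (0.28, 0.14),
    "e": (0.14, 0.28),
}

# analyte: (baseline mean, within-group SD) on the measurement scale
ANALYTE_BASELINES = {
    "ALT": (74.0, 10.0),
    "AST": (105.0, 18.0),
    "ALP": (310.0, 70.0),
    "TBIL": (0.15, 0.04),
    "BUN": (16.0, 1.8),
    "LDH": (400.0, 110.0),
}


def _default_counts() -> dict[str, int]:
    return {k: 25 for k in CATEGORY_SLOPES}


@dataclass
class SimulationConfig:
    n_per_group: int = 12
    dose_levels: tuple[int, ...] = (0, 1, 2, 3)
    n_genes_per_category: dict[str, int] = field(default_factory=_default_counts)
    n_null_genes: int = 1800
    slope_effect: float = 2.0          # SD units of expression change per dose step
    residual_sd: float = 0.25          # within-group SD, log2 scale
    baseline_mean_range: tuple[float, float] = (6.0, 12.0)
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (5, 20)
    n_susceptible: int = 2
    susceptible_shift_sd: float = 4.0  # outlier shift, in residual-SD units
    susceptible_analytes: tuple[str, ...] = ("ALT", "AST", "TBIL")
    n_susceptible_genes: int = 6       # T-category genes elevated per animal
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 1 or self.n_null_genes < 0:
            raise ValueError("counts must be non-negative (n_per_group >= 1)")
        if any(v < 0 for v in self.n_genes_per_category.values()):
            raise ValueError("negative per-category gene count")
        unknown = set(self.n_genes_per_category) - set(CATEGORY_SLOPES)
        if unknown:
            raise ValueError(f"unknown categories {sorted(unknown)}")
        if self.slope_effect < 0:
            raise ValueError("negative effect size")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        if tuple(sorted(set(self.dose_levels))) != tuple(self.dose_levels):
            raise ValueError("dose_levels must be strictly increasing")
        if self.n_susceptible < 0 or self.susceptible_shift_sd < 0:
            raise ValueError("susceptible parameters must be non-negative")


@dataclass
class SyntheticStudy:
    expression: pd.DataFrame           # genes x samples, log2 scale
    metadata: pd.DataFrame             # animal_id, drug, dose_code, dose_mgkg
    truth: pd.Series                   # gene -> planted category
    gene_sets: dict[str, list[str]]
    clinchem: pd.DataFrame             # animals x analytes
    susceptible_truth: list[dict]      # animal_id, analytes, genes

    @property
    def groups(self) -> pd.Series:
        m = self.metadata
        g = np.where(m["drug"] == "V", "V",
                     m["drug"].astype(str) + m["dose_code"].astype(str))
        return pd.Series(g, index=m["animal_id"].tolist(), name="group")


def _build_metadata(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    i = 1
    for drug, codes in (("V", (0,)), ("E", config.dose_levels[1:]),
                        ("T", config.dose_levels[1:])):
        for code in codes:
            mg = 0.0 if drug == "V" else DOSES_MGKG[drug][code - 1]
            for _ in range(config.n_per_group):
                rows.append({"animal_id": f"A{i:03d}", "drug": drug,
                             "dose_code": int(code), "dose_mgkg": mg})
                i += 1
    return pd.DataFrame(rows)


def generate_study(config: SimulationConfig | None = None) -> SyntheticStudy:
    """Generate a complete synthetic study; bit-identical for a fixed seed."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    meta = _build_metadata(config)
    n_samples = len(meta)
    dose = meta["dose_code"].to_numpy(float)
    is_T = (meta["drug"] == "T").to_numpy()
    is_E = (meta["drug"] == "E").to_numpy()

    gene_ids, truths, slope_T, slope_E = [], [], [], []
    for cat in CATEGORY_SLOPES:  # fixed order => deterministic layout
        n_cat = config.n_genes_per_category.get(cat, 0)
        mT, mE = CATEGORY_SLOPES[cat]
        for j in range(n_cat):
            gene_ids.append(f"g{cat}{j:04d}")
            truths.append(cat)
            sign = rng.choice((-1.0, 1.0))
            s = config.slope_effect * config.residual_sd
            slope_T.append(sign * mT * s)
            slope_E.append(sign * mE * s)
    for j in range(config.n_null_genes):
        gene_ids.append(f"gnull{j:05d}")
        truths.append("none")
        slope_T.append(0.0)
        slope_E.append(0.0)

    n_genes = len(gene_ids)
    slope_T = np.array(slope_T)
    slope_E = np.array(slope_E)
    lo, hi = config.baseline_mean_range
    baseline = rng.uniform(lo, hi, size=n_genes)

    mean = (baseline[:, None]
            + np.outer(slope_T, dose * is_T)
            + np.outer(slope_E, dose * is_E))
    values = mean + rng.normal(0.0, config.residual_sd, size=(n_genes, n_samples))
    expr = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene"),
                        columns=meta["animal_id"].tolist())
    truth = pd.Series(truths, index=expr.index, name="category")

    gene_sets = _make_gene_sets(config, gene_ids, rng)
    clin = _make_clinchem(config, meta, rng)
    susceptible = _inject_susceptible(config, meta, expr, clin, truth, rng)

    return SyntheticStudy(expression=expr, metadata=meta, truth=truth,
                          gene_sets=gene_sets, clinchem=clin,
                          susceptible_truth=susceptible)


def _make_gene_sets(config, gene_ids, rng) -> dict[str, list[str]]:
    if config.n_pathways == 0 or not gene_ids:
        return {}
    lo, hi = config.pathway_size_range
    sets = {}
    for k in range(config.n_pathways):
        size = min(int(rng.integers(lo, hi + 1)), len(gene_ids))
        members = rng.choice(len(gene_ids), size=size, replace=False)
        sets[f"PW{k:03d}"] = [gene_ids[i] for i in sorted(members)]
    return sets


def _make_clinchem(config, meta, rng) -> pd.DataFrame:
    data = {}
    for analyte, (mu, sd) in ANALYTE_BASELINES.items():
        data[analyte] = rng.normal(mu, sd, size=len(meta))
    return pd.DataFrame(data, index=pd.Index(meta["animal_id"].tolist(),
                                             name="animal_id"))


def _inject_susceptible(config, meta, expr, clin, truth, rng) -> list[dict]:
    """Shift analytes and T-category genes of chosen T-high animals upward.

    Monitored analytes are split across the susceptible animals (each
    animal is extreme on its own analytes, the usual presentation of
    sensitive individuals); the elevated marker genes are shared by all
    of them.  Two same-group animals extreme on the same analyte would
    also mask each other under the within-group IQR rule.
    """
    if config.n_susceptible == 0:
        return []
    high = config.dose_levels[-1]
    pool = meta.loc[(meta["drug"] == "T") & (meta["dose_code"] == high),
                    "animal_id"].tolist()
    n_pick = min(config.n_susceptible, len(pool))
    animals = [pool[i] for i in sorted(rng.choice(len(pool), n_pick, replace=False))]
    t_genes = truth.index[truth == "T"].tolist()
    genes = t_genes[:config.n_susceptible_genes]
    analytes = [a for a in config.susceptible_analytes if a in clin.columns]
    splits = [[str(a) for a in chunk]
              for chunk in np.array_split(np.array(analytes), n_pick)]
    out = []
    for animal, own_analytes in zip(animals, splits):
        for a in own_analytes:
            clin.loc[animal, a] += config.susceptible_shift_sd * ANALYTE_BASELINES[a][1]
        if genes:
            expr.loc[genes, animal] += config.susceptible_shift_sd * config.residual_sd
        out.append({"animal_id": animal, "analytes": own_analytes,
                    "genes": list(genes)})
    return out


def write_study(study: SyntheticStudy, directory) -> dict[str, Path]:
    """Write the study as TSV/CSV/GMT files; round-trips via read_study."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "metadata": directory / "metadata.tsv",
        "gene_sets": directory / "gene_sets.gmt",
        "clinchem": directory / "clinchem.csv",
        "truth": directory / "truth.tsv",
    }
    study.expression.to_csv(paths["expression"], sep="\t")
    study.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    ptio.write_gmt(study.gene_sets, paths["gene_sets"])
    study.clinchem.to_csv(paths["clinchem"])
    study.truth.rename("category").to_frame().to_csv(paths["truth"], sep="\t")
    return paths


def read_study(directory) -> SyntheticStudy:
    directory = Path(directory)
    expr = ptio.read_expression(directory / "expression.tsv")
    meta = ptio.read_metadata(directory / "metadata.tsv")
    ptio.reconcile(expr, meta)
    sets = ptio.read_gmt(directory / "gene_sets.gmt")
    clin = ptio.read_clinchem(directory / "clinchem.csv")
    truth = pd.read_csv(directory / "truth.tsv", sep="\t", index_col=0)["category"]
    return SyntheticStudy(expression=expr, metadata=meta, truth=truth,
                          gene_sets=sets, clinchem=clin, susceptible_truth=[])
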