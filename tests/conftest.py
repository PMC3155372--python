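import numpy as np
import pandas as pd
import pytest

from pairtox import categorize as cat
from pairtox.dose_response import AnalysisConfig, analyze_genes
from pairtox.synthetic_data import SimulationConfig, generate_study


@pytest.fixture(scope="session")
def study():
    """Small planted study shared by the module tests."""
    cfg = SimulationConfig(
        seed=11,
        n_genes_per_category={k: 20 for k in "TECD"},
        n_null_genes=300,
        n_pathways=10,
        pathway_size_range=(5, 10),
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def markers(study):
    """Categorized marker table for the shared study."""
    res = analyze_genes(study.expression, study.metadata,
                     AnalysisConfig(n_permutations=499, seed=5))
    return cat.categorize_all(res, alpha=0.05)


@pytest.fixture(scope="session")
def toy_meta():
    """2 animals per group: permutations are exhaustively enumerable."""
    rows, i = [], 0
    for drug, codes in (("V", [0]), ("E", [1, 2, 3]), ("T", [1, 2, 3])):
        for c in codes:
            for _ in range(2):
                rows.append({"animal_id": f"A{i}", "drug": drug,
                             "dose_code": c, "dose_mgkg": float(10 * c)})
                i += 1
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def three_group_meta():
    """Vehicle + two high-dose groups, 12 animals each (gene-set design)."""
    return pd.DataFrame({
        "animal_id": [f"A{i}" for i in range(36)],
        "drug": ["V"] * 12 + ["E"] * 12 + ["T"] * 12,
        "dose_code": [0] * 12 + [3] * 12 + [3] * 12,
    })


def make_expr(meta, n_genes, rng, shift=None):
    """iid normal expression; optional per-group mean shift dict."""
    X = rng.normal(size=(n_genes, len(meta)))
    if shift:
        for g, delta in shift.items():
            X[:, (meta["drug"] + meta["dose_code"].astype(str) == g).to_numpy()] += delta
    return pd.DataFrame(X, index=[f"g{i}" for i in range(n_genes)],
                        columns=meta["animal_id"].tolist())
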