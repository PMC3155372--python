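import numpy as np
import pandas as pd
import pytest

from pairtox import som_validate as som


def _profiles(n, rng, centers):
    X, labels = [], []
    for k, c in enumerate(centers):
        for _ in range(n):
            X.append(np.asarray(c, float) + rng.normal(0, 0.05, 8))
            labels.append(k)
    X = np.array(X)
    X = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
    return pd.DataFrame(X, index=[f"g{i}" for i in range(len(X))],
                        columns=som.PROFILE_GROUPS), labels


def test_profile_vector_has_eight_features(study):
    prof = som.build_profiles(study.expression, study.metadata,
                              list(study.expression.index[:10]))
    assert prof.shape[1] == 8
    assert np.allclose(prof.mean(axis=1), 0, atol=1e-12)


def test_constant_gene_excluded_with_warning(study):
    expr = study.expression.copy()
    expr.loc["flatgene"] = 3.0
    with pytest.warns(UserWarning, match="constant"):
        prof = som.build_profiles(expr, study.metadata,
                                  ["flatgene", *study.expression.index[:5]])
    assert "flatgene" not in prof.index


def test_planted_tolcapone_gene_profile_shape(study):
    """T genes: near-flat entacapone half, monotone tolcapone half."""
    t_genes = study.truth.index[study.truth == "T"][:10]
    prof = som.build_profiles(study.expression, study.metadata, list(t_genes))
    ent = prof.to_numpy()[:, :4]
    tol = prof.to_numpy()[:, 4:]
    assert (np.abs(np.diff(tol, axis=1)).sum(1)
            > np.abs(np.diff(ent, axis=1)).sum(1)).mean() >= 0.9


def test_identical_profiles_collapse_to_one_unit():
    prof = pd.DataFrame(np.tile([1.0, -1, 1, -1, 1, -1, 1, -1], (30, 1)),
                        index=[f"g{i}" for i in range(30)],
                        columns=som.PROFILE_GROUPS)
    model = som.train_som(prof, som.SomConfig(seed=0, epochs=10))
    assert model.unit_of_gene.nunique() == 1


def test_quantization_error_decreases_over_training():
    rng = np.random.default_rng(1)
    prof, _ = _profiles(25, rng, [[0, 0, 0, 0, 0, 1, 2, 3],
                                  [0, 1, 2, 3, 0, 0, 0, 0],
                                  [0, 1, 2, 3, 0, 1, 2, 3],
                                  [0, 1, 2, 3, 0, -1, -2, -3]])
    model = som.train_som(prof, som.SomConfig(seed=2))
    assert model.qe_trace[-1] < model.qe_trace[0]


def test_training_is_deterministic(study, markers):
    genes = markers.index[markers["category"] != "none"].tolist()
    prof = som.build_profiles(study.expression, study.metadata, genes)
    m1 = som.train_som(prof, som.SomConfig(seed=7, epochs=10))
    m2 = som.train_som(prof, som.SomConfig(seed=7, epochs=10))
    assert np.array_equal(m1.codebook, m2.codebook)
    assert m1.unit_of_gene.equals(m2.unit_of_gene)


def test_pure_unit_gets_its_category():
    model = som.SomModel(codebook=np.zeros((4, 8)), grid=np.zeros((4, 2)),
                         unit_of_gene=pd.Series([0, 0, 0, 1, 1], index=list("abcde")))
    cats = pd.Series(["t", "t", "t", "e", "e"], index=list("abcde"))
    labels = som.label_clusters(model, cats)
    assert labels[0] == "t" and labels[1] == "e"
    assert labels[2] is None  # empty unit stays unlabeled


def test_binomial_labeling_prefers_rarer_enrichment():
    """8 of 10 't' (global prevalence .32) beats 2 of 10 'e' (prevalence .46)."""
    genes = [f"g{i}" for i in range(50)]
    cats = pd.Series(["t"] * 16 + ["e"] * 23 + ["c"] * 11, index=genes)
    units = pd.Series(0, index=genes)
    unit0 = genes[:8] + genes[16:18]            # 8 t, 2 e
    units[:] = 1
    units[unit0] = 0
    model = som.SomModel(codebook=np.zeros((2, 8)), grid=np.zeros((2, 2)),
                         unit_of_gene=units)
    labels = som.label_clusters(model, cats)
    assert labels[0] == "t"


def test_labels_invariant_to_gene_order(study, markers):
    genes = markers.index[markers["category"] != "none"].tolist()
    prof = som.build_profiles(study.expression, study.metadata, genes)
    model = som.train_som(prof, som.SomConfig(seed=3, epochs=10))
    l1 = som.label_clusters(model, markers["category"])
    shuffled = markers["category"].sample(frac=1.0, random_state=0)
    l2 = som.label_clusters(model, shuffled)
    assert l1 == l2


def test_concordance_bounds_and_perfect_case():
    genes = list("abcd")
    units = pd.Series([0, 0, 1, 1], index=genes)
    model = som.SomModel(codebook=np.zeros((2, 8)), grid=np.zeros((2, 2)),
                         unit_of_gene=units)
    cats = pd.Series(["t", "T", "e", "e"], index=genes)
    som.label_clusters(model, cats)
    conc = som.concordance(cats, model)
    assert conc["overall"] == 1.0
    assert conc["ideal"] == 1.0 and conc["n_total_ideal"] == 1


def test_random_labels_near_chance():
    """4 balanced categories, category-blind units: concordance ~ 25%."""
    rng = np.random.default_rng(5)
    genes = [f"g{i}" for i in range(400)]
    cats = pd.Series(rng.permutation(np.repeat(list("tecd"), 100)), index=genes)
    units = pd.Series(np.arange(400) % 4, index=genes)  # units independent of cats
    model = som.SomModel(codebook=np.zeros((4, 8)), grid=np.zeros((4, 2)),
                         unit_of_gene=units)
    som.label_clusters(model, cats)
    conc = som.concordance(cats, model)
    assert 0.15 <= conc["overall"] <= 0.40
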