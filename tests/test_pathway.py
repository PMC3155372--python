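import numpy as np
import pandas as pd
import pytest

from pairtox import pathway as pw
from conftest import make_expr


def _markers_table(cats):
    """Minimal categorize_all-shaped table: index gene, column category."""
    return pd.DataFrame({"category": pd.Series(cats)})


def test_sets_without_categorized_genes_dropped():
    markers = _markers_table({"g1": "T", "g2": "none", "g3": "none"})
    sets = {"hit": ["g1", "g2"], "miss": ["g2", "g3"], "offarray": ["zz"]}
    cands = pw.filter_candidate_sets(sets, markers)
    assert list(cands["set"]) == ["hit"]
    assert cands.iloc[0]["categorized_members"] == [("g1", "T")]


def test_tolcapone_specific_flag_requires_only_t_members():
    markers = _markers_table({"g1": "T", "g2": "t", "g3": "e", "g4": "none"})
    sets = {"pure": ["g1", "g2", "g4"], "mixed": ["g1", "g3"]}
    cands = pw.filter_candidate_sets(sets, markers).set_index("set")
    assert bool(cands.loc["pure", "tol_specific"])
    assert not bool(cands.loc["mixed", "tol_specific"])


def test_identical_groups_give_p_one(three_group_meta):
    block = np.random.default_rng(0).normal(size=(4, 12))
    expr = pd.DataFrame(np.tile(block, (1, 3)),
                        index=[f"g{i}" for i in range(4)],
                        columns=three_group_meta["animal_id"])
    res = pw.manova_gene_set(expr, three_group_meta, list(expr.index),
                             pw.PathwayConfig(n_permutations=99, seed=0))
    assert res["p"] == 1.0


def test_permutation_p_floor(three_group_meta):
    rng = np.random.default_rng(1)
    expr = make_expr(three_group_meta, 3, rng, shift={"T3": 3.0})
    res = pw.manova_gene_set(expr, three_group_meta, list(expr.index),
                             pw.PathwayConfig(n_permutations=199, seed=0))
    assert res["p"] == pytest.approx(1 / 200)


def test_set_larger_than_df_uses_shrinkage(three_group_meta):
    """p >= within-group df would make plain Wilks singular; still finite."""
    rng = np.random.default_rng(2)
    expr = make_expr(three_group_meta, 40, rng, shift={"T3": 1.0})
    res = pw.manova_gene_set(expr, three_group_meta, list(expr.index),
                             pw.PathwayConfig(n_permutations=99, seed=1))
    assert 0 < res["statistic"] < 1
    assert res["p"] <= 0.05


def test_missing_set_genes_returns_none(three_group_meta):
    expr = make_expr(three_group_meta, 2, np.random.default_rng(0))
    assert pw.manova_gene_set(expr, three_group_meta, ["nope"]) is None


def test_noise_gene_does_not_move_p_much(three_group_meta):
    rng = np.random.default_rng(3)
    expr = make_expr(three_group_meta, 6, rng, shift={"T3": 0.9})
    expr.loc["noise"] = rng.normal(size=36)  # overwrite adds a null gene
    cfg = pw.PathwayConfig(n_permutations=2000, seed=5)
    p_base = pw.manova_gene_set(expr, three_group_meta,
                                [f"g{i}" for i in range(5)], cfg)["p"]
    p_plus = pw.manova_gene_set(expr, three_group_meta,
                                [f"g{i}" for i in range(5)] + ["noise"], cfg)["p"]
    assert abs(p_base - p_plus) <= 0.03


def test_pillai_agrees_with_wilks_on_strong_effect(three_group_meta):
    rng = np.random.default_rng(6)
    expr = make_expr(three_group_meta, 4, rng, shift={"T3": 2.0})
    for stat in ("wilks", "pillai"):
        res = pw.manova_gene_set(expr, three_group_meta, list(expr.index),
                                 pw.PathwayConfig(n_permutations=199, seed=2,
                                                  statistic=stat))
        assert res["p"] <= 0.05


def test_ranking_is_stable_under_ties():
    res = pd.DataFrame({
        "set": ["b", "a", "c"], "size": [3, 3, 3],
        "categorized_genes": ["x", "y", "z"],
        "p": [0.01, 0.01, 0.2],
        "tol_specific": [True, True, True],
        "significant": [True, True, False]})
    ranked = pw.rank_tolcapone_specific(res)
    assert list(ranked["set"]) == ["a", "b", "c"]


def test_planted_tol_pathway_detected_end_to_end(study, markers):
    """A set of planted T genes carries a real 3-group effect: p <= 0.05."""
    t_cat = markers.index[markers["category"].isin(["T", "t"])]
    t_genes = [g for g in study.truth.index[study.truth == "T"]
               if g in t_cat][:8]
    sets = {"tolpath": t_genes,
            "nullpath": study.truth.index[study.truth == "none"][:8].tolist()}
    cands = pw.filter_candidate_sets(sets, markers)
    res = pw.analyze_sets(study.expression, study.metadata, cands,
                          pw.PathwayConfig(n_permutations=499, seed=9))
    assert res.set_index("set").loc["tolpath", "p"] <= 0.05
    assert res.set_index("set").loc["tolpath", "tol_specific"]
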