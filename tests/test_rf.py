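"""Per-target regression forest and its two importance scores."""

import numpy as np
import pytest

from rfgsea import ExpressionMatrix, fit_target_model
from rfgsea.rf import (
    RFConfig,
    _fit_forest,
    impurity_importance,
    permutation_importance,
)


def linear_matrix(seed, n_samples=100, n_background=49, beta=2.0, noise=0.25):
    """Target = beta * x1 + eps with independent background predictors."""
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n_samples)
    y = beta * x1 + rng.normal(0.0, noise, n_samples)
    bg = rng.normal(size=(n_background, n_samples))
    genes = ("T", "X1") + tuple(f"B{i}" for i in range(n_background))
    return ExpressionMatrix(
        genes, tuple(f"S{j}" for j in range(n_samples)), np.vstack([y, x1, bg])
    )


def noise_matrix(seed, n_genes=51, n_samples=100):
    rng = np.random.default_rng(seed)
    return ExpressionMatrix(
        tuple(f"G{i}" for i in range(n_genes)),
        tuple(f"S{j}" for j in range(n_samples)),
        rng.normal(size=(n_genes, n_samples)),
    )


CFG = RFConfig(n_trees=50)


def test_informative_predictor_ranks_first_by_both_scores():
    wins_mse = wins_purity = 0
    for seed in range(10):
        r = fit_target_model(linear_matrix(seed), "T", RFConfig(n_trees=50, seed=seed))
        i = list(r.predictor_genes).index("X1")
        wins_mse += int(np.argmax(r.pct_inc_mse) == i)
        wins_purity += int(np.argmax(r.inc_node_purity) == i)
    assert wins_mse == 10
    assert wins_purity == 10


def test_duplicated_target_dominates_importance():
    """A leaked copy of the target is a perfect predictor and must attain
    the maximum permutation importance."""
    for seed in range(5):
        m = linear_matrix(seed)
        vals = np.vstack([m.values, m.values[0]])
        leaky = ExpressionMatrix(m.gene_ids + ("T_dup",), m.sample_ids, vals)
        r = fit_target_model(leaky, "T", RFConfig(n_trees=50, seed=seed))
        top = r.predictor_genes[int(np.argmax(r.pct_inc_mse))]
        assert top == "T_dup"


def test_correlated_informative_predictors_share_importance():
    """Two identical informative predictors each score lower than the
    single-copy run but still occupy the top two ranks."""
    shared_lower = both_top2 = 0
    n_seeds = 10
    for seed in range(n_seeds):
        m = linear_matrix(seed)
        single = fit_target_model(m, "T", RFConfig(n_trees=50, seed=seed))
        i1 = list(single.predictor_genes).index("X1")
        dup_vals = np.vstack([m.values, m.values[1]])
        dup = ExpressionMatrix(m.gene_ids + ("X1b",), m.sample_ids, dup_vals)
        r = fit_target_model(dup, "T", RFConfig(n_trees=50, seed=seed))
        j1 = list(r.predictor_genes).index("X1")
        j2 = list(r.predictor_genes).index("X1b")
        order = np.argsort(-r.pct_inc_mse)
        both_top2 += int({order[0], order[1]} == {j1, j2})
        shared_lower += int(
            max(r.pct_inc_mse[j1], r.pct_inc_mse[j2]) < single.pct_inc_mse[i1]
        )
    assert both_top2 >= 8
    assert shared_lower >= 8


def test_never_split_predictor_scores_exactly_zero():
    m = linear_matrix(0, n_samples=60, n_background=30)
    r = fit_target_model(m, "T", RFConfig(n_trees=30, seed=4))
    forest = _fit_forest(m, "T", RFConfig(n_trees=30, seed=4))
    used = set()
    for tree in forest.trees:
        used |= set(tree.tree_.feature[tree.tree_.feature >= 0].tolist())
    unused = [j for j in range(len(r.predictor_genes)) if j not in used]
    assert unused, "fixture must leave some predictors unused"
    assert np.all(r.pct_inc_mse[unused] == 0.0)
    assert np.all(r.inc_node_purity[unused] == 0.0)


def test_impurity_importance_non_negative():
    for seed in range(5):
        r = fit_target_model(noise_matrix(seed), "G0", RFConfig(n_trees=20, seed=seed))
        assert np.all(r.inc_node_purity >= 0.0)


def test_negative_permutation_importance_under_global_null():
    """Independence of target and predictors yields negative %IncMSE for
    some predictors — the premise of the negative-enrichment split."""
    for seed in range(5):
        r = fit_target_model(noise_matrix(seed), "G0", RFConfig(n_trees=50, seed=seed))
        assert np.any(r.pct_inc_mse < 0.0)


def test_deterministic_given_seed():
    m = linear_matrix(1)
    a = fit_target_model(m, "T", RFConfig(n_trees=25, seed=42))
    b = fit_target_model(m, "T", RFConfig(n_trees=25, seed=42))
    np.testing.assert_array_equal(a.pct_inc_mse, b.pct_inc_mse)
    np.testing.assert_array_equal(a.inc_node_purity, b.inc_node_purity)
    assert a.oob_mse == b.oob_mse


def test_errors_for_bad_targets(small_matrix):
    with pytest.raises(KeyError):
        fit_target_model(small_matrix, "nope", CFG)
    vals = small_matrix.values.copy()
    vals[0] = 3.0
    m = ExpressionMatrix(small_matrix.gene_ids, small_matrix.sample_ids, vals)
    with pytest.raises(ValueError, match="zero variance"):
        fit_target_model(m, "G0", CFG)


def test_permutation_importance_requires_bootstrap():
    m = linear_matrix(0, n_samples=40, n_background=10)
    forest = _fit_forest(m, "T", RFConfig(n_trees=10, seed=0, bootstrap=False))
    with pytest.raises(ValueError, match="out-of-bag"):
        permutation_importance(forest)


def test_impurity_invariant_to_sample_order_with_synced_bootstrap():
    """Reordering samples while re-indexing the bootstrap draw consistently
    leaves the impurity importance unchanged."""
    m = linear_matrix(3, n_samples=50, n_background=10)
    cfg = RFConfig(n_trees=10, seed=5)
    rng = np.random.default_rng(0)
    boot = rng.integers(0, m.n_samples, size=(cfg.n_trees, m.n_samples))
    f1 = _fit_forest(m, "T", cfg, bootstrap_indices=boot)
    perm = rng.permutation(m.n_samples)
    inv = np.argsort(perm)
    m2 = ExpressionMatrix(
        m.gene_ids, tuple(m.sample_ids[i] for i in perm), m.values[:, perm]
    )
    f2 = _fit_forest(m2, "T", cfg, bootstrap_indices=inv[boot])
    np.testing.assert_allclose(
        impurity_importance(f1), impurity_importance(f2), atol=1e-9
    )


def test_ranking_table_ranks_break_ties_by_gene_id():
    m = linear_matrix(0, n_samples=40, n_background=10)
    df = fit_target_model(m, "T", RFConfig(n_trees=10, seed=0)).to_frame()
    assert set(df.columns) == {
        "predictor", "pct_inc_mse", "inc_node_purity", "rank_mse", "rank_purity"
    }
    assert sorted(df["rank_mse"]) == list(range(1, len(df) + 1))
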