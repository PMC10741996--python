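"""Random-forest regression of one gene on all others, with two importances.

For a target gene *n* in a universe of *N* genes, an ensemble of
regression trees is fit with the target's expression as the response and
the remaining N-1 genes as predictors.  Two variable-importance scores
are produced for every predictor:

* **%IncMSE** (permutation importance): for each tree, the increase in
  out-of-bag mean squared error after permuting one predictor within the
  tree's out-of-bag samples; the reported score is the mean increase
  across trees divided by its standard error (the raw mean when the
  standard error is zero).  A predictor that does not help prediction
  fluctuates around zero and can be negative.
* **IncNodePurity** (impurity importance): the total decrease in node
  residual sum of squares over all splits on a predictor, summed over
  trees and divided by the number of trees; non-negative by construction.

Defaults follow the bagged-ensemble recipe the screen is built on:
500 unpruned CART trees, all N-1 predictors examined at every split,
bootstrap resampling of samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .io import ExpressionMatrix

__all__ = [
    "RFConfig",
    "ImportanceRanking",
    "TargetForest",
    "fit_target_model",
    "permutation_importance",
    "impurity_importance",
]


@dataclass(frozen=True)
class RFConfig:
    """Configuration of the per-target regression forest.

    ``predictors_per_split="all"`` examines every predictor at every node
    (bagged trees); a numeric value gives classic random-subspace forests.
    Trees are unpruned; ``min_samples_leaf`` is the only growth bound.
    ``scale_importance=False`` reports the raw mean out-of-bag MSE increase
    instead of the standard-error-scaled score.  ``n_permutations`` repeats
    of the per-tree permutation are averaged (one pass is the standard
    estimator).
    """

    n_trees: int = 500
    predictors_per_split: int | Literal["all"] = "all"
    min_samples_leaf: int = 5
    bootstrap: bool = True
    seed: int = 0
    scale_importance: bool = True
    n_permutations: int = 1

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.predictors_per_split != "all" and self.predictors_per_split < 1:
            raise ValueError("predictors_per_split must be 'all' or a positive int")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass(frozen=True)
class TargetForest:
    """A fitted per-target ensemble plus the resampling record needed
    for out-of-bag permutation importance."""

    target_gene: str
    predictor_genes: tuple[str, ...]
    trees: tuple[DecisionTreeRegressor, ...]
    bootstrap_indices: np.ndarray | None  # (n_trees, S) or None when disabled
    X: np.ndarray  # (S, N-1) predictor matrix
    y: np.ndarray  # (S,) target values
    config: RFConfig


@dataclass(frozen=True)
class ImportanceRanking:
    """Both importance vectors for one target gene.

    ``pct_inc_mse`` may be negative; ``inc_node_purity`` is non-negative;
    a predictor never split on in any tree scores exactly 0 on both.
    """

    target_gene: str
    predictor_genes: tuple[str, ...]
    pct_inc_mse: np.ndarray
    inc_node_purity: np.ndarray
    oob_mse: float

    def to_frame(self) -> pd.DataFrame:
        """TSV-ready table: predictor, both scores, both ranks (1 = best)."""
        df = pd.DataFrame(
            {
                "predictor": list(self.predictor_genes),
                "pct_inc_mse": self.pct_inc_mse,
                "inc_node_purity": self.inc_node_purity,
            }
        )
        # descending score, gene id breaks ties (stable across platforms)
        for col, rank_col in [
            ("pct_inc_mse", "rank_mse"),
            ("inc_node_purity", "rank_purity"),
        ]:
            order = np.lexsort((df["predictor"].to_numpy(), -df[col].to_numpy()))
            ranks = np.empty(len(df), dtype=int)
            ranks[order] = np.arange(1, len(df) + 1)
            df[rank_col] = ranks
        return df


def _fit_forest(
    matrix: ExpressionMatrix,
    target_gene: str,
    config: RFConfig,
    bootstrap_indices: np.ndarray | None = None,
) -> TargetForest:
    """Fit the ensemble.  ``bootstrap_indices`` overrides the seed-driven
    bootstrap draw (used to test resampling-synchronized invariances)."""
    t_idx = matrix.gene_index(target_gene)
    y = matrix.values[t_idx]
    if y.std() == 0.0:
        raise ValueError(
            f"target gene {target_gene!r} has zero variance across samples; "
            "its regression model is undefined"
        )
    keep = [i for i in range(matrix.n_genes) if i != t_idx]
    predictor_genes = tuple(matrix.gene_ids[i] for i in keep)
    X = matrix.values[keep].T.copy()  # samples x predictors
    n_samples, n_pred = X.shape
    if config.predictors_per_split == "all":
        max_features = None
    else:
        if config.predictors_per_split > n_pred:
            raise ValueError(
                f"predictors_per_split={config.predictors_per_split} exceeds "
                f"the {n_pred} available predictors"
            )
        max_features = config.predictors_per_split

    rng = np.random.default_rng(config.seed)
    tree_seeds = rng.integers(0, 2**31 - 1, size=config.n_trees)
    trees = []
    boot = None
    if config.bootstrap:
        drawn = rng.integers(0, n_samples, size=(config.n_trees, n_samples))
        boot = drawn if bootstrap_indices is None else np.asarray(bootstrap_indices)
    for t in range(config.n_trees):
        idx = boot[t] if boot is not None else np.arange(n_samples)
        tree = DecisionTreeRegressor(
            max_features=max_features,
            min_samples_leaf=config.min_samples_leaf,
            random_state=int(tree_seeds[t]),
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)
    return TargetForest(
        target_gene=target_gene,
        predictor_genes=predictor_genes,
        trees=tuple(trees),
        bootstrap_indices=boot,
        X=X,
        y=y,
        config=config,
    )


def impurity_importance(forest: TargetForest) -> np.ndarray:
    """Total split-wise decrease in node residual sum of squares per
    predictor, summed over all trees and divided by the number of trees."""
    n_pred = len(forest.predictor_genes)
    total = np.zeros(n_pred)
    for tree in forest.trees:
        t = tree.tree_
        # node "impurity" is within-node MSE; weighted by node size it is
        # the node residual sum of squares
        node_sse = t.impurity * t.weighted_n_node_samples
        internal = t.children_left >= 0
        dec = (
            node_sse[internal]
            - node_sse[t.children_left[internal]]
            - node_sse[t.children_right[internal]]
        )
        np.add.at(total, t.feature[internal], dec)
    return total / len(forest.trees)


def permutation_importance(forest: TargetForest) -> tuple[np.ndarray, float]:
    """Out-of-bag permutation importance (%IncMSE) and the ensemble OOB MSE.

    For tree *t* and predictor *j*, ``d[t, j]`` is the tree's OOB MSE after
    permuting column *j* within its OOB samples minus its unpermuted OOB
    MSE.  Only predictors actually split on in a tree can change its
    predictions, so unused predictors get ``d = 0`` exactly.  The reported
    score is ``mean_t(d) / stderr_t(d)`` (raw mean when the standard error
    is zero, e.g. for a never-used predictor).
    """
    if forest.bootstrap_indices is None:
        raise ValueError(
            "permutation importance requires bootstrap resampling: without it "
            "no out-of-bag samples exist"
        )
    cfg = forest.config
    X, y = forest.X, forest.y
    # trees store float32 thresholds; predicting on float32 matches fit
    # exactly and allows the fast low-level predictor
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    n_samples, n_pred = X.shape
    n_trees = len(forest.trees)
    d = np.zeros((n_trees, n_pred))
    valid = np.zeros(n_trees, dtype=bool)
    oob_pred_sum = np.zeros(n_samples)
    oob_pred_count = np.zeros(n_samples, dtype=int)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x0F0B]))
    perm_seeds = rng.integers(0, 2**31 - 1, size=n_trees)

    for t, tree in enumerate(forest.trees):
        oob_mask = np.ones(n_samples, dtype=bool)
        oob_mask[forest.bootstrap_indices[t]] = False
        n_oob = int(oob_mask.sum())
        if n_oob == 0:
            continue
        valid[t] = True
        Xo = X32[oob_mask].copy()
        yo = y[oob_mask]
        base_pred = tree.tree_.predict(Xo).ravel()
        base_mse = float(np.mean((yo - base_pred) ** 2))
        oob_pred_sum[oob_mask] += base_pred
        oob_pred_count[oob_mask] += 1
        used = np.unique(tree.tree_.feature[tree.tree_.feature >= 0])
        tree_rng = np.random.default_rng(perm_seeds[t])
        for j in used:
            col = Xo[:, j].copy()
            acc = 0.0
            for _ in range(cfg.n_permutations):
                Xo[:, j] = col[tree_rng.permutation(n_oob)]
                perm_pred = tree.tree_.predict(Xo).ravel()
                acc += float(np.mean((yo - perm_pred) ** 2)) - base_mse
            Xo[:, j] = col
            d[t, j] = acc / cfg.n_permutations

    if not valid.any():
        raise ValueError("no tree has out-of-bag samples; increase sample size")
    dv = d[valid]
    mean = dv.mean(axis=0)
    if cfg.scale_importance and dv.shape[0] > 1:
        stderr = dv.std(axis=0, ddof=1) / np.sqrt(dv.shape[0])
        score = np.where(stderr > 0, mean / np.where(stderr > 0, stderr, 1.0), mean)
    else:
        score = mean
    covered = oob_pred_count > 0
    oob_mse = float(
        np.mean((y[covered] - oob_pred_sum[covered] / oob_pred_count[covered]) ** 2)
    )
    return score, oob_mse


def fit_target_model(
    matrix: ExpressionMatrix, target_gene: str, config: RFConfig | None = None
) -> ImportanceRanking:
    """Fit the per-target ensemble and compute both importance vectors.

    Deterministic given ``(matrix, target_gene, config.seed)``.  Raises for
    a missing or zero-variance target.
    """
    config = config or RFConfig()
    forest = _fit_forest(matrix, target_gene, config)
    purity = impurity_importance(forest)
    if config.bootstrap:
        mse_score, oob_mse = permutation_importance(forest)
    else:
        mse_score = np.zeros(len(forest.predictor_genes))
        oob_mse = float("nan")
    return ImportanceRanking(
        target_gene=target_gene,
        predictor_genes=forest.predictor_genes,
        pct_inc_mse=mse_score,
        inc_node_purity=purity,
        oob_mse=oob_mse,
    )
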