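"""Preranked gene-set enrichment: weighted running-sum score and
gene-label permutation null.

Given a ranked, scored gene list (here: all predictor genes of one target,
ranked by a random-forest importance score) and a prior gene set, the
enrichment score (ES) is the signed maximum deviation of a weighted
Kolmogorov-Smirnov-style running sum: walking down the list, a set member
("hit") at position *i* adds ``|score_i|^w / sum_hits |score|^w`` and a
non-member subtracts ``1 / (N - N_hit)``.  A positive ES means the set
concentrates at the top of the ranking; a negative ES at the bottom.

The null distribution fixes the scores and redraws the hit positions
uniformly without replacement (gene-label permutation).  The p-value uses
a +1 pseudo-count and is sign-conditional; the normalized enrichment
score (NES) divides the observed ES by the mean magnitude of same-sign
null scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io import GeneSet

logger = logging.getLogger("rfgsea")

__all__ = ["RankedList", "GseaResult", "enrichment_score", "gsea_test"]

MIN_PERMUTATIONS = 100


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by non-increasing score.

    Build with :meth:`from_scores`, which sorts by descending score and
    breaks ties by gene id so the ordering is platform-independent.
    """

    genes: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if len(self.genes) < 2:
            raise ValueError("ranked list needs at least 2 genes")
        if len(self.genes) != len(scores):
            raise ValueError("genes and scores differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate genes")
        if not np.all(np.isfinite(scores)):
            raise ValueError("ranked list scores must be finite")
        if np.any(np.diff(scores) > 0):
            raise ValueError("scores must be non-increasing")

    @classmethod
    def from_scores(cls, genes: Iterable[str], scores: Iterable[float]) -> "RankedList":
        genes = tuple(genes)
        scores = np.asarray(list(scores), dtype=float)
        order = np.lexsort((genes, -scores))
        return cls(tuple(genes[i] for i in order), scores[order])

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GseaResult:
    """Outcome of one preranked enrichment test.

    ``nes`` is NaN when no null score shares the observed sign (logged;
    ``p_value`` is then 1).  ``p_value`` uses a +1 pseudo-count and is
    never exactly 0.
    """

    es: float
    nes: float
    p_value: float
    direction: str  # positive | negative | zero
    n_permutations: int
    n_hits: int
    hit_indices: tuple[int, ...]
    running_score: np.ndarray


def _hit_weights(scores: np.ndarray, hit_mask: np.ndarray, weight_exponent: float):
    w = np.abs(scores) ** weight_exponent
    if w[hit_mask].sum() == 0.0:
        # all hits carry zero score: fall back to unweighted steps
        logger.warning("all hit scores are zero; using unweighted hit increments")
        w = np.ones_like(w)
    return w


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet, weight_exponent: float = 1.0
) -> tuple[float, np.ndarray, np.ndarray]:
    """Weighted running-sum enrichment score of a set in a ranked list.

    Returns ``(es, running_score, hit_indices)``.  The ES is the element
    of the running score with the largest absolute value; an exact tie
    between the positive and negative extremes resolves to the positive
    one (probability zero for continuous scores) and is logged.
    """
    members = set(gene_set.genes)
    hit_mask = np.fromiter((g in members for g in ranked.genes), bool, len(ranked))
    n = len(ranked)
    k = int(hit_mask.sum())
    if k == 0:
        raise ValueError(
            f"gene set {gene_set.name!r} has no member in the ranked list"
        )
    if k == n:
        raise ValueError(
            f"gene set {gene_set.name!r} covers the whole ranked list; "
            "enrichment is undefined"
        )
    w = _hit_weights(ranked.scores, hit_mask, weight_exponent)
    hit_steps = np.where(hit_mask, w, 0.0)
    p_hit = np.cumsum(hit_steps)
    p_hit /= p_hit[-1]
    p_miss = np.cumsum(~hit_mask) / (n - k)
    running = p_hit - p_miss
    i_max, i_min = int(np.argmax(running)), int(np.argmin(running))
    pos, neg = running[i_max], running[i_min]
    if pos == -neg and pos > 0:
        logger.info("ES extremum tie (+/-%.6g); resolved to the positive value", pos)
    es = float(pos if pos >= -neg else neg)
    return es, running, np.flatnonzero(hit_mask)


def _null_enrichment_scores(
    weights: np.ndarray, k: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized ES for ``n_perm`` uniformly drawn hit-position sets.

    Evaluates the running sum only at hit positions (its local extrema
    candidates), which reproduces the full walk's extremes exactly.
    """
    n = len(weights)
    # k positions without replacement per permutation
    pos = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k]
    pos.sort(axis=1)
    wh = weights[pos]
    cw = np.cumsum(wh, axis=1)
    total = cw[:, -1].copy()
    degenerate = total == 0.0
    if degenerate.any():
        # all-zero hit scores: unweighted steps, same fallback as observed ES
        cw[degenerate] = np.arange(1, k + 1)
        total[degenerate] = k
    miss_before = pos - np.arange(k)
    denom = n - k
    r_after = cw / total[:, None] - miss_before / denom
    r_before = (cw - wh) / total[:, None] - miss_before / denom
    if degenerate.any():
        r_before[degenerate] = (
            (cw[degenerate] - 1.0) / k - miss_before[degenerate] / denom
        )
    es_pos = r_after.max(axis=1)
    es_neg = r_before.min(axis=1)
    return np.where(es_pos >= -es_neg, es_pos, es_neg)


def gsea_test(
    ranked: RankedList,
    gene_set: GeneSet,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> GseaResult:
    """Enrichment score plus gene-label permutation p-value and NES.

    The null redraws ``n_hits`` positions uniformly without replacement,
    keeping the scores fixed.  With observed ES of sign *s*:

    ``p = (1 + #{null of sign s with |ES| >= |ES_obs|}) / (1 + #{null of sign s})``

    ``nes = ES_obs / mean(|null ES of sign s|)``.  Deterministic given
    ``seed``; ``n_perm < 100`` is rejected (p-resolution too coarse).
    """
    if n_perm < MIN_PERMUTATIONS:
        raise ValueError(
            f"n_perm={n_perm} is below the minimum of {MIN_PERMUTATIONS}"
        )
    es, running, hit_idx = enrichment_score(ranked, gene_set, weight_exponent)
    k = len(hit_idx)
    hit_mask = np.zeros(len(ranked), dtype=bool)
    hit_mask[hit_idx] = True
    weights = _hit_weights(ranked.scores, hit_mask, weight_exponent)
    rng = np.random.default_rng(seed)
    null_es = _null_enrichment_scores(weights, k, n_perm, rng)

    if es > 0:
        direction = "positive"
        same = null_es[null_es > 0]
    elif es < 0:
        direction = "negative"
        same = null_es[null_es < 0]
    else:
        direction = "zero"
        same = np.empty(0)

    if direction == "zero" or len(same) == 0:
        if direction != "zero":
            logger.warning(
                "no null enrichment score shares the observed sign (%s); "
                "NES undefined, p set to 1",
                direction,
            )
        p_value, nes = 1.0, float("nan")
    else:
        p_value = (1 + int(np.sum(np.abs(same) >= abs(es)))) / (1 + len(same))
        nes = float(es / np.mean(np.abs(same)))

    return GseaResult(
        es=float(es),
        nes=nes,
        p_value=float(p_value),
        direction=direction,
        n_permutations=n_perm,
        n_hits=k,
        hit_indices=tuple(int(i) for i in hit_idx),
        running_score=running,
    )
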