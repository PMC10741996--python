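"""Two-group differential expression between consensus clusters.

Input values are already on a log2 scale, so the log2 fold change is
simply the difference of group means (group 1 minus group 2, where group
numbering follows the consensus labels: cluster 1 is the larger one).
The default test is a moderated t-statistic with empirical-Bayes
variance shrinkage: per-gene pooled variances are shrunk toward a
scaled-inverse-chi-square prior fitted across genes by the method of
moments, which stabilises small-sample variance estimates exactly as
the classic microarray linear-model framework does.  A plain Welch test
is available as a fallback.  Significance requires both
``|log2FC| > lfc_threshold`` and a Benjamini-Hochberg adjusted p-value
below ``padj_threshold``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

logger = logging.getLogger("rfgsea")

__all__ = ["DEConfig", "differential_expression", "fit_variance_prior"]

#: degrees of freedom treated as "infinite" shrinkage (prior dominates)
_DF_CAP = 1e6


@dataclass(frozen=True)
class DEConfig:
    """Effect-size and significance filters (|log2FC| > 1, BH p-adj < 0.05
    by default) and the choice of test."""

    lfc_threshold: float = 1.0
    padj_threshold: float = 0.05
    test: str = "moderated"  # moderated | welch
    adjust: str = "fdr_bh"  # fdr_bh | bonferroni
    prior_df: float | None = None  # override the fitted prior df (moderated only)

    def __post_init__(self) -> None:
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be >= 0")
        if not 0.0 < self.padj_threshold < 1.0:
            raise ValueError("padj_threshold must be in (0, 1)")
        if self.test not in ("moderated", "welch"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.adjust not in ("fdr_bh", "bonferroni"):
            raise ValueError(f"unknown adjustment {self.adjust!r}")


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of a scaled-inverse-chi-square prior
    (``d0``, ``s0^2``) to per-gene sample variances with ``df`` degrees
    of freedom each.

    Under the prior, ``s2 ~ s0^2 * F(df, d0)``; matching the first two
    moments of ``s2`` gives ``d0``.  When the observed spread of the
    variances does not exceed what sampling alone explains, ``d0`` is
    effectively infinite (complete shrinkage to the common variance).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2)]
    if len(s2) < 2:
        return _DF_CAP, float(s2.mean()) if len(s2) else 1.0
    m = float(s2.mean())
    if m <= 0:
        return _DF_CAP, max(m, 0.0)
    u = float(s2.var(ddof=1)) / m**2
    if u * df <= 2.0:
        return _DF_CAP, m
    d0 = (2.0 * df - 4.0 + 4.0 * u * df) / (u * df - 2.0)
    d0 = min(d0, _DF_CAP)
    s0_sq = m * (d0 - 2.0) / d0 if d0 > 2.0 else m
    return float(d0), float(s0_sq)


def _resolve_groups(
    matrix: ExpressionMatrix, labels: Mapping[str, object] | Sequence[object]
) -> tuple[np.ndarray, np.ndarray, tuple[object, object]]:
    if isinstance(labels, Mapping):
        missing = [s for s in matrix.sample_ids if s not in labels]
        if missing:
            raise ValueError(f"labels missing for samples: {missing}")
        lab = np.array([labels[s] for s in matrix.sample_ids])
    else:
        lab = np.asarray(list(labels))
        if len(lab) != matrix.n_samples:
            raise ValueError(
                f"{len(lab)} labels for {matrix.n_samples} samples"
            )
    levels = sorted(set(lab.tolist()))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels}")
    g1 = lab == levels[0]
    g2 = lab == levels[1]
    if g1.sum() < 3 or g2.sum() < 3:
        raise ValueError(
            f"both groups need >= 3 samples (got {int(g1.sum())} and {int(g2.sum())})"
        )
    return g1, g2, (levels[0], levels[1])


def differential_expression(
    matrix: ExpressionMatrix,
    labels: Mapping[str, object] | Sequence[object],
    config: DEConfig | None = None,
) -> pd.DataFrame:
    """Per-gene two-group test with effect-size and BH significance filters.

    Returns a table with columns gene, log2fc, p, p_adj, significant,
    direction.  ``log2fc`` is the mean of the first label level minus the
    mean of the second (levels sorted; consensus labels put the larger
    cluster first).  Genes constant within both groups with equal means
    get p = 1 by convention.
    """
    config = config or DEConfig()
    g1, g2, levels = _resolve_groups(matrix, labels)
    X = matrix.values
    n1, n2 = int(g1.sum()), int(g2.sum())
    m1, m2 = X[:, g1].mean(axis=1), X[:, g2].mean(axis=1)
    v1 = X[:, g1].var(axis=1, ddof=1)
    v2 = X[:, g2].var(axis=1, ddof=1)
    lfc = m1 - m2

    if config.test == "welch":
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = lfc / np.sqrt(se2)
            df = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        p = 2.0 * stats.t.sf(np.abs(t), df)
    else:
        df_resid = n1 + n2 - 2
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_resid
        if config.prior_df is None:
            d0, s0_sq = fit_variance_prior(s2, df_resid)
        else:
            d0 = max(float(config.prior_df), 0.0)
            _, s0_sq = fit_variance_prior(s2, df_resid)
        if d0 >= _DF_CAP:
            s2_post = np.full_like(s2, s0_sq)
            df_total = _DF_CAP
        else:
            s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
            df_total = d0 + df_resid
        se2 = s2_post * (1.0 / n1 + 1.0 / n2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = lfc / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    # degenerate genes: no variance anywhere and no mean difference
    degenerate = (v1 == 0) & (v2 == 0) & (lfc == 0)
    p = np.where(degenerate, 1.0, p)
    p = np.where(np.isnan(p), 1.0, p)

    p_adj = multipletests(p, method=config.adjust)[1]
    significant = (np.abs(lfc) > config.lfc_threshold) & (
        p_adj < config.padj_threshold
    )
    logger.info(
        "differential expression (%s vs %s): %d/%d significant at "
        "|log2FC|>%g, p_adj<%g",
        levels[0],
        levels[1],
        int(significant.sum()),
        matrix.n_genes,
        config.lfc_threshold,
        config.padj_threshold,
    )
    return pd.DataFrame(
        {
            "gene": list(matrix.gene_ids),
            "log2fc": lfc,
            "p": p,
            "p_adj": p_adj,
            "significant": significant,
            "direction": np.where(lfc > 0, "up", "down"),
        }
    )
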