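"""Genome-wide screen: forest importance -> enrichment -> classification
-> candidate-set algebra.

Each gene in the matrix is taken in turn as the regression target; its
predictors are ranked twice (by %IncMSE and by IncNodePurity) and each
ranking is tested for enrichment of the prior set.  A gene is classified
on the %IncMSE test by enrichment sign (POSITIVE: the prior concentrates
among its most important predictors; NEGATIVE: among its least important
ones, evidence *against* membership) and flagged on the IncNodePurity
test by significance alone.  The final candidate list is the
intersection of the %IncMSE-positive set, the IncNodePurity set and the
differentially expressed genes between consensus clusters; the
%IncMSE-negative set is excluded by construction.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from joblib import Parallel, delayed
from statsmodels.stats.multitest import multipletests

from .gsea import RankedList, gsea_test
from .io import DEFAULT_MIN_OVERLAP, ExpressionMatrix, GeneSet, restrict_to_universe
from .rf import RFConfig, fit_target_model

logger = logging.getLogger("rfgsea")

__all__ = [
    "ScreenConfig",
    "GeneScreenRecord",
    "CandidateSets",
    "screen_gene",
    "screen_all",
    "assemble_candidates",
]

SCREEN_COLUMNS = [
    "gene",
    "es_mse",
    "p_mse",
    "p_mse_adj",
    "es_purity",
    "p_purity",
    "p_purity_adj",
    "mse_class",
    "purity_hit",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Screen-wide settings.

    ``alpha`` is the raw per-gene enrichment threshold (the screen
    deliberately thresholds unadjusted p-values; BH-adjusted companions
    are emitted in the output table but not acted on).
    ``split_purity_by_sign`` additionally requires positive enrichment
    for the IncNodePurity flag (off by default: only the %IncMSE set is
    split by sign).
    """

    alpha: float = 0.05
    rf: RFConfig = field(default_factory=RFConfig)
    n_perm: int = 1000
    root_seed: int = 0
    target_genes: tuple[str, ...] | None = None
    weight_exponent: float = 1.0
    min_prior_overlap: int = DEFAULT_MIN_OVERLAP
    split_purity_by_sign: bool = False
    workers: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("workers")  # parallelism must not change results
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class GeneScreenRecord:
    """Per-target outcome of the two enrichment tests."""

    gene: str
    es_mse: float
    p_mse: float
    es_purity: float
    p_purity: float
    mse_class: str  # POSITIVE | NEGATIVE | NONE
    purity_hit: bool


def _child_seeds(root_seed: int, gene: str, n: int = 3) -> list[int]:
    """Stable per-gene seeds: independent of iteration order and workers."""
    digest = hashlib.sha256(f"{root_seed}:{gene}".encode()).digest()
    return [
        int.from_bytes(digest[4 * i : 4 * i + 4], "big") % (2**31) for i in range(n)
    ]


def _classify_mse(es: float, p: float, alpha: float) -> str:
    if p < alpha and es > 0:
        return "POSITIVE"
    if p < alpha and es < 0:
        return "NEGATIVE"
    return "NONE"


def screen_gene(
    matrix: ExpressionMatrix,
    gene: str,
    prior: GeneSet,
    config: ScreenConfig | None = None,
) -> GeneScreenRecord:
    """Run the four-step screen for one target gene.

    The ranked universe is the N-1 predictor genes; the prior is
    intersected with it (the target's own prior membership is irrelevant
    because the target is absent from its own ranking).
    """
    config = config or ScreenConfig()
    seed_rf, seed_mse, seed_purity = _child_seeds(config.root_seed, gene)
    ranking = fit_target_model(matrix, gene, replace(config.rf, seed=seed_rf))
    prior_members = [g for g in prior.genes if g != gene]
    if not prior_members:
        raise ValueError(f"prior set is empty after removing target {gene!r}")
    local_prior = GeneSet(name=prior.name, genes=tuple(prior_members))

    ranked_mse = RankedList.from_scores(ranking.predictor_genes, ranking.pct_inc_mse)
    ranked_purity = RankedList.from_scores(
        ranking.predictor_genes, ranking.inc_node_purity
    )
    res_mse = gsea_test(
        ranked_mse, local_prior, config.n_perm, seed_mse, config.weight_exponent
    )
    res_purity = gsea_test(
        ranked_purity, local_prior, config.n_perm, seed_purity, config.weight_exponent
    )
    purity_hit = res_purity.p_value < config.alpha
    if config.split_purity_by_sign:
        purity_hit = purity_hit and res_purity.es > 0
    return GeneScreenRecord(
        gene=gene,
        es_mse=res_mse.es,
        p_mse=res_mse.p_value,
        es_purity=res_purity.es,
        p_purity=res_purity.p_value,
        mse_class=_classify_mse(res_mse.es, res_mse.p_value, config.alpha),
        purity_hit=purity_hit,
    )


def _records_to_frame(records: Sequence[GeneScreenRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "es_mse": [r.es_mse for r in records],
            "p_mse": [r.p_mse for r in records],
            "es_purity": [r.es_purity for r in records],
            "p_purity": [r.p_purity for r in records],
            "mse_class": [r.mse_class for r in records],
            "purity_hit": [r.purity_hit for r in records],
        }
    )
    # BH-adjusted companions are reported but the screen thresholds raw p
    for col in ("p_mse", "p_purity"):
        df[col + "_adj"] = multipletests(df[col].to_numpy(), method="fdr_bh")[1]
    return df[SCREEN_COLUMNS]


def write_screen_table(
    df: pd.DataFrame, path: str | Path, header_comment: str
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_screen_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df["purity_hit"] = df["purity_hit"].astype(bool)
    return df


def screen_all(
    matrix: ExpressionMatrix,
    prior: GeneSet,
    config: ScreenConfig | None = None,
    checkpoint: str | Path | None = None,
) -> pd.DataFrame:
    """Screen every eligible target gene; returns one row per target.

    Zero-variance targets are skipped with a logged reason.  Per-gene
    seeds derive from ``root_seed`` and the gene id, so results are
    independent of iteration order and of ``config.workers``.  With a
    ``checkpoint`` path, finished genes are streamed to disk and an
    interrupted run resumes without recomputing them (keyed on the
    config hash).
    """
    config = config or ScreenConfig()
    prior = restrict_to_universe(prior, matrix, config.min_prior_overlap)

    targets = list(config.target_genes or matrix.gene_ids)
    unknown = [g for g in targets if g not in set(matrix.gene_ids)]
    if unknown:
        raise KeyError(f"target genes not in matrix: {unknown}")
    zero_var = set(matrix.zero_variance_genes())
    eligible = []
    for g in targets:
        if g in zero_var:
            logger.warning("skipping target %s: zero variance across samples", g)
        else:
            eligible.append(g)

    done: dict[str, GeneScreenRecord] = {}
    cfg_hash = config.config_hash()
    ckpt_path = Path(checkpoint) if checkpoint else None
    if ckpt_path is not None and ckpt_path.exists():
        done = _load_checkpoint(ckpt_path, cfg_hash)
        if done:
            logger.info("resuming: %d of %d targets already done", len(done), len(eligible))

    todo = [g for g in eligible if g not in done]
    chunk = max(1, min(25, len(todo)))
    runner = Parallel(n_jobs=config.workers) if config.workers != 1 else None
    for start in range(0, len(todo), chunk):
        batch = todo[start : start + chunk]
        if runner is None:
            results = [screen_gene(matrix, g, prior, config) for g in batch]
        else:
            results = runner(
                delayed(screen_gene)(matrix, g, prior, config) for g in batch
            )
        for rec in results:
            done[rec.gene] = rec
        if ckpt_path is not None:
            _append_checkpoint(ckpt_path, cfg_hash, results)

    records = [done[g] for g in eligible]
    return _records_to_frame(records)


def _load_checkpoint(path: Path, cfg_hash: str) -> dict[str, GeneScreenRecord]:
    done: dict[str, GeneScreenRecord] = {}
    with open(path) as fh:
        header = fh.readline().strip()
        if header != f"# rfgsea-checkpoint config={cfg_hash}":
            logger.warning("checkpoint %s has a different config; ignoring it", path)
            path.unlink()
            return {}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                continue  # truncated trailing line from an interrupted run
            rec = GeneScreenRecord(
                gene=parts[0],
                es_mse=float(parts[1]),
                p_mse=float(parts[2]),
                es_purity=float(parts[3]),
                p_purity=float(parts[4]),
                mse_class=parts[5],
                purity_hit=parts[6] == "True",
            )
            done[rec.gene] = rec
    return done


def _append_checkpoint(
    path: Path, cfg_hash: str, records: Iterable[GeneScreenRecord]
) -> None:
    new = not path.exists()
    with open(path, "a") as fh:
        if new:
            fh.write(f"# rfgsea-checkpoint config={cfg_hash}\n")
        for r in records:
            fh.write(
                f"{r.gene}\t{r.es_mse:.17g}\t{r.p_mse:.17g}\t{r.es_purity:.17g}"
                f"\t{r.p_purity:.17g}\t{r.mse_class}\t{r.purity_hit}\n"
            )


@dataclass(frozen=True)
class CandidateSets:
    """Derived gene sets of the screen and their final intersection.

    ``final = mse_positive & purity & degs``; ``mse_positive`` and
    ``mse_negative`` are disjoint by the sign split, so the final list
    can never contain a negatively enriched gene.
    """

    mse_positive: frozenset[str]
    mse_negative: frozenset[str]
    purity: frozenset[str]
    degs: frozenset[str]
    final: frozenset[str]

    def __post_init__(self) -> None:
        assert not (self.mse_positive & self.mse_negative)
        assert self.final == self.mse_positive & self.purity & self.degs
        assert not (self.final & self.mse_negative)

    def summary(self) -> pd.DataFrame:
        """Venn-style count summary of the derived sets."""
        rows = [
            ("mse_positive", len(self.mse_positive)),
            ("mse_negative", len(self.mse_negative)),
            ("purity", len(self.purity)),
            ("degs", len(self.degs)),
            ("mse_positive&purity", len(self.mse_positive & self.purity)),
            ("mse_positive&degs", len(self.mse_positive & self.degs)),
            ("purity&degs", len(self.purity & self.degs)),
            ("mse_negative&purity", len(self.mse_negative & self.purity)),
            ("mse_negative&degs", len(self.mse_negative & self.degs)),
            ("final", len(self.final)),
        ]
        return pd.DataFrame(rows, columns=["set", "n_genes"])


def assemble_candidates(
    records: pd.DataFrame | Sequence[GeneScreenRecord],
    degs: Iterable[str],
) -> CandidateSets:
    """Set algebra over screen records and differentially expressed genes.

    The final candidate list is the three-way intersection of the
    %IncMSE-positive set, the IncNodePurity set and the DEGs.
    """
    if not isinstance(records, pd.DataFrame):
        records = _records_to_frame(list(records))
    genes = records["gene"].astype(str)
    mse_positive = frozenset(genes[records["mse_class"] == "POSITIVE"])
    mse_negative = frozenset(genes[records["mse_class"] == "NEGATIVE"])
    purity = frozenset(genes[records["purity_hit"].astype(bool)])
    degs = frozenset(str(g) for g in degs)
    final = mse_positive & purity & degs
    sets = CandidateSets(
        mse_positive=mse_positive,
        mse_negative=mse_negative,
        purity=purity,
        degs=degs,
        final=final,
    )
    logger.info(
        "candidate sets: %s",
        "; ".join(f"{r.set}={r.n_genes}" for r in sets.summary().itertuples()),
    )
    return sets
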