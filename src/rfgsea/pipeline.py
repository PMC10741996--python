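"""End-to-end orchestration and benchmark reporting.

``run_all`` composes the stages in the order the screen defines them:
consensus clustering of samples on the prior-gene features, differential
expression between the two clusters, the genome-wide importance +
enrichment screen, and the candidate-set intersection.  Every stage
writes its table under the output directory and the run is summarised in
a JSON manifest (tool version, config hash, input digests, per-stage
wall times, seeds, output paths).  Re-running with unchanged inputs
reuses the screen checkpoint.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .cluster import ConsensusConfig, consensus_cluster
from .de import DEConfig, differential_expression
from .io import ExpressionMatrix, GeneSet, restrict_to_universe
from .screen import (
    CandidateSets,
    ScreenConfig,
    assemble_candidates,
    screen_all,
    write_screen_table,
)
from .simulate import SimulatedStudy

logger = logging.getLogger("rfgsea")

__all__ = ["RunConfig", "RunManifest", "run_all", "benchmark_report"]


@dataclass(frozen=True)
class RunConfig:
    """Joint configuration of all stages.

    ``k`` fixes the number of sample clusters for the DE stage; ``None``
    defers to the CDF/delta-area choice (advisory — the DE stage needs
    exactly two clusters, so a different chosen k is an error the user
    resolves by passing ``k`` explicitly).
    """

    screen: ScreenConfig = field(default_factory=ScreenConfig)
    cluster: ConsensusConfig = field(default_factory=ConsensusConfig)
    de: DEConfig = field(default_factory=DEConfig)
    k: int | None = 2

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class RunManifest:
    version: str
    config_hash: str
    input_digests: dict[str, str]
    seeds: dict[str, int]
    stage_seconds: dict[str, float]
    outputs: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _digest_matrix(matrix: ExpressionMatrix) -> str:
    h = hashlib.sha256()
    h.update("\x1f".join(matrix.gene_ids).encode())
    h.update("\x1f".join(matrix.sample_ids).encode())
    h.update(np.ascontiguousarray(matrix.values).tobytes())
    return h.hexdigest()[:16]


def _digest_gene_set(gene_set: GeneSet) -> str:
    h = hashlib.sha256()
    h.update(gene_set.name.encode())
    h.update("\x1f".join(gene_set.genes).encode())
    return h.hexdigest()[:16]


def run_all(
    matrix: ExpressionMatrix,
    prior: GeneSet,
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> RunManifest:
    """Cluster -> differential expression -> screen -> assemble.

    Writes labels.tsv, degs.tsv, screen.tsv, candidate gene lists and a
    Venn-count summary plus manifest.json under ``out_dir``.  A stage
    failure aborts with the stage name after persisting the
    manifest-so-far.
    """
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    manifest_path = out / "manifest.json"
    digests = {"expression": _digest_matrix(matrix), "prior": _digest_gene_set(prior)}
    seeds = {
        "screen_root_seed": config.screen.root_seed,
        "cluster_seed": config.cluster.seed,
    }
    times: dict[str, float] = {}
    outputs: dict[str, str] = {}

    def _persist() -> RunManifest:
        manifest = RunManifest(
            version=__version__,
            config_hash=cfg_hash,
            input_digests=digests,
            seeds=seeds,
            stage_seconds={k: round(v, 3) for k, v in times.items()},
            outputs=outputs,
        )
        manifest_path.write_text(manifest.to_json() + "\n")
        return manifest

    stage = "cluster"
    try:
        t0 = time.perf_counter()
        prior_in_universe = restrict_to_universe(
            prior, matrix, config.screen.min_prior_overlap
        )
        clustering = consensus_cluster(
            matrix, list(prior_in_universe.genes), config.cluster
        )
        k = config.k if config.k is not None else clustering.chosen_k
        if k not in clustering.labels:
            raise ValueError(
                f"k={k} not in the evaluated range {sorted(clustering.labels)}"
            )
        labels = clustering.labels[k]
        labels_path = out / "labels.tsv"
        with open(labels_path, "w") as fh:
            fh.write(f"# rfgsea v{__version__} config={cfg_hash} chosen_k={k}\n")
            fh.write("sample\tcluster\n")
            for s, c in zip(matrix.sample_ids, labels):
                fh.write(f"{s}\t{c}\n")
        kcurve_path = out / "k_selection.tsv"
        with open(kcurve_path, "w") as fh:
            fh.write(f"# rfgsea v{__version__} config={cfg_hash}\n")
            fh.write("k\tcdf_area\tdelta_area\n")
            for kk in sorted(clustering.cdf_areas):
                fh.write(
                    f"{kk}\t{clustering.cdf_areas[kk]:.6g}"
                    f"\t{clustering.delta_areas[kk]:.6g}\n"
                )
        outputs["labels"] = str(labels_path)
        outputs["k_selection"] = str(kcurve_path)
        times["cluster"] = time.perf_counter() - t0

        stage = "diffexp"
        t0 = time.perf_counter()
        de_table = differential_expression(matrix, labels, config.de)
        degs = de_table.loc[de_table["significant"], "gene"].tolist()
        degs_path = out / "degs.tsv"
        with open(degs_path, "w") as fh:
            fh.write(
                f"# rfgsea v{__version__} config={cfg_hash} "
                "log2fc=cluster1-cluster2\n"
            )
            de_table.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        deg_list_path = out / "degs.txt"
        deg_list_path.write_text("".join(g + "\n" for g in degs))
        outputs["degs"] = str(degs_path)
        outputs["deg_list"] = str(deg_list_path)
        times["diffexp"] = time.perf_counter() - t0

        stage = "screen"
        t0 = time.perf_counter()
        screen_path = out / "screen.tsv"
        records = screen_all(
            matrix, prior, config.screen, checkpoint=out / "screen.checkpoint.tsv"
        )
        write_screen_table(
            records, screen_path, f"rfgsea v{__version__} config={cfg_hash}"
        )
        outputs["screen"] = str(screen_path)
        times["screen"] = time.perf_counter() - t0

        stage = "assemble"
        t0 = time.perf_counter()
        sets = assemble_candidates(records, degs)
        cand_dir = out / "candidates"
        cand_dir.mkdir(exist_ok=True)
        for name in ("mse_positive", "mse_negative", "purity", "degs", "final"):
            p = cand_dir / f"{name}.txt"
            p.write_text("".join(g + "\n" for g in sorted(getattr(sets, name))))
            outputs[f"candidates_{name}"] = str(p)
        venn_path = cand_dir / "venn_counts.tsv"
        with open(venn_path, "w") as fh:
            fh.write(f"# rfgsea v{__version__} config={cfg_hash}\n")
            sets.summary().to_csv(fh, sep="\t", index=False)
        outputs["venn_counts"] = str(venn_path)
        times["assemble"] = time.perf_counter() - t0
    except Exception:
        logger.exception("stage %r failed; manifest-so-far persisted", stage)
        _persist()
        raise

    manifest = _persist()
    missing = [p for p in outputs.values() if not Path(p).exists()]
    assert not missing, f"manifest lists missing outputs: {missing}"
    return manifest


# ---------------------------------------------------------------------------
# benchmarking against simulated ground truth


def _clopper_pearson(successes: int, trials: int, level: float = 0.95):
    """Exact binomial confidence interval."""
    if trials == 0:
        return float("nan"), float("nan")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2, successes, trials - successes + 1)
    )
    hi = 1.0 if successes == trials else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes)
    )
    return lo, hi


def benchmark_report(
    runs: Sequence[tuple[SimulatedStudy, CandidateSets]],
) -> tuple[pd.DataFrame, str]:
    """Sensitivity / specificity summary of completed simulated runs.

    For each run with a planted module: sensitivity = recovered module
    genes / module size and decoy rejection = rejected decoys / decoys.
    Null runs (no module) contribute the empirical screen-wide type-I
    rate |final| / n_genes.  Aggregates carry exact binomial 95%
    confidence intervals.  Raises if no run is provided.
    """
    if not runs:
        raise ValueError("benchmark_report needs at least one completed run")
    rows = []
    for i, (study, sets) in enumerate(runs):
        module = study.module_genes
        decoys = study.decoy_genes
        is_null = len(module) == 0
        rows.append(
            {
                "run": i,
                "kind": "null" if is_null else "planted",
                "n_genes": study.matrix.n_genes,
                "module_size": len(module),
                "n_final": len(sets.final),
                "module_recovered": len(sets.final & module),
                "decoys_in_final": len(sets.final & decoys),
                "n_decoys": len(decoys),
                "sensitivity": (
                    len(sets.final & module) / len(module) if module else float("nan")
                ),
                "decoy_rejection": (
                    1.0 - len(sets.final & decoys) / len(decoys)
                    if decoys
                    else float("nan")
                ),
                "final_fraction": len(sets.final) / study.matrix.n_genes,
            }
        )
    df = pd.DataFrame(rows)
    lines = [f"benchmark over {len(df)} runs"]
    planted = df[df["kind"] == "planted"]
    if len(planted):
        rec = int(planted["module_recovered"].sum())
        tot = int(planted["module_size"].sum())
        lo, hi = _clopper_pearson(rec, tot)
        lines.append(
            f"planted runs: {len(planted)}; aggregate sensitivity "
            f"{rec}/{tot} = {rec / tot:.3f} (95% CI {lo:.3f}-{hi:.3f})"
        )
        drej = int(planted["n_decoys"].sum() - planted["decoys_in_final"].sum())
        dtot = int(planted["n_decoys"].sum())
        lo, hi = _clopper_pearson(drej, dtot)
        lines.append(
            f"aggregate decoy rejection {drej}/{dtot} = {drej / dtot:.3f} "
            f"(95% CI {lo:.3f}-{hi:.3f})"
        )
    nulls = df[df["kind"] == "null"]
    if len(nulls):
        hits = int(nulls["n_final"].sum())
        tot = int(nulls["n_genes"].sum())
        lo, hi = _clopper_pearson(hits, tot)
        lines.append(
            f"null runs: {len(nulls)}; empirical type-I {hits}/{tot} = "
            f"{hits / tot:.4f} (95% CI {lo:.4f}-{hi:.4f})"
        )
    return df, "\n".join(lines)
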