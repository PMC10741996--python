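"""Synthetic expression studies with a planted co-regulated module.

The screen's premise is that genes participating in one biological
process predict each other within the regulatory network.  The minimal
structure with that property is a single latent factor: module genes are
noisy linear readouts of a shared per-sample factor ``z`` while
background genes are independent noise.  The prior set overlaps the
module imperfectly (true members plus background decoys with mimicked
confidence tiers), and an optional mean shift of the latent factor in
half the samples gives the clustering and differential-expression
stages real signal.  Every generated study carries its ground truth, so
power and error of the full screen are measurable without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .io import ExpressionMatrix, GeneSet, write_expression

__all__ = [
    "SimulationParams",
    "SimulatedStudy",
    "simulate_study",
    "simulate_null_study",
    "write_study",
]

_TIER_CYCLE = ("validated", "screened", "deduced")


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings.

    ``beta_range`` bounds the module loadings on the latent factor;
    module-gene residual noise has standard deviation ``0.5 * noise_sd``
    so module and background genes have comparable marginal variances
    (the forest cannot find the module by variance alone).
    ``group_shift`` moves the latent-factor mean of the second half of
    the samples (0 disables group structure).
    """

    n_genes: int = 200
    n_samples: int = 120
    module_size: int = 30
    prior_true: int = 20
    prior_decoys: int = 10
    beta_range: tuple[float, float] = (0.6, 1.2)
    noise_sd: float = 1.0
    group_shift: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.module_size < self.n_genes:
            raise ValueError("module_size must satisfy 0 <= module_size < n_genes")
        if self.prior_true > self.module_size:
            raise ValueError("prior_true cannot exceed module_size")
        if self.prior_true + self.prior_decoys < 5:
            raise ValueError("prior must hold at least 5 genes")
        if self.prior_decoys > self.n_genes - self.module_size:
            raise ValueError("not enough background genes for the decoys")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.beta_range[0] > self.beta_range[1]:
            raise ValueError("beta_range must be (low, high) with low <= high")
        if self.n_genes < 3 or self.n_samples < 3:
            raise ValueError("need at least 3 genes and 3 samples")


@dataclass(frozen=True)
class SimulatedStudy:
    """A generated matrix plus its ground truth."""

    matrix: ExpressionMatrix
    module_genes: frozenset[str]
    prior: GeneSet
    group_labels: tuple[int, ...]
    params: SimulationParams

    @property
    def background_genes(self) -> frozenset[str]:
        return frozenset(self.matrix.gene_ids) - self.module_genes

    @property
    def decoy_genes(self) -> frozenset[str]:
        return frozenset(self.prior.genes) - self.module_genes


def simulate_study(params: SimulationParams | None = None) -> SimulatedStudy:
    """Draw one study from the latent-factor model; reproducible from
    ``params.seed``.

    Per sample ``s``: ``z_s ~ N(mu, 1)`` with ``mu = 0`` (group 1) or
    ``group_shift`` (group 2, second half of samples).  Module gene g:
    ``x_gs = beta_g * z_s + eps``, ``beta_g ~ U(beta_range)``,
    ``eps ~ N(0, 0.5 * noise_sd)``; background gene:
    ``x_gs ~ N(0, noise_sd)`` independently.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)
    n_g, n_s = params.n_genes, params.n_samples

    width = len(str(n_g))
    gene_ids = tuple(f"G{i + 1:0{width}d}" for i in range(n_g))
    sample_ids = tuple(f"S{j + 1:0{len(str(n_s))}d}" for j in range(n_s))

    n_group1 = (n_s + 1) // 2
    groups = np.array([1] * n_group1 + [2] * (n_s - n_group1))
    mu = np.where(groups == 1, 0.0, params.group_shift)
    z = rng.normal(mu, 1.0)

    module_idx = np.sort(rng.choice(n_g, size=params.module_size, replace=False))
    module_set = set(module_idx.tolist())
    background_idx = np.array([i for i in range(n_g) if i not in module_set])

    values = rng.normal(0.0, params.noise_sd, size=(n_g, n_s))
    if params.module_size:
        betas = rng.uniform(*params.beta_range, size=params.module_size)
        eps = rng.normal(0.0, 0.5 * params.noise_sd, size=(params.module_size, n_s))
        values[module_idx] = betas[:, None] * z[None, :] + eps

    true_prior_idx = np.sort(
        rng.choice(module_idx, size=params.prior_true, replace=False)
    ) if params.prior_true else np.array([], dtype=int)
    decoy_idx = np.sort(
        rng.choice(background_idx, size=params.prior_decoys, replace=False)
    ) if params.prior_decoys else np.array([], dtype=int)
    prior_genes = tuple(
        gene_ids[i] for i in np.concatenate([true_prior_idx, decoy_idx])
    )
    tiers = {g: _TIER_CYCLE[i % 3] for i, g in enumerate(prior_genes)}

    matrix = ExpressionMatrix(gene_ids, sample_ids, values)
    prior = GeneSet(name="sim_prior", genes=prior_genes, tiers=tiers,
                    description="simulated prior with decoys")
    return SimulatedStudy(
        matrix=matrix,
        module_genes=frozenset(gene_ids[i] for i in module_idx),
        prior=prior,
        group_labels=tuple(int(g) for g in groups),
        params=params,
    )


def simulate_null_study(params: SimulationParams | None = None) -> SimulatedStudy:
    """Study with no planted module: all genes independent background.

    The prior (same total size) is drawn entirely from background genes,
    so the type-I behaviour of the full screen is measurable.
    """
    params = params or SimulationParams()
    null_params = replace(
        params,
        module_size=0,
        prior_true=0,
        prior_decoys=params.prior_true + params.prior_decoys,
    )
    study = simulate_study(null_params)
    # keep the caller's requested params on record, with the null override
    return replace(study, params=null_params)


def write_study(study: SimulatedStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write expr.tsv, prior.gmt, truth.tsv and labels.tsv to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expr": out / "expr.tsv",
        "prior": out / "prior.gmt",
        "truth": out / "truth.tsv",
        "labels": out / "labels.tsv",
    }
    write_expression(study.matrix, paths["expr"])
    with open(paths["prior"], "w") as fh:
        fh.write(
            study.prior.name
            + "\t"
            + study.prior.description
            + "\t"
            + "\t".join(study.prior.genes)
            + "\n"
        )
    tiers = study.prior.tiers or {}
    with open(paths["truth"], "w") as fh:
        fh.write("gene\tis_module\tin_prior\ttier\n")
        prior_set = set(study.prior.genes)
        for g in study.matrix.gene_ids:
            fh.write(
                f"{g}\t{int(g in study.module_genes)}\t{int(g in prior_set)}"
                f"\t{tiers.get(g, '')}\n"
            )
    with open(paths["labels"], "w") as fh:
        fh.write("sample\tgroup\n")
        for s, g in zip(study.matrix.sample_ids, study.group_labels):
            fh.write(f"{s}\t{g}\n")
    return paths
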