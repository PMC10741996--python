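"""Expression-matrix and gene-set input/output.

The screening method operates on a gene x sample matrix of log-scale
expression values (``log2(TPM + 1)`` for RNA-seq) together with a prior
gene set describing the biological process of interest.  Everything
downstream assumes the invariants enforced here: unique non-empty gene and
sample identifiers, finite numeric values, and at least three genes and
three samples (a regression forest with fewer than two predictors or a
ranked list of fewer than two genes is meaningless).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("rfgsea")

VALID_TIERS = frozenset({"validated", "screened", "deduced"})

#: minimum prior-set overlap with the expression universe below which
#: enrichment is considered undefined
DEFAULT_MIN_OVERLAP = 5


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample matrix of finite, log-scale expression values.

    ``gene_ids`` index the rows and ``sample_ids`` the columns of
    ``values``.  Both identifier lists are unique and non-empty, and the
    matrix has at least 3 genes and 3 samples.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        _check_ids(self.gene_ids, "gene")
        _check_ids(self.sample_ids, "sample")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value array of shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.gene_ids) < 3 or len(self.sample_ids) < 3:
            raise ValueError(
                "expression matrix must have at least 3 genes and 3 samples; "
                f"got {len(self.gene_ids)} x {len(self.sample_ids)}"
            )
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{self.gene_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index(gene)]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Row-subset preserving the requested order."""
        idx = [self.gene_index(g) for g in genes]
        return ExpressionMatrix(tuple(genes), self.sample_ids, self.values[idx])

    def zero_variance_genes(self) -> tuple[str, ...]:
        """Genes constant across samples; excluded as regression targets."""
        sd = self.values.std(axis=1)
        return tuple(g for g, s in zip(self.gene_ids, sd) if s == 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class GeneSet:
    """Named prior gene list with optional per-gene confidence tiers."""

    name: str
    genes: tuple[str, ...]
    tiers: Mapping[str, str] | None = None
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate genes")
        if any(not g for g in self.genes):
            raise ValueError(f"gene set {self.name!r} contains an empty gene id")
        if self.tiers is not None:
            members = set(self.genes)
            for g, tier in self.tiers.items():
                if g not in members:
                    raise ValueError(
                        f"tier assigned to {g!r}, which is not in set {self.name!r}"
                    )
                if tier not in VALID_TIERS:
                    raise ValueError(
                        f"unknown tier {tier!r} for gene {g!r}; "
                        f"expected one of {sorted(VALID_TIERS)}"
                    )

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


def _check_ids(ids: Sequence[str], kind: str) -> None:
    if any(not isinstance(i, str) or i == "" for i in ids):
        raise ValueError(f"empty or non-string {kind} identifier")
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} identifier {i!r}")
        seen.add(i)


# ---------------------------------------------------------------------------
# expression I/O


def read_expression(
    path: str | Path,
    delimiter: str = "\t",
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read a delimited expression table into an :class:`ExpressionMatrix`.

    The first column holds gene identifiers and the header row sample
    identifiers (``transpose=True`` for sample-major files).  Gzip
    compression is detected from the filename.  Duplicate gene ids,
    non-numeric cells and undersized matrices are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path,
        sep=delimiter,
        index_col=0,
        comment="#",
        float_precision="round_trip",
        na_filter=False,
    )
    if transpose:
        df = df.T
    ids = [str(i) for i in df.index]
    dup = pd.Index(ids).duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate gene id {ids[int(np.argmax(dup))]!r} in {path.name}"
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy() | ~np.isfinite(
        numeric.to_numpy(dtype=float, na_value=np.nan)
    )
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric cell {df.iat[i, j]!r} at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r} in {path.name}"
        )
    # numeric columns pass through read_csv's exact parser untouched;
    # apply/to_numeric only re-parses cells read as strings
    return ExpressionMatrix(
        tuple(ids), tuple(str(c) for c in df.columns), numeric.to_numpy(float)
    )


def write_expression(
    matrix: ExpressionMatrix,
    path: str | Path,
    delimiter: str = "\t",
    header_comment: str | None = None,
) -> None:
    """Write a matrix as delimited text (17 significant digits: lossless)."""
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("gene" + delimiter + delimiter.join(matrix.sample_ids) + "\n")
        for gene, row in zip(matrix.gene_ids, matrix.values):
            fh.write(
                gene + delimiter + delimiter.join(f"{v:.17g}" for v in row) + "\n"
            )


def log2_tpm_transform(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Apply ``log2(x + 1)`` to a matrix of non-negative TPM values.

    Negative inputs are a hard error: they indicate data that is already
    on a log scale and must not be transformed twice.
    """
    if np.any(raw.values < 0):
        i, j = np.argwhere(raw.values < 0)[0]
        raise ValueError(
            "negative value at gene "
            f"{raw.gene_ids[i]!r}, sample {raw.sample_ids[j]!r}: input to the "
            "log2(TPM+1) transform must be non-negative (already-logged data?)"
        )
    return ExpressionMatrix(raw.gene_ids, raw.sample_ids, np.log2(raw.values + 1.0))


# ---------------------------------------------------------------------------
# gene-set I/O


def read_gene_set(path: str | Path, set_name: str | None = None) -> GeneSet:
    """Read one gene set from a GMT file (name TAB description TAB gene...).

    With ``set_name=None`` the first set in the file is returned.  Duplicate
    genes within a line are collapsed with a logged warning; a line with no
    genes is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    names_seen = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            name = fields[0]
            names_seen.append(name)
            if set_name is not None and name != set_name:
                continue
            if len(fields) < 3:
                raise ValueError(
                    f"gene set line {name!r} in {path.name} has no genes"
                )
            description = fields[1]
            genes: list[str] = []
            seen: set[str] = set()
            n_dups = 0
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    n_dups += 1
                    continue
                seen.add(g)
                genes.append(g)
            if n_dups:
                logger.warning(
                    "gene set %s: collapsed %d duplicate gene entries", name, n_dups
                )
            if not genes:
                raise ValueError(
                    f"gene set line {name!r} in {path.name} has no genes"
                )
            return GeneSet(name=name, genes=tuple(genes), description=description)
    if set_name is not None:
        raise KeyError(
            f"gene set {set_name!r} not found in {path.name}; "
            f"available: {names_seen}"
        )
    raise ValueError(f"no gene sets found in {path.name}")


def read_tiers(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (gene, tier) of confidence tiers."""
    tiers: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            gene, tier = line.split("\t")[:2]
            tiers[gene] = tier
    return tiers


def with_tiers(gene_set: GeneSet, tiers: Mapping[str, str]) -> GeneSet:
    """Attach confidence tiers (restricted to set members) to a gene set."""
    members = set(gene_set.genes)
    return GeneSet(
        name=gene_set.name,
        genes=gene_set.genes,
        tiers={g: t for g, t in tiers.items() if g in members},
        description=gene_set.description,
    )


def load_packaged_prior() -> GeneSet:
    """Load the packaged disulfidptosis prior gene set.

    This is a synthetic stand-in assembled from published
    disulfidptosis / actin-cytoskeleton / NADPH-metabolism gene symbols;
    it mirrors the size (84 genes) and three-tier confidence structure
    (validated / screened / deduced) of the FerrDb disulfidptosis list,
    but is not that database's exact list.
    """
    data = resources.files("rfgsea") / "data"
    with resources.as_file(data / "disulfidptosis_prior_synthetic.gmt") as p:
        gs = read_gene_set(p)
    with resources.as_file(data / "disulfidptosis_prior_synthetic_tiers.tsv") as p:
        tiers = read_tiers(p)
    return with_tiers(gs, tiers)


def restrict_to_universe(
    gene_set: GeneSet,
    matrix: ExpressionMatrix,
    min_size: int = DEFAULT_MIN_OVERLAP,
) -> GeneSet:
    """Intersect a gene set with the genes present in the matrix.

    Enrichment is only defined over genes present in the ranking, so the
    prior is restricted to the expression universe before any test.  An
    intersection smaller than ``min_size`` is an error.
    """
    universe = set(matrix.gene_ids)
    kept = tuple(g for g in gene_set.genes if g in universe)
    dropped = [g for g in gene_set.genes if g not in universe]
    if dropped:
        logger.info(
            "gene set %s: dropped %d genes absent from the matrix: %s",
            gene_set.name,
            len(dropped),
            ", ".join(dropped),
        )
    if len(kept) < min_size:
        raise ValueError(
            f"gene set {gene_set.name!r} retains only {len(kept)} of "
            f"{len(gene_set.genes)} genes in the expression universe "
            f"(minimum {min_size}); enrichment is undefined"
        )
    tiers = None
    if gene_set.tiers is not None:
        tiers = {g: t for g, t in gene_set.tiers.items() if g in kept}
    return GeneSet(
        name=gene_set.name, genes=kept, tiers=tiers, description=gene_set.description
    )
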