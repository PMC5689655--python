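"""In-memory containers shared across the pipeline.

Genotypes are additive alt-allele dosages (real values in [0, 2], one
column per variant), expression is a continuous, normalized, log-scale
matrix (one column per gene), and covariates are per-sample adjustment
variables (technical covariates plus expression principal components).
Sample order is the alignment contract: every container carries its own
ordered sample list, and :func:`check_aligned` enforces identity before
any cross-container computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "ExpressionMatrix",
    "CovariateSet",
    "check_aligned",
]

#: columns required in a variant annotation table
VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt")
#: columns required in a gene annotation table
GENE_COLUMNS = ("chrom", "start", "end")


def _as_str_list(samples) -> list[str]:
    return [str(s) for s in samples]


@dataclass
class GenotypeMatrix:
    """Sample x variant additive dosage matrix with variant coordinates.

    Parameters
    ----------
    samples
        Ordered sample identifiers (length n).
    variants
        DataFrame indexed by variant id with columns ``chrom`` (str),
        ``pos`` (1-based int), ``ref``, ``alt`` and optionally ``maf``.
    dosage
        ``(n_samples, n_variants)`` float array, values in [0, 2].
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.samples = _as_str_list(self.samples)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if np.isnan(self.dosage).any():
            raise ValueError("missing dosages are not allowed after load")
        if self.dosage.size and (self.dosage.min() < 0 or self.dosage.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        if not self.variants.index.is_unique:
            dup = self.variants.index[self.variants.index.duplicated()][0]
            raise ValueError(f"duplicate variant id: {dup!r}")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table lacks columns: {missing}")
        pos = self.variants["pos"]
        if len(pos) and (pos <= 0).any():
            bad = self.variants.index[pos <= 0][0]
            raise ValueError(f"variant {bad!r} has non-positive position")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants.index)

    def dosage_of(self, variant_id: str) -> np.ndarray:
        """Dosage vector (length n_samples) for one variant."""
        j = self.variants.index.get_loc(variant_id)
        return self.dosage[:, j]


@dataclass
class ExpressionMatrix:
    """Sample x gene expression matrix with gene coordinates.

    ``genes`` is indexed by gene id with columns ``chrom``, ``start``,
    ``end`` (1-based inclusive). Values are continuous on a normalized
    log-like scale; missing values are an error (matrices are assumed
    post-QC complete).
    """

    samples: list[str]
    genes: pd.DataFrame
    values: np.ndarray

    def __post_init__(self) -> None:
        self.samples = _as_str_list(self.samples)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.genes)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.genes)} genes"
            )
        if np.isnan(self.values).any():
            raise ValueError("missing expression values are not allowed")
        if not self.genes.index.is_unique:
            dup = self.genes.index[self.genes.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        missing = [c for c in GENE_COLUMNS if c not in self.genes.columns]
        if missing:
            raise ValueError(f"gene table lacks columns: {missing}")
        if len(self.genes) and (self.genes["start"] > self.genes["end"]).any():
            bad = self.genes.index[self.genes["start"] > self.genes["end"]][0]
            raise ValueError(f"gene {bad!r} has start > end")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes.index)

    def expression_of(self, gene_id: str) -> np.ndarray:
        j = self.genes.index.get_loc(gene_id)
        return self.values[:, j]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        idx = [self.genes.index.get_loc(g) for g in gene_ids]
        return ExpressionMatrix(
            samples=list(self.samples),
            genes=self.genes.loc[list(gene_ids)].copy(),
            values=self.values[:, idx].copy(),
        )


@dataclass
class CovariateSet:
    """Named per-sample adjustment variables.

    ``data`` is a DataFrame with one row per sample (in sample order) and
    one named column per covariate. An intercept is never stored; model
    code adds it.
    """

    samples: list[str]
    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.samples = _as_str_list(self.samples)
        if self.data.empty and len(self.data.columns) == 0:
            self.data = pd.DataFrame(index=range(len(self.samples)))
        if len(self.data) != len(self.samples):
            raise ValueError(
                f"covariate rows ({len(self.data)}) != samples ({len(self.samples)})"
            )

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    def matrix(self) -> np.ndarray:
        """Covariates as an (n_samples, k) float array (no intercept)."""
        if not self.data.columns.size:
            return np.empty((len(self.samples), 0))
        return self.data.to_numpy(dtype=float)

    def check_full_rank(self) -> None:
        """Raise if [1 | covariates] is column-rank deficient, naming a culprit.

        Columns are checked incrementally so the first column that adds no
        rank is reported.
        """
        n = len(self.samples)
        design = np.ones((n, 1))
        rank = 1
        for name in self.data.columns:
            cand = np.column_stack([design, self.data[name].to_numpy(dtype=float)])
            cand_rank = np.linalg.matrix_rank(cand)
            if cand_rank == rank:
                raise ValueError(
                    f"covariate {name!r} is collinear with the preceding design"
                )
            design, rank = cand, cand_rank

    def merged(self, other: "CovariateSet") -> "CovariateSet":
        """Column-bind two covariate sets over the same samples."""
        if self.samples != other.samples:
            raise ValueError("covariate sets have different sample orders")
        clash = set(self.data.columns) & set(other.data.columns)
        if clash:
            raise ValueError(f"duplicate covariate names: {sorted(clash)}")
        merged = pd.concat(
            [self.data.reset_index(drop=True), other.data.reset_index(drop=True)],
            axis=1,
        )
        return CovariateSet(samples=list(self.samples), data=merged)


def check_aligned(*objs) -> list[str]:
    """Assert identical sample order across containers; return the samples."""
    samples = None
    for o in objs:
        if o is None:
            continue
        s = o.samples
        if samples is None:
            samples = list(s)
        elif list(s) != samples:
            raise ValueError(
                f"sample order mismatch between inputs ({type(o).__name__})"
            )
    if samples is None:
        raise ValueError("no inputs given")
    return samples
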