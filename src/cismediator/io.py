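"""Readers and writers for the pipeline's plain-text formats.

Conventions (all tab-separated, ``#``-prefixed comment headers allowed):

* expression TSV — rows are genes, first column ``gene_id``, remaining
  columns one per sample;
* dosage TSV — rows are variants, first column ``variant_id``, remaining
  columns one per sample;
* gene annotation — ``gene_id  chrom  start  end`` (1-based inclusive);
* variant annotation — ``variant_id  chrom  pos  ref  alt``;
* truth record — ``key=value`` lines for test harnesses.

VCF input is read through cyvcf2; per-sample dosage comes from the DS
FORMAT field when present, otherwise from the GT alt-allele count.
Missing dosages are mean-imputed at load (with a logged count); missing
expression values are an error.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_variant_annotation",
    "write_variant_annotation",
    "read_vcf_dosages",
    "write_truth_record",
    "read_truth_record",
    "FLOAT_FORMAT",
]

#: fixed float format so identical runs produce byte-identical files
FLOAT_FORMAT = "%.10g"


def _mean_impute(mat: np.ndarray, axis_name: str) -> np.ndarray:
    n_missing = int(np.isnan(mat).sum())
    if n_missing:
        logger.warning("mean-imputing %d missing %s values", n_missing, axis_name)
        col_mean = np.nanmean(mat, axis=0)
        idx = np.where(np.isnan(mat))
        mat[idx] = col_mean[idx[1]]
    return mat


def write_expression_tsv(expression: ExpressionMatrix, path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df = pd.DataFrame(
            expression.values.T, index=expression.genes.index, columns=expression.samples
        )
        df.index.name = "gene_id"
        df.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT)


def read_expression_tsv(path, gene_annotation: pd.DataFrame) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    values = df.to_numpy(dtype=float).T
    if np.isnan(values).any():
        raise ValueError("expression matrix contains missing values")
    genes = gene_annotation.loc[df.index]
    return ExpressionMatrix(samples=list(df.columns), genes=genes, values=values)


def write_dosage_tsv(genotypes: GenotypeMatrix, path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df = pd.DataFrame(
            genotypes.dosage.T, index=genotypes.variants.index, columns=genotypes.samples
        )
        df.index.name = "variant_id"
        df.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT)


def read_dosage_tsv(path, variant_annotation: pd.DataFrame) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    dosage = _mean_impute(df.to_numpy(dtype=float).T, "dosage")
    variants = variant_annotation.loc[df.index]
    return GenotypeMatrix(samples=list(df.columns), variants=variants, dosage=dosage)


def write_gene_annotation(genes: pd.DataFrame, path) -> None:
    out = genes[["chrom", "start", "end"]].copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_gene_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype={"chrom": str})
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_variant_annotation(variants: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "pos", "ref", "alt", "maf") if c in variants.columns]
    out = variants[cols].copy()
    out.index.name = "variant_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_variant_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype={"chrom": str})
    df["pos"] = df["pos"].astype(int)
    return df


def read_vcf_dosages(path) -> GenotypeMatrix:
    """Load a VCF into a GenotypeMatrix (DS field preferred, else GT)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    for i, rec in enumerate(vcf):
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        ids.append(vid)
        chroms.append(str(rec.CHROM).removeprefix("chr"))
        poss.append(int(rec.POS))
        refs.append(rec.REF)
        alts.append(rec.ALT[0] if rec.ALT else ".")
        ds = None
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            row = np.asarray(ds, dtype=float).reshape(-1)
        else:
            # gt_types: 0=hom-ref, 1=het, 2=hom-alt (cyvcf2 with gts012=False
            # uses 3 for hom-alt; use genotype arrays instead for robustness)
            gts = rec.genotype.array()
            alleles = gts[:, :2].astype(float)
            alleles[alleles < 0] = np.nan  # missing calls
            row = np.nansum(np.where(np.isnan(alleles), np.nan, alleles > 0), axis=1)
            row = np.where(np.isnan(alleles).all(axis=1), np.nan, row)
        rows.append(row)
    dosage = _mean_impute(np.array(rows, dtype=float).T, "dosage")
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts},
        index=pd.Index(ids, name="variant_id"),
    )
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


def write_truth_record(truth: dict, path) -> None:
    """Serialize a generator truth record as key=value text (no arrays)."""
    with open(path, "w") as fh:
        for key, val in truth.items():
            if isinstance(val, np.ndarray):
                continue
            if isinstance(val, (list, tuple)):
                val = ";".join(
                    "-".join(map(str, v)) if isinstance(v, (list, tuple)) else str(v)
                    for v in val
                )
            if isinstance(val, dict):
                val = ";".join(f"{k}:{v}" for k, v in val.items())
            fh.write(f"{key}={val}\n")


def read_truth_record(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            out[key] = val
    return out
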