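"""Covariate-adjusted eQTL scanning, cis/trans classification and screening.

The scan fits, for every (variant, gene) pair, ordinary least squares of
expression on dosage plus an intercept and shared covariates, and reports
the dosage slope, its standard error, the t statistic and a two-sided
p-value on n - k - 2 residual degrees of freedom (k covariates). The
implementation residualizes both expression and dosage on the covariate
design once and then scans all pairs with matrix products — the
MatrixEQTL-style fast path — which is algebraically identical to the
per-pair fit (Frisch-Waugh-Lovell).

Distance conventions: a variant inside a transcript is at distance 0,
otherwise distance is measured to the nearest transcript boundary; the
cis window (<= 1 Mb) and the trans exclusion (>= 10 Mb) are both
boundary-inclusive.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CovariateSet, check_aligned
from ._lm import design_with_intercept, residualizer

__all__ = [
    "CIS_WINDOW",
    "TRANS_EXCLUSION",
    "compute_expression_pcs",
    "eqtl_scan",
    "variant_gene_distance",
    "gene_gene_distance",
    "classify_relation",
    "screen_transcripts",
    "bh_fdr",
    "peak_cis_selection",
    "bonferroni_threshold",
]

CIS_WINDOW = 1_000_000
TRANS_EXCLUSION = 10_000_000


def compute_expression_pcs(expression, min_variance_fraction=0.01):
    """Principal-component scores of the (column-centred) expression matrix.

    Returns a CovariateSet holding every leading PC whose variance
    fraction is at least ``min_variance_fraction`` (default 1%), ordered
    by explained variance and named PC1, PC2, ... Signs are fixed so the
    largest-magnitude loading of each component is positive.
    """
    if expression.n_samples < 2:
        raise ValueError("need at least 2 samples for PCA")
    X = expression.values - expression.values.mean(axis=0)
    if not np.any(np.abs(X) > 1e-12):
        warnings.warn("expression matrix is constant; returning zero PCs")
        return CovariateSet(samples=list(expression.samples))
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float((s**2).sum())
    frac = s**2 / total
    keep = np.flatnonzero((frac >= min_variance_fraction) & (s > 1e-12))
    cols = {}
    for rank, j in enumerate(keep, start=1):
        sign = np.sign(Vt[j, np.argmax(np.abs(Vt[j]))]) or 1.0
        cols[f"PC{rank}"] = sign * U[:, j] * s[j]
    return CovariateSet(samples=list(expression.samples), data=pd.DataFrame(cols))


def variant_gene_distance(pos, start, end):
    """bp distance from a variant to a transcript (0 if inside)."""
    if start <= pos <= end:
        return 0
    return min(abs(pos - start), abs(pos - end))


def gene_gene_distance(start_a, end_a, start_b, end_b):
    """bp gap between nearest transcript boundaries (0 if overlapping)."""
    if end_a >= start_b and end_b >= start_a:
        return 0
    return max(start_b - end_a, start_a - end_b)


def classify_relation(
    variant,
    gene,
    cis_window=CIS_WINDOW,
    trans_exclusion=TRANS_EXCLUSION,
    cis_gene=None,
):
    """Classify a variant-gene pair as ``cis``, ``trans`` or ``other``.

    ``cis``: same chromosome and variant within ``cis_window`` of the
    transcript (boundary inclusive). ``trans``: the gene is eligible as a
    cis-mediated trans gene — at least ``trans_exclusion`` away from the
    reference locus, or on a different chromosome. The reference locus is
    the cis gene when ``cis_gene`` is given (the default rule, measured
    between transcript boundaries) and the variant position otherwise.
    Everything else is ``other``.

    ``variant`` needs ``chrom``/``pos``; gene records need
    ``chrom``/``start``/``end`` (1-based inclusive).
    """
    vchrom, vpos = str(variant["chrom"]), int(variant["pos"])
    gchrom = str(gene["chrom"])
    gstart, gend = int(gene["start"]), int(gene["end"])
    if vchrom == gchrom and variant_gene_distance(vpos, gstart, gend) <= cis_window:
        return "cis"
    if cis_gene is not None:
        ref_chrom = str(cis_gene["chrom"])
        if gchrom != ref_chrom:
            return "trans"
        dist = gene_gene_distance(
            int(cis_gene["start"]), int(cis_gene["end"]), gstart, gend
        )
    else:
        if gchrom != vchrom:
            return "trans"
        dist = variant_gene_distance(vpos, gstart, gend)
    return "trans" if dist >= trans_exclusion else "other"


def eqtl_scan(
    genotypes,
    expression,
    covariates=None,
    pairs="all",
    cis_window=CIS_WINDOW,
    trans_exclusion=TRANS_EXCLUSION,
):
    """Linear-model eQTL scan over variant-gene pairs.

    Parameters
    ----------
    genotypes, expression, covariates
        Sample-aligned containers; covariates may be None/empty.
    pairs
        ``"all"`` for the full cross, or an explicit list of
        ``(variant_id, gene_id)`` tuples.

    Returns
    -------
    DataFrame with columns ``variant_id, gene_id, relation, beta, se,
    stat, p, note``. Monomorphic variants yield ``p = 1`` records flagged
    ``"monomorphic"``. Relation is determined solely by coordinates (the
    trans label here uses the variant itself as reference locus; trio
    construction re-checks eligibility against the actual cis gene).
    """
    check_aligned(genotypes, expression, covariates)
    n = genotypes.n_samples
    if covariates is not None and covariates.names:
        covariates.check_full_rank()
        X = covariates.matrix()
    else:
        X = np.empty((n, 0))
    k = X.shape[1]
    df = n - k - 2
    if df <= 0:
        raise ValueError("not enough samples for the covariate design")

    G = design_with_intercept(X if k else None, n=n)
    _, project = residualizer(G)
    D = project(genotypes.dosage)
    Y = project(expression.values)

    dd = (D * D).sum(axis=0)
    mono = genotypes.dosage.std(axis=0) == 0
    if pairs == "all":
        pair_idx = [
            (i, j)
            for i in range(len(genotypes.variants))
            for j in range(len(expression.genes))
        ]
    else:
        pair_idx = [
            (
                genotypes.variants.index.get_loc(v),
                expression.genes.index.get_loc(g),
            )
            for v, g in pairs
        ]

    vi = np.array([p[0] for p in pair_idx], dtype=int)
    gj = np.array([p[1] for p in pair_idx], dtype=int)

    if pairs == "all":
        num = (D.T @ Y)[vi, gj]
    else:
        num = np.einsum("ni,ni->i", D[:, vi], Y[:, gj])
    yy = (Y * Y).sum(axis=0)[gj]
    ddp = dd[vi]
    safe = ~mono[vi] & (ddp > 0)
    beta = np.zeros(len(pair_idx))
    se = np.full(len(pair_idx), np.nan)
    tstat = np.zeros(len(pair_idx))
    pval = np.ones(len(pair_idx))
    beta[safe] = num[safe] / ddp[safe]
    rss = np.maximum(yy - beta**2 * ddp, 0.0)
    sigma2 = rss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se[safe] = np.sqrt(sigma2[safe] / ddp[safe])
        tstat[safe] = np.where(
            se[safe] > 0, beta[safe] / se[safe], np.sign(beta[safe]) * np.inf
        )
    pval[safe] = 2 * stats.t.sf(np.abs(tstat[safe]), df)

    vrec = genotypes.variants
    grec = expression.genes
    relations = [
        classify_relation(
            vrec.iloc[i], grec.iloc[j], cis_window, trans_exclusion, cis_gene=None
        )
        for i, j in pair_idx
    ]
    return pd.DataFrame(
        {
            "variant_id": vrec.index[vi],
            "gene_id": grec.index[gj],
            "relation": relations,
            "beta": beta,
            "se": se,
            "stat": tstat,
            "p": pval,
            "note": np.where(mono[vi], "monomorphic", ""),
        }
    )


def bh_fdr(pvalues):
    """Benjamini-Hochberg step-up q-values for a vector of p-values.

    Implements the step-up definition ``q_(i) = min_{j >= i} m p_(j) / j``
    (capped at 1) directly, so the output matches the textbook formula to
    the last bit; statsmodels' ``fdr_bh`` agrees to floating-point noise
    and serves as a cross-check in the test suite.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def screen_transcripts(records, n_loci, fdr_level=0.2):
    """Transcriptome screen: per-gene minimum p, locus-count Bonferroni, BH.

    For each gene, ``min_p`` is the smallest scan p-value across tested
    variants, ``adj_p = min(1, min_p * n_loci)`` (Bonferroni for the
    number of seed risk loci), ``q`` is the BH q-value across genes, and
    a gene is selected when ``q < fdr_level``.
    """
    if len(records) == 0:
        return pd.DataFrame(columns=["gene_id", "min_p", "adj_p", "q", "selected"])
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    grp = records.groupby("gene_id", sort=True)["p"].min()
    out = pd.DataFrame({"gene_id": grp.index, "min_p": grp.to_numpy()})
    out["adj_p"] = np.minimum(1.0, out["min_p"] * n_loci)
    out["q"] = bh_fdr(out["adj_p"].to_numpy())
    out["selected"] = out["q"] < fdr_level
    return out


def bonferroni_threshold(alpha, n_tests):
    """The Bonferroni-adjusted per-test significance threshold alpha/n."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def peak_cis_selection(cis_records, alpha=0.05, n_cis_tests=None):
    """Pick the peak cis variant per gene and keep Bonferroni-significant pairs.

    The peak variant is the one with the smallest p-value (ties broken by
    genomic position, then variant id, so selection is deterministic). A
    pair is retained iff its p-value is below ``alpha / n_cis_tests``,
    where ``n_cis_tests`` defaults to the number of cis records scanned
    in this run.

    ``cis_records`` must carry a ``pos`` column (or be joinable by the
    caller); if absent, ties fall back to variant id alone.
    """
    recs = cis_records[cis_records["relation"] == "cis"].copy()
    if n_cis_tests is None:
        n_cis_tests = len(recs)
    if len(recs) == 0:
        out = recs.copy()
        out.attrs["threshold"] = np.nan
        return out
    threshold = bonferroni_threshold(alpha, n_cis_tests)
    sort_cols = ["gene_id", "p"]
    if "pos" in recs.columns:
        sort_cols += ["pos", "variant_id"]
    else:
        sort_cols += ["variant_id"]
    peaks = (
        recs.sort_values(sort_cols, kind="mergesort")
        .groupby("gene_id", sort=True)
        .head(1)
        .reset_index(drop=True)
    )
    out = peaks[peaks["p"] < threshold].reset_index(drop=True)
    out.attrs["threshold"] = threshold
    out.attrs["n_cis_tests"] = int(n_cis_tests)
    return out
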