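"""End-to-end pipeline: screen -> network -> peak cis -> trios -> mediation.

The flow mirrors a network-directed trans-eQTL mediation study:

1. expression PCs are computed and appended to the covariates;
2. all candidate risk variants are scanned against all genes;
3. transcripts are screened (per-gene min p, Bonferroni for the number
   of risk loci, BH FDR) to get the network gene set;
4. a sparse co-expression graph is estimated on the screened genes
   (expression residualized on the covariates by default);
5. peak cis-eQTL pairs are selected at a Bonferroni threshold over the
   cis tests actually run;
6. graph neighbors of each significant cis gene that are trans-eligible
   (>= 10 Mb from the cis gene, or another chromosome) define the
   candidate trios;
7. each trio gets the omnibus mediation test; trios below the Bonferroni
   threshold 0.05 / n_trios are significant; optionally a
   genotype-stratified permutation p is added for robust trios.

Reruns with the same config and data are bit-identical: all random
streams derive from the config seed, and outputs are written with a
fixed float format.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, citmed, coexnet, io as cio
from .containers import CovariateSet, check_aligned
from .citmed import Trio

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "PipelineResult",
    "build_trios",
    "mediate_trios",
    "run_pipeline",
    "sensitivity_scan",
    "report",
    "load_inputs",
]


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; echoed into every output header."""

    # input paths (unused when containers are passed to run_pipeline directly)
    dosage_path: str | None = None
    expression_path: str | None = None
    gene_annotation_path: str | None = None
    variant_annotation_path: str | None = None
    covariates_path: str | None = None
    output_dir: str | None = None

    n_loci: int | None = None          # default: number of candidate variants
    screen_fdr: float = 0.2
    cis_window: int = assoc.CIS_WINDOW
    trans_exclusion: int = assoc.TRANS_EXCLUSION
    pc_min_variance: float = 0.01
    use_pcs: bool = True
    residualize_network: bool = True
    n_lambda: int = 10
    lambda_min_ratio: float = 0.1
    symmetrize_rule: str = "OR"
    stars_subsamples: int = 20
    stars_threshold: float = 0.1
    stars_subsample_size: int | None = None
    cis_alpha: float = 0.05
    trio_alpha: float = 0.05
    B_cond4: int = 1000
    run_permutations: bool = False
    B_perm: int = 1000
    suggestive_p: float = 1e-3
    trans_rule: str = "cis_gene"       # or "variant"
    sensitivity_budget: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in [
            ("screen_fdr", 0, 1),
            ("pc_min_variance", 0, 1),
            ("cis_alpha", 0, 1),
            ("trio_alpha", 0, 1),
            ("lambda_min_ratio", 0, 1),
            ("stars_threshold", 0, 1),
        ]:
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")
        if self.trans_rule not in ("cis_gene", "variant"):
            raise ValueError("trans_rule must be 'cis_gene' or 'variant'")

    def header_lines(self) -> list[str]:
        return [f"{k}: {v}" for k, v in asdict(self).items()]


@dataclass
class RunManifest:
    """Per-stage record counts, seeds and warnings for one run."""

    n_samples: int = 0
    n_variants: int = 0
    n_genes: int = 0
    n_pcs: int = 0
    n_screened: int = 0
    n_graph_edges: int = 0
    n_cis_tests: int = 0
    n_significant_cis: int = 0
    n_trios: int = 0
    n_significant_trios: int = 0
    trio_threshold: float = float("nan")
    seed: int = 0
    stage_seconds: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    timestamp: str = ""

    def validate(self) -> None:
        counts = [
            self.n_samples, self.n_variants, self.n_genes, self.n_screened,
            self.n_graph_edges, self.n_cis_tests, self.n_significant_cis,
            self.n_trios, self.n_significant_trios,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("manifest counts must be non-negative")
        if self.n_significant_trios > self.n_trios:
            raise ValueError("significant trios exceed eligible trios")


@dataclass
class PipelineResult:
    manifest: RunManifest
    screen: pd.DataFrame
    graph: "coexnet.CoexpressionGraph | None"
    cis_pairs: pd.DataFrame
    trios: list
    mediation: pd.DataFrame
    covariates: CovariateSet


def _stage(manifest, name, t0):
    manifest.stage_seconds[name] = round(time.perf_counter() - t0, 3)
    logger.info("stage %s done in %.2fs", name, manifest.stage_seconds[name])


def build_trios(cis_pairs, graph, variants, genes, config=None):
    """Eligible trios: trans-eligible graph neighbors of significant cis genes.

    One trio per (significant cis pair, trans-eligible neighbor of the
    cis gene in the graph); deduplicated and ordered by (variant id, cis
    gene, trans gene). A cis gene absent from the graph contributes no
    trios (logged).
    """
    cfg = config or PipelineConfig()
    trios = []
    seen = set()
    for _, row in cis_pairs.iterrows():
        vid, cg = row["variant_id"], row["gene_id"]
        if cg not in graph.graph:
            logger.warning("cis gene %s absent from graph; no trios", cg)
            continue
        variant = variants.loc[vid]
        cis_gene = genes.loc[cg]
        for nb in coexnet.neighbors(graph, cg):
            if nb == cg or nb not in genes.index:
                continue
            rel = assoc.classify_relation(
                variant,
                genes.loc[nb],
                cis_window=cfg.cis_window,
                trans_exclusion=cfg.trans_exclusion,
                cis_gene=cis_gene if cfg.trans_rule == "cis_gene" else None,
            )
            key = (str(vid), str(cg), str(nb))
            if rel == "trans" and key not in seen:
                seen.add(key)
                trios.append(Trio(variant_id=str(vid), cis_gene=str(cg), trans_gene=str(nb)))
    return sorted(trios, key=lambda t: (t.variant_id, t.cis_gene, t.trans_gene))


def mediate_trios(trios, genotypes, expression, covariates, config, seed_seq=None):
    """Run the omnibus mediation test for each trio; return a tidy frame."""
    ss = seed_seq or np.random.SeedSequence(config.seed)
    children = ss.spawn(max(len(trios), 1))
    rows = []
    for trio, child in zip(trios, children):
        L = genotypes.dosage_of(trio.variant_id)
        C = expression.expression_of(trio.cis_gene)
        T = expression.expression_of(trio.trans_gene)
        res = citmed.cit_test(
            L, C, T, covariates, B_cond4=config.B_cond4, seed=child
        )
        rows.append(
            {
                "variant_id": trio.variant_id,
                "cis_gene": trio.cis_gene,
                "trans_gene": trio.trans_gene,
                "p1": res.p1,
                "p2": res.p2,
                "p3": res.p3,
                "p4": res.p4,
                "mediation_p": res.p_omnibus,
                "beta_T": res.beta_T,
                "beta_Tadj": res.beta_Tadj,
                "M": res.M,
                "B_cond4": res.B_cond4,
            }
        )
    cols = [
        "variant_id", "cis_gene", "trans_gene", "p1", "p2", "p3", "p4",
        "mediation_p", "beta_T", "beta_Tadj", "M", "B_cond4",
    ]
    return pd.DataFrame(rows, columns=cols)


def run_pipeline(config, genotypes=None, expression=None, covariates=None):
    """Execute the full pipeline; returns a PipelineResult.

    Inputs may be passed as containers or loaded from the config paths.
    Every stage failure is re-raised with the stage name attached.
    """
    if genotypes is None or expression is None:
        genotypes, expression, covariates = load_inputs(config)
    if covariates is None:
        covariates = CovariateSet(samples=list(expression.samples))
    check_aligned(genotypes, expression, covariates)

    manifest = RunManifest(
        n_samples=genotypes.n_samples,
        n_variants=len(genotypes.variants),
        n_genes=len(expression.genes),
        seed=config.seed,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    ss = np.random.SeedSequence(config.seed)
    ss_stars, ss_trios = ss.spawn(2)

    stage = "pcs"
    try:
        t0 = time.perf_counter()
        if config.use_pcs:
            pcs = assoc.compute_expression_pcs(expression, config.pc_min_variance)
            covariates = covariates.merged(pcs)
            manifest.n_pcs = len(pcs.names)
        _stage(manifest, stage, t0)

        stage = "eqtl_scan"
        t0 = time.perf_counter()
        scan = assoc.eqtl_scan(
            genotypes, expression, covariates,
            cis_window=config.cis_window, trans_exclusion=config.trans_exclusion,
        )
        _stage(manifest, stage, t0)

        stage = "screen"
        t0 = time.perf_counter()
        n_loci = config.n_loci or len(genotypes.variants)
        screen = assoc.screen_transcripts(scan, n_loci=n_loci, fdr_level=config.screen_fdr)
        selected_genes = list(screen.loc[screen["selected"], "gene_id"])
        manifest.n_screened = len(selected_genes)
        _stage(manifest, stage, t0)

        stage = "network"
        t0 = time.perf_counter()
        graph = None
        if len(selected_genes) >= 3:
            sub = expression.subset_genes(selected_genes)
            net_values = sub.values
            if config.residualize_network and covariates.names:
                from ._lm import design_with_intercept, residualizer

                G = design_with_intercept(covariates.matrix(), n=sub.n_samples)
                _, project = residualizer(G)
                net_values = project(sub.values)
            net_df = pd.DataFrame(net_values, columns=selected_genes)
            path = coexnet.neighborhood_selection_path(
                net_df, n_lambda=config.n_lambda,
                lambda_min_ratio=config.lambda_min_ratio,
                rule=config.symmetrize_rule,
            )
            graph = coexnet.select_graph(
                path,
                subsample_size=config.stars_subsample_size,
                n_subsamples=config.stars_subsamples,
                instability_threshold=config.stars_threshold,
                seed=int(ss_stars.generate_state(1)[0] % (2**31)),
            )
            manifest.n_graph_edges = graph.n_edges
        else:
            manifest.warnings.append("fewer than 3 screened genes; network skipped")
        _stage(manifest, stage, t0)

        stage = "peak_cis"
        t0 = time.perf_counter()
        cis_scan = scan[scan["relation"] == "cis"].copy()
        cis_scan = cis_scan.merge(
            genotypes.variants[["pos"]], left_on="variant_id", right_index=True,
        )
        manifest.n_cis_tests = len(cis_scan)
        cis_pairs = assoc.peak_cis_selection(
            cis_scan, alpha=config.cis_alpha, n_cis_tests=len(cis_scan) or None
        )
        manifest.n_significant_cis = len(cis_pairs)
        _stage(manifest, stage, t0)

        stage = "trios"
        t0 = time.perf_counter()
        trios = build_trios(
            cis_pairs, graph, genotypes.variants, expression.genes, config
        ) if graph is not None else []
        manifest.n_trios = len(trios)
        _stage(manifest, stage, t0)

        stage = "mediation"
        t0 = time.perf_counter()
        mediation = mediate_trios(
            trios, genotypes, expression, covariates, config, seed_seq=ss_trios
        )
        if len(mediation):
            threshold = config.trio_alpha / len(mediation)
            mediation["significant"] = mediation["mediation_p"] < threshold
        else:
            threshold = float("nan")
            mediation["significant"] = pd.Series(dtype=bool)
        manifest.trio_threshold = threshold
        manifest.n_significant_trios = int(mediation["significant"].sum())
        _stage(manifest, stage, t0)

        stage = "permutation"
        t0 = time.perf_counter()
        mediation["perm_p"] = np.nan
        mediation["B_perm"] = 0
        if config.run_permutations and len(mediation):
            perm_children = ss.spawn(len(mediation))
            for i, row in mediation.iterrows():
                if row["mediation_p"] >= config.suggestive_p:
                    continue
                p_perm = citmed.permutation_robustness(
                    genotypes.dosage_of(row["variant_id"]),
                    expression.expression_of(row["cis_gene"]),
                    expression.expression_of(row["trans_gene"]),
                    covariates,
                    p_observed=row["mediation_p"],
                    B=config.B_perm,
                    B_cond4=config.B_cond4,
                    seed=perm_children[i],
                )
                mediation.loc[i, "perm_p"] = p_perm
                mediation.loc[i, "B_perm"] = config.B_perm
        _stage(manifest, stage, t0)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest.validate()
    result = PipelineResult(
        manifest=manifest,
        screen=screen,
        graph=graph,
        cis_pairs=cis_pairs,
        trios=trios,
        mediation=mediation,
        covariates=covariates,
    )
    if config.output_dir:
        _write_outputs(result, config, genotypes, expression)
    return result


def _write_outputs(result, config, genotypes, expression):
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    hdr = config.header_lines()

    def _write(df, name):
        with open(out / name, "w") as fh:
            for line in hdr:
                fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t", index=False, float_format=cio.FLOAT_FORMAT)

    _write(result.screen, "screen.tsv")
    _write(result.cis_pairs, "cis_pairs.tsv")
    _write(result.mediation, "mediation.tsv")
    _write(table1_style(result, genotypes, expression), "results_table.tsv")
    if result.graph is not None:
        coexnet.write_graph_tsv(result.graph, out / "graph_edges.tsv", out / "graph_nodes.tsv")
    man = {k: v for k, v in asdict(result.manifest).items()}
    with open(out / "manifest.txt", "w") as fh:
        for k, v in man.items():
            fh.write(f"{k}={v}\n")


def table1_style(result, genotypes, expression, cis_stats=None):
    """Mediation results in a per-trio summary table.

    Columns: rsID, chr:pos, alleles, cis gene and its cis-eQTL effect,
    trans gene and its marginal trans-eQTL effect, omnibus mediation p,
    adjusted trans slope, mediated proportion M, permutation p and B.
    """
    rows = []
    cis_lookup = {}
    if cis_stats is None and len(result.cis_pairs):
        cis_lookup = {
            (r["variant_id"], r["gene_id"]): (r["beta"], r["p"])
            for _, r in result.cis_pairs.iterrows()
        }
    for _, r in result.mediation.iterrows():
        v = genotypes.variants.loc[r["variant_id"]]
        bc, pc = cis_lookup.get((r["variant_id"], r["cis_gene"]), (np.nan, np.nan))
        rows.append(
            {
                "rsID": r["variant_id"],
                "chr_pos": f"{v['chrom']}:{v['pos']}",
                "alleles": f"{v['ref']}/{v['alt']}",
                "cis_gene": r["cis_gene"],
                "beta_C": bc,
                "P_C": pc,
                "trans_gene": r["trans_gene"],
                "beta_T": r["beta_T"],
                "P_T": r["p1"],
                "mediation_P": r["mediation_p"],
                "beta_Tadj": r["beta_Tadj"],
                "M": r["M"],
                "perm_P": r.get("perm_p", np.nan),
                "B": r.get("B_perm", 0),
            }
        )
    cols = [
        "rsID", "chr_pos", "alleles", "cis_gene", "beta_C", "P_C",
        "trans_gene", "beta_T", "P_T", "mediation_P", "beta_Tadj", "M",
        "perm_P", "B",
    ]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(
        ["mediation_P", "rsID", "cis_gene", "trans_gene"], kind="mergesort"
    ).reset_index(drop=True)


def sensitivity_scan(
    cis_pairs, genotypes, expression, covariates, config, allow_large=False,
    seed_seq=None,
):
    """Network-agnostic mediation scan over every trans-eligible gene.

    The same mediation machinery is applied to all genes trans-eligible
    for each significant cis pair, not just graph neighbors. Aborts when
    the pair count exceeds ``config.sensitivity_budget`` unless
    ``allow_large``. Output rows carry ``network_agnostic = True``.
    """
    trios = []
    for _, row in cis_pairs.iterrows():
        vid, cg = row["variant_id"], row["gene_id"]
        variant = genotypes.variants.loc[vid]
        cis_gene = expression.genes.loc[cg]
        for g in expression.genes.index:
            if g == cg:
                continue
            rel = assoc.classify_relation(
                variant,
                expression.genes.loc[g],
                cis_window=config.cis_window,
                trans_exclusion=config.trans_exclusion,
                cis_gene=cis_gene if config.trans_rule == "cis_gene" else None,
            )
            if rel == "trans":
                trios.append(Trio(variant_id=str(vid), cis_gene=str(cg), trans_gene=str(g)))
    trios = sorted(set(trios), key=lambda t: (t.variant_id, t.cis_gene, t.trans_gene))
    if len(trios) > config.sensitivity_budget and not allow_large:
        raise RuntimeError(
            f"sensitivity scan would test {len(trios)} trios "
            f"(budget {config.sensitivity_budget}); pass allow_large=True to override"
        )
    ss = seed_seq or np.random.SeedSequence(config.seed + 1)
    res = mediate_trios(trios, genotypes, expression, covariates, config, seed_seq=ss)
    res["network_agnostic"] = True
    if len(res):
        res["significant"] = res["mediation_p"] < config.trio_alpha / len(res)
    else:
        res["significant"] = pd.Series(dtype=bool)
    return res


def report(result, threshold=None):
    """Human-readable summary of a pipeline run.

    Cross-checks the manifest against the result tables (raising on
    inconsistency) and returns a summary string. Empty results are valid
    when the run genuinely found nothing.
    """
    man = result.manifest
    man.validate()
    if man.n_trios != len(result.mediation):
        raise ValueError("manifest inconsistent: trio count != mediation rows")
    n_sig = int(result.mediation.get("significant", pd.Series(dtype=bool)).sum())
    if n_sig != man.n_significant_trios:
        raise ValueError("manifest inconsistent: significant trio count")
    threshold = threshold if threshold is not None else man.trio_threshold
    med = result.mediation.sort_values(
        ["mediation_p", "variant_id", "cis_gene", "trans_gene"], kind="mergesort"
    )
    lines = [
        f"samples: {man.n_samples}  variants: {man.n_variants}  genes: {man.n_genes}",
        f"screened transcripts: {man.n_screened}",
        f"graph edges: {man.n_graph_edges}",
        f"significant cis pairs: {man.n_significant_cis} (of {man.n_cis_tests} cis tests)",
        f"eligible trios: {man.n_trios}",
        f"significant trios (p < {threshold:.3g}): {man.n_significant_trios}",
    ]
    n_suggestive = 0
    for _, r in med.iterrows():
        star = "*" if r.get("significant", False) else ""
        if not r.get("significant", False) and r["mediation_p"] < 1e-3:
            n_suggestive += 1
        lines.append(
            f"  {r['variant_id']} -> {r['cis_gene']} -> {r['trans_gene']}: "
            f"mediation p = {r['mediation_p']:.3g}{star}  M = {r['M']:.2f}"
        )
    lines.append(f"suggestive (non-significant, p < 1e-03): {n_suggestive}")
    return "\n".join(lines)


def load_inputs(config):
    """Load genotype/expression/covariate containers from config paths."""
    genes = cio.read_gene_annotation(config.gene_annotation_path)
    variants = cio.read_variant_annotation(config.variant_annotation_path)
    if str(config.dosage_path).endswith((".vcf", ".vcf.gz")):
        genotypes = cio.read_vcf_dosages(config.dosage_path)
    else:
        genotypes = cio.read_dosage_tsv(config.dosage_path, variants)
    expression = cio.read_expression_tsv(config.expression_path, genes)
    covariates = None
    if config.covariates_path:
        cov = pd.read_csv(config.covariates_path, sep="\t", comment="#", index_col=0)
        covariates = CovariateSet(samples=list(cov.index.astype(str)), data=cov.reset_index(drop=True))
    return genotypes, expression, covariates
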