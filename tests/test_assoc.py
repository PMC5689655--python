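"""Scan, screening and multiplicity machinery: OLS-oracle agreement,
distance conventions, BH step-up correctness and peak-variant selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import cismediator as cm
from cismediator.containers import CovariateSet, ExpressionMatrix
from cismediator.studies import (
    bh_agreement_study,
    brute_force_bh,
    fastpath_agreement_study,
    simulate_trio_dataset,
)


def _toy_dataset(n=120, n_variants=3, n_genes=4, seed=0):
    rng = np.random.default_rng(seed)
    specs = [(f"v{i}", "1", 1000 + 10 * i, 0.3) for i in range(n_variants)]
    g = cm.simulate_genotypes(n, specs, seed=seed)
    genes = pd.DataFrame(
        {"chrom": "2", "start": np.arange(n_genes) * 10_000 + 1,
         "end": np.arange(n_genes) * 10_000 + 2_000},
        index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id"),
    )
    values = rng.normal(size=(n, n_genes))
    e = ExpressionMatrix(samples=list(g.samples), genes=genes, values=values)
    return g, e


class TestExpressionPCs:
    def test_rank_one_matrix_yields_single_pc(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=100)
        genes = pd.DataFrame(
            {"chrom": ["1", "1"], "start": [1, 10_001], "end": [2000, 12_000]},
            index=pd.Index(["a", "b"], name="gene_id"),
        )
        e = ExpressionMatrix(
            samples=[f"s{i}" for i in range(100)],
            genes=genes,
            values=np.column_stack([base, base]),
        )
        pcs = cm.compute_expression_pcs(e)
        assert pcs.names == ["PC1"]

    def test_variance_fractions_sum_to_one(self):
        g, e = _toy_dataset(n=500, n_genes=50, seed=1)
        X = e.values - e.values.mean(axis=0)
        s = np.linalg.svd(X, compute_uv=False)
        assert np.isclose((s**2 / (s**2).sum()).sum(), 1.0)
        pcs = cm.compute_expression_pcs(e, min_variance_fraction=0.0)
        # total PC variance equals total expression variance
        assert np.isclose(pcs.matrix().var(axis=0, ddof=0).sum() * 500,
                          (X**2).sum(), rtol=1e-8)

    def test_constant_matrix_warns_and_returns_zero_pcs(self):
        genes = pd.DataFrame(
            {"chrom": ["1", "1"], "start": [1, 10_001], "end": [2000, 12_000]},
            index=pd.Index(["a", "b"], name="gene_id"),
        )
        e = ExpressionMatrix(samples=["s1", "s2", "s3"], genes=genes,
                             values=np.ones((3, 2)))
        with pytest.warns(UserWarning):
            pcs = cm.compute_expression_pcs(e)
        assert pcs.names == []

    def test_top_pc_recovers_strong_confounder(self):
        rng = np.random.default_rng(42)
        n, p = 1000, 50
        conf = rng.normal(size=n)
        values = rng.normal(size=(n, p))
        loaded = rng.choice(p, size=p * 4 // 10, replace=False)
        values[:, loaded] += np.outer(conf, np.full(loaded.size, 1.0))
        genes = pd.DataFrame(
            {"chrom": "1", "start": np.arange(p) * 10_000 + 1,
             "end": np.arange(p) * 10_000 + 2_000},
            index=pd.Index([f"g{i}" for i in range(p)], name="gene_id"),
        )
        e = ExpressionMatrix(samples=[f"s{i}" for i in range(n)], genes=genes,
                             values=values)
        pcs = cm.compute_expression_pcs(e)
        r = np.corrcoef(pcs.data["PC1"], conf)[0, 1]
        assert abs(r) > 0.9


class TestEqtlScan:
    def test_perfect_fit(self):
        g, e = _toy_dataset(seed=2)
        e.values[:, 0] = g.dosage[:, 0]
        scan = cm.eqtl_scan(g, e, pairs=[("v0", "g0")])
        row = scan.iloc[0]
        assert np.isclose(row["beta"], 1.0)
        assert row["p"] < 1e-200

    def test_fastpath_matches_per_pair_ols(self):
        out = fastpath_agreement_study(seed=3)
        assert out["max_relative_error"] < 1e-10

    def test_null_pvalues_uniform(self):
        g, e = _toy_dataset(n=300, n_variants=25, n_genes=40, seed=4)
        scan = cm.eqtl_scan(g, e)
        ks = stats.kstest(scan["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_monomorphic_variant_flagged(self):
        g, e = _toy_dataset(seed=5)
        g.dosage[:, 1] = 1.0
        scan = cm.eqtl_scan(g, e, pairs=[("v1", "g0")])
        assert scan.iloc[0]["note"] == "monomorphic"
        assert scan.iloc[0]["p"] == 1.0

    def test_rank_deficient_covariates_named(self):
        g, e = _toy_dataset(seed=6)
        x = np.random.default_rng(0).normal(size=g.n_samples)
        cov = CovariateSet(
            samples=list(g.samples),
            data=pd.DataFrame({"ok": x, "dup": 2 * x}),
        )
        with pytest.raises(ValueError, match="dup"):
            cm.eqtl_scan(g, e, cov)

    def test_shift_invariance_and_beta_scaling(self):
        g, e = _toy_dataset(seed=7)
        base = cm.eqtl_scan(g, e, pairs=[("v0", "g1")]).iloc[0]
        e2 = ExpressionMatrix(samples=list(e.samples), genes=e.genes,
                              values=e.values + 5.0)
        shifted = cm.eqtl_scan(g, e2, pairs=[("v0", "g1")]).iloc[0]
        assert np.isclose(base["beta"], shifted["beta"])
        assert np.isclose(base["p"], shifted["p"])
        g2 = cm.GenotypeMatrix(samples=list(g.samples), variants=g.variants,
                               dosage=g.dosage / 2.0)
        scaled = cm.eqtl_scan(g2, e, pairs=[("v0", "g1")]).iloc[0]
        assert np.isclose(scaled["beta"], 2 * base["beta"])
        assert np.isclose(scaled["p"], base["p"])

    def test_type_one_error_calibrated(self):
        g, e = _toy_dataset(n=250, n_variants=20, n_genes=50, seed=8)
        scan = cm.eqtl_scan(g, e)
        frac = (scan["p"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(scan))
        assert abs(frac - 0.05) < 3 * se


class TestClassifyRelation:
    def test_cis_boundary_inclusive(self, small_annotation):
        variant, genes = small_annotation
        gene = pd.Series({"chrom": "17", "start": 37_101_926, "end": 37_121_925})
        assert cm.classify_relation(variant, gene) == "cis"  # exactly 1 Mb

    def test_other_chromosome_is_trans(self, small_annotation):
        variant, genes = small_annotation
        assert cm.classify_relation(variant, genes.loc["GT_OTHER"]) == "trans"

    def test_trans_boundary_inclusive_from_cis_gene(self, small_annotation):
        variant, genes = small_annotation
        cis = genes.loc["GC"]
        exactly = pd.Series(
            {"chrom": "17", "start": int(cis["end"]) + 10_000_000,
             "end": int(cis["end"]) + 10_020_000}
        )
        just_under = pd.Series(
            {"chrom": "17", "start": int(cis["end"]) + 9_999_999,
             "end": int(cis["end"]) + 10_019_999}
        )
        assert cm.classify_relation(variant, exactly, cis_gene=cis) == "trans"
        assert cm.classify_relation(variant, just_under, cis_gene=cis) == "other"

    def test_variant_inside_transcript_is_cis(self, small_annotation):
        variant, _ = small_annotation
        gene = pd.Series({"chrom": "17", "start": 36_000_000, "end": 36_500_000})
        assert cm.classify_relation(variant, gene) == "cis"


class TestScreening:
    def test_bonferroni_arithmetic_and_cap(self):
        recs = pd.DataFrame(
            {"gene_id": ["a", "b"], "p": [1e-4, 0.01]}
        )
        out = cm.screen_transcripts(recs, n_loci=202)
        a = out.set_index("gene_id")
        assert np.isclose(a.loc["a", "adj_p"], 0.0202)
        assert a.loc["b", "adj_p"] == 1.0

    def test_bh_on_known_vector(self):
        # q_i = min_{j>=i} m p_(j) / j applied to (0.01, 0.02, 0.04)
        q = cm.bh_fdr([0.01, 0.02, 0.04])
        assert np.allclose(q, [0.03, 0.03, 0.04])

    def test_selected_iff_q_below_level(self):
        recs = pd.DataFrame(
            {"gene_id": list("abcd"), "p": [1e-6, 0.001, 0.3, 0.9]}
        )
        out = cm.screen_transcripts(recs, n_loci=10, fdr_level=0.2)
        assert (out["selected"] == (out["q"] < 0.2)).all()

    def test_empty_input(self):
        out = cm.screen_transcripts(pd.DataFrame(columns=["gene_id", "p"]), n_loci=5)
        assert len(out) == 0


class TestBhFdr:
    def test_constant_vector(self):
        assert np.allclose(cm.bh_fdr([0.05] * 10), 0.05)

    def test_single_p(self):
        assert np.allclose(cm.bh_fdr([0.3]), [0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cm.bh_fdr([0.1, 1.5])

    def test_matches_brute_force_oracle(self):
        out = bh_agreement_study(seed=0, n_vectors=20, m=60)
        assert out["max_abs_difference"] == 0.0

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        p = np.random.default_rng(1).random(200)
        assert np.allclose(cm.bh_fdr(p), multipletests(p, method="fdr_bh")[1])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_stepup_definition_property(self, pvals):
        q = cm.bh_fdr(pvals)
        assert np.allclose(q, brute_force_bh(pvals))
        # monotone in p and bounded by 1
        order = np.argsort(pvals, kind="mergesort")
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()
        assert (q <= 1).all()


class TestPeakCisSelection:
    def test_paper_scale_threshold(self):
        assert f"{cm.bonferroni_threshold(0.05, 144_628):.1e}" == "3.5e-07"

    def test_trivial_threshold(self):
        assert cm.bonferroni_threshold(0.05, 1) == 0.05

    def test_tie_broken_by_position(self):
        recs = pd.DataFrame(
            {
                "variant_id": ["v2", "v1"],
                "gene_id": ["g", "g"],
                "relation": ["cis", "cis"],
                "p": [1e-9, 1e-9],
                "pos": [500, 100],
            }
        )
        out = cm.peak_cis_selection(recs, alpha=0.05, n_cis_tests=2)
        assert list(out["variant_id"]) == ["v1"]

    def test_peak_recovered_in_mediated_scenario(self):
        # planted cis pair recovered as significant peak in >= 95/100 runs
        sc = cm.TrioScenario(n_samples=500, n_background_genes=0)
        hits = 0
        for r in range(100):
            g, e, cov, _ = simulate_trio_dataset(sc, seed=20_000 + r)
            scan = cm.eqtl_scan(g, e, cov)
            cis = scan[scan["relation"] == "cis"].copy()
            cis["pos"] = 36_101_926
            out = cm.peak_cis_selection(cis, alpha=0.05)
            if (
                len(out)
                and out.iloc[0]["variant_id"] == "rs_L"
                and out.iloc[0]["gene_id"] == "CIS_GENE"
            ):
                hits += 1
        assert hits >= 95
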