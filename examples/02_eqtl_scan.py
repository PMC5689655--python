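"""Covariate-adjusted eQTL scan, transcript screening and peak-cis pick.

Scans the planted variant against every gene, Bonferroni-adjusts each
gene's best p-value for the number of seed loci, applies BH FDR to
screen transcripts for the network stage, and selects the peak cis pair
at the Bonferroni threshold over the cis tests actually run.
"""

import cismediator as cm
from cismediator.studies import simulate_trio_dataset

scenario = cm.TrioScenario(n_samples=500, seed=1)
genotypes, expression, covariates, _ = simulate_trio_dataset(scenario, seed=1)

scan = cm.eqtl_scan(genotypes, expression, covariates)
print(scan.sort_values("p").head(3)[["variant_id", "gene_id", "relation",
                                     "beta", "p"]].to_string(index=False))
print("(the two smallest p-values are the planted cis and trans signals)")

screen = cm.screen_transcripts(scan, n_loci=1, fdr_level=0.2)
print(f"\nscreened transcripts (q < 0.2): "
      f"{int(screen['selected'].sum())} of {len(screen)}")

cis = scan[scan["relation"] == "cis"].copy()
cis["pos"] = genotypes.variants.loc[cis["variant_id"], "pos"].to_numpy()
peaks = cm.peak_cis_selection(cis, alpha=0.05)
print(f"significant peak cis pairs (p < {peaks.attrs['threshold']:.3g}):")
print(peaks[["variant_id", "gene_id", "beta", "p"]].to_string(index=False))
print("beta is the expression change per alt allele on the log scale.")
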