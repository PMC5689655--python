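"""The whole pipeline on one synthetic dataset, plus the sensitivity scan.

Simulates a mediated trio among 30 background genes, runs screen ->
network -> peak cis -> trios -> mediation, prints the run report, and
re-tests every trans-eligible gene ignoring the graph (the
network-agnostic sensitivity scan).
"""

import cismediator as cm
from cismediator.studies import simulate_trio_dataset

scenario = cm.TrioScenario(n_samples=500, n_background_genes=30, seed=6)
genotypes, expression, covariates, _ = simulate_trio_dataset(scenario, seed=6)

config = cm.PipelineConfig(use_pcs=False, screen_fdr=1.0, B_cond4=1000, seed=6)
result = cm.run_pipeline(
    config, genotypes=genotypes, expression=expression, covariates=covariates
)
print(cm.report(result))

scan = cm.sensitivity_scan(
    result.cis_pairs, genotypes, expression, result.covariates, config
)
print(f"\nsensitivity scan (graph-agnostic): {len(scan)} trios tested, "
      f"{int(scan['significant'].sum())} significant")
print("the graph-restricted significant trios are a subset of the "
      "sensitivity-scan trios; agreement here shows the planted signal "
      "does not depend on graph quality.")
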