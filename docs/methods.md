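# Methods

This note documents the statistical model behind `cismediator`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions a maintainer would want to
know about.

## Model and assumptions

The object of inference is the causal chain **L → C → T**: a risk
variant *L* (additive dosage in [0, 2]) regulates a proximal gene *C*
in cis, and *C*'s product regulates a distal gene *T* in trans. All
models are linear-Gaussian on the analysis scale (normalized, roughly
log-scale expression), with shared covariates *X* (technical variables
plus expression principal components) entering every regression
additively. The approach assumes:

- additive allelic effects (no dominance or interaction terms);
- expression matrices are complete post-QC (missing expression is an
  error; missing dosages are mean-imputed at load with a logged count);
- confounding is captured by observed covariates and expression PCs;
- co-expression partial correlation is informative about regulatory
  adjacency (the graph is a search-space reduction device, not itself a
  causal claim).

### Component tests

For a trio with covariate matrix X (intercept always added):

- p1: F test of L in `T ~ X + L` (the marginal trans-eQTL);
- p2: F test of L in `C ~ X + T + L`;
- p3: F test of C in `T ~ X + L + C`;
- p4: equivalence-style permutation test of L ⟂ T | C.

p4's construction (the omnibus form constrains only the maximum; the
internals follow the causal-inference-test literature): let F_obs be the
F statistic of L in `T ~ X + C + L`. For each of B_cond4 permutations,
the residuals of `C ~ X` are permuted *within genotype classes of L*
and added back to the fitted values, producing C\*: this preserves the
L–C and X–C relations while destroying the C–T linkage given L. With
F\*_b the corresponding statistic, p4 = (1 + #{F\*_b ≤ F_obs}) /
(B_cond4 + 1). Under pure mediation F_obs is a central-F draw while the
F\*_b recover the full marginal L–T effect, so p4 is small; under a
direct L→T effect F_obs ≈ F\*_b and p4 is uniform-ish. The omnibus
p-value is max(p1..p4) — an intersection-union test, conservative by
construction.

Degrees of freedom are n − p with p counting the intercept, covariates
and model terms (the scan: n − k − 2 for k covariates).

### Mediated proportion

M = (β̂_T − β̂_Tadj)/β̂_T, where β̂_T comes from `T ~ X + L` and β̂_Tadj
from `T ~ X + C + L`. M is reported unclamped (values outside [0, 1]
are informative: sampling noise around complete mediation, suppression,
or inflation) and flagged undefined (NaN) when β̂_T = 0. β̂_T uses the
same covariate-adjusted model as the scan so result tables are
internally consistent. Note that M is a ratio of estimates: replicate
means can drift slightly above 1 under complete mediation, and mediator
measurement error biases M downward (the package's measurement-error
study quantifies this).

### Permutation robustness

For a reported trio, T is shuffled within genotype classes of L
(dosages rounded to the nearest of {0, 1, 2}; a strict flag refuses
non-integer dosages; classes with fewer than two members stay fixed,
logged), the full omnibus p is recomputed per permutation, and
p_perm = (count + 1)/(B + 1) — the (count+1) estimator guarantees a
floor of 1/(B+1), e.g. 1.0e-5 at B = 100,000. "As or more extreme" is
`≤` by default, `<` by flag. Class members are canonically ordered by
value before shuffling, making the draws invariant to relabeling
samples within a genotype class.

## Pipeline thresholds and defaults

| parameter | default | rationale |
|---|---|---|
| cis window | 1 Mb (boundary-inclusive, nearest transcript edge; 0 inside) | standard cis definition |
| trans exclusion | 10 Mb from the cis gene (or another chromosome) | guards against long-range LD masquerading as trans; measured from the cis gene by default, from the variant by flag |
| PC inclusion | every PC with variance fraction ≥ 0.01 | keeps latent technical/biological axes without fixing a count |
| screen | per-gene min p × n_loci (capped at 1), BH q < 0.20 | permissive by design: a dimensionality-reduction step, not an inference |
| peak cis | smallest p per gene; ties by position then variant id; keep if p < 0.05/n_cis_tests | deterministic and recomputed from the cis tests actually run |
| trio significance | p_omnibus < 0.05/n_trios | denominator recomputed from the realized trio list, recorded in the manifest |
| B_cond4 | 1000 | p4 floor ≈ 1e-3, far below desk-scale trio thresholds; raise for large trio counts |
| network path | 10 penalties, log-spaced, λ_min = 0.1 λ_max | the reference neighborhood-selection implementation's documented defaults |
| symmetrization | OR (AND by flag) | matches the reference implementation's neighborhood-selection behavior |
| StARS | 20 subsamples of size ⌊10√n⌋ (capped at n−1), instability ≤ 0.1 | the standard stability companion to neighborhood selection; reproducible under a seed; fixed-λ override available |

FDR is Benjamini–Hochberg step-up, implemented directly from the
definition q\_(i) = min\_{j≥i} m p\_(j)/j (adjusted p-values capped at 1
before FDR); statsmodels' `fdr_bh` is used as a cross-check in the
tests. The step-up choice and the cap are conventions; both are the
field default.

## Network estimation details

Per-node lasso solved by scikit-learn coordinate descent with warm
starts along the path (tolerance 1e-6); columns standardized
internally, supports read off the standardized scale (only supports
matter). λ_max is the largest absolute pairwise correlation, inflated
by 1e-6 so the top of the grid is empty despite floating-point rounding
of the entry condition. Before network estimation the pipeline
residualizes expression on the same covariates used for the scan
(disable with `residualize_network=False`); this is an interpretation —
whether to pre-adjust is genuinely open — chosen so graph edges reflect
co-expression beyond the adjusted axes.

StARS selection: per-edge selection frequency ξ across subsamples,
instability 2ξ(1−ξ) averaged over pairs, monotonized from the sparsest
penalty down; keep the densest penalty within the threshold. One
documented fallback: for very small gene sets the single boundary edge
at λ_max (subsample correlation straddling the grid top) has ξ ≈ 0.5
and, averaged over a handful of pairs, pushes the monotonized
instability over the threshold everywhere; selection then falls back to
the raw instability profile, and to the sparsest penalty if even that
never qualifies. With realistically many genes the fallback never
triggers. If the sample is too small to subsample (b < 10), selection
falls back to the middle of the grid with a warning.

## The synthetic generator

`TrioScenario` defaults are the package's reference study conditions: a
study-sized cohort (471 samples), a common risk allele (MAF 0.3,
Hardy-Weinberg binomial(2, MAF) integer dosages), cis effect a = 0.5
per allele on unit-variance noise (a strong but realistic cis-eQTL,
detectable at n ≈ 500), mediation effect b = 0.8 per expression unit,
no direct effect, two latent confounders loading 0.3 on both C and T,
two generic technical covariates (tissue-composition style) loading
0.2, and 30 background genes from a chain precision matrix with partial
correlation 0.3 (hub studies use 0.2, near the positive-definiteness
cap for a 20-gene star). Scenario labels (mediated / direct / reverse /
independent) are derivable from the coefficients. Confounders are
returned in the covariate set by default; a flag hides them to exercise
PC-based recovery. Coordinates are 1-based inclusive; the cis gene is
placed 50 kb from the anchor variant, trans genes ≥ 10 Mb away,
background genes on other chromosomes (trans-eligible but unlinked).

What it does *not* emulate: count-scale data and normalization
artifacts, LD between candidate variants (an explicit variant list
replaces LD-based expansion; computing LD from a reference panel is out
of scope), read-level noise, isoform structure, and non-linear or
non-Gaussian effects. Passing tests therefore demonstrate correctness
of the statistical machinery under the linear-Gaussian design, not
robustness to those real-data features.

## Study sizes and design choices in the reproduction script

The operating-characteristic studies use: 500 replicates at n = 500
(type-I / specificity, B_cond4 = 500), 500 replicates at n = 1000
(power and M), 100 replicates for measurement-error attenuation
(SNR 1:1), 100 replicates of 20-gene chain/hub graphs at n = 500, and
50 end-to-end replicates with 30 background genes at n = 500 — sizes at
which every rate is estimated to a standard error of ~1–2% while the
whole script completes in minutes on one CPU.

The end-to-end study runs the pipeline with a fully liberal screen
(`screen_fdr = 1.0`) and without PCs: with a single seed locus the
screen has no testing dimensionality to reduce and would leave fewer
genes than network estimation needs, and the confounders are observed
in that design, making PCs redundant (worse: with 32 genes the trio
itself dominates the PCs and would absorb its own signal — at
transcriptome scale, where PCs are computed over ~17,000 genes, this
self-adjustment is negligible). The screen and PC machinery are
validated by their own tests at their own settings.

## Degenerate inputs and numerical conventions

- monomorphic variants: scan records emitted with p = 1 and a
  "monomorphic" note rather than an error;
- constant expression in a trio, single-genotype-class variants,
  rank-deficient covariates (offending column named), and singular
  background precision structures are rejected with messages;
- a constant expression matrix yields zero PCs with a warning; PC signs
  are fixed (largest loading positive) for cross-run determinism;
- all permutation p-values use (count+1)/(B+1); ties in permuted
  statistics count as "as extreme" by default;
- all outputs are written with a fixed `%.10g` float format, and every
  random stream derives from the config seed via `SeedSequence`, so a
  rerun with the same config and data is byte-identical (output
  directory aside).

## Known limitations

- The omnibus test is conservative (its p-value is a maximum); true
  mediation p-values are bounded below by 1/(B_cond4 + 1), so the trio
  Bonferroni threshold must stay above that floor — the pipeline leaves
  B_cond4 to the user rather than auto-scaling it.
- Reverse causation (L → T → C) is probed only through the generator's
  reverse scenario; the pipeline does not fit a separate reverse-model
  omnibus test.
- Neighborhood selection assumes roughly Gaussian residual expression;
  heavy tails inflate spurious edges (no nonparanormal transform is
  provided).
- M is a plug-in ratio without a standard error; interpret it jointly
  with the component p-values.
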