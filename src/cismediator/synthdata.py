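"""Synthetic genotype/expression generator with known causal structure.

The generator emulates the design of a tissue eQTL study: a risk variant
``L`` with additive dosage genotypes under Hardy-Weinberg equilibrium, a
cis-regulated gene ``C`` whose expression is a linear function of the
dosage, a distal gene ``T`` driven (or not) by ``C``, shared latent
confounders standing in for expression principal components, and a block
of background genes drawn from a multivariate normal with a known sparse
precision matrix, so that graph-recovery stages have ground truth.

Scenario labels:

``mediated``
    ``a != 0, b != 0, d = 0`` — the trans association is fully mediated
    by the cis gene (the causal chain L -> C -> T holds).
``direct``
    ``d != 0, b = 0`` — L affects T directly, not through C.
``reverse``
    the chain runs L -> T -> C instead.
``independent``
    ``a = b = d = 0`` — no association at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, ExpressionMatrix, CovariateSet

__all__ = [
    "TrioScenario",
    "simulate_genotypes",
    "simulate_trio_expression",
    "assign_coordinates",
    "make_precision_matrix",
    "sample_background",
]


@dataclass
class TrioScenario:
    """Generative parameters for one (L, C, T) trio plus background genes.

    Defaults mirror a common-variant tissue eQTL setting: a study-sized
    cohort, a common risk allele (MAF 0.3), a strong cis effect on the
    standardized expression scale (a = 0.5 per alt-allele dose), strong
    downstream propagation (b = 0.8 per expression unit), no direct
    effect, unit residual noise, two latent confounders loading 0.3 on
    both C and T, and a 30-gene chain-structured background block.
    """

    n_samples: int = 471
    maf: float = 0.3
    a: float = 0.5           # L -> C effect (expression units per dose)
    b: float = 0.8           # C -> T effect (per expression unit)
    d: float = 0.0           # direct L -> T effect
    sigma_C: float = 1.0
    sigma_T: float = 1.0
    n_confounders: int = 2
    confounder_loading_C: float = 0.3
    confounder_loading_T: float = 0.3
    n_technical: int = 2     # generic technical covariates (tissue-composition style)
    technical_loading: float = 0.2
    n_background_genes: int = 30
    background_structure: str = "chain"   # chain | hub | random
    background_magnitude: float = 0.3     # target partial correlation per edge
    reverse: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_C <= 0 or self.sigma_T <= 0:
            raise ValueError("sigma_C and sigma_T must be positive")
        if self.background_structure not in ("chain", "hub", "random"):
            raise ValueError(f"unknown background structure {self.background_structure!r}")

    @property
    def label(self) -> str:
        if self.reverse:
            return "reverse"
        if self.a == 0 and self.b == 0 and self.d == 0:
            return "independent"
        if self.d != 0 and self.b == 0:
            return "direct"
        if self.a != 0 and self.b != 0 and self.d == 0:
            return "mediated"
        return "mixed"


def simulate_genotypes(n_samples, variant_specs, seed):
    """Draw additive dosage genotypes under Hardy-Weinberg equilibrium.

    Parameters
    ----------
    n_samples
        Number of samples (> 0).
    variant_specs
        Iterable of ``(id, chromosome, position, maf)`` tuples; each MAF
        must lie in (0, 0.5].
    seed
        Seed for the genotype random stream.

    Returns
    -------
    GenotypeMatrix
        Integer-valued 0/1/2 dosages stored as floats; ref/alt alleles
        are filled with placeholder A/G.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    specs = list(variant_specs)
    for vid, _, _, maf in specs:
        if not (0 < maf <= 0.5):
            raise ValueError(f"variant {vid!r}: MAF {maf} outside (0, 0.5]")
    rng = np.random.default_rng(seed)
    mafs = np.array([s[3] for s in specs], dtype=float)
    dosage = rng.binomial(2, mafs, size=(n_samples, len(specs))).astype(float)
    variants = pd.DataFrame(
        {
            "chrom": [str(s[1]) for s in specs],
            "pos": [int(s[2]) for s in specs],
            "ref": "A",
            "alt": "G",
            "maf": mafs,
        },
        index=pd.Index([s[0] for s in specs], name="variant_id"),
    )
    samples = [f"S{i:04d}" for i in range(n_samples)]
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


def make_precision_matrix(p, structure="chain", magnitude=0.3, seed=0):
    """Build a sparse positive-definite precision matrix with unit diagonal.

    ``magnitude`` is the partial correlation attached to each edge, i.e.
    off-diagonal entries are ``-magnitude``. Structures: ``chain`` (path
    graph), ``hub`` (star centred on gene 0), ``random`` (Erdos-Renyi
    with edge probability 2/p). A magnitude that makes the matrix
    singular or indefinite is rejected: pick a weaker edge instead.

    Returns ``(omega, edges)`` where ``edges`` is a sorted list of
    ``(i, j)`` index pairs (i < j).
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    rng = np.random.default_rng(seed)
    edges = []
    if structure == "chain":
        edges = [(i, i + 1) for i in range(p - 1)]
    elif structure == "hub":
        edges = [(0, j) for j in range(1, p)]
    elif structure == "random":
        prob = min(1.0, 2.0 / max(p - 1, 1))
        for i in range(p):
            for j in range(i + 1, p):
                if rng.random() < prob:
                    edges.append((i, j))
    else:
        raise ValueError(f"unknown structure {structure!r}")
    omega = np.eye(p)
    for i, j in edges:
        omega[i, j] = omega[j, i] = -magnitude
    w = np.linalg.eigvalsh(omega)
    if w.min() <= 1e-6:
        raise ValueError(
            f"precision structure {structure!r} with edge magnitude {magnitude} "
            f"is singular or indefinite (min eigenvalue {w.min():.3g})"
        )
    return omega, edges


def sample_background(n, omega, rng):
    """Sample n rows from N(0, omega^{-1}) via the Cholesky factor of omega."""
    p = omega.shape[0]
    L = np.linalg.cholesky(omega)
    z = rng.standard_normal((n, p))
    # x = L^{-T} z has covariance (L L^T)^{-1} = omega^{-1}
    return np.linalg.solve(L.T, z.T).T


def simulate_trio_expression(genotypes, scenario, variant_id=None, hide_confounders=False):
    """Generate expression for (C, T, background genes) given genotypes.

    The structural equations (non-reverse case) are::

        C = a*L + sum_k gamma_k U_k + tech + eps_C,   eps_C ~ N(0, sigma_C^2)
        T = b*C + d*L + sum_k delta_k U_k + tech + eps_T

    with ``U_k`` iid standard normal latent confounders and ``tech`` the
    technical covariate contribution. In the reverse scenario the roles
    of C and T in the chain are swapped (L -> T -> C) while keeping the
    gene names, so downstream code can probe directionality.

    Returns ``(expression, covariates, truth)``; gene coordinates are
    placed by :func:`assign_coordinates` around the chosen variant.
    ``truth`` records true edges, true coefficients and the scenario
    label. Confounders appear in the returned CovariateSet unless
    ``hide_confounders`` (technical covariates are always returned).
    """
    vid = variant_id or genotypes.variant_ids[0]
    if vid not in genotypes.variants.index:
        raise ValueError(f"variant {vid!r} not present in genotypes")
    rng = np.random.default_rng(scenario.seed)
    n = genotypes.n_samples
    L = genotypes.dosage_of(vid)

    K = scenario.n_confounders
    U = rng.standard_normal((n, K)) if K else np.empty((n, 0))
    gamma = np.full(K, scenario.confounder_loading_C)
    delta = np.full(K, scenario.confounder_loading_T)
    ntech = scenario.n_technical
    tech = rng.standard_normal((n, ntech)) if ntech else np.empty((n, 0))
    tech_effect = tech.sum(axis=1) * scenario.technical_loading

    eps_C = rng.normal(0, scenario.sigma_C, n)
    eps_T = rng.normal(0, scenario.sigma_T, n)
    shared = U @ gamma if K else 0.0
    shared_T = U @ delta if K else 0.0
    if not scenario.reverse:
        C = scenario.a * L + shared + tech_effect + eps_C
        T = scenario.b * C + scenario.d * L + shared_T + tech_effect + eps_T
    else:
        # chain runs L -> T -> C: reuse a as the L->T effect, b as T->C
        T = scenario.a * L + shared_T + tech_effect + eps_T
        C = scenario.b * T + shared + tech_effect + eps_C

    p_bg = scenario.n_background_genes
    if p_bg:
        omega, bg_edges = make_precision_matrix(
            p_bg, scenario.background_structure, scenario.background_magnitude,
            seed=scenario.seed,
        )
        background = sample_background(n, omega, rng)
    else:
        omega, bg_edges = np.empty((0, 0)), []
        background = np.empty((n, 0))

    gene_ids = ["CIS_GENE", "TRANS_GENE"] + [f"BG{i:03d}" for i in range(p_bg)]
    values = np.column_stack([C, T, background])
    anchor = genotypes.variants.loc[vid]
    genes = assign_coordinates(
        gene_ids,
        anchor_chrom=str(anchor["chrom"]),
        anchor_pos=int(anchor["pos"]),
        cis_gene_id="CIS_GENE",
        trans_gene_ids=["TRANS_GENE"],
    )
    expression = ExpressionMatrix(samples=list(genotypes.samples), genes=genes, values=values)

    cov = pd.DataFrame({f"TECH{k+1}": tech[:, k] for k in range(ntech)})
    if K and not hide_confounders:
        for k in range(K):
            cov[f"CONF{k+1}"] = U[:, k]
    covariates = CovariateSet(samples=list(genotypes.samples), data=cov)

    truth = {
        "label": scenario.label,
        "variant": vid,
        "cis_gene": "CIS_GENE",
        "trans_gene": "TRANS_GENE",
        "a": scenario.a,
        "b": scenario.b,
        "d": scenario.d,
        "edges": [("L", "CIS_GENE"), ("CIS_GENE", "TRANS_GENE")]
        if scenario.label == "mediated"
        else [],
        "background_edges": [(gene_ids[2 + i], gene_ids[2 + j]) for i, j in bg_edges],
        "background_precision": omega,
        "confounders_hidden": bool(hide_confounders),
        "scenario": asdict(scenario),
    }
    return expression, covariates, truth


def assign_coordinates(
    gene_ids,
    anchor_chrom,
    anchor_pos,
    cis_gene_id,
    trans_gene_ids,
    cis_offset=50_000,
    gene_length=20_000,
    trans_gap=10_000_000,
):
    """Place genes deterministically around an anchor variant.

    The cis gene starts ``cis_offset`` bp downstream of the anchor (so its
    nearest boundary is well within the 1 Mb cis window). Each trans gene
    is placed on the anchor chromosome with a gap of at least
    ``trans_gap`` (default 10 Mb) from the cis gene's far boundary,
    successive trans genes spaced 1 Mb apart. Background genes are spread
    over other chromosomes, 1 Mb apart, so they are trans-eligible but
    unlinked to the anchor.
    """
    gene_ids = list(gene_ids)
    if cis_gene_id not in gene_ids:
        raise ValueError(f"cis gene {cis_gene_id!r} not in gene list")
    for t in trans_gene_ids:
        if t not in gene_ids:
            raise ValueError(f"trans gene {t!r} not in gene list")
    chroms, starts, ends = {}, {}, {}
    cis_start = anchor_pos + cis_offset
    chroms[cis_gene_id] = str(anchor_chrom)
    starts[cis_gene_id] = cis_start
    ends[cis_gene_id] = cis_start + gene_length - 1
    for i, t in enumerate(trans_gene_ids):
        s = ends[cis_gene_id] + trans_gap + i * 1_000_000 + 1
        chroms[t] = str(anchor_chrom)
        starts[t] = s
        ends[t] = s + gene_length - 1
    other_chroms = [c for c in [str(c) for c in range(1, 23)] if c != str(anchor_chrom)]
    k = 0
    for g in gene_ids:
        if g in chroms:
            continue
        chroms[g] = other_chroms[k % len(other_chroms)]
        starts[g] = 1_000_000 * (k // len(other_chroms) + 1) + 1
        ends[g] = starts[g] + gene_length - 1
        k += 1
    return pd.DataFrame(
        {
            "chrom": [chroms[g] for g in gene_ids],
            "start": [starts[g] for g in gene_ids],
            "end": [ends[g] for g in gene_ids],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
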