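"""Causal mediation testing for (L, C, T) trios.

For a variant L, cis gene C and trans gene T, the causal chain
L -> C -> T is probed with a conservative intersection-union test over
four component hypotheses, all adjusted for shared covariates X:

1. L and T are associated (F test of L in ``T ~ X + L``);
2. L and C are associated given T (F test of L in ``C ~ X + T + L``);
3. C and T are associated given L (F test of C in ``T ~ X + L + C``);
4. L is independent of T given C — an equivalence-style permutation
   test: the observed F statistic of L in ``T ~ X + C + L`` is compared
   with its distribution when the C residuals (after regressing C on X)
   are permuted within genotype classes of L. The permutation preserves
   the L-C and X-C relations while destroying the C-T linkage, so under
   pure mediation the permuted statistics recover the full marginal L-T
   effect and dwarf the observed one (small p supports conditional
   independence), whereas a direct L->T effect leaves the two
   comparable.

The omnibus p-value is the maximum of the four components (an
intersection-union test, hence conservative). Mediation strength is
summarized by M = (beta_T - beta_Tadj) / beta_T, the fraction of the
marginal trans-eQTL slope removed by adjusting for C.

Permutation p-values use the (count + 1)/(B + 1) estimator, so the
smallest attainable value at B permutations is 1/(B + 1) — e.g. 1.0e-5
at B = 100,000.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import CovariateSet
from ._lm import design_with_intercept, residualizer, coef_test

logger = logging.getLogger(__name__)

__all__ = [
    "Trio",
    "MediationResult",
    "cit_test",
    "mediated_proportion",
    "trans_effect_attenuation",
    "permutation_robustness",
    "permutation_pvalue",
    "genotype_classes",
]


@dataclass(frozen=True)
class Trio:
    """One candidate cis-mediator trio."""

    variant_id: str
    cis_gene: str
    trans_gene: str
    covariate_names: tuple = ()


@dataclass
class MediationResult:
    """Component and omnibus p-values plus effect summaries for one trio."""

    p1: float
    p2: float
    p3: float
    p4: float
    beta_T: float
    se_T: float
    beta_Tadj: float
    se_Tadj: float
    M: float            # NaN when beta_T == 0 (undefined flag)
    B_cond4: int
    p_perm: float | None = None
    B_perm: int | None = None

    @property
    def p_omnibus(self) -> float:
        return max(self.p1, self.p2, self.p3, self.p4)

    @property
    def M_defined(self) -> bool:
        return not np.isnan(self.M)


def permutation_pvalue(n_as_extreme, B):
    """(count + 1) / (B + 1) permutation p-value (floor 1/(B+1))."""
    if B < 1:
        raise ValueError("B must be >= 1")
    return (1 + n_as_extreme) / (B + 1)


def genotype_classes(L, strict=False):
    """Integer genotype class per sample, from dosages.

    Dosages are rounded to the nearest of {0, 1, 2}; with ``strict`` a
    non-integer dosage raises instead. Raises if all samples fall in a
    single class (no stratification possible).
    """
    L = np.asarray(L, dtype=float)
    if strict and not np.allclose(L, np.rint(L)):
        raise ValueError("non-integer dosages with strict genotype classes")
    classes = np.clip(np.rint(L), 0, 2).astype(int)
    if len(np.unique(classes)) < 2:
        raise ValueError("all samples in one genotype class; cannot stratify")
    return classes


def _covariate_matrix(X, n):
    if X is None:
        return np.empty((n, 0))
    if isinstance(X, CovariateSet):
        return X.matrix()
    X = np.asarray(X, dtype=float)
    return X[:, None] if X.ndim == 1 else X


def _permute_within_classes(values, classes, B, rng, canonical=False):
    """B row-permutations of ``values``, shuffling only within classes.

    Classes with fewer than 2 members are left unpermuted (logged). With
    ``canonical`` the members of each class are first ordered by value,
    which makes the permutation draws invariant to relabeling samples
    within a class (almost surely, for continuous values).
    """
    values = np.asarray(values, dtype=float)
    out = np.tile(values, (B, 1))
    for c in np.unique(classes):
        idx = np.flatnonzero(classes == c)
        if idx.size < 2:
            logger.info("genotype class %s has <2 members; left unpermuted", c)
            continue
        if canonical:
            idx = idx[np.argsort(values[idx], kind="mergesort")]
        order = np.argsort(rng.random((B, idx.size)), axis=1)
        out[:, idx] = values[idx][order]
    return out


def _f_two_predictors(Tt, Ct, Lt, df):
    """F statistic for the L coefficient in T~ (C, L) after residualizing on G.

    Inputs are already orthogonal to the base design; df is the residual
    degrees of freedom of the full model.
    """
    S11 = float(Ct @ Ct)
    S12 = float(Ct @ Lt)
    S22 = float(Lt @ Lt)
    r1 = float(Ct @ Tt)
    r2 = float(Lt @ Tt)
    det = S11 * S22 - S12 * S12
    if det <= 0:
        return np.inf
    bC = (S22 * r1 - S12 * r2) / det
    bL = (S11 * r2 - S12 * r1) / det
    rss = max(float(Tt @ Tt) - (bC * r1 + bL * r2), 0.0)
    sigma2 = rss / df
    if sigma2 <= 0:
        return np.inf
    return bL * bL * det / (S11 * sigma2)


def cit_test(L, C, T, covariates=None, B_cond4=1000, seed=None, strict_dosage=False):
    """Run the four-component mediation test for one trio.

    Parameters
    ----------
    L, C, T
        Sample-aligned dosage and expression vectors.
    covariates
        CovariateSet, array, or None.
    B_cond4
        Permutations for the conditional-independence component.
    seed
        Seed for the component-4 permutation stream.

    Returns
    -------
    MediationResult (without the optional whole-test permutation p).
    """
    L = np.asarray(L, dtype=float)
    C = np.asarray(C, dtype=float)
    T = np.asarray(T, dtype=float)
    n = L.size
    if C.size != n or T.size != n:
        raise ValueError("L, C, T must have equal length")
    if np.std(L) == 0:
        raise ValueError("L is constant; not a valid eQTL variant")
    if np.std(C) == 0 or np.std(T) == 0:
        raise ValueError("constant expression vector (C or T)")
    classes = genotype_classes(L, strict=strict_dosage)
    X = _covariate_matrix(covariates, n)
    G = design_with_intercept(X if X.shape[1] else None, n=n)
    m = G.shape[1]

    # components 1-3 (single-df F tests = squared t tests)
    beta_T, se_T, _, p1, _ = coef_test(T, np.column_stack([G, L]), m)
    _, _, _, p2, _ = coef_test(C, np.column_stack([G, T, L]), m + 1)
    full = np.column_stack([G, L, C])
    _, _, _, p3, _ = coef_test(T, full, m + 1)
    beta_Tadj, se_Tadj, _, _, _ = coef_test(T, np.column_stack([G, C, L]), m + 1)

    # component 4: equivalence-style permutation test of L _||_ T | C
    Q, project = residualizer(G)
    Tt = project(T)
    Lt = project(L)
    e = project(C)  # residuals of C on [1, X]; fitted part lies in span(G)
    df = n - (m + 2)
    if df <= 0:
        raise ValueError("not enough samples for the mediation design")
    F_obs = _f_two_predictors(Tt, e, Lt, df)

    rng = np.random.default_rng(seed)
    # canonical ordering keeps the draws invariant to sample relabeling
    E = _permute_within_classes(e, classes, B_cond4, rng, canonical=True)
    Et = E - (E @ Q) @ Q.T  # re-orthogonalize permuted residuals against G
    S11 = np.einsum("bn,bn->b", Et, Et)
    S12 = Et @ Lt
    r1 = Et @ Tt
    S22 = float(Lt @ Lt)
    r2 = float(Lt @ Tt)
    Tss = float(Tt @ Tt)
    det = S11 * S22 - S12 * S12
    with np.errstate(divide="ignore", invalid="ignore"):
        bC = (S22 * r1 - S12 * r2) / det
        bL = (S11 * r2 - S12 * r1) / det
        rss = np.maximum(Tss - (bC * r1 + bL * r2), 0.0)
        sigma2 = rss / df
        F_perm = np.where(
            (det > 0) & (sigma2 > 0), bL * bL * det / (S11 * sigma2), np.inf
        )
    p4 = permutation_pvalue(int(np.count_nonzero(F_perm <= F_obs)), B_cond4)

    return MediationResult(
        p1=p1,
        p2=p2,
        p3=p3,
        p4=p4,
        beta_T=beta_T,
        se_T=se_T,
        beta_Tadj=beta_Tadj,
        se_Tadj=se_Tadj,
        M=mediated_proportion(beta_T, beta_Tadj),
        B_cond4=B_cond4,
    )


def mediated_proportion(beta_T, beta_Tadj):
    """Mediated proportion M = (beta_T - beta_Tadj) / beta_T.

    Returns NaN (an "undefined" flag, not an exception) when beta_T is
    exactly zero. M is not clamped: values outside [0, 1] are meaningful
    diagnostics (suppression / inflation).
    """
    if beta_T == 0:
        return float("nan")
    return (beta_T - beta_Tadj) / beta_T


def trans_effect_attenuation(L, C, T, covariates=None):
    """Marginal and C-adjusted trans-eQTL slopes, with standard errors.

    Returns ``((beta_T, se_T), (beta_Tadj, se_Tadj))`` from
    ``T ~ X + L`` and ``T ~ X + C + L``.
    """
    L = np.asarray(L, dtype=float)
    n = L.size
    X = _covariate_matrix(covariates, n)
    G = design_with_intercept(X if X.shape[1] else None, n=n)
    m = G.shape[1]
    beta_T, se_T, _, _, _ = coef_test(np.asarray(T, float), np.column_stack([G, L]), m)
    beta_Tadj, se_Tadj, _, _, _ = coef_test(
        np.asarray(T, float), np.column_stack([G, C, L]), m + 1
    )
    return (beta_T, se_T), (beta_Tadj, se_Tadj)


def permutation_robustness(
    L,
    C,
    T,
    covariates,
    p_observed,
    B=1000,
    B_cond4=1000,
    seed=None,
    strict_dosage=False,
    tie_rule="le",
):
    """Genotype-stratified permutation p-value for the omnibus test.

    For each of B permutations, trans-gene expression T is shuffled
    across samples *within* each genotype class of L (classes with fewer
    than 2 members stay fixed), all other measurements held fixed; the
    full omnibus mediation p-value is recomputed; and

        p_perm = (1 + #{p*_b as or more extreme than p_observed}) / (B + 1).

    "As or more extreme" is ``<=`` by default (``tie_rule="lt"`` for
    strict). The within-class multiset of T values is preserved by
    construction. Class members are canonically ordered by T value before
    shuffling, so relabeling samples within a genotype class does not
    change the draws.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if tie_rule not in ("le", "lt"):
        raise ValueError("tie_rule must be 'le' or 'lt'")
    L = np.asarray(L, dtype=float)
    T = np.asarray(T, dtype=float)
    classes = genotype_classes(L, strict=strict_dosage)
    ss = np.random.SeedSequence(seed)
    perm_seed, *child = ss.spawn(B + 1)
    rng = np.random.default_rng(perm_seed)
    T_perms = _permute_within_classes(T, classes, B, rng, canonical=True)
    count = 0
    for b in range(B):
        res = cit_test(
            L, C, T_perms[b], covariates, B_cond4=B_cond4, seed=child[b],
            strict_dosage=strict_dosage,
        )
        pb = res.p_omnibus
        if (pb <= p_observed) if tie_rule == "le" else (pb < p_observed):
            count += 1
    return permutation_pvalue(count, B)
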