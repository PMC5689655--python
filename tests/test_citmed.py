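"""Mediation machinery: component tests against statsmodels, the
intersection-union identity, the mediated proportion M, and the
genotype-stratified permutation scheme."""

import numpy as np
import pandas as pd
import pytest

import cismediator as cm
from cismediator import citmed
from cismediator.studies import (
    measurement_error_study,
    mediation_error_study,
    simulate_trio_dataset,
)


@pytest.fixture(scope="module")
def mediated_trio():
    sc = cm.TrioScenario(n_samples=1000, n_background_genes=0)
    g, e, cov, _ = simulate_trio_dataset(sc, seed=31)
    return (
        g.dosage_of("rs_L"),
        e.expression_of("CIS_GENE"),
        e.expression_of("TRANS_GENE"),
        cov,
    )


class TestComponents:
    def test_omnibus_is_max_of_components(self, mediated_trio):
        L, C, T, cov = mediated_trio
        res = cm.cit_test(L, C, T, cov, B_cond4=200, seed=0)
        assert res.p_omnibus == max(res.p1, res.p2, res.p3, res.p4)

    def test_component_pvalues_match_statsmodels(self, mediated_trio):
        import statsmodels.api as sm

        L, C, T, cov = mediated_trio
        res = cm.cit_test(L, C, T, cov, B_cond4=10, seed=0)
        X = cov.matrix()

        def sm_p(y, cols):
            design = sm.add_constant(np.column_stack(cols))
            return sm.OLS(y, design).fit().pvalues[-1]

        assert np.isclose(res.p1, sm_p(T, [X, L]), rtol=1e-8)
        assert np.isclose(res.p2, sm_p(C, [X, T, L]), rtol=1e-8)
        assert np.isclose(res.p3, sm_p(T, [X, L, C]), rtol=1e-8)

    def test_betaT_matches_scan_convention(self, mediated_trio):
        L, C, T, cov = mediated_trio
        res = cm.cit_test(L, C, T, cov, B_cond4=10, seed=0)
        (bT, seT), (bTadj, seTadj) = cm.trans_effect_attenuation(L, C, T, cov)
        assert np.isclose(res.beta_T, bT)
        assert np.isclose(res.beta_Tadj, bTadj)
        assert seT > 0 and seTadj > 0

    def test_constant_inputs_rejected(self):
        n = 50
        L = np.repeat([0.0, 1.0], 25)
        with pytest.raises(ValueError, match="constant"):
            cm.cit_test(L, np.ones(n), np.random.default_rng(0).normal(size=n))
        with pytest.raises(ValueError, match="genotype|constant"):
            cm.cit_test(np.ones(n), np.random.default_rng(0).normal(size=n),
                        np.random.default_rng(1).normal(size=n))

    def test_bit_exact_reproducibility(self, mediated_trio):
        L, C, T, cov = mediated_trio
        r1 = cm.cit_test(L, C, T, cov, B_cond4=300, seed=99)
        r2 = cm.cit_test(L, C, T, cov, B_cond4=300, seed=99)
        assert (r1.p1, r1.p2, r1.p3, r1.p4) == (r2.p1, r2.p2, r2.p3, r2.p4)


class TestMediatedProportion:
    @pytest.mark.parametrize(
        "bT,bTadj,expected",
        [(0.10, 0.05, 0.5), (0.3, 0.0, 1.0), (-0.10, -0.02, 0.8)],
    )
    def test_arithmetic(self, bT, bTadj, expected):
        assert np.isclose(cm.mediated_proportion(bT, bTadj), expected)

    def test_undefined_flag_not_exception(self):
        assert np.isnan(cm.mediated_proportion(0.0, 0.1))

    def test_two_decimal_rounded_inputs_stay_near_reported_value(self):
        # a strongly mediated trans effect of 0.21 attenuated to 0.10:
        # M from the 2-dp inputs is 0.52, within 0.05 of the 0.55 obtained
        # from unrounded effects
        assert abs(cm.mediated_proportion(0.21, 0.10) - 0.55) <= 0.05


class TestPermutationMachinery:
    def test_pvalue_floor(self):
        assert cm.permutation_pvalue(0, 100_000) == pytest.approx(1.0e-5, rel=0.01)
        assert f"{cm.permutation_pvalue(0, 100_000):.1e}" == "1.0e-05"
        with pytest.raises(ValueError):
            cm.permutation_pvalue(0, 0)

    def test_observed_p_of_one_gives_pperm_one(self):
        sc = cm.TrioScenario(n_samples=300, a=0, b=0, d=0, n_background_genes=0)
        g, e, cov, _ = simulate_trio_dataset(sc, seed=5)
        p = cm.permutation_robustness(
            g.dosage_of("rs_L"), e.expression_of("CIS_GENE"),
            e.expression_of("TRANS_GENE"), cov,
            p_observed=1.0, B=20, B_cond4=50, seed=0,
        )
        assert p == 1.0

    def test_permutation_preserves_class_multisets(self):
        rng = np.random.default_rng(0)
        L = rng.integers(0, 3, 200).astype(float)
        T = rng.normal(size=200)
        classes = citmed.genotype_classes(L)
        perms = citmed._permute_within_classes(T, classes, 50, rng)
        for c in np.unique(classes):
            idx = classes == c
            for b in range(50):
                assert np.isclose(perms[b, idx].mean(), T[idx].mean())
                assert np.allclose(np.sort(perms[b, idx]), np.sort(T[idx]))

    def test_pperm_invariant_to_within_class_relabeling(self):
        sc = cm.TrioScenario(n_samples=200, n_background_genes=0)
        g, e, cov, _ = simulate_trio_dataset(sc, seed=8)
        L = g.dosage_of("rs_L")
        C = e.expression_of("CIS_GENE")
        T = e.expression_of("TRANS_GENE")
        X = cov.matrix()
        res = cm.cit_test(L, C, T, X, B_cond4=100, seed=1)
        args = dict(p_observed=res.p_omnibus, B=30, B_cond4=100, seed=7)
        p_a = cm.permutation_robustness(L, C, T, X, **args)
        # swap two samples in the same genotype class (entire rows)
        classes = citmed.genotype_classes(L)
        i, j = np.flatnonzero(classes == 1)[:2]
        perm = np.arange(len(L))
        perm[[i, j]] = perm[[j, i]]
        p_b = cm.permutation_robustness(L[perm], C[perm], T[perm], X[perm], **args)
        assert p_a == p_b

    def test_genotype_classes_strict_flag(self):
        with pytest.raises(ValueError, match="non-integer"):
            citmed.genotype_classes(np.array([0.0, 0.5, 1.0, 2.0]), strict=True)
        classes = citmed.genotype_classes(np.array([0.1, 0.9, 1.9, 0.0]))
        assert list(classes) == [0, 1, 2, 0]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="one genotype class"):
            citmed.genotype_classes(np.zeros(10))


class TestOperatingCharacteristics:
    def test_component4_power_and_specificity(self):
        med = mediation_error_study("mediated", n_replicates=100, n_samples=1000,
                                    B_cond4=500, seed=41)
        direct = mediation_error_study("direct", n_replicates=100, n_samples=1000,
                                       B_cond4=500, seed=42)
        assert med["component_rejection"][3] > 0.8
        assert direct["component_rejection"][3] <= 0.1

    def test_attenuation_limits(self):
        # complete mediation: adjusted slope ~ 0, M ~ 1 (averaged over
        # replicates; a single draw of M has sd ~ 0.04 at n = 5000)
        sc = cm.TrioScenario(n_samples=5000, n_background_genes=0)
        Ms, inside = [], 0
        for r in range(10):
            g, e, cov, _ = simulate_trio_dataset(sc, seed=5100 + r)
            L = g.dosage_of("rs_L")
            (bT, _), (bTadj, seTadj) = cm.trans_effect_attenuation(
                L, e.expression_of("CIS_GENE"), e.expression_of("TRANS_GENE"), cov
            )
            inside += abs(bTadj) < 3 * seTadj
            Ms.append(cm.mediated_proportion(bT, bTadj))
        assert inside >= 9
        assert abs(np.mean(Ms) - 1.0) < 0.1
        # no mediation (direct effect only): adjusted ~ marginal, M ~ 0
        sc2 = cm.TrioScenario(n_samples=5000, a=0.5, b=0.0, d=0.5,
                              n_background_genes=0)
        g2, e2, cov2, _ = simulate_trio_dataset(sc2, seed=52)
        (bT2, seT2), (bTadj2, _) = cm.trans_effect_attenuation(
            g2.dosage_of("rs_L"), e2.expression_of("CIS_GENE"),
            e2.expression_of("TRANS_GENE"), cov2
        )
        assert abs(bT2 - bTadj2) < 3 * seT2
        assert abs(cm.mediated_proportion(bT2, bTadj2)) < 0.15

    def test_measurement_error_attenuates_M(self):
        out = measurement_error_study(n_replicates=60, n_samples=1000, seed=61)
        assert out["mean_M_noisy"] < out["mean_M_clean"]
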