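"""Normality gate, test selection, oracles, post-hocs, morphometry."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from synapkit import (compare_groups, density_per_area, dunn_test,
                      mannwhitney_exact_oracle, normality_gate)
from synapkit.stats import Branch
from synapkit.stats import TestKind as TK  # alias avoids pytest collection


def dagostino_k2(x):
    """Direct evaluation of the published K^2 statistic (test oracle)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    m = x.mean()
    m2 = ((x - m) ** 2).mean()
    m3 = ((x - m) ** 3).mean()
    m4 = ((x - m) ** 4).mean()
    # skewness transform (D'Agostino)
    b1 = m3 / m2 ** 1.5
    y = b1 * np.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = (3.0 * (n**2 + 27 * n - 70) * (n + 1) * (n + 3)
             / ((n - 2.0) * (n + 5) * (n + 7) * (n + 9)))
    w2 = -1.0 + np.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / np.sqrt(0.5 * np.log(w2))
    alpha = np.sqrt(2.0 / (w2 - 1.0))
    z1 = delta * np.log(y / alpha + np.sqrt((y / alpha) ** 2 + 1.0))
    # kurtosis transform (Anscombe-Glynn)
    b2 = m4 / m2 ** 2
    eb2 = 3.0 * (n - 1) / (n + 1)
    vb2 = 24.0 * n * (n - 2) * (n - 3) / ((n + 1) ** 2 * (n + 3) * (n + 5))
    xx = (b2 - eb2) / np.sqrt(vb2)
    sqrtbeta1 = (6.0 * (n**2 - 5 * n + 2) / ((n + 7.0) * (n + 9))
                 * np.sqrt(6.0 * (n + 3) * (n + 5)
                           / (n * (n - 2.0) * (n - 3))))
    a = 6.0 + 8.0 / sqrtbeta1 * (2.0 / sqrtbeta1
                                 + np.sqrt(1.0 + 4.0 / sqrtbeta1**2))
    z2 = ((1.0 - 2.0 / (9.0 * a))
          - ((1.0 - 2.0 / a) / (1.0 + xx * np.sqrt(2.0 / (a - 4.0))))
          ** (1.0 / 3.0)) / np.sqrt(2.0 / (9.0 * a))
    return z1**2 + z2**2


class TestNormalityGate:
    def test_k2_statistic_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        for dist in (rng.normal(0, 1, 150), rng.lognormal(0, 1, 150),
                     rng.uniform(0, 1, 120)):
            assert sps.normaltest(dist).statistic == pytest.approx(
                dagostino_k2(dist), abs=1e-9)

    def test_k2_power_on_lognormal(self):
        """Lognormal(0,1) samples of n=150 rejected with power > 0.9."""
        rng = np.random.default_rng(10)
        rejections = sum(
            sps.normaltest(rng.lognormal(0, 1, 150)).pvalue < 0.05
            for _ in range(200))
        assert rejections / 200 > 0.9

    def test_lognormal_group_routes_to_mann_whitney(self):
        rng = np.random.default_rng(1)
        groups = {"a": rng.normal(1, 0.1, 75), "b": rng.lognormal(0, 1, 75)}
        plan = normality_gate(groups)
        assert plan.gate_applied
        assert plan.branch is Branch.NONPARAMETRIC
        assert plan.test is TK.MANN_WHITNEY

    def test_small_n_experiments_skip_gate_select_t(self):
        """N=3 experiments, small n: gate not applied, unpaired t chosen."""
        plan = normality_gate({"a": [1.0, 2, 3], "b": [2.0, 3, 4]},
                              n_experiments=3)
        assert not plan.gate_applied
        assert plan.test is TK.T_UNPAIRED

    def test_single_group_selects_one_sample_branch(self):
        rng = np.random.default_rng(2)
        plan = normality_gate({"norm": rng.lognormal(0, 1, 120) * 100})
        assert plan.test in (TK.ONE_SAMPLE_T,
                             TK.ONE_SAMPLE_WILCOXON)
        assert plan.test is TK.ONE_SAMPLE_WILCOXON  # lognormal data

    def test_gate_skipped_below_validity_floor(self):
        plan = normality_gate({"a": [1.0, 2, 3], "b": [2.0, 3, 4]},
                              n_experiments=10)
        assert not plan.gate_applied
        assert "floor" in plan.gate_skipped_reason

    def test_multigroup_tests_selected_by_branch(self):
        rng = np.random.default_rng(4)
        normal = {k: rng.normal(0, 1, 50) for k in "abc"}
        skewed = {k: rng.lognormal(0, 1, 50) for k in "abc"}
        assert normality_gate(normal).test is TK.ANOVA_TUKEY
        assert normality_gate(skewed).test is TK.KRUSKAL_DUNN


class TestCompareGroups:
    def test_mann_whitney_exact_small_sample(self):
        plan = normality_gate({"a": [1.0] * 5, "b": [1.0] * 5},
                              n_experiments=None)
        plan.test = TK.MANN_WHITNEY
        res = compare_groups({"a": [1, 2, 3, 4, 5], "b": [6, 7, 8, 9, 10]},
                             plan)
        assert res.p_value == pytest.approx(2 / 252, abs=1e-12)

    def test_identical_groups_rank_p_one(self):
        plan = normality_gate({"a": [5.0] * 6, "b": [5.0] * 6})
        plan.test = TK.MANN_WHITNEY
        res = compare_groups({"a": [5.0] * 6, "b": [5.0] * 6}, plan)
        assert res.p_value == 1.0

    def test_one_sample_tests_against_reference(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(100, 5, 20)
        plan = normality_gate({"g": vals})
        res = compare_groups({"g": vals}, plan, reference_value=100.0)
        assert 0.0 <= res.p_value <= 1.0
        with pytest.raises(ValueError, match="reference"):
            compare_groups({"g": vals}, plan)

    def test_anova_limiting_behaviour(self):
        plan = normality_gate({"a": [0.0] * 5, "b": [0.0] * 5, "c": [0.0] * 5})
        plan.test = TK.ANOVA_TUKEY
        with pytest.raises(ValueError, match="undefined"):
            compare_groups({"a": [1.0] * 5, "b": [1.0] * 5, "c": [1.0] * 5},
                           plan)
        jitter = {k: np.full(5, i) + np.arange(5) * 1e-9
                  for i, k in enumerate("abc")}
        res = compare_groups(jitter, plan)
        assert res.p_value < 1e-12
        assert (res.posthoc["p_adjusted"] < 1e-6).all()

    def test_oracle_agreement_exhaustive_n5(self):
        """compare_groups exact MW == enumeration oracle to 1e-12."""
        rng = np.random.default_rng(8)
        plan = normality_gate({"a": np.arange(5.0), "b": np.arange(5.0) + 9})
        plan.test = TK.MANN_WHITNEY
        for _ in range(25):
            vals = rng.permutation(1000)[:10].astype(float)
            a, b = vals[:5], vals[5:]
            res = compare_groups({"a": a, "b": b}, plan)
            assert res.p_value == pytest.approx(
                mannwhitney_exact_oracle(a, b), abs=1e-12)


class TestExactOracle:
    def test_hand_enumerated_two_by_two(self):
        assert mannwhitney_exact_oracle([1, 2], [3, 4]) == pytest.approx(2 / 6)

    def test_symmetric_under_group_swap(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 4), rng.normal(1, 1, 5)
        assert mannwhitney_exact_oracle(a, b) == pytest.approx(
            mannwhitney_exact_oracle(b, a), abs=1e-15)

    def test_enumeration_cap(self):
        with pytest.raises(ValueError, match="cap"):
            mannwhitney_exact_oracle(np.arange(7), np.arange(7))


class TestPosthocs:
    def test_adjusted_p_never_below_unadjusted(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            groups = {k: rng.normal(i * 0.3, 1, 12)
                      for i, k in enumerate("abcd")}
            dn = dunn_test(groups)
            assert (dn["p_adjusted"] >= dn["p_unadjusted"] - 1e-15).all()
            plan = normality_gate(groups)
            plan.test = TK.ANOVA_TUKEY
            ph = compare_groups(groups, plan).posthoc
            assert (ph["p_adjusted"] >= ph["p_unadjusted"] - 1e-12).all()

    def test_dunn_pair_count(self):
        groups = {k: np.arange(6.0) + i for i, k in enumerate("abcd")}
        assert len(dunn_test(groups)) == 6


class TestDensity:
    def test_density_arithmetic(self):
        rec = pd.DataFrame({"synapse_id": [0, 1], "bouton_area": [0.5, 1.0],
                            "svs": [50, 10]})
        s = density_per_area(rec, "svs")
        assert list(s.densities) == [100.0, 10.0]

    def test_all_zero_counts(self):
        rec = pd.DataFrame({"bouton_area": [1.0] * 4, "svs": [0] * 4})
        s = density_per_area(rec, "svs")
        assert s.mean == 0.0 and s.sem == 0.0

    def test_zero_area_rejected_with_report(self):
        rec = pd.DataFrame({"bouton_area": [1.0, 0.0, 2.0],
                            "svs": [5, 7, 10]})
        s = density_per_area(rec, "svs")
        assert len(s.rejected) == 1 and s.n == 2

    def test_order_invariance(self):
        rng = np.random.default_rng(13)
        rec = pd.DataFrame({"bouton_area": rng.uniform(0.2, 1.5, 40),
                            "svs": rng.poisson(40, 40)})
        s1 = density_per_area(rec, "svs")
        s2 = density_per_area(rec.sample(frac=1, random_state=1), "svs")
        assert s1.mean == pytest.approx(s2.mean)
        assert s1.sem == pytest.approx(s2.sem)
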