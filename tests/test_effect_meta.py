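import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metaexpr.core import GroupStats
from metaexpr.effect_meta import (EffectSize, beggs_test, cohort_effect,
                                  funnel_points, hedges_g, hedges_g_effect,
                                  leave_one_out, pool, subgroup_pool)
from metaexpr.synthetic import SyntheticConfig, generate


def eff(g, var, cid=""):
    return EffectSize(cohort_id=cid, g=g, var_g=var)


class TestHedgesG:
    def test_hand_example(self):
        e = hedges_g_effect(GroupStats(3, 2.0, 1.0), GroupStats(3, 4.0, 1.0))
        assert e.g == pytest.approx(-1.6)
        assert e.var_g == pytest.approx(0.88)

    def test_equal_means_zero_effect(self):
        e = hedges_g_effect(GroupStats(5, 3.0, 1.2), GroupStats(7, 3.0, 0.8))
        assert e.g == 0.0
        assert e.var_g == pytest.approx((5 + 7) / (5 * 7))

    def test_swapping_groups_flips_sign_keeps_variance(self):
        a, b = GroupStats(4, 2.5, 1.1), GroupStats(6, 4.0, 0.9)
        e1, e2 = hedges_g_effect(a, b), hedges_g_effect(b, a)
        assert e1.g == pytest.approx(-e2.g)
        assert e1.var_g == pytest.approx(e2.var_g)

    def test_zero_pooled_sd_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate variance"):
            hedges_g(GroupStats(3, 1.0, 0.0), GroupStats(3, 2.0, 0.0))


class TestPool:
    def test_two_study_closed_form(self):
        res = pool([eff(0.0, 1.0), eff(2.0, 1.0)])
        assert res.Q == pytest.approx(2.0)
        assert res.df == 1
        assert res.i2 == pytest.approx(0.5)
        assert res.tau2 == pytest.approx(1.0)
        assert res.fixed.pooled == pytest.approx(1.0)
        assert res.random.pooled == pytest.approx(1.0)
        assert res.model == "fixed"  # I2 = 0.5 is not > 0.5

    def test_identical_effects_are_homogeneous(self):
        res = pool([eff(0.7, 0.2)] * 4)
        assert res.Q == pytest.approx(0.0, abs=1e-12)
        assert res.i2 == 0.0 and res.tau2 == 0.0
        assert res.pooled == pytest.approx(0.7)

    def test_equal_variances_reduce_to_mean(self):
        g = [0.1, 0.5, -0.3, 0.8]
        res = pool([eff(x, 0.4) for x in g])
        assert res.fixed.pooled == pytest.approx(np.mean(g))

    def test_bruteforce_oracle_small_k(self):
        rng = np.random.default_rng(42)
        for k in (2, 3, 4):
            g = rng.normal(size=k)
            v = rng.uniform(0.1, 2.0, size=k)
            res = pool([eff(gi, vi) for gi, vi in zip(g, v)])
            w = 1 / v
            mu = sum(wi * gi for wi, gi in zip(w, g)) / sum(w)
            q = sum(wi * (gi - mu) ** 2 for wi, gi in zip(w, g))
            tau2 = max(0.0, (q - (k - 1)) / (sum(w) - sum(wi**2 for wi in w) / sum(w)))
            assert res.Q == pytest.approx(q, abs=1e-12)
            assert res.tau2 == pytest.approx(tau2, abs=1e-12)

    def test_requires_two_effects(self):
        with pytest.raises(ValueError):
            pool([eff(0.0, 1.0)])

    def test_simulation_recovery_k40(self):
        cfg = SyntheticConfig(n_cohorts=40, n_case=30, n_control=30,
                              n_genes=5, n_pos_ceg=0, n_neg_ceg=0,
                              n_up_deg=0, n_down_deg=0,
                              true_smd=-0.5, tau=0.0, seed=3)
        cohorts, _, _ = generate(cfg)
        res = pool([cohort_effect(c, "MAOA") for c in cohorts])
        assert res.pooled == pytest.approx(-0.5, abs=0.1)

    @given(st.lists(st.tuples(st.floats(-3, 3), st.floats(0.05, 5)),
                    min_size=2, max_size=12))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_invariants(self, pairs):
        res = pool([eff(g, v) for g, v in pairs])
        assert 0.0 <= res.i2 < 1.0
        assert res.tau2 >= 0.0
        assert sum(res.weights) == pytest.approx(1.0)
        fixed_width = res.fixed.ci95[1] - res.fixed.ci95[0]
        random_width = res.random.ci95[1] - res.random.ci95[0]
        assert random_width >= fixed_width - 1e-12


class TestLeaveOneOut:
    def test_count_and_tags(self):
        effects = [eff(0.1, 0.5, "a"), eff(0.2, 0.5, "b"), eff(0.3, 0.5, "c")]
        out = leave_one_out(effects)
        assert [r.omitted for r in out] == ["a", "b", "c"]

    def test_identical_effects_all_equal(self):
        out = leave_one_out([eff(0.4, 0.3, str(i)) for i in range(5)])
        assert all(r.pooled == pytest.approx(0.4) for r in out)

    def test_omitting_central_cohort_stays_in_ci(self):
        effects = [eff(0.0, 0.2, "lo"), eff(0.5, 0.2, "mid"), eff(1.0, 0.2, "hi")]
        full = pool(effects)
        omitted_mid = [r for r in leave_one_out(effects) if r.omitted == "mid"][0]
        lo, hi = full.ci95
        assert lo <= omitted_mid.pooled <= hi


class TestSubgroups:
    def test_single_category_matches_pool(self):
        effects = [eff(0.1, 0.5, "a"), eff(0.3, 0.4, "b")]
        sub = subgroup_pool(effects, {"a": "x", "b": "x"})
        assert sub["x"].pooled == pytest.approx(pool(effects).pooled)

    def test_singleton_category_warned_and_dropped(self):
        effects = [eff(0.1, 0.5, "a"), eff(0.3, 0.4, "b"), eff(0.2, 0.3, "c")]
        with pytest.warns(UserWarning, match="single cohort"):
            sub = subgroup_pool(effects, {"a": "x", "b": "x", "c": "y"})
        assert set(sub) == {"x"}

    def test_planted_subgroup_ordering(self):
        effects = []
        labels = {}
        for name, smd, seed in [("weak", -0.2, 5), ("strong", -0.8, 6)]:
            cfg = SyntheticConfig(n_cohorts=6, n_case=40, n_control=40,
                                  n_genes=5, n_pos_ceg=0, n_neg_ceg=0,
                                  n_up_deg=0, n_down_deg=0,
                                  true_smd=smd, tau=0.0, seed=seed)
            cohorts, _, _ = generate(cfg)
            for c in cohorts:
                e = cohort_effect(c, "MAOA")
                e = EffectSize(cohort_id=f"{name}_{e.cohort_id}", g=e.g,
                               var_g=e.var_g)
                effects.append(e)
                labels[e.cohort_id] = name
        sub = subgroup_pool(effects, labels)
        assert sub["strong"].pooled < sub["weak"].pooled < 0


class TestBeggAndFunnel:
    def test_all_variances_equal_is_degenerate(self):
        tau, p, flag = beggs_test([eff(0.1, 0.5), eff(0.4, 0.5), eff(0.2, 0.5)])
        assert (tau, p, flag) == (0.0, 1.0, True)

    def test_symmetric_funnel_not_biased(self):
        effects = []
        for i, v in enumerate([0.3, 0.6, 1.0, 1.5]):
            se = math.sqrt(v)
            effects.append(eff(+se, v, f"p{i}"))
            effects.append(eff(-se, v, f"m{i}"))
        tau, p, flag = beggs_test(effects)
        assert not flag
        assert p > 0.5

    def test_funnel_points_one_row_per_cohort(self):
        effects = [eff(0.1, 0.5, "a"), eff(0.4, 0.6, "b"), eff(0.2, 0.7, "c")]
        table = funnel_points(effects)
        assert len(table) == 3
        assert table["se_g"].tolist() == pytest.approx(
            [math.sqrt(0.5), math.sqrt(0.6), math.sqrt(0.7)])
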