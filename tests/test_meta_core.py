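import math

import numpy as np
import pytest
from statsmodels.stats.meta_analysis import combine_effects

from snpmeta import (ContrastTable, EffectEstimate, cochran_q, dl_tau2,
                     i_squared, meta_analyse, pool_fixed, pool_fixed_mh,
                     pool_random, select_model, study_log_or, z_test)
from snpmeta.errors import (EstimationError, HeterogeneityUndefinedError,
                            InsufficientStudiesError)


def table(a, b, c, d, model="dominant"):
    return ContrastTable(model=model, a=a, b=b, c=c, d=d)


def effects(*pairs):
    return [EffectEstimate(f"s{i}", th, se) for i, (th, se) in enumerate(pairs)]


class TestStudyLogOr:
    def test_symmetric_table_gives_or_one(self):
        e = study_log_or(table(10, 10, 10, 10))
        assert e.log_or == 0.0 and e.odds_ratio == 1.0 and not e.corrected

    def test_hand_cross_product_and_woolf_variance(self):
        e = study_log_or(table(20, 10, 10, 20))
        assert e.odds_ratio == pytest.approx(4.0)
        assert e.log_or == pytest.approx(math.log(4), abs=1e-6)
        assert e.se == pytest.approx(math.sqrt(0.3), abs=1e-9)
        assert e.ci_low == pytest.approx(math.exp(e.log_or - 1.959964 * e.se))
        assert e.ci_low < e.odds_ratio < e.ci_high

    def test_zero_cell_triggers_haldane_anscombe_correction(self):
        e = study_log_or(table(0, 10, 10, 10))
        assert e.corrected
        assert e.log_or == pytest.approx(
            math.log(0.5 * 10.5 / (10.5 * 10.5)))

    def test_empty_arm_is_estimation_error(self):
        with pytest.raises(EstimationError, match="empty arm"):
            study_log_or(table(0, 0, 10, 10), study_id="sX")


class TestFixedPooling:
    def test_single_study_identity(self):
        e = effects((0.7, 0.3))
        assert pool_fixed(e) == (pytest.approx(0.7), pytest.approx(0.3))

    def test_hand_inverse_variance(self):
        lo, se = pool_fixed(effects((0.0, 0.5), (1.0, 0.5)))
        assert lo == pytest.approx(0.5)
        assert se == pytest.approx(1 / math.sqrt(8))

    def test_m_copies_shrink_se_by_sqrt_m(self):
        one = effects((0.4, 0.2))
        four = effects(*[(0.4, 0.2)] * 4)
        lo1, se1 = pool_fixed(one)
        lo4, se4 = pool_fixed(four)
        assert lo4 == pytest.approx(lo1)
        assert se4 == pytest.approx(se1 / 2)

    def test_empty_collection_is_usage_error(self):
        with pytest.raises(InsufficientStudiesError):
            pool_fixed([])

    def test_matches_statsmodels_combine_effects(self):
        rng = np.random.default_rng(17)
        th = rng.normal(0.2, 0.4, 12)
        var = rng.uniform(0.02, 0.3, 12)
        eff = [EffectEstimate(f"s{i}", float(t), float(math.sqrt(v)))
               for i, (t, v) in enumerate(zip(th, var))]
        res = combine_effects(th, var, method_re="dl")
        lo, se = pool_fixed(eff)
        assert lo == pytest.approx(res.mean_effect_fe, rel=1e-10)
        assert se == pytest.approx(res.sd_eff_w_fe, rel=1e-10)
        q, _ = cochran_q(eff)
        tau2 = dl_tau2(eff, q)
        assert tau2 == pytest.approx(res.tau2, rel=1e-8)
        lo_r, se_r = pool_random(eff, tau2)
        assert lo_r == pytest.approx(res.mean_effect_re, rel=1e-10)


class TestHeterogeneity:
    def test_identical_studies_give_q_zero(self):
        q, p_h = cochran_q(effects((0.3, 0.2), (0.3, 0.2), (0.3, 0.2)))
        assert q == pytest.approx(0.0, abs=1e-12)
        assert p_h == pytest.approx(1.0)

    def test_hand_q_and_tau2(self):
        eff = effects((0.0, 0.5), (1.0, 0.5))
        q, p_h = cochran_q(eff)
        assert q == pytest.approx(2.0)
        assert p_h == pytest.approx(0.157, abs=1e-3)
        assert dl_tau2(eff, q) == pytest.approx(0.25)  # c = 8 - 32/8 = 4

    def test_single_study_heterogeneity_undefined(self):
        with pytest.raises(HeterogeneityUndefinedError):
            cochran_q(effects((0.5, 0.2)))

    @pytest.mark.parametrize("q, k, expected", [
        (0.0, 5, 0.0), (2.0, 2, 0.5), (0.5, 3, 0.0)])
    def test_i_squared(self, q, k, expected):
        assert i_squared(q, k) == pytest.approx(expected)

    def test_tau2_truncates_at_zero_when_q_below_df(self):
        eff = effects((0.30, 0.5), (0.31, 0.5), (0.29, 0.5))
        q, _ = cochran_q(eff)
        assert q < 2
        assert dl_tau2(eff, q) == 0.0


class TestRandomPooling:
    def test_tau2_zero_degenerates_to_fixed(self):
        eff = effects((0.0, 0.5), (1.0, 0.5), (0.4, 0.3))
        assert pool_random(eff, 0.0) == pool_fixed(eff)

    def test_hand_random_effects(self):
        lo, se = pool_random(effects((0.0, 0.5), (1.0, 0.5)), tau2=0.25)
        assert lo == pytest.approx(0.5)
        assert se == pytest.approx(0.5)

    def test_single_study_se_inflated_by_tau(self):
        lo, se = pool_random(effects((0.4, 0.3)), tau2=0.16)
        assert lo == pytest.approx(0.4)
        assert se == pytest.approx(math.sqrt(0.09 + 0.16))

    def test_random_ci_at_least_as_wide_as_fixed(self):
        eff = effects((0.0, 0.5), (1.0, 0.4), (0.2, 0.3))
        tau2 = dl_tau2(eff)
        _, se_f = pool_fixed(eff)
        _, se_r = pool_random(eff, tau2)
        assert se_r >= se_f


class TestZTestAndModelSelection:
    def test_null_effect(self):
        assert z_test(0.0, 0.3) == (0.0, pytest.approx(1.0))

    def test_hand_z(self):
        z, p = z_test(0.5, 0.25)
        assert z == pytest.approx(2.0)
        assert p == pytest.approx(0.0455, abs=5e-4)

    def test_two_sided_symmetry(self):
        assert z_test(0.5, 0.25)[1] == pytest.approx(z_test(-0.5, 0.25)[1])

    @pytest.mark.parametrize("p_h, k, expected", [
        (0.3, 10, "fixed"), (0.001, 10, "random"), (0.001, 1, "fixed"),
        (float("nan"), 1, "fixed")])
    def test_heterogeneity_rule(self, p_h, k, expected):
        assert select_model(p_h, k) == expected


class TestMantelHaenszel:
    def test_single_table_hand_cross_product(self):
        or_mh, lo, hi = pool_fixed_mh([table(20, 10, 10, 20)])
        assert or_mh == pytest.approx(4.0)
        assert lo < 4.0 < hi

    def test_null_tables_pool_to_one(self):
        tabs = [table(10, 10, 10, 10), table(30, 15, 40, 20)]
        assert pool_fixed_mh(tabs)[0] == pytest.approx(1.0)


class TestPipelineInvariants:
    def test_arm_swap_negates_pooled_log_or_exactly(self):
        tabs = [table(20, 10, 12, 25), table(8, 30, 9, 28), table(15, 5, 9, 11)]
        swapped = [table(t.c, t.d, t.a, t.b) for t in tabs]
        pooled = meta_analyse([study_log_or(t) for t in tabs])
        pooled_sw = meta_analyse([study_log_or(t) for t in swapped])
        assert pooled_sw.log_or == pytest.approx(-pooled.log_or, abs=1e-14)
        assert pooled_sw.se == pytest.approx(pooled.se, abs=1e-14)

    def test_fixed_ci_never_wider_than_narrowest_study_ci(self):
        eff = effects((0.1, 0.5), (0.2, 0.2), (0.3, 0.4))
        _, se = pool_fixed(eff)
        assert se <= min(e.se for e in eff)

    def test_meta_analyse_selects_random_under_heterogeneity(self):
        eff = effects((0.0, 0.1), (1.5, 0.1), (3.0, 0.1))
        pooled = meta_analyse(eff)
        assert pooled.model_used == "random"
        assert pooled.tau2 > 0
        eff_h = effects((0.49, 0.3), (0.50, 0.3), (0.51, 0.3))
        assert meta_analyse(eff_h).model_used == "fixed"
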