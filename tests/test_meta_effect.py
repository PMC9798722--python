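"""SMD, heterogeneity, DL pooling, subgroups, sensitivity, Begg, Fisher z."""

import math

import numpy as np
import pytest
from statsmodels.stats.meta_analysis import combine_effects

from cohortmeta import meta_effect
from cohortmeta.types import CorrelationStudy, GroupSummary, StudyEffect


def effect(estimate, variance, label=""):
    half = 1.96 * math.sqrt(variance)
    return StudyEffect(
        estimate=estimate, variance=variance,
        ci_low=estimate - half, ci_high=estimate + half, label=label,
    )


class TestSmd:
    def test_ihc_cohort_cohen_d_matches_published_value(self):
        summary = GroupSummary(n1=110, mean1=6.83, sd1=1.56, n0=47, mean0=2.15, sd0=1.46)
        result = meta_effect.smd(summary, "cohen")
        assert result.estimate == pytest.approx(3.054, abs=0.01)
        assert result.ci_low == pytest.approx(2.572, abs=0.01)
        assert result.ci_high == pytest.approx(3.536, abs=0.01)

    def test_equal_means_give_zero(self):
        summary = GroupSummary(n1=10, mean1=5.0, sd1=1.0, n0=10, mean0=5.0, sd0=2.0)
        assert meta_effect.smd(summary).estimate == 0.0

    def test_hedges_small_sample_factor(self):
        summary = GroupSummary(n1=10, mean1=1.0, sd1=1.0, n0=10, mean0=0.0, sd0=1.0)
        result = meta_effect.smd(summary, "hedges")
        assert result.estimate == pytest.approx(1.0 * (1 - 3 / 71), rel=1e-12)

    def test_antisymmetric_under_group_swap(self, rng):
        for _ in range(20):
            n1, n0 = rng.integers(3, 40, size=2)
            m1, m0 = rng.normal(size=2)
            s1, s0 = rng.uniform(0.5, 2.0, size=2)
            fwd = meta_effect.smd(GroupSummary(n1, m1, s1, n0, m0, s0))
            rev = meta_effect.smd(GroupSummary(n0, m0, s0, n1, m1, s1))
            assert fwd.estimate == pytest.approx(-rev.estimate, rel=1e-12)
            assert fwd.variance == pytest.approx(rev.variance, rel=1e-12)

    def test_both_sds_zero_is_an_error(self):
        with pytest.raises(ValueError, match="SMD undefined"):
            meta_effect.smd(GroupSummary(5, 1.0, 0.0, 5, 0.0, 0.0))


class TestHeterogeneity:
    def test_identical_effects_give_zero(self):
        effects = [effect(1.0, 0.5) for _ in range(4)]
        Q, df, p, I2 = meta_effect.heterogeneity(effects)
        assert Q == pytest.approx(0.0, abs=1e-12)
        assert I2 == 0.0 and df == 3

    def test_hand_computed_two_study_case(self):
        Q, df, p, I2 = meta_effect.heterogeneity([effect(0.0, 1.0), effect(2.0, 1.0)])
        assert Q == pytest.approx(2.0)
        assert df == 1 and I2 == pytest.approx(0.5)

    def test_i2_clamped_to_unit_interval(self, rng):
        for _ in range(30):
            k = rng.integers(2, 8)
            effects = [effect(rng.normal(), rng.uniform(0.1, 2)) for _ in range(k)]
            _, _, _, I2 = meta_effect.heterogeneity(effects)
            assert 0.0 <= I2 < 1.0

    def test_fewer_than_two_studies_error(self):
        with pytest.raises(ValueError):
            meta_effect.heterogeneity([effect(1.0, 1.0)])


class TestPool:
    def test_dersimonian_laird_hand_example(self):
        # effects {0,2}, variances {1,1}: tau2 = 1, pooled = 1, se = 1
        result = meta_effect.pool([effect(0.0, 1.0), effect(2.0, 1.0)], "random")
        assert result.tau2 == pytest.approx(1.0)
        assert result.pooled == pytest.approx(1.0)
        assert result.se == pytest.approx(1.0)

    def test_homogeneous_random_reduces_to_fixed(self):
        effects = [effect(1.2, v) for v in (0.3, 0.5, 0.8)]
        random = meta_effect.pool(effects, "random")
        fixed = meta_effect.pool(effects, "fixed")
        assert random.tau2 == 0.0
        assert random.pooled == pytest.approx(fixed.pooled, rel=1e-12)
        assert random.se == pytest.approx(fixed.se, rel=1e-12)

    def test_pooled_estimate_within_study_range(self, rng):
        for model in ("fixed", "random"):
            for _ in range(20):
                k = rng.integers(2, 9)
                effects = [effect(rng.normal(), rng.uniform(0.05, 2)) for _ in range(k)]
                result = meta_effect.pool(effects, model)
                estimates = [e.estimate for e in effects]
                assert min(estimates) - 1e-12 <= result.pooled <= max(estimates) + 1e-12

    def test_auto_model_selection_rule(self):
        # homogeneous -> fixed; wildly heterogeneous -> random
        assert meta_effect.pool([effect(1.0, 1.0), effect(1.1, 1.0)], "auto").model == "fixed"
        assert (
            meta_effect.pool([effect(0.0, 0.01), effect(3.0, 0.01)], "auto").model
            == "random"
        )

    def test_agrees_with_statsmodels_combine_effects(self, rng):
        """Independent cross-check of fixed and DL pooling."""
        for _ in range(10):
            k = int(rng.integers(3, 10))
            e = rng.normal(size=k)
            v = rng.uniform(0.05, 1.0, size=k)
            ours_fixed = meta_effect.pool([effect(a, b) for a, b in zip(e, v)], "fixed")
            ours_random = meta_effect.pool([effect(a, b) for a, b in zip(e, v)], "random")
            ref = combine_effects(e, v, method_re="dl")
            frame = ref.summary_frame()
            assert ours_fixed.pooled == pytest.approx(frame.loc["fixed effect", "eff"], rel=1e-8)
            # statsmodels leaves a negative DL tau2 unclipped; ours clips at 0
            assert ours_random.tau2 == pytest.approx(max(ref.tau2, 0.0), rel=1e-8, abs=1e-12)
            if ref.tau2 > 0:
                assert ours_random.pooled == pytest.approx(
                    frame.loc["random effect", "eff"], rel=1e-8
                )


class TestSubgroupPool:
    def test_all_same_label_equals_plain_pool(self):
        effects = [effect(e, 0.5) for e in (0.5, 1.0, 1.5)]
        per_label, overall = meta_effect.subgroup_pool(effects, ["x"] * 3)
        plain = meta_effect.pool(effects, "auto")
        assert per_label["x"].pooled == pytest.approx(plain.pooled)
        assert overall.pooled == pytest.approx(plain.pooled)

    def test_singleton_subgroup_reports_own_ci(self):
        single = effect(3.05, 0.06, "ihc")
        effects = [effect(1.0, 0.2, "a"), effect(2.0, 0.2, "b"), single]
        per_label, _ = meta_effect.subgroup_pool(effects, ["mrna", "mrna", "ihc"])
        assert per_label["ihc"].pooled == single.estimate
        assert per_label["ihc"].ci_low == pytest.approx(single.ci_low)
        assert per_label["ihc"].k == 1


class TestLeaveOneOut:
    def test_identical_effects_give_identical_results(self):
        effects = [effect(1.0, 0.4) for _ in range(3)]
        results = meta_effect.leave_one_out(effects)
        assert len(results) == 3
        assert len({round(r.pooled, 12) for r in results}) == 1

    def test_removing_outlier_moves_pooled_toward_rest(self):
        effects = [effect(1.0, 0.1), effect(1.1, 0.1), effect(0.9, 0.1), effect(5.0, 0.1)]
        results = meta_effect.leave_one_out(effects, "fixed")
        full = meta_effect.pool(effects, "fixed").pooled
        without_outlier = results[3].pooled
        assert abs(without_outlier - 1.0) < abs(full - 1.0)

    def test_k_below_three_errors(self):
        with pytest.raises(ValueError):
            meta_effect.leave_one_out([effect(1, 1), effect(2, 1)])


class TestBeggsTest:
    def test_hand_computed_concordant_case(self):
        # k=4, deviates perfectly concordant with variances, no ties:
        # P-Q = 6, z = (6-1)/sqrt(4*3*13/18) = 1.698
        effects = [effect(e, v) for e, v in zip([0.0, 1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0])]
        tau, z, p = meta_effect.beggs_test(effects)
        assert tau == pytest.approx(1.0)
        assert z == pytest.approx(5 / math.sqrt(4 * 3 * 13 / 18), rel=1e-9)
        assert p == pytest.approx(2 * (1 - 0.955435), abs=1e-3)

    def test_reversing_variance_order_flips_tau_sign(self):
        effects = [effect(e, v) for e, v in zip([0.0, 1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0])]
        reversed_v = [effect(e, v) for e, v in zip([0.0, 1.0, 2.0, 3.0], [4.0, 3.0, 2.0, 1.0])]
        tau_fwd, _, _ = meta_effect.beggs_test(effects)
        tau_rev, _, _ = meta_effect.beggs_test(reversed_v)
        assert tau_rev == pytest.approx(-tau_fwd)

    def test_k_below_three_errors(self):
        with pytest.raises(ValueError):
            meta_effect.beggs_test([effect(1, 1), effect(2, 1)])


class TestPoolCorrelations:
    def test_single_study_closed_form(self):
        result = meta_effect.pool_correlations([CorrelationStudy(r=0.5, n=30)])
        z = math.atanh(0.5)
        half = 1.959963984540054 / math.sqrt(27)
        assert result.pooled == pytest.approx(0.5, rel=1e-12)
        assert result.ci_low == pytest.approx(math.tanh(z - half), rel=1e-12)
        assert result.ci_high == pytest.approx(math.tanh(z + half), rel=1e-12)

    def test_equal_studies_pool_to_same_r(self):
        studies = [CorrelationStudy(r=0.5, n=40, label=str(i)) for i in range(3)]
        assert meta_effect.pool_correlations(studies).pooled == pytest.approx(0.5, rel=1e-12)

    def test_null_correlations_pool_to_zero(self):
        studies = [CorrelationStudy(r=0.0, n=25) for _ in range(4)]
        assert meta_effect.pool_correlations(studies).pooled == pytest.approx(0.0, abs=1e-15)

    def test_fisher_z_round_trip_precision(self, rng):
        for r in rng.uniform(-0.99, 0.99, size=50):
            assert math.tanh(math.atanh(r)) == pytest.approx(r, abs=1e-12)

    def test_invalid_r_rejected(self):
        with pytest.raises(ValueError):
            CorrelationStudy(r=1.0, n=30)


class TestParameterRecovery:
    def test_planted_smd_recovered_in_most_replicates(self):
        """Nine cohorts with the study's group sizes, true SMD 2.0: the DL
        random-effects pooled estimate lands in [1.6, 2.4] in >=90% of 200
        seeded replicates (run at 40 replicates here; the full 200 live in
        the acceptance suite)."""
        from cohortmeta.preprocess import summarize_group
        from cohortmeta.simulate import simulate_cohorts
        from tests.conftest import small_spec

        hits = 0
        for rep in range(40):
            cohorts, _ = simulate_cohorts(small_spec(seed=10_000 + rep, target_smd=2.0))
            effects = [
                meta_effect.smd(summarize_group(c, "TARGET")) for c in cohorts
            ]
            pooled = meta_effect.pool(effects, "random").pooled
            hits += 1.6 <= pooled <= 2.4
        assert hits >= 36
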