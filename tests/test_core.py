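"""Tail resolution, the test statistic, empirical nulls, and thresholds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rvkt.core import (
    DegenerateTraitWarning,
    NullDistribution,
    TailSpec,
    build_null,
    empirical_pvalue,
    format_pvalue,
    min_p_over_tails,
    null_support_summary,
    rejection_threshold,
    rvkt_statistic,
    select_tail,
    tail_count,
)
from rvkt.core import test_trait as score_trait
from rvkt.pedigree import compute_kinship
from rvkt.simulate import make_nuclear_families, make_sibpair_families


def make_null(values, fraction=0.02, n_tail=10, h2=0.4):
    spec = TailSpec(side="upper", fraction=fraction, n_tail=n_tail)
    return NullDistribution(tail=spec, h2=h2, values=np.asarray(values, float), seed=0)


class TestTailCount:
    @pytest.mark.parametrize(
        "n, fraction, expected",
        [
            (1481, 0.01, 15), (1481, 0.02, 30), (1481, 0.04, 59),
            (1481, 0.06, 89), (1481, 0.08, 118),
            (1482, 0.01, 15), (100, 0.04, 4), (1484, 0.01, 15),
        ],
    )
    def test_round_half_up(self, n, fraction, expected):
        assert tail_count(n, fraction) == expected

    def test_count_below_two_is_error(self):
        with pytest.raises(ValueError, match="undefined"):
            tail_count(100, 0.01)

    @given(n=st.integers(4, 5000), f=st.floats(0.002, 0.499))
    @settings(max_examples=200, deadline=None)
    def test_matches_decimal_round_half_up(self, n, f):
        import decimal

        exact = int(
            (decimal.Decimal(n) * decimal.Decimal(repr(f))).quantize(
                0, rounding=decimal.ROUND_HALF_UP
            )
        )
        if exact < 2:
            return
        assert tail_count(n, f) == exact


class TestSelectTail:
    def test_lower_tail_smallest_values(self):
        trait = pd.Series(
            np.arange(1, 101, dtype=float), index=[f"i{k:03d}" for k in range(100)]
        )
        spec = TailSpec.resolve("lower", 0.04, 100)
        assert select_tail(trait, spec) == ["i000", "i001", "i002", "i003"]

    def test_constant_trait_id_order_with_warning(self):
        trait = pd.Series(1.0, index=[f"i{k}" for k in range(10)])
        spec = TailSpec(side="upper", fraction=0.3, n_tail=3)
        with pytest.warns(DegenerateTraitWarning):
            ids = select_tail(trait, spec)
        assert ids == sorted(trait.index)[:3]

    def test_missing_values_excluded_before_counting(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=100)
        vals[:5] = np.nan
        trait = pd.Series(vals, index=[f"i{k:03d}" for k in range(100)])
        spec = TailSpec.resolve("upper", 0.08, int(trait.notna().sum()))
        assert spec.n_tail == 8  # round-half-up of 95 * 0.08 = 7.6
        assert len(select_tail(trait, spec)) == 8

    def test_too_few_nonmissing(self):
        trait = pd.Series([1.0, np.nan, np.nan])
        with pytest.raises(ValueError, match="non-missing"):
            select_tail(trait, TailSpec(side="upper", fraction=0.4, n_tail=2))


class TestStatistic:
    def test_whole_family_tail(self):
        ped = make_nuclear_families(30)
        K = compute_kinship(ped)
        # family 1 has the 4 largest values
        trait = pd.Series(0.0, index=ped.study_subject_ids)
        trait += pd.Series(
            np.linspace(-1, 0, len(trait)), index=sorted(trait.index)
        )
        trait.loc[["F0001_P1", "F0001_P2", "F0001_C1", "F0001_C2"]] = [5, 6, 7, 8]
        spec = TailSpec(side="upper", fraction=0.03, n_tail=4)
        assert rvkt_statistic(trait, spec, K) == pytest.approx(1.25 / 6)

    def test_unrelated_tail_is_zero(self):
        ped = make_sibpair_families(20)
        K = compute_kinship(ped)
        trait = pd.Series(
            [k if i.endswith("C1") else 100.0 + k
             for k, i in enumerate(ped.study_subject_ids)],
            index=ped.study_subject_ids, dtype=float,
        )
        # top 10 values are the C2 sibs of 10 different families
        spec = TailSpec(side="upper", fraction=0.25, n_tail=10)
        top = select_tail(trait, spec)
        assert len({i.split("_")[0] for i in top}) == 10
        assert rvkt_statistic(trait, spec, K) == 0.0

    def test_rank_invariance_under_monotone_transform(self):
        ped = make_nuclear_families(25)
        K = compute_kinship(ped)
        rng = np.random.default_rng(3)
        trait = pd.Series(rng.normal(size=100), index=ped.study_subject_ids)
        spec = TailSpec(side="upper", fraction=0.08, n_tail=8)
        s1 = rvkt_statistic(trait, spec, K)
        s2 = rvkt_statistic(np.exp(trait * 2) + 7, spec, K)
        assert s1 == s2


class TestBuildNull:
    def test_sibpair_null_on_lattice(self):
        ped = make_sibpair_families(100)
        K = compute_kinship(ped)
        spec = TailSpec.resolve("upper", 0.05, 200)  # 10-subject tail
        null = build_null(ped, K, 0.4, [spec], n_replicates=500, seed=1)[spec]
        lattice = 0.25 / (10 * 9 / 2)
        k = null.values / lattice
        assert np.allclose(k, np.round(k), atol=1e-9)

    def test_shared_replicates_across_tails(self):
        # identical seeds: the 2% tail statistic is built from the same trait
        # draws as the 1% tail, so the 1%-tail members are a subset
        ped = make_nuclear_families(50)
        K = compute_kinship(ped)
        s1 = TailSpec.resolve("upper", 0.01, 200)
        s2 = TailSpec.resolve("upper", 0.02, 200)
        nulls = build_null(ped, K, 0.4, [s1, s2], n_replicates=300, seed=5)
        again = build_null(ped, K, 0.4, [s1], n_replicates=300, seed=5)
        assert np.array_equal(nulls[s1].values, again[s1].values)

    def test_replicate_floor(self):
        ped = make_nuclear_families(5)
        K = compute_kinship(ped)
        with pytest.raises(ValueError, match="100"):
            build_null(ped, K, 0.4, [("upper", 0.2)], n_replicates=50)


class TestEmpiricalPvalue:
    def test_observation_beyond_all_null(self):
        null = make_null(np.linspace(0, 0.1, 10_000))
        assert empirical_pvalue(0.5, null) == 0.0
        assert format_pvalue(0.0, 10_000) == "<0.0001"

    def test_observation_at_null_minimum(self):
        null = make_null(np.linspace(0.01, 0.1, 1000))
        assert empirical_pvalue(0.01, null) == 1.0

    def test_four_of_ten_thousand(self):
        values = np.concatenate([np.zeros(9996), np.full(4, 0.08)])
        assert empirical_pvalue(0.08, make_null(values)) == pytest.approx(0.0004)

    def test_monotone_in_observation(self):
        rng = np.random.default_rng(7)
        null = make_null(rng.exponential(size=2000))
        obs = np.sort(rng.exponential(size=50))
        ps = [empirical_pvalue(o, null) for o in obs]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestMinPOverTails:
    def _result(self, p, fraction, side="upper"):
        from rvkt.core import RvktResult

        return RvktResult(
            trait="t", tail=TailSpec(side=side, fraction=fraction, n_tail=10),
            observed_stat=0.0, p_value=p, tail_member_ids=list("abcdefghij"),
            expected_stat=0.0, null_ci=(0.0, 0.0), n_replicates=100,
        )

    def test_selects_smallest_p(self):
        rs = [self._result(p, f) for p, f in [(0.2, 0.01), (0.05, 0.02), (0.3, 0.04)]]
        assert min_p_over_tails(rs, "upper").tail.fraction == 0.02

    def test_tie_prefers_smaller_fraction(self):
        rs = [self._result(0.1, f) for f in (0.01, 0.02, 0.04)]
        assert min_p_over_tails(rs, "upper").tail.fraction == 0.01

    def test_single_result_identity(self):
        rs = [self._result(0.7, 0.08)]
        assert min_p_over_tails(rs, "upper") is rs[0]


class TestRejectionThreshold:
    def test_exact_size_available(self):
        values = np.concatenate([np.zeros(950), np.full(30, 0.1), np.full(20, 0.2)])
        rule = rejection_threshold(make_null(values), alpha=0.05)
        assert rule.feasible
        assert rule.threshold == pytest.approx(0.1)
        assert rule.size == pytest.approx(0.05)

    def test_infeasible_reports_minimum_size(self):
        values = np.concatenate([np.zeros(983), np.full(17, 0.2)])
        rule = rejection_threshold(make_null(values), alpha=0.01)
        assert not rule.feasible
        assert rule.min_size == pytest.approx(0.017)
        with pytest.raises(ValueError, match="0.017"):
            rule.rejects(0.5)

    def test_alpha_near_one(self):
        # rejecting at the null minimum always has exceedance size 1.0, so
        # the threshold settles on the second-smallest distinct value
        values = np.concatenate([np.full(500, 0.01), np.full(500, 0.3)])
        rule = rejection_threshold(make_null(values), alpha=0.999999)
        assert rule.threshold == pytest.approx(0.3)
        assert rule.size == pytest.approx(0.5)

    def test_type_one_error_on_fresh_null(self):
        """Size on independent replicates stays within the binomial bound."""
        ped = make_nuclear_families(60)
        K = compute_kinship(ped)
        spec = TailSpec.resolve("upper", 0.04, 240)
        null = build_null(ped, K, 0.4, [spec], n_replicates=4000, seed=21)[spec]
        rule = rejection_threshold(null, alpha=0.05)
        fresh = build_null(ped, K, 0.4, [spec], n_replicates=4000, seed=22)[spec]
        rate = np.mean([rule.rejects(v) for v in fresh.values])
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 4000)

    def test_pvalues_conservative_on_fresh_null(self):
        """Empirical p on fresh null draws is stochastically >= uniform."""
        ped = make_sibpair_families(80)
        K = compute_kinship(ped)
        spec = TailSpec.resolve("upper", 0.05, 160)
        null = build_null(ped, K, 0.4, [spec], n_replicates=2000, seed=31)[spec]
        fresh = build_null(ped, K, 0.4, [spec], n_replicates=2000, seed=32)[spec]
        ps = np.array([empirical_pvalue(v, null) for v in fresh.values])
        for alpha in (0.01, 0.05, 0.1, 0.25, 0.5):
            se = np.sqrt(alpha * (1 - alpha) / len(ps))
            assert (ps <= alpha).mean() <= alpha + 3 * se


class TestNullSupportSummary:
    def test_continuous_null_all_distinct(self):
        rng = np.random.default_rng(5)
        null = make_null(rng.random(1000))
        assert null_support_summary(null, 0.2) == 200

    def test_constant_null(self):
        assert null_support_summary(make_null(np.zeros(1000)), 0.2) == 1

    def test_sibpair_lattice_counts_realized_points(self):
        ped = make_sibpair_families(100)
        K = compute_kinship(ped)
        spec = TailSpec.resolve("upper", 0.05, 200)
        null = build_null(ped, K, 0.4, [spec], n_replicates=1000, seed=9)[spec]
        m = 200
        top = np.sort(null.values)[-m:]
        lattice = 0.25 / 45
        expected = len({int(round(v / lattice)) for v in top})
        assert null_support_summary(null, 0.2) == expected


class TestTestTrait:
    def test_end_to_end_with_planted_relatedness(self):
        ped = make_nuclear_families(80)
        K = compute_kinship(ped)
        subjects = ped.study_subject_ids
        tails = [TailSpec.resolve("upper", 0.05, len(subjects))]
        nulls = build_null(ped, K, 0.4, tails, n_replicates=500, seed=41)
        rng = np.random.default_rng(42)
        trait = pd.Series(rng.normal(size=len(subjects)), index=subjects)
        # plant four whole families in the upper tail
        for fam in ("F0001", "F0002", "F0003", "F0004"):
            for member in ("P1", "P2", "C1", "C2"):
                trait.loc[f"{fam}_{member}"] += 10
        res = score_trait(trait, K, nulls, trait_name="planted")[0]
        assert res.p_value <= 1 / 500 + 1e-12
        assert set(f"F000{k}_P1" for k in (1, 2, 3, 4)) <= set(res.tail_member_ids)
        assert res.observed_stat > res.null_ci[1]
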