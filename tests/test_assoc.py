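"""Unit and property tests for the single-SNP association statistics."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gwascreen.assoc import (
    GenotypeCounts,
    HaplotypeCounts,
    MetaStudy,
    allelic_or,
    assoc_table,
    call_rate,
    catt_test,
    compute_maf,
    fixed_effects_meta,
    genotypic_chi2_test,
    hwe_exact_test,
    ld_r2,
)

triples = st.tuples(
    st.integers(0, 60), st.integers(0, 60), st.integers(0, 60)
).filter(lambda t: sum(t) >= 1)


def hwe_exact_oracle(hom_min: int, het: int, hom_maj: int) -> Fraction:
    """Exact-arithmetic HWE p-value: conditional probability of each
    heterozygote configuration computed with integer factorials."""
    n = hom_min + het + hom_maj
    na = 2 * hom_min + het
    if na == 0 or na == 2 * n:
        return Fraction(1)
    f = math.factorial
    denom = Fraction(f(2 * n), f(na) * f(2 * n - na))

    def prob(h: int) -> Fraction:
        hm = (na - h) // 2
        return Fraction(f(n) * 2**h, f(hm) * f(h) * f(n - hm - h)) / denom

    ps = {h: prob(h) for h in range(na % 2, min(na, 2 * n - na) + 1, 2)}
    p_obs = ps[het]
    return sum(p for p in ps.values() if p <= p_obs)


class TestMafAndCallRate:
    @pytest.mark.parametrize(
        "triple, expected, places",
        [
            ((176, 477, 335), 0.4195, 4),
            ((19, 207, 762), 0.124, 3),
            ((0, 0, 500), 0.0, 10),
            ((500, 0, 0), 1.0, 10),
        ],
    )
    def test_known_values(self, triple, expected, places):
        assert round(compute_maf(triple), places) == expected

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            compute_maf((0, 0, 0))

    @pytest.mark.parametrize(
        "genotyped, total, expected",
        [(2520, 2521, 0.9996), (988, 988, 1.0), (0, 10, 0.0)],
    )
    def test_call_rate(self, genotyped, total, expected):
        assert round(call_rate(genotyped, total), 4) == expected

    def test_call_rate_bad_inputs(self):
        with pytest.raises(ValueError):
            call_rate(1, 0)
        with pytest.raises(ValueError):
            call_rate(11, 10)


class TestTrendTest:
    def test_identical_distributions_null(self):
        res = catt_test((10, 20, 10), (10, 20, 10))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_monomorphic_returns_unit_p_with_flag(self):
        with pytest.warns(UserWarning):
            res = catt_test((0, 0, 10), (0, 0, 20))
        assert res == (0.0, 1.0, True)

    @given(case=triples, control=triples)
    @settings(max_examples=100, deadline=None)
    def test_reversal_invariance_and_range(self, case, control):
        """Simultaneously reversing genotype order in both groups (i.e.
        swapping which allele is called minor) leaves the trend test
        unchanged, and p is always in (0, 1]."""
        a = catt_test(case, control)
        b = catt_test(case[::-1], control[::-1])
        assert a.statistic == pytest.approx(b.statistic, rel=1e-9, abs=1e-9)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-9, abs=1e-12)
        assert 0 < a.p_value <= 1

    def test_statistic_equals_n_times_squared_correlation(self):
        """Brute-force oracle: the trend chi-square equals N * r^2 where r
        is the Pearson correlation between allele dose and case status over
        the expanded individual-level sample (50 random small tables)."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            case = tuple(int(x) for x in rng.integers(1, 30, 3))
            control = tuple(int(x) for x in rng.integers(1, 30, 3))
            got = catt_test(case, control).statistic
            dose = np.concatenate(
                [np.repeat([0, 1, 2], case), np.repeat([0, 1, 2], control)]
            )
            y = np.concatenate([np.ones(sum(case)), np.zeros(sum(control))])
            if dose.std() == 0:
                continue
            r = stats.pearsonr(dose, y).statistic
            assert got == pytest.approx(len(dose) * r * r, rel=1e-8)


class TestGenotypicTest:
    def test_proportional_rows_null(self):
        res = genotypic_chi2_test((30, 60, 30), (60, 120, 60))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.df == 2
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_summed_formula(self):
        case, control = (5, 5, 0), (0, 5, 5)
        obs = np.array([case, control], dtype=float)
        col = obs.sum(axis=0)
        row = obs.sum(axis=1)
        exp = np.outer(row, col) / obs.sum()
        hand = float(((obs - exp) ** 2 / exp).sum())
        res = genotypic_chi2_test(case, control)
        assert res.statistic == pytest.approx(hand, rel=1e-10)

    def test_empty_column_dropped_reduces_df(self):
        res = genotypic_chi2_test((10, 5, 0), (5, 10, 0))
        assert res.df == 1

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            genotypic_chi2_test((0, 10, 0), (0, 20, 0))


class TestHweExact:
    def test_two_minor_alleles_in_two_samples(self):
        # with 2 minor alleles among n=2 samples, het in {0, 2} with null
        # probabilities 1/3 and 2/3; observing het=0 gives p = 1/3
        assert hwe_exact_test((1, 0, 1)) == pytest.approx(1 / 3)

    def test_monomorphic_is_one(self):
        assert hwe_exact_test((0, 0, 200)) == 1.0
        assert hwe_exact_test((200, 0, 0)) == 1.0

    @given(t=triples)
    @settings(max_examples=150, deadline=None)
    def test_matches_exact_arithmetic_oracle(self, t):
        """The float implementation agrees with an exact rational-arithmetic
        enumeration of the conditional null distribution."""
        expected = float(hwe_exact_oracle(*t))
        assert hwe_exact_test(t) == pytest.approx(expected, rel=1e-9, abs=1e-12)

    @given(t=triples)
    @settings(max_examples=80, deadline=None)
    def test_allele_swap_symmetry(self, t):
        assert hwe_exact_test(t) == pytest.approx(
            hwe_exact_test(t[::-1]), rel=1e-9
        )


class TestAllelicOr:
    def test_null_table_or_one(self):
        res = allelic_or((10, 20, 10), (10, 20, 10))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high
        assert not res.corrected

    def test_haldane_correction_on_zero_cell(self):
        res = allelic_or((10, 0, 0), (0, 0, 10))
        # all case alleles minor, all control alleles major
        assert res.corrected
        expected = (20.5 * 20.5) / (0.5 * 0.5)
        assert res.odds_ratio == pytest.approx(expected)

    @given(case=triples, control=triples, level=st.sampled_from([0.8, 0.9, 0.95, 0.99]))
    @settings(max_examples=100, deadline=None)
    def test_ci_brackets_point(self, case, control, level):
        res = allelic_or(case, control, level=level)
        assert res.ci_low <= res.odds_ratio <= res.ci_high
        assert res.odds_ratio == pytest.approx(math.exp(res.log_or))


class TestLdR2:
    @pytest.mark.parametrize(
        "h, expected",
        [
            (HaplotypeCounts(50, 0, 0, 50), 1.0),
            (HaplotypeCounts(25, 25, 25, 25), 0.0),
            (HaplotypeCounts(40, 10, 10, 40), 0.36),  # D=0.15, denom 0.0625
            (HaplotypeCounts(0, 30, 30, 0), 1.0),  # repulsion-phase perfect LD
        ],
    )
    def test_known_values(self, h, expected):
        assert ld_r2(h) == pytest.approx(expected)

    def test_monomorphic_locus_rejected(self):
        with pytest.raises(ValueError):
            ld_r2(HaplotypeCounts(50, 50, 0, 0))

    @given(
        counts=st.tuples(*(st.integers(0, 100),) * 4).filter(lambda t: sum(t) >= 1)
    )
    @settings(max_examples=150, deadline=None)
    def test_bounds_and_perfect_ld_characterization(self, counts):
        """r^2 is in [0,1] and equals 1 exactly when only two complementary
        haplotypes are present."""
        h = HaplotypeCounts(*counts)
        p_a = (h.AB + h.Ab) / h.total
        p_b = (h.AB + h.aB) / h.total
        if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
            with pytest.raises(ValueError):
                ld_r2(h)
            return
        r2 = ld_r2(h)
        assert 0.0 <= r2 <= 1.0
        complementary = (h.Ab == h.aB == 0 and h.AB > 0 and h.ab > 0) or (
            h.AB == h.ab == 0 and h.Ab > 0 and h.aB > 0
        )
        assert (r2 == pytest.approx(1.0)) == complementary


class TestMeta:
    def test_single_study_identity(self):
        s = MetaStudy("s1", 0.2355, 0.0542)
        res = fixed_effects_meta([s])
        assert res.pooled_log_or == pytest.approx(s.log_or)
        assert res.pooled_se == pytest.approx(s.se)

    def test_hand_weighted_mean(self):
        res = fixed_effects_meta(
            [MetaStudy("a", 0.2, 0.1), MetaStudy("b", 0.4, 0.2)]
        )
        assert res.pooled_log_or == pytest.approx(0.24)
        assert res.pooled_se == pytest.approx(1 / math.sqrt(125))

    @given(
        log_or=st.floats(-2, 2, allow_nan=False),
        se=st.floats(0.01, 1.0, allow_nan=False),
        k=st.integers(1, 8),
    )
    @settings(max_examples=60, deadline=None)
    def test_k_replicates_shrink_se_by_sqrt_k(self, log_or, se, k):
        studies = [MetaStudy(f"s{i}", log_or, se) for i in range(k)]
        res = fixed_effects_meta(studies)
        assert res.pooled_log_or == pytest.approx(log_or, rel=1e-9, abs=1e-12)
        assert res.pooled_se == pytest.approx(se / math.sqrt(k), rel=1e-9)
        assert res.pooled_se <= min(s.se for s in studies) + 1e-12
        assert res.ci_low <= res.or_pooled <= res.ci_high
        assert 0 < res.p <= 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fixed_effects_meta([])


class TestAssocTable:
    def test_duplicate_snp_id_rejected(self, rit2_rows):
        with pytest.raises(ValueError, match="duplicate"):
            assoc_table(rit2_rows + [rit2_rows[0]])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assoc_table([])

    def test_order_preserved_and_fields_consistent(self, rit2_rows):
        results = assoc_table(rit2_rows)
        assert [r.snp_id for r in results] == [g.snp_id for g in rit2_rows]
        for r in results:
            assert 0 < r.p_trend <= 1
            assert 0 < r.p_genotypic <= 1
            assert 0 < r.p_hwe_case <= 1
            assert r.ci_low <= r.or_allelic <= r.ci_high

    def test_null_synthetic_row_sane(self):
        gc = GenotypeCounts(
            "null1", "1", 100, "A", "G", (45, 210, 245), (55, 190, 255)
        )
        (r,) = assoc_table([gc])
        assert 0 < r.p_trend <= 1
        assert r.ci_low <= r.or_allelic <= r.ci_high
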