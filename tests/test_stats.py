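"""Exact binomial sex-ratio tests, median splits and correlation tests."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import radsexing as rs


def enumerated_p(k: int, n: int) -> Fraction:
    """Independent oracle: exact rational two-sided p at p0 = 1/2 by direct
    enumeration of all n+1 outcomes (point-probability convention)."""
    pmf = [Fraction(comb(n, i), 2 ** n) for i in range(n + 1)]
    return sum(p for p in pmf if p <= pmf[k])


class TestBinomTest:
    @pytest.mark.parametrize("k,n,expected", [
        (11, 13, 184 / 8192),
        (0, 10, 2 / 1024),
    ])
    def test_exact_rational_values(self, k, n, expected):
        assert rs.binom_test_two_sided(k, n).p_value == pytest.approx(expected, rel=1e-12)

    def test_center_outcome_gives_p_one(self):
        assert rs.binom_test_two_sided(34, 69).p_value == 1.0
        assert rs.binom_test_two_sided(35, 70).p_value == 1.0

    def test_matches_enumeration_for_all_small_cases(self):
        for n in range(1, 13):
            for k in range(n + 1):
                ours = rs.binom_test_two_sided(k, n).p_value
                exact = float(enumerated_p(k, n))
                assert ours == pytest.approx(exact, rel=1e-10), (k, n)

    def test_matches_scipy_binomtest(self):
        from scipy.stats import binomtest

        for k, n, p0 in [(905, 1936, 0.5), (948, 1750, 0.5), (7, 50, 0.2),
                         (40, 100, 0.3), (247, 460, 0.5)]:
            ours = rs.binom_test_two_sided(k, n, p0).p_value
            ref = binomtest(k, n, p0).pvalue
            assert ours == pytest.approx(ref, rel=1e-6)

    @given(st.integers(min_value=1, max_value=400).flatmap(
        lambda n: st.tuples(st.just(n), st.integers(min_value=0, max_value=n))))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_symmetry_at_half(self, nk):
        n, k = nk
        a = rs.binom_test_two_sided(k, n).p_value
        b = rs.binom_test_two_sided(n - k, n).p_value
        assert a == pytest.approx(b, rel=1e-12)
        assert 0.0 < a <= 1.0

    @pytest.mark.parametrize("k,n,p0", [(-1, 5, 0.5), (6, 5, 0.5),
                                        (1, 0, 0.5), (1, 5, 0.0), (1, 5, 1.0)])
    def test_invalid_inputs_rejected(self, k, n, p0):
        with pytest.raises((ValueError, TypeError)):
            rs.binom_test_two_sided(k, n, p0)

    def test_non_integer_rejected(self):
        with pytest.raises(TypeError):
            rs.binom_test_two_sided(2.5, 10)

    def test_conservative_type_i_error_at_n589(self):
        # exact test: rejection rate at alpha = 0.05 stays <= 0.055
        n = 589
        p_by_k = np.array([rs.binom_test_two_sided(k, n).p_value
                           for k in range(n + 1)])
        rng = np.random.default_rng(77)
        ks = rng.binomial(n, 0.5, size=10_000)
        rate = float((p_by_k[ks] < 0.05).mean())
        assert rate <= 0.055


class TestProportions:
    @pytest.mark.parametrize("k,n,expected", [
        (623, 1441, 0.432),
        (309, 589, 0.525),
        (653, 1081, 0.604),
        (0, 5, 0.000),
    ])
    def test_proportion_female_rounding(self, k, n, expected):
        assert round(rs.proportion_female(k_female=k, n=n), 3) == expected

    def test_from_records(self):
        records = pd.DataFrame({"sex": ["F", "F", "M"]})
        assert rs.proportion_female(records) == pytest.approx(2 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rs.proportion_female(k_female=0, n=0)


class TestGroupReport:
    def test_cohort_margins_reproduce_printed_rows(self):
        rows = []
        margins = {"young seedling": (23, 26), "seedling": (28, 26),
                   "juvenile": (247, 213), "adolescent": (11, 15)}
        for cohort, (f, m) in margins.items():
            rows += [{"sex": "F", "cohort": cohort}] * f
            rows += [{"sex": "M", "cohort": cohort}] * m
        report = rs.group_sexratio_report(pd.DataFrame(rows), "cohort")
        juv = report.set_index("group").loc["juvenile"]
        assert (juv["n_female"], juv["n_male"], juv["total"]) == (247, 213, 460)
        assert round(juv["p_value"], 2) == 0.12
        seedling = report.set_index("group").loc["seedling"]
        assert round(seedling["p_value"], 2) == 0.89

    def test_single_group_duplicates_overall_row(self):
        records = pd.DataFrame({"sex": ["F"] * 309 + ["M"] * 280, "all": "x"})
        report = rs.group_sexratio_report(records, "all")
        assert len(report) == 1
        assert round(report.iloc[0]["p_value"], 2) == 0.25
        assert round(report.iloc[0]["prop_female"], 3) == 0.525

    def test_per_mother_grouping(self):
        records = pd.DataFrame({
            "sex": ["F"] * 11 + ["M"] * 2 + ["F"] * 10 + ["M"] * 2,
            "mother_id": ["vdm1"] * 13 + ["cu1"] * 12,
        })
        report = rs.group_sexratio_report(records, "mother_id").set_index("group")
        assert round(report.loc["vdm1", "p_value"], 2) == 0.02
        assert round(report.loc["cu1", "p_value"], 2) == 0.04

    def test_missing_key_rejected(self):
        with pytest.raises(ValueError):
            rs.group_sexratio_report(pd.DataFrame({"sex": ["F"]}), "cohort")


class TestMedianSplit:
    def test_even_count_splits_in_half(self):
        df = pd.DataFrame({"v": [2, 4, 6, 8]})
        out = rs.median_split(df, "v", label_col="grp")
        assert sorted(out.loc[out["grp"] == "low", "v"]) == [2, 4]
        assert sorted(out.loc[out["grp"] == "high", "v"]) == [6, 8]

    def test_ties_at_median_go_low(self):
        df = pd.DataFrame({"v": [1.0, 21.9, 21.9, 30.0]})
        out = rs.median_split(df, "v", label_col="grp")
        assert (out.loc[out["v"] == 21.9, "grp"] == "low").all()

    def test_study_design_split_70_69(self):
        # 139 offspring with distinct pollen distances and median 21.9 m
        # partition into 70 "low" (<= median) and 69 "high"
        rng = np.random.default_rng(5)
        low = np.sort(rng.uniform(1, 21.8, size=69))
        high = np.sort(rng.uniform(22.0, 120, size=69))
        df = pd.DataFrame({"pollen_distance_m": np.concatenate([low, [21.9], high])})
        out = rs.median_split(df, "pollen_distance_m", label_col="grp")
        assert out.attrs["median"] == pytest.approx(21.9)
        assert (out["grp"] == "low").sum() == 70
        assert (out["grp"] == "high").sum() == 69

    def test_all_identical_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            rs.median_split(pd.DataFrame({"v": [3.0, 3.0, 3.0]}), "v")


class TestPearson:
    @pytest.mark.parametrize("r,n,expected", [(0.252, 58, 0.06), (-0.177, 58, 0.18)])
    def test_p_from_summary_statistics(self, r, n, expected):
        assert round(rs.p_from_r(r, n), 2) == expected

    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, df, p = rs.pearson_test(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert df == 8

    def test_matches_scipy_pearsonr(self):
        from scipy.stats import pearsonr

        rng = np.random.default_rng(3)
        x, y = rng.normal(size=40), rng.normal(size=40)
        r, df, p = rs.pearson_test(x, y)
        ref = pearsonr(x, y)
        assert r == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            rs.pearson_test([1, 1, 1, 1], [1, 2, 3, 4])


class TestSeedDimorphism:
    def test_constant_trait_gives_zero_se(self):
        df = pd.DataFrame({"sex": ["F"] * 4 + ["M"] * 4, "mass": 8.0})
        out = rs.seed_dimorphism_summary(df, "mass")
        assert (out["mean"] == 8.0).all()
        assert (out["se"] == 0.0).all()

    def test_study_design_sample_sizes(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({
            "sex": ["F"] * 23 + ["M"] * 26,
            "mass": np.concatenate([rng.normal(8.9, 1.9, 23),
                                    rng.normal(8.4, 2.5, 26)]),
        })
        out = rs.seed_dimorphism_summary(df, "mass").set_index("sex")
        assert out.loc["F", "n"] == 23 and out.loc["M", "n"] == 26
        vals = df.loc[df.sex == "F", "mass"]
        assert out.loc["F", "se"] == pytest.approx(vals.std(ddof=1) / np.sqrt(23))
        assert 0.0 < out.attrs["p_value"] <= 1.0

    def test_null_p_values_are_uniform(self):
        from scipy.stats import kstest

        ps = []
        rng = np.random.default_rng(123)
        for _ in range(200):
            df = pd.DataFrame({
                "sex": np.where(rng.uniform(size=200) < 0.5, "F", "M"),
                "mass": rng.normal(8.5, 2.0, size=200),
            })
            ps.append(rs.seed_dimorphism_summary(df, "mass").attrs["p_value"])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_single_sex_rejected(self):
        df = pd.DataFrame({"sex": ["F"] * 5, "mass": np.arange(5.0)})
        with pytest.raises(ValueError):
            rs.seed_dimorphism_summary(df, "mass")
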