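"""Privacy-rarefaction scan: exact small-case behaviour and invariances."""

import numpy as np
import pandas as pd
import pytest

import radsexing as rs
from conftest import presence_from_bool


class TestBuildPresenceMatrix:
    def test_thresholding(self):
        counts = pd.DataFrame([[0, 3], [5, 0]], index=["c1", "c2"], columns=["i1", "i2"])
        pm = rs.build_presence_matrix(counts)
        assert pm.matrix.tolist() == [[False, True], [True, False]]

    @pytest.mark.parametrize("count,min_reads,present",
                             [(0, 1, False), (1, 1, True), (1, 2, False)])
    def test_min_reads_boundary(self, count, min_reads, present):
        counts = pd.DataFrame([[count]], index=["c"], columns=["i"])
        pm = rs.build_presence_matrix(counts, min_reads=min_reads)
        assert pm.matrix[0, 0] == present

    def test_duplicate_ids_rejected(self):
        dup = pd.DataFrame([[1], [2]], index=["c", "c"], columns=["i"])
        with pytest.raises(ValueError):
            rs.build_presence_matrix(dup)
        dup2 = pd.DataFrame([[1, 2]], index=["c"], columns=["i", "i"])
        with pytest.raises(ValueError):
            rs.build_presence_matrix(dup2)

    def test_negative_counts_rejected(self):
        bad = pd.DataFrame([[-1]], index=["c"], columns=["i"])
        with pytest.raises(ValueError):
            rs.build_presence_matrix(bad)


class TestScan:
    def test_noiseless_planted_full_support(self, noiseless_cohort):
        truth, counts = noiseless_cohort
        pm = rs.build_presence_matrix(counts)
        res = rs.scan(pm, truth.sexes, n_boot=50, seed=1)
        (y,) = truth.y_loci
        yi = pm.contig_ids.index(y)
        for si in range(len(res.stringencies)):
            assert np.all(res.male_counts[si] == 1)
            assert np.all(res.female_counts[si] == 0)
            assert res.male_support[yi, si] == 1.0

    def test_enumeration_oracle_2m2f(self):
        # locus X present in both males and one of two females:
        # s=1 -> male-private in exactly 2 of the 4 equiprobable draws (the
        # two picking the absent female); s=2 -> 0 of the single draw
        pm = presence_from_bool([[1, 1, 1, 0]], ["m1", "m2", "f1", "f2"], ids=["X"])
        sexes = {"m1": "M", "m2": "M", "f1": "F", "f2": "F"}
        res = rs.scan(pm, sexes, exhaustive=True)
        assert res.male_support[0, 0] == 0.5
        assert res.male_support[0, 1] == 0.0
        assert list(res.male_counts[0]) == [0, 1, 0, 1]
        assert list(res.male_counts[1]) == [0]

    def test_monte_carlo_matches_exhaustive_within_3se(self):
        truth, counts = rs.simulate_cohort(4, 4, 60, n_y_loci=2,
                                           dropout_prob=0.3, seed=21)
        pm = rs.build_presence_matrix(counts)
        exact = rs.scan(pm, truth.sexes, exhaustive=True)
        n_boot = 2000
        mc = rs.scan(pm, truth.sexes, n_boot=n_boot, seed=22)
        for sup_e, sup_m in ((exact.male_support, mc.male_support),
                             (exact.female_support, mc.female_support)):
            se = np.sqrt(np.clip(sup_e * (1 - sup_e), 1e-12, None) / n_boot)
            # supports of 0/1 are deterministic; others within MC error
            fixed = (sup_e == 0) | (sup_e == 1)
            assert np.array_equal(sup_m[fixed], sup_e[fixed])
            z = np.abs(sup_m - sup_e) / se
            assert (z[~fixed] > 3).mean() <= 0.02  # multiplicity across cells
            assert np.all(z[~fixed] <= 6)

    def test_sex_swap_symmetry_is_exact(self):
        truth, counts = rs.simulate_cohort(5, 5, 80, n_y_loci=1,
                                           dropout_prob=0.25, seed=31)
        pm = rs.build_presence_matrix(counts)
        res = rs.scan(pm, truth.sexes, n_boot=80, seed=32)
        swapped = {i: ("F" if s == "M" else "M") for i, s in truth.sexes.items()}
        res_sw = rs.scan(pm, swapped, n_boot=80, seed=32)
        assert np.array_equal(res.male_support, res_sw.female_support)
        assert np.array_equal(res.female_support, res_sw.male_support)
        for a, b in zip(res.male_counts, res_sw.female_counts):
            assert np.array_equal(a, b)

    def test_label_invariance_under_reordering(self):
        truth, counts = rs.simulate_cohort(4, 4, 50, n_y_loci=1,
                                           dropout_prob=0.2, seed=41)
        res = rs.scan(rs.build_presence_matrix(counts), truth.sexes,
                      n_boot=60, seed=42)
        rng = np.random.default_rng(0)
        shuffled = counts.iloc[rng.permutation(len(counts)),
                               rng.permutation(counts.shape[1])]
        res2 = rs.scan(rs.build_presence_matrix(shuffled), truth.sexes,
                       n_boot=60, seed=42)
        order = [res2.contig_ids.index(c) for c in res.contig_ids]
        assert np.array_equal(res.male_support, res2.male_support[order])
        assert np.array_equal(res.female_support, res2.female_support[order])

    def test_null_curves_decay_and_sexes_indistinguishable(self):
        from scipy import stats as sps

        diffs = []
        for seed in range(30):
            truth, counts = rs.simulate_cohort(10, 10, 200, n_y_loci=0,
                                               dropout_prob=0.2, seed=100 + seed)
            res = rs.scan(rs.build_presence_matrix(counts), truth.sexes,
                          n_boot=100, seed=200 + seed)
            m, f = res.mean_counts()
            diffs.append(m.mean() - f.mean())
            # artefact counts decay with stringency (allow tiny MC wiggle)
            assert m[0] > m[-1] and f[0] > f[-1]
        signs = sum(d > 0 for d in diffs if d != 0)
        n = sum(1 for d in diffs if d != 0)
        p = rs.binom_test_two_sided(signs, n).p_value if n else 1.0
        assert p > 0.01  # paired sign test: no systematic male/female excess

    def test_max_stringency_validated(self, noiseless_cohort):
        truth, counts = noiseless_cohort
        pm = rs.build_presence_matrix(counts)
        with pytest.raises(ValueError):
            rs.scan(pm, truth.sexes, max_stringency=4)


class TestCandidateContigs:
    def test_noiseless_planted_passes_all_high_levels(self, noiseless_cohort):
        truth, counts = noiseless_cohort
        res = rs.scan(rs.build_presence_matrix(counts), truth.sexes,
                      n_boot=40, seed=3)
        cands = rs.candidate_contigs(res, min_support=0.5, min_stringency=3)
        (y,) = truth.y_loci
        assert list(cands["contig_id"]) == [y]
        assert cands.iloc[0]["sex"] == "M"
        assert cands.iloc[0]["passed_levels"] == (3,)  # S = 3 for a 3+3 cohort

    def test_support_just_below_threshold_excluded(self):
        pm = presence_from_bool([[1, 1, 1, 1, 1, 1]],
                                [f"m{i}" for i in range(3)] + [f"f{i}" for i in range(3)])
        res = rs.scan(pm, {f"m{i}": "M" for i in range(3)} |
                      {f"f{i}": "F" for i in range(3)}, n_boot=10, seed=1)
        object.__setattr__(res, "male_support", np.full_like(res.male_support, 0.49))
        assert rs.candidate_contigs(res).empty

    def test_support_below_min_stringency_does_not_count(self):
        pm = presence_from_bool([[1, 1, 1, 1, 1, 1]],
                                [f"m{i}" for i in range(3)] + [f"f{i}" for i in range(3)])
        res = rs.scan(pm, {f"m{i}": "M" for i in range(3)} |
                      {f"f{i}": "F" for i in range(3)}, n_boot=10, seed=1)
        sup = np.zeros_like(res.male_support)
        sup[0, 1] = 0.6  # level 2 only
        object.__setattr__(res, "male_support", sup)
        object.__setattr__(res, "female_support", np.zeros_like(sup))
        assert rs.candidate_contigs(res, min_stringency=3).empty


class TestClassifyHeterogamety:
    def test_planted_y_is_xy_like(self):
        truth, counts = rs.simulate_cohort(6, 6, 300, n_y_loci=3,
                                           dropout_prob=0.1, seed=51)
        res = rs.scan(rs.build_presence_matrix(counts), truth.sexes,
                      n_boot=100, seed=52)
        assert rs.classify_heterogamety(res)[0] == "XY-like"

    def test_planted_w_is_zw_like(self):
        truth, counts = rs.simulate_cohort(6, 6, 300, n_w_loci=3,
                                           dropout_prob=0.1, seed=53)
        res = rs.scan(rs.build_presence_matrix(counts), truth.sexes,
                      n_boot=100, seed=54)
        assert rs.classify_heterogamety(res)[0] == "ZW-like"

    def test_needs_three_levels(self):
        pm = presence_from_bool([[1, 0, 1, 0]], ["m1", "f1", "m2", "f2"])
        res = rs.scan(pm, {"m1": "M", "m2": "M", "f1": "F", "f2": "F"},
                      n_boot=5, seed=1)
        with pytest.raises(ValueError):
            rs.classify_heterogamety(res)


class TestIncidence:
    @pytest.mark.parametrize("mean_count,total,text", [
        (5.29, 94968, "0.0056 %"),
        (0.59, 38830, "0.0015 %"),
        (0.0, 1000, "0 %"),
    ])
    def test_incidence_formatting(self, mean_count, total, text):
        assert rs.format_incidence(100.0 * mean_count / total) == text

    def test_incidence_from_scan(self, noiseless_cohort):
        truth, counts = noiseless_cohort
        res = rs.scan(rs.build_presence_matrix(counts), truth.sexes,
                      n_boot=20, seed=5)
        # one planted Y locus in a 20-contig assembly, noiseless: 5 %
        assert rs.incidence_report(res, assembly_total=20) == pytest.approx(5.0)

    def test_total_must_be_positive(self, noiseless_cohort):
        truth, counts = noiseless_cohort
        res = rs.scan(rs.build_presence_matrix(counts), truth.sexes,
                      n_boot=5, seed=5)
        with pytest.raises(ValueError):
            rs.incidence_report(res, assembly_total=0)
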