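"""Sync I/O, SNP calling and filtering, heterozygosity/F_ST, genome scans and
multiple-testing machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from relaxev import poolseq, synth
from relaxev.phenostats import cmh_counts
from relaxev.poolseq import (SyncParseError, SyncTable, call_snps, cmh_scan,
                             correct, fst, glm_scan, group_mean_het,
                             merge_regions, permutation_threshold, read_sync,
                             rescale_coverage, storey_qvalues,
                             window_heterozygosity, write_sync)

from conftest import make_snp_table

GROUP_A, GROUP_B = [0, 1, 2, 3, 4], [5, 6, 7, 8, 9]


class TestSyncIO:
    def test_round_trip_identity(self, random_sync, tmp_path):
        path = tmp_path / "x.sync"
        write_sync(random_sync, path)
        back = read_sync(path)
        np.testing.assert_array_equal(back.counts, random_sync.counts)
        np.testing.assert_array_equal(back.pos, random_sync.pos)
        assert list(back.chrom) == list(random_sync.chrom)

    def test_count_string_semantics(self, tmp_path):
        path = tmp_path / "x.sync"
        path.write_text("2L\t17\tA\t12:0:30:0:0:0\t0:5:0:1:0:0\n")
        t = read_sync(path)
        assert t.counts[0, 0, 0] == 12 and t.counts[0, 0, 2] == 30  # A and C
        assert t.counts[0, 1, 1] == 5 and t.counts[0, 1, 3] == 1    # T and G
        assert t.n_pops == 2

    def test_ten_population_rows(self, tmp_path):
        path = tmp_path / "x.sync"
        path.write_text("3R\t5\tG\t" + "\t".join(["1:2:3:4:0:0"] * 10) + "\n")
        assert read_sync(path).n_pops == 10

    def test_malformed_line_reports_position(self, tmp_path):
        path = tmp_path / "bad.sync"
        path.write_text("2L\t1\tA\t1:2:3:4:0:0\n2L\t2\tA\t1:2:3\n")
        with pytest.raises(SyncParseError, match="line 2"):
            read_sync(path)


def _sync_from_counts(rows):
    """rows: list of per-population ACGT 4-tuples lists, one entry per site."""
    n = len(rows)
    npop = len(rows[0])
    counts = np.zeros((n, npop, 6), dtype=np.int64)
    for i, pops in enumerate(rows):
        for j, acgt in enumerate(pops):
            counts[i, j, :4] = acgt
    return SyncTable(chrom=np.array(["2L"] * n, dtype=object),
                     pos=np.arange(1, n + 1, dtype=np.int64),
                     ref=np.array(["A"] * n, dtype=object), counts=counts)


class TestCallSNPs:
    def test_low_coverage_population_discards_site(self):
        sync = _sync_from_counts([[(20, 5, 0, 0), (40, 10, 0, 0)]])  # pop 1 at 25x
        assert call_snps(sync).n_sites == 0
        sync_ok = _sync_from_counts([[(25, 5, 0, 0), (40, 10, 0, 0)]])
        assert call_snps(sync_ok).n_sites == 1

    def test_pooled_maf_boundary(self):
        # 5 pools at 200x, pooled coverage 1000: 19 minor reads -> MAF 0.019
        # discarded, 21 -> 0.021 retained
        lo = _sync_from_counts([[(196, 4, 0, 0)] * 4 + [(197, 3, 0, 0)]])
        hi = _sync_from_counts([[(196, 4, 0, 0)] * 4 + [(195, 5, 0, 0)]])
        assert call_snps(lo).n_sites == 0
        assert call_snps(hi).n_sites == 1

    def test_major_minor_and_tie_break(self):
        t = call_snps(_sync_from_counts([[(10, 40, 0, 0), (20, 30, 0, 0)]]))
        assert t.major[0] == "T" and t.minor[0] == "A"
        # exact tie between A and T -> alphabetical: A major
        t2 = call_snps(_sync_from_counts([[(25, 25, 0, 0), (25, 25, 0, 0)]]))
        assert t2.major[0] == "A" and t2.minor[0] == "T"

    def test_triallelic_collapsed_to_top_two_and_flagged(self):
        sync = _sync_from_counts([[(30, 15, 6, 0), (28, 14, 5, 0)]])
        t = call_snps(sync)
        assert t.triallelic[0]
        # brute-force recount oracle: top two alleles by summed counts
        totals = sync.counts[0, :, :4].sum(axis=0)
        order = np.argsort(-totals, kind="stable")
        assert t.major_counts[0].tolist() == sync.counts[0, :, order[0]].tolist()
        assert t.minor_counts[0].tolist() == sync.counts[0, :, order[1]].tolist()


class TestRescale:
    def test_exact_linear_scaling(self):
        t = make_snp_table([[0.4, 0.4]], coverage=100)
        r = rescale_coverage(t, target=50, min_cov=50, max_cov=200)
        assert (r.minor_counts == 20).all() and (r.major_counts == 30).all()

    def test_low_coverage_site_dropped(self):
        t = make_snp_table([[0.2, 0.2]], coverage=49)
        assert rescale_coverage(t).n_sites == 0

    def test_identity_at_target(self):
        t = make_snp_table([[17 / 50]], coverage=50)
        r = rescale_coverage(t)
        assert r.minor_counts[0, 0] == 17 and r.major_counts[0, 0] == 33

    def test_target_must_not_exceed_min(self):
        with pytest.raises(ValueError):
            rescale_coverage(make_snp_table([[0.5]]), target=60, min_cov=50)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(50, 200), st.integers(0, 200))
    def test_frequency_preserved_within_half_read(self, cov, k):
        k = min(k, cov)
        t = poolseq.SNPTable(
            chrom=np.array(["2L"], dtype=object), pos=np.array([1]),
            major=np.array(["A"], dtype=object), minor=np.array(["T"], dtype=object),
            major_counts=np.array([[cov - k]]), minor_counts=np.array([[k]]))
        r = rescale_coverage(t)
        assert r.n_sites == 1
        assert abs(r.minor_counts[0, 0] / 50 - k / cov) <= 1 / (2 * 50) + 1e-12


class TestHeterozygosityFst:
    def test_window_values(self):
        t = make_snp_table([[0.5], [0.5]], coverage=50)
        w = window_heterozygosity(t)
        assert w["het0"].iloc[0] == pytest.approx(0.5)
        # monomorphic-in-population site contributes 0
        t2 = make_snp_table([[1.0], [0.5]], coverage=50)
        assert window_heterozygosity(t2)["het0"].iloc[0] == pytest.approx(0.25)
        # mixed window of frequencies 0.5, 0.9, 0.7 -> mean(0.5, 0.18, 0.42)
        t3 = make_snp_table([[0.5], [0.9], [0.7]], coverage=100)
        assert window_heterozygosity(t3)["het0"].iloc[0] == pytest.approx(
            np.mean([0.5, 0.18, 0.42]), abs=1e-12)

    def test_windows_are_half_open_150kb(self):
        t = poolseq.SNPTable(
            chrom=np.array(["2L", "2L"], dtype=object),
            pos=np.array([150_000, 150_001]),
            major=np.array(["A", "A"], dtype=object),
            minor=np.array(["T", "T"], dtype=object),
            major_counts=np.array([[30], [30]]), minor_counts=np.array([[20], [20]]))
        w = window_heterozygosity(t)
        assert len(w) == 2 and w["start"].tolist() == [0, 150_000]

    def test_group_mean_and_ttest(self):
        t = make_snp_table(np.full((100, 4), 0.3), coverage=50)
        means = group_mean_het(t, [0, 1])
        np.testing.assert_allclose(means, 2 * 0.3 * 0.7, atol=1e-12)
        tt, p = poolseq.het_ttest([0.24, 0.25, 0.26], [0.26, 0.265, 0.27])
        assert p < 0.2 and tt < 0

    def test_fst_closed_forms(self):
        per, mean = fst(make_snp_table([[0.5, 0.5]]), [0, 1])
        assert per[0] == pytest.approx(0.0, abs=1e-12)
        per, _ = fst(make_snp_table([[0.0, 1.0]]), [0, 1])
        assert per[0] == pytest.approx(1.0, abs=1e-12)
        per, _ = fst(make_snp_table([[0.3, 0.5]]), [0, 1])
        assert per[0] == pytest.approx(1 / 24, abs=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=6))
    def test_fst_bounds_and_label_swap_invariance(self, freqs):
        t = make_snp_table([freqs], coverage=1000)
        per, _ = fst(t, list(range(len(freqs))))
        if np.isnan(per[0]):
            return  # monomorphic site skipped
        assert -1e-12 <= per[0] <= 1 + 1e-12
        swapped = poolseq.SNPTable(t.chrom, t.pos, t.minor, t.major,
                                   t.minor_counts, t.major_counts)
        per2, _ = fst(swapped, list(range(len(freqs))))
        assert per2[0] == pytest.approx(per[0], abs=1e-9)

    def test_fst_zero_iff_equal_frequencies(self):
        per, _ = fst(make_snp_table([[0.3, 0.3, 0.3]]), [0, 1, 2])
        assert per[0] == pytest.approx(0.0, abs=1e-12)
        per, _ = fst(make_snp_table([[0.3, 0.31, 0.3]], coverage=100), [0, 1, 2])
        assert per[0] > 0


class TestCMHScan:
    def test_identical_groups_p_near_one(self):
        t = make_snp_table([[0.3] * 10], coverage=50)
        res = cmh_scan(t, GROUP_A, GROUP_B)
        assert res.p[0] > 0.9

    def test_consistent_shift_detected(self):
        t = make_snp_table([[0.3] * 5 + [0.5] * 5], coverage=50)
        assert cmh_scan(t, GROUP_A, GROUP_B).p[0] < 1e-3

    def test_equals_single_test_oracle(self, rng):
        f = rng.uniform(0.05, 0.95, size=(100, 10))
        t = make_snp_table(f, coverage=60)
        res = cmh_scan(t, GROUP_A, GROUP_B)
        for i in range(100):
            a = t.minor_counts[i, :5]
            b = t.minor_counts[i, 5:]
            c = t.major_counts[i, :5]
            d = t.major_counts[i, 5:]
            _, p = cmh_counts(a, b, c, d)
            assert res.p[i] == pytest.approx(p, abs=1e-12)

    def test_population_order_within_group_irrelevant(self, rng):
        f = rng.uniform(0.05, 0.95, size=(20, 10))
        t = make_snp_table(f, coverage=60)
        base = cmh_scan(t, GROUP_A, GROUP_B).p
        perm = cmh_scan(t, [4, 3, 2, 1, 0], [9, 8, 7, 6, 5]).p
        np.testing.assert_allclose(perm, base, atol=1e-12)

    def test_unequal_groups_rejected(self):
        t = make_snp_table([[0.3] * 10])
        with pytest.raises(ValueError):
            cmh_scan(t, [0, 1], [2, 3, 4])


class TestPermutationThreshold:
    def test_near_independence_order_statistic(self):
        """Null threshold within a factor of 3 of 1 - 0.95^(1/m)."""
        cfg = synth.SyncGenConfig(n_snps=1000)
        sync, _ = synth.gen_sync_dataset(cfg, seed=9)
        snps = call_snps(sync)
        thr = permutation_threshold(snps, GROUP_A, GROUP_B, n_perm=300, seed=10)
        approx = 1 - 0.95 ** (1 / snps.n_sites)
        assert approx / 3 < thr < approx * 3

    def test_threshold_tightens_with_more_sites(self):
        thrs = []
        for m in (1000, 10_000):
            sync, _ = synth.gen_sync_dataset(synth.SyncGenConfig(n_snps=m), seed=21)
            thrs.append(permutation_threshold(call_snps(sync), GROUP_A, GROUP_B,
                                              n_perm=150, seed=22))
        assert thrs[1] < thrs[0]

    def test_too_few_partitions_rejected(self):
        t = make_snp_table([[0.3, 0.4]], coverage=50)
        with pytest.raises(ValueError, match="partitions"):
            permutation_threshold(t, [0], [1], n_perm=100)

    def test_nperm_floor(self):
        t = make_snp_table([[0.3] * 10], coverage=50)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_threshold(t, GROUP_A, GROUP_B, n_perm=10)


class TestGLMScan:
    def test_zero_counts_adjusted_and_finite(self):
        f = np.zeros((1, 10))
        f[0, 5:] = 0.5
        t = make_snp_table(f, coverage=50)  # group A all 0:50
        res = glm_scan(t, GROUP_A, GROUP_B)
        assert np.isfinite(res.p[0]) and 0 < res.p[0] <= 1
        assert res.p[0] < 1e-4

    def test_identical_groups_huge_coverage_p_one(self):
        t = make_snp_table([[0.4] * 10], coverage=10_000)
        assert glm_scan(t, GROUP_A, GROUP_B).p[0] == pytest.approx(1.0)

    def test_matches_statsmodels_quasibinomial_oracle(self, rng):
        import statsmodels.api as sm

        f = rng.uniform(0.1, 0.9, size=(8, 10))
        t = make_snp_table(f, coverage=50)
        res = glm_scan(t, GROUP_A, GROUP_B)
        group = np.repeat([0.0, 1.0], 5)
        X = np.column_stack([np.ones(10), group])
        for i in range(8):
            minor = t.minor_counts[i].astype(float)
            major = t.major_counts[i].astype(float)
            zero = (minor == 0) | (major == 0)
            minor, major = minor + zero, major + zero
            fit = sm.GLM(np.column_stack([minor, major]), X,
                         family=sm.families.Binomial()).fit()
            disp = fit.pearson_chi2 / fit.df_resid  # quasibinomial dispersion
            tstat = fit.params[1] / (fit.bse[1] * np.sqrt(disp))
            p = 2 * stats.t.sf(abs(tstat), 8)
            assert res.p[i] == pytest.approx(p, rel=1e-6)

    def test_population_order_within_group_irrelevant(self, rng):
        f = rng.uniform(0.1, 0.9, size=(20, 10))
        t = make_snp_table(f, coverage=50)
        base = glm_scan(t, GROUP_A, GROUP_B).p
        perm = glm_scan(t, [2, 0, 1, 4, 3], [7, 9, 5, 6, 8]).p
        np.testing.assert_allclose(perm, base, atol=1e-12)


class TestCorrection:
    def test_bonferroni_boundary(self):
        p = np.full(100, 0.5)
        p[3] = 4e-4
        sig, _ = correct(p, "bonferroni", level=0.05)
        assert sig[3] and sig.sum() == 1

    def test_qvalue_null_sets_mostly_empty(self):
        empty = 0
        for seed in range(40):
            p = np.random.default_rng(seed).uniform(size=10_000)
            sig, q = correct(p, "qvalue", level=0.05)
            empty += not sig.any()
        assert empty >= 36

    def test_qvalues_monotone_in_p(self, rng):
        p = rng.uniform(size=500)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            correct(np.array([]))

    def test_merge_regions_constructed(self):
        regions = merge_regions(np.array(["X", "X", "X"], dtype=object),
                                np.array([100, 200, 90_000]), max_gap=50_000)
        assert len(regions) == 2
        first = regions.iloc[0]
        assert first["start"] == 99 and first["end"] == 200 and first["n_sites"] == 2

    def test_merge_regions_respects_chromosomes(self):
        regions = merge_regions(np.array(["2L", "3R"], dtype=object),
                                np.array([100, 120]), max_gap=10_000)
        assert len(regions) == 2
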