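"""Window calling, breakpoint localization, binning and segregation filter."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from binqtl.core import A, B, H, MISSING, UNCALLED, SNPMatrix
from binqtl.genotyping import (
    BinMap,
    build_bins,
    call_windows,
    detect_breakpoints,
    filter_segregation,
    filter_snps,
)


def make_matrix(calls: np.ndarray, chrom="Pv01", spacing=1000) -> SNPMatrix:
    """SNP matrix from an (n_samples, n_snps) int8 call array."""
    calls = np.asarray(calls, dtype=np.int8)
    n = calls.shape[1]
    snps = pd.DataFrame({"chrom": chrom, "pos": spacing * (np.arange(n) + 1)})
    samples = [f"S{i}" for i in range(calls.shape[0])]
    return SNPMatrix(snps, samples, calls)


class TestFilterSnps:
    def test_missingness_threshold(self):
        # one SNP missing in 30% of samples must go at the 20% threshold
        rng = np.random.default_rng(0)
        calls = rng.choice([A, B], size=(10, 4)).astype(np.int8)
        calls[:3, 1] = MISSING  # 30% missing
        out = filter_snps(make_matrix(calls), max_missing=0.20, min_maf=0.0)
        assert out.n_snps == 3 and 2000 not in out.snps["pos"].values

    def test_monomorphic_removed(self):
        calls = np.full((6, 2), A, dtype=np.int8)
        calls[:3, 1] = B
        out = filter_snps(make_matrix(calls), max_missing=1.0, min_maf=0.01)
        assert list(out.snps["pos"]) == [2000]

    def test_matches_bruteforce_on_toy_matrix(self):
        rng = np.random.default_rng(1)
        calls = rng.choice([A, B, H, MISSING], size=(20, 10), p=[0.4, 0.35, 0.1, 0.15]).astype(np.int8)
        sm = make_matrix(calls)
        out = filter_snps(sm, max_missing=0.2, min_maf=0.1)
        expect = []
        for j in range(10):
            col = calls[:, j]
            miss = (col == MISSING).mean()
            a = 2 * (col == A).sum() + (col == H).sum()
            b = 2 * (col == B).sum() + (col == H).sum()
            maf = min(a, b) / max(a + b, 1)
            if miss <= 0.2 and maf >= 0.1:
                expect.append(1000 * (j + 1))
        assert list(out.snps["pos"]) == expect

    def test_empty_matrix_warns_not_fails(self):
        sm = make_matrix(np.empty((2, 0), dtype=np.int8))
        with pytest.warns(UserWarning):
            out = filter_snps(sm)
        assert out.n_snps == 0


class TestCallWindows:
    @pytest.mark.parametrize(
        "n_a, n_b, expected",
        [(15, 0, A), (11, 4, A), (4, 11, B), (10, 5, H), (5, 10, H)],
    )
    def test_proportion_rule(self, n_a, n_b, expected):
        row = np.array([A] * n_a + [B] * n_b, dtype=np.int8)
        calls = np.vstack([row, row])
        wg = call_windows(make_matrix(calls))
        assert wg.chrom_windows["Pv01"]["codes"][0, 0] == expected

    def test_insufficient_informative_calls_uncalled(self):
        row = np.array([A] * 6 + [MISSING] * 9, dtype=np.int8)
        wg = call_windows(make_matrix(np.vstack([row, row])))
        assert wg.chrom_windows["Pv01"]["codes"][0, 0] == UNCALLED

    def test_short_chromosome_truncated_window(self):
        calls = np.full((2, 8), A, dtype=np.int8)
        with pytest.warns(UserWarning, match="fewer SNPs"):
            wg = call_windows(make_matrix(calls))
        assert wg.chrom_windows["Pv01"]["codes"].shape == (2, 1)
        assert wg.chrom_windows["Pv01"]["codes"][0, 0] == A

    def test_parameter_validation(self):
        sm = make_matrix(np.full((2, 20), A, dtype=np.int8))
        with pytest.raises(ValueError):
            call_windows(sm, window_size=2)
        with pytest.raises(ValueError):
            call_windows(sm, call_threshold=0.5)


class TestBreakpoints:
    def test_constant_genotype_no_breakpoints(self):
        calls = np.vstack([np.full(60, A, np.int8), np.full(60, B, np.int8)])
        sm = make_matrix(calls)
        bp = detect_breakpoints(call_windows(sm), sm)
        assert bp.total == 0

    def test_transient_het_run_absorbed_into_single_breakpoint(self):
        # A...A B...B transition: windows sweep through an H zone which must
        # collapse to one A->B breakpoint in the crossover gap
        row = np.array([A] * 30 + [B] * 30, dtype=np.int8)
        calls = np.vstack([row, np.full(60, A, np.int8)])
        sm = make_matrix(calls)
        wg = call_windows(sm)
        codes = wg.chrom_windows["Pv01"]["codes"][0]
        assert (codes == H).any()  # the transient zone exists at window level
        bp = detect_breakpoints(wg, sm)
        sub = bp.table[bp.table["sample"] == "S0"]
        assert len(sub) == 1
        assert (sub["before"].iloc[0], sub["after"].iloc[0]) == ("A", "B")
        # midpoint of the true gap between SNP 30 and SNP 31
        assert sub["pos"].iloc[0] == pytest.approx((30_000 + 31_000) / 2)
        assert len(bp.table[bp.table["sample"] == "S1"]) == 0

    def test_all_windows_uncalled_flags_low_quality(self):
        calls = np.vstack(
            [np.full(40, MISSING, np.int8), np.array([A] * 20 + [B] * 20, np.int8)]
        )
        sm = make_matrix(calls)
        with pytest.warns(UserWarning, match="low-quality"):
            bp = detect_breakpoints(call_windows(sm), sm)
        assert "S0" in bp.low_quality
        assert bp.per_sample()["S0"] == 0

    def test_noiseless_recovery_is_exact(self, inbred_pop, inbred_snps, genome3):
        """Every SNP-resolution true junction recovered inside its gap."""
        wg = call_windows(inbred_snps)
        bp = detect_breakpoints(wg, inbred_snps, min_discordant_run=1)
        for ci, chrom in enumerate(genome3.chroms):
            snppos = genome3.snp_pos[ci]
            anc = inbred_pop.ancestry_at(chrom, genome3.snp_cm(ci))
            for si, name in enumerate(inbred_pop.sample_names):
                true_gaps = np.flatnonzero(anc[si, 1:] != anc[si, :-1])
                rec = bp.table[
                    (bp.table["sample"] == name) & (bp.table["chrom"] == chrom)
                ]["pos"].to_numpy()
                assert len(rec) == len(true_gaps)
                for gidx in true_gaps:
                    lo, hi = snppos[gidx], snppos[gidx + 1]
                    assert ((rec > lo) & (rec < hi)).any()


class TestBuildBins:
    def test_no_recombinants_one_bin_per_chromosome(self):
        calls = np.vstack([np.full(40, A, np.int8), np.full(40, B, np.int8)])
        sm = make_matrix(calls)
        bm = build_bins(detect_breakpoints(call_windows(sm), sm), sm)
        assert bm.n_bins == 1
        assert bm.bins["n_snps"].iloc[0] == 40

    def test_two_samples_distinct_breakpoints_make_three_bins(self):
        s0 = np.array([A] * 20 + [B] * 40, dtype=np.int8)  # junction in gap 19-20
        s1 = np.array([A] * 40 + [B] * 20, dtype=np.int8)  # junction in gap 39-40
        sm = make_matrix(np.vstack([s0, s1]))
        bm = build_bins(detect_breakpoints(call_windows(sm), sm), sm)
        assert bm.n_bins == 3
        assert bm.bins["n_snps"].sum() == 60
        # middle bin: S0 already B, S1 still A
        assert bm.geno[0, 1] == B and bm.geno[1, 1] == A

    def test_partition_invariant(self, snps157, binmap157):
        from binqtl.genotyping import filter_snps as _f

        assert binmap157.bins["n_snps"].sum() == snps157.n_snps
        for chrom, grp in binmap157.bins.groupby("chrom", sort=False):
            assert (grp["start"].to_numpy()[1:] > grp["end"].to_numpy()[:-1]).all()

    def test_bin_genotypes_match_truth_at_f6_with_noise(self, pop157, genome3, binmap157):
        """>= 99% accuracy on noisy data (0.5% error), missing excluded."""
        errs, n = 0, 0
        for bi in range(binmap157.n_bins):
            chrom = binmap157.bins["chrom"].iloc[bi]
            ci = genome3.chroms.index(chrom)
            mid_cm = (
                (binmap157.bins["start"].iloc[bi] + binmap157.bins["end"].iloc[bi])
                / 2 * genome3.cm_per_mb[ci] / 1e6
            )
            truth = pop157.ancestry_at(chrom, mid_cm)[:, 0]
            g = binmap157.geno[:, bi]
            m = g != MISSING
            n += m.sum()
            errs += (g[m] != truth[m]).sum()
        assert errs / n < 0.01

    def test_label_symmetry(self):
        rng = np.random.default_rng(5)
        base = np.array([A] * 25 + [B] * 25, dtype=np.int8)
        calls = np.vstack([np.roll(base, rng.integers(-5, 5)) for _ in range(8)])
        flip = {A: B, B: A, H: H, MISSING: MISSING}
        flipped = np.vectorize(flip.get)(calls).astype(np.int8)
        bm1 = filter_segregation(
            build_bins(detect_breakpoints(call_windows(make_matrix(calls)), make_matrix(calls)), make_matrix(calls))
        )
        sm2 = make_matrix(flipped)
        bm2 = filter_segregation(build_bins(detect_breakpoints(call_windows(sm2), sm2), sm2))
        pd.testing.assert_frame_equal(
            bm1.bins[["chrom", "start", "end", "n_snps", "p"]],
            bm2.bins[["chrom", "start", "end", "n_snps", "p"]],
        )
        assert np.array_equal(bm1.kept, bm2.kept)
        assert np.array_equal(bm1.geno, -bm2.geno)  # labels swapped, structure equal


class TestSegregationFilter:
    def _binmap_with_counts(self, n_a, n_b, n_h=0, n_miss=0):
        col = np.array([A] * n_a + [B] * n_b + [H] * n_h + [MISSING] * n_miss, np.int8)
        bins = pd.DataFrame(
            {"bin": ["Bin0001"], "chrom": ["Pv01"], "start": [1], "end": [2], "n_snps": [1]}
        )
        return BinMap(bins, [f"S{i}" for i in range(len(col))], col[:, None])

    def test_balanced_counts_kept(self):
        bm = filter_segregation(self._binmap_with_counts(78, 79))
        assert bm.kept[0]
        assert bm.bins["chi2"].iloc[0] == pytest.approx((0.5**2 / 78.5) * 2, rel=1e-6)
        assert bm.bins["p"].iloc[0] == pytest.approx(0.94, abs=0.01)

    def test_distorted_counts_removed(self):
        bm = filter_segregation(self._binmap_with_counts(120, 37))
        assert not bm.kept[0]
        assert bm.bins["chi2"].iloc[0] == pytest.approx(43.88, abs=0.01)
        assert bm.bins["p"].iloc[0] < 1e-10

    def test_uninformative_bin_distinct_flag(self):
        bm = filter_segregation(self._binmap_with_counts(0, 0, n_h=3, n_miss=3))
        assert not bm.kept[0]
        assert bm.bins["flag"].iloc[0] == "uninformative"

    def test_chi2_matches_scipy_closed_form(self, binmap157):
        n_a = (binmap157.geno == A).sum(axis=0)
        n_b = (binmap157.geno == B).sum(axis=0)
        tot = n_a + n_b
        ok = tot > 0
        stat = (n_a[ok] - n_b[ok]) ** 2 / tot[ok]
        np.testing.assert_allclose(binmap157.bins["chi2"].to_numpy()[ok], stat)
        np.testing.assert_allclose(
            binmap157.bins["p"].to_numpy()[ok], chi2.sf(stat, 1)
        )
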