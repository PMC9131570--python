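"""ICIM components: conditional probabilities, cofactors, scan, threshold, calling."""
from itertools import product

import numpy as np
import pandas as pd
import pytest

from binqtl.core import A, B
from binqtl.linkage import LinkageMap, construct_linkage_map, ril_observed_R
from binqtl.qtl import (
    build_scan_grid,
    call_qtls,
    code_genotypes,
    conditional_qtl_probs,
    icim_scan,
    permutation_threshold,
    select_cofactors,
)
from binqtl.sim import GenomeSpec, simulate_ril_population


# --------- exact 3-locus selfing enumeration (independent oracle) ----------

_HAPS = list(product([0, 1], repeat=3))
_HIDX = {h: i for i, h in enumerate(_HAPS)}


def _gamete_dist(h1, h2, r1, r2):
    d = np.zeros(8)
    for x1 in (0, 1):
        for x2 in (0, 1):
            p = (r1 if x1 else 1 - r1) * (r2 if x2 else 1 - r2) / 2
            for strands in ((h1, h2), (h2, h1)):
                c = 0
                seq = [strands[0]]
                for xi in (x1, x2):
                    if xi:
                        c ^= 1
                    seq.append(strands[c])
                g = (seq[0][0], seq[1][1], seq[2][2])
                d[_HIDX[g]] += p
    return d


def _selfing_fixation_probs(r1, r2, gens=200):
    """Distribution over fixed 3-locus haplotypes after exhaustive selfing."""
    dist = np.zeros((8, 8))
    dist[_HIDX[(0, 0, 0)], _HIDX[(1, 1, 1)]] = 1.0
    for _ in range(gens):
        new = np.zeros((8, 8))
        for i in range(8):
            for j in range(8):
                p = dist[i, j]
                if p < 1e-18:
                    continue
                gd = _gamete_dist(_HAPS[i], _HAPS[j], r1, r2)
                new += p * np.outer(gd, gd)
        dist = new
    hom = np.array([dist[k, k] for k in range(8)])
    return hom / hom.sum()


class TestConditionalProbs:
    def test_collapse_at_marker(self):
        p_qq, p_qq_bar = conditional_qtl_probs(A, B, 0.0, 0.1)
        assert p_qq[0] == pytest.approx(1.0)
        p_qq, _ = conditional_qtl_probs(B, A, 0.0, 0.1)
        assert p_qq[0] == pytest.approx(0.0)

    def test_midpoint_symmetry(self):
        p_qq, p_qq_bar = conditional_qtl_probs(A, B, 0.07, 0.07)
        assert p_qq[0] == pytest.approx(0.5)
        assert p_qq[0] + p_qq_bar[0] == 1.0

    def test_missing_flanks_fall_back_to_prior(self):
        p_qq, _ = conditional_qtl_probs(0, 0, 0.1, 0.2)
        assert p_qq[0] == pytest.approx(0.5)

    def test_matches_markov_chain_composition_exactly(self):
        # the implementation's own contract: 2-state chain with transition R(r)
        for r1, r2 in [(0.02, 0.05), (0.1, 0.3)]:
            R1, R2 = ril_observed_R(r1), ril_observed_R(r2)
            w_a = (1 - R1) * (1 - R2)
            w_b = R1 * R2
            p_qq, _ = conditional_qtl_probs(A, A, r1, r2)
            assert p_qq[0] == pytest.approx(w_a / (w_a + w_b), rel=1e-12)

    @pytest.mark.parametrize("r1,r2", [(0.01, 0.02), (0.05, 0.05), (0.02, 0.04)])
    def test_close_to_exact_selfing_enumeration_at_scan_scale(self, r1, r2):
        """Markov form vs exhaustive two-interval RIL haplotype classes.

        Selfed RILs are not exactly Markov; at the interval sizes a dense
        bin map produces (r <= 0.05) the discrepancy is below 0.01.
        """
        hom = _selfing_fixation_probs(r1, r2)
        for gl, gr in [(0, 0), (0, 1)]:
            num = hom[_HIDX[(gl, 0, gr)]]
            den = num + hom[_HIDX[(gl, 1, gr)]]
            exact = num / den
            p_qq, _ = conditional_qtl_probs(
                A if gl == 0 else B, A if gr == 0 else B, r1, r2, None
            )
            assert p_qq[0] == pytest.approx(exact, abs=0.01)

    def test_negative_rf_rejected(self):
        with pytest.raises(ValueError):
            conditional_qtl_probs(A, B, -0.1, 0.1)


@pytest.fixture(scope="module")
def mapped(binmap157):
    eff = binmap157.effective()
    lmap, rf, groups = construct_linkage_map(eff, expected_groups=3, generations=6)
    grid = build_scan_grid(lmap, eff, step_cm=1.0, generations=6)
    return eff, lmap, grid


class TestCofactorSelection:
    def test_exact_linear_marker_selected_first(self, mapped):
        eff, lmap, grid = mapped
        X = code_genotypes(eff)
        y = 3.0 * X[:, 40] + 1.0
        active, coefs = select_cofactors(y, X)
        assert active[0] == 40
        assert coefs[0] == pytest.approx(3.0, abs=1e-6)

    def test_null_false_entry_rate(self):
        # 500 independent markers, p_in = 1e-3: ~0.5 false cofactors/scan
        rng = np.random.default_rng(0)
        counts = []
        for _ in range(100):
            X = rng.choice([-1.0, 1.0], size=(100, 500))
            y = rng.standard_normal(100)
            active, _ = select_cofactors(y, X)
            counts.append(len(active))
        assert 0.2 <= np.mean(counts) <= 0.9

    def test_duplicate_bins_enter_once(self, mapped):
        eff, _, _ = mapped
        X = code_genotypes(eff)
        X_dup = np.column_stack([X, X[:, 40]])
        y = 3.0 * X[:, 40] + np.random.default_rng(1).standard_normal(X.shape[0])
        active, _ = select_cofactors(y, X_dup)
        assert not (40 in active and X_dup.shape[1] - 1 in active)

    def test_planted_qtl_region_enters(self, genome3):
        """The nearest marker to a 16%-PVE QTL joins the model consistently."""
        marker_cm = np.arange(0.0, 100.0, 2.0)
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            pop = simulate_ril_population(
                GenomeSpec(np.array([100.0]), np.array([2.0]), np.array([20]), seed=1),
                157, 6, seed=3000 + rep,
            )
            Xm = pop.ancestry_at("Pv01", marker_cm).astype(float)
            x = Xm[:, 25]  # QTL at 50 cM, exactly on a marker
            rng = np.random.default_rng(rep)
            y = 10.0 * x + np.sqrt(100 * 0.84 / 0.16) * rng.standard_normal(157)
            active, _ = select_cofactors(y, Xm)
            if any(abs(marker_cm[a] - 50.0) <= 10.0 for a in active):
                hits += 1
        assert hits >= 0.9 * n_rep


class TestScan:
    def test_reduces_to_single_marker_regression_at_marker(self, inbred_snps):
        """Full-information, noise-free data: at a marker position the
        interval scan collapses onto the marker and its LOD equals the
        closed-form single-marker regression LOD."""
        from binqtl.genotyping import build_bins, call_windows, detect_breakpoints

        bm = build_bins(
            detect_breakpoints(call_windows(inbred_snps), inbred_snps), inbred_snps
        )
        lmap, _, _ = construct_linkage_map(bm, expected_groups=3)
        grid = build_scan_grid(lmap, bm, step_cm=1.0)
        X = code_genotypes(bm)
        rng = np.random.default_rng(2)
        j = lmap.group_table(1)["bin_idx"].iloc[0]  # first marker: cm = 0
        y = 2.0 * X[:, j] + rng.standard_normal(X.shape[0])
        scan = icim_scan(y, grid, X, cofactors=None)
        row = scan[(scan["group"] == 1) & (scan["cm"] == 0.0)]
        c = np.corrcoef(y, X[:, j])[0, 1]
        expected = -0.5 * len(y) * np.log10(1 - c * c)
        assert row["lod"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_lod_invariant_under_affine_phenotype_transform(self, mapped):
        eff, lmap, grid = mapped
        X = code_genotypes(eff)
        rng = np.random.default_rng(3)
        y = rng.standard_normal(X.shape[0])
        s1 = icim_scan(y, grid, X)
        s2 = icim_scan(5.0 * y - 7.0, grid, X)
        np.testing.assert_allclose(s1["lod"], s2["lod"], atol=1e-8)
        np.testing.assert_allclose(s1["pve"], s2["pve"], atol=1e-8)
        np.testing.assert_allclose(s2["add"], 5.0 * s1["add"], atol=1e-8)

    def test_pve_bounded(self, mapped):
        eff, lmap, grid = mapped
        X = code_genotypes(eff)
        y = np.random.default_rng(4).standard_normal(X.shape[0])
        scan = icim_scan(y, grid, X)
        assert (scan["pve"] >= 0).all() and (scan["pve"] <= 100).all()
        assert (scan["lod"] >= 0).all()


class TestPermutationThreshold:
    def test_alpha_one_gives_distribution_minimum(self, mapped):
        eff, _, grid = mapped
        X = code_genotypes(eff)
        y = np.random.default_rng(5).standard_normal(X.shape[0])
        t_min = permutation_threshold(y, grid, X, n_perm=100, alpha=1.0, seed=9)
        t_05 = permutation_threshold(y, grid, X, n_perm=100, alpha=0.05, seed=9)
        assert t_min <= t_05

    def test_monotone_in_alpha_and_reproducible(self, mapped):
        eff, _, grid = mapped
        X = code_genotypes(eff)
        y = np.random.default_rng(6).standard_normal(X.shape[0])
        ts = [
            permutation_threshold(y, grid, X, n_perm=120, alpha=a, seed=9)
            for a in (0.5, 0.2, 0.05)
        ]
        assert ts[0] <= ts[1] <= ts[2]
        again = permutation_threshold(y, grid, X, n_perm=120, alpha=0.05, seed=9)
        assert again == ts[2]

    def test_small_n_perm_rejected(self, mapped):
        eff, _, grid = mapped
        X = code_genotypes(eff)
        with pytest.raises(ValueError):
            permutation_threshold(np.zeros(X.shape[0]), grid, X, n_perm=50)


def _synthetic_scan(lods_by_group: dict[int, np.ndarray]) -> tuple[pd.DataFrame, LinkageMap]:
    rows, mrows = [], []
    for gid, lods in lods_by_group.items():
        for i, l in enumerate(lods):
            rows.append((gid, float(i), l, 0.5, 10.0))
        for i in range(len(lods)):
            mrows.append((gid, f"Bin{gid}{i:03d}", i, float(i), f"Pv{gid:02d}", i * 1000, i * 1000 + 10, 1))
    scan = pd.DataFrame(rows, columns=["group", "cm", "lod", "add", "pve"])
    lmap = LinkageMap(
        pd.DataFrame(mrows, columns=["group", "marker", "bin_idx", "cm", "chrom", "start", "end", "n_snps"])
    )
    return scan, lmap


class TestCallQtls:
    def test_below_floor_returns_empty(self):
        scan, lmap = _synthetic_scan({1: np.full(50, 2.5)})
        assert len(call_qtls(scan, threshold=2.0, lmap=lmap)) == 0

    def test_two_distant_peaks_called_separately(self):
        lod = np.zeros(80)
        lod[10:17] = [3, 5, 6.5, 7, 6.6, 5, 3]
        lod[50:56] = [3, 5, 6, 5, 3, 1]
        scan, lmap = _synthetic_scan({1: lod})
        qtls = call_qtls(scan, threshold=3.0, lmap=lmap, trait="PDS")
        assert len(qtls) == 2
        assert qtls["qtl"].tolist() == ["qPDS1.1", "qPDS1.2"]
        assert qtls["peak_cm"].tolist() == [13.0, 52.0]
        assert (qtls["ci_lo_cm"] <= qtls["peak_cm"]).all()
        assert (qtls["ci_hi_cm"] >= qtls["peak_cm"]).all()
        # gentle shoulders within 1 LOD of the first peak widen its interval
        assert qtls["ci_lo_cm"].iloc[0] == 12.0 and qtls["ci_hi_cm"].iloc[0] == 14.0

    def test_threshold_floor_applies(self):
        scan, lmap = _synthetic_scan({1: np.array([0, 2.0, 3.5, 2.0, 0])})
        # permutation threshold below the fixed 3.0 floor: floor wins
        qtls = call_qtls(scan, threshold=1.5, lmap=lmap)
        assert len(qtls) == 1 and qtls["lod"].iloc[0] == 3.5
        assert len(call_qtls(scan, threshold=4.0, lmap=lmap)) == 0
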