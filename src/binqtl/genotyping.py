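"""Sliding-window genotype calling and bin-map construction.

The resequencing-based genotyping strategy for RIL populations: SNP calls
are noisy and locally redundant, so per-sample genotypes are called on
15-SNP sliding windows, recombination breakpoints are localized at the
transitions between window-genotype runs, and the population-wide union of
breakpoints partitions each chromosome into recombination *bins* that act
as single markers for linkage mapping.  Bins whose parental genotype
counts deviate from the expected 1:1 RIL segregation are flagged by a
chi-square filter.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .core import A, B, H, MISSING, UNCALLED, SNPMatrix, informative

# ------------------------------------------------------------- SNP filter


def filter_snps(snps: SNPMatrix, max_missing: float = 0.20, min_maf: float = 0.05) -> SNPMatrix:
    """Drop SNPs by missingness and minor-allele frequency.

    A SNP is kept when its missing fraction is <= ``max_missing`` and its
    MAF (heterozygous calls contributing half an allele each) is
    >= ``min_maf``.  SNP order is preserved.
    """
    for t in (max_missing, min_maf):
        if not (0 <= t <= 1):
            raise ValueError("thresholds must lie in [0, 1]")
    if snps.n_snps == 0:
        warnings.warn("empty SNP matrix: nothing to filter")
        return snps
    calls = snps.calls
    n = snps.n_samples
    missing = (calls == MISSING).sum(axis=0)
    n_a = (calls == A).sum(axis=0)
    n_b = (calls == B).sum(axis=0)
    n_h = (calls == H).sum(axis=0)
    a_alleles = 2 * n_a + n_h
    b_alleles = 2 * n_b + n_h
    total = a_alleles + b_alleles
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(total > 0, np.minimum(a_alleles, b_alleles) / np.maximum(total, 1), 0.0)
    keep = (missing / n <= max_missing) & (maf >= min_maf)
    out = snps.subset_snps(keep)
    out.meta["n_filtered_out"] = int((~keep).sum())
    return out


# --------------------------------------------------------- window calling


@dataclass
class WindowGenotypes:
    """Per-sample sliding-window genotype calls.

    For each chromosome: window start SNP indices, the per-sample window
    codes (``A``/``B``/``H``/``UNCALLED``) and the fraction of A alleles
    among informative calls.
    """

    samples: list[str]
    window_size: int
    step: int
    call_threshold: float
    min_informative: int
    chrom_windows: dict = field(default_factory=dict)
    # chrom -> dict(starts, codes (n_samples, n_windows), frac_a)


def call_windows(
    snps: SNPMatrix,
    window_size: int = 15,
    step: int = 1,
    call_threshold: float = 11 / 15,
    min_informative: int = 10,
) -> WindowGenotypes:
    """Call window genotypes from the A/B proportion of informative SNPs.

    Within each window the homozygous (non-missing, non-H) calls are
    counted: the window is called ``A`` when the A fraction is
    >= ``call_threshold``, ``B`` symmetrically, otherwise ``H``; windows
    with fewer than ``min_informative`` informative calls are uncalled.
    """
    if window_size < 3:
        raise ValueError("window_size must be >= 3")
    if not (0.5 < call_threshold <= 1):
        raise ValueError("call_threshold must lie in (0.5, 1]")
    wg = WindowGenotypes(list(snps.samples), window_size, step, call_threshold, min_informative)
    for chrom in snps.chroms:
        sl = snps.chrom_slice(chrom)
        calls = snps.calls[:, sl]
        n_snp = calls.shape[1]
        w = window_size
        if n_snp < window_size:
            warnings.warn(f"{chrom}: fewer SNPs ({n_snp}) than window size; single truncated window")
            w = n_snp
            starts = np.array([0])
        else:
            starts = np.arange(0, n_snp - w + 1, step)
        is_a = (calls == A).astype(np.int32)
        is_b = (calls == B).astype(np.int32)
        ca = np.cumsum(np.concatenate([np.zeros((calls.shape[0], 1), np.int32), is_a], axis=1), axis=1)
        cb = np.cumsum(np.concatenate([np.zeros((calls.shape[0], 1), np.int32), is_b], axis=1), axis=1)
        n_a = ca[:, starts + w] - ca[:, starts]
        n_b = cb[:, starts + w] - cb[:, starts]
        inf = n_a + n_b
        with np.errstate(invalid="ignore"):
            frac_a = np.where(inf > 0, n_a / np.maximum(inf, 1), np.nan)
        codes = np.full(n_a.shape, H, dtype=np.int8)
        codes[n_a >= call_threshold * inf] = A
        codes[n_b >= call_threshold * inf] = B
        codes[inf < min(min_informative, w)] = UNCALLED
        wg.chrom_windows[chrom] = {"starts": starts, "codes": codes, "frac_a": frac_a}
    return wg


# ---------------------------------------------------- breakpoint detection


@dataclass
class BreakpointSet:
    """Recombination breakpoints and the per-sample segmentations.

    ``table`` has one row per breakpoint: sample, chrom, left/right flank
    bp, midpoint position, genotype before/after.  ``segments`` maps
    ``chrom -> list over samples of (boundaries_bp, states)``: boundaries
    are the breakpoint midpoints plus the SNP-covered chromosome ends (so
    ``len(boundaries) == len(states) + 1``).  ``coverage`` marks, per
    sample, which SNPs fall under at least one called window.
    """

    samples: list[str]
    table: pd.DataFrame
    segments: dict
    coverage: dict
    low_quality: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return len(self.table)

    def per_sample(self) -> pd.Series:
        counts = self.table.groupby("sample").size()
        return counts.reindex(self.samples, fill_value=0)

    def to_bed(self, path) -> None:
        """Breakpoint intervals as BED (0-based half-open flank span)."""
        bed = pd.DataFrame(
            {
                "chrom": self.table["chrom"],
                "start": self.table["left_bp"].astype(np.int64) - 1,
                "end": self.table["right_bp"].astype(np.int64),
                "name": self.table["sample"]
                + ":"
                + self.table["before"].astype(str)
                + ">"
                + self.table["after"].astype(str),
            }
        )
        bed.to_csv(path, sep="\t", index=False, header=False)


_CODE_STR = {A: "A", B: "B", H: "H"}


def _rle(values: np.ndarray, index: np.ndarray):
    """Run-length encode; returns (value, first_idx_pos, last_idx_pos) triples."""
    if values.size == 0:
        return []
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change - 1, [values.size - 1]])
    return [(int(values[s]), int(index[s]), int(index[e])) for s, e in zip(starts, ends)]


def _side_match(seg: np.ndarray, g_self: int, g_other: int) -> np.ndarray:
    """Calls supporting genotype ``g_self`` on one side of a boundary.

    For a homozygous side these are the calls equal to it; for an H side
    any non-missing call different from the opposite homozygote counts
    (the SNPs under an H window run are typically the *other* parent's
    calls or heterozygous calls, not literal H)."""
    if g_self in (A, B):
        return (seg == g_self).astype(np.int32)
    return ((seg != g_other) & (seg != MISSING)).astype(np.int32)


def _refine_boundary(calls: np.ndarray, lo: int, hi: int, g1: int, g2: int):
    """SNP-level boundary between flanking genotypes within [lo, hi].

    Chooses the split maximizing (#left-supporting calls before it) +
    (#right-supporting calls after it); returns (last_left_snp,
    first_right_snp) indices.  In noiseless data this recovers the exact
    inter-SNP gap of the crossover.
    """
    seg = calls[lo : hi + 1]
    m1 = _side_match(seg, g1, g2)
    m2 = _side_match(seg, g2, g1)
    left = np.concatenate([[0], np.cumsum(m1)])  # left-support among first k
    right = np.concatenate([np.cumsum(m2[::-1])[::-1], [0]])  # right-support from k on
    score = left + right  # split after k-1 elements, k = 0..len
    k = int(np.argmax(score))
    last_left = lo + k - 1
    first_right = lo + k
    last_left = max(last_left, lo)
    first_right = min(first_right, hi)
    if first_right <= last_left:
        first_right = min(last_left + 1, hi)
    return last_left, first_right


def _majority_code(calls: np.ndarray, s0: int, s1: int, fallback: int) -> int:
    """Majority A/B/H call over SNP indices [s0, s1]; ties keep fallback."""
    seg = calls[s0 : s1 + 1]
    counts = [(int((seg == g).sum()), g) for g in (A, B, H)]
    best, g = max(counts, key=lambda t: t[0])
    if best == 0 or sum(c == best for c, _ in counts) > 1:
        return fallback
    return g


def _rescue_subsegments(calls: np.ndarray, s0: int, s1: int, g: int, min_run: int):
    """Sub-window segments hidden inside a window-level run.

    Maximal runs of >= ``min_run`` consecutive non-missing calls discordant
    with the run genotype ``g`` are promoted to segments of their own
    (typed by their majority call).  Returns a list of
    (sub_start, sub_end, genotype) SNP-index triples.
    """
    span = calls[s0 : s1 + 1]
    disc = (span != g) & (span != MISSING)
    out = []
    for v, i0, i1 in _rle(disc.astype(np.int8), np.arange(disc.size)):
        if v and (i1 - i0 + 1) >= min_run:
            sub_g = _majority_code(calls, s0 + i0, s0 + i1, g)
            if sub_g != g:
                out.append((s0 + i0, s0 + i1, sub_g))
    return out


def detect_breakpoints(
    wg: WindowGenotypes, snps: SNPMatrix, min_discordant_run: int = 3
) -> BreakpointSet:
    """Segment window-genotype runs into breakpoints per sample.

    Uncalled windows are transparent (they do not break runs).  A
    "transient" H run — shorter than ``window_size`` windows and flanked by
    the two different homozygotes — is the signature of a single crossover
    sweeping through the window and is absorbed into one A<->B breakpoint.
    Remaining runs are re-typed by the majority SNP call over their span
    (an H window run produced by a sub-window homozygous segment becomes
    that homozygote), each transition is localized at SNP level between
    the centers of the two flanking edge windows, and segments shorter
    than a window are rescued when >= ``min_discordant_run`` consecutive
    SNP calls disagree with the surrounding run (with noise-free data a
    value of 1 makes the segmentation exact at SNP resolution).
    Breakpoints are placed at the midpoint of the two refined flank SNPs.
    """
    w = wg.window_size
    half = (w - 1) // 2
    rows = []
    segments: dict = {}
    coverage: dict = {}
    called_any = np.zeros(len(wg.samples), dtype=bool)
    for chrom, cw in wg.chrom_windows.items():
        sl = snps.chrom_slice(chrom)
        pos = snps.snps["pos"].to_numpy()[sl]
        calls = snps.calls[:, sl]
        n_snp = pos.size
        starts, codes = cw["starts"], cw["codes"]
        eff_w = min(w, n_snp)
        seg_list = []
        cov = np.zeros((len(wg.samples), n_snp), dtype=bool)
        for si in range(len(wg.samples)):
            sample_codes = codes[si]
            called = sample_codes != UNCALLED
            if not called.any():
                seg_list.append((np.array([pos[0] - 0.5, pos[-1] + 0.5]), np.array([MISSING], dtype=np.int8)))
                continue
            called_any[si] = True
            # coverage: SNPs under at least one called window
            for v, i0, i1 in _rle(called.astype(np.int8), np.arange(called.size)):
                if v:
                    cov[si, starts[i0] : starts[i1] + eff_w] = True
            runs = _rle(sample_codes[called], starts[called])
            # absorb transient H runs between differing homozygotes
            merged = []
            i = 0
            while i < len(runs):
                g, s0, s1 = runs[i]
                if (
                    g == H
                    and 0 < i < len(runs) - 1
                    and runs[i - 1][0] != runs[i + 1][0]
                    and runs[i - 1][0] in (A, B)
                    and runs[i + 1][0] in (A, B)
                    and (s1 - s0 + 1) < w
                ):
                    i += 1
                    continue
                merged.append((g, s0, s1))
                i += 1
            # re-type runs by the majority call over their SNP span
            retyped = []
            for g, s0, s1 in merged:
                g2 = _majority_code(calls[si], s0, min(s1 + eff_w - 1, n_snp - 1), g)
                retyped.append((g2, s0, s1))
            # merge identical neighbours created by absorption/re-typing
            runs2 = []
            for r in retyped:
                if runs2 and runs2[-1][0] == r[0]:
                    runs2[-1] = (r[0], runs2[-1][1], r[2])
                else:
                    runs2.append(r)
            # refine each transition at SNP level; track segment SNP spans
            cut_left = []  # last SNP of segment k (k = 0..n_runs-2)
            cut_right = []  # first SNP of segment k+1
            for (g1, _, e1), (g2, s2, _) in zip(runs2[:-1], runs2[1:]):
                cl = min(e1 + half, n_snp - 1)  # center SNP of left run's last window
                cr = min(s2 + half, n_snp - 1)  # center SNP of right run's first window
                ll, rr = _refine_boundary(calls[si], min(cl, cr), max(cl, cr), g1, g2)
                cut_left.append(ll)
                cut_right.append(rr)
            # segment spans in SNP indices
            span_lo = [0] + [r for r in cut_right]
            span_hi = [l for l in cut_left] + [n_snp - 1]
            # rescue sub-window segments inside each span
            final: list[tuple[int, int, int]] = []  # (snp_lo, snp_hi, genotype)
            for (g, _, _), lo, hi in zip(runs2, span_lo, span_hi):
                subs = _rescue_subsegments(calls[si], lo, hi, g, min_discordant_run)
                cursor = lo
                for a0, a1, sg in subs:
                    if a0 > cursor:
                        final.append((cursor, a0 - 1, g))
                    final.append((a0, a1, sg))
                    cursor = a1 + 1
                if cursor <= hi:
                    final.append((cursor, hi, g))
            # merge any identical neighbours once more
            fused: list[list[int]] = []
            for lo, hi, g in final:
                if fused and fused[-1][2] == g:
                    fused[-1][1] = hi
                else:
                    fused.append([lo, hi, g])
            # final polish: re-refine each boundary over the two segments'
            # full SNP extent (window centers can sit several SNPs past a
            # junction close to a chromosome end)
            for k in range(len(fused) - 1):
                lo, hi = fused[k][0], fused[k + 1][1]
                ll, rr = _refine_boundary(calls[si], lo, hi, fused[k][2], fused[k + 1][2])
                if ll >= fused[k][0] and rr <= fused[k + 1][1]:
                    fused[k][1] = ll
                    fused[k + 1][0] = rr
            bounds = [pos[0] - 0.5]
            states = []
            for (lo1, hi1, g1), (lo2, hi2, g2) in zip(fused[:-1], fused[1:]):
                mid = (pos[hi1] + pos[lo2]) / 2.0
                rows.append(
                    (
                        wg.samples[si],
                        chrom,
                        int(pos[hi1]),
                        int(pos[lo2]),
                        mid,
                        _CODE_STR[g1],
                        _CODE_STR[g2],
                    )
                )
                bounds.append(mid)
                states.append(g1)
            states.append(fused[-1][2])
            bounds.append(pos[-1] + 0.5)
            seg_list.append((np.array(bounds), np.array(states, dtype=np.int8)))
        segments[chrom] = seg_list
        coverage[chrom] = cov
    table = pd.DataFrame(
        rows, columns=["sample", "chrom", "left_bp", "right_bp", "pos", "before", "after"]
    )
    if len(table):
        table = table.sort_values(["sample", "chrom", "pos"], kind="stable").reset_index(drop=True)
    low_q = [s for s, ok in zip(wg.samples, called_any) if not ok]
    if low_q:
        warnings.warn(f"{len(low_q)} sample(s) with no called window flagged low-quality")
    return BreakpointSet(list(wg.samples), table, segments, coverage, low_q)


# ------------------------------------------------------------------- bins


@dataclass
class BinMap:
    """Population-wide recombination bins with per-sample genotypes.

    ``bins``: one row per bin (bin, chrom, start, end — 1-based inclusive
    bp of the first/last SNP — n_snps, plus filter columns after
    :func:`filter_segregation`).  ``geno``: int8 (n_samples, n_bins).
    """

    bins: pd.DataFrame
    samples: list[str]
    geno: np.ndarray
    kept: np.ndarray = None

    def __post_init__(self):
        if self.kept is None:
            self.kept = np.ones(len(self.bins), dtype=bool)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def effective(self) -> "BinMap":
        """Bins surviving the segregation filter."""
        mask = np.asarray(self.kept, bool)
        return BinMap(
            self.bins.loc[mask].reset_index(drop=True), list(self.samples), self.geno[:, mask]
        )

    def summary(self) -> dict:
        lengths = (self.bins["end"] - self.bins["start"]).to_numpy()
        return {
            "n_bins": self.n_bins,
            "mean_length_bp": float(lengths.mean()) if self.n_bins else 0.0,
            "mean_snps": float(self.bins["n_snps"].mean()) if self.n_bins else 0.0,
        }

    def to_tsv(self, path) -> None:
        chars = {A: "A", B: "B", H: "H", MISSING: "-"}
        geno_cols = pd.DataFrame(
            {s: [chars[int(c)] for c in self.geno[i]] for i, s in enumerate(self.samples)}
        )
        pd.concat([self.bins.reset_index(drop=True), geno_cols], axis=1).to_csv(
            path, sep="\t", index=False
        )


def build_bins(bp: BreakpointSet, snps: SNPMatrix) -> BinMap:
    """Partition each chromosome at the union of all samples' breakpoints.

    Every SNP is assigned to exactly one bin; a bin's per-sample genotype
    is the sample's segment genotype over the bin, or missing when none of
    the bin's SNPs lie under a called window of that sample.
    """
    n_samples = len(bp.samples)
    bin_rows = []
    geno_cols = []
    bin_id = 0
    for chrom in snps.chroms:
        sl = snps.chrom_slice(chrom)
        pos = snps.snps["pos"].to_numpy()[sl]
        cuts = np.unique(bp.table.loc[bp.table["chrom"] == chrom, "pos"].to_numpy())
        edges = np.concatenate([[pos[0] - 1.0], cuts, [pos[-1] + 1.0]])
        snp_bin = np.searchsorted(edges, pos, side="left") - 1
        seg_list = bp.segments[chrom]
        cov = bp.coverage.get(chrom)
        for b in np.unique(snp_bin):
            snp_idx = np.flatnonzero(snp_bin == b)
            lo, hi = pos[snp_idx[0]], pos[snp_idx[-1]]
            mid = (lo + hi) / 2.0
            g = np.empty(n_samples, dtype=np.int8)
            for si in range(n_samples):
                bounds, states = seg_list[si]
                k = np.clip(np.searchsorted(bounds, mid, side="left") - 1, 0, len(states) - 1)
                g[si] = states[k]
                if cov is not None and states[k] != MISSING:
                    if not cov[si, snp_idx[0] : snp_idx[-1] + 1].any():
                        g[si] = MISSING
            bin_id += 1
            bin_rows.append((f"Bin{bin_id:04d}", chrom, int(lo), int(hi), len(snp_idx)))
            geno_cols.append(g)
    bins = pd.DataFrame(bin_rows, columns=["bin", "chrom", "start", "end", "n_snps"])
    geno = np.stack(geno_cols, axis=1) if geno_cols else np.empty((n_samples, 0), np.int8)
    return BinMap(bins, list(bp.samples), geno)


def filter_segregation(binmap: BinMap, alpha: float = 0.05) -> BinMap:
    """Chi-square 1:1 segregation test per bin (df=1, H/missing excluded).

    Bins with p < ``alpha`` are flagged removed ("distorted"); bins with no
    informative sample are removed with the distinct "uninformative" flag.
    """
    n_a = (binmap.geno == A).sum(axis=0).astype(float)
    n_b = (binmap.geno == B).sum(axis=0).astype(float)
    total = n_a + n_b
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(total > 0, (n_a - n_b) ** 2 / np.maximum(total, 1), np.nan)
    pval = chi2.sf(stat, df=1)
    kept = np.where(np.isnan(stat), False, pval >= alpha)
    flag = np.where(
        total == 0, "uninformative", np.where(kept, "kept", "distorted")
    )
    bins = binmap.bins.copy()
    bins["chi2"] = stat
    bins["p"] = pval
    bins["flag"] = flag
    return BinMap(bins, list(binmap.samples), binmap.geno, kept=kept)
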