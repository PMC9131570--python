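"""Two-point linkage analysis and Kosambi map construction.

Recombination between bin markers is estimated from jointly homozygous
RILs; because each selfing generation adds meioses, the observed fraction
of recombinant lines R overstates the per-meiosis fraction r, and the
Haldane–Waddington relation for selfed RILs, R = 2r/(1+2r), is inverted to
recover r.  Markers are grouped by two-point LOD (single-linkage), ordered
by minimizing the sum of adjacent recombination fractions (greedy chaining
plus 2-opt), and placed on a cumulative Kosambi-centiMorgan scale.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import A, B
from .genotyping import BinMap

R_CAP = 0.4999  # observed RF cap: R = 0.5 means free recombination


# ----------------------------------------------------------- map function

def kosambi(r):
    """Kosambi map distance d = 25 ln[(1+2r)/(1-2r)] in cM.

    Accepts scalars or arrays; r >= 0.5 maps to ``inf`` (unlinked
    sentinel), invalid negatives raise.
    """
    r = np.asarray(r, dtype=float)
    if (r < 0).any():
        raise ValueError("recombination fraction must be >= 0")
    with np.errstate(divide="ignore"):
        d = np.where(r < 0.5, 25.0 * np.log((1 + 2 * r) / np.maximum(1 - 2 * r, 1e-300)), np.inf)
    return d if d.ndim else float(d)


def kosambi_inv(d):
    """Inverse Kosambi: genetic distance (cM) back to recombination fraction."""
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distance must be >= 0")
    r = 0.5 * np.tanh(d / 50.0)
    return r if r.ndim else float(r)


def ril_meiotic_r(R, generations: int | None = None):
    """Selfed-RIL correction: observed recombinant-line fraction R -> meiotic r.

    With ``generations=None`` (complete inbreeding) this is the
    Haldane–Waddington inversion r = R/(2(1-R)).  For a finite selfing
    generation the exact two-locus selfing recursion is inverted
    numerically instead: conditioning on joint homozygosity at F_g selects
    chromatin that fixed early and accumulated fewer junctions, so the
    complete-inbreeding formula understates r (at F6 the small-r slope of
    R(r) is ~1.68 rather than 2).
    """
    R = np.asarray(R, dtype=float)
    if generations is None:
        r = R / (2.0 * (1.0 - R))
    else:
        r_grid, R_grid = _selfing_curve(generations)
        r = np.interp(R, R_grid, r_grid)
    return r if r.ndim else float(r)


def ril_observed_R(r, generations: int | None = None):
    """Meiotic r -> expected fraction of recombinant homozygous RIL lines."""
    r = np.asarray(r, dtype=float)
    if generations is None:
        R = 2.0 * r / (1.0 + 2.0 * r)
    else:
        r_grid, R_grid = _selfing_curve(generations)
        R = np.interp(r, r_grid, R_grid)
    return R if R.ndim else float(R)


_SELFING_CURVES: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _selfing_curve(generations: int, n_grid: int = 512):
    """R(r) for doubly homozygous F_g lines, by exact 2-locus recursion.

    Tracks the ordered-diplotype distribution over the 4 two-locus
    haplotypes through g-1 rounds of selfing (gamete recombinant with
    probability r, no interference) starting from the F1 coupling
    heterozygote, then returns P(recombinant | homozygous at both loci)
    on an r grid.  Cached per generation.
    """
    if generations in _SELFING_CURVES:
        return _SELFING_CURVES[generations]
    if generations < 2:
        raise ValueError("generations must be >= 2")
    r = np.linspace(0.0, R_CAP, n_grid)
    # haplotypes: 0=(A,A) 1=(A,B) 2=(B,A) 3=(B,B); gamete distribution from
    # ordered diplotype (i,j): parental haplotypes with prob (1-r)/2 each,
    # recombinants with prob r/2 each.
    gd = np.zeros((4, 4, 4, len(r)))  # (i, j, gamete, r)
    hap = [(0, 0), (0, 1), (1, 0), (1, 1)]
    hidx = {h: k for k, h in enumerate(hap)}
    for i in range(4):
        for j in range(4):
            gd[i, j, i] += (1 - r) / 2
            gd[i, j, j] += (1 - r) / 2
            gd[i, j, hidx[(hap[i][0], hap[j][1])]] += r / 2
            gd[i, j, hidx[(hap[j][0], hap[i][1])]] += r / 2
    dist = np.zeros((4, 4, len(r)))
    dist[0, 3] = 1.0  # F1: AA / BB coupling
    for _ in range(generations - 1):
        new = np.zeros_like(dist)
        for i in range(4):
            for j in range(4):
                p = dist[i, j]
                if not p.any():
                    continue
                g = gd[i, j]  # (4, n_r)
                new += p * g[:, None, :] * g[None, :, :]
        dist = new
    p_hom = sum(dist[k, k] for k in range(4))
    p_rec = dist[1, 1] + dist[2, 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(p_hom > 0, p_rec / np.maximum(p_hom, 1e-300), 0.0)
    R[0] = 0.0
    _SELFING_CURVES[generations] = (r, R)
    return r, R


# -------------------------------------------------------- rf estimation


class RFEstimate(NamedTuple):
    R: float  # observed RIL recombination fraction
    r: float  # meiotic recombination fraction
    lod: float
    n: int  # jointly homozygous sample count


def _lod_from_R(R, n):
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(R > 0, R * np.log10(np.maximum(R, 1e-300)), 0.0)
        lod = n * (term + (1 - R) * np.log10(np.maximum(1 - R, 1e-300)) - np.log10(0.5))
    return lod


def estimate_rf(
    calls_i: np.ndarray, calls_j: np.ndarray, generations: int | None = None
) -> RFEstimate:
    """Two-point recombination estimate from two genotype columns.

    Only samples homozygous at both markers are informative: R is the
    discordant fraction (capped below 0.5), r applies the selfed-RIL
    correction, and the LOD is the binomial likelihood ratio against free
    recombination (R = 0.5).
    """
    gi = np.asarray(calls_i, dtype=np.int16)
    gj = np.asarray(calls_j, dtype=np.int16)
    both = (np.abs(gi) == 1) & (np.abs(gj) == 1)
    n = int(both.sum())
    if n < 2:
        raise ValueError("need >= 2 jointly informative samples")
    disc = int((gi[both] != gj[both]).sum())
    R = min(disc / n, R_CAP)
    return RFEstimate(R, ril_meiotic_r(R, generations), float(_lod_from_R(R, n)), n)


@dataclass
class PairwiseRF:
    """Symmetric marker x marker recombination tables."""

    R: np.ndarray
    r: np.ndarray
    lod: np.ndarray
    n: np.ndarray
    markers: list[str]

    @property
    def n_markers(self) -> int:
        return len(self.markers)


def pairwise_rf(
    binmap: BinMap, min_informative: int = 2, generations: int | None = None
) -> PairwiseRF:
    """All-pairs two-point estimates from a bin map's genotype matrix.

    Vectorized via indicator matrix products; pairs with fewer than
    ``min_informative`` jointly homozygous samples are undefined (R, r and
    LOD set to NaN) and excluded from grouping.
    """
    G = binmap.geno
    P = (G == A).astype(np.float32)
    M = (G == B).astype(np.float32)
    conc = P.T @ P + M.T @ M
    disc = P.T @ M + M.T @ P
    n = conc + disc
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(n > 0, disc / np.maximum(n, 1), np.nan)
    R = np.minimum(R, R_CAP)
    undefined = n < min_informative
    R[undefined] = np.nan
    lod = _lod_from_R(R, n)
    lod[undefined] = np.nan
    r = ril_meiotic_r(R, generations)
    np.fill_diagonal(R, 0.0)
    np.fill_diagonal(r, 0.0)
    return PairwiseRF(R, r, lod, n.astype(np.int32), list(binmap.bins["bin"]))


# ---------------------------------------------------------------- groups

def group_markers(
    rf: PairwiseRF,
    lod_min: float = 2.0,
    lod_max: float = 10.0,
    expected: int | None = None,
) -> list[np.ndarray]:
    """Single-linkage grouping under a two-point LOD threshold.

    Integer thresholds are scanned upward from ``lod_min``; the chosen
    threshold is the first to yield ``expected`` groups when given, else
    the smallest whose group count is unchanged for 3 consecutive integer
    thresholds (fallback: ``lod_min``).  Groups are returned as marker
    index arrays sorted by decreasing size.
    """
    if not (2 <= lod_min <= lod_max):
        raise ValueError("need 2 <= lod_min <= lod_max")
    m = rf.n_markers
    lod = np.nan_to_num(rf.lod, nan=0.0)

    def components(t):
        adj = csr_matrix(lod >= t)
        n_comp, labels = connected_components(adj, directed=False)
        return n_comp, labels

    thresholds = np.arange(np.ceil(lod_min), np.floor(lod_max) + 1.0)
    counts, labelings = [], []
    chosen = None
    for t in thresholds:
        n_comp, labels = components(t)
        counts.append(n_comp)
        labelings.append(labels)
        if expected is not None and n_comp == expected:
            chosen = len(counts) - 1
            break
        if expected is None and len(counts) >= 3 and counts[-1] == counts[-2] == counts[-3]:
            chosen = len(counts) - 3
            break
    if chosen is None:
        chosen = 0
        _, labels = components(lod_min)
        labelings[0] = labels
    labels = labelings[chosen]
    groups = [np.flatnonzero(labels == k) for k in range(labels.max() + 1)]
    groups.sort(key=lambda g: (-len(g), g[0]))
    if all(len(g) == 1 for g in groups) and m > 1:
        warnings.warn("no marker pair exceeds lod_min: all singletons")
    return groups


# --------------------------------------------------------------- ordering

def _sarf(order: np.ndarray, r: np.ndarray) -> float:
    return float(r[order[:-1], order[1:]].sum())


def order_markers(group: np.ndarray, rf: PairwiseRF) -> tuple[np.ndarray, float]:
    """Order one linkage group by minimizing the sum of adjacent RFs.

    Greedy chaining from the tightest pair, extending the nearer end, then
    2-opt segment reversals to convergence.  Ties break on the lower
    marker index, so the result is deterministic.  Returns the ordered
    marker indices and the achieved SARF.
    """
    group = np.asarray(group)
    m = len(group)
    if m <= 2:
        return group.copy(), 0.0 if m < 2 else float(np.nan_to_num(rf.r[group[0], group[1]], nan=0.5))
    r = rf.r[np.ix_(group, group)].astype(float)
    r = np.nan_to_num(r, nan=0.5)  # undefined pairs treated as unlinked
    np.fill_diagonal(r, np.inf)
    # greedy chain
    i, j = np.unravel_index(np.argmin(r), r.shape)
    if i > j:
        i, j = j, i
    order = [i, j]
    used = {i, j}
    while len(order) < m:
        free = np.array([k for k in range(m) if k not in used])
        d_head = r[order[0], free]
        d_tail = r[order[-1], free]
        if d_head.min() < d_tail.min() or (
            d_head.min() == d_tail.min() and free[np.argmin(d_head)] < free[np.argmin(d_tail)]
        ):
            k = free[np.argmin(d_head)]
            order.insert(0, k)
        else:
            k = free[np.argmin(d_tail)]
            order.append(k)
        used.add(k)
    order = np.array(order)
    np.fill_diagonal(r, 0.0)

    def two_opt_pass(order):
        improved = False
        for a in range(m - 1):
            for b in range(a + 1, m):
                before = (r[order[a - 1], order[a]] if a > 0 else 0.0) + (
                    r[order[b], order[b + 1]] if b < m - 1 else 0.0
                )
                after = (r[order[a - 1], order[b]] if a > 0 else 0.0) + (
                    r[order[a], order[b + 1]] if b < m - 1 else 0.0
                )
                if after < before - 1e-12:
                    order[a : b + 1] = order[a : b + 1][::-1]
                    improved = True
        return improved

    def or_opt_pass(order):
        # relocate blocks of 1-3 markers (either orientation) wherever the
        # sum of adjacent RFs drops; catches misplaced blocks that segment
        # reversal alone cannot fix
        improved = False
        for size in (1, 2, 3):
            i = 0
            while i + size <= len(order):
                j = i + size - 1
                bs, be = order[i], order[j]
                left = r[order[i - 1], bs] if i > 0 else 0.0
                right = r[be, order[j + 1]] if j < m - 1 else 0.0
                bridge = r[order[i - 1], order[j + 1]] if 0 < i and j < m - 1 else 0.0
                gain = left + right - bridge
                rest = np.concatenate([order[:i], order[j + 1 :]])
                k = len(rest)
                # insertion cost between rest[t-1] and rest[t], t = 0..k
                prev_r = np.concatenate([[0.0], r[rest, bs]])
                next_r = np.concatenate([r[be, rest], [0.0]])
                gap_r = np.concatenate([[0.0], r[rest[:-1], rest[1:]], [0.0]])
                cost_fwd = prev_r + next_r - gap_r
                prev_rv = np.concatenate([[0.0], r[rest, be]])
                next_rv = np.concatenate([r[bs, rest], [0.0]])
                cost_rev = prev_rv + next_rv - gap_r
                t_f = int(np.argmin(cost_fwd))
                t_r = int(np.argmin(cost_rev))
                best_cost, t_best, rev = (
                    (cost_fwd[t_f], t_f, False)
                    if cost_fwd[t_f] <= cost_rev[t_r]
                    else (cost_rev[t_r], t_r, True)
                )
                if best_cost < gain - 1e-12:
                    block = order[i : j + 1][::-1] if rev else order[i : j + 1]
                    order = np.concatenate([rest[:t_best], block, rest[t_best:]])
                    improved = True
                else:
                    i += 1
                if improved and i + size > len(order):
                    break
        return order, improved

    for _ in range(40):
        imp1 = two_opt_pass(order)
        order, imp2 = or_opt_pass(order)
        if not (imp1 or imp2):
            break
    # canonical orientation: lower marker index first
    if order[0] > order[-1]:
        order = order[::-1]
    return group[order], _sarf(np.searchsorted(group, group[order]), np.nan_to_num(rf.r[np.ix_(group, group)], nan=0.5))


# ------------------------------------------------------------------- map


@dataclass
class LinkageMap:
    """Ordered bin markers with cumulative Kosambi positions.

    ``table`` columns: group (1-based id), marker, cm, plus the marker's
    chromosome and physical extent carried from the bin map.
    """

    table: pd.DataFrame

    @property
    def n_groups(self) -> int:
        return int(self.table["group"].nunique())

    def group_table(self, gid: int) -> pd.DataFrame:
        return self.table[self.table["group"] == gid].reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def build_map(
    groups: list[np.ndarray],
    rf: PairwiseRF,
    binmap: BinMap,
    max_adjacent_r: float = 0.45,
) -> LinkageMap:
    """Cumulative Kosambi positions along each ordered group.

    Adjacent meiotic r is capped at ``max_adjacent_r`` before conversion so
    a single bad adjacency cannot blow up the map length.  Groups are
    oriented to increase with physical position when a dominant chromosome
    is identifiable.
    """
    rows = []
    bins = binmap.bins
    for gid, group in enumerate(groups, start=1):
        order, _ = order_markers(group, rf)
        r_adj = np.nan_to_num(rf.r[order[:-1], order[1:]], nan=0.5) if len(order) > 1 else np.array([])
        r_adj = np.minimum(r_adj, max_adjacent_r)
        cm = np.concatenate([[0.0], np.cumsum(kosambi(r_adj))]) if len(order) > 1 else np.array([0.0])
        starts = bins["start"].to_numpy()[order]
        if len(order) > 2 and cm.std() > 0 and starts.std() > 0 and np.corrcoef(cm, starts)[0, 1] < 0:
            order = order[::-1]
            cm = cm[-1] - cm[::-1]
        for k, (mi, c) in enumerate(zip(order, cm)):
            rows.append(
                (
                    gid,
                    bins["bin"].iloc[mi],
                    int(mi),
                    float(c),
                    bins["chrom"].iloc[mi],
                    int(bins["start"].iloc[mi]),
                    int(bins["end"].iloc[mi]),
                    int(bins["n_snps"].iloc[mi]),
                )
            )
    table = pd.DataFrame(
        rows, columns=["group", "marker", "bin_idx", "cm", "chrom", "start", "end", "n_snps"]
    )
    return LinkageMap(table)


def construct_linkage_map(
    binmap: BinMap,
    lod_min: float = 2.0,
    lod_max: float = 10.0,
    expected_groups: int | None = None,
    generations: int | None = None,
) -> tuple[LinkageMap, PairwiseRF, list[np.ndarray]]:
    """Grouping + ordering + Kosambi placement in one call."""
    rf = pairwise_rf(binmap, generations=generations)
    groups = [g for g in group_markers(rf, lod_min, lod_max, expected=expected_groups) if len(g) > 0]
    lmap = build_map(groups, rf, binmap)
    return lmap, rf, groups


# ---------------------------------------------------------------- summary

def summary_totals(per_group: pd.DataFrame) -> pd.Series:
    """Grand totals of a per-group summary table.

    Total map length is the sum of group lengths; the headline overall
    marker interval is the mean of the per-group average distances (an
    alternative, total length / total markers, is also reported).
    """
    return pd.Series(
        {
            "n_markers": int(per_group["n_markers"].sum()),
            "length_cm": float(per_group["length_cm"].sum()),
            "avg_distance_cm": float(per_group["avg_distance_cm"].mean()),
            "avg_distance_cm_alt": float(
                per_group["length_cm"].sum() / max(per_group["n_markers"].sum(), 1)
            ),
            "max_gap_cm": float(per_group["max_gap_cm"].max()),
        }
    )


def map_summary(lmap: LinkageMap) -> tuple[pd.DataFrame, pd.Series]:
    """Per-group marker counts, lengths, gaps and cM/Mb, plus grand totals."""
    rows = []
    for gid in sorted(lmap.table["group"].unique()):
        t = lmap.group_table(gid)
        cm = t["cm"].to_numpy()
        gaps = np.diff(cm)
        length = float(cm[-1] - cm[0]) if len(cm) > 1 else 0.0
        chrom = t["chrom"].mode().iloc[0]
        tc = t[t["chrom"] == chrom]
        span_mb = (tc["end"].max() - tc["start"].min()) / 1e6
        rows.append(
            {
                "group": gid,
                "chrom": chrom,
                "n_markers": len(t),
                "length_cm": length,
                "avg_distance_cm": float(gaps.mean()) if len(gaps) else 0.0,
                "max_gap_cm": float(gaps.max()) if len(gaps) else 0.0,
                "cm_per_mb": length / span_mb if span_mb > 0 else np.nan,
            }
        )
    per_group = pd.DataFrame(rows)
    return per_group, summary_totals(per_group)
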