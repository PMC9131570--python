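"""Candidate-region single-marker GLM association scan.

For a diversity panel genotyped at dense SNPs inside a mapped candidate
interval: variants are filtered on missingness and minor-allele frequency,
each surviving SNP is tested by ordinary least-squares regression of the
phenotype on allele dosage (0/1/2), and SNPs passing a fixed genome-wide
p-value threshold are reported, together with simple interval arithmetic
and gene-overlap queries against an annotation table.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist


@dataclass(frozen=True)
class RegionSpec:
    """A physical candidate interval between two anchor markers."""

    chrom: str
    left_name: str
    left_bp: int
    right_name: str
    right_bp: int

    def __post_init__(self):
        if self.left_bp >= self.right_bp:
            raise ValueError("left anchor must precede right anchor")


def interval_length(region: RegionSpec) -> float:
    """Interval size in kb, reported to one decimal."""
    return round((region.right_bp - region.left_bp) / 1000.0, 1)


def filter_variants(
    dosage: np.ndarray,
    max_missing: float = 0.10,
    min_maf: float = 0.05,
) -> np.ndarray:
    """Keep mask over SNPs of a dosage matrix (0/1/2; negative = missing).

    A SNP survives when its missing fraction is <= ``max_missing`` and its
    MAF (from the non-missing dosages) is >= ``min_maf`` (inclusive, both).
    Both statistics are computed on the raw column, so filter order is
    irrelevant.
    """
    for thr in (max_missing, min_maf):
        if not (0 <= thr <= 1):
            raise ValueError("thresholds must lie in [0, 1]")
    D = np.asarray(dosage)
    n = D.shape[0]
    miss = (D < 0).sum(axis=0) / n
    valid = np.maximum((D >= 0).sum(axis=0), 1)
    with np.errstate(invalid="ignore"):
        freq = np.where(D >= 0, D, 0).sum(axis=0) / (2.0 * valid)
    maf = np.minimum(freq, 1 - freq)
    return (miss <= max_missing) & (maf >= min_maf)


def glm_scan(
    dosage: np.ndarray,
    phenotype: np.ndarray,
    positions: np.ndarray | None = None,
    min_samples: int = 10,
) -> pd.DataFrame:
    """Per-SNP OLS of phenotype on allele dosage (pairwise-complete).

    Returns one row per SNP: position, maf, missing fraction, slope,
    two-sided p from the slope's t statistic, and a ``tested`` flag (SNPs
    with zero dosage variance or fewer than ``min_samples`` complete pairs
    are skipped with p = NaN).
    """
    D = np.asarray(dosage, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    n, m = D.shape
    M = D >= 0
    Dm = np.where(M, D, 0.0)
    cnt = M.sum(axis=0)
    sum_x = Dm.sum(axis=0)
    sum_x2 = (Dm * Dm).sum(axis=0)
    sum_y = M.T @ y
    sum_y2 = M.T @ (y * y)
    sum_xy = (Dm * y[:, None]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_x = sum_x / cnt
        mean_y = sum_y / cnt
        sxx = sum_x2 - cnt * mean_x**2
        syy = sum_y2 - cnt * mean_y**2
        sxy = sum_xy - cnt * mean_x * mean_y
        beta = sxy / sxx
        rss = syy - sxy**2 / sxx
        dof = cnt - 2
        se = np.sqrt(np.maximum(rss, 0) / np.maximum(dof, 1) / sxx)
        tstat = beta / np.maximum(se, 1e-300)
    tested = (cnt >= min_samples) & (sxx > 1e-12)
    p = np.full(m, np.nan)
    p[tested] = 2 * t_dist.sf(np.abs(tstat[tested]), dof[tested])
    p[tested] = np.maximum(p[tested], np.finfo(float).tiny)
    freq = sum_x / (2 * np.maximum(cnt, 1))
    out = pd.DataFrame(
        {
            "snp": [f"snp{i}" for i in range(m)]
            if positions is None
            else [f"{int(p_)}" for p_ in positions],
            "pos": positions if positions is not None else np.arange(m),
            "maf": np.minimum(freq, 1 - freq),
            "missing": 1 - cnt / n,
            "beta": beta,
            "p": p,
            "tested": tested,
        }
    )
    return out


def significant_hits(result: pd.DataFrame, p_threshold: float = 1e-6) -> pd.DataFrame:
    """SNPs with p < threshold, ascending by p (the first row is the peak)."""
    hits = result[result["p"] < p_threshold].sort_values("p", kind="stable")
    return hits.reset_index(drop=True)


def shared_hits(res1: pd.DataFrame, res2: pd.DataFrame, p_threshold: float = 1e-6) -> pd.DataFrame:
    """Intersection of two traits' hit sets, by SNP position."""
    h1 = significant_hits(res1, p_threshold)
    h2 = significant_hits(res2, p_threshold)
    both = sorted(set(h1["pos"]) & set(h2["pos"]))
    return h1[h1["pos"].isin(both)].sort_values("pos").reset_index(drop=True)


# ----------------------------------------------------------- annotation


def load_candidate_genes() -> pd.DataFrame:
    """Bundled gene annotation for the Pv06 candidate region (G19833 v1.0)."""
    with importlib.resources.files("binqtl.data").joinpath("candidate_genes_pv06.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def genes_in_region(genes: pd.DataFrame, region: RegionSpec) -> pd.DataFrame:
    """Genes whose start position lies inside the region (same chromosome).

    The start-based rule keeps a gene that begins inside the interval but
    ends past the right anchor, matching how candidate lists are drawn up
    from anchor-marker intervals.
    """
    sel = (
        (genes["chrom"] == region.chrom)
        & (genes["start"] >= region.left_bp)
        & (genes["start"] <= region.right_bp)
    )
    return genes[sel].reset_index(drop=True)
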