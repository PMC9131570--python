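"""Trait computation and distribution diagnostics.

PDS (percentage of damaged seeds) and NP (number of perforations) are the
two bruchid-resistance assay readouts: PDS is the percentage of infested
seeds among those assayed, averaged over replicates; NP is the total count
of perforation holes across all assayed seeds.  The module also provides
the sample skewness/kurtosis used to judge approximate normality of a
segregating trait, trait correlation, and the 2^-ddCt relative-expression
calculator for qRT-PCR validation of a candidate gene.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def compute_traits(
    damaged: np.ndarray, total: np.ndarray, holes: np.ndarray
) -> dict:
    """PDS and NP for one line from per-replicate assay counts.

    ``damaged[i]`` / ``total[i]`` are infested and assayed seed counts of
    replicate i; ``holes[i]`` its total perforation count.  PDS is the
    mean of the per-replicate percentages; NP is the total across all
    assayed seeds.
    """
    damaged = np.asarray(damaged, dtype=float)
    total = np.asarray(total, dtype=float)
    holes = np.asarray(holes, dtype=float)
    if (total <= 0).any():
        raise ValueError("total seed counts must be positive")
    if (damaged > total).any() or (damaged < 0).any() or (holes < 0).any():
        raise ValueError("damaged counts must lie in [0, total] and holes be >= 0")
    return {
        "PDS": float((100.0 * damaged / total).mean()),
        "NP": float(holes.sum()),
    }


def moments(values: np.ndarray) -> tuple[float, float]:
    """Bias-adjusted sample skewness and excess kurtosis (normal -> 0, 0)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 4:
        raise ValueError("need at least 4 values")
    if np.var(x) == 0:
        return float("nan"), float("nan")
    return (
        float(stats.skew(x, bias=False)),
        float(stats.kurtosis(x, fisher=True, bias=False)),
    )


def trait_correlation(t1: np.ndarray, t2: np.ndarray) -> float:
    """Pearson correlation with pairwise-complete handling of NaNs."""
    a = np.asarray(t1, dtype=float)
    b = np.asarray(t2, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    a, b = a[ok], b[ok]
    if np.var(a) == 0 or np.var(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def trait_summary(traits: pd.DataFrame) -> pd.DataFrame:
    """Per-trait mean, range, skewness and excess kurtosis."""
    rows = []
    for col in ("PDS", "NP"):
        v = traits[col].to_numpy(dtype=float)
        sk, ku = moments(v)
        rows.append(
            {
                "trait": col,
                "mean": float(np.nanmean(v)),
                "min": float(np.nanmin(v)),
                "max": float(np.nanmax(v)),
                "skewness": sk,
                "kurtosis": ku,
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------ expression


@dataclass
class CtRecord:
    """qPCR cycle thresholds for one target/reference gene pair.

    Each array holds replicate Ct values; ``test`` is the condition of
    interest, ``calibrator`` the baseline it is expressed relative to.
    """

    target_test: np.ndarray
    ref_test: np.ndarray
    target_calibrator: np.ndarray
    ref_calibrator: np.ndarray

    def __post_init__(self):
        for name in ("target_test", "ref_test", "target_calibrator", "ref_calibrator"):
            v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if v.size < 1 or (v <= 0).any():
                raise ValueError(f"{name}: need >= 1 positive Ct value(s)")
            setattr(self, name, v)


def fold_change_ddct(ct: CtRecord) -> dict:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct_target - Ct_reference per condition (replicate-wise for the
    test condition, mean for the calibrator); ddCt = dCt_test -
    dCt_calibrator; fold = 2^-ddCt.  Returns the per-replicate folds, their
    mean and standard error.
    """
    dct_test = ct.target_test - ct.ref_test
    dct_cal = float(np.mean(ct.target_calibrator - ct.ref_calibrator))
    ddct = dct_test - dct_cal
    fold = np.power(2.0, -ddct)
    se = float(fold.std(ddof=1) / np.sqrt(fold.size)) if fold.size > 1 else 0.0
    return {"fold": fold, "mean_fold": float(fold.mean()), "se_fold": se, "ddct": ddct}
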