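"""Shared genotype encodings and containers.

Genotype calls are polarized against the two inbred parents of the cross:
``A`` is the parent-A homozygote, ``B`` the parent-B homozygote, ``H`` the
heterozygote.  Calls are stored as ``int8`` codes so that whole matrices can
be manipulated with plain numpy arithmetic (``abs(call) == 1`` selects the
informative, homozygous calls).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# int8 genotype codes
A: int = 1
B: int = -1
H: int = 0
MISSING: int = 9
# window-level code for windows with too few informative calls
UNCALLED: int = 7

CALL_CHAR = {A: "A", B: "B", H: "H", MISSING: "-"}
CHAR_CALL = {v: k for k, v in CALL_CHAR.items()}


@dataclass
class SNPMatrix:
    """Samples x SNPs matrix of parent-polarized biallelic calls.

    Parameters
    ----------
    snps
        One row per SNP with columns ``chrom``, ``pos`` (1-based bp) and,
        when the matrix originates from the simulator, ``cm`` (genetic
        position).  Positions must be strictly increasing within a
        chromosome.
    samples
        Sample identifiers, one per row of ``calls``.
    calls
        ``int8`` array of shape ``(n_samples, n_snps)`` using the module
        codes ``A``/``B``/``H``/``MISSING``.
    """

    snps: pd.DataFrame
    samples: list[str]
    calls: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.snps = self.snps.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if len(self.samples) < 2:
            raise ValueError("a SNP matrix needs at least 2 samples")
        valid = np.isin(self.calls, [A, B, H, MISSING])
        if not valid.all():
            raise ValueError("calls contain codes outside {A,B,H,MISSING}")
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def chroms(self) -> list:
        return list(dict.fromkeys(self.snps["chrom"]))

    def chrom_slice(self, chrom) -> slice:
        idx = np.flatnonzero((self.snps["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            raise KeyError(chrom)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def subset_snps(self, mask: np.ndarray) -> "SNPMatrix":
        mask = np.asarray(mask)
        return SNPMatrix(
            self.snps.loc[mask].reset_index(drop=True),
            list(self.samples),
            self.calls[:, mask],
            dict(self.meta),
        )

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path) -> None:
        """Write the long-format TSV dialect (sample, chrom, pos, call)."""
        n_s, n_p = self.calls.shape
        flat = self.calls.ravel()
        chars = np.select(
            [flat == A, flat == B, flat == H], ["A", "B", "H"], default="-"
        )
        df = pd.DataFrame(
            {
                "sample": np.repeat(self.samples, n_p),
                "chrom": np.tile(self.snps["chrom"].to_numpy(), n_s),
                "pos": np.tile(self.snps["pos"].to_numpy(), n_s),
                "call": chars,
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SNPMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
        samples = list(dict.fromkeys(df["sample"]))
        snps = (
            df[df["sample"] == samples[0]][["chrom", "pos"]]
            .reset_index(drop=True)
        )
        codes = df["call"].map(CHAR_CALL).to_numpy(dtype=np.int8)
        calls = codes.reshape(len(samples), len(snps))
        return cls(snps, samples, calls)


def informative(calls: np.ndarray) -> np.ndarray:
    """Boolean mask of homozygous (parent-informative) calls."""
    return np.abs(calls.astype(np.int16)) == 1
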