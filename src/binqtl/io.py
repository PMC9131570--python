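"""Readers, writers and run configuration.

VCF handling goes through pysam; the package's own tabular formats are
plain TSV.  Coordinates are 1-based inclusive in all user-facing tables
and VCF, 0-based half-open only in BED exports.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import A, B, H, MISSING, SNPMatrix

# Defaults follow the study design where it states them (15-SNP windows,
# 1:1 segregation test, LOD grouping range 2-10, 1000 permutations, LOD
# >= 3.0 calling floor, association filters 10%/0.05 and p < 1e-6); the
# remainder are package defaults documented in the methods note.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "n_lines": 157,
        "generations": 6,
        "n_snps_per_chrom": 1500,
        "error_rate": 0.005,
        "missing_rate": 0.05,
        "qtl": {"chrom": "Pv06", "pos_cm": 3.6, "add_pds": -10.0, "add_np": -30.0, "pve": 0.16},
        "trait_correlation": 0.88,
    },
    "genotyping": {
        "max_missing": 0.20,
        "min_maf": 0.05,
        "window_size": 15,
        "step": 1,
        "call_threshold": 11 / 15,
        "min_informative": 10,
        "min_discordant_run": 3,
        "segregation_alpha": 0.05,
    },
    "linkage": {"lod_min": 2.0, "lod_max": 10.0, "expected_groups": None},
    "qtl": {
        "step_cm": 1.0,
        "n_perm": 1000,
        "alpha": 0.05,
        "lod_min": 3.0,
        "p_in": 0.001,
        "p_out": 0.002,
        "exclusion_cm": 10.0,
    },
    "assoc": {
        "enabled": False,
        "n_accessions": 628,
        "max_missing": 0.10,
        "min_maf": 0.05,
        "p_threshold": 1e-6,
        "causal_pve": 0.2,
    },
}


def merge_config(user: dict | None) -> dict:
    """User settings layered over the defaults (one level of nesting)."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in (user or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        return merge_config(yaml.safe_load(fh) or {})


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


# -------------------------------------------------------------------- VCF


def write_vcf(snps: SNPMatrix, path) -> None:
    """SNP matrix as VCF 4.2 with the parent-A allele as REF (GT only)."""
    gt = {A: "0/0", B: "1/1", H: "0/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##binqtl=parent-A allele encoded as REF\n")
        for chrom in snps.chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(snps.samples) + "\n")
        chroms = snps.snps["chrom"].to_numpy()
        pos = snps.snps["pos"].to_numpy()
        for j in range(snps.n_snps):
            calls = "\t".join(gt[int(c)] for c in snps.calls[:, j])
            fh.write(f"{chroms[j]}\t{pos[j]}\t.\tA\tT\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf(path, parents: tuple[str, str] | None = None) -> SNPMatrix:
    """Read a biallelic VCF into a parent-polarized SNP matrix.

    Without ``parents`` the REF allele is taken as the parent-A allele
    (the convention of :func:`write_vcf`).  With ``parents`` =
    (parent_A_sample, parent_B_sample) each record is polarized by the two
    parents' homozygous calls, and records where the parents are not
    informative are skipped.  Multiallelic and indel records are skipped
    and counted.
    """
    import pysam

    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    if parents is not None:
        for p in parents:
            if p not in samples:
                raise ValueError(f"parent sample {p!r} not in VCF")
        ril_samples = [s for s in samples if s not in parents]
    else:
        ril_samples = samples
    rows, cols = [], []
    skipped = {"multiallelic_or_indel": 0, "uninformative_parents": 0}
    for rec in vf:
        if len(rec.alleles) != 2 or any(len(a) != 1 for a in rec.alleles):
            skipped["multiallelic_or_indel"] += 1
            continue
        a_allele = 0
        if parents is not None:
            ga = rec.samples[parents[0]]["GT"]
            gb = rec.samples[parents[1]]["GT"]
            if None in (ga + gb) or ga[0] != ga[1] or gb[0] != gb[1] or ga[0] == gb[0]:
                skipped["uninformative_parents"] += 1
                continue
            a_allele = ga[0]
        calls = np.empty(len(ril_samples), dtype=np.int8)
        for i, s in enumerate(ril_samples):
            gt = rec.samples[s]["GT"]
            if gt is None or None in gt:
                calls[i] = MISSING
            elif gt[0] == gt[1]:
                calls[i] = A if gt[0] == a_allele else B
            else:
                calls[i] = H
        rows.append((rec.chrom, rec.pos))
        cols.append(calls)
    vf.close()
    snps = pd.DataFrame(rows, columns=["chrom", "pos"])
    calls = np.stack(cols, axis=1) if cols else np.empty((len(ril_samples), 0), np.int8)
    out = SNPMatrix(snps, ril_samples, calls, meta={"skipped": skipped})
    if sum(skipped.values()):
        warnings.warn(f"skipped records: {skipped}")
    return out


# ------------------------------------------------------------------- TSV


def write_traits(traits: pd.DataFrame, path) -> None:
    traits[["sample", "PDS", "NP"]].to_csv(path, sep="\t", index=False)


def read_traits(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    missing = {"sample", "PDS", "NP"} - set(df.columns)
    if missing:
        raise ValueError(f"trait table lacks columns: {sorted(missing)}")
    return df
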