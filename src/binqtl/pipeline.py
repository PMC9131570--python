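"""End-to-end orchestration: simulate -> bin map -> linkage map -> QTL scan.

``run_pipeline`` executes the stages on a simulated RIL study (or on a
user-provided VCF + trait table), writes one TSV per stage plus the
effective configuration and a structured log into the run directory, and
returns the in-memory results.  Identical configuration and seed give
identical outputs.
"""
from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc as assoc_mod
from . import genotyping, linkage, phenostats, qtl, sim
from .core import SNPMatrix
from .io import DEFAULT_CONFIG, merge_config, save_config, write_traits, write_vcf

log = logging.getLogger("binqtl")


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)]


def run_pipeline(
    config: dict | None = None,
    out_dir=None,
    snps: SNPMatrix | None = None,
    traits: pd.DataFrame | None = None,
) -> dict:
    """Run the configured stages and return a dict of results.

    Without external ``snps``/``traits`` the bundled simulator generates
    the study (the default configuration emulates 157 F6 RILs on 11
    chromosomes with one planted 16%-PVE QTL and two correlated traits).
    """
    cfg = merge_config(config)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        save_config(cfg, out / "config.yaml")
    seeds = _spawn_seeds(int(cfg["seed"]), 6)
    results: dict = {"config": cfg}
    timings: dict = {}

    t0 = time.time()
    truth = None
    if snps is None:
        scfg = cfg["simulate"]
        if scfg.get("lengths_cm"):
            lengths = np.asarray(scfg["lengths_cm"], dtype=float)
            rates = np.asarray(
                scfg.get("cm_per_mb", [2.0] * len(lengths)), dtype=float
            )
            genome = sim.GenomeSpec(
                lengths, rates, np.full(len(lengths), scfg["n_snps_per_chrom"]), seed=seeds[0]
            )
        else:
            genome = sim.GenomeSpec.default(scfg["n_snps_per_chrom"], seed=seeds[0])
        truth = sim.simulate_ril_population(
            genome, scfg["n_lines"], scfg["generations"], seed=seeds[1]
        )
        snps = sim.observe_snps(truth, scfg["error_rate"], scfg["missing_rate"], seed=seeds[2])
        qspec = sim.QTLSpec(**scfg["qtl"])
        traits = sim.simulate_traits(
            truth, qspec, scfg["trait_correlation"], seed=seeds[3]
        )
        results["truth"] = truth
        if out is not None:
            write_vcf(snps, out / "snps.vcf")
            write_traits(traits, out / "traits.tsv")
            truth.to_bed(out / "true_segments.bed")
    if traits is None:
        raise ValueError("traits are required when snps are supplied")
    results["snps"] = snps
    results["traits"] = traits
    timings["simulate"] = time.time() - t0

    # genotype calling and binning
    t0 = time.time()
    gcfg = cfg["genotyping"]
    filtered = genotyping.filter_snps(snps, gcfg["max_missing"], gcfg["min_maf"])
    wg = genotyping.call_windows(
        filtered,
        gcfg["window_size"],
        gcfg["step"],
        gcfg["call_threshold"],
        gcfg["min_informative"],
    )
    bp = genotyping.detect_breakpoints(wg, filtered, gcfg["min_discordant_run"])
    binmap = genotyping.filter_segregation(
        genotyping.build_bins(bp, filtered), gcfg["segregation_alpha"]
    )
    effective = binmap.effective()
    results.update(breakpoints=bp, binmap=binmap, effective=effective)
    log.info(
        "binning: %d SNPs -> %d bins (%d effective), %d breakpoints",
        filtered.n_snps, binmap.n_bins, effective.n_bins, bp.total,
    )
    if out is not None:
        binmap.to_tsv(out / "binmap.tsv")
        bp.to_bed(out / "breakpoints.bed")
    timings["binmap"] = time.time() - t0

    # linkage map
    t0 = time.time()
    lcfg = cfg["linkage"]
    generations = cfg["simulate"]["generations"]
    lmap, rf, groups = linkage.construct_linkage_map(
        effective,
        lcfg["lod_min"],
        lcfg["lod_max"],
        expected_groups=lcfg["expected_groups"],
        generations=generations,
    )
    per_group, totals = linkage.map_summary(lmap)
    results.update(linkage_map=lmap, rf=rf, groups=groups, map_summary=per_group, map_totals=totals)
    log.info("linkage map: %d groups, %.2f cM", lmap.n_groups, totals["length_cm"])
    if out is not None:
        lmap.to_tsv(out / "linkage_map.tsv")
        per_group.to_csv(out / "map_summary.tsv", sep="\t", index=False)
    timings["linkmap"] = time.time() - t0

    # QTL scans per trait
    t0 = time.time()
    qcfg = cfg["qtl"]
    grid = None
    scans, thresholds, calls = {}, {}, []
    for k, trait in enumerate(("PDS", "NP")):
        y = traits[trait].to_numpy(dtype=float)
        scan, thr, qtls, grid = qtl.icim_pipeline(
            y,
            effective,
            lmap,
            step_cm=qcfg["step_cm"],
            n_perm=qcfg["n_perm"],
            alpha=qcfg["alpha"],
            lod_min=qcfg["lod_min"],
            p_in=qcfg["p_in"],
            p_out=qcfg["p_out"],
            exclusion_cm=qcfg["exclusion_cm"],
            generations=generations,
            seed=seeds[4] + k,
            trait=trait,
            grid=grid,
        )
        scans[trait] = scan
        thresholds[trait] = thr
        calls.append(qtls)
    qtl_table = pd.concat(calls, ignore_index=True) if calls else pd.DataFrame()
    results.update(scans=scans, thresholds=thresholds, qtls=qtl_table)
    if out is not None:
        pd.concat(
            [s.assign(trait=t) for t, s in scans.items()], ignore_index=True
        ).to_csv(out / "qtl_scan.tsv", sep="\t", index=False)
        qtl_table.to_csv(out / "qtl_table.tsv", sep="\t", index=False)
    timings["qtlscan"] = time.time() - t0

    # candidate-region association (optional demo on a simulated panel)
    acfg = cfg["assoc"]
    if acfg.get("enabled"):
        t0 = time.time()
        positions, dosage, y_panel, causal = sim.simulate_panel(
            acfg["n_accessions"], causal_pve=acfg["causal_pve"], seed=seeds[5]
        )
        keep = assoc_mod.filter_variants(dosage, acfg["max_missing"], acfg["min_maf"])
        res = assoc_mod.glm_scan(dosage[:, keep], y_panel, positions[keep])
        hits = assoc_mod.significant_hits(res, acfg["p_threshold"])
        results.update(assoc=res, assoc_hits=hits, assoc_causal_pos=int(positions[causal]))
        if out is not None:
            res.to_csv(out / "association.tsv", sep="\t", index=False)
        timings["assoc"] = time.time() - t0

    results["trait_correlation"] = phenostats.trait_correlation(
        traits["PDS"].to_numpy(), traits["NP"].to_numpy()
    )
    results["timings"] = timings
    if out is not None:
        with open(out / "run_log.json", "w") as fh:
            json.dump(
                {
                    "timings_s": {k: round(v, 2) for k, v in timings.items()},
                    "seed": cfg["seed"],
                    "n_bins": int(binmap.n_bins),
                    "n_effective": int(effective.n_bins),
                    "n_groups": int(lmap.n_groups),
                    "map_length_cm": float(totals["length_cm"]),
                    "thresholds": {k: float(v) for k, v in thresholds.items()},
                },
                fh,
                indent=2,
            )
    return results
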