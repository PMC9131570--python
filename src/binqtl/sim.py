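"""Synthetic RIL-population generator.

Emulates the study design of a biparental common-bean mapping experiment:
two fully inbred parents crossed to F1, then advanced by single-seed-descent
selfing to F6, giving a recombinant-inbred-line (RIL) population genotyped
at dense biallelic SNPs by resequencing.  The generator produces

* true ancestry mosaics per line (parent-A / parent-B / heterozygous
  segments with genetic-coordinate breakpoints),
* noisy SNP observations of those mosaics (genotyping error + missingness),
* two positively correlated quantitative traits (a 0-100% "damaged seeds"
  percentage and a non-negative perforation count) controlled by one
  planted additive QTL,
* a diversity panel (coalescent, via msprime) for the candidate-region
  association module.

Crossovers are drawn from a Poisson process (no interference): the count on
a chromosome of genetic length L cM is Poisson(L/100) and positions are
uniform.  The map functions downstream assume moderate interference
(Kosambi); the mismatch is deliberate and documented in the methods note.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import A, B, H, MISSING, SNPMatrix

# Defaults emulating an 11-chromosome bean genome: per-linkage-group map
# lengths (cM) and cM/Mb conversion rates typical of a ~1284 cM, ~537 Mb map.
DEFAULT_LENGTHS_CM = (
    95.36, 104.37, 159.84, 128.37, 116.43, 96.32,
    141.40, 166.73, 79.23, 100.12, 95.51,
)
DEFAULT_CM_PER_MB = (1.67, 1.93, 2.79, 2.52, 2.54, 2.61, 2.49, 2.58, 1.87, 2.07, 1.76)


def _chrom_names(n: int) -> list[str]:
    return [f"Pv{i + 1:02d}" for i in range(n)]


@dataclass
class GenomeSpec:
    """Chromosome layout and SNP placement for the simulated genome.

    Physical length of each chromosome is derived from its genetic length
    and a constant per-chromosome cM/Mb rate, so the physical<->genetic
    coordinate link is piecewise linear; SNP genetic position is then a
    strictly increasing function of physical position.
    """

    lengths_cm: np.ndarray
    cm_per_mb: np.ndarray
    n_snps: np.ndarray
    seed: int = 0
    snp_pos: list[np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.lengths_cm = np.atleast_1d(np.asarray(self.lengths_cm, dtype=float))
        self.cm_per_mb = np.atleast_1d(np.asarray(self.cm_per_mb, dtype=float))
        self.n_snps = np.atleast_1d(np.asarray(self.n_snps, dtype=int))
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if (self.lengths_cm <= 0).any() or (self.cm_per_mb <= 0).any():
            raise ValueError("chromosome lengths and cM/Mb rates must be positive")
        if len(self.cm_per_mb) != self.n_chromosomes or len(self.n_snps) != self.n_chromosomes:
            raise ValueError("per-chromosome arrays must have equal length")
        rng = np.random.default_rng(self.seed)
        self.snp_pos = []
        for L, n, plen in zip(self.lengths_cm, self.n_snps, self.phys_len_bp):
            pos = np.unique(rng.integers(1, plen, size=int(n)))
            while pos.size < n:  # top up collisions (rare: n << plen)
                extra = rng.integers(1, plen, size=int(n) - pos.size)
                pos = np.unique(np.concatenate([pos, extra]))
            self.snp_pos.append(pos.astype(np.int64))

    @property
    def n_chromosomes(self) -> int:
        return len(self.lengths_cm)

    @property
    def chroms(self) -> list[str]:
        return _chrom_names(self.n_chromosomes)

    @property
    def phys_len_bp(self) -> np.ndarray:
        return np.round(self.lengths_cm / self.cm_per_mb * 1e6).astype(np.int64)

    def snp_cm(self, i: int) -> np.ndarray:
        """Genetic positions (cM) of chromosome *i*'s SNPs."""
        return self.snp_pos[i] * self.cm_per_mb[i] / 1e6

    @property
    def total_cm(self) -> float:
        return float(self.lengths_cm.sum())

    @classmethod
    def default(cls, n_snps_per_chrom: int = 1500, seed: int = 0) -> "GenomeSpec":
        return cls(
            np.array(DEFAULT_LENGTHS_CM),
            np.array(DEFAULT_CM_PER_MB),
            np.full(len(DEFAULT_LENGTHS_CM), n_snps_per_chrom),
            seed=seed,
        )


@dataclass(frozen=True)
class QTLSpec:
    """One planted additive QTL shared by the two traits.

    ``add_pds``/``add_np`` are the half-differences between the parental
    homozygote trait means (trait units per allele substitution); ``pve``
    is the target fraction of phenotypic variance explained.
    """

    chrom: str
    pos_cm: float
    add_pds: float = -10.0
    add_np: float = -30.0
    pve: float = 0.16

    def __post_init__(self) -> None:
        if not (0 < self.pve < 1):
            raise ValueError("target PVE must lie in (0, 1)")


# ---------------------------------------------------------------- meiosis

Haplotype = tuple[np.ndarray, np.ndarray]  # (segment end positions cM, parent states)


def _pure_hap(L: float, state: int) -> Haplotype:
    return np.array([L], dtype=float), np.array([state], dtype=np.int8)


def _hap_states_at(hap: Haplotype, x: np.ndarray) -> np.ndarray:
    ends, states = hap
    return states[np.searchsorted(ends, x, side="left")]


def _merge_runs(ends: np.ndarray, states: np.ndarray) -> Haplotype:
    keep = np.ones(len(states), dtype=bool)
    keep[:-1] = states[:-1] != states[1:]
    return ends[keep], states[keep]


def simulate_meiosis(diplotype: tuple[Haplotype, Haplotype], length_cm: float,
                     rng: np.random.Generator) -> Haplotype:
    """Generate one gamete haplotype from a diplotype.

    Crossover count ~ Poisson(length_cm / 100), positions uniform on
    (0, L); the gamete is the alternating mosaic of the two parental
    strands starting from a randomly chosen strand.
    """
    if length_cm < 0:
        raise ValueError("chromosome length must be non-negative")
    n_xo = rng.poisson(length_cm / 100.0)
    strand = int(rng.integers(2))
    if n_xo == 0:
        ends, states = diplotype[strand]
        return ends.copy(), states.copy()
    xos = np.sort(rng.uniform(0.0, length_cm, size=n_xo))
    out_ends: list[float] = []
    out_states: list[int] = []
    prev = 0.0
    cuts = np.append(xos, length_cm)
    for cut in cuts:
        ends, states = diplotype[strand]
        i0 = np.searchsorted(ends, prev, side="right")
        i1 = np.searchsorted(ends, cut, side="left")
        for i in range(i0, min(i1 + 1, len(ends))):
            out_ends.append(min(float(ends[i]), cut))
            out_states.append(int(states[i]))
        prev = cut
        strand ^= 1
    e = np.array(out_ends)
    s = np.array(out_states, dtype=np.int8)
    keep = np.ones(len(e), dtype=bool)
    keep[1:] = e[1:] > e[:-1]
    return _merge_runs(e[keep], s[keep])


def _self_once(diplo, L, rng):
    g1 = simulate_meiosis(diplo, L, rng)
    g2 = simulate_meiosis(diplo, L, rng)
    return (g1, g2)


def _ancestry_from_diplo(diplo: Haplotype) -> Haplotype:
    """Collapse a diplotype into ancestry segments (A=+1, B=-1, H=0)."""
    (e1, s1), (e2, s2) = diplo
    cuts = np.union1d(e1, e2)
    mids = np.concatenate([[cuts[0] / 2], (cuts[1:] + cuts[:-1]) / 2])
    a1 = _hap_states_at((e1, s1), mids)
    a2 = _hap_states_at((e2, s2), mids)
    # parent states are 0 (A) / 1 (B): map pairs to ancestry codes
    anc = np.where((a1 == 0) & (a2 == 0), A, np.where((a1 == 1) & (a2 == 1), B, H))
    return _merge_runs(cuts, anc.astype(np.int8))


@dataclass
class TrueGenotypes:
    """True ancestry mosaics for a simulated RIL population.

    ``lines[i][chrom]`` is ``(ends_cm, states)``: ancestry segments tiling
    ``[0, L]`` with states ``A``/``B``/``H``.
    """

    genome: GenomeSpec
    generation: int | None
    lines: list[dict[str, Haplotype]]
    seed: int | None = None

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def sample_names(self) -> list[str]:
        return [f"RIL{i + 1:03d}" for i in range(self.n_lines)]

    def ancestry_at(self, chrom: str, cm: np.ndarray | float) -> np.ndarray:
        """Ancestry codes of every line at genetic position(s) ``cm``."""
        x = np.atleast_1d(np.asarray(cm, dtype=float))
        out = np.empty((self.n_lines, x.size), dtype=np.int8)
        for i, line in enumerate(self.lines):
            out[i] = _hap_states_at(line[chrom], x)
        return out

    def het_fraction(self) -> np.ndarray:
        """Per-line genome fraction that is heterozygous."""
        total = self.genome.total_cm
        out = np.zeros(self.n_lines)
        for i, line in enumerate(self.lines):
            het = 0.0
            for ends, states in line.values():
                seg = np.diff(np.concatenate([[0.0], ends]))
                het += seg[states == H].sum()
            out[i] = het / total
        return out

    def breakpoint_count(self) -> np.ndarray:
        """Per-line number of ancestry changes (segment boundaries)."""
        return np.array(
            [sum(len(h[0]) - 1 for h in line.values()) for line in self.lines]
        )

    def to_bed(self, path) -> None:
        """BED-like TSV of true segments (0-based half-open, bp coordinates)."""
        rows = []
        for name, line in zip(self.sample_names, self.lines):
            for ci, chrom in enumerate(self.genome.chroms):
                ends, states = line[chrom]
                rate = self.genome.cm_per_mb[ci]
                bp = np.round(ends / rate * 1e6).astype(np.int64)
                starts = np.concatenate([[0], bp[:-1]])
                for s, e, st in zip(starts, bp, states):
                    rows.append((chrom, s, e, name, {A: "A", B: "B", H: "H"}[int(st)]))
        pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "ancestry"]).to_csv(
            path, sep="\t", index=False
        )


def simulate_ril_population(
    genome: GenomeSpec,
    n_lines: int = 157,
    generations: int | None = 6,
    seed: int = 0,
) -> TrueGenotypes:
    """Simulate an F_g RIL population by single-seed descent.

    Each line is an independent lineage F1 -> F_g (``generations - 1``
    selfing meioses); ``generations=None`` selfs every line to complete
    fixation (an idealized fully inbred population).  Expected residual
    heterozygosity at F_g is ``(1/2)**(g-1)``.  One root seed spawns an
    independent child stream per line, so output is reproducible and
    insensitive to ``n_lines`` ordering.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if generations is not None and generations < 2:
        raise ValueError("generations must be >= 2 (F2 onward)")
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_lines)]
    lines = []
    for rng in streams:
        line: dict[str, Haplotype] = {}
        for ci, chrom in enumerate(genome.chroms):
            L = float(genome.lengths_cm[ci])
            diplo = (_pure_hap(L, 0), _pure_hap(L, 1))  # F1
            if generations is None:
                for _ in range(64):
                    diplo = _self_once(diplo, L, rng)
                    anc = _ancestry_from_diplo(diplo)
                    if not (anc[1] == H).any():
                        break
                line[chrom] = anc
            else:
                for _ in range(generations - 1):
                    diplo = _self_once(diplo, L, rng)
                line[chrom] = _ancestry_from_diplo(diplo)
        lines.append(line)
    return TrueGenotypes(genome, generations, lines, seed=seed)


# ------------------------------------------------------------ observation

def observe_snps(
    truth: TrueGenotypes,
    error_rate: float = 0.005,
    missing_rate: float = 0.05,
    seed: int = 0,
) -> SNPMatrix:
    """Observe the true mosaics at the genome's SNP positions.

    Each call equals the true ancestry state except: with probability
    ``error_rate`` a homozygous call is flipped to the other homozygote
    (a heterozygous truth is mis-called as a random homozygote), and with
    probability ``missing_rate`` the call is set missing; both independent
    per call.
    """
    for r in (error_rate, missing_rate):
        if not (0 <= r < 1):
            raise ValueError("error/missing rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    genome = truth.genome
    snp_tabs = []
    call_blocks = []
    for ci, chrom in enumerate(genome.chroms):
        cm = genome.snp_cm(ci)
        calls = truth.ancestry_at(chrom, cm)
        flip = rng.random(calls.shape) < error_rate
        rand_hom = rng.choice(np.array([A, B], dtype=np.int8), size=calls.shape)
        flipped = np.where(calls == H, rand_hom, -calls)
        calls = np.where(flip, flipped, calls).astype(np.int8)
        calls[rng.random(calls.shape) < missing_rate] = MISSING
        call_blocks.append(calls)
        snp_tabs.append(
            pd.DataFrame({"chrom": chrom, "pos": genome.snp_pos[ci], "cm": cm})
        )
    return SNPMatrix(
        pd.concat(snp_tabs, ignore_index=True),
        truth.sample_names,
        np.concatenate(call_blocks, axis=1),
        meta={"error_rate": error_rate, "missing_rate": missing_rate},
    )


# ----------------------------------------------------------------- traits

def simulate_traits(
    truth: TrueGenotypes,
    qtl: QTLSpec,
    trait_correlation: float = 0.88,
    mu_pds: float = 50.0,
    mu_np: float = 120.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the two resistance traits from a planted additive QTL.

    Both traits follow ``mu + a*x + e`` with ``x`` in {-1, +1} coded by QTL
    ancestry (heterozygotes 0); residual SDs are set so each trait's
    expected PVE equals ``qtl.pve``, and the residuals share a correlation
    ``(rho - pve) / (1 - pve)`` so the total trait correlation targets
    ``trait_correlation``.  PDS is clipped to [0, 100] (percentage); NP is
    rounded to a non-negative integer (count).  Clipping/rounding introduce
    a small documented downward bias in realized PVE and correlation.
    """
    if abs(trait_correlation) > 1:
        raise ValueError("|trait_correlation| must be <= 1")
    p = qtl.pve
    rho_e = (trait_correlation - p) / (1 - p)
    if abs(rho_e) > 1:
        raise ValueError("trait_correlation unattainable for this PVE")
    rng = np.random.default_rng(seed)
    x = truth.ancestry_at(qtl.chrom, qtl.pos_cm)[:, 0].astype(float)
    n = truth.n_lines
    sd1 = abs(qtl.add_pds) * math.sqrt((1 - p) / p) if qtl.add_pds != 0 else 1.0
    sd2 = abs(qtl.add_np) * math.sqrt((1 - p) / p) if qtl.add_np != 0 else 1.0
    z1 = rng.standard_normal(n)
    z2 = rho_e * z1 + math.sqrt(1 - rho_e**2) * rng.standard_normal(n)
    pds = np.clip(mu_pds + qtl.add_pds * x + sd1 * z1, 0.0, 100.0)
    np_count = np.maximum(np.rint(mu_np + qtl.add_np * x + sd2 * z2), 0.0)
    df = pd.DataFrame({"sample": truth.sample_names, "PDS": pds, "NP": np_count})
    df.attrs["qtl_genotype"] = x
    df.attrs["qtl"] = qtl
    return df


def realized_pve(trait: np.ndarray, x: np.ndarray) -> float:
    """R-squared of a trait on the true QTL genotype code (fraction)."""
    trait = np.asarray(trait, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.var(x) == 0 or np.var(trait) == 0:
        return 0.0
    r = np.corrcoef(trait, x)[0, 1]
    return float(r * r)


# ----------------------------------------------------- association panel

def simulate_panel(
    n_accessions: int = 628,
    region: tuple[int, int] = (1_367_622, 1_489_891),
    causal_pve: float = 0.2,
    missing_rate: float = 0.0,
    seed: int = 0,
):
    """Coalescent diversity panel for the candidate-region association scan.

    Simulates ``n_accessions`` diploid accessions over the physical
    ``region`` (bp) with msprime (Ne 1e4, r 1e-8, mu 2e-8) and plants one
    causal SNP (MAF >= 0.2) explaining ``causal_pve`` of trait variance.

    Returns
    -------
    positions : int array of SNP bp positions (offset into ``region``)
    dosage : int8 array (n_accessions, n_snps), 0/1/2 copies of the ALT
        allele, -1 for injected missing calls
    trait : float array, phenotype with the planted causal effect
    causal : index of the causal SNP in ``positions``
    """
    import msprime

    rng = np.random.default_rng(seed)
    length = region[1] - region[0]
    ts = msprime.sim_ancestry(
        samples=n_accessions,
        sequence_length=length,
        recombination_rate=1e-8,
        population_size=10_000,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    ts = msprime.sim_mutations(ts, rate=2e-8, random_seed=int(rng.integers(1, 2**31 - 1)))
    geno = ts.genotype_matrix()  # (sites, 2n) haploid
    biallelic = geno.max(axis=1) == 1
    geno = geno[biallelic]
    positions = ts.sites_position[biallelic].astype(np.int64) + region[0]
    dosage = (geno[:, ::2] + geno[:, 1::2]).T.astype(np.int8)  # (n, m)
    freq = dosage.mean(axis=0) / 2
    maf = np.minimum(freq, 1 - freq)
    candidates = np.flatnonzero(maf >= 0.2)
    if candidates.size == 0:
        raise RuntimeError("no common SNP to use as causal variant")
    causal = int(rng.choice(candidates))
    g = dosage[:, causal].astype(float)
    beta = 1.0
    var_g = np.var(g)
    sd_e = math.sqrt(var_g * (1 - causal_pve) / causal_pve)
    trait = beta * g + sd_e * rng.standard_normal(n_accessions)
    if missing_rate > 0:
        dosage = dosage.copy()
        dosage[rng.random(dosage.shape) < missing_rate] = -1
    return positions, dosage, trait, causal
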