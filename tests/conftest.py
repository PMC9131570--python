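"""Shared fixtures: small simulated populations reused across test modules."""
import numpy as np
import pytest

from binqtl.genotyping import (
    build_bins,
    call_windows,
    detect_breakpoints,
    filter_segregation,
)
from binqtl.sim import GenomeSpec, observe_snps, simulate_ril_population


@pytest.fixture(scope="session")
def genome3():
    """Three chromosomes, ~6 SNPs/cM."""
    return GenomeSpec(
        np.array([100.0, 90.0, 80.0]),
        np.array([2.0, 2.0, 2.0]),
        np.array([420, 400, 360]),
        seed=11,
    )


@pytest.fixture(scope="session")
def pop157(genome3):
    """The default study design: 157 F6 RILs."""
    return simulate_ril_population(genome3, n_lines=157, generations=6, seed=12)


@pytest.fixture(scope="session")
def snps157(pop157):
    """Noisy observations of the F6 population (0.5% error, 5% missing)."""
    return observe_snps(pop157, error_rate=0.005, missing_rate=0.05, seed=13)


@pytest.fixture(scope="session")
def binmap157(snps157):
    wg = call_windows(snps157)
    bp = detect_breakpoints(wg, snps157)
    return filter_segregation(build_bins(bp, snps157))


@pytest.fixture(scope="session")
def inbred_pop(genome3):
    """Fully inbred (selfed to fixation) 60-line population."""
    return simulate_ril_population(genome3, n_lines=60, generations=None, seed=21)


@pytest.fixture(scope="session")
def inbred_snps(inbred_pop):
    """Noise-free observations of the fully inbred population."""
    return observe_snps(inbred_pop, error_rate=0.0, missing_rate=0.0, seed=22)


def true_cm_of_bp(genome: GenomeSpec, chrom: str, pos_bp: float) -> float:
    """Physical bp -> true genetic cM under the genome's linear link."""
    ci = genome.chroms.index(chrom)
    return float(pos_bp * genome.cm_per_mb[ci] / 1e6)
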