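# Methods

`binqtl` reimplements, as one tested pipeline, the genotype-to-QTL analysis
used for resequenced biparental RIL populations: sliding-window genotype
calling, bin-map construction, Kosambi linkage mapping, ICIM-ADD QTL
scanning with permutation thresholds, and a candidate-region GLM
association scan. Because no real accessions ship with the package, a
first-class simulator generates study data with known truth; every claim
the test suite makes is a claim about recovery of that truth.

## The simulated study

**Genome.** Eleven chromosomes with per-group genetic lengths summing to
1283.68 cM and constant per-chromosome cM/Mb rates in the 1.67–2.79 range,
giving a ~560 Mb physical genome. SNP positions are uniform draws per
chromosome (default 1500/chromosome; analyses in the test suite use
300–600/chromosome — problem sizes chosen so a full pipeline replicate
runs in seconds). The physical↔genetic link is piecewise linear, so a
SNP's genetic position is strictly increasing in its physical position.

**Population.** Each RIL is an independent single-seed-descent lineage
from the F1: per selfing generation, two gametes are drawn from the same
parent by a no-interference meiosis (crossover count Poisson with mean
L/100, positions uniform). Defaults: 157 lines, F6, hence expected
residual heterozygosity (1/2)^5 ≈ 3.1%. `generations=None` selfs to
complete fixation — the idealized material used by the noise-free
round-trip tests. One root seed spawns a child RNG stream per line.
The Poisson (Haldane) crossover model deliberately ignores interference
even though distances are later reported on the Kosambi scale; at the
inter-marker distances a dense bin map produces (≪ 10 cM) the two map
functions differ negligibly, and the map-length recovery test bounds the
combined effect.

**Observation model.** Each SNP call equals the line's true ancestry
except: with probability `error_rate` (default 0.005, the scale expected
of ~14× resequencing calls) a homozygote is flipped to the other
homozygote (a true heterozygote mis-called as a random homozygote), and
with probability `missing_rate` (default 0.05) the call is missing —
independent per call.

**Traits.** Both traits follow `mu + a·x + e` with `x ∈ {−1, +1}` the QTL
ancestry code (heterozygotes 0). Residual SDs are set so each trait's
expected PVE equals the target (default 0.16); the residual correlation is
`(rho − p)/(1 − p)` so the total trait correlation targets `rho` (default
0.88). Defaults `mu = (50, 120)`, `a = (−10, −30)` put the percentage
trait mid-scale and give effect sizes of the magnitude reported for
bruchid-resistance assays (an additive effect of ~−0.11 on a 0–1 damaged
fraction is −11 in percent; ~−27 holes for the count trait). PDS is
clipped to [0, 100] and NP rounded to a non-negative integer; both
truncations bias realized PVE and correlation slightly downward (≈1 point
at the defaults; the Monte-Carlo tests bound it). Giving *both* traits
the QTL at equal PVE, rather than deriving the count trait purely from
the percentage trait's latent, reproduces the empirical shape of two
co-localized QTLs with ~16% PVE each.

**What the simulator does not emulate:** crossover interference, sharing
of lineages (every RIL is independent), depth-dependent error/missingness,
segregation distortion with a biological cause, multi-QTL architectures
(unless planted explicitly), and population structure in the association
panel beyond what the neutral coalescent provides. Passing tests
therefore show the pipeline recovers *this* generative model; on real
data the error model and distortion patterns will be less kind.

## Sliding-window genotyping

Windows of 15 SNPs advance by 1 SNP. Within a window only homozygous
calls are informative: the window is called A when the A fraction is at
least 11/15 (B symmetrically), H otherwise, and uncalled with fewer than
10 informative calls. The 11/15 default follows the sliding-window
genotyping tradition for resequenced populations; both threshold and
window size are configurable.

Breakpoint detection segments each sample's called windows (uncalled
windows are transparent). Three refinements make the segmentation exact
at SNP resolution on noise-free data:

1. **Transient-H absorption.** An H run shorter than one window flanked by
   the two different homozygotes is the signature of a single crossover
   sweeping through the window and collapses into one A↔B breakpoint.
   "Shorter than one window" is the operational definition of transient: a
   genuine segment must span at least `window_size` SNPs to fill a window.
2. **Majority re-typing + SNP-level boundary refinement.** Runs are
   re-typed by the majority call over their span (an H window run caused
   by a sub-window homozygous segment becomes that homozygote); each
   boundary is then refined to the SNP split maximizing flank-supporting
   calls, first between the adjacent runs' window centers and finally over
   the two segments' full extent (junctions near chromosome ends sit
   outside the window-center range). The breakpoint is placed at the
   midpoint of the two refined flank SNPs, i.e. inside one inter-SNP gap.
3. **Sub-window rescue.** Within each segment, a run of at least
   `min_discordant_run` consecutive discordant calls is promoted to a
   segment of its own. The default of 3 makes a false segment require
   three consecutive genotyping errors (~e³ per SNP triple); setting it to
   1 makes the caller exact on noise-free data, which is how the
   round-trip validation runs it.

Residual heterozygous segments at F6 are invisible to the informative-call
window rule (their windows are uncalled): short ones vanish into the
flanking homozygous segments, long ones surface as *missing* bin calls via
the coverage rule (a bin with no called window over any of its SNPs is
missing for that sample). This is the main known blind spot of the window
method as specified; measured bin-genotype accuracy at F6 with 0.5% error
is ≈ 99.9% with ≈ 3% missing.

Bins are the intervals between the union of all samples' breakpoint
midpoints; every SNP falls in exactly one bin, and no sample recombines
within a bin by construction. The 1:1 segregation filter removes bins
with χ² p < 0.05 (df 1, H and missing excluded); bins with no informative
sample carry a distinct "uninformative" flag.

## Linkage mapping

Pairwise recombination between bins is counted over jointly homozygous
lines, R capped at 0.4999. The meiotic fraction is recovered by inverting
the selfed-RIL relation. The classical complete-inbreeding form
r = R/(2(1−R)) is the API default, but the pipeline inverts the **exact
finite-generation curve** R_g(r), computed by the two-locus selfing
recursion and cached on an r-grid: conditioning on joint homozygosity at
F6 selects chromatin that fixed early and accumulated fewer junctions, so
the small-r slope of R(r) is ~1.68 at F6 rather than 2. Using the F∞ form
on F6 data shortens the map by ~19%; with the F6 correction the recovery
tests sit within ~4% of truth (tolerance ±15%).

Grouping is single-linkage on two-point LOD (likelihood ratio of binomial
R against 0.5), scanning integer thresholds from 2 to 10 and keeping the
smallest whose group count is stable for three consecutive thresholds (or
matching a user-supplied expected count). Ordering minimizes the sum of
adjacent recombination fractions by greedy chaining from the tightest
pair, refined by alternating 2-opt (segment reversal) and or-opt
(relocation of 1–3-marker blocks, either orientation) passes to
convergence; or-opt rescues misplaced blocks that reversal alone cannot
fix. Ties break on the lower marker index, so orders are deterministic;
for ≤ 8 markers the result matches the exhaustive-permutation optimum in
tests. Cumulative positions are running sums of Kosambi distances over
adjacent meiotic r, with adjacent r capped at 0.45 (≈ 36 cM) so one bad
adjacency cannot blow up a group's length; groups are oriented to
increase with physical position when a dominant chromosome is
identifiable.

The summary table reports per group: marker count, length, mean adjacent
gap, max gap, and cM/Mb over the physical span. The headline overall
marker interval is the *mean of per-group averages* (consistent with how
such tables are usually totalled); the alternative total-length /
total-markers figure is also reported.

## ICIM-ADD scan

Stage 1 selects background cofactors by forward–backward stepwise
regression on all bin markers (codes +1/−1, H and missing 0), with entry
p < 0.001 and removal p > 0.002 (common ICIM practice; configurable), a
model-size cap of min(n/5, 20), and collinear duplicates barred from
re-entry. Stage 2 scans a 1-cM grid: at each position the phenotype,
adjusted for all cofactors except those within ±10 cM on the same group,
is regressed on the expected QTL code E[x] = P(QQ) − P(qq) from the
flanking markers (Haley–Knott regression form; a deterministic,
closed-form-testable approximation to the EM mixture likelihood, left as
an extension point). LOD = (n/2)·log₁₀(RSS₀/RSS₁); the additive effect is
the fitted slope (positive ⇔ parent-A allele increases the trait); PVE is
the explained fraction of the *unadjusted* phenotypic sum of squares.
With no cofactors the scan reduces exactly to simple interval mapping.

Flanking-marker conditional probabilities treat the RIL genotype sequence
as a two-state Markov chain with transition probability R(r) per
interval. Selfed RILs are not exactly Markov: against the exact 3-locus
selfing enumeration the approximation is off by up to ~0.06 at r ≈ 0.3,
but below 0.01 at the r ≤ 0.05 intervals a dense bin map actually
produces, which the oracle test pins down. Heterozygous or missing flanks
contribute no information; with both flanks uninformative the prior
(1/2, 1/2) applies.

The permutation threshold re-runs the full ICIM procedure (cofactor
reselection + scan) on each permuted phenotype and takes the empirical
(1−α) quantile of the genome-wide maximum LOD (default 1000 permutations,
α = 0.05). Permutations in which no marker would enter the stepwise model
— the overwhelming majority under the null — take a vectorized
no-cofactor path that is numerically identical to the loop. QTLs are
called at peaks (prominence ≥ 1 LOD) above max(threshold, 3.0), reported
with flanking bin markers, the flanking interval size, a 1-LOD support
interval, and named `q<TRAIT><group>.<k>`. Calibration: across 300 null
studies the 200-permutation threshold is exceeded by its own scan 5% ± 2%
of the time.

Peak-PVE estimates carry the usual winner's-curse inflation plus the
sampling noise of R² itself (sd ≈ 5 points at n = 157, PVE 16%); recovery
is therefore validated on the *mean* peak PVE over replicates (±5 points)
while position recovery (±5 cM) is validated per replicate.

## Candidate-region association

Variants are filtered on missing fraction ≤ 0.10 and MAF ≥ 0.05 (both
boundaries inclusive, both computed on the raw column so filter order is
irrelevant). Each SNP is tested by OLS of phenotype on allele dosage
0/1/2 (heterozygotes kept and coded 1), pairwise-complete over missing
calls, two-sided p from the slope's t statistic, significance at
p < 1×10⁻⁶. No structure covariates are fitted by default, matching the
naive GLM such scans traditionally use; the scan is cross-checked against
statsmodels OLS in tests and its null p-values are uniform by KS test.
The demo panel is a neutral msprime coalescent (628 diploids, Ne 10⁴,
r 1e-8, mu 2e-8 over the 122.3 kb region) with one planted causal SNP.
Gene overlap uses the gene-start-within-region rule, which keeps a gene
that begins inside but ends past the right anchor — the convention that
reproduces published candidate lists drawn from anchor-marker intervals.

## Phenotype statistics

PDS is the mean over replicates of 100·damaged/total; NP is the total
hole count over all assayed seeds. Skewness and kurtosis are the
bias-adjusted sample estimators (normal ⇒ 0, 0); correlation is Pearson
with pairwise-complete missing handling; zero-variance inputs return NaN
sentinels rather than raising mid-pipeline. The 2^−ΔΔCt calculator takes
per-replicate ΔCt for the test condition against the mean calibrator ΔCt
and reports per-replicate folds with mean ± s.e.; swapping test and
calibrator inverts the fold exactly.

## Numerical choices and degenerate inputs

Chromosomes with fewer SNPs than one window get a single truncated window
(with a warning); samples with no callable window are flagged low-quality
and contribute missing bins; pairs with < 2 jointly homozygous lines are
undefined and excluded from grouping; zero-variance phenotypes or SNPs
are flagged, not fatal; r ≥ 0.5 maps to an infinite-distance sentinel.
Quantile interpolation for the permutation threshold is numpy's linear
default, so α = 1 returns the distribution minimum. All randomness flows
from explicit integer seeds through `numpy.random.SeedSequence`.

## Known limitations

Window genotyping cannot see segments shorter than `min_discordant_run`
SNPs or heterozygous segments shorter than roughly two windows; the
Markov flanking approximation and the regression (rather than mixture)
likelihood are small, documented approximations; JoinMap's regression
ordering and EM-based ICIM are not reproduced; the association module
fits no kinship or structure covariates. Map-length recovery inherits a
small downward bias (~2–4%) from sub-resolution segments lost to the
window caller.
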