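# Methods

## Deterministic selection model

The model describes two competing classes in an asexually reproducing cell
population: a focal clone at frequency *p*ₜ and the pooled background at
*q*ₜ = 1 − *p*ₜ. With relative fitness *w\** (the ratio of per-generation
multiplication factors), the odds update is *p*ₜ/*q*ₜ = (*p*₀/*q*₀)·*w\*ᵗ*,
equivalent to iterating *p* ← *p·w\** / (*p·w\** + *q*) once per generation.
The closed form is evaluated as 1/(1 + (*q*₀/*p*₀)·*w\**⁻ᵗ), which stays
finite and monotone for large *t*; beyond *t* ≈ 50 at the reference
parameter point the focal odds are within double precision of 1 and *p*ₜ
rounds to 1.0 exactly.

Assumptions: exactly two fitness classes, constant *w\** over the
experiment, no de-novo mutation (adaptation comes from pre-existing
variants), and deterministic dynamics (no drift) — drift lives in the
simulator, not the fitted model.

**Link function.** The measured observable is the population growth rate
(doublings/day). We link frequency to growth rate by the frequency-weighted
arithmetic mean of the per-capita rates,
GR(*t*) = η_anc + (η_sel − η_anc)·*p*ₜ. This is the simplest link whose
endpoints match the observations: GR(0) ≈ η_anc when the focal clone is
rare, and GR → η_sel as the sweep completes. It is an instantaneous
(per-day) mixture; over a finite passage the realized log-growth of a
mixture is log₂(*q*·2^(η_anc·d) + *p*·2^(η_sel·d))/d, which converges to
GR(*t*) as the passage length shrinks. The simulator tests exploit this by
comparing realized per-passage rates against GR evaluated at the passage
midpoint.

**Fitting.** `SelectionModel.fit()` minimises the residual sum of squares
over (*p*₀, *w\**, η_anc, η_sel) with `scipy.optimize.least_squares`
(trust-region reflective) under bounds *p*₀ ∈ (10⁻⁶, 1 − 10⁻⁶),
*w\** ∈ (10⁻³, 10³), η ∈ (−10, 10), tolerances 10⁻¹⁴ on cost, step and
gradient. Because *p*₀ and *w\** trade off along a ridge (a smaller initial
frequency with a larger advantage produces a similar sigmoid), the fit uses
seeded multi-start: one heuristic or user-supplied start plus, by default,
10 random restarts with log-uniform *p*₀ and *w\** and endpoint-anchored η
guesses; the best local optimum wins. Options pin η_anc/η_sel to supplied
values (a 2-parameter fit) and weight residuals by 1/SEM. A trajectory
whose range is below 10⁻⁶ doublings/day carries no selection signal: the
fit reports the mean rate for both endpoints and flags *p*₀ as
unidentifiable rather than raising. Confidence intervals are parametric
bootstrap (resampling each point from a normal with its SEM, refitting from
the point estimate, percentile intervals) and therefore require SEMs.

`time_to_frequency` solves *w\*ᵗ* = (θ/(1−θ))·(*q*₀/*p*₀) analytically,
takes the ceiling, and nudges the integer by ±1 against the closed form to
guard the boundary against floating-point error. When *w\** ≤ 1 and the
threshold exceeds *p*₀ the threshold is never reached and the function
returns `None`.

The generation axis is configurable: the default conversion is
1.875 days/generation (75 days ≈ 40 generations at the observed doubling
times).

## Barcode lineage tracing

Pipeline order is merge → quality filter → extract → cluster, per sample.

- **Merging** reverse-complements mate 2 and scans overlap lengths from
  longest to shortest, accepting the first overlap of ≥ 10 bases with
  mismatch fraction ≤ 0.1; disagreeing positions take the higher-quality
  base. Unmergeable pairs are dropped and counted.
- **Quality** is mean read Phred ≥ 30. The alternative reading (per-base
  minimum) is exposed as `min_base_phred`; mean-quality filtering is the
  common choice for short amplicons where a single low tail base would
  otherwise discard an informative read.
- **Extraction** finds the 5′ flank `GAGCCTCGTCTCCCACCG` allowing
  ⌊0.1·18⌋ = 1 substitution, takes the next 20 bases, and verifies the 3′
  flank `GTTTTGAGACGCATGCTGCA` within ⌊0.1·20⌋ = 2 substitutions; the
  leftmost anchor whose 3′ check passes wins, and barcodes containing N are
  rejected. Matching is substitution-only: it is deterministic, fast, and
  amplicon indels are rare relative to substitutions; an indel-tolerant
  matcher would change counts by well under the clustering tolerance.
- **Clustering** processes barcodes in descending count order (ties
  lexicographic). A barcode joins the cluster holding the most reads among
  those with *any member* within Levenshtein distance 1 (edlib) and a
  running total ≥ 3× the barcode's own count; otherwise it founds a
  cluster. Absorption passes repeat until stable, so a double-error read
  can chain through its observed single-error intermediate into the parent
  lineage (message-passing-style clustering). Matching against members
  rather than only the founding sequence is deliberate: with substitution
  errors at 0.005/base, ~5% of erroneous reads carry two errors and sit at
  distance 2 from the parent; member chaining recovers nearly all of them,
  while reads with no observed distance-1 intermediate are unreachable for
  any distance-1 method and remain as singleton clusters. Total read count
  is conserved exactly.
- **Retention criteria.** A lineage is kept iff it (1) exceeds 0.1%
  frequency in some sample *and* is detected in the ancestral sample, or
  (2) is detected in both selected groups or in more than two samples of
  one selected group, or (3) exceeds 0.5% in at least one gel-selected
  sample. Frequencies for rule 1 are per-sample ("in any sample"); the
  rule-level annotations are returned so displays can show which criterion
  fired. The rules are monotone in a lineage's own count.
- **Metrics.** log₂ fold changes use a pseudocount defaulting to one read
  in the shallowest library (so lineages absent from a sample have a
  finite, depth-aware fold change); the preference score is the mean soft
  log₂FC minus the mean stiff log₂FC; diversity collapse is
  100·(1 − detected-union-across-selected-replicates / ancestral count).

## RRBS differential methylation

Loci are read from Bismark-style coverage files (1-based, percentage
validated against the counts to 0.1). The coverage filter keeps a locus
only when depth ≥ 25 in *every* sample — the strictest reading, avoiding
condition-imbalanced regions; a pooled mode is available. Chaining is
greedy over sorted loci with the gap measured between consecutive member
positions (≤ 200 bp), so a long region may span more than 200 bp end to
end; region counts are sums over members. The methylation-level filter
keeps a region iff some condition has region-level M/T ≥ 0.5 in more than
75% of its replicates.

Per region, a binomial-logistic GLM logit(πⱼ) = β₀ + β₁·condⱼ is fitted by
IRLS (deviance tolerance 10⁻⁸, ≤ 50 iterations), with observed proportions
clamped to [0.5/T, 1 − 0.5/T] so complete separation yields finite
estimates without penalised likelihood. The LRT statistic is
deviance(null) − deviance(full) against χ²₁. With two conditions the full
model fits each condition's pooled proportion, so the statistic equals the
G-test on the pooled 2×2 table — the oracle used in the tests, alongside an
independent `statsmodels.GLM` cross-check. Binomial proportions are
scale-free, so library-size normalisation reduces to each sample's own T;
no TMM-style factor is applied. BH adjustment is
`statsmodels.stats.multitest`; the DMR call applies both thresholds
(p_adjust ≤ 0.01 and p ≤ 0.05) literally even though BH guarantees
adjusted ≥ raw, making the second threshold redundant under this
adjustment. BED export converts the 1-based inclusive region bounds to
0-based half-open.

At low coverage the LRT is visibly discrete (the pooled 2×2 lattice), so
its null distribution is compared to χ²₁ at per-sample depth 400, where the
continuous approximation is accurate; the ~5% type-I-error check runs at
depth 50. Neither depth is a property of the method — only of how finely
the lattice approximates a continuous statistic.

## Phenotype quantification

Spreading area is the shoelace area of the traced outline (shapely) scaled
by pixel size squared; orientation-independent. The N/C ratio is
(nuclear − background)/(cytoplasmic − background); a non-positive
denominator returns NaN rather than raising, since such cells are real and
must be flagged, not crash a batch. When masks are supplied, the cytoplasm
is cell minus nucleus and the default background is everything outside the
cell mask. RhoA activation is lysate/positive-control. Group comparisons
use the exact Mann–Whitney null for min(n) ≤ 8 without ties and the
tie-corrected normal approximation otherwise (two-sided, α = 0.05
convention); Welch's unequal-variance t-test covers the two-group ANOVA
case.

## Simulator

Within a passage every clone grows deterministically,
Nᵢ ← Nᵢ·2^(ηᵢ·days); drift enters only at the bottleneck, a multinomial
draw of exactly 2 × 10⁴ cells (deterministic mode: largest-remainder
rounding, bit-reproducible). This is the standard serial-dilution
idealisation: at a 2 × 10⁴-cell bottleneck the sampling noise dominates
birth–death noise within the passage. Replicate streams are independent
spawns of one master seed. The harvest size is uncapped exponential growth
over the passage; a carrying-capacity cap is not modelled.

The default sweep configuration mirrors the study conditions: 220 founder
lineages at uniform abundance, 2 × 10⁴ founder cells, 10 passages of ~7
days, one focal clone at ~1% with per-generation relative fitness 2.23
(neutral clones double once per generation; the focal clone's η is offset
by generations-per-passage·log₂ *w\**/days). Generations are counted in
units of a reference clone's doublings (default: the fastest clone).

Read generation draws lineages multinomially, embeds each barcode between
the true vector flanks with random pads, splits the 70-base template into
two 60-base mates (50-base overlap), and applies independent per-base
substitution errors to each mate; a configurable fraction of reads gets
mean Phred ~20 to exercise the quality filter, the rest ~37. Methylation
generation draws a per-region true level π ~ U(0.55, 0.9) — high enough to
survive the ≥ 50%-methylation filter, as in the CpG-island-like regions the
assay enriches — and shifts a truth-labelled subset of regions by a
log-odds effect in condition B, with per-locus counts binomial at constant
depth 50 by default. Image generation rasterises a disk nucleus inside a
disk cell over flat background with optional Gaussian noise and emits the
analytic truth.

### What the generators do not emulate

Real amplicon data also contain indels, chimeric PCR products, quality
drop-off along the read, and unequal library depths; real RRBS has
non-uniform coverage, beta-binomial overdispersion between replicates and
CpG-density-dependent region structure; real trajectories have
passage-to-passage environmental noise beyond i.i.d. Gaussian error; real
images have uneven illumination and segmentation error. Passing tests
therefore demonstrate correctness of the computations under the stated
generative assumptions, not robustness to every artefact of real data —
with the partial exception of overdispersion, which the binomial GLM would
understate on real replicates (a beta-binomial model is out of scope).

## Problem sizes used in the test suite

Closed-form-vs-iteration checks run on a (p₀, w\*) grid to t = 100;
noiseless fit recovery on a 3 × 3 parameter grid; noisy-recovery Monte
Carlo on 60 datasets with 8 restarts each (median-based assertions);
clustering recovery on 10⁵ simulated reads at the count level and 4 × 10³
read pairs through the full FASTQ path; null calibrations at 1000 regions;
multinomial-moment checks at 1000 bottleneck draws. The full suite runs in
well under a minute on one CPU.
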