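# Methods

## Model

The package estimates historical effective population size from the decay
of linkage disequilibrium with genetic distance. For two bi-allelic loci
with haplotype frequency f(AB) and allele frequencies f(A), f(B),

    D  = f(AB) − f(A) f(B)
    r² = D² / [ f(A) f(a) f(B) f(b) ]

Under drift–recombination equilibrium Sved's approximation gives
E(r²) = 1 / (1 + 4 N_e c) for markers c Morgans apart, and the LD at
distance c is attributed to the effective size T = 1/(2c) generations ago.
Inverting, N_e(T) = (1/4c) (1/E(r²) − 1). The default grid spans 0.5–50 cM
in 2000 equal steps, i.e. T from 100 down to 1 generation.

Assumptions inherited from this model: random mating, no selection or
migration at the probed timescale, markers in drift equilibrium, and a
map accurate enough that c is right on the 0.5–50 cM scale. The last
assumption is the reason the package carries three map methods (M1
constant ratio, M2 per-chromosome ratio, M3 loess interpolation of sparse
linkage anchors) and a bootstrap to compare them.

## r² estimation

The default estimator is the squared Pearson correlation of unphased
dosage vectors over pairwise-complete individuals ("composite" LD), which
is what genotype data supports without phasing; under random mating its
expectation matches the haplotype r² (property-tested by simulation). The
haplotype-frequency form of the formula is available for phased data, and
an EM estimator resolves the double-heterozygote phase ambiguity when
haplotype-level r² is wanted from genotypes. Composite r² carries a
finite-sample floor of about 1/n; the Weir–Hill-style correction
(subtract 1/n from E(r²) before inversion) is implemented but off by
default, so reported N_e at deep times (small c, r² near the floor) is
conservative (biased low) rather than corrected.

## LD-decay curves and combination across chromosomes

Per chromosome, 20 000 distinct marker pairs are drawn uniformly without
replacement (all pairs if fewer exist), r² is regressed on genetic
distance with a tricube-weighted local-linear smoother, and the fit is
read off on the fixed grid. The draw+fit is repeated 30 times with seeds
`seed + r`; the replicate mean and variance per grid point summarise each
chromosome. Chromosomes combine by inverse-variance weights w_c = 1/var_c
(weighted mean, SE = sqrt(1/Σw), 95% CI = mean ± 1.96 SE). A zero
replicate variance would give infinite weight; its weight is capped at
the largest finite weight at that grid point. A Shapiro–Wilk screen
across chromosomes at each grid point (Bonferroni threshold 0.05/2000)
checks the normality the weighting implicitly assumes.

**Smoother bandwidth.** The smoother's span is the fraction of pairs in
each local window. Pairs span whole chromosomes (100–300 cM), while the
decay curve drops hyperbolically inside the first ~10 cM; a wide span
(e.g. 0.3, a 30+ cM window) fits a local line across that convexity and
overestimates r² several-fold at short distances — on known-truth
simulations the resulting N_e comes out ~4× too low. The default span is
therefore 0.05, which at the short-distance end (where pair density is
highest) gives ~2–5 cM windows of ~1000 pairs: narrow enough to track
the decay, populated enough that replicate noise stays small. The span is
configurable; the map (M3) smoother is a separate setting (below).

**Loess acceleration.** Above 4000 pairs the points are pre-aggregated
into 1000 equal-width distance bins and the smoother runs on bin means
with count weights. Bin width (~0.1 cM) is far below any bandwidth in
use; on a noisy 20 000-pair fixture the binned and exact curves agree to
<0.003 while the fit is ~50× faster.

## N_e curves

Each chromosome's N_e curve is the Sved inversion of its replicate-mean
r² curve. Its variance per grid point is the variance of N_e across the
replicate-level curves pushed through the same inversion — the same
resampling scheme as the LD variances, rather than a delta-method
linearisation. The combined curve uses the same inverse-variance rule.
Generation-targeted values (e.g. at T = 1, 5, 20, 50, 100) are linear
interpolations on the T axis. Grid points where E(r²) ≤ 0 after any
correction are flagged NaN rather than extrapolated.

## Comparing map methods

At a grid point, the per-chromosome N_e values under two map methods are
compared with a parametric bootstrap (B = 1000, normality assumed, α =
0.05):

* mean test — studentised statistic |m₁ − m₂| / sqrt(v₁/n + v₂/n); null
  resamples draw both samples at the pooled mean with each sample's own
  variance and are re-studentised (bootstrap-t). The studentised form
  measures a type-I error of 0.050 over 5000 null trials at n = 26,
  where the raw |m₁ − m₂| statistic with plug-in variances is liberal
  (0.065) — the usual z-versus-t effect at small n.
* variance test — |log(v₁/v₂)|; null resamples keep each sample's mean
  and draw at the pooled variance.

p = (1 + #{T* ≥ T_obs}) / (B + 1); the +1 avoids zero p-values.

## Genetic maps

* **M1**: cM = Mb × ratio, default 1 cM/Mb (a single overall estimator,
  e.g. the genome mean 1.51, can be substituted).
* **M2**: per-chromosome ratio = total linkage cM / physical Mb, with
  physical length defined as the last chip SNP's position.
* **M3**: consecutive-anchor intervals are trimmed when their cM/Mb ratio
  reaches the genome-wide 99.9th percentile (type-7 quantile; genome-wide
  because assembly artefacts do not respect chromosome boundaries) or
  when ΔcM < 0 (implying an alternative marker order). Trimmed intervals
  collapse to zero genetic length — anchors stay addressable — and a
  local-quadratic loess (span 0.3) of anchor cM on physical Mb is
  evaluated at every chip SNP. Predictions are made non-decreasing by a
  running-maximum clamp, floored at 0, and extended past the anchor range
  at the chromosome's M2 ratio. Chromosomes with fewer than 10 surviving
  anchors fall back to M2 with a warning. On a degenerate constant-ratio
  map every interval ties at the percentile; trimming is skipped there
  (dispersion ≤ 1e-9 relative) instead of deleting the map.

Genetic positions are stored in cM; Morgans appear only inside the
N_e/T formulas. Kosambi and Haldane map functions are provided
(r = 0.5·tanh(2d) and r = 0.5(1 − e^(−2d)), d in Morgans): linkage-map
inputs follow the Kosambi convention, while the simulator places
crossovers without interference (Haldane). At the ≤ 50 cM distances that
drive N_e the two conventions differ by less than the recovery tolerance.

## Quality control

Filter order: SNP call rate (< 0.95 removed; the threshold is
configurable since published pipelines rarely print it) → MAF (> 0
required; monomorphic SNPs out) → Hardy–Weinberg (1-df chi-square without
continuity correction, removal at p ≤ 1e-6; an exact test is available —
at this extreme threshold the choice rarely matters) → sex check → drop
non-autosomal SNPs → animal call rate (≤ 0.95 removed, as an inclusive
bound) → IBS duplicates. HWE is only tested on autosomes: hemizygous
males put X markers out of HWE regardless of data quality. In `combined`
mode (all breeds pooled) the per-dataset HWE test is skipped — a mixture
of diverged populations fails HWE for reasons that are not genotyping
error — and a SNP is removed only when it fails within **every** breed
group.

The sex check infers female when > 3% (strict) of an animal's non-missing
X calls are heterozygous, male otherwise, and flags disagreements with
the recorded sex; animals with fewer than 10 X calls are not called.
IBS uses 2000 randomly chosen autosomal markers (seeded; all markers if
fewer) with IBS(i,j) = mean of (2 − |d_i − d_j|)/2 over shared calls;
pairs at ≥ 0.95 are flagged and the lower-call-rate member removed (ties
break toward the lexicographically later id, for determinism). The
stricter MAF ≥ 0.05 filter applies only to the LD stage's input, so
diversity statistics keep rare variants.

Breed groups follow the composition rules: a pure group at ≥ 75% of one
breed; otherwise composites by the Romney+Coopworth+Perendale total (RCP):
RCP > 0.5 splits on Texel < / ≥ 0.25, and 0.3 < RCP ≤ 0.5 is its own
group (half-open boundary).

## Diversity

Observed heterozygosity is computed before any missing-data imputation
(imputation inflates it). The GRM is G = ZZ'/Σ2p(1−p) with Z centred at
2p; three centring models (pooled, per-group, and per-animal expected
dosages from a least-squares regression on breed-composition columns) make
the breed-composition adjustment explicit — the regression variant is a
generic stand-in for published breed-adjusted GRMs, not a reimplementation
of any specific one. Missing dosages contribute zero after centring
(mean imputation per SNP). Inbreeding is mean(diag G) − 1 per group;
distances are d_ij = 1 − g_ij (diagonal forced 0); MDS is classical
Torgerson scaling with negative eigenvalues truncated (warned). Within
each group the ceil(1%) animals with the largest Σ_j d_ij² are flagged as
probable pedigree/breed-recording errors.

## The simulator and what passing tests mean

`simulate_population` is a discrete-generation diploid Wright–Fisher
model: parents drawn uniformly with replacement, gametes recombine with
Poisson(map length in Morgans) crossovers placed uniformly on the genetic
map, no mutation (standing variation only — irrelevant over ≤ 100
generations), no selection, non-overlapping generations. Initial
haplotypes are independent draws at uniform(0.05, 0.5) frequencies, so
all LD is built by drift during burn-in (default 400 generations ≥ 4N;
a warning fires below that). The N_e trajectory is piecewise constant,
most recent epoch first. When the genotyped cohort exceeds the breeding
population (the recovery fixture genotypes 200 animals from N_e = 100),
the cohort is drawn as offspring of the final generation — the usual
relationship between a livestock drop and its breeding flock.

Default study conditions: the recovery fixture runs constant N_e = 100,
3 chromosomes × 2000 SNPs at 100 cM (1 cM/Mb), burn-in 400, cohort 200,
five seeds; the tiny fixture (N = 50, 2 × 250 SNPs, cohort 50) is a
seconds-scale smoke profile whose heavy drift fixes most loci — realistic
for its size, but only the recovery profile is used for parameter
recovery claims.

What the simulator does **not** emulate: mutation, gene conversion,
overlapping generations, assortative mating, selection, genotyping error
beyond MCAR missingness, and real chip ascertainment bias. Passing
recovery tests therefore shows the estimator chain is correct under the
model's own assumptions, not that real-data estimates are unbiased —
e.g. ascertainment and admixture effects on r² are out of scope.
`corrupt` adds MCAR missingness, exact duplicate animals (missingness
applied after duplication, so copies differ in their missing patterns)
and an X chromosome with sex-consistent heterozygosity for exercising QC.

## Numerical choices and degenerate inputs

* All stochastic steps take explicit integer seeds; replicate r uses
  seed + r; the pipeline fans one config seed out by fixed stage offsets.
* Decay-curve predictions are clamped to [0, 1]; fewer than 50 pairs
  inside the grid range flags the chromosome absent for that replicate.
* A single replicate reports its mean with variance missing; a grid point
  with fewer than two finite replicate N_e values reports variance NaN.
* Pairs beyond 50 cM still inform the smoother near the boundary; the
  grid itself never extends past the printed range.
* `sample_pairs` decodes uniform draws from the triangular pair index, so
  the 20 000 pairs are exactly uniform over distinct unordered pairs.
* Interval trimming uses ≥ on the percentile; an all-tied (constant
  ratio) map skips the percentile trim entirely.
* Outlier pruning rounds the 1% up (ceil), so a 50-animal group flags one.

## Known limitations

* N_e beyond ~100 generations needs sub-0.5 cM marker density; the grid
  deliberately stops there.
* The loess span defaults are tuned to 50K-chip-scale marker density; far
  denser panels may want smaller spans.
* The breed-composition GRM regression is one reasonable adjustment, not
  a validated match to any specific published variant.
* Composite r² on small cohorts carries the 1/n floor; with the
  correction off, deep-time N_e is systematically conservative.
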