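# Methods

This note documents the statistical model, the numerical choices, and the
limits of what the synthetic-data validation shows. Notation: positions in a
context window are −5..+5 with 0 the mutated base; b ranges over {A, C, G, T}.

## Weight matrices

A context set is a collection of 11-mers centered on mutated cytosines,
strand-normalized so the center is always C (a G-centered site contributes
the reverse complement of its context; complementary substitutions are
pooled into six classes because the mutated strand is unknown). From n
windows we tabulate counts n(b, j) and frequencies f(b, j) = n(b, j)/n. The
background e(b) is the mean of f(b, j) over the four outermost positions
(−5, −4, +4, +5), which are taken to be uninformative; this normalizes away
the base composition of the training genome. The log-odds table is

    W(b, j) = log2[ f(b, j) / e(b) ]   (bits).

**Smoothing.** Zero counts would make W infinite, so 0.5 (a Jeffreys-style
pseudocount) is added to every count before frequencies are formed, and e(b)
is floored at 1/(4n) and renormalized to sum to 1. Both corrections are
O(1/n) and negligible at the set sizes used here (hundreds of windows); the
floor and renormalization only bind when a base is entirely absent from the
flanks.

**Scoring.** Matrices are stored over −5..+5 but scored over −3..+3 (seven
positions, the informative core). A window's matching score is
S = Σ_j W(b_j, j); the bounds Smin = Σ_j min_b W(b, j) and
Smax = Σ_j max_b W(b, j) over the scoring window rescale it to the percent
matching score ("weight") 100·(S − Smin)/(Smax − Smin) ∈ [0, 100]. A matrix
with Smax = Smin (flat log-odds) is rejected as degenerate. The percent
score is invariant under adding a constant to any column of W and under
scaling W; both invariances are property-tested.

**Information content.** IC(j) = 2 + Σ_b f log2 f bits, in [0, 2]. For text
consensus output the most frequent base is printed upper case at IC ≥ 1 bit,
lower case at 0.25–1 bit, '.' below. The two thresholds are display
conventions of this package, not measured quantities.

**Comparing context sets.** Two sets are compared by a per-position 2×4
contingency χ² on raw counts, summed over the 10 flanking positions (the
center is constant). Degrees of freedom are computed structurally as
10 × (4 − 1) = 30; a user-supplied df override is accepted for comparison
with analyses that used a different convention (e.g. 42, which corresponds
to a ±7-window scheme). A Bonferroni-corrected critical value is exposed for
a user-supplied family size.

## The footprint statistic

For each somatic C:G mutation with a full ±60 bp context, the 121-bp
neighborhood is extracted. The *mutated* weight is the percent score of the
mutation's own window; the *background* weights are the percent scores of
every other C/G site in the neighborhood whose ±5 window lies inside it
(offsets 5..115, center excluded; G sites are scored on the reverse
complement). Only C/G-centered positions are scoreable by the C-centered
deaminase matrices, which makes the background site set symmetric with the
treatment of the mutated sites. Overlapping neighborhoods of nearby
mutations may share background sites; each mutation is treated as an
independent observation.

The **ratio** is mean(mutated weights) / mean(background weights); values
above 1 indicate motif enrichment at mutated sites. Two tests gate a claim:

* **t-test** — Welch's unequal-variance 2-sample, 2-tailed, of mutated vs.
  pooled background weights. Welch is used because the background pool is
  much larger and differently dispersed than the mutated sample. The gate
  compares the t statistic against a conservative large-sample critical
  value, the normal quantile at the Bonferroni-corrected level
  α/(number of tests in the scan)/2 (e.g. 3.1 for α = 0.05 over 24 tests).
* **Monte Carlo test** — 1-tailed: in each of mc_iters iterations (default
  1000), one uniformly random eligible site is drawn from each mutation's
  own neighborhood and the mean of the draws is compared with the observed
  mutated mean; p = (1 + #{means ≥ observed}) / (mc_iters + 1) with the
  standard permutation +1 correction, so the smallest attainable p is
  1/(mc_iters + 1) ≈ 0.001. Per-neighborhood resampling (rather than pooled)
  preserves each record's local composition.

A result is **significant** only when both tests pass and the group holds at
least n_min = 50 mutations (smaller groups are reported with a null
significance flag). Random seeds for each (tissue, class, matrix) cell are
derived by hashing the labels with the master seed, and records are put in
canonical order before resampling, so results are independent of input
order. Scans stratify by tissue × substitution class × matrix, and the
Bonferroni family defaults to (groups × matrices).

Ratio tables are clustered by UPGMA (average linkage) on Euclidean distances
between ratio vectors, rows and columns separately; ties are broken by
merging the pair with lexicographically smallest leaf labels, and output is
Newick with branch lengths (merge height = distance/2). Heatmap export bins
values with class-specific (min, max, step) grayscale ranges — C:G>T:A:
(1, 1.573, 0.01); C:G>G:C: (1, 1.802, 0.01); C:G>A:T: (1, 1.362, 0.02);
false-positive-fraction maps: (0.01, 0.84, 0.05) — with values below the
class floor rendered white.

## Attributable-fraction estimation

The weight distribution of mutated sites is modeled as a two-component
normal mixture fitted by EM. The mixing weight of the higher-mean component
estimates the fraction of mutations attributable to the deaminase, by
analogy with coding-density estimation from score distributions.

EM specifics (all exposed as parameters): initialization at the 25th/75th
percentiles with equal mixing weights and pooled variance; convergence when
the mean per-observation log-likelihood gain falls below tol = 1e-6 (the
per-observation convention keeps near-degenerate single-component data from
spinning for thousands of iterations while leaving genuine mixtures
unaffected); max 1000 iterations; σ floored at 0.5 weight units, with one
restart from a perturbed initialization if a component collapses, after
which the fit is flagged and the fraction withheld. The log-likelihood path
is retained and asserted non-decreasing in tests. At least 100 observations
are required.

**Goodness-of-fit gate.** Observed counts in decade bins [0,10), ...,
[90,100] are compared with expected counts from the fitted mixture CDF
(tails folded into the end bins); adjacent bins are pooled until every
expected count is ≥ 5; df = pooled bins − 1 − 5 fitted parameters, floored
at 1. The fraction is reported only when the χ² test does not reject
(p ≥ 0.05) and the fit converged without collapse.

**Boundary pileup.** Weights live on [0, 100] but the components are
untruncated normals. When the last decade bin exceeds its neighbor by more
than 2×, a boundary-pileup warning is raised: distributions crushed against
the scale boundary are the known failure mode of this decomposition and can
yield badly distorted mixing weights even when the fit formally converges.

## Control experiments

1. **Negative set** — a plain scan on a mutation table where no enrichment
   is expected (mitochondrial catalogues in practice; synthetic motif-free
   tables here). Expected: ratios ≤ ~1, no dual-test significance; isolated
   single-test hits are reported but not counted.
2. **Shuffled matrices** — each training window's 10 flanking bases are
   permuted (center fixed, per-sequence composition preserved exactly), the
   matrices rebuilt, and the scan re-run. The fraction of dual-significant
   outcomes on null mutation sets estimates the false-discovery behavior.
3. **Random matrices** — matrices built from composition-matched random
   genomic C/G sites ("pseudo-mutable motifs"). Matching draws a random
   site sample and then applies a local search over single-window swaps
   until every base's set-level frequency is within 1 percentage point of
   the template's, followed by a 2-tailed t-test on per-window A+T fraction;
   a significant difference triggers a full redraw (up to 1000 attempts,
   then an error). Any template whose aggregate false-positive fraction
   exceeds 0.25 is flagged unreliable.
4. **Positive set** — a scan on mutations planted in a known motif (the
   immunoglobulin somatic-hypermutation analog): the matching matrix must
   fire, non-matching matrices must not.

Replicate counts default to desk scale (enzyme sets × a few shuffles /
samples); all runs are exactly reproducible from the configuration and the
master seed.

An **A/T-content filter** is provided for A/T-rich mutation catalogues:
contexts with ≥ 50% A+T among the 10 flanking bases (inclusive) are removed
before analysis, because A/T-rich mutable motifs inflate false positives on
A/T-rich backgrounds.

## Synthetic data

`simulate_genome` draws i.i.d. bases at a specified composition (default
uniform). `simulate_context_set` draws 11-mers position-independently from a
motif specification; the default enzyme emulations encode the qualitative
structure of the six deaminase motifs (T at −1 for APOBEC1/3A/3B, APOBEC1
with an extra weak T at −3; T at −2 for APOBEC3C; a wcCCw-like pattern for
APOBEC3G; WRC for AID) with 0.9 of the probability mass on the preferred
base(s) at strongly informative positions and 0.7 at weakly informative
ones. These conservation levels were chosen once as a realistic contrast
between "upper case" and "lower case" motif positions; the emulations are
synthetic stand-ins, not experimentally derived matrices.

`simulate_mutation_dataset` plants a fraction π of n mutations into eligible
C/G sites with probability proportional to 2^S (S the site's matching score
in bits) — a Boltzmann weighting that yields a smooth, tunable enrichment
without inventing a hard score cutoff — and draws the rest uniformly; every
record's true origin is kept in a truth sidecar. On a uniform genome the
2^S weighting makes planted-site contexts converge exactly to the motif
distribution (the factorized weight cancels the uniform base measure), which
is property-tested.

**What the generator does not emulate:** kataegis/processive mutation
clusters, replication- or transcription-strand asymmetry, regional mutation
rate variation, 5-methylcytosine deamination, and real-genome composition
structure (repeats, isochores). Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under the stated
model, not robustness to every property of real tumor genomes; the control
experiments are the tool for assessing a real dataset.

## Problem sizes used in validation

The test suite and the acceptance script run at desk scale, chosen as the
package's own validation conditions: genomes of 50–100 kb, context sets of
300–1000 windows, mutation tables of 250–2000 records, 200–1000 Monte Carlo
iterations, and mixture fits at n = 5000. The shuffle-control validation
measures the dual-gate false-positive fraction over 100 matrix-by-set
combinations (five enzyme context sets × four shuffle replicates × five
motif-free 500-record sets) on a 100 kb uniform genome.

## Known limitations

* The background model e(b) assumes the outer ±4/±5 positions are
  uninformative; motifs with genuine signal there would be mis-normalized.
* The mixture uses untruncated normals on a bounded scale; the GOF gate and
  pileup warning mitigate but do not remove boundary distortion.
* Pure rejection/swap composition matching can declare "composition
  unmatchable" when a template's composition is genuinely unreachable from
  the sampling genome (e.g. strongly motif-biased templates on a genome of
  opposite skew).
* Dinucleotide and higher-order dependencies between positions are not
  modeled (mononucleotide matrices only), and motif discovery is out of
  scope: matrices are always built from aligned mutation contexts.
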