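# Methods

`proxitome` re-implements, as a tested library, the computational workflow
by which a TurboID proximity-labeling screen turns replicate LC-MS/MS
intensity tables into a high-confidence interactome, and the downstream
genomic and gene-set analyses that characterize that interactome. This
note documents the models, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
conventions.

## Differential enrichment model

For one experiment the processing chain is fixed:

1. **log2 transform** of raw intensities; missing cells stay missing.
2. **Per-sample mean normalization**: each sample column is shifted so its
   mean over present values equals the grand mean of all present values.
   Centering to the grand mean rather than to zero keeps the matrix on an
   interpretable log2-intensity scale for the imputation parameters; the
   test statistics are identical either way. Note that mean normalization
   attenuates fold changes by roughly the fraction of differential signal
   in the bait columns (a few percent under the default study design);
   this is inherent to the method, not an implementation artifact.
3. **Downshifted-normal (MNAR) imputation**: each missing cell is drawn
   from Normal(μ − d·σ, (w·σ)²) where μ, σ are the mean and SD of present
   values in the cell's scope. Defaults: downshift d = 2.0 (the standard
   "two standard deviations below the mean" treatment of
   missing-not-at-random dropout), width factor w = 0.3 (the widely used
   Perseus convention; imputing at the full observed σ inflates the
   variance of largely-missing proteins), scope = per sample (sample-wise
   detection limits differ). The imputation RNG is seeded; identical
   inputs and seed reproduce identical values bit-exactly.
4. **Welch (heteroscedastic) t-test** per protein, bait vs reference, with
   Welch–Satterthwaite degrees of freedom and a two-sided p-value.
   Degenerate inputs follow documented conventions: two identical
   constant groups give t = 0, p = 1; two unequal constant groups give
   p = 0 with a warning.

A protein is **enriched** at level α when p < α (strict) *and* its log2
fold change (bait − reference) is positive: the screen seeks proteins
biotinylated above background, so enrichment is one-directional although
both tails are reported. No multiple-testing correction enters the
filtering path (the workflow filters on raw p at 0.05 and 0.1);
Benjamini–Hochberg q-values are emitted as an audit column only.

A protein is **testable** only with at least one non-imputed measurement
in the bait group (configurable); calls driven purely by imputed noise are
meaningless. Proteins with no measurement anywhere in an experiment were
not identified in that MS run and are dropped before imputation, surfacing
downstream as `not_tested`. Normalization and imputation run on the full
per-experiment matrix, before any subsetting to nuclear proteins.

### Calibration properties

The Welch test at 4 vs 4 replicates is intrinsically slightly
conservative (true level ≈ 0.0415 at nominal 0.05); this is a property of
the Welch–Satterthwaite approximation at small n, shared by every correct
implementation. MNAR dropout plus downshifted imputation adds further
conservatism under the null (imputed cells inflate within-group variance),
so pipeline p-values on incomplete null data under-reject — the safe
direction. Type-I calibration in the test suite is therefore measured on
complete-data null studies, where the test's null sampling distribution
holds; the additional conservatism under dropout is asserted
directionally.

## High-confidence interactor (HCI) rule

Six datasets: per bait terminus (N- and C-terminal fusion), comparisons to
control in experiment 1 and to both control and the DNA-adjacent
dCas9-fusion control in experiment 2. With k_NT and k_CT the per-terminus
counts of enriched calls at p < 0.1, a protein is high confidence iff it
is nuclear, k_NT + k_CT ≥ 2, and each terminus has either 0 (exclusive to
the other terminus) or ≥ 2 of 3. Categories: `shared` (both termini ≥ 2),
`nt_exclusive` / `ct_exclusive` (other terminus 0). Conventions: "2 of 3"
means ≥ 2 (a protein enriched in all three qualifies); `not_tested`
counts as not enriched (absence of evidence cannot support a
high-confidence call; flagged as a sensitivity-analysis point); thresholds
are strict (<); the nuclear gate is applied last so near-miss non-nuclear
proteins remain auditable in the output.

## Peak-overlap permutation test

A query interval overlaps when it shares ≥ 1 bp with any target interval;
all coordinates are 0-based half-open, so intervals touching at a boundary
share no base. The null relocates each interval of the permuted set
(default: the target set; selectable) uniformly on its own chromosome with
length preserved — keeping per-chromosome peak density, the standard null
for genome-shuffle tests. Permuted intervals may overlap one another (no
rejection sampling; the independence null stays simple). With 100
permutations the add-one empirical p, (1 + #{perm ≥ obs})/101, bottoms out
at 1/101 ≈ 0.0099; fold enrichment is observed / mean permuted count, the
divisor clamped away from zero (flagged when clamped). Because the count
statistic is integer-valued, the permutation p is super-uniform
(conservative at tie points) under the null — significance is never
overstated. The significance flag defaults to p ≤ 0.05; the test RNG is
salted with a fixed namespace constant so reusing one seed for both data
generation and testing cannot alias the two streams.

## Signal profiles

Reference-point matrices bin a piecewise-constant signal track around each
region's midpoint (floor for even lengths; summit-based referencing would
need summit calls the inputs do not carry). Defaults: ±2,000 bp flanks,
5 bp bins — a 4 kb window. Bin values are exact coverage-weighted means
computed from a prefix integral of the track, so results are invariant to
bedGraph line order and to splitting runs; bases beyond chromosome ends or
without a bedGraph line contribute 0. The meta-profile (column mean) is
classified flat / unimodal / bimodal by plateau-aware local maxima of a
moving-average smoothed profile (window 5 bins) that rise a configurable
prominence (default 0.5 signal units) above the baseline (the smoothed
median). Bimodality is a qualitative judgement; the parameters are
deliberately exposed and the defaults suit peak-over-background tracks
with order-one contrast and windows not saturated by neighboring peaks.

## Gene-set overlap

Ortholog conversion keeps records with integrated confidence score
strictly above the threshold (default > 8 of 15), expands one-to-many, and
reports unmapped sources. Overlap significance is the upper-tail
hypergeometric probability P(X ≥ k) — over-representation only. The
background universe must be supplied explicitly: an overlap p-value is
meaningless without a stated universe, so there is no silent default and
the choice of universe is treated as user input.

## Synthetic studies and what they show

The generator plants known structure at every level so each stage is
testable without external data:

* **Abundances**: log2-space model `baseline_i + condition effect + batch
  shift + Normal(0, replicate_sd)`, exponentiated to the raw scale.
  Defaults emulate the scale of a head-tissue screen: 1,500 proteins, 35%
  nuclear, baselines Normal(20, 2), replicate SD 0.5, experiment-2 batch
  shift 0.5, quadruplicate/triplicate designs with the dCas9 control only
  in experiment 2, and 90 planted interactors (60 shared, 15 per-terminus
  exclusive) at a 2 log2-unit mean enrichment. TurboID-alone chromatin
  bias is an extra positive effect (default 1.5 log2 units) on 100 random
  nuclear proteins in the `turboid` condition only.
* **Missingness** is applied to the raw matrix before any analysis, cell
  by cell with probability `logistic(slope · (midpoint − log2 intensity))`.
  The mechanism of real MS dropout is not characterized by intensity alone;
  this logistic MNAR model is an assumption of the artifact. Defaults
  (midpoint 16.5, slope 1.5) model a steep detection limit: overall ~6%
  missing, concentrated in the lowest-abundance decile and negligible more
  than ~2 log2 units above the limit, so that a planted 2-unit enrichment
  at 4 vs 4 replicates is detected at p < 0.05 in ≥ 95% of runs — the
  operating regime the filtering workflow is designed around. A shallower
  curve makes the whole pipeline strictly more conservative (dropped bait
  replicates are imputed far downward and defeat single comparisons).
* **Annotations**: the nuclear list contains all planted interactors; the
  known-interactor list mixes 7 planted proteins with 8 nuclear decoys,
  emulating a curated complex list only partly recoverable by one screen;
  every protein gets a confident primary ortholog (planted interactors
  always pass the > 8 threshold) plus occasional extra paralogs; disease
  lists contain planted overlaps (defaults 26 and 24 with 14 shared,
  capped by the planted count) topped up with fillers disjoint from all
  ortholog targets, so planted overlap counts are exact by construction.
* **Peaks and signal**: target peaks placed uniformly; query peaks
  coincident (Gaussian jitter), flanking at ± a fixed offset with random
  sign (the two-divergent-promoters geometry that produces bimodal
  profiles), or independent. Signal tracks are piecewise constant
  (background everywhere, peak height on peak unions).

What passing tests on these data do *not* show: real spectra, peptide
inference, search-engine FDR, correlated protein abundances (complex
stoichiometry), intensity-dependent variance, or real ChIP-seq peak-width
and density distributions. The synthetic studies validate the statistics
and the filtering logic, not the upstream measurement process.

## Reproducibility

All randomness flows from explicit seeds; the pipeline spawns per-stage
seeds from one global seed via a seed sequence and records them in the run
manifest together with parameter echoes and a sha256 per output file. No
output embeds a timestamp, so re-running a configuration reproduces every
file byte-exactly. Results tables carry `#`-prefixed provenance headers
(tool version, stage parameters, seeds).

## Problem sizes in the test suite

The suite exercises the statistics at the sizes that make each check
meaningful while keeping the default run quick: 200 random vectors against
the Welch oracle; 20 null studies of 2,000 proteins for calibration;
10,000 imputed draws for the moment checks; 20 default studies for planted
recovery; 200 random instances against the interval brute force; 100
simulated peak-set pairs for the permutation null; exhaustive enumeration
for all hypergeometric universes up to N = 20.
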