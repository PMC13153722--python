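# Methods

## The screening problem

Given a pool of candidate core promoters (80 bp inserts destined for a
constant scaffold between poly-T and poly-A elements), the pipeline ranks
candidates by predicted expression, subjects the top cohort to simulated
neutral point mutation, and classifies each founder by how its predicted
expression behaves across generations. The deliverable is the set of
promoters that are simultaneously strong and robust to substitutions.

## Base mutation model

One generation is one mutation iteration, not a culture passage. Per
generation the simulator draws a substitution count m uniformly from
{min..max} (defaults 1..3), chooses m *distinct* sites uniformly, and
replaces each site's base with a uniform draw from the three alternatives.
Consequences and choices:

* With distinct sites the per-step Hamming distance equals m, so the
  "1–3 substitutions per generation" contract holds exactly; a
  with-replacement option exists for users who prefer the laxer reading.
* The count distribution is uniform by default but configurable
  (`mutation_count_weights`) since nothing pins down the within-range
  distribution.
* No transition/transversion bias, hotspots, indels or selection:
  synthetic promoters lack the genomic context those phenomena depend on,
  so mutation is modeled as purely random and length-preserving.
* Reproducibility: each founder's lineage runs on an RNG substream keyed on
  (seed, SHA-256 of the founder sequence, duplicate index). Results are
  invariant to founder order and to how lineages are scheduled; duplicate
  founders still receive independent streams.

A quantitative fact that shapes everything downstream: at 1–3 substitutions
per generation for 100 generations on 80 bp, each site is hit ~2.5 times in
expectation. Lineages are essentially randomized by the end of the walk, so
*any* fixed sequence→expression map relaxes to its background level along
every lineage.

## Synthetic fitness landscape

Expression is additive over exact motif occurrences:
y(s) = baseline + Σ_motifs w · #occurrences(s) · positional multiplier
+ N(0, σ²). Weights may be negative (repressive sites). This family was
chosen because it is the simplest in which distinct robustness classes can
be constructed and *audited by brute force* (every class property below is
checkable by scanning all 3L single mutants through the oracle). It is a
test oracle, not a biological model: real promoter landscapes contain
epistasis, positional context and saturation that this family deliberately
omits, so passing tests demonstrate pipeline correctness, not biological
validity.

Defaults: motif length 4 (making the landscape exactly linear in 4-mer
counts, i.e. well-specified for the surrogate; longer motifs exercise
misspecification), 3–8 motifs with weights 0.5–3.0, baseline 1,
noise σ = 0.1 expression units. Datasets emulate two artifacts of real
training corpora: Gaussian measurement noise and a Bernoulli(ρ)
subpopulation whose expression is rounded to an exact integer
(single-dish measurements; default ρ = 0.05). The integer filter removes
rows with |y − round(y)| ≤ 1e−9 — the tolerance is a declared choice, far
above float round-off after text round-trips and far below genuine
fractional parts.

## Planted robustness classes

All classes start at exactly baseline + 8 expression units and are defined
purely by construction:

* **resistant** — four copies of small-weight (2.0) 4-mer motifs. No single
  substitution can move expression by more than 2.0, one quarter of the
  motif contribution: the class degrades in small steps.
* **declining** — one large-weight (8.0) 8-mer. Its first hit collapses
  expression to baseline; the walk rarely rebuilds an 8-mer.
* **volatile** — two large-weight activator copies, two copies of an
  equally large *negative*-weight repressor, three 6-mer medium sites
  (weight 8/3) restoring the shared start level, and two near-miss
  activator sites one substitution from completion. Repressor losses and
  near-miss completions jump expression up by 8; activator losses drop it
  by 8.

Design rationale recorded for the genuinely open choices:

* **Strong motifs are 8-mers.** A 4-mer has ~0.3 expected occurrences in a
  random 80-mer, so drifting backgrounds of *every* class would create and
  destroy strong sites constantly (±8 jumps, class cross-talk). 8-mers cut
  this "flicker" to a few percent of 100-generation walks.
* **The repressor copies.** Near-miss completion alone fires in under a
  third of walks, which cannot support a volatile class defined by
  guaranteed up-jumps; repressor destruction is near-certain within the
  first generations and provides the up-jump, while the near-miss sites
  remain as a secondary channel.
* **Medium sites are 6-mers at weight 8/3.** They restore the volatile
  start level without being visible to a 4-mer surrogate (which would make
  volatile founders mimic resistant ones under the surrogate) and bound
  the distortion of the large-step balance from same-generation coincident
  site deaths to ±8/3, below the large-step threshold's margin.
* **Clean backgrounds.** Backgrounds are rejection-sampled so each planted
  sequence carries exactly its intended motif content at generation 0 —
  no stray occurrences and no windows within Hamming distance 1 of any
  strong motif (besides the intended near-miss sites).

## Surrogate predictor

Ridge regression on overlapping k-mer counts (k = 4). The penalty defaults
to leave-one-out generalized cross-validation over a fixed grid
(10^−4…10^4), keeping fits deterministic while adapting shrinkage to the
training-set size, in the same spirit as per-size hyperparameter tuning of
larger models. On data from a linear 4-mer landscape the surrogate is
well-specified: noiseless held-out PCC ≈ 1, and with noise σ the held-out
PCC approaches the analytic ceiling √(v/(v+σ²)) where v is the signal
variance. Metrics are computed on raw expression values; undefined cases
(constant vectors) raise instead of returning NaN so a degenerate
benchmark row cannot pass silently. R² follows the
coefficient-of-determination-about-the-mean convention and may be negative.

External predictors (e.g. fine-tuned DNA language models) wrap a batch
callable; output length and finiteness are validated on every call. Their
training is out of scope here.

## Trajectory features and clustering

Because final expression equilibrates identically for all classes (see
above), the screen classifies by trajectory *shape*. Features per founder:
start, final, mean, sd, min, max, net drop, volatility (mean |successive
difference|), the largest single-step rise and drop — each also over an
early window (first 30% of generations, where the founder's own
architecture rather than background drift determines the steps) — and the
**large-step balance**: Σ(large drops) − Σ(large rises) over steps of
magnitude ≥ 5 expression units. The balance equals the founder's net loss
of strong-site content and is invariant to destroy–rebuild–destroy cycles,
which is what cleanly separates declining (+8) from volatile (≈0) walks.
The threshold 5 sits between the landscape's weak-site (2) and strong-site
(8) effect sizes and is exposed as a parameter for other landscapes.

Clustering: k-means (k = 3, fixed seed, n_init = 10) on standardized
features `[start, volatility, max_rise_early, max_drop_early,
large_step_balance]`. Magnitude-like features are log1p-compressed first so
the weak-vs-strong distinction (2 vs 8) is not drowned by spread among
already-large steps (8 vs 24); features that are numerically constant
across the cohort (e.g. a shared exact start) are centred rather than
noise-amplified. Clusters are then mapped to classes deterministically:
highest mean resilience (start − largest early drop) → resistant; of the
rest, higher mean large-step balance → declining (ties: lower early rise,
then lower index); last → volatile. Both the feature list and k are
config-exposed.

Selection ranks resistant-labeled founders whose final expression is at or
above the cohort's `min_final_quantile` (default 0.5) and whose net drop is
at or below the `max_drop_quantile` (default 0.25) of cohort drops, ordered
by descending final, then mean, then founder id. Quantiles are taken over
the cohort's own outcome distributions: after 100 generations of neutral
mutation no founder retains its starting level, so thresholds anchored to
starting expressions would select nothing. An empty selection is a logged
result, not an error.

## Problem sizes used in the checks

The test suite and acceptance script run at the protocol's native cohort
scale (1000 founders × 100 generations for geometry; 20 founders per
planted class for recovery; 10,000 steps for mutation-model audits;
surrogate training at n = 20,000 and ladder sizes 300/3K/30K). These sizes
make every check complete in seconds to tens of seconds on a single CPU
while keeping each statistic's sampling error far below its acceptance
margin.

## Known limitations

* The landscape's additivity excludes epistasis and saturation; planted
  classes are archetypes, not a claim about the taxonomy of real promoters.
* The surrogate cannot represent motifs longer than its k; under a k = 4
  surrogate, 8-mer-driven declining and volatile promoters look alike
  (both flat), which the screen's guarantees account for (resistant
  precision is preserved; declining/volatile discrimination needs the
  oracle or a higher-capacity predictor).
* Scaffold sequences for construct assembly are user-supplied; the package
  ships only a toy default layout, and TSS-relative coordinates are
  carried as metadata.
* Trajectory clustering assumes the cohort actually contains distinct
  behavior classes; k-means with k = 3 will partition even a homogeneous
  cohort, and the semantic mapping then reflects gradations rather than
  kinds.
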