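# Methods

This note records the statistical models, defaults and design decisions
behind `kinact`, and what the synthetic-data experiments do and do not
establish.

## Array preprocessing

The input is a nonnegative end-level kinetic signal tensor, peptide ×
sample × technical replicate, with saturation flags assigned at load time
(`saturated` implies signal at/above the instrument's raw-scale ceiling).
Three rules are applied, in this order:

1. **Saturation masking.** Saturated spots become missing; peptides with no
   usable entry left are dropped. Masking rather than clipping means a
   saturated spot never contributes a (downward-biased) ceiling value to any
   mean.
2. **Replicate collapse.** "High variation among replicates" is quantified
   as the raw-scale coefficient of variation (sample SD / mean, ddof = 1)
   exceeding `replicate_cv_max` (default **0.5**); in that case the single
   replicate farthest from the replicate median is excluded. This is a
   deliberate single-pass rule: it is deterministic, removes at most one
   replicate, and cannot empty a cell. Remaining replicates are averaged on
   the raw scale and log2-transformed (`input_scale="log2"` skips the
   transform and averages the supplied log2 values directly, computing the
   CV on 2^x).
3. **Detection filter.** A value counts as detected when non-missing and
   strictly above `detection_floor` (default 0). Peptides detected in fewer
   than `min_detect_frac` (default **0.25**, boundary inclusive — "at least
   25%") of samples are removed. The filter is idempotent because the
   detected fraction of a retained row does not change on reapplication.

Kinetic-curve fitting is out of scope: end-level values are the input.
No operation reorders or renames samples.

## Differential phosphorylation

Welch's unequal-variance t-test on log2 values is used for all two-group
comparisons. The choice over a pooled-variance t-test or a rank test:
log-intensity array data routinely violate equal variance between clinical
subgroups, the reported quantities (group means, LFC) are mean-based, and
Welch keeps per-peptide type-I error close to nominal at the study's sample
sizes (verified by the null-calibration experiment below). Missing values
are dropped pairwise per peptide; a peptide needs ≥ 2 values per group or it
is skipped with a log entry. Multiplicity is controlled with
Benjamini–Hochberg across all tested peptides, reported as `q`. Bonferroni
(`min(1, p·G)`) is used instead for the expression cohort, where the gene
universe is large and the published convention for that analysis is
family-wise control.

Peptide clustering is agglomerative with Euclidean distance and complete
linkage, tree cut at k (default 3); sample clustering in the integration
stage uses the same recipe at k = 2. Complete linkage was chosen because it
is the common default of the heatmap tooling used for such figures and gives
compact, balanced clusters on log-intensity data; labels are relabelled by
first appearance (peptides) or oriented by signature mean (samples) so the
assignment is deterministic and sample-order invariant. NaNs are imputed
with the row mean for distance computation only.

## Upstream kinase analysis

Per-substrate effect: δ = (mean_neg − mean_pos) / pooled SD, the
standardized mean difference with the classical pooled variance
((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2). Substrates with fewer than two values in
either group or zero pooled variance are excluded. The sign convention makes
τ > 0 mean lower activity in the PR+ group.

The kinase statistic τ is the prediction-weighted mean of δ over the
kinase's substrate set. A weighted mean (rather than a sum or a KS-style
enrichment statistic) keeps τ on the δ scale, comparable across set sizes,
and is the simplest statistic to which **both** permutation nulls apply
unchanged. Prediction weights default to uniform; a weights TSV can supply
per-(kinase, substrate) strengths.

Both Q-scores use Q = −10·log10(max(m/M, 1/M)) with a **base-10** logarithm
(the Phred-like convention for such scores) and **strict** exceedance
|τ_p| > |τ|; ties never count. M defaults to 500. Exhaustive enumeration
replaces Monte Carlo whenever the number of distinct label splits C(n, n₁)
or substrate subsets C(U, |S|) is ≤ M; sampled permutations are drawn
without a uniqueness constraint (plain Monte Carlo, unbiased and seeded).
In `rank_kinases` the same sampled label permutations are shared by all
kinases, so significance scores are computed against a common null; the
specificity null is drawn per kinase from a child generator. Ranking is by
combined = Q_sig + Q_spec descending, ties broken by |τ| descending then
kinase name.

The proprietary scoring engine that motivated this stage does not document
its difference statistic; τ as defined here is this package's own, stated
openly so results are interpretable and reproducible.

## Survival stage

The Kaplan–Meier estimator and the two-sample log-rank test are implemented
from their defining formulas: the product-limit curve over distinct event
times, and at each event time t the observed group-1 events d₁ₜ against
expectation dₜ·n₁ₜ/nₜ with hypergeometric variance
dₜ(n₁ₜ/nₜ)(1−n₁ₜ/nₜ)(nₜ−dₜ)/(nₜ−1); the squared standardized sum is χ²₁.
The test suite cross-checks the implementation against an independent
survival-analysis library on simulated cohorts and against a six-subject
hand-worked oracle.

## Synthetic data

**Arrays.** Log2 signal = per-peptide baseline N(7.0, 1.8²) + array-level
sample effect N(0, 0.3²) + planted group shift + biological noise
N(0, 0.95²) + replicate noise N(0, 0.5²); raw signal is 2^log2, hard-clipped
and flagged at a raw saturation threshold of 4096 (log2 = 12, so a small
fraction of high-baseline spots saturate). Detection dropout acts on whole
(peptide, sample) spots: 5% baseline, and 85% for a planted 25% of
"low-signal" peptides, which reproduces the study-scale attrition from 144
spotted peptides to ~105–115 surviving the 25% detection filter. With three
replicates the collapsed per-sample SD is √(0.95² + 0.3² + 0.5²/3) ≈ 1.04,
so a planted log2 effect of 1.0 is a standardized effect of ≈ 1. Driver
kinases shift their predicted substrates upward in PR− samples. Defaults are
study-sized: 144 peptides, 29 ER+ samples (62% PR+, 76% HER2−), 3
replicates. Low-signal peptides are drawn from non-driver peptides so
recovery experiments measure ranking, not dropout.

**Cohort.** A scaled-down stand-in for a large ER+ consortium cohort:
default 300 samples (30% PR−, 93% HER2−) and 1000 genes, Gaussian
log-intensity around per-gene baselines. A 24-kinase-gene signature (14 up,
10 down, |effect| = 2.5, including LCK/FGFR4 up and FRK/MST1R down) is
carried by a **latent high-risk cluster**, itself a noisy copy of
PR-negativity (15% flip probability). Routing the signature through the
latent cluster rather than PR status directly reproduces the qualitative
structure the integration stage assumes: PR-based differential expression
recovers the signature (the induced PR-group difference is effect × (1 −
2·flip) = 0.7 × effect, still decisive at n = 300), signature clustering
recovers the latent clusters with PR− enriched in cluster 2 "with some
exceptions", and survival differs by cluster. Survival is exponential with
baseline hazard 0.08 per time unit, multiplied by the cluster hazard ratio
(default 2) in the high-risk cluster; independent exponential censoring is
rate-matched to the requested censoring fraction (default 0.3). Problem
sizes (1000 genes, 300 samples, 50-seed repetitions) were chosen as the
smallest at which the planted effects are comfortably detectable and
repetition averages are stable.

**What passing tests do not show.** The generators are Gaussian on the
analysis scale with independent peptides/genes apart from the planted
structure; real arrays have correlated substrates, batch (PamStation run)
effects, heavy-tailed noise and prediction sets of very uneven quality, and
the real prediction database is proprietary. Recovery and calibration
results therefore validate the machinery (filters, statistics, permutation
nulls, ranking), not field performance on clinical data; the published
per-dataset counts (e.g. 75 ranked kinases, 648 DE genes) depend on
unreleased data and are not reproduction targets.

## Numerical choices and degenerate inputs

- Missing values are NaN throughout; group statistics are NaN-aware with
  explicit count guards rather than silent zero-fills.
- Zero pooled variance excludes a substrate from δ (logged); a gene with
  zero variance in both groups gets adjusted p = 1 but stays in the tested
  universe (it was tested, it is simply uninformative).
- Specificity is undefined when a set covers the scoreable universe
  (error), and `|set| ≥ |universe|` cannot arise after set restriction.
- Identical samples make the two-cluster cut degenerate; this raises rather
  than returning a single-cluster "stratification".
- All hierarchical-clustering tie-breaks inherit SciPy's deterministic
  linkage order; determinism is tested at the byte level through the
  pipeline.
- Every generator and permutation routine takes an explicit seed; the
  pipeline derives per-stage seeds from the single top-level seed.

## Known limitations

- The replicate-CV exclusion rule and the detection definition are this
  package's explicit quantifications of informally stated quality filters;
  both are configurable.
- τ is a stand-in for an undocumented proprietary statistic; absolute Q
  values are comparable within a run (fixed M), not across tools.
- BH q-values here are genuine adjusted p-values; published tables in this
  area sometimes print step-up critical thresholds under the same name, so
  numerical q columns from other tools may not match even on identical data.
- The kinome list ships as a convenience default (~85 PTK symbols plus
  substrate-derived gene symbols); real analyses should supply their own
  curated list.
- No batch correction across array runs and no Cox modelling; the survival
  stage is a two-group comparison only.
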