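# Methods

`mircoop` re-implements, as a tested and re-runnable pipeline, an integrated
mRNA–miRNA analysis for triple-negative breast cancer (TNBC): discovery of
microRNAs whose expression tracks an anchor tumor-suppressor gene (PTEN by
default), survival stratification of a PTEN-low/miR-low subgroup, its
differential-expression and genomic landscape, and connectivity-map drug
repurposing against its expression signature. Because the cohorts this kind
of analysis is run on are controlled-access, the package ships a synthetic
cohort generator that plants the structure the analysis assumes, together
with a ground-truth record, so every stage can be exercised and its recovery
quantified at desk scale.

## Data model and normalization

Expression data are features x samples log2 matrices. All analyses run on
median-centered data: each feature's cohort median is subtracted, so 0 is
"typical expression" and the twofold-below-median rule becomes the threshold
−1 on the log2 scale. Median centering is per feature, idempotent, and
shift-equivariant; missing values are kept explicit and excluded pairwise in
correlations and per-feature in medians (real matrices have holes; the
safest default is never to impute silently). When cohort components disagree
on samples, the bundle is the intersection, with per-component drop counts
reported — union-with-imputation is deliberately not offered.

## Discovery: subgroup correlation ranking

The cohort (and separately its TNBC subset) is split into `b` independent
random bipartitions; the halves plus the full set give `2b + 1` groups per
cohort class (default `b = 3`, hence 7 + 7 = 14 groups). Within each group,
Pearson correlation (pairwise-complete) is computed between the anchor gene
and every miRNA; miRNAs are ranked per group (descending r for the positive
direction, ascending for the negative; ties get average ranks) and the ranks
are averaged across groups. Averaging raw ranks rather than rank percentiles
is justified because group sizes are near-equal by construction. The
averaged ranking's ties are broken by mean |r|, then lexicographic id, so
output order is deterministic. The top-k (default 5) candidates feed the
stratification stage. Features with fewer than 3 pairwise-complete
observations or zero variance in a group are flagged with a reason, never
silently dropped; a feature missing in more than half the groups is excluded
with a warning.

## Survival machinery

Kaplan-Meier, the two-group log-rank (Mantel-Cox) test, and the hazard ratio
are implemented from first principles (`survstats`), with lifelines used
only as an independent cross-check in the test suite.

- KM: product-limit over distinct event times; censored subjects at time t
  remain at risk for events at t. Greenwood variance is available but off by
  default.
- Log-rank: chi2 = (Σ_j (d_1j − E_1j))² / Σ_j V_j with the hypergeometric
  variance V_j; p from χ² with 1 df. The statistic is invariant to strictly
  monotone time transforms, and a cohort compared against an exact copy of
  itself gives chi2 = 0 exactly (the expected counts are computed so the
  cancellation is exact in floating point).
- Hazard ratio: the observed/expected ratio (O1/E1)/(O2/E2) from the
  log-rank tables — the estimator that accompanies the Mantel-Cox test in
  standard survival software — rather than a Cox coefficient, because no
  covariates appear anywhere in the analysis. When a group has zero expected
  events the HR is reported as missing with a reason.
- Cutoff optimization: candidate thresholds are sample quantiles at levels
  0.10–0.90 in steps of 0.05 (defaults); candidates leaving less than
  `min_group_frac` (default 0.10) of samples on either side are infeasible;
  the feasible candidate with the smallest log-rank p wins, ties going to
  the threshold nearest the median. The optimized p-value is *not*
  internally corrected — the result instead carries the full evaluated grid
  and the number of candidates, so callers can see (and adjust for) the
  multiplicity of the search.

## Stratification rules

PTEN-low is a fixed rule: median-centered log2 value ≤ −1, boundary
inclusive. The call refuses uncentered input (median beyond 1e-6) rather
than re-centering silently; the pipeline therefore calls PTEN-low on the
full assembled cohort (whose centering median is 0) and subsets afterwards.
miRNA low/high calls use the survival-optimized per-miRNA cutoffs, reused
unchanged for all downstream analyses. Among PTEN-low TNBC samples, the
k-of-n rule (default 4 of 5) labels a sample "a" when at least k panel
miRNAs are low, "c" when at least k are high, and "b" otherwise; PTEN-high
TNBC samples are `pten_positive` and the rest `non_tnbc`. Requiring
k > n/2 makes "a" and "c" provably disjoint, and the 5-of-5 variant of "a"
is a subset of the 4-of-5 variant (monotonicity, tested). Group "b"/"c" are
defined within the PTEN-low TNBC set; comparisons of "a" against "all other
TNBC" simply binarize the labels.

## Pathway activity

Published probability-of-pathway-activity frameworks are trained binary
regressions on external cohorts; reproducing their exact probabilities would
require their training data. `pathscore` provides a z-score/logistic
surrogate: per-gene z-scores across samples, direction-weighted (+1/−1),
averaged over the signature genes present, then squashed through a logistic
whose scale is the cohort standard deviation of the raw score. The surrogate
is monotone in aggregate signature expression, which is the only property
the downstream consumers (group t-tests, median-split high/low calls,
composite PTEN-low x pathway-high survival) rely on, and is labelled as a
surrogate in outputs. It is invariant to per-gene affine rescaling and maps
sign-flipped weights to 1 − activity exactly. Signatures are user-supplied
GMT files with optional +/− gene prefixes; none are bundled.

## Differential expression

Two-group empirical-Bayes moderated t, implemented from the published
formulas rather than called from an external package: per-gene pooled
variance s² with d residual df; prior (d0, s0²) estimated by matching the
mean and variance of log s² to the scaled-F model via digamma/trigamma
moment equations, inverting trigamma with Newton iteration; posterior
variance s̃² = (d0 s0² + d s²)/(d0 + d); t = Δmean / sqrt(s̃²(1/n1 + 1/n2))
with d + d0 df. Homogeneous variances give d0 = ∞ (complete shrinkage);
d0 = 0 reproduces the classic pooled t exactly (tested to 1e-12).
Benjamini-Hochberg step-up is likewise implemented directly and
cross-checked against statsmodels. Only the two-group contrast exists — the
analysis never needs general design matrices — and the log-odds B-statistic
is omitted as nothing downstream consumes it.

## Connectivity mapping

Query signatures take the top and bottom size/2 genes by moderated t among
FDR < 0.05 genes (sizes 100/150/200/298 by default, always equal up/down).
Two scores are computed over the genes common to the query and each drug's
perturbation signature:

- GSEA-KS: the drug's genes are ranked by effect (descending; ties broken
  by gene id for determinism). For each of the up/down sets the enrichment
  score is the signed maximum of the running empirical-CDF difference
  D(i) = (#set genes at rank ≤ i)/t − i/n, evaluated on an integer lattice
  so extreme ties compare exactly; an exact tie between the positive and
  negative extremes yields 0. The connectivity score is
  (ES_up − ES_down)/2, zeroed when the two enrichments share a sign. This
  bridge form differs from the textbook "max(V_j/n − (j−1)/t)" lower
  deviation by 1/n; it is chosen because it is *exactly* antisymmetric
  under reversal of the drug ranking (verified by exhaustive enumeration
  over all 5040 rankings of a 7-gene universe), which the half-open variant
  is not.
- GWC: a significance-weighted Spearman — per-gene weights are the mean of
  the query's and the drug's −log10 p, and the score is the weighted Pearson
  correlation of the rank-transformed statistics, clipped to [−1, 1]. The
  averaging rule for the two significances is recorded in output metadata.

Permutation p-values permute the drug signature's gene labels (preserving
the query's structure), two-sided, with the +1 correction; they are
deterministic given the seed. Note the KS score's sign-agreement zero rule
makes its null distribution atomic at 0, so its permutation p has a
conservative atom at 1 — approximately uniform null p-values hold for the
continuous GWC score only (both behaviours are tested).

Hits per method are drugs scoring below the cutoff (default −0.5) in *all*
signature sizes; the reported common set is the intersection across methods.
A per-method cutoff mapping supports the documented fallback of relaxing the
GWC cutoff to −0.45 when nothing clears −0.5 across all runs.

## Landscape comparisons

Per-feature one-way ANOVA across the a/b/c/PTEN-positive groups (levels with
fewer than 2 samples dropped with a warning) and two-group Welch t-tests
(pooled-variance optional, which makes the two-group F = t² identity exact),
both vectorized with nan-aware statistics and BH-adjusted. Copy-number
burden counts gains (+1/+2) and losses (−1/−2) per sample; group comparisons
of burden go through the same t/ANOVA machinery, and per-gene code
frequencies can be compared by chi-square — both views are reported because
applying a t-test to categorical CNA codes alone is statistically unusual.
Mutation comparisons drop genes mutated nowhere, then use Fisher's exact
test for two groups (group sizes here are tiny, where asymptotic tests are
unreliable) or chi-square for more. Top-k selection takes features with
ANOVA p below alpha, sorted by p with ties broken by id.

## Synthetic cohorts

The generator (`syndata`) encodes the study conditions:

- Cohort: n = 600 samples by default, 16% TNBC, with 10% of TNBC planted as
  the "aggressive" PTEN-low/miR-low subgroup (at least 2 aggressive samples
  are required for a feasible configuration).
- Expression: all features are unit-variance Gaussians on the log2 scale.
  The anchor gene is shifted down by 3 log2 units in aggressive samples;
  each of the 5 planted miRNAs is a·(anchor expression) + unit noise, with
  its own additional downshift of 2.5 log2 units in aggressive samples.
  The coupling a is solved from the full population model (a quadratic
  accounting for the covariance the shared downshift induces) so the
  population Pearson correlation with the anchor equals the configured
  `planted_correlation` (default 0.5) exactly; with no shifts the solution
  reduces to the familiar a = r/√(1−r²). The anchor and miRNA shift
  magnitudes are calibrated defaults: they are sized so the
  twofold-below-median rule and the survival-optimized miR cutoffs capture
  planted aggressive samples with high probability (group-"a" recall ≥ 0.9
  at the default conditions), which is the property the stratification
  stage's recovery guarantees rest on.
- A planted expression program for the aggressive group — 30 pathway
  signature genes (+1.0), 200 up- and 200 down-regulated genes (±1.5) —
  gives the differential-expression and connectivity stages a recoverable
  signature large enough for the 298-gene query size.
- Survival: exponential event times with hazard 0.01/month times
  `true_hr` (default 4.0) for aggressive samples — exponential rather than
  Weibull so the hazard ratio is the exact rate ratio and everything is
  closed-form checkable. Censoring is an independent exponential whose rate
  is solved numerically so the expected censored fraction equals
  `censoring_rate` (default 0.4); the observed event rate is verified to be
  calibrated across replicates.
- Genomics: CNA codes and mutation flags drawn with group-specific
  probabilities; TP53 is mutated with probability 1 in aggressive samples.
- Drug signatures: planted reversal drugs are the sign-flipped
  differential-expression profile plus Gaussian noise (sd 0.3 of the
  profile scale); other drugs are independent noise at the same scale, with
  pseudo p-values from a normal reference on the standardized effects.

A single seed feeds a hierarchical stream-splitting scheme
(`numpy.random.SeedSequence.spawn`), so outputs are bit-identical given the
config and each sub-generator is independently reproducible.

What the generator does *not* emulate: array platform or batch structure,
correlated gene-gene networks beyond the planted program, realistic gene
identifiers beyond the anchor symbol, informative censoring, or
non-proportional hazards. Passing recovery tests therefore demonstrate that
the *procedures* recover the structure they assume when it is present — not
that the biological findings transfer to any particular real cohort.

## Scale of the shipped evaluations

The recovery evaluations run at: discovery — 100 cohorts of n = 600 with
300 miRNAs; prognosis — 200 all-TNBC cohorts of n = 1000 (10% aggressive,
true HR 4); drug repurposing — 100 drug sets of 100 drugs with 3 planted
reversals scored at sizes 100/150/200/298; plus one full default-scale
pipeline run. These sizes give stable rates (binomial SE ≤ 5 percentage
points on the recovery fractions) while keeping a full evaluation under a
minute on a laptop-class CPU. In the all-TNBC prognosis setting the
aggressive fraction is large (10% of the whole cohort), so the
correlation-preserving coupling is small and group-"a" recall is lower
(~70%) than at default conditions; the hazard-ratio estimate is driven by
the most extreme samples and remains close to the planted value.

## Numerical choices and degenerate inputs

- Pearson correlations are clipped to [−1, 1] after computation; zero
  variance or fewer than 3 complete pairs yield a flagged missing r.
- The log-rank variance term is skipped at event times with one subject at
  risk; all-censored data yield chi2 = NaN with a reason rather than 0.
- Prior estimation requires ≥ 10 genes with positive variance; genes with
  fewer than 2 observations per group are excluded with per-gene reasons.
- Pathway activity with a constant raw score warns and sets the logistic
  scale to 1; a quantile cutoff of 1.0 deliberately produces an empty
  "high" group, which downstream survival comparison refuses loudly.
- p-values are floored at 1e-300 before −log10 weighting in GWC.
- The pipeline summary is serialized with sorted keys and no timestamps, so
  identical configs and seeds produce byte-identical summaries.

## Known limitations

- No Cox regression, covariate adjustment, competing risks, or confidence
  bands beyond the optional Greenwood variance.
- The minimal-p cutoff search reports, but does not correct, its
  multiplicity, matching the way such optimized cutoffs are usually
  reported; treat the per-miRNA p-values accordingly.
- The pathway surrogate preserves ordering, not calibrated probabilities;
  absolute activity values are not comparable across cohorts.
- The PTEN fallback-merge across expression platforms (when the anchor is
  absent from the primary matrix) is out of scope — callers supply one
  merged matrix.
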