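# Methods

This note documents the models, parameter choices and numerical
conventions behind `g2i`, and what the synthetic test bed does and does
not establish about real array-CGH data.

## Data model

Profiles are vectors of normalized log2 tumor/reference ratios aligned
to an ordered clone map (1-based, closed coordinates; chromosomes
1–22, X, Y).  A clone spanning the centromere belongs to the arm
containing its midpoint.  Missing measurements are explicit (NaN) and
are excluded from every statistic; runs of statuses bridge up to 4
consecutive missing clones and break at gaps of 5 or more, so probe
dropouts neither create nor join altered regions.  Sex chromosomes are
carried in profiles but excluded from the residual-SD estimate and from
both index parameters by default (configurable), since the calling
threshold is defined on autosomes.

## Segmentation and GNL calling

Smoothing is exact penalized least-squares segmentation, computed per
chromosome by an O(n²) dynamic programme minimizing

    sum of squared errors + penalty × (number of segments)

with a minimum segment length of 2 clones.  The default penalty is the
BIC-like 2·σ̂²·log n, with σ̂ estimated robustly from median absolute
first differences within chromosomes (divided by √2·0.6745), so sparse
true breakpoints do not inflate the noise estimate.  The programme is
globally optimal at every size — the small-case exhaustive-search
equivalence that the test suite checks holds by construction — and
deterministic (ties resolve to the earliest admissible segment start).
`penalty=inf` collapses each chromosome to one segment; a NaN penalty
is rejected.

A clone is called gained/lost when its smoothed value strictly exceeds
±(multiplier × residual SD), where the residual SD is the sample
standard deviation (n−1) of normalized − smoothed over autosomal
clones and the multiplier defaults to 1.  Values exactly at the
threshold are normal.  A zero residual SD (noise-free input) is a
degenerate estimate: a warning is logged and any nonzero smoothed value
is called altered.

This segmenter is the package's own smoothing stage, not a
re-implementation of any published segmentation algorithm; its contract
is only "piecewise-constant fit with a documented penalty".

## The instability index

* **Local-score smoothing.**  Before counting regions, any maximal run
  shorter than `min_run` (default 2, i.e. isolated single clones) whose
  two within-chromosome neighbours share a status is reassigned that
  status, iterated to a fixed point.  The rule is idempotent, never
  increases the region count, and leaves runs at chromosome boundaries
  or between disagreeing neighbours unchanged.  This is the weakest
  artifact-removal rule consistent with a "local score" smoothing step;
  stronger variants can be expressed by raising `min_run`.
* **A** is the unweighted mean over arms of the altered-clone fraction;
  arms with no usable clone are dropped from the average (with a
  warning) rather than imputed.  The default array design carries 39
  autosomal arms: acrocentric p arms (13p, 14p, 15p, 21p, 22p) hold no
  clones, matching BAC-array practice.
* **N** counts maximal non-normal runs per chromosome summed over
  autosomes.  A run crossing the centromere without an intervening
  normal clone is one region; runs never span chromosomes.
* **Grading.**  The published prose convention is adopted: grade 1 iff
  A < a₁ and N ≤ n₁; grade 3 iff A > a₂ and N ≥ n₂ (strict on A,
  inclusive on N); else grade 2.  A `boundary="strict"` switch makes
  all four inequalities strict, since the two published formulations
  differ on the boundary.  At the published thresholds the two
  predicates are disjoint (n₁ < n₂); for user thresholds where they
  could overlap, grade 3 takes precedence — a deliberate tie-break
  favouring the high-risk call.
* **Threshold optimization** is an exhaustive grid search minimizing
  the deviance of the saturated per-grade relapse-rate model; ties
  break toward fewer grade-2 samples, then lexicographically on
  (a₁, n₁, a₂, n₂).  Overlapping A thresholds (a₁ ≥ a₂) are allowed,
  as in the published values.

## Amplicons

Copy number is inferred as ploidy × 2^(smoothed log2), assuming a
diploid reference and full tumor cellularity; both assumptions are
exposed (`ploidy`, and cellularity can be folded into a rescaled
threshold).  An amplicon is a maximal run of at least `min_clones`
(default 2) contiguous clones with copy number strictly above
`cn_threshold` (default 3), i.e. smoothed log2 > log2(3/2) ≈ 0.585 at
defaults.  Calling uses segment means rather than raw probes for
robustness; contiguity breaks at missing clones and chromosome
boundaries.

## Clustering and screens

GNL profiles are compared by 1 − Pearson correlation of status vectors
(missing clones pairwise-excluded); a pair involving a constant profile
has undefined correlation and is assigned distance 0 when the vectors
are identical and 1 otherwise, so fully quiet genomes still cluster
together.  Linkage is Ward by default (average linkage and a Manhattan
distance are available); the tree is cut at k = 6 groups by default,
with no automatic model selection — k is a scientific choice, not an
estimate.  Cluster labels are canonicalized by order of first
appearance, making assignments deterministic and order-invariant up to
renaming.

The differential screen tests, per clone and per direction, altered
versus not between two groups with a two-sided Fisher exact test and
reports maximal runs of clones passing both a raw p-value filter
(default p ≤ 1e-4) and a focal-group frequency filter (default ≥ 50%).
No multiplicity correction is applied — the screen reproduces a
fixed-filter convention, not an error-rate guarantee.

## Statistics layer

Odds ratios are cross-product ratios with Wald 95% CIs
(exp(log OR ± 1.96·SE), SE = √Σ1/nᵢⱼ) and the Haldane–Anscombe +0.5
correction, flagged, when a cell is zero.  Chi-square tests are Pearson
without continuity correction.  Logistic regression is iteratively
reweighted maximum likelihood (tolerance 1e-10) with a pre-fit check
that raises, naming the covariate, on perfectly separated data.
Kaplan–Meier estimation and the log-rank test come from `lifelines`;
the hazard ratio is the ratio of observed/expected event counts from
the pooled risk-set tabulation, matching the convention of attributing
the HR to the log-rank test rather than to a Cox model (Cox regression
is out of scope).

The Welch-t signature module computes unequal-variance t statistics
with Satterthwaite degrees of freedom and selects probes at a raw
two-sided p < 5e-3 by default; a Benjamini–Hochberg mode exists but is
off, matching the raw-threshold derivation convention.  Probes with
zero variance in both groups are skipped with a warning.

## The synthetic cohort generator

The generator emulates the study conditions end to end: a 5,878-clone
map laid proportionally over chromosome arms (median spacing ≈ 0.5 Mb),
six genomic archetypes mirroring the recurrent breast-carcinoma profile
families (quiet; 1q+/16q−; 1q+ with chromosome 7 gain; 8p−/8q+ with
16p+/16q−; multi-arm complex with scattered focal events; firestorm
with ~90 focal events, mainly losses, plus amplicons), Gaussian probe
noise (sd 0.1), and relapse drawn conditionally on the planted grade
with probabilities 1/19, 23/88 and 21/28 for grades 1/2/3.  Relapse
times are uniform on (6, 120) months; non-relapsers are censored
uniformly on (131, 180) months, respecting the cohort's minimum
follow-up.  Default archetype mixture weights follow the cohort's
cluster sizes (34/25/16/13/35/12 of 135).

Planted segment means are −0.5 (loss), +0.4 (gain) and +1.0
(amplicon, copy number 4): one-copy events comfortably exceed the
residual SD at the default noise, which is the regime the calling rule
assumes.  Focal events are placed on still-normal autosomal clones,
longest first, into free intervals sampled proportionally to capacity;
an event either touches an interval edge or leaves at least two normal
clones, so planted events never merge in the truth tiling and every
normal gap is segmentable at the default minimum segment length.  Each
sample's truth record stores the planted status vector, amplicons, the
(A, N) pair and grade computed from the truth, and the relapse draw;
at zero noise the full calling chain reproduces the planted statuses
exactly.

What the simulator does *not* model: tumor cellularity and normal-cell
contamination (log2 shrinkage), spatial array artifacts, wavy baselines,
clone-specific noise, or correlated probe effects.  Passing tests on
synthetic cohorts therefore validate the pipeline's logic and its
statistical calibration under idealized noise, not its robustness to
the full messiness of real hybridizations; on real data the residual-SD
threshold and the segmentation penalty are the knobs that absorb those
effects.

## Problem sizes in the test suite

The suite runs the full pipeline at the native 5,878-clone design.
Cohort-level checks use 30–120 samples per property; the odds-ratio
coverage check uses 100 replicate cohorts of 116 samples with a
76/24 complex/firestorm mixture (≈ the 88/28 grade split of the
development cohort); the clustering check uses 20 samples per
archetype.  The exhaustive segmentation oracle enumerates all
segmentations up to 20 clones per chromosome; the permutation check of
the chi-square test uses 100,000 fixed-margin tables.

## Known limitations

* The original study's exact segmentation (GLAD), normalization (MANOR)
  and clustering metric are not reproduced; the substitutes are
  documented above, so cluster-level agreement with the original
  partition of the real cohort is not claimed.
* The A denominator depends on the arm catalogue in use (39 autosomal
  arms by default); supplying an arm table with acrocentric p arms
  changes A's scale slightly.
* The node-negative subgroup table in `g2i.datasets` is reconstructed
  from published subgroup rates rather than printed directly; the
  reconstruction is exact given those rates (16/20 and 8/43).
* Inferred copy number assumes 100% tumor cellularity; in admixed
  samples the amplicon threshold corresponds to a higher true copy
  number.
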