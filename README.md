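# g2i — an array-CGH genomic instability index for tumor profiles

`g2i` scores the genomic instability of tumors profiled on BAC
comparative-genomic-hybridization arrays and relates the resulting
grades to clinical outcome.  It is aimed at cancer-genomics analysts
working with per-clone log2 copy-number ratios (the classic ~0.5 Mb
BAC-array design, ~5,900 clones) and at method developers who need a
fully synthetic, ground-truthed test bed for copy-number pipelines.

## The index

Each sample's normalized log2 profile is smoothed by exact penalized
least-squares segmentation, and every clone is called **G**ain /
**N**ormal / **L**oss: a clone is altered when its smoothed value
exceeds, in absolute value, the residual standard deviation σ̂ between
normalized and smoothed ratios over all autosomes.  From the GNL vector
two parameters are computed:

* **A** — the mean over chromosome arms of the fraction of altered
  clones per arm (whole-arm aneusomy level, A ∈ [0, 1]);
* **N** — the number of altered genomic regions: maximal non-normal
  runs within chromosomes, a proxy for breakpoint count.  Short
  artifactual runs are first removed by a local-score rule.

Grades follow published thresholds a₁ = 0.48, n₁ = 42, a₂ = 0.35,
n₂ = 65:

```
grade 1 (stable)    if A < a1 and N <= n1
grade 3 (unstable)  if A > a2 and N >= n2
grade 2             otherwise
```

Around the index the package provides Ward clustering of GNL profiles
into genomic archetype groups, amplicon calling (inferred copy number
> 3 over ≥ 2 contiguous clones), Fisher-exact differential-region
screens, the association statistics used in the original cohort
analysis (Wald odds ratios, Pearson chi-square, logistic regression,
Kaplan-Meier/log-rank with O/E hazard ratios), a Welch-t transcriptomic
signature module, and a six-archetype cohort simulator with planted
ground truth.

## Worked example

```python
from g2i import SimulationConfig, score_cohort, simulate_clone_map, simulate_cohort

clone_map = simulate_clone_map(5878, seed=1)          # ~0.5 Mb BAC design
config = SimulationConfig(n_samples=60, seed=7)
profiles, clinical, truths = simulate_cohort(config, clone_map=clone_map)
scores = score_cohort(profiles, clone_map)
print(scores.head(4))
```

prints (from `examples/simulate_and_score.py`):

```
sample_id        A  N  grade
    T0000 0.000000  0      1
    T0001 0.000000  0      1
    T0002 0.104728  5      1
    T0003 0.469189 48      2
```

`T0003` is a complex-aneusomy tumor: 47% of its genome altered by arm
(A = 0.47) across 48 distinct regions — too many breakpoints for grade
1, too few for grade 3.  On this cohort the called grade matches the
planted truth in 98% of samples, and relapse concentrates in grade 3
(5/8 events versus 0/37 in grade 1), reproducing the prognostic
gradient the index was designed to capture.  The other scripts in
`examples/` walk through segmentation and GNL calling, archetype
clustering, amplicon surveys, association statistics, survival
analysis and the expression signature.

A thin CLI mirrors the library (`g2i simulate`, `g2i gnl`, `g2i score`,
`g2i cluster`, `g2i amplicons`, `g2i stats`, `g2i survival`,
`g2i diffregions`, `g2i signature`); run `g2i --help`.

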