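# Methods notes

This note records the models, parameter choices and numerical conventions
behind `srcprog`, including the decisions taken where the underlying study
design leaves details open.

## Synthetic probe-level experiments

The microarray generator emulates perfect-match (PM) probe data from
short-oligo arrays:

```
PM(i, j) = φ(i) · θ(g(i), c(j)) · 2^ε,    ε ~ Normal(0, noise_sd²)
```

- **Probe affinities** φ are log-normal with unit *geometric* mean per probe
  set (log2 sd 0.7), so probe-set summaries on the log scale are unbiased.
  Multiplicative (log-normal) noise is the standard error model for
  hybridization intensities; no background, spatial or batch artifacts are
  simulated.
- **True expression** θ is a per-gene log2 baseline (Normal(7, 1), i.e.
  intensities around 128) modified by planted effects: up/down genes carry a
  linear fold change drawn from `fold_change_range` (default 2–8) in the
  designated test condition; temperature-responsive genes carry a fold change
  (default 1.5–3×, random sign — the study observed cold-shock inductions of
  three-fold or less) wherever the array temperature differs from the
  baseline condition's.
- **Redundancy**: a fraction of genes (default 0.1) carries two probe sets
  with identical true expression but independent affinities, mimicking
  probe sets with identical gene annotations.
- **Defaults** (2,000 probe sets × 11 probes, 3 replicates per condition,
  100 up + 100 down planted genes, log2 noise sd 0.25) are calibration
  choices, not measured values: the study reports no noise or effect-size
  magnitudes for its arrays. The defaults produce realized fold changes
  within ±20% of truth and pipeline sensitivity just below 1, i.e. a regime
  that exercises rather than trivializes the callers.
- `simulate_discovery_scenario` builds the full four-experiment design
  (three-condition discovery experiment, two temperature-sensitive
  experiments, temperature control) over one gene universe, with planted
  *common*, *ts-only*, *TR-only* and *temperature* gene classes. Temperature
  genes deliberately confound the two ts comparisons (those compare the two
  temperatures) and are the targets of the temperature filter.

What a green synthetic test does **not** establish: correctness on real CEL
data (no background correction or mismatch probes are modeled), robustness to
batch effects, or the biological validity of any particular gene list.

## Tumor cohorts

Log2 expression is Normal(μ_g, 1) around per-gene baselines μ_g ~ Normal(7, 1).
A planted aggressive subgroup (default 25% of tumors) has the signature genes
shifted by `expression_shift` (default +2 log2 units). Survival times are
exponential with hazard `baseline_hazard · hazard_ratio^is_aggressive`
(defaults 0.1/year and 3). Censoring is independent exponential; its rate is
solved with Brent's method so the expected censoring proportion equals
`censoring_rate` (default 0.3), using
`P(censored) = E[c / (c + h)]` over the hazard mixture. Event = 1 iff the
event time precedes the censoring time; observed time is the minimum.
Exponential survival means the proportional-hazards assumption holds exactly —
real cohorts need not satisfy it.

## Normalization and expression index

- **Median scaling**: every array is scaled multiplicatively to a common
  median ("auto" = mean of the input medians) before normalization, so the
  separate experiments have comparable probe intensities.
- **Invariant set**: probes whose normalized rank difference between target
  and baseline array is below `rank_threshold` are retained iteratively
  (ranks recomputed within the retained set) until the set shrinks by < 1% or
  30 iterations. The original method publications do not fix these thresholds;
  `rank_threshold = 0.005` is a declared substitute, configurable. An emptied
  set falls back to the N/10 smallest full-array rank differences.
- **Normalization curve**: a running median (window = 10% of the invariant
  set) of (target, baseline) pairs over the invariant probes, made monotone
  by cumulative maxima, interpolated piecewise-linearly, with linear
  extrapolation at the tails and a floor at zero. Monotonicity guarantees
  rank preservation; the curve inverts a global monotone distortion to within
  1% away from the extreme tails.
- **Baseline array**: the array whose median intensity is the median of the
  per-array medians within its experimental group; each experimental group is
  normalized within itself.
- **Expression index**: per probe set, alternating least squares for the
  rank-1 model with identifiability constraint mean(φ) = 1 (convergence at
  relative change < 1e-10, ≤ 60 iterations), one outlier pass masking
  residuals beyond 3 sd followed by a weighted refit, and a positivity floor
  at 1e-6 × the median index so downstream log transforms are safe.
  Single-probe sets pass their intensity row through. The fit is exact on
  noise-free rank-1 data and scale-equivariant.

## Differential calling

All tests operate on log2 values; fold changes are ratios of group geometric
means (equivalently anti-logged mean log differences — the study does not say
which convention it used; geometric means are the self-consistent choice when
testing on logs). t-tests are pooled-variance by default (Welch available).
Degenerate rows (zero variance in both groups) get p = 1 when the means agree
and p → 0 otherwise.

The ANOVA regime additionally requires the test condition to differ from the
pooled controls by ≥ the fold threshold *in a consistent direction* (same sign
against both controls); features whose only large contrast is
control-vs-control are assigned direction "none" and rejected, because the
transformation-regulated class is defined by test-condition-specific change.

**Permutation FDR**: sample-to-group labels are permuted within the
experimental group and the identical call rule re-applied; the estimate is
mean null pass count / observed pass count (0 when nothing is observed, with
a warning). Arrangements that reproduce the observed partition are excluded:
in a 3 vs 3 design, 2 of the 20 distinct arrangements are the observed split
and would leak the entire signal into the null, inflating the estimate by
roughly 10% of the observed calls. Excluding them leaves the complete-null
estimate unbiased (measured ≈ 1.0) and the strong-signal estimate in the
sub-1% range. Designs with fewer than 20 distinct arrangements are enumerated
exactly.

**Temperature filter**: a ts-called gene is removed iff it passes the
temperature-control comparison and its temperature |log2 FC| is ≥ its |log2
FC| in the transforming-vs-control comparison at the non-permissive
temperature; genes absent from that comparison count as fold change 1, the
conservative convention (such genes are removed).

**Collapse**: among probe sets sharing a gene, the smallest p-value wins, ties
broken by lexicographic probe-set ID. For a bare expression matrix with no
accompanying differential result, the highest-mean-intensity probe set is
retained instead (maxMean convention).

## Signature derivation

- Clustering uses 1 − Pearson correlation between tumors over the gene-wise
  mean-centered feature subset (centering only, no unit-variance scaling),
  average linkage, dendrogram cut to k = 4 — the training panels of the
  original analysis show four tumor clusters; the tree-cut rule itself is not
  stated. Both k and centering are configurable.
- "Poorest estimated mean survival" is implemented as the restricted mean
  survival (area under the KM curve) truncated at the largest observed time
  in the cohort; the truncation convention of the original is unstated.
- Clusters with fewer than 2 tumors are excluded from poor-cluster candidacy
  (correlation-distance clustering of noise tumors regularly yields
  singletons); ties resolve to the smallest cluster index, with warnings.
  Even so, a small eligible noise cluster occasionally wins the selection by
  chance, in which case the candidate lists share nothing and the pipeline
  aborts with a diagnostic rather than emitting an empty signature — at the
  default synthetic scale this happens in a minority of seeds and is scored
  as a miss in recovery statistics.
- Candidates are genes with one-tailed (greater-in-poor-cluster)
  pooled-variance t-test p < 0.05 against *all* other tumors pooled; the
  signature is the intersection of the two training candidate lists, and
  concordance is reported against the smaller list.

## Survival evaluation

Scores are means of gene-wise mean-centered log2 expression over the present
signature genes (absent genes dropped with a log entry), so scores sum to zero
across tumors and are invariant to per-gene shifts. The upper-quartile split
takes the ceil(n/4) largest scores, boundary ties broken by lexicographic
tumor ID for determinism. KM estimation and the unweighted k-group log-rank
test are delegated to lifelines (events precede censorings at tied times; p
from χ² with k − 1 df); restricted means integrate the step function directly,
holding S at its last value (with a warning) when the truncation time exceeds
the group's last observed time. Time units are carried through verbatim and
never converted.

## Known limitations

- No CEL parsing, mismatch probes, background correction or batch
  correction; no Cox modeling, multivariable adjustment or competing risks;
  no GO/pathway enrichment.
- The permutation FDR is a ratio estimator and is reported as 0 when no
  features pass, which under-states uncertainty in near-null regimes.
- The paired northern-vs-array validation table is part of the originally
  published supplementary material and is not bundled; `fixtures.load_concordance_table`
  accepts a user-supplied copy.
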