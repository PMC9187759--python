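# Methods

This note documents the models and procedures implemented in
`tnbcstrat`, the choices made where the design was genuinely open, and
what the synthetic cohorts do and do not establish about real data.

## Problem setting

Triple-negative breast cancer (TNBC) cohorts can be stratified in at
least two ways: by a per-sample epithelial–mesenchymal-transition (EMT)
score split into risk groups, or by tumor-immune-microenvironment
metasignature groups (Immune, Fibrosis, Cholesterol, Interferon). The
package implements both constructions plus the statistics needed to ask
whether they are related: correlation tests between the EMT score and
metasignature or pathway-deregulation scores, Kolmogorov–Smirnov tests
between groups, and Kaplan–Meier survival comparisons.

The EMT scorer itself (a Boolean-network method producing an integer
score) is external to this package and deliberately not reimplemented;
the pipeline accepts precomputed scores from file. A clearly labelled
surrogate scorer — rank-normalized mesenchymal-set mean minus
epithelial-set mean, discretized to 11 integer levels — exists so the
pipeline can be exercised end to end; its provenance field says
`kind: surrogate` and it should never be mistaken for the real scorer.

## Normalization

Arrays are normalized per sample column in three steps: values are
floored at `floor` (default 1.0, so summarized intensities in (0,1)
map to log2 = 0) and log2-transformed; the column median is subtracted
(even-length median = mean of the two central values); the column is
divided by the root of its sum of squares, leaving every sample with
unit magnitude (checked to 1e-10). Median centering and magnitude
normalization are per array over **all** genes, not per gene and not
over signature genes only; signature genes are inspected afterwards via
`normalization_report`, which gives per-gene quartiles and a two-sample
KS statistic across datasets. Matrices carry a stage tag
(raw → log2 → centered → normalized) and operations refuse inputs at
the wrong stage, so the normalization can never be skipped or applied
twice. Constant columns (zero magnitude after centering) are an error
naming the sample. There is no quantile normalization or batch
correction: the point of the fixed recipe is comparability with a
scorer trained under the same normalization.

## Cross-dataset sample matching

When the same tumors appear in two datasets without shared
identifiers, each query sample is matched to the target sample with the
highest transcriptome correlation (Pearson on normalized values by
default; Spearman available), computed over the shared-gene
intersection (at least 30 shared genes required). A match is *reliable*
when best minus runner-up correlation is at least `margin_min`
(default 0.10 — the literature gives no number, so the margin is a
surfaced config parameter). Matches are then verified against clinical
fields: agreement means |Δage| ≤ 1 year and relative tumor-size
difference ≤ 10% over all non-missing paired fields; disagreement
excludes the match. A pair with no comparable clinical field keeps
`clinical_ok` missing rather than false. Matching is one-directional
(query → target); many-to-one collisions are flagged, never silently
dropped.

## Metasignature scores and groups

A metasignature score is the plain mean of normalized expression over
the set's present genes (coverage below 50% warns). Group construction
is rank-based throughout, so assignments are invariant under any
strictly increasing transform of the scores, and tie-breaking by
ascending sample id makes counts exact and reruns byte-identical:

* **Immune/Fibrosis**: the top 60% by immune score are
  Immune-high/Fibrosis-low candidates; the top 40% by fibrosis score
  are Immune-low/Fibrosis-high candidates. Samples satisfying both
  criteria are *Intermediate*. Samples satisfying neither criterion
  also go to Intermediate: only the dual-member rule is pinned down by
  the construction this mirrors, and neither-members need a
  deterministic home — Intermediate is the conservative bucket.
* **Cholesterol/Interferon**: the Immune-high group is ranked by the
  composite (interferon − cholesterol) and cut in half, the extra
  sample on odd n going to the cholesterol-low/interferon-high side. A
  single composite rank is used because two independent median splits
  cannot guarantee exactly 50% per group.

## Pathway deregulation scores (PDS)

The PDS of a sample for a pathway is its arc-length position along a
principal curve fitted in the pathway's gene subspace, with the zero
placed at the reference group's mean position.

Fitting is Hastie–Stuetzle: initialize at the first
principal-component line; alternate (i) projecting all points onto the
current polyline and (ii) re-estimating each coordinate as a smoothed
function of the projection parameter; reparameterize by arc length;
stop when the mean squared vertex shift drops below `tol` (default
1e-4 in standardized units) or at `max_iter` (50), in which case the
result is flagged `converged=False` rather than failing silently.

Numerical choices that matter:

* **Smoother.** Default is a tri-cube kernel over a bandwidth of
  `span/2` times the parameter range (span default 0.3). Weights
  depend only on parameter distances, which makes the smoother exactly
  invariant under duplicating the data and keeps weighted averages of
  collinear points on their line; the hard averaging it replaces can
  limit-cycle on small samples. A rank-window local average is
  available as `smoother="rank"`.
* **End behaviour.** A truncated polyline biases end projections
  inward, so the first and last segments are extended to infinity
  during the final projection and the polyline is grown to cover the
  projected range; every reported parameter lies in [0, total length].
  Float-noise micro-segments are dropped before the tangent at an end
  is estimated.
* **Standardization.** Each pathway gene is standardized to zero mean
  and unit variance across samples before fitting; genes with (numerically)
  zero variance are dropped with a warning.
* **Anchoring.** The zero of the PDS scale is the mean arc-length
  parameter of the reference samples, so the reference group's mean
  PDS is zero by construction (to 1e-8) and any other anchor choice
  shifts all scores by the same constant — pairwise PDS differences
  are anchor-invariant. The sign is oriented so the median PDS of
  non-reference samples is ≥ 0.
* **Reference group.** Real-data runs should pass normal/adjacent
  samples; the pipeline's declared fallback is the lowest decile of
  the EMT score. With no reference at all the cohort mean anchors the
  scale (degraded mode, warned).

## EMT risk groups

Samples are sorted ascending by (score, sample id) and cut into 2 or 3
contiguous near-equal blocks (remainder to the lowest blocks); the
2-group split is a median split. Boundary scores are recorded and
flagged when tied across the boundary. The split depends only on
ranks.

## Statistics

* **Correlation significance** uses the t transform of Pearson's r,
  t = r·√((n−2)/(1−r²)) on n−2 df — algebraically the regression-slope
  t test (asserted to 1e-12 against an independent OLS fit in the
  tests). α = 0.05 with no multiple-testing correction is the default
  policy; Benjamini–Hochberg is available but off.
* **KS tests** evaluate the ECDF difference at the pooled sorted
  points; the asymptotic p comes from scipy, and for n+m ≤ 12 an exact
  mode enumerates all label assignments of the pooled values.
* **Survival** uses the Kaplan–Meier product-limit estimator and the
  standard log-rank test via lifelines; censored observations at an
  event time count as at risk for that event. Times are months
  throughout. The log-rank comparison is provided to quantify
  synthetic survival separation; a zero-event arm computes with a
  warning.

## Synthetic cohorts

`generate_cohort` emulates the statistical skeleton the analysis
assumes. Latents are standard normal; fibrosis = −0.5·immune +
residual (opposed Immune/Fibrosis axes), interferon/cholesterol =
±0.3·immune + residual, all scaled to keep unit marginal variance. The
EMT latent is independent of immune by default — the null the
comparison probes — with `emt_immune_loading` available to plant a
dependence. Compartments (bulk/stroma/epithelium, assigned
round-robin) shift the EMT latent by +1/0/−1. Each signature block (30
genes by default; 400 background genes) loads 1.0 on its latent, the
epithelial block negatively on EMT; expression is
exp2(7 + loading·latent + N(0, 0.5)), so log2 recovers the linear model
exactly at zero noise. Survival times are exponential with hazard
(ln 2 / 60 months)·2^z where z is the standardized EMT latent (hazard
ratio 2 per SD); independent exponential censoring is tuned to ~30%.
`generate_duplicate` permutes columns with a seeded permutation, adds
log2-scale noise, and can scramble the clinical fields of a chosen
number of samples to exercise clinical exclusion. All randomness flows
from mandatory seeds; identical seeds give byte-identical cohorts.

These defaults were chosen as a plausible bulk-microarray caricature:
block sizes and noise give per-gene signal-to-noise around 2:1, the
hazard ratio and censoring produce clearly separated but overlapping
KM curves at n = 200, and the ±0.3/−0.5 cross-loadings give
recoverable but imperfect latent correlations. What the generator does
**not** emulate: probe-level noise models, real MAS5 value
distributions, batch effects, correlated gene-gene noise within
blocks, or informative censoring. Passing tests therefore establish
that the pipeline's constructions and statistics behave as specified
under their own assumptions — not that any biological conclusion about
real cohorts follows.

## Problem sizes

The test suite and the acceptance script run at desk scale: cohorts of
20–200 samples and ~600 genes, 20-seed replicates for matching and the
null/alternative correlation checks, 50 seeds for log-rank power.
These sizes keep every check comfortably reproducible on one CPU while
leaving the measured rates (recovery 100%, null non-significance
~95%, power ~100%) far from their thresholds.

## Known limitations

* The principal curve is a single open curve: no branching, no closed
  loops, and strongly non-monotone manifolds can fold projections.
* The 60/40 membership rule beyond dual members is this package's
  declared convention; other implementations re-assign dual members
  instead.
* The surrogate EMT scorer is monotone in mesenchymal-vs-epithelial
  rank balance only; it does not reproduce the integer scale or the
  dynamics of the Boolean-network scorer it stands in for.
* Real-data mode (user-supplied series-matrix files) is supported as
  plumbing but no claim is made that results on downloaded cohorts
  reproduce published figures; that depends on probe collapse rules
  and reference-sample choices not fixed by the published methods.
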