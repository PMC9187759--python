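# tnbcstrat

Compare two ways of stratifying triple-negative breast-cancer (TNBC)
expression cohorts: an epithelial–mesenchymal-transition (EMT) score
split into risk groups, versus tumor-immune-microenvironment
metasignature groups — and test whether the two stratifications are
related.

The package is aimed at computational biologists working with bulk
expression cohorts. It provides, as a library and a CLI:

* the fixed three-step array normalization (log2 of summarized
  intensities, per-array median centering, per-array unit magnitude:
  Σᵢ xᵢ² = 1 per sample), which keeps new cohorts comparable with a
  scorer trained under the same recipe;
* cross-dataset sample matching by transcriptome correlation with a
  reliability margin and clinical (age / tumor-size) verification;
* metasignature scoring (mean normalized expression over the Immune,
  Fibrosis, Cholesterol and Interferon gene sets) and the rank-based
  group constructions: top-60% immune / top-40% fibrosis with an
  Intermediate class, and the 50/50 Cholesterol/Interferon refinement
  of the immune-high group;
* Pathway Deregulation Scores: the arc-length position of each sample
  along a Hastie–Stuetzle principal curve fitted in a pathway's gene
  subspace, with PDS = 0 at the reference samples' mean position;
* EMT risk groups by sorting and splitting a per-sample score
  (precomputed integer scores from file, or a clearly labelled
  surrogate scorer for end-to-end testing);
* the statistical layer: Pearson correlation with regression-based
  significance, two-sample Kolmogorov–Smirnov tests (exact by
  enumeration for small samples), Kaplan–Meier curves and the log-rank
  test (via lifelines);
* a seeded synthetic-cohort generator that plants an EMT latent (with
  survival hazard), four metasignature latents, three tissue
  compartments and a noisy permuted duplicate dataset, so the whole
  pipeline runs and is validated without any download.

See `docs/methods.md` for the models, defaults and limitations.

## Worked example

```python
from tnbcstrat import (generate_cohort, cohort_gene_sets, normalize_expression,
                       score_gene_set, surrogate_emt_score, split_by_score,
                       classify_immune_fibrosis, pearson_test, kaplan_meier,
                       logrank_test)

matrix, clinical, truth = generate_cohort(n_samples=200, seed=1)
norm = normalize_expression(matrix)
sets = cohort_gene_sets()

immune = score_gene_set(norm, sets["immune"])
emt = surrogate_emt_score(norm, sets["emt_e"], sets["emt_m"])
groups = split_by_score(emt, n_groups=2)
print("EMT groups:", groups.counts())

res = pearson_test(immune, emt)
print(f"EMT vs immune: r = {res.statistic:.3f}, p = {res.pvalue:.3f}, "
      f"significant = {res.significant}")

if_groups = classify_immune_fibrosis(immune, score_gene_set(norm, sets["fibrosis"]))
print("Immune/Fibrosis groups:", if_groups.counts())

surv = clinical.survival()
lo, hi = groups.members("low"), groups.members("high")
lr = logrank_test(surv.loc[lo, "followup_time"], surv.loc[lo, "event"],
                  surv.loc[hi, "followup_time"], surv.loc[hi, "event"])
print(f"log-rank low vs high EMT: chi2 = {lr.statistic:.2f}, p = {lr.pvalue:.2e}")
km = kaplan_meier(surv.loc[hi, "followup_time"], surv.loc[hi, "event"])
print(f"high-EMT 5-year survival: {km.survival_at(60):.2f}")
```

Output:

```
EMT groups: {'low': 100, 'high': 100}
EMT vs immune: r = 0.075, p = 0.294, significant = False
Immune/Fibrosis groups: {'ImmuneHigh_FibrosisLow': 86, 'ImmuneLow_FibrosisHigh': 46, 'Intermediate': 68}
log-rank low vs high EMT: chi2 = 30.47, p = 3.38e-08
high-EMT 5-year survival: 0.23
```

Reading it: the default cohort plants an EMT latent that is
*independent* of the immune latent, and the correlation test correctly
finds no significant association (r = 0.075, p = 0.29) — the null this
comparison is designed to probe. The same EMT split is strongly
prognostic (log-rank p ≈ 3×10⁻⁸) because the generator plants a hazard
ratio of 2 per EMT standard deviation: being unrelated to the immune
stratification does not stop the EMT score from predicting survival.
The Immune/Fibrosis groups hold the immune-high-only, fibrosis-high-only
and Intermediate (both-or-neither) samples.

The same pipeline runs from the shell:

```bash
tnbcstrat simulate --out sim --seed 1 --n-samples 200 --duplicate --n-corrupt 4
tnbcstrat normalize sim/expression.tsv --out sim/normalized.tsv
tnbcstrat match sim/expression.tsv sim/expression_dup.tsv \
    --clinical-a sim/clinical.csv --clinical-b sim/clinical_dup.csv \
    --out sim/matches.tsv
tnbcstrat classify sim/expression.tsv --gene-sets sim/gene_sets.gmt --out sim/groups
tnbcstrat run --config config.yaml --out report --seed 1
```

Real cohorts are supplied as TSV or GEO series-matrix expression files
plus a clinical CSV; see the config layout in
`tnbcstrat/pipeline.py` and the CLI `--help` for the options.

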