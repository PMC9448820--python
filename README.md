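# thyropanel

Protein-panel classification of thyroid nodules, end to end: synthetic
DIA-proteome cohort generation, detection-limit (MNAR) imputation with
discovery-anchored normalization, genetic-algorithm selection of a
fixed-size protein panel, a manifold-regularized neural classifier, and
diagnostic-performance / differential-expression reporting.

## What is in here

| Module | Purpose |
| --- | --- |
| `thyropanel.cohort` | Synthetic cohorts: quartile-calibrated log2 abundances, planted benign/malignant signal, logistic detection-limit censoring calibrated to a target missing fraction, replicate structure, stratified nodule-level splits. |
| `thyropanel.preprocess` | Imputation with the ceiling of the discovery minimum, per-feature z-normalization anchored to the discovery set, replicate QC (CV, Spearman), missing-rate filtering, replicate averaging. |
| `thyropanel.panel` | Feature screening (differential expression + whitelist + missing-rate cutoff) and a genetic algorithm over fixed-size feature subsets with 3-fold cross-validated fitness on dataset A and a one-shot holdout ranking on dataset B. |
| `thyropanel.dmt` | The neural classifier: Student-t kernel pairwise similarities, symmetrization, cross-layer two-way divergence, class-weighted cross-entropy, L2 penalty; minibatch SGD with exact autodiff gradients; 5-fold model selection by validation AUC. |
| `thyropanel.metrics` | Confusion counts, sensitivity/specificity/PPV/NPV/accuracy with Wilson 95% intervals, rank-based AUC with tie correction, ROC points, prevalence re-projection of PPV/NPV, stratified accuracy tables. |
| `thyropanel.dep` | Pairwise differential-expression counting (Welch t-test on observed values, Benjamini-Hochberg, fold change > 4 and adjusted p < 0.01) and per-protein one-way ANOVA. |

Matrices travel as TSV (rows = samples, columns = proteins, empty cell =
missing); models and configs as JSON. Everything is seeded and
deterministic.

## Command line

```bash
thyropanel simulate --config cohort.json --out cohort/ --seed 1
thyropanel preprocess fit   --matrix cohort/matrix.tsv --out norm.json
thyropanel preprocess apply --model norm.json --matrix cohort/matrix.tsv --out normed.tsv
thyropanel preprocess qc    --matrix cohort/matrix.tsv --annotation cohort/annotation.tsv
thyropanel select  --matrix a.tsv --labels a_ann.tsv --holdout b.tsv \
                   --holdout-labels b_ann.tsv --out panel.json --seed 1
thyropanel train   --matrix normed.tsv --labels ann.tsv --out clf.json --seed 1
thyropanel predict --model clf.json --matrix normed.tsv --out pred.tsv
thyropanel embed   --model clf.json --matrix normed.tsv --out latent.tsv
thyropanel evaluate --pred pred.tsv --truth ann.tsv --stratify histotype --prevalence 0.30
thyropanel dep      --matrix cohort/matrix.tsv --groups cohort/annotation.tsv --group-key histotype
```

`cohort.json` holds a `CohortConfig` (see `thyropanel.cohort`), e.g.

```json
{
  "n_per_histotype": {"MNG": 203, "FA": 137, "N": 40, "FTC": 75, "PTC": 124},
  "n_proteins": 1000,
  "n_informative": 19,
  "effect_size": 2.0,
  "missing_fraction_target": 0.51,
  "seed": 1
}
```

## Conventions

- Malignant is the positive class everywhere; class labels are the
  strings `benign` / `malignant`, and the classifier's integer labels use
  1 = benign, 0 = malignant with ties resolved to malignant.
- Histotype to class: N, MNG, FA, L, HCA are benign; FTC, PTC, HCC,
  fvPTC are malignant. Stratified reports can merge HCA into FA and HCC
  into FTC.
- Fold changes are computed on the log2 scale (fold change > 4 means
  |delta log2| > 2).
- Wilson intervals use the uncorrected score interval.
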