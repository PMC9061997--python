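# icpattern

Immune-checkpoint regulation-pattern discovery and the PCA-based **ICscore**
for gastric-cancer-like bulk expression cohorts.

Tumors coordinate many costimulatory and coinhibitory checkpoint molecules at
once, and the joint expression pattern of this panel — not any single gene —
tracks how inflamed ("hot") or deserted ("cold") the tumor microenvironment
is. `icpattern` implements the full analysis a translational group would run
on a multi-cohort gastric-cancer dataset:

1. **Batch integration** — empirical-Bayes location/scale correction
   (ComBat model) across cohorts/batches.
2. **Pattern discovery** — resampling consensus clustering (PAM k-medoids on
   a 1 − Pearson distance) over a fixed 31-gene immune-checkpoint panel,
   with the number of clusters chosen by minimum PAC (proportion of
   ambiguous clustering). Clusters are renamed A, B, C in decreasing mean
   panel expression, so A is always the immune-hot pattern.
3. **Immune infiltration** — single-sample gene-set enrichment (ssGSEA) for
   immune-cell signatures and ESTIMATE-style stromal/immune summary scores.
4. **Signature and score** — pattern-contrast differential expression
   (Welch t + Benjamini–Hochberg per contrast), intersection of significant
   genes across all contrasts, then PCA on the z-scored signature matrix.
   The per-sample score is

   ICscore(s) = Σᵢ (PC1ᵢ,ₛ + PC2ᵢ,ₛ) = PC1 coordinate + PC2 coordinate of s,

   with each component oriented so its loading sum is ≤ 0 — high signature
   expression (immune-hot) drives the score *down*.
5. **Stratification** — maximally selected log-rank cutpoint (with a
   minimum group-proportion guard) splits patients into low/high ICscore
   groups; Kaplan–Meier, log-rank, and Efron-tie Cox models quantify the
   survival contrast.
6. **Genomics** — tumor mutation burden from MAF, per-gene mutation
   frequencies by score group, Fisher-exact mutation co-occurrence, and CNV
   gain/loss frequencies.

A first-class synthetic-cohort generator (`icpattern.simulate`) emits linked
expression / clinical / MAF / CNV / gene-set data with planted patterns,
batch effects, survival structure and TMB gradients, so the entire pipeline
is testable without any download.

## Worked example

```python
from icpattern import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1, simulate={})   # default synthetic conditions
bundle = run_pipeline(cfg, "out/")
print(bundle.summary)
```

which prints (seed 1, 3 × 80 patients):

```
{'n_samples': 240, 'chosen_k': 3, 'k_used': 3, 'n_signature_genes': 906,
 'cutpoint': 10.637, 'mean_icscore_by_pattern': {'A': -19.652, 'B': 0.335,
 'C': 19.555}, 'logrank_p_icscore_group': 1.05e-11,
 'cox_hr_high_vs_low': 3.037, 'spearman_icscore_tmb': -0.689,
 'pattern_recovery_ari': 0.9875, ...}
```

Reading this: PAC selected k = 3 patterns, which match the planted labels
almost perfectly (adjusted Rand index 0.99). The intersection of pairwise
differentially expressed genes gives a 906-gene signature; the immune-hot
pattern A has the lowest mean ICscore (−19.7 vs +19.6 for cold pattern C),
the score is negatively correlated with mutation burden (Spearman ρ −0.69),
and the high-score group dies faster (hazard ratio ≈ 3, log-rank p ≈ 1e−11).

The same stages are exposed on the command line:

```sh
icpattern simulate --seed 1 --out cohort/
icpattern cluster --expr cohort/expression.tsv --clinical cohort/clinical.tsv \
    --batch-col batch --genes icg --k-grid 2:6 --seed 1 --out clust/
icpattern all --config cfg.yaml --out out/
```

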