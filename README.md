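# metbc

Statistical and machine-learning analysis of panel-sequenced metastatic
breast cancer cohorts, built for biostatisticians who work with targeted
clinical sequencing panels (sample metadata + MAF-like alteration calls)
and want the full inferential pipeline — not just single tests — in one
tested package:

* **Covariate-adjusted enrichment scanning.** For each alteration feature
  *j*, a logistic regression
  `P(met) = logit⁻¹(β₀ + β₁·xⱼ + β₂·P(ER+) + β₃·HER2 + β₄·TMB)`
  with a two-sided Wald test on β₁, over the whole gene panel, with
  family-wise error controlled by **min-p (maxT) permutation**: the
  met/local labels are permuted, the full scan is re-run per permutation,
  and each observed p is compared against the permutation distribution of
  the minimum p across features, `p_corr = (1 + #{min-p ≤ p_raw}) / (B + 1)`.
* **Site-specific scans** (each metastatic site vs all local disease) and
  supporting exact/nonparametric tests: Fisher 2×2 and r×c (exact
  enumeration or fixed-margin Monte Carlo), Mann-Whitney, two-sample
  Kolmogorov–Smirnov, and beta regression for comparing classifier score
  distributions under covariates.
* **ER-subtype imputation** with class-balanced random forests (per-tree
  stratified bootstrap, out-of-bag vote fractions as probabilities, mtry by
  10-fold CV, permutation variable importance).
* **ESR1 hotspot analysis**: named ligand-binding-domain hotspots (D538G,
  Y537S, Y537N, Y537C, E380Q, L536H, V422del), recurrence-pooled long-tail
  sets (seen once / 2–3 times), hotspot-by-site/histology contingency
  tables, and the visceral-vs-bone D538G contrast.
* **Tissue-of-origin misdiagnosis detection**: breast-vs-other classifiers
  with the site-enriched genes masked, applied to alteration-stratified
  metastases.
* **Pathology-report ER parsing** (anchor + keyword + negation rules) and
  **CHIP diagnostics** (age-binned mutation rates normalized to ages
  20–39, VAF-vs-age trends).
* A **synthetic cohort generator** whose default configuration plants the
  published prevalences and effect sizes, with per-sample ground truth, so
  every stage is validated by parameter recovery.

## Worked example

```python
from dataclasses import replace
import pandas as pd
import metbc

config = replace(metbc.default_config_from_paper(),
                 n_local=2000, n_lymph=0, n_met=2500, n_ambiguous=0)
cohort, truth = metbc.simulate_cohort(config, seed=1)
fm = metbc.build_feature_matrix(cohort)

keep = cohort.samples["group"].isin(["local", "metastasis"]).to_numpy()
y = cohort.samples.loc[keep, "group"].eq("metastasis").astype(float).to_numpy()
cov = pd.DataFrame({
    "er": truth.loc[keep, "true_er"].eq("positive").astype(float).to_numpy(),
    "her2": truth.loc[keep, "her2"].astype(float).to_numpy(),
    "tmb": fm.tmb_per_mb.to_numpy()[keep],
})
res = metbc.maxt_permutation_correct(
    fm.X.loc[keep].reset_index(drop=True), y, cov, n_perm=500, seed=1,
    min_count=10)
print(res[["feature", "rate_group1", "rate_group0", "odds_ratio",
           "p_raw", "p_corrected"]].head(4).to_string(index=False))
```

prints

```
  feature  rate_group1  rate_group0  odds_ratio        p_raw  p_corrected
 ESR1_mut       0.1744       0.0230    6.776729 8.409656e-33     0.003992
FGF19_amp       0.2236       0.1045    2.064937 7.796303e-16     0.003992
 FGF4_amp       0.2272       0.1080    1.998185 8.072739e-15     0.003992
 FGF3_amp       0.2216       0.1080    1.976113 2.241646e-14     0.003992
```

ESR1 mutation is the strongest metastatic enrichment (17.4% vs 2.3% at
this scaled-down cohort size, odds ratio ≈ 6.8 after adjusting for subtype
and mutation load), followed by the FGF3/4/19 amplicon;
`p_corrected ≈ 0.004` is the floor of a 500-permutation min-p correction —
no permutation produced a minimum p smaller than these observed values.

A thin CLI wraps the same functions:

```bash
metbc simulate --seed 1 --out demo/ --n-reports 50
metbc enrich --samples demo/samples.tsv --alterations demo/alterations.tsv \
    --n-perm 1000 --min-count 10 --seed 1 --out enrichment.tsv
metbc esr1 --samples demo/samples.tsv --alterations demo/alterations.tsv \
    --stratify site --out esr1.tsv
metbc chip --samples demo/samples.tsv --alterations demo/alterations.tsv \
    --out chip.tsv
metbc parse-reports --dir demo/reports --out er_status.tsv
```

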