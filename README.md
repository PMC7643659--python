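# metaexpr

Integrative multi-cohort meta-analysis of a single target gene's expression
in case/control transcriptomic studies — the statistical workup used to
appraise a candidate cancer biomarker (the motivating case is *MAOA* in
hepatocellular carcinoma) across dozens of public microarray and RNA-seq
datasets, packaged as a tested, reusable pipeline with a ground-truthed
synthetic-cohort generator so every stage is verifiable without downloads.

## What it computes

Given K cohorts, each a log2 gene × sample matrix with case/control labels:

- **Effect-size meta-analysis.** Per cohort, Hedges' g — the standardized
  mean difference d = (m̄₁ − m̄₀)/s_p corrected by J = 1 − 3/(4(n₁+n₀−2)−1) —
  with variance (n₁+n₀)/(n₁n₀) + g²/(2(n₁+n₀)). Pooled by inverse-variance
  fixed effect and DerSimonian–Laird random effects
  (τ̂² = max(0, (Q−df)/(Σw − Σw²/Σw))), with Cochran's Q,
  I² = max(0,(Q−df)/Q), the I² > 0.50 model-selection rule, leave-one-out
  sensitivity analysis, platform/ethnicity subgroups, and the Begg–Mazumdar
  rank-correlation test for funnel asymmetry.
- **Diagnostic-accuracy meta-analysis.** Per cohort: Mann–Whitney AUC
  (orientation auto-flipped so a downregulated marker is read as
  "low expression = test positive"), Youden-optimal cutoff, 2×2 table. DL
  pooling of sensitivity/specificity on the logit scale and of
  ln DLR±/ln DOR on the log scale; Moses–Littenberg summary ROC
  (D = a + bS); Fagan post-test probabilities from any pre-test probability.
- **Prognosis.** Kaplan–Meier curves for marker-high vs marker-low (median
  split), log-rank test, and Peto hazard ratio lnHR = (O−E)/V.
- **Discovery.** Cross-cohort vote counting: co-expressed genes (per-cohort
  Pearson |r| > 0.3, p < .05, same sign in ≥ 9 cohorts), differentially
  expressed genes (|log2FC| > 1, BH-adjusted p < .05, same direction in
  ≥ 8 cohorts), and the two intersections (positively co-expressed ∩
  downregulated; negatively co-expressed ∩ upregulated).
- **Enrichment.** Hypergeometric over-representation of the intersection
  lists against any GMT collection, BH-corrected, plus degree-based
  hub-gene ranking on a user-supplied interaction edge list.

The synthetic module plants all of this structure (per-cohort SMD with
between-cohort heterogeneity τ, latent-factor co-expression, DEG shifts,
exponential proportional-hazards survival) so recovery can be measured
against known truth.

## Worked example

Simulate a 12-cohort study (30 cases / 30 controls each, 200 genes, planted
SMD −0.5 with τ = 0.2, co-expression loading 0.7, DEG shift 1.5 log2 units,
survival hazard ratio 2) and run each stage:

```
$ metaexpr simulate --seed 1 --out demo/sim
$ metaexpr meta      --registry demo/sim/registry.json --gene MAOA --out demo/meta
pooled g (fixed) = -0.6020 [-0.7520, -0.4521], I2=0.052
$ metaexpr dx-meta   --registry demo/sim/registry.json --gene MAOA --out demo/dx
pooled sens=0.628 spec=0.717 sROC AUC=0.778
$ metaexpr survival  --table demo/sim/survival.tsv --out demo/surv
HR(high vs low)=2.136 [1.611, 2.833], logrank p=1.355e-07
$ metaexpr discover  --registry demo/sim/registry.json --gene MAOA --out demo/disc
15 pos CEGs, 10 neg CEGs, 25 up DEGs, 30 down DEGs; intersections 15/10
```

Reading: the pooled Hedges g of −0.60 (95% CI −0.75 to −0.45) recovers the
planted downregulation; I² = 0.05 correctly reports the mild heterogeneity
as non-significant, so the fixed-effect model is selected. The marker
separates cases from controls with summary ROC AUC 0.78, the high-expression
survival group has 2.1-fold the hazard of the low group (truth: 2.0), and
the discovery screen returns exactly the 15 planted positively co-expressed
(and hence downregulated) genes and the 10 negative/upregulated ones.

The published diagnostic arithmetic can be re-derived directly:

```
$ metaexpr reproduce-fagan
      posttest_pos_pct: computed     48 published     48  [OK]
      posttest_neg_pct: computed     11 published     11  [OK]
            diag_score: computed   1.98 published   1.98  [OK]
      diag_score_ci_lo: computed   1.73 published   1.73  [OK]
      diag_score_ci_hi: computed   2.23 published   2.23  [OK]
```

`metaexpr run-all --registry … --gene MAOA --out dir/` chains every stage
and writes a consolidated `report.json` plus plot-ready TSVs (forest,
funnel, sROC curve, KM curves, vote table).

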