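# Methods

This note documents the statistical models, the synthetic data-generating
process, the numerical conventions, and the design choices behind
`metaexpr`, in the spirit of the model documentation shipped by mature
statistical packages.

## Effect-size meta-analysis

Each cohort contributes a standardized mean difference on the log2
expression scale, computed as Hedges' g (case minus control over the pooled
SD, small-sample corrected):

    d = (m̄₁ − m̄₀) / s_p,   s_p² = ((n₁−1)s₁² + (n₀−1)s₀²) / (n₁+n₀−2)
    g = J·d,  J = 1 − 3/(4(n₁+n₀−2) − 1)
    var(g) = (n₁+n₀)/(n₁n₀) + g²/(2(n₁+n₀))

The case-minus-control orientation means a downregulated marker yields a
negative pooled estimate. Pooling uses inverse-variance fixed-effect
weights and the DerSimonian–Laird method-of-moments between-study variance

    τ̂² = max(0, (Q − df) / (Σw − Σw²/Σw)),  w_i = 1/var_i

with Cochran's Q, I² = max(0, (Q−df)/Q), and 95% CIs of the form
estimate ± 1.96·SE throughout (no Knapp–Hartung adjustment — the classical
software convention for this analysis family). Both fixed and random fits
are always reported; the I² > 0.50 rule picks which one a summary labels as
"the" model. Note the rule is strict: I² = 0.50 exactly selects fixed.

Sensitivity analysis is leave-one-out re-pooling. Subgroup analysis pools
independently within categories (platform, ethnicity); singleton categories
are dropped with a warning rather than reported as degenerate "pools".
Publication-bias screening is the Begg–Mazumdar test: Kendall's τ_b between
the variances and the standardized deviates
t_i = (g_i − μ̂_FE)/√(var_i − 1/Σw), with the asymptotic normal two-sided p;
all-equal variances make the ranking undefined, returned as
(τ=0, p=1, degenerate flag). Egger regression and trim-and-fill are
deliberately out of scope.

## Diagnostic-accuracy meta-analysis

Per cohort, the AUC is the Mann–Whitney estimate (ties counted ½) with
Hanley–McNeil standard error and a normal test against 0.5. If the raw
P(case > control) falls below 0.5 the marker orientation is flipped to
"low expression = test positive" and 1−AUC reported, so downregulated and
upregulated markers are handled symmetrically. The 2×2 table comes from the
Youden-optimal cutoff over midpoints of adjacent sorted unique values; ties
on J break toward higher sensitivity, then toward the cutoff further from
the case mean. The cutoff rule is a package convention: reproducible and
conventional, but any per-study choice differing from the original
software's internal rule will shift pooled accuracy numbers on real data.

Pooling is univariate DerSimonian–Laird on transformed scales:
logit(sens) and logit(spec) separately, and ln DLR+, ln DLR−, ln DOR from
per-study cells, each back-transformed for reporting. Tables containing a
zero cell get +0.5 added to all four cells (only those tables). The
diagnostic score is the pooled ln DOR and DOR = exp(score), so that pair is
exactly consistent; because sens, spec and the DLRs are pooled on their own
scales, DLR+/DLR− ≈ DOR holds only approximately across tracks — the same
discrepancy visible in published outputs of the standard tooling (e.g.
3.74/0.51 = 7.33 vs a printed DOR of 7.26). The summary ROC is
Moses–Littenberg: least squares of D = ln DOR on S = logit(sens) +
logit(1−spec), the curve traced by logit(tpr) = (a + (1+b)·logit(fpr))/(1−b)
and integrated by the trapezoid rule on a 2001-point grid with endpoints
clamped to (0,0) and (1,1). All-equal S is fitted as slope 0 and flagged.
The bivariate Reitsma model would be the natural extension; the univariate
pipeline is deterministic and optimizer-free, which is what the test suite
pins down.

Fagan's update is plain Bayes on the odds scale:
post-odds = pre-odds × LR, reported for positive and negative results.

## Survival

The marker is dichotomized at the cohort median, defined as the lower of
the two middle order statistics for even n so that both groups are
non-empty and the split is deterministic; samples at or above the median
are "high". Kaplan–Meier curves use the product-limit estimator with the
standard tie convention (events processed before censorings at the same
time). The two-group comparison is the log-rank test over pooled event
times with hypergeometric variance per time, and the hazard ratio is Peto's
one-step estimator lnHR = (O−E)/V with var(lnHR) = 1/V — closed-form,
adequate for moderate effects, and exactly consistent with the log-rank
statistic. A Cox model would add covariate adjustment; it is an extension,
not part of this stage.

## Discovery (vote counting)

Correlations are Pearson r between each gene and the target over all
samples of a cohort, cases and controls pooled (maximizing n; note this
means a strong case/control shift in both genes contributes positively to
r — see the generator discussion below). p-values use the exact-null t
transform t = r√((n−2)/(1−r²)) with n−2 df. Differential expression is
Welch's t per gene with log2FC = mean(case) − mean(control) and BH
adjustment within each cohort. All thresholds are strict inequalities
(r > 0.3, not ≥; |log2FC| > 1; p < .05), and membership requires an
absolute number of same-direction votes (≥ 9 for co-expression, ≥ 8 for
DE) regardless of how many cohorts tested the gene. Opposite-direction
votes are tallied separately and never cancel. Genes constant within a
cohort contribute r = 0, p = 1 there. The moderated-t machinery of
limma-voom is intentionally not reproduced: the cross-cohort vote counting
is the method under test, and a Welch t is its well-defined per-cohort
ingredient; an empirical-Bayes variant could be slotted in per cohort
without touching the voting layer.

## Enrichment and hubs

Over-representation uses the hypergeometric upper tail
P(X ≥ overlap), X ~ HG(N = |universe|, K = |set ∩ universe|,
n = |query ∩ universe|), BH-corrected across sets. The default universe is
the set of genes tested for DE across cohorts (config-overridable); no
ontology content is bundled — any GMT works. The hub gene is the
highest-degree node in the subgraph induced by the query on the supplied
edge list, ties broken alphabetically.

## Synthetic data-generating process

One seed drives everything; cohort i uses the substream seeded
`seed + 1 + i`, and survival uses `seed + 1 + n_cohorts`. Identical seeds
give bit-identical output.

- Gene-level means μ_g ~ U(4,12) and SDs σ_g ~ U(0.5,1.5) are drawn once
  from the master stream and shared by all cohorts, so between-cohort
  heterogeneity enters only through the target gene.
- The target's cohort-level effect is δ_i ~ N(true_smd, τ²); case samples
  are shifted by δ_i·σ_t. Background genes are i.i.d. normal.
- Planted co-expressed genes come from a single latent factor: with z_t the
  empirically standardized target within the cohort,
  x_g = ρ·z_t + √(1−ρ²)·ε rescaled to (μ_g, σ_g), ρ = ±ceg_loading, so the
  expected Pearson r with the target is ±ceg_loading.
- Planted DEGs shift the case mean by ±deg_log2fc.
- Coupling: positively co-expressed genes additionally receive the
  deg_log2fc case shift in the target's direction (and negative CEGs the
  opposite shift). This mirrors the empirical situation the pipeline is
  built for — genes that track a downregulated target are themselves down
  in cases — and it gives the truth object a well-defined, non-empty
  planted intersection (positively co-expressed ∩ downregulated = the
  positive-CEG list). It can be disabled (`couple_ceg_deg=False`) for
  pure-correlation experiments.
- Survival: marker ~ N(8,1); T ~ Exponential(h₀·exp(β·1[marker ≥ median]))
  with h₀ = 0.03/month (median survival near two years, the scale of the
  liver-cancer cohorts this emulates); each subject is censored with
  probability censor_rate at a U(0,T) time, so the expected censored
  fraction equals censor_rate exactly.

Default study conditions: 12 cohorts × 30/30 samples × 200 genes,
true_smd = −0.5, τ = 0.2, ceg_loading = 0.7, 15/10 positive/negative CEGs,
15/15 up/down DEGs at ±1.5 log2 units, survival n = 300 with β = ln 2 and
20% censoring. The SMD and τ are the package's canonical recovery
conditions; the −0.5 magnitude also keeps the two planted screens
separable: with a much stronger target effect (|SMD| ≳ 1.5) the shared
case/control structure alone pushes the pooled-sample correlation between
the target and any strong DEG past the 0.3 screen, so planted DEGs start
voting as CEGs. That behaviour is statistically faithful (pooled
correlations are confounded by group structure) and worth knowing when
interpreting real-data CEG lists, but it makes planted-class recovery the
wrong yardstick at extreme effect sizes.

What the generator does not emulate: platform-specific artifacts (probe
saturation, library-size effects), correlated background genes, batch
effects, non-normal expression marginals, or informative censoring.
Passing recovery tests on this process therefore demonstrates correctness
of the statistical machinery under its own assumptions, not robustness to
real-data pathologies.

## Numerical conventions and degenerate inputs

- 95% intervals use z = 1.96 exactly.
- Zero pooled SD raises "degenerate variance" (no effect size defined).
- All-tied diagnostic values report AUC 0.5, p 1, flagged.
- Vote screens treat within-cohort-constant genes as non-votes.
- The log-rank stage refuses groups with no events and splits with all
  markers equal.
- Probe collapsing is the arithmetic mean of duplicate gene rows
  (order-independent and idempotent); gene identity is the trimmed,
  uppercased symbol, with no alias resolution.
- Matrices are assumed log2; `log2_transform` applies log2(x+1) on load
  for count-scale inputs. No other normalization is performed.

## Problem sizes

The shipped tests and the acceptance script run on desk-scale simulations
chosen to make each property measurable with comfortable margin: 50
replicates × 15 cohorts for coverage, 12 cohorts × 200 genes × 30/30 for
discovery and null calibration, n = 500–2000 single cohorts for
distributional checks, 10⁵ draws for permutation/Monte-Carlo oracles.

## Known limitations

- Univariate diagnostic pooling (not the bivariate model) — pooled accuracy
  from real, heterogeneous studies will differ from bivariate-model output.
- Peto HR is biased toward the null for large effects and unbalanced
  censoring; Cox regression is the documented extension.
- The Youden cutoff rule is a convention, not a reconstruction of any
  specific original analysis.
- Vote counting discards effect magnitude beyond the threshold; it is a
  robustness device across heterogeneous platforms, not an efficient
  estimator.
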