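# lipidflow

Analysis toolkit for case/control serum lipidomics studies of severe
preeclampsia, built around the design of a 64-sample maternal-serum
cohort (44 severe preeclampsia cases, 20 full-term controls, 729
annotated lipid species). It is aimed at computational biologists who
want the full analysis chain of such a study as tested, reusable Python
— from raw abundance matrix to differential lipids, condition-specific
correlation networks, lipid-class enrichment, a biomarker classifier,
and pseudo-time causality — together with a synthetic-cohort generator
that makes every stage testable against planted ground truth.

## The methods at its core

**Preprocessing.** Missing values (left-censored, as at MS
quantification limits) are imputed by k-nearest-sample means over
mutually observed, z-scored lipids; abundances are then log₂-transformed
and median-normalized per sample.

**Cohort statistics.** Fisher's exact test for 2×2 tables, the
Freeman–Halton exact test for R×C tables (full enumeration of the
fixed-margin polytope, with a permutation Monte-Carlo fallback), Welch's
unequal-variance *t* from group summaries, and the phi coefficient
φ = (ad−bc)/√((a+b)(c+d)(a+c)(b+d)).

**Screening and differential analysis.** Per-lipid multi-factor ANOVA
(Type II sums of squares) ranks clinical factors by their *F*
statistics; lipids with a case/control *F* > 1 pass the screen. Each
screened lipid is then modelled by OLS on status plus confounders with
empirical-Bayes variance moderation: the prior (d₀, s₀²) is estimated by
moment-matching the scaled-F distribution of log s², the posterior
variance is s̃² = (d₀s₀² + d·s²)/(d₀+d), and the moderated *t* has
d₀+d degrees of freedom. The final lipid list requires raw p < 0.01 for
status, no confounder association, in both the full cohort and a subset
free of case-only confounders (non-smokers without gestational
diabetes).

**Networks.** Unsigned weighted correlation networks, A_ij = |cor|^β
with β chosen by the scale-free topology fit (R² ≥ 0.85); topological
overlap TOM_ij = (Σ_u A_iu A_uj + A_ij)/(min(k_i,k_j)+1−A_ij);
average-linkage clustering of 1−TOM into modules (minimum size 10,
eigenlipid merging at correlation distance 0.25); per-module density,
module overlap between conditions, module–trait association, and
differential connectivity Δk with the ±5 rule.

**Enrichment, classification, causality.** One-sided Fisher tests for
lipid-class over/under-representation; information-gain feature
selection (> 0.1 bits) feeding a cross-validated random forest evaluated
on repeated 80/20 splits (base seed 1996) with F1, balanced accuracy,
AUROC and PR-area, plus a confounder-specificity check; and lag-1
Granger *F* tests over samples ordered by gestational age, assembling
the p < 0.05 directed graph with mediator annotation.

## Worked example

`examples/table_one.py` recomputes the reference cohort's clinical
statistics from its published counts and summaries:

```
exact tests on categorical variables (p-values):
  gestational_diabetes   p = 0.013
  smoker                 p = 0.088
  chronic_hypertension   p = 0.085
  membrane_rupture       p = 0.250
  baby_gender            p = 0.419
  abruption              p = 0.546
  parity                 p = 0.017  (Freeman-Halton)
  ethnicity              p = 0.228  (Freeman-Halton)

Welch t tests from printed summaries (p-values):
  maternal_age           t =  -0.99  p = 0.327
  bmi                    t =   0.05  p = 0.962
  gestational_age        t =   6.90  p = 4.93e-09

phi(status, gestational diabetes) = 0.307
```

Cases deliver significantly earlier than controls, and gestational
diabetes and parity are the significant categorical associations — the
confounder structure every downstream stage has to adjust for.

`examples/granger_causality.py` recovers a planted lipid → mediator →
outcome chain on a synthetic cohort:

```
planted chain: LPC 48:2 -> DAG 25:4 -> outcome

significant Granger edges (p < 0.05):
  LPC 48:2     -> DAG 25:4     F =  83.11  p = 6.3e-13
  DAG 25:4     -> status       F =  21.43  p = 2e-05

mediators (inbound lipid edge + outbound edge to outcome): ['DAG 25:4']
```

The other examples cover cohort simulation, differential analysis,
network rewiring, and the biomarker classifier. The whole chain also
runs as a CLI:

```sh
lipidflow run-all --seed 1 --out my_run     # 10 stages, JSON run report
```

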