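# Methods

This note documents the statistical models implemented in `lipidflow`,
the defaults and why they were chosen, what the synthetic cohort
generator does and does not emulate, and the numerical decisions that
affect results.

## Synthetic cohort generator

The generator (`lipidflow.simulate`) draws log₂ abundances from a
multivariate normal with block-correlation structure and exponentiates
— the log-normal abundance model standard in lipidomics, which makes
the log-transform stage exact. Defaults reproduce the reference study
conditions:

- 44 cases / 20 controls, 729 lipid species over 15 classes (TAG, PC,
  PE, LPC, LPE, OxPC, OxPE, DAG, CE, Cer, SM, PI, PG, PA, MAG) in
  roughly the proportions of an untargeted serum panel.
- Three correlated blocks: a TAG-like block (60 species, within-block
  correlation 0.6 in both conditions), an oxidized-phospholipid block
  (30 species, correlation 0.8 in cases vs 0.3 in controls — the
  planted "rewiring"), and a PC block (20 species, 0.7). Blocks are
  exchangeable-correlation constructions (shared latent factor), which
  are positive semidefinite for any correlation in [0, 1]; out-of-range
  requests fail naming the offending module.
- Ten planted case/control effects at log₂ fold change −1.0 on
  background (non-module) species, mirroring the predominance of
  down-regulated serum markers. Per-lipid baseline log₂ means are
  uniform on [8, 16] with unit log₂ standard deviation (≈ a typical
  2-fold biological coefficient of variation).
- Clinical covariates drawn per group from the published cohort
  summary: gestational age N(35.82, 2.89²) in cases vs N(39.10, 0.85²)
  in controls, maternal age, BMI, and categorical covariates at the
  published level frequencies. Smoking and gestational diabetes have
  zero control-group counts, so they occur only among cases — the
  case-only confounding the dual-cohort rule exists to handle.
- Missingness is MNAR left-censored: the per-cell missing probability
  is logistic in the per-lipid z-scored log abundance,
  `sigmoid(c − steepness·z)`, with the intercept bisected so the
  expected missing fraction equals the requested rate (default 0.10, a
  free parameter — the reference study does not report its rate;
  steepness default 2).
- The causal chain is generated along the gestational-age ordering:
  the root lipid is a lag-1 autoregression, each downstream lipid is
  driven by its predecessor's previous value, and the last chain lipid
  additionally anticipates the next sample's outcome label. Because
  the 0/1 outcome is fixed by design, "lipid Granger-causes outcome"
  is planted by inverting the regression direction at generation time;
  this is exactly the signal the pseudo-time Granger stage can
  legitimately recover. Default coefficients 0.8 (lipid→lipid) and 1.0
  (lipid→outcome).

One global seed feeds per-stage substreams
(`default_rng([seed, stage])`), so covariates, abundances, the chain,
and missingness are independently reproducible; identical configs give
bit-identical cohorts.

**What the generator does not emulate:** raw spectra, retention times,
adducts, internal standards, batch drift, heavy-tailed abundance noise,
class-structured correlation beyond the planted blocks, or confounder →
lipid effects (lipids depend on covariates only through the case/control
label). Passing recovery tests therefore show that the algorithms
recover the structure they target under the study's sample sizes and
noise, not that real serum data are this clean.

## Preprocessing

KNN imputation operates in sample space on the raw scale: the distance
between two samples is the plain Euclidean distance over the lipids
both observed, computed on per-lipid z-scores so abundant species do
not dominate; a missing cell is the unweighted mean of the k nearest
donor samples observed for that lipid (k defaults to 10 and must be
smaller than both the sample count and each lipid's observed count).
Observed cells are never altered and the original mask is kept.
Imputation precedes the log transform (the order is a convention;
imputing on the raw scale keeps donor means on the measurement scale).
Log base is 2; the base only rescales coefficients. Median
normalization shifts each sample's logged row so its median equals the
grand median of per-sample medians — additive on the log scale, hence
invariant to per-sample multiplicative scaling, and centered at an
interpretable abundance level rather than zero.

## Cohort statistics

The two-sided Fisher rule sums all fixed-margin tables at most as
probable as the observed one (with a 1e-7 relative tie tolerance). The
Freeman–Halton R×C test enumerates the margin polytope depth-first with
log-factorial arithmetic; a feasibility bound (~2×10⁷ tables) guards
the recursion and points to the permutation Monte-Carlo estimator.
Welch's t is used rather than the pooled test: the pooled test cannot
reproduce the printed gestational-age p-value given the groups' very
unequal SDs (0.85 vs 2.89). Odds ratios are sample cross-product
ratios (infinite allowed). A zero-margin 2×2 carries no information
and returns p = 1 by convention.

## SOV screen

Per lipid, an additive linear model on all clinical factors;
categorical factors dummy-coded against a first-level reference, parity
as a 4-level categorical. Type II sums of squares (marginal SS given
all other factors) are order-independent, which matters because no
factor order is canonical. F = (SS_f/df_f)/(SS_e/df_e); the screen
keeps lipids with status F > 1, i.e. status mean square above the error
mean square. An `ss_ratio` rule (SS_f > SS_e) is provided because the
two differ whenever df_f ≠ df_e. Constant factors are excluded with a
warning; aliased (rank-deficient) factor sets are reported by name.

## Differential analysis

Empirical-Bayes moderation follows the standard hierarchical model of
per-feature variances: with z = log s², E[z] and Var[z] are matched to
the digamma/trigamma moments of the scaled-F distribution, giving d₀
via a Newton trigamma inverse and s₀² in closed form. The moderated
t uses s̃² = (d₀s₀² + d·s²)/(d₀+d) on d₀+d degrees of freedom. Edge
cases: literally identical sample variances carry no pooling
information (ordinary t, flagged by infinite d₀); homogeneous but noisy
variances shrink fully to the pooled prior. `prior_df=0` disables
moderation and reproduces the ordinary per-lipid t exactly.

"Associated with a confounder" means any non-status coefficient in the
same per-lipid model with p below the fit's alpha (0.01 default); for
multi-level factors the smallest coefficient p is used. The
dual-cohort rule intersects the significant-and-unconfounded lists of
the full cohort and the subset without smokers or gestational-diabetes
pregnancies; the intersection's alpha applies to the status p only,
with the fit-time confounder flags, so the final list is monotone in
alpha. No multiplicity correction by default (raw p < 0.01 is the
reference procedure); Benjamini–Hochberg is available.

Power context, computed by the acceptance suite rather than asserted
here: with unit log₂ noise at 44/20, a |log₂FC| = 1 species has a
standardized effect of 1, and requiring raw p < 0.01 in two nested
cohorts after adjusting for a collinear confounder set leaves per-lipid
recovery well below one; the recovery rates the acceptance script
reports quantify this.

## Networks

Unsigned adjacency |cor|^β (Pearson); unsigned is the method's default
and the reference analysis does not state signedness. The soft
threshold is the smallest power whose signed scale-free fit R² (log₁₀
p(k) on log₁₀ k over 10 bins, sign from the slope) reaches 0.85; if no
power qualifies, the best-fitting power is returned with a warning.
Case and control networks share one β (the larger of the two
per-condition picks) so connectivities are comparable; the combined
network picks its own β. TOM follows the standard formula with
diag(A) = 1; 1−TOM is the clustering distance.

Module detection is a documented simplification of the dynamic hybrid
tree cut: average-linkage clustering, candidate clusters from a fixed
cut at 0.95 of the maximum merge height (the intermediate-split
preset), clusters under the 10-species minimum pooled into "grey", then
iterative merging of the closest eigenlipid pair while their
correlation distance is below 0.25. Eigenlipids are first
principal-component scores of the standardized member profiles,
oriented to correlate positively with their members. Labels are
deterministic, ordered by size. Module density is the mean
off-diagonal TOM among members (TOM rather than raw adjacency; the
choice is switchable by reading the model's matrices directly).
Differential connectivity is Δk = k_case − k_ctrl on adjacency-based
connectivity (the "sum of edge weights" reading), with the ±5 rule.

## Enrichment

Per class, a 2×2 in-set × in-class table against the universe;
enrichment is the greater tail, depletion the lesser tail, and the
reported p matches the observed direction (so null p concentrates
below 0.5 by construction — both tails are always reported). Odds
ratios are cross-product ratios with the infinite case preserved.

## Classifier

Information gain uses equal-frequency binning (10 bins; effectively
discrete features use their values as bins), in bits, with the 0.1
selection threshold. Evaluation is leakage-free by construction:
each repeat draws a stratified 80/20 split (base seed 1996, per-repeat
substreams), selection and hyperparameter tuning (stratified 10-fold CV
on F1) see only the training portion. The primary model is a random
forest (200 trees, max-features grid); gradient boosting and
elastic-net logistic regression sit behind the same interface. PR-area
is trapezoidal in threshold order, so vertical segments at duplicate
recall contribute zero width and a perfect ranking scores 1.
Importances are scaled to sum to one (recorded in the report). The
specificity check rescales nothing: each trained model scores its own
test split against an alternative binary label, and AUROC near 0.5 with
PR-area near the label's prevalence indicates no confounder signal.

## Causality

Samples ordered ascending by gestational age, ties broken by stable
input order (recorded behaviour, since ordering affects results).
Lag-1 by default; both models include an intercept; the F statistic's
denominator degrees of freedom are T′ − 2·lag − 1 with T′ the usable
observations, matching the standard two-regression formulation and the
general-linear-hypothesis F identically. The binary outcome enters as
a numeric 0/1 series — a deliberate replication of the reference
procedure; the statistical awkwardness (a fixed design label treated as
a stochastic series) is acknowledged, not repaired, and no causal
identification claim attaches to Granger edges.

## Pipeline

Ten stages (simulate, preprocess, tableone, sov, differential,
network_conditions, network_combined, enrichment, classifier,
causality) write plain-text TSV/JSON artifacts with SHA-256 checksums
in the run report; identical configs reproduce identical checksums.
Confounder sets are pruned of aliased factors before fitting (rare
case-only binaries can coincide by chance in a finite draw), with the
dropped factors noted in the report. Stage parameters default to the
reference values: differential alpha 0.01, TOM edge retention 0.5,
Δk threshold 5, information-gain cut 0.1, 80/20 × 10 repeats with seed
1996, causality alpha 0.05.

## Problem sizes used in tests

Unit and acceptance tests run at the study scale (64 samples; the full
729-lipid panel for differential recovery, calibration at 1000 lipids)
except where a stage is tested in isolation: module recovery uses two
20-species blocks plus 40 noise species at β = 4 on the log scale
(median normalization is skipped there because on an 80-lipid panel
two 20-species blocks dominate the per-sample median and induce
compositional anti-correlation between blocks — a real phenomenon that
is negligible at the 729-lipid scale), and rewiring recovery uses a
30-species block among 200. Null calibrations use 2000 replicates
(Granger size) and 10 permutations (classifier null).

## Known limitations

- Module detection approximates the dynamic hybrid tree cut; very
  nested module structures that the recursive cut would split can land
  in one candidate cluster here.
- The Freeman–Halton enumeration is exponential in table size; beyond
  the feasibility bound only the Monte-Carlo estimate is available.
- The screen-then-test sequence shared with the reference procedure
  conditions the differential tests on the screen, so raw p-values
  downstream of the screen are optimistic; the package reproduces the
  procedure rather than correcting it.
- Granger edges on pseudo-time-ordered cross-sectional samples are a
  heuristic ordering device, not longitudinal inference.
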