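# Methods

This note documents the models and procedures implemented in
`sclc_subtyping`, the choices made where the design was genuinely open, and
what the synthetic-cohort experiments do and do not demonstrate.

## Quantification

Raw label-free intensities are converted to iBAQ by dividing each protein's
intensity by its count of theoretically observable peptides (length
normalisation), then to FOT by dividing by the sample's iBAQ total, so each
sample becomes a unit-sum composition over its *identified* proteins.
Zeros in the input mean "not identified in this run" and are tracked in a
detection mask.

Missing values are imputed with one tenth of the sample's smallest non-zero
FOT.  Two readings of "the global non-zero minimum value of the sample" are
possible; we take the per-sample minimum as the default (the phrase "of the
sample" governs) and expose a dataset-global switch
(`impute_missing(global_minimum=True)`) for sensitivity analysis.
Imputation happens after normalisation and columns are not re-normalised:
FOT is defined over identified proteins, and the imputed mass (≤ the number
of missing entries × min/10) is negligible by construction.  Imputation is
idempotent, and imputed values are strictly below every detected value in
their sample.

## Feature selection

Clustering features: the union over samples of each sample's 1100
highest-FOT detected proteins, filtered to detection in strictly more than
10% of samples and coefficient of variation strictly greater than 1.9.
Decisions worth stating because they affect reproducibility:

* Detection thresholds are strict fractions of cohort size ("> 10%",
  "> 25%"), which reproduces "at least 8 of 75" at the discovery scale.
* Ties at the top-N boundary are all included, making the union
  permutation-invariant; dropping arbitrary tied members would make the
  panel depend on input order.
* CV uses the sample standard deviation (n−1) over the mean, computed on
  the imputed matrix across all samples.  Detected-only CV would be
  undefined for singleton detections; imputed near-zero values are exactly
  what gives partially detected proteins their high CV, and that behaviour
  is intended — the CV filter selects proteins whose presence/absence
  pattern varies, which is where subtype information lives.

Classifier candidates use the same machinery with top-500 and > 25%
detection, without the CV filter.

## Consensus NMF subtyping

The factorisation is the multiplicative-update NMF for the generalised
Kullback–Leibler divergence: with WH floored at 1e−12,

    H ← H ⊙ (Wᵀ(V⊘WH)) ⊘ (Wᵀ1),  W ← W ⊙ ((V⊘WH)Hᵀ) ⊘ (1Hᵀ).

These updates never increase D(V‖WH); the divergence trace is recorded each
iteration and checked in tests to 1e−8 relative tolerance.  W and H start
uniform-random in (0, 1] from the run seed; iteration stops at 2000
iterations or when the relative divergence change over a 10-iteration
window drops below 1e−6.  Terms with V = 0 contribute only (WH) to the
divergence.

Before factorisation each retained protein is min–max scaled to [0, 1]
across samples.  FOT spans several orders of magnitude, and unscaled KL-NMF
is dominated by the few most abundant features; per-feature scaling gives
every retained feature comparable influence.  Constant rows cannot be
scaled and must be filtered first (the CV filter guarantees this).

Consensus clustering runs 50 random restarts per k (the run count is a
restart count: a consensus matrix from one run is a 0/1 connectivity matrix
and carries no stability information).  Each restart assigns samples by the
argmax of their H column; the consensus matrix is the mean of the restart
connectivity matrices.  Final labels: average-linkage hierarchical
clustering of the dissimilarity 1 − consensus, cut at k.  Silhouettes use
the same dissimilarity; singleton clusters score 0 by convention.

k is selected over 2..6 jointly on stability and prognosis: eligible k need
average silhouette > 0.8, smallest class ≥ 10, and multi-group log-rank
P < 0.01 on overall survival across the k labels; among eligible k the
maximum silhouette wins, ties to the smaller k.  The prognostic test is the
overall multi-group log-rank (not a best pairwise split).  When no k
qualifies, the per-k report is returned as a first-class result rather than
an exception, so the caller can inspect why.

Recovered clusters are named S-I, S-II, S-III by ascending crude event
hazard (events per person-year), making names reproducible across runs and
cohorts; S-I is always the best-prognosis subtype.

## Signatures and classifier

Subtype signatures are one-vs-rest: fold change is the ratio of arithmetic
means of imputed FOT (subtype vs all other samples pooled), so "FC > 3"
reads literally as a 3-fold abundance ratio; significance is the two-sided
Wilcoxon rank-sum P < 0.05 on the same values.  Thresholds are strict, FC 3
for the two better-prognosis subtypes and 10 for S-III.  With three groups
and pooled-rest means, thresholds ≥ 3 make the per-subtype sets disjoint.

The classifier panel applies, per candidate protein, a one-vs-rest Welch
t-test on log10 FOT for each subtype ("adjusted t-test" is read as Welch +
Benjamini–Hochberg across the candidate panel, the field-standard reading);
proteins with any contrast at FC > 1.5 and BH-adjusted P < 0.05 enter the
panel, ordered by minimum adjusted P then id.  The classifier is a
500-tree random forest on log10 FOT, with candidate-features-per-split
tuned over {√p, p/4, p/2} by stratified 10-fold cross-validation; the
reported accuracy is the mean held-out accuracy at the chosen grid point,
and all folds and forests are deterministic in the seed.  When the panel is
applied to an external cohort, panel proteins missing there are filled per
sample by the same min/10 imputation rule; if more than half the panel is
absent the panel is declared non-transferable.

## Survival analysis

Kaplan–Meier is the product-limit estimator over distinct event times;
subjects censored exactly at an event time remain in the risk set at that
time; variance by Greenwood's formula.  The multi-group log-rank test
accumulates observed-minus-expected events over event times and uses the
full (k−1)×(k−1) covariance matrix — the sum-of-marginal-variances shortcut
is wrong for k > 2.  Cox proportional hazards is fit by Newton–Raphson on
the partial likelihood with step-halving; ties are handled by Efron's
method by default (better with the heavy ties that year-granular follow-up
produces), with Breslow selectable; standard errors come from the inverse
observed information, and runaway coefficients (|β| > 15) set a separation
flag.  In the multivariate model, subtype enters as indicators against
S-I, TNM stage as categorical with stage I reference, and VALG, gender,
smoking, LNM and chemotherapy as binaries.

Chemotherapy benefit is evaluated only within TNM II/III (stages I and IV
dominate prognosis by themselves), as a two-group log-rank of chemo vs none
within each subtype; a subtype with an empty arm is reported not-evaluable.
ICI analysis restricts to first-line-treated patients and compares
progression-free survival pairwise between subtypes.  The IHC H-score is
staining intensity (1–3) × percent positive cells, binned < 10 → 0,
10–40 → 1+, 41–140 → 2+, 141–300 → 3+, positive iff score > 10; note the
deliberate quirk that a score of exactly 10 is bin 1+ yet negative — the
scoring rubric is implemented literally.

## Synthetic cohort generator

The generator emulates the data structure the pipeline assumes, not the
biology of any particular tumour:

* **Abundance.** Per-protein baseline log10 intensity ~ N(6.0, 1.2), shared
  across samples; protein-level properties (baselines, peptide counts) come
  from a `proteome_seed` stream so two cohorts can share one proteome, as
  real discovery/validation cohorts do (by default the proteome follows the
  cohort seed).  Sample noise is multiplicative log-normal with log10-sd
  0.4, the scale of combined technical and biological variation in
  label-free FFPE data.
* **Signatures.** Disjoint protein blocks per subtype, multiplied by the
  subtype fold change (3, 3, 10) in samples of that subtype.  Default block
  sizes are 350/300/50: the planted programmes of the two better-prognosis
  subtypes are broad with modest fold change, while the worst-prognosis
  programme is small and strong — mirroring the observed pattern in which
  the strong-FC subtype has the fewest signature proteins.  After the
  abundance and CV filters roughly 40–60 features per subtype survive,
  enough for the three programmes to be mutually distinguishable at
  comparable scale.  An optional per-sample activation multiplier
  (`signature_activation_sd`) emulates tumour-purity dilution; it is off by
  default.
* **Dropout.** Detection probability is logistic in log10 intensity
  (midpoint 6.0, slope 1.0/decade), applied before observation; undetected
  entries are recorded as zero with a detection mask.  At the defaults this
  yields about 50% overall missingness and ~3500 of 7000 proteins detected
  in more than half the samples, matching the published depth of an FFPE
  label-free experiment.  A slope of zero switches dropout off entirely
  (detection probability one), which the fold-change recovery tests use.
* **Survival.** Exponential event times with hazard
  h[subtype] × exp(loghr[subtype] × chemo); defaults 0.0575/0.2/0.66 per
  year give 5-year OS of 75% / ~37% / 3.7% for S-I/S-II/S-III, and
  treatment log-HRs (−1, 0.7, 0) plant chemotherapy benefit in S-I and harm
  in S-II.  Censoring is exponential (0.05/year) plus an administrative
  cutoff at 8 years.  Weibull hazards are a possible extension, not
  implemented.
* **Clinical covariates.** Age, gender, smoking and nodal status are drawn
  independently of subtype so that adjusted Cox models isolate the subtype
  effect; TNM stage follows the published 13/19/28/13 split and VALG
  extensive stage coincides with TNM IV.  The joint distribution of stage
  and subtype is deliberately not asserted — nothing in the source material
  pins it down — and is exposed through `tnm_probs`.

What passing tests on these cohorts shows: the pipeline recovers planted
structure of realistic shape (three subtypes, heavy dropout, modest fold
changes, subtype-dependent survival) at the discovery sample size.  What it
does not show: robustness to batch effects, correlated co-expression
programmes, peptide-level artefacts, or real inter-tumour heterogeneity,
none of which the generator models.

## Problem sizes and numerical choices

The stochastic recovery suites run ten cohorts of 75 samples × 7000
proteins with 20 NMF restarts per k over k = 2..6; twenty restarts already
give stable consensus matrices at this sample size, and the pipeline
default remains 50 restarts, which the acceptance script and the analysis
drivers use.  Convergence: NMF tol 1e−6 over 10 iterations, max 2000
iterations; Cox tol 1e−9 on the log-likelihood with 20 step-halvings
maximum.  (WH) is floored at 1e−12 in the KL objective; Wald CIs use
z = 1.96; BH adjustment is the standard step-up procedure.

## Known limitations

* The consensus matrix is built from full-data restarts (no sample or
  feature subsampling), so on very clean data low k can look spuriously
  stable: on a minority of synthetic draws (roughly one in ten) the two
  modest-fold-change programmes merge with perfect rank-2 stability and
  selection returns k = 2.  The recovery suites therefore evaluate the
  selection across ten cohorts rather than one.
* The Cox implementation handles neither time-varying covariates nor
  stratification, and flags but does not resolve separation.
* FOT compositions are treated as ordinary non-negative data; no
  compositional (log-ratio) transformation is applied, matching the
  upstream convention at the cost of compositional artefacts in principle.
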