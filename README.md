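# sclc-subtyping

Proteomic stratification of small cell lung cancer (SCLC), implemented as a
tested, reusable analysis pipeline.

SCLC is an aggressive neuroendocrine lung tumour with few stratification
markers: staging systems (TNM, VALG limited/extensive) and transcription-
factor classification (ASCL1/NeuroD1/YAP1) predict outcome poorly.  This
package implements a proteome-based alternative: starting from label-free
protein intensity tables of FFPE tumours, it quantifies relative abundance,
clusters tumours into molecular subtypes by consensus non-negative matrix
factorisation, derives per-subtype signature proteins and a transferable
random-forest classifier, and asks the clinical questions that make the
subtypes useful — which subtype has the best overall survival, which benefits
from chemotherapy, and which from first-line immunotherapy.

## Method core

* **Quantification.** iBAQ = raw intensity / number of theoretically
  observable peptides; FOT = iBAQ / Σ iBAQ of the sample (unit-sum
  composition per run).  Missing values are imputed with 1/10 of the
  sample's smallest non-zero FOT.
* **Feature selection.** Union over samples of each sample's top-1100
  most abundant detected proteins, then keep proteins detected in > 10% of
  samples with coefficient of variation > 1.9.
* **Consensus NMF.** V ≈ WH with W, H ≥ 0 minimising the generalised
  Kullback–Leibler divergence D(V‖WH) by multiplicative updates (the
  classic "brunet" NMF).  Fifty random restarts per k; co-clustering
  indicators (argmax over metagene coefficients) are averaged into a
  consensus matrix; labels come from average-linkage clustering of
  1 − consensus.  k ∈ {2..6} is chosen jointly on average silhouette > 0.8,
  minimum class size ≥ 10, and multi-group log-rank P < 0.01 on overall
  survival; subtypes are named S-I/S-II/S-III by ascending event hazard.
* **Signatures and classifier.** One-vs-rest signatures by fold change
  (> 3 for S-I/S-II, > 10 for S-III) with Wilcoxon rank-sum P < 0.05; the
  classifier panel by Welch t-test on log10 FOT with Benjamini–Hochberg
  FDR < 0.05, FC > 1.5, detection > 25%; random forest (500 trees,
  stratified 10-fold CV over a small max-features grid).
* **Survival.** Kaplan–Meier with Greenwood variance, multi-group log-rank
  with full covariance, Cox proportional hazards (Newton–Raphson partial
  likelihood, Efron or Breslow ties) with Wald HRs and 95% CIs;
  chemotherapy benefit assessed per subtype within TNM II/III; ICI
  progression-free survival compared between subtypes among first-line
  treated patients; IHC H-score = intensity (1–3) × % positive cells.

Because real cohort data cannot ship with the package, a first-class
synthetic cohort generator (`sclc_subtyping.synthetic`) reproduces the
statistical shape of such a study — 75 tumours × 7000 proteins, abundance-
dependent dropout, three planted subtypes with fold-change signatures
(3, 3, 10), subtype-dependent exponential survival and a chemotherapy
interaction — so every stage runs end-to-end against known ground truth.

## Worked example

```python
from sclc_subtyping import SyntheticConfig, generate_cohort, PipelineConfig, run_discovery

intensity, clinical, truth = generate_cohort(SyntheticConfig(seed=20231))
result = run_discovery(intensity, clinical, PipelineConfig(seed=11))

print(result.k_selection.report)
print(result.subtype_labels.value_counts())
print(result.classifier.cv_accuracy)
```

A run of the bundled drivers (`python analysis/01_simulate_cohorts.py`,
then `python analysis/02_discovery_analysis.py`) prints, for that seed:

```
clustering features retained: 417
   average_silhouette  min_class_size  logrank_p  eligible
k
2              0.7789              22        0.0     False
3              1.0000              22        0.0      True
4              0.7168               2        0.0     False
5              0.4940               2        0.0     False
6              0.3646               2        0.0     False
chosen k = 3
subtype sizes: {'S-I': 30, 'S-II': 23, 'S-III': 22}
signature proteins S-I: 142 / S-II: 159 / S-III: 40
classifier panel: 27 proteins; 10-fold CV accuracy 96.0%
OS log-rank across subtypes: p = 1.05e-12
multivariate Cox: S-III vs S-I HR = 34.1 (95% CI 10.8-107.5)
```

Reading the numbers: 417 proteins pass the abundance/variability filters;
only k = 3 satisfies all three selection criteria (k = 2 is less stable,
k ≥ 4 produces tiny classes); the three recovered subtypes separate
overall survival by orders of magnitude in hazard, as planted.  Exact
values vary with the seed — the structure is the reproducible finding.
`analysis/03_external_validation.py` transfers the classifier to an
independent 52-sample cohort (90.4% agreement with the planted truth,
log-rank p = 2.7e-06 across predicted subtypes for this seed) and
`analysis/04_ici_analysis.py` compares first-line ICI progression-free
survival between predicted subtypes.

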