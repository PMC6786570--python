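# Methods

## Pipeline

`rdscreen` classifies 53-item ordinal questionnaires (1 = "completely
false" … 4 = "completely true") into rare-disease vs comparison-group
answer patterns. The pipeline has five stages:

1. **Encoding.** A complete record becomes a 55-element vector: the 53
   answers verbatim, a binary gender code (female 0, male 1), and age in
   years. Records missing any answer, age or gender are excluded rather
   than imputed; the completeness filter is a pure partition so exclusion
   counts are auditable against the generator's bookkeeping.
2. **Subset assembly.** Three pairwise designs contrast rare-disease
   composites against NRO, CD and PSY groups at 90:90, 90:90 and 42:38.
   Membership is drawn uniformly at random (seeded) from the eligible
   pool, in fixed order 1→2→3 with a shared consumed set, so no
   questionnaire appears in two subsets and assembly is reproducible. The
   diagnosis-to-class mapping is an editable dictionary: unmatched
   diagnoses are ineligible, never guessed.
3. **Base classifiers.** Four families per subset: degree-3
   polynomial-kernel SVM, random forest, logistic regression, linear
   discriminant analysis. Each emits a coded diagnosis (0 = rare-disease
   side) and the probability of that diagnosis.
4. **Fusion.** The four (index, probability) pairs concatenate, in fixed
   family order, into an 8-element meta-feature; a further degree-3
   polynomial SVM is trained on out-of-fold meta-features (k_inner
   stratified folds; base models fitted on k−1 folds predict the held-out
   fold) and the base bundle is then refit on all rows. Fold provenance is
   stored so the no-leakage property — no meta-training row predicted by a
   model that saw it — is assertable after the fact.
5. **Evaluation and reporting.** Stratified 10-fold cross-validation with
   counts pooled into one confusion matrix per classifier (per-fold
   sensitivities are stored as well); ROC by threshold sweep over the
   fusion probabilities; the three subset sensitivities average into the
   headline rare-disease sensitivity. For one patient, the three fusion
   probabilities form the suggestion: rare disease at the argmax subset if
   any P(RD) ≥ 0.5, otherwise the comparison group with the largest
   complement.

## Parameters

| parameter | default | notes |
|---|---|---|
| SVM C / degree / coef0 | 1.0 / 3 / 1.0 | inhomogeneous cubic kernel; C at the library convention |
| SVM calibration | Platt sigmoid, 5 internal folds | margin methods have no native probability; calibration is fitted within whatever split the model trains on |
| forest size | 100 trees | library-convention default, ample at n ≤ 180 |
| logistic C / max_iter | 1.0 / 2000 | L2, lbfgs |
| LDA shrinkage | Ledoit–Wolf ("auto") | p = 55 is comparable to the per-class n (38–90); shrinkage is selected analytically and keeps the pooled covariance non-singular when an item is constant within a class |
| base-feature standardization | on | raw age (0–120 y) would dominate kernel distances against the 1–4 answer scale; the fitted scaler is stored in the bundle so train and predict transforms are identical; trees see raw features |
| meta-feature standardization | off | the 8 elements are already on a common bounded scale (indices in {0,1}, probabilities in [0,1]); z-scoring near-constant probability columns amplifies noise directions and measurably degrades fusion sensitivity in cross-validation |
| k (outer CV) | 10 | stratified; per-class fold counts differ by ≤ 1 |
| k_inner (stacking) | 5 | leaves ≈ 27 class-2 rows per inner training split even in the 42:38 subset |
| decision threshold | 0.5, ties → rare-disease side | the tool is an alarm for considering a rare disease, so ties err toward sensitivity |

All stochastic components (sampling, fold shuffles, forest, calibration
splits) consume a single integer seed per call. `train_fusion`
canonically orders its training rows (lexicographic on features, then
label) before the inner split, so fitted models are invariant to the order
in which records are supplied.

## Reporting conventions

Sensitivity = 100·TP/(TP+FN), specificity = 100·TN/(TN+FP), with the
rare-disease side positive. Reported percentages are **truncated**, not
rounded, to one decimal (79/90 = 87.77… → 87.7); raw double precision is
kept internally. The headline rare-disease sensitivity is the arithmetic
mean of the three subset sensitivities — the only aggregation consistent
with mean(87.7, 93.3, 85.7) = 88.9 on the published matrices. AUC equals
the Mann–Whitney concordance probability with ties counted half; the test
suite checks this against an exhaustive pair-counting oracle. Pooled
counts (not fold-metric averages) define the reported metrics; per-fold
values are stored alongside for curve plots.

## The synthetic generator

Each item is an independent categorical draw over {1,2,3,4}. The
unaffected profile is (0.40, 0.30, 0.20, 0.10) on every item — answers
lean "false" for respondents without the rare-disease experience. Group
separation shifts mass toward answer 4 on 20 of the 53 items by an effect
size δ ∈ [0,1]: p' = (1−δ)p + δ·e4, so δ = 0 gives identically
distributed groups (the chance-level null) and δ = 1 degenerates affected
items at 4. The default grid {0, 0.2, 0.4, 0.6} spans chance to
near-separable regimes. Ages are truncated-normal (mean 45, sd 15, bounds
5–90), gender Bernoulli(0.6 female), missingness item-wise Bernoulli.

The study-shaped pool reproduces the return-rate structure: 758
rare-disease records over named diagnoses (sarcoidosis 144, PAH 50,
syringomyelia 44, SLE 31, …) plus an umbrella remainder, with 200 NRO,
149 CD and 48 PSY — 1155 in total, from which the three subsets consume
440 and leave 715. Where the published per-diagnosis counts cannot be
reconciled exactly with the subset capacities (e.g. cystic fibrosis), the
composition is filled so every design is satisfiable; it is a package
constant, editable per run.

What the generator deliberately does **not** model: inter-item correlation
beyond the shared shift, ordinal smoothness (answer 3 carries no
information about answer 4), diagnosis-specific answer signatures within
the rare-disease side, and age/gender–group associations. Passing tests
therefore demonstrate that the pipeline recovers categorical answer-pattern
differences at realistic sample sizes and degrades to chance on
exchangeable groups — not that real questionnaires are this clean, nor
that the published per-subset sensitivities would be reproduced on the
original answer collections (whose subset memberships and software defaults
are unpublished).

## Problem sizes in the test and acceptance runs

Monte-Carlo properties are checked at the design's own sizes: null
behavior over 20 seeds and signal recovery over 10 seeds, each a full
10-fold cross-validation of a 90:90 subset; unit tests use 30:30 cohorts
and 2-feature toys. The acceptance script performs one complete synthetic
study (three subsets, 10-fold CV) plus the metric arithmetic on the
published confusion matrices.

## Known limitations

- The fusion's advantage over the best single family is small on this
  generator (the forest is near-ceiling when items are independent); the
  comparison is meaningful as "fusion never materially worse than any
  family", which is what the Monte-Carlo test asserts.
- Exact numeric parity with the original R-based implementation is not
  attainable: its library defaults (tree count, SVM cost, kernel scaling)
  and the true subset memberships are unpublished. The package pins every
  hyperparameter explicitly instead.
- Calibrated probabilities at n = 80–180 carry calibration noise of a few
  percent; downstream thresholds (0.5) are robust to this but reported
  probabilities should be read with that granularity in mind.
- No imputation: real-world deployments with sparse answers would need a
  missing-data strategy before encoding.
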