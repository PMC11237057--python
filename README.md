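# mtqsar

Multi-target QSAR classification of dual ACE/NEP inhibitors.

Hypertension therapy increasingly looks for single molecules that inhibit
both the angiotensin-converting enzyme (ACE) and neprilysin (NEP).
`mtqsar` implements a multi-target (mt-QSAR) classification workflow for
exactly this setting: one model that predicts active/inactive across
several experimental conditions at once — target enzyme (ACE/NEP),
standard type (IC50/Ki) and assay type (binding/functional) — instead of
one model per assay.  It is aimed at cheminformaticians who have a
curated bioactivity table and a descriptor matrix from any descriptor
engine and want a tested, reproducible modelling and screening pipeline.

## The method

1. **Curation.** Activities are normalised to nM; compounds with
   IC50/Ki ≤ 600 nM are labelled active (inclusive cutoff); duplicates
   per (compound, target, standard type, assay type) collapse to the
   median record; the dataset splits 70/30 at random into training and
   test sets.
2. **Box-Jenkins condition-deviation descriptors.** Raw descriptors
   carry no information about the assay condition, so for every element
   *e* of each condition axis the mean of each descriptor over the
   *training-set actives* measured under *e* is formed,
   avg(D)ₑ = (1/n) Σ Dᵢ, and every data point is re-expressed as
   Δ(D)ₑ = D − avg(D)ₑ.  Each raw descriptor yields three features
   (`_tn`, `_st`, `_at`); test and library compounds reuse the training
   averages unchanged.
3. **GA-LDA.** An elitist genetic algorithm searches descriptor subsets
   that minimise a size-penalised Wilks λ = det(W)/det(T) (within- over
   total-SSCP determinants; small λ = strong separation), and a Fisher
   discriminant with standardized coefficients is fitted on the winning
   subset.  A bagged-CART random forest is the non-linear counterpart.
4. **Validation.** Accuracy, sensitivity, specificity, precision,
   F-measure and MCC from the confusion matrix; ROC/AUC by the
   Mann–Whitney rank formulation; a 50-permutation Y-randomization test
   (labels scrambled, discriminant refitted, λ compared); and a
   standardization applicability domain (per-descriptor deviates
   s = |x−μ|/σ with the max ≤ 3 / min > 3 / mean(s)+1.28·sd(s) ≤ 3
   rules).
5. **Consensus screening.** A library compound is selected only if it is
   inside the applicability domain under every evaluated condition and
   both models call it active against both ACE and NEP.

A synthetic-data generator reproduces the statistical structure of the
curated two-target dataset (sample sizes, 70% prevalence at the cutoff,
log-normal activities, partially overlapping informative descriptor sets
per target), so the entire pipeline is testable without any downloads.

## Worked example

```bash
python examples/03_fit_and_validate.py
```

prints (seed 1, 715 synthetic compounds, 50 raw descriptors):

```
lda_test {"counts": {"tp": 136, "fp": 4, "tn": 66, "fn": 8}, "accuracy": 94.39,
          "sensitivity": 94.44, "specificity": 94.29, "precision": 97.14,
          "f_measure": 0.9577, "mcc": 0.8752, "auc": 0.9861}
rf_test  {"counts": {"tp": 141, "fp": 19, "tn": 51, "fn": 3}, "accuracy": 89.72, ...}
Wilks lambda: fitted 0.3602 vs label-scrambled mean 0.9753
```

The held-out accuracy near 90% is the regime the generator is calibrated
to; the scrambled-label λ near 1 against a fitted λ of 0.36 shows the
discriminant is not a chance artefact.  The other examples cover data
generation/curation, the deviation transform on a tiny worked dataset,
and consensus screening.  The same stages are available from the shell:

```bash
mtqsar fit --seed 1 --out artifacts/
mtqsar screen --seed 1 --library library.csv --out screen.csv
```

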