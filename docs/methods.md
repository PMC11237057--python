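# Methods

## Model and assumptions

The pipeline treats a bioactivity record — a compound measured against
one target (ACE or NEP), as one standard type (IC50 or Ki), in one assay
type (binding or functional) — as the modelling unit.  Records are
labelled active iff the nM-normalised activity is ≤ 600 nM; the
comparison is inclusive, so a compound at exactly 600 nM is active.
Duplicate records under the same (compound, target, standard type, assay
type) key collapse to the one holding the (lower) median activity:
stable under resampling and robust to assay outliers.  The 70/30
train/test split draws the test set uniformly at random; the test size
is the nearest integer (half-to-even) of 0.30·n, which maps a
715-record dataset to 501 train / 214 test.  A stratified split is
available behind a flag but is not the default, since plain random
splitting is the simpler assumption.

### Condition-deviation (Box-Jenkins) features

For each element *e* of each condition axis — the two targets, the two
standard types, the two assay types — and each raw descriptor D, the
arithmetic mean avg(D)ₑ is taken over the **training-set actives**
measured under *e*, and every record is recoded as the deviation
Δ(D)ₑ = D − avg(D)ₑ under its own three condition elements.  Averaging
over actives only makes the deviation a distance from "what an active
under this condition looks like"; an all-compounds variant exists behind
a flag for sensitivity analysis.  The three axes are transformed
independently (no joint (tn, st, at) cells), giving exactly 3× the raw
width with `_tn`/`_st`/`_at` suffixes; raw descriptors are dropped from
the modelling space afterwards.  Test and screening data always reuse
the training averages, so no label information leaks out of the training
set.  Missing descriptor values are rejected rather than imputed.

Two identities pin the implementation down: over the training actives of
any condition element the corresponding Δ columns average to exactly 0,
and adding a constant to a raw descriptor leaves every Δ unchanged.
Both are property-tested.

### Feature selection and classifiers

Wilks λ = det(W)/det(T) (pooled within-class over total SSCP) scores a
candidate subset; it is computed through eigenvalues rather than raw
determinants because deviation features can be *exactly* collinear: for
any three descriptors, the pairwise differences of their `_st` and `_at`
features are piecewise-constant over the four (st, at) groups and span
only ~2 dimensions after centring, making W and T exactly singular.
Such subsets are rejected as degenerate (relative eigenvalue threshold
1e-10) and receive the worst fitness in the search rather than a
spuriously perfect λ.

The GA minimises λ + 0.01·|subset|/subset_max over fixed-length binary
chromosomes: population 100, 100 generations, tournament size 3,
one-point crossover 0.8, per-bit mutation 0.01, one elite, subset bounds
2–12 repaired by random bit flips toward the nearest bound.  Fitness is
memoised per chromosome.  Ties break toward smaller subsets, then
lexicographic names, so results are reproducible.  An exhaustive
enumerator provides the global optimum on small pools and is the GA's
test oracle.

The linear model is a two-class Fisher discriminant on z-scored
features: w = S_pooled⁻¹(μ_active − μ_inactive), score centred at the
midpoint of the class mean scores (equal priors; prevalence priors
behind a flag), score > 0 ⇒ active.  Coefficients are therefore
standardized coefficients; raw-scale coefficients are derived and
serialized alongside.  The random forest is a bagged Gini CART ensemble
(scikit-learn), 100 trees, unlimited depth, √p features per split; vote
fractions are tallied tree by tree and a tied vote predicts inactive,
so screening errs conservative.  The forest is fitted on the full
deviation feature space — non-linear ensembles do not need the
parsimony that motivates subset selection for the discriminant.

### Validation battery

Confusion-derived statistics follow the textbook formulas, with
percentages displayed at 2 dp and fractions (F, MCC) at 4 dp; a metric
with a vanishing denominator is reported as NaN and flagged, never
silently zeroed.  AUC uses the rank (Mann–Whitney) formulation with
average ranks, so ties count half; the curve is tabulated at every
distinct threshold.  Cross-validation is stratified k-fold (k = 10 by
default), each sample scored exactly once out of fold.  Y-randomization
scrambles the labels 50 times and refits the discriminant **on the same
selected subset** each time; rerunning selection per permutation would
conflate chance correlation with selection variance, which is the
deliberate reading implemented here.

### Applicability domain

The standardization approach stores each selected descriptor's training
mean and sample (n−1) sd; a query's deviates s_k = |x_k − μ_k|/σ_k are
tested: all ≤ 3 → inside; all > 3 → outside; otherwise
S = mean(s) + 1.28·sd(s) ≤ 3 decides.  Both constants are configurable.
The AD lives in the fitted model's selected feature space, where
predictions are actually made.  One subtlety: the tail rule is *not*
monotone in every deviate — raising a small s_k can shrink sd(s) enough
to pull S under 3 — so the tested monotonicity property is the provable
one, monotonicity in the largest deviate.

### Consensus screening

Library compounds carry no measured activity; their condition vectors
are synthesized per evaluated target with standard and assay type fixed
to the training majority values.  Selection requires inside-AD under
every evaluated condition and active calls from both models for both
targets; single-target mode exists for reuse.  The selected set is, by
construction, the intersection of the per-rule pass sets, and that is
verified independently in the tests.

## Synthetic data generator

The generator emulates the curated two-target dataset the pipeline is
designed for and is itself first-class, tested code.  Defaults are the
study conditions: 357 ACE + 358 NEP records; activities log-normal in nM
with ln-scale spread σ = 1.5 (several orders of magnitude, as bioassay
panels show) and median calibrated so that P(activity ≤ 600 nM) equals
the requested 70% prevalence; 200 raw descriptors of which 10 are
informative; standard type drawn IC50 with probability 0.65 and assay
type binding with probability 0.70, independently of class, so the
`_st`/`_at` deviations carry only weak signal — mirroring their sparse
role in practice.  Each target's informative set has 6 of the 10
informative columns with an overlap of 2 (dual-inhibitor structure: some
chemistry drives both activities, some only one).  An informative
descriptor for a compound's own target is N(±effect/2, noise_sd²)
conditional on class; everything else is standard normal.  The default
effect size of 1.5 places the end-to-end held-out accuracy in the
85–95% band (the ~90% regime the pipeline targets); with effect 0 the
pipeline sits at chance, which is checked as the null.

What the generator does **not** emulate: descriptor correlation
structure beyond the class-conditional means, chemically meaningful
SMILES, assay-dependent noise, or activity cliffs.  Passing tests
therefore demonstrate the statistical machinery, not performance on
real chemistry.

## Numerical choices and degenerate inputs

- Wilks λ clipped to [0, 1]; exact within-class collinearity with a
  regular T returns 0 (total separation); singular T raises.
- z-scoring rejects zero-variance columns by name; singular pooled
  covariance raises rather than pseudo-inverting.
- The nearest-integer split size uses Python's round (half-to-even),
  the variant consistent with the 501/214 partition of 715 records.
- Unit conversion uses exact decimal factors (pM…M → nM).
- All stage randomness derives from one master seed through fixed
  offsets (simulate +0, split +1, GA +2, RF +3, CV +4, Y-rand +5,
  modulo 2³¹−1), so each stage is independently reproducible.

## Problem sizes used in the checks

The acceptance script and the heavier tests run the generator at
357+358 records with 50–200 raw descriptors (150–600 deviation
features), GA population 60 × 40 generations, 100 trees, 50
permutations, and tenfold CV; these sizes keep a full from-scratch run
in seconds while leaving every statistic in its asymptotic regime.

## Known limitations

- Wide near-collinear subsets may pass the 1e-10 eigenvalue gate yet
  yield unstable discriminant coefficients; the size penalty and subset
  cap mitigate but do not eliminate this.
- The GA is single-objective; no wrapper selection around the forest.
- The AD treats descriptors independently (no leverage/Williams
  variant).
- The fitness of the selection search is pluggable but only the
  penalised-λ default is tuned.
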