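# Methods

This note documents the statistical models, the synthetic-data
assumptions, and the numerical and design choices behind `vasokin`.

## Data model

A cohort consists of N = n₁ + n₂ patients. Each patient carries, per
progenitor population p and time point t ∈ {PostInduction, Sternotomy,
H0, H1, H6, H24}, a count c_{p,t} of cells per 10⁶ lympho-monocytic
flow-cytometry events, plus a total norepinephrine dose (mg/kg), an
optional EuroSCORE II estimated % mortality, and clinical covariates.
The vasoplegia group is a deterministic function of the dose: G1 if
dose ≤ 0.02 mg/kg, G2 strictly above. The dose exactly at the cutoff is
G1, because the significant-vasoplegia group is defined by doses *above*
the cutoff.

The analysis features are natural-log fold changes
L_{p,t|b} = ln(c_{p,t}/c_{p,b}) against a baseline b ∈ {B1 =
post-induction, B2 = sternotomy, P0 = pump start}. Natural log is used
throughout; Cohen's d and every rank statistic are invariant to the log
base, so this is a presentation choice, not a scientific one. When a
count is zero a pseudocount of 0.5 is added to both numerator and
denominator; it is applied *only* when a zero occurs, so nonzero ratios
are never perturbed. A zero count against a zero baseline with
pseudocount disabled is an error rather than a silent NaN.

## Synthetic cohort generator

The generator exists so that every downstream stage is testable at the
study's scale without patient data. Per patient it draws

1. a baseline count B ~ LogNormal with arithmetic mean
   `baseline_count_mean` (default 600 cells/10⁶ events — mid-range for
   circulating CD34-family populations in adults) and coefficient of
   variation `baseline_count_cv` (default 0.4);
2. for each later time point an independent log fold change
   L ~ Normal(μ_{g,p,t}, σ_{g,p,t}) versus post-induction, optionally
   shifted by a patient-level Normal intercept (default SD 0, i.e. no
   within-patient correlation);
3. counts round(B·e^L), rounded to the nearest integer with floor 1,
   so generated log fold changes are Normal up to a rounding error of
   order 1/(2·count), negligible at the default count scale;
4. a norepinephrine dose uniform in a per-group range (defaults
   0.004–0.019 mg/kg for G1, 0.025–0.10 for G2), so the dose rule and
   the group label agree by construction;
5. a EuroSCORE II value, log-normal with median 1.5% (G1) / 1.7% (G2)
   and log-SD 0.45 — typical elective cardiac surgery risk, deliberately
   similar across groups so that risk-matched subsets exist;
6. covariates (age, sex, diabetes, hypertension, renal failure) with
   plausible prevalences. These are schema filler for I/O and matching
   tests; no analysis consumes them.

The default scenario has n₁ = 8 and n₂ = 7 — the sizes used in the
power analysis — and CD34+ trajectory parameters anchored to the three
published discriminative features: group means 1.23/−0.51 (H0 vs B1),
0.68/−0.50 (H0 vs B2) and 0.37/−0.09 (H24 vs B2), and SDs 1.08/1.05 for
H0 vs B1. Because the generator parameterizes fold changes versus B1,
the vs-B2 feature *means* follow exactly by telescoping
(L_{t|B2} = L_{t|B1} − L_{Sternotomy|B1}). The vs-B2 feature *SDs* do
not: under independent per-time-point deviations,
SD(L_{H0|B2}) = √(SD(L_{H0|B1})² + SD(L_{St|B1})²) necessarily exceeds
SD(L_{H0|B1}), whereas the published table reports it *smaller* (0.53 <
1.08). Matching all three printed SD pairs simultaneously would require
a specific strongly positive within-patient correlation structure that
no reported quantity pins down. The package's choice: keep the simple
independent-deviation model, reproduce all feature means and the
H0-vs-B1 SDs exactly, and let the vs-B2 SDs be what independence
implies. Consequently, effect sizes computed *on simulated cohorts* for
vs-B2 features are attenuated relative to the published d values; all
parameter-recovery guarantees are stated for feature means and for the
H0-vs-B1 feature, which the tests enforce.

Populations other than CD34+ get synthetic trajectory magnitudes shaped
like the observed kinetics (early CD34+/HSC rise in G1, CD133+ and HSC
peaks at 6 h, late VEGFR2+ rise, blunted response in G2); their
absolute values are package defaults, not published quantities.

What passing tests on this generator show: the pipeline is correct on
data satisfying its own distributional assumptions (log-normal counts,
Normal log fold changes, independent patients, complete six-point
series). What they do not show: robustness to real-data features the
generator omits — within-patient serial correlation, heavy-tailed count
noise, missing draws, outlier patients, or group-size imbalance beyond
what config covers.

## Hypothesis tests

With 7–11 patients per group, asymptotic rank tests are unreliable, so
both rank tests enumerate their exact nulls:

* **Mann–Whitney U**: the null distribution of U over all C(n₁+n₂, n₁)
  group assignments is built by the standard recurrence
  c(u; m, n) = c(u−n; m−1, n) + c(u; m, n−1), used whenever
  n₁+n₂ ≤ 16 and the combined sample is tie-free. Exact p-values are
  rationals with denominator C(n₁+n₂, n₁). Ties break the permutation
  argument for this enumeration, so tied data (and larger samples) use
  the tie-corrected normal approximation with continuity correction, in
  the exact algebraic form used by `scipy.stats.mannwhitneyu`
  (verified to float precision in the tests).
* **Wilcoxon signed-rank**: zero differences are discarded; for m ≤ 14
  nonzero differences all 2^m sign patterns are enumerated (this
  sign-flip null remains exact under tied |d| via midranks, so ties do
  not force the approximate path here). Larger m uses the
  tie-corrected, continuity-corrected normal form matching
  `scipy.stats.wilcoxon(method="approx")`.
* Two-sided p-values are min(1, 2·min(lower tail, upper tail)).
* **Normality screening** uses the KS distance against a normal with
  estimated mean/SD. Estimated parameters invalidate the standard KS
  table, so the p-value is Lilliefors-corrected by simulation: a null
  table of 2000 KS distances per sample size (fixed seed, cached), with
  p = (r+1)/(R+1) where r counts null distances ≥ the observed one.
* The paired/unpaired t-tests are thin wrappers over the scipy closed
  forms; they are not a bespoke surface of this package.

## Effect size and power

Cohen's d uses the df-weighted pooled SD; that convention reproduces
the published pooled SDs to within 0.01. Recomputing d from the
published (rounded) means/SDs gives 1.632/1.554/1.083 against printed
values 1.63/1.56/1.10 — the printed values were evidently computed from
differently rounded intermediates, so the package treats agreement
within ±0.03 as reproduction and does not chase the last digit.

`simulate_power` draws reps pairs of Normal samples (unit SD, mean
separation d), applies the chosen two-sided test (pooled t by default;
Mann–Whitney with its exact null as an alternative) and reports the
rejection fraction with its binomial Monte-Carlo SE. For the t-test the
noncentral-t closed form (noncentrality d·√(n₁n₂/(n₁+n₂))) is the
analytic cross-check; the simulation matches it within 3 MC SEs across
d ∈ {0, 0.5, 1, 1.5, 2} in the test suite. The originally reported
simulated power column (e.g. 0.20 at d = 1.0 for 8 vs 7, where the
noncentral-t value is 0.43) cannot be reproduced by any of these
procedures; the generating procedure behind those numbers is not
recoverable from the description, so this package reports its own
simulation alongside the analytic value and asserts nothing against
that column.

## Classifiers and significance

Both classifiers are implemented in-package; scikit-learn and xgboost
appear only as independent cross-checks in the tests.

* **Logistic regression** maximizes the Bernoulli log-likelihood minus
  (λ/2)‖slope‖² by IRLS/Newton (intercept unpenalized), converged when
  the coefficient step falls below 1e-8, capped at 100 iterations. With
  λ = 0 on separable data the optimum is at infinity; the fit returns
  flagged as non-converged and the LOO driver refits with λ = 1e-4.
* **Gradient boosting** starts from the base-rate log-odds; each of
  `rounds` (default 100) iterations fits a regression tree (default
  depth 1) to the loss gradient g_i = p_i − y_i with Hessian
  h_i = p_i(1−p_i), splitting by exact scan over midpoints of sorted
  unique feature values to maximize the gain
  G_L²/H_L + G_R²/H_R − G²/H, leaf values −ΣG/ΣH scaled by the
  learning rate (default 0.1). No split regularization beyond depth —
  at n ≈ 14 training points per fold the shrinkage dominates anyway.
* **Leave-one-out**: exactly n fits, fold i trained without patient i;
  a fold whose training set loses a whole class predicts the training
  majority and is flagged. The headline MAE is computed on hard labels
  at the 0.5 threshold, making MAE·n the integer misclassification
  count; the probability-based MAE is reported alongside.
* **Permutation significance**: the observed LOO MAE is compared with
  the MAEs of randomized datasets, re-running the *full* LOO loop per
  randomization (a conservative reading of "similar or better fit by
  chance" — scoring a single fit would understate the null variance).
  Label shuffling preserves the group sizes exactly; the aggressive
  scheme redraws each feature value uniformly on [min x, max x] with
  labels fixed. p = #{null MAE ≤ observed}/reps, a multiple of 1/reps;
  the closed inequality follows the definition "fraction of random
  data-sets with a similar or lower MAE". An add-one variant
  ((r+1)/(R+1)) is available behind a flag for users who want to avoid
  p = 0. Default reps = 10,000 (the study's value); the pipeline default
  is 1,000 with the logistic classifier to keep interactive runs fast,
  and both are configurable.

## Risk-score matching

Matching is on a single dimension (EuroSCORE II), where an optimal
1:1 matching never crosses: if a < b are matched to d > c, swapping to
(a,c), (b,d) never increases |a−c| + |b−d|. The k-pair minimum-cost
matching is therefore computed exactly by dynamic programming over the
two score-sorted lists (states: prefix of list 1, prefix of list 2,
pairs used; O(n₁n₂k)), rather than by greedy nearest-neighbour, which
is order-dependent and suboptimal. Score ties are broken by patient id
for determinism. A caliper (maximum allowed pair distance) is optional
and off by default — no caliper width is published; infeasible calipers
raise an error reporting the largest feasible k.

## Pipeline determinism

One global seed drives everything. Each stage derives an independent
substream via SeedSequence(seed, crc32(stage name)), so adding a stage
never perturbs earlier stages' randomness, and reruns with the same
configuration are byte-identical (asserted on file checksums in the
tests).

## Problem sizes

The test suite and the acceptance script run at the study's own scale
(8 vs 7 patients) with simulation sizes chosen to make the Monte-Carlo
error a small fraction of each tolerance: 20,000 replicates for power
curves (MC SE ≤ 0.0035), 500 replicate cohorts for parameter recovery
(MC SE ≈ 0.017 on a group mean), 100 null cohorts × 200 randomizations
for permutation calibration, and 1,000–2,000 randomizations for single
permutation p-values.

## Known limitations

* No outlier-removal procedure is implemented: the original analysis
  excluded four patients using an unstated statistical-package rule that
  cannot be reproduced.
* Only complete six-point series are analysed; missing counts are
  rejected at I/O unless explicitly allowed, and downstream operations
  require the baseline count.
* The generator's independence-across-time assumption understates the
  within-patient correlation real trajectories likely have (see above);
  the optional patient-level intercept is a crude remedy, off by
  default.
* Patient-level findings of the original study (which individual cases
  are misclassified, the magnitude of individual rises) depend on the
  unpublished raw data and are outside what synthetic cohorts can
  reproduce; the package's guarantees are distributional.
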