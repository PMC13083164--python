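# Methods

## Data model

The unit of analysis is a patient; the unit of observation is one binary
recommendation by one rater on one task variant (optionally repeated).
Labels (1 = intervention performed), age and sex attach to the patient and
are repeated across rows of the interchange CSV
(`patient_id,model,task,replicate,prediction,label,age,sex`), cross-checked
on load. Task identifiers are free strings; the default grouping scheme
assigns the conventional nine tasks to three input-modality groups
(CAG {T1,T4,T7}, CTA {T2,T5,T8}, MULTI {T3,T6,T9}). Groups must be disjoint
and cover every task present. All patients must share the same
(rater, task, replicate) grid; `validate_dataset` reports violations rather
than raising, naming the invariant and the offending keys.

## Synthetic cohorts

The generator emulates the statistical structure the analysis depends on,
not any particular clinical narrative.

* **Outcome and covariates.** Labels are Bernoulli(prevalence); ages are
  normal truncated to a range by rejection sampling; sex is Bernoulli and
  purely descriptive. Defaults: 93 patients, prevalence 0.681, age
  66.63 ± 9.30 years on [35, 83], 67.7% male — the reference cohort summary.
* **Predictions.** A Gaussian latent-threshold (copula) construction: for
  each (patient, cluster, task) a shared standard-normal factor is mixed
  with an idiosyncratic factor at weights √r vs √(1−r), r ∈ [0, 1) the
  cluster correlation, and thresholded separately for positive and negative
  patients so the marginal sensitivity and specificity equal the configured
  per-(rater, task-group) values exactly in expectation. Se or Sp of 0 or 1
  clamp the threshold to ±∞ and yield deterministic raters, never an error.
  This is the simplest mechanism giving controllable marginals plus block
  correlation; it does not model any content-level behaviour of real raters.
* **Replicates.** Repeat queries equal the first answer with independent
  flips at a per-rater rate ε (default ≈ 0.05), giving within-rater
  reproducibility that Fleiss' κ can quantify. Tasks T4–T6 carry 3
  replicates in the default configuration.
* **Age effects.** `apply_age_effect` re-draws affected raters' predictions
  with the per-(rater, task, label) empirical match rate shifted on the
  logit scale by slope × (age − pivot). It provides ground truth for the
  heterogeneity analyses; slope 0 reproduces the original match rates.

What passing tests on these cohorts show: the estimators, selection loops
and error control behave correctly under a known generative law at the
study's sample sizes. What they cannot show: performance on real clinical
text, rater biases that correlate with unmodelled covariates, or
non-exchangeable replicate noise.

## Metrics and agreement

Confusion-matrix metrics use the standard definitions with an explicit
undefined marker (`None`) for 0/0 cells — a report renders a blank, never a
silent 0. F1 follows the 2TP/(2TP+FP+FN) convention (0 when positives exist
but none are predicted). ROC-AUC is the midrank statistic
P(s⁺ > s⁻) + ½P(tie); for a binary score this equals (Se + Sp)/2, which is
the convention used for single raters (their only score is the binary
recommendation), while ensembles are scored on the continuous vote.
Fleiss' κ uses the classical items × categories formula; unanimity gives
κ = 1 by construction. Rater similarity is Spearman ρ on flattened
(patient, task) vectors with average linkage on 1 − ρ; constant raters are
excluded from the clustering and their ρ entries are undefined.

## Ensemble construction

* The inner objective is F1 by default (configurable to accuracy).
* **Diversity term.** The "complementarity" of a candidate m to members S is
  div(m, S) = mean pairwise disagreement rate — chosen over 1 − ρ because it
  is well-defined for constant raters. F1 is min–max normalized across
  raters before being mixed with β so the two terms of
  J(m | S) = f1̂(m) + β·div(m, S) share scale.
* **Greedy addition** of 2 members to the F1 baseline (an exhaustive-pair
  mode is available via `SearchConfig(exhaustive=True)`); member sets
  proposed by each β are deduplicated, then τ is searched on the 15-value
  grid by inner-CV mean objective. Ties break toward smaller β, smaller τ,
  then lexicographic member names, so selection is bit-reproducible.
* The ensemble size is fixed at 3 (baseline + 2) by default and
  configurable. Advanced ensembles use equal member weights; the classical
  "weighted" benchmark uses training-F1 weights and the "confidence"
  benchmark uses replicate-consistency weights (fraction of
  replicate-unanimous cases; 1.0 for single-replicate raters — binary
  raters carry no native confidence, so reproducibility stands in for it).

## Nested evaluation

Folds are stratified on the patient-level label by an assignment that keeps
per-fold positive counts, negative counts and total sizes each within one
of each other; repeat r uses seed + r. All rows (tasks) of a patient move
together between train and test. Within each outer iteration, every
selection uses only outer-train rows; an audit log records the patient sets
and the test suite asserts their disjointness. Degenerate inner folds
(single-class validation) are skipped and logged; an outer test fold with a
single class yields an undefined AUC excluded from AUC aggregation only.

Aggregates are mean ± sd and percentile [2.5%, 97.5%] intervals over outer
iterations. Method comparisons: F1 by patient-level paired bootstrap
(cluster bootstrap over patients of the pooled outer-test rows, two-sided
Monte-Carlo p with plus-one correction), accuracy by McNemar on pooled
matched rows (exact binomial below 25 discordant pairs, else χ² with
continuity correction), each family Holm-adjusted across the method pairs.

## Calibration and decision curves

Platt scaling fits σ(a·s + b) by Newton steps on the cross-entropy with
Platt's smoothed targets t⁺ = (N⁺+1)/(N⁺+2), t⁻ = 1/(N⁻+2), which keeps the
optimum finite on separable data. Isotonic regression is the PAV solution
with clamped extrapolation. The family is chosen per outer iteration by
inner-CV mean Brier (ties → Platt as the smoother map), and the chosen
calibrator is fitted on outer-train scores only. ECE/MCE use 10 equal-width
bins with empty bins dropped. Net benefit uses positivity p ≥ t; treat-all
and treat-none reference curves are always attached.

## Age heterogeneity

The cut-point scan considers every integer age c with at least `min_n`
(default 10) patients on each side. ΔAUC = AUC(age < c) − AUC(age ≥ c);
bootstrap resampling is stratified by label within each subgroup so every
replicate keeps both classes. The two-sided Monte-Carlo p is
2·min(frac(Δ* ≤ 0), frac(Δ* ≥ 0)) floored at 1/(B+1); a zero raw exceedance
count is flagged (`below_floor`) so reports can render the conventional
"p < 1/(B+1)". Holm adjustment spans all scanned cut-points. Note that the
floor puts a hard lower bound of m/(B+1) on the smallest achievable Holm p
across m cut-points — B must be large enough (B = 1000 with ~30 cut-points)
for significance to be attainable at all.

The spline model places df + 1 knots at Harrell's quantiles
((0.05, 0.275, 0.50, 0.725, 0.95) for df = 4) and uses the truncated-power
restricted-cubic basis (linear beyond the boundary knots; verified
numerically to 1e-8). The reduced model is
logit P(y=1) = α + γ·score + spline(age); the full model adds
score × spline(age), so the LRT has df degrees of freedom. Fitting is IRLS
with a 1e-8 ridge and step-halving (log-likelihood non-decreasing across
iterations); a diverging coefficient norm is reported as a separation
error, never returned silently. Probability curves and the smallest score
reaching 50% predicted probability are reported at the 25th/50th/75th age
percentiles.

## Problem sizes and numerical choices

Defaults follow the reference design (outer 5 folds × 200 repeats, inner 3
folds, B = 1000 bootstrap replicates). The package's own desk-scale
defaults for examples, the acceptance script and the test suite are R = 20
repeats (R = 3–5 in the heaviest simulation loops) and B = 200–1000; all
aggregates are over outer iterations, so R scales precision, not validity.
Every source of randomness flows from a single seed through fixed
child-seed derivations, making every run — including the full pipeline and
its artifact hashes — bit-reproducible.

## Known limitations

* The generator's conditional-independence-given-cluster-factor structure
  cannot represent raters whose errors correlate only on specific patient
  subtypes.
* Single-rater ROC-AUC from a binary recommendation is (Se + Sp)/2 and is
  not comparable to AUCs of continuous scores; the reports keep the two
  conventions separate.
* The paired F1 bootstrap treats pooled outer-test rows of one patient as a
  resampling cluster; repeat-level resampling is not implemented.
* Decision-curve analysis is unweighted; interventions-avoided scaling and
  clustered variants are out of scope.
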