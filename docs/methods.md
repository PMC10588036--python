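# Methods

This note records the statistical model behind `mirisk`, the defaults and the
reasoning for them, what the synthetic cohort does and does not emulate, and
the numerical conventions a reader would need to reproduce any number the
package prints.

## The hazard-ratio-splitting survival tree

The method grows a binary CART on time-to-event data where the split
criterion is a Cox hazard-ratio test rather than an impurity measure. For a
node with subjects `S` and a candidate `(variable v, cutoff c)`, the
candidate's score is obtained by fitting the univariate Cox model

    λ(t | x) = λ0(t) · exp(β · 1[v > c])

within `S` and taking the Wald statistic `χ² = (β̂/SE)²`. Candidate cutoffs
are midpoints between consecutive distinct observed values of `v`
(exhaustive for ≤ 50 distinct values, otherwise thinned to 50 evenly spaced
quantile positions of that midpoint list; a binary variable contributes
exactly one candidate). A candidate is admissible if both children meet the
minimum size and minimum event count.

**Why the Wald statistic and not the raw hazard ratio.** Maximising |HR|
degenerates: the most extreme hazard ratios come from the smallest admissible
child nodes, where the estimate is noise. The Wald statistic is the natural
test of the same quantity — monotone in |log HR| at fixed precision — and is
what "splitting on hazard ratios" means once candidates of different sizes
compete. Likelihood-ratio and logrank-score variants are available
(`TreeParams.statistic`); all three agree asymptotically.

**Stopping rule and multiplicity.** The winning candidate is accepted only if
its p-value, Bonferroni-adjusted for the number of admissible candidates
examined at the node, is below `alpha_split`. The adjustment is what makes
`alpha_split` a real per-node error rate: a node of a few hundred subjects
examines hundreds of correlated Wald tests, and the unadjusted minimum
p-value is almost surely significant even under the null. With the
adjustment, a pure-noise cohort yields a root-only tree in ≈ (1 − α) of
simulations (Bonferroni is conservative under the strong correlation of
neighbouring cutoffs, so the realised rate is slightly above 1 − α). Growth
also stops on `max_depth` and on the child-size minima; there is no
cost-complexity pruning — stopping *is* the regularisation.

**Defaults.** `max_depth = 3` (at most eight terminal nodes, the scale of
subphenotype analyses in cohorts of ~600), `min_node_n = 30`,
`min_node_events = 10` (a Cox fit on fewer events is not meaningful),
`alpha_split = 0.05`, Bonferroni multiplicity, 50 candidate cutoffs per
variable. All configurable.

**Conventions.** Values `≤ cutoff` go left, including the boundary. Ties in
the split statistic break by smaller p, then variable name, then smaller
cutoff, so the fitted tree is invariant to row order. Subjects missing the
chosen split variable are excluded from that node's children and are
unassignable at prediction time (no surrogate splits); the condition is
reported, not silently absorbed.

**Bagging.** `bagging_select` draws B bootstrap resamples (size n, with
replacement), grows one tree per resample, and records which variables appear
in any split. Selection frequency over resamples screens variables (retention
threshold 0.5 by default). Error measurement is honest in the out-of-bag
sense: subjects absent from a resample are routed through that resample's
tree, given its ordinal node risk (node rank by training incidence rate), and
scored by the integrated cumulative/dynamic AUC; the report carries the mean
± SD over iterations. B defaults to 1000 in the CLI; the analysis drivers use
B = 200 and the end-to-end tests B = 50, which is enough for frequencies to
stabilise to ± 0.05.

## Node and tree risk metrics

Incidence rates are events per 100 patient-years of observed follow-up,
`IR_i = 100 · d_i / Σ t_ij`. Node hazard ratios come from a single Cox fit on
terminal-node indicators with the lowest-IR node as reference; a node with
zero events keeps IR = 0 and is flagged non-estimable rather than forced into
the fit. The dispersion of the stratification is the incidence-rate variation
index

    IRV = (1/N) · Σ_i n_i · |IR_i − IR|,

where IR is the *pooled* population rate (total events over total
person-years, not the n-weighted mean of node rates). IRV is zero exactly
when every node shares the population rate, and it grows as risk concentrates.

Discrimination of a marker (for trees: the ordinal node risk, ranked by IR)
uses the cumulative/dynamic AUC: at horizon t, cases are subjects with an
event by t and controls those event-free beyond t. Censoring is handled by
inverse-probability-of-censoring weights from the Kaplan–Meier of the
censoring distribution: cases weighted 1/G(T_i−), controls 1/G(t); tied
marker values count one half. A naive unweighted mode exists for cross-checks
(the two coincide without censoring, and the IPCW estimator matches
scikit-survival's `cumulative_dynamic_auc` exactly). The integrated AUC
averages AUC(t) over the event-time grid in a window — 0.25 to 5 years by
default, reading "3 months" as exactly 0.25 y — with weights proportional to
the Kaplan–Meier event mass at each grid point (a uniform/trapezoid mode is
available); the weights sum to 1, so the iAUC always lies between the minimum
and maximum AUC(t). Confidence intervals are percentile bootstrap over
subjects. Risk bands map node HRs onto {low, intermediate, high, very high}
at edges 2/5/10, chosen to mirror the published grouping pattern of node HRs
(reference node always low).

Whether the ordinal marker should rank nodes by IR or by HR is not fixed by
the method; IR is the default because it is defined for every node (including
zero-event ones) and identical in ordering to the HR whenever both exist.

## Cox engine

`fit_cox` maximises the Efron-tie-corrected partial likelihood by
Newton–Raphson with step-halving (the log partial likelihood never decreases
across iterations), stopping at score infinity-norm < 1e-8. Covariates are
centred for numerical stability; collinear or constant covariates raise an
error naming the offending pair; monotone-likelihood separation is flagged as
non-convergence with a diagnostic rather than raised, because in split
scoring it simply marks a candidate inadmissible. Efron is the default tie
correction (and coincides with Breslow when event times are unique — a test
asserts agreement with lifelines to 1e-6). The tree's inner loop uses a
specialised single-binary-covariate path in which the Efron denominators
reduce to `a + e^β b` with β-independent coefficient arrays, making one fit a
handful of vectorised operations over event times.

Absolute risk at a horizon uses Breslow's baseline cumulative hazard,
`P(event ≤ t | x) = 1 − exp(−H0(t) e^{x'β})`. Harrell's c-index counts
concordant usable pairs (event subject vs longer-surviving comparator;
score ties 0.5; censored-censored pairs excluded) and is computed by direct
pair enumeration, cross-checked in tests against lifelines.

## Incremental value of a marker

The nested clinical models are: model 1 — treatment arm, age, sex; model 2 —
model 1 + SBP < 120 mmHg, diabetes, diuretic, cardiac device, 6-min walk
distance, atrial fibrillation; model 3 — model 2 + log NT-proBNP. Marker
hazard ratios are reported per one log-unit of the marker (a per-SD option
exists; the choice of increment is a genuine ambiguity in this literature, so
both are first-class). Within-arm fits drop the then-constant arm indicator.

Reclassification at a horizon (2 years by default) uses IPCW estimators on
the complete cases of the augmented covariate set, with predicted event
probabilities from each model's Breslow baseline: the continuous NRI is the
weighted fraction of cases whose predicted risk rises minus falls, plus the
same with signs flipped for controls (range [−2, 2]); the IDI is the change
in discrimination slope (mean case risk minus mean control risk). Identical
models give exactly zero, and swapping base and augmented flips both signs.
Confidence intervals and p-values come from subject-level bootstrap with both
models refitted per replicate — the package's resampling choice standing in
for perturbation schemes used elsewhere; 300 replicates by default, seed
mandatory. Null simulations show ≈ 95% (slightly conservative) coverage of
zero for both indexes.

## The synthetic cohort

The generator emulates a SERVE-HF-like miRNA substudy so that the whole
pipeline is exercisable and *checkable* without the original data, which are
not publicly deposited. Covariate marginals follow the published baseline
table (age 69.5 ± 9.8 y truncated at ±4 SD, male 89.8%, ASV arm 50.8%,
diabetes 41.7%, diuretic 86.7%, atrial fibrillation 30.7%, cardiac device
53.3%, 6-min walk 329 ± 125 m floored at 0, NT-proBNP lognormal with
log-mean 7.24 / log-SD 1.20 matching the printed median and quartiles,
miRNA levels lognormal in relative units with median 1.5). The negative rank
correlation between the miRNA and NT-proBNP (target −0.167) is induced by
Iman–Conover-style reordering — Gaussian scores correlated at
`2 sin(πρ/6)` decide a permutation of the miRNA column — which preserves the
marginal exactly.

Survival is piecewise-exponential on a planted three-level tree: low
NT-proBNP refined by the miRNA level (hazards 0.055/0.13 per year), middle
band refined by walk distance (0.20/0.35), high band refined by low SBP
(0.50/0.80). Censoring is administrative (uniform on 0.5–5.5 y) plus
exponential dropout at 0.02/y. Under these conditions the expected event
fraction is ≈ 51–53% and node incidence rates span ~5.5–80 per 100
patient-years. Child seeds for covariates, reordering, event times and
censoring are spawned from one global seed at fixed offsets, so partial
re-runs are reproducible.

A two-level benchmark (`recovery_benchmark_*`, hazard ratios ≈ 4 per split,
three decoy covariates) serves structure-recovery experiments, and a
no-signal configuration (`null_*`) serves calibration experiments. The
screening-matrix generator plants a 1.5-fold down-regulation on a lognormal
background with log-SD 0.30 — typical RT-qPCR replicate variability — under
which the fold-change/p screen detects a planted transcript in ~85% of runs.

**What the generator does not emulate:** covariate-dependent censoring,
missing data, measurement error in the miRNA assay, non-proportional or
time-varying hazards, and any within-node heterogeneity — each terminal node
is exactly exponential. Passing recovery tests therefore demonstrates that
the estimators find structure that is truly there under clean conditions; it
does not certify behaviour under model misspecification, and real-data
hazard-ratio spreads will generally be flatter than planted ones.

## Other conventions and choices

* "Log-transformed" is the natural logarithm throughout (ln NT-proBNP ≈ 7.2
  at the observed median ≈ 1400 pg/mL, which makes the clinically used
  cutoff of 6 log-units ≈ 403 pg/mL sensible).
* Screening fold change is the ratio of arithmetic group means on the linear
  scale, reported as larger/smaller with direction stored separately; a
  geometric-mean mode (`scale="log"`) is provided because the original scale
  convention is ambiguous. Pass rule: FC ≥ 1.25 **and** p < 0.1, boundaries
  as written. No multiplicity correction at screening — the p < 0.1 threshold
  is a discovery filter, not an inference.
* Median split: subjects ≤ the sample median (type-7 quantiles, the R
  default) are "low"; ties at the median go low; an all-identical column is
  an error.
* Fisher's exact test is two-sided by the minimum-likelihood rule;
  Wilcoxon uses exact enumeration when the pooled tie-free sample has ≤ 20
  observations and the tie/continuity-corrected normal approximation
  otherwise. Both delegate to scipy, whose conventions match these.
* Baseline tables drop missing values per variable and report per-variable N;
  variables with no observations in a group are skipped.
* All stochastic routines take explicit seeds; pipeline artifacts contain no
  timestamps, so a rerun under the same config and seed is byte-identical.

## Problem sizes used by the test and acceptance suites

Simulation-based checks run at sizes chosen to keep the whole suite in the
minutes range on one CPU while leaving comfortable statistical margins:
structure recovery at n = 600 over 100 seeds; node-HR recovery on three
n = 2000 cohorts with log-HR estimates averaged across them (the lowest-risk
reference node contributes ~30 events per cohort, so a single draw has ~20%
Monte-Carlo noise on the HR scale; averaging three keeps the check sharp
without weakening the 25% tolerance); null calibration of the tree over 100
seeds at n = 400; cNRI/IDI null coverage over 60–100 seeds at n = 600 with
80–100 bootstrap replicates; end-to-end runs at n = 587 with B = 50 bags.

## Known limitations

* Cutoff estimates in CART-type splits converge slowly (cube-root rate);
  reported cutoffs should be read as regions, not points.
* The Bonferroni stopping rule is conservative; with many weakly informative
  variables it will under-split relative to an oracle.
* cNRI/IDI bootstrap CIs are mildly conservative under the null and, like all
  reclassification indexes, say nothing about calibration.
* The bagging report aggregates variable usage, not predictions; it is a
  selection and error-estimation device, not a random forest.
* No competing-risks handling (the composite endpoint is treated as a single
  event type) and no time-varying covariates.
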