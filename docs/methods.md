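# Methods

This note documents the statistical procedures `immunosig` implements, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about real data.

## Data model

A cytokine panel is a subjects × features table of plasma concentrations
(pg/mL), one feature per (cytokine, time point) pair named `NAME_Tk`
(e.g. `IL-17_T1`). The canonical study layout is 16 cytokines × 3 exercise
time points (rest, peak effort, 4 h post exercise) = 48 features; other
panel shapes are accepted, but the study workflow asserts 16×3. Missing
assay values are carried as an explicit mask (NaN) until imputation —
never as sentinel numbers — so provenance survives preprocessing. Feature
ordering is fixed (cytokine-major, T0 < T1 < T2), making every downstream
matrix deterministic across reads of the same file.

## Assay calibration

Each cytokine's standard curve is a least-squares polynomial of known
concentration on powers of measured signal, Y_p = b₀ + b₁X + … + b_kX^k,
degree k = 2 by default. Requirements: at least k+1 distinct signal
values; an all-identical signal design raises (singular). Negative
predicted concentrations are clipped to 0 and flagged rather than
propagated, keeping the later log2 transform definable while preserving
the information that the reading was out of range; signals outside the
standards' range are flagged as extrapolated. A fitted curve whose
derivative changes sign inside the standard range is usable but triggers a
curve-quality warning, since a non-monotone calibration cannot be
inverted unambiguously. Detection limits are optional per-cytokine bounds
(values outside become missing); no default limits are shipped because
they are assay-specific. Assay repeatability is summarised as the
coefficient of variability, sample SD (n−1) over mean, per replicate set
and averaged.

## Preprocessing

The chain is impute → log2 → per-feature z-score.

* **Imputation** replaces missing cells with a small positive constant,
  0.0001 by default. The stage is configurable: `before_log` (default)
  imputes on the concentration scale, so a missing cell becomes
  log2(0.0001) ≈ −13.29 — an extreme but finite value that keeps every
  profile usable; `after_log` inserts the constant directly into the log2
  matrix. The original description lists imputation among the regression
  preparations without fixing the order; both readings are supported and
  tested.
* **z-scoring** uses the sample (n−1) standard deviation; this is a
  documented package-wide constant, tested explicitly and configurable via
  `ddof`. Standardization is idempotent to 1e-10.
* **Fitting scope.** By default the preprocessor is fitted once on the
  full cohort before cross-validation, matching the one-shot preprocessing
  of the original workflow; a leakage-free mode (`leakage_free=True` in the
  run config) refits the statistics inside each LOOCV training fold.
  Reported cross-validation rates are mildly optimistic in the default
  mode — that is a property of the replicated procedure, not a bug.

## Univariate comparisons

Per feature, two tests as in the replicated workflow: a two-sample t test
on log2 concentrations (pooled-variance/Student by default — the classical
reading of a "standard" t test — with Welch behind a flag) and a Wilcoxon
rank-sum test on the raw values as a distribution-free confirmation. The
rank-sum p is exact when the pooled sample is ≤ 20 without ties, otherwise
the normal approximation with midrank tie correction and continuity
correction. A one-way ANOVA (between/within mean squares, (g−1, N−g) df)
covers multi-group cohort descriptors. No multiplicity adjustment is
applied in the replication tables, mirroring the original reporting; a
Benjamini–Hochberg column is emitted for reuse but never drives the
workflow. Comparison tables use complete observations per feature (the
imputation constant would otherwise dominate raw-scale means).

## Discriminant models

Two-class Gaussian/Fisher LDA. Coefficients B = S⁻¹(m_J − m_I) with S the
pooled within-group covariance (denominator n − 2); the intercept absorbs
the midpoint and the log prior ratio. The decision rule is strict: group J
(always the second-listed group — female, GWI or CFS) is assigned when the
score is ≥ 0, so an exact-zero score goes to J. Design choices:

* **Priors** default to equal — the stratified group sizes are of
  comparable order and the source software's setting is unrecoverable —
  with proportional priors available; the run config records which is used.
* **Covariance modes**: `pooled_full` (classical) and `diagonal`, which
  zeroes off-diagonal covariance. The diagonal mode is the stabilising
  correction used throughout the ensemble procedure, where deliberately
  co-expressed markers would otherwise inflate coefficient variance.
* **Singular covariance** in pooled mode raises with instructions (use
  diagonal mode or a ridge); an opt-in relative ridge ε·trace(S)/p·I is
  available rather than silently regularising.
* **Singleton classes** are tolerated at fit time (their scatter
  contribution is zero; the pooled denominator still needs n ≥ 3), which
  is what makes leave-one-out feasible at very small strata.
* **Standardized canonical coefficients**: B is rescaled to unit pooled
  within-group variance of the discriminant score, then multiplied
  per-feature by the pooled within-group SD. A single-marker model
  therefore always reports ±1.00, and magnitudes are comparable across
  features; the sign convention points positive coefficients toward
  group J.

Performance is always reported from LOOCV: each subject is assigned by a
model refitted without that subject, counts are tallied into a 2×2 matrix
(rows true group, columns assigned group, negative class first), and the
five rates follow the published definitions — accuracy (TP+TN)/N,
sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP), NPV
TN/(TN+FN). Zero-denominator metrics are flagged undefined, not raised.
Table output rounds half-up to 2 decimals. Inside LOOCV the selected
feature set is held fixed and only coefficients are refitted per fold
(the most direct reading of "models constructed in the absence of that
subject's profile"); a full per-fold reselection mode exists for
sensitivity analysis. A fast vectorised LOOCV path for the
diagonal/equal-priors model (leave-one-out mean and scatter updates) is
algebraically identical to the generic fold loop — exact agreement is
enforced by test — and is what makes 500-draw ensembles cheap.

## Stepwise partial-F selection

The classical stepwise-discriminant/regression equivalence: a ±1 group
indicator is regressed on the current feature set by OLS, and a
candidate's partial F is the residual-sum-of-squares drop on entry scaled
by the full-model residual mean square, F(1, n − s − 2). At the empty
model this reduces exactly to the squared pooled t statistic (enforced to
1e-10 in tests). Entry: smallest p below `p_enter` = 0.05, ties broken by
larger F then feature order; after each entry, any included feature whose
revised p exceeds `p_remove` = 0.10 is removed, largest p first, until
stable. `p_enter ≤ p_remove` is enforced (prevents enter/remove cycling)
plus a `max_steps` guard; every decision's (F, p) is recorded in a replayable
trace. An empty final set is a valid outcome rendered as "NA — no model",
as the original tables print for contrasts where no marker qualifies. A
Wilks-lambda formulation was considered and not implemented; the OLS
partial-F route is the classical equivalent for two groups.

## Random-subset ensemble ranking

Per iteration, `subset_size` = 5 features are drawn uniformly without
replacement from the 48 candidates (duplicate subsets across the 500
iterations are allowed — the procedure is a random search, not an
enumeration); each subset is fitted as a diagonal-covariance discriminant
and scored by LOOCV accuracy; members of subsets reaching the 0.80
threshold earn a count. Features are ranked by count with deterministic
tie-breaking (feature order). Selection frequencies are reported over
passing models (with an all-models diagnostic count as well). An
`exhaustive` mode evaluates every subset once (feasible ≤ 20 features) and
serves as the enumeration oracle for the randomised mode. With no passing
model the ranking is all-zero and a warning is raised. All randomness
flows from one integer seed.

A practical note on stability: when the planted signal is strong enough
that essentially every subset containing an informative feature passes,
the *uninformative* features' counts become exchangeable, so rank
correlations of raw counts across seeds are weak even though the top of
the ranking — the part that matters — is stable. Reproducibility is
therefore specified as: identical seed ⇒ identical output; different
seeds ⇒ identical top-feature identification and strongly correlated
count profiles.

## Synthetic cohorts

The generator draws each subject's 48-vector from a multivariate normal
on the log2 scale — mean = baseline + stratum effect, covariance D·R·D —
and exponentiates base 2, giving log-normal concentrations; missingness is
completely at random (no mechanism is documented for the real assay). The
correlation recipe is separable: r_time within a cytokine across time
points, r_cytokine across cytokines within a time point (Kronecker
product, PSD by construction), plus named strong co-expression pairs
applied block-consistently across the two cytokines' time blocks (a single
off-diagonal override of r = 0.81 would break positive semidefiniteness at
the default base correlations; the block-consistent form keeps a minimum
eigenvalue ≈ 0.095, and the matrix is re-verified PSD at generation time
regardless).

`study_template()` fixes the stratum sizes to the real cohort's
(male HC/GWI/CFS = 21/20/12, female = 9/10/10; 82 subjects), baseline
log2 levels spanning ~2–32 pg/mL, unit log2 SDs, 2% missingness, and a
*synthetic* plausible effect pattern (elevated IL-23/IL-12p70 in females;
IL-13/IL-10 shifts in male GWI; IL-2/IL-23 in male CFS; IL-5/IL-17/IL-23
in female GWI; IL-17/IL-10 in female CFS) of roughly one within-group SD.
These are testbed effects, not estimates from the study. The
planted-design helper `two_group_design` adds a redundant-marker option:
a copy of an informative feature plus noise chosen so the copy correlates
with its source at r ≈ 0.81 — the strongest co-expression the pipeline is
expected to handle.

What passing tests on these cohorts shows: the selection machinery
recovers planted signatures of the stated size at the study's sample
sizes, the tests hold their nominal levels under the generator's null, and
the full workflow runs end to end at study scale. What they do not show:
robustness to non-lognormal tails, assay batch effects, informative
missingness, or longitudinal autocorrelation beyond the block correlation
— none of which the generator emulates.

## Numerical and procedural details

* Rounding for table comparison is half-up (ties away from zero) to 2
  decimals via decimal arithmetic, so 0.865 → 0.87.
* Polynomial fits use numpy's least-squares polynomial machinery; t, F,
  rank-sum and BH computations delegate to scipy.
* Panel I/O parses numeric cells with exact float conversion, so a
  write/read round trip is bit-identical (pandas' fast parser can be off
  by one ulp).
* Problem sizes used by the test suite and acceptance script — 1,000-draw
  oracle comparisons, 20-seed ensemble and 100-seed stepwise recovery,
  1,000 null simulations, 200 label permutations, 2,000-subject moment
  checks — were chosen as the smallest sizes at which the Monte-Carlo
  tolerances quoted in the tests are meaningful.
* Null LOOCV accuracy has a small pessimistic bias (≈ −0.006 at
  n = 15/15): leaving a subject out shifts its own class mean away from
  it. The "centred on chance" checks use a ±0.025 band, which covers the
  bias plus Monte-Carlo noise without hiding real miscalibration.

## Known limitations

* Quadratic discriminants, >2-class problems, probability calibration and
  ROC analysis are out of scope, as are 4PL/5PL logistic calibration
  curves and plate-effect modelling.
* The stepwise procedure's p-value thresholds are selection heuristics;
  no inferential guarantee attaches to the final model's nominal p values
  (post-selection inference is not attempted, matching the replicated
  procedure).
* With 48 candidates at p_enter = 0.05, null data still admit occasional
  chance entries (~2–3 expected candidates at the first step across all
  features); "no model" outcomes on null data are common but not
  guaranteed — as in the original tables, where some contrasts produced
  models of modest cross-validated accuracy.
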