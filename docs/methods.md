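# Methods

## Surrogate mechanical power

The package computes the mechanical power of pressure-controlled
ventilation with the surrogate `MP = 0.098 · TV · RR · (PEEP + ΔP)`
(J/min), where ΔP is the inspiratory pressure above PEEP, so the pressure
term is the peak inspiratory pressure. The coefficient 0.098 converts
L·cmH2O/min to J/min. The surrogate's common citation sometimes typesets
the pressure factors without an operator; the additive reading is the one
consistent with the surrogate's derivation and with plausible magnitudes
(typical adult settings give ~15–30 J/min, versus >100 J/min under a
literal product). The product variant is retained behind
`mechanical_power(..., pressure_mode="product")` strictly for audit.

The full elastic-power decomposition (resistive and elastic terms, I:E
dependence) is out of scope; the surrogate is the modeled quantity.

## Time-weighted averaging

Ventilator settings are step signals: a recorded value holds until the
next record. `twa()` therefore integrates sample-and-hold over the window
`[0, W)` and divides by the covered duration; trapezoidal weighting was
rejected because it would smear discrete setting changes. The last sample
before the window end is held to the boundary; if the first sample arrives
after t=0 the average covers only the observed span. Windows are anchored
at the start of mechanical ventilation (the series' t=0); a user whose
series is anchored at ICU admission can shift `t_min` before calling.

MP is computed per time point and then averaged. The TWA of MP is **not**
the MP of the TWAs of its inputs — the product of averages is not the
average of products — and the pipeline never computes the latter. The 48 h
MP variability feature (`sd48_mp`) is the plain (time-unweighted) standard
deviation of per-time-point MP within 48 h.

## Ideal body weight

The Devine formula (male `50 + 0.91·(h − 152.4)`, female intercept 45.5)
was chosen because it reproduces the height↔IBW correspondence of the
reference adult-ICU population exactly (175 cm ↔ 70.57 kg; 165 ↔ 61.47;
185 ↔ 79.67). Values are kept at full precision internally and rounded to
2 decimals only at reporting time.

## Hypoxemia stratification

Strata come from the PaO2/FiO2 ratio (PFR) over the first six hours of
ventilation, summarized by default as the time-weighted mean (a
worst-value option is exposed via `method="worst"`). Boundaries: > 300
nonhypoxemic; [200, 300] mild; [100, 200) moderate; < 100 severe. The
mild stratum is upper-inclusive so the printed integer ranges "200–300"
and "100–199" tile the line without overlap. Admissions lacking any
PaO2/FiO2 pair in the window are flagged unclassifiable rather than
guessed.

## Preprocessing

Inclusion: age ≥ 18 y, ≥ 48 h of ventilation, known ICU outcome; each
exclusion is tallied under the first rule that fires, giving a flow-chart
style table. Plausibility cleaning removes exact duplicate samples and
values outside per-variable bounds (defaults: TV 0.05–1.5 L, RR 4–60,
PEEP 0–30, ΔP 1–60 cmH2O, pH 6.5–7.9, PaO2 20–600 mmHg, FiO2 0.21–1.0);
the rule is part of the design, the numeric bounds are package defaults
and fully configurable. Missing values are imputed with a k-nearest-
neighbor imputer (k = 7 by default) over z-scored features, features
missing in more than 10% of rows are dropped and reported, observed cells
are never altered, and a column-mean fallback (flagged) covers tables with
fewer than k complete rows.

## Safe upper limits

Per stratum, variable (MP, MP/IBW) and window (24 h, 48 h), a one-sided
Mann–Whitney test of "nonsurvivors stochastically greater" gates the
threshold: if p < α (default 0.05), the limit is the survivors'
(1−α)·100th percentile. The percentile uses linear interpolation between
order statistics (numpy's default), exposed as the reporting convention.
The "(1−α) percentile" reading is the order-consistent one — the limit
sits in the upper tail of the survivor exposure distribution, of the same
magnitude as published per-kg thresholds (0.22–0.34 J/min/kg against
survivor medians of 0.2–0.4); the α·100th-percentile alternative would
place "limits" below nearly all observed exposures. For arms of ≤ 8
observations the p-value is computed by exact enumeration of all label
arrangements, tie-aware (each tied pair contributes ½ to U); larger arms
use the normal approximation with tie correction. A stratum that fails
the gate returns no limit — an expected outcome for severe hypoxemia,
where mortality is dominated by the underlying disease.

With linear interpolation the limit commutes with monotone transforms of
both arms only when the percentile lands exactly on an order statistic;
this matters for property tests, not for practice.

## Survival stratification

Cox proportional-hazards fits compare above- vs below-limit groups per
stratum, with the covariate list taken as explicit configuration (the
noncollinear-significant-covariate selection is dataset-bound and cannot
be hard-coded). Follow-up is administratively censored at 90 days, and
Kaplan–Meier curves per group accompany each fit. Degenerate designs
(single group, no events) are flagged, not fitted.

## Mortality prediction

Seven ventilation features are mandatory (MP, MP/IBW, TV per kg IBW,
48 h SD of MP, PEEP, RR, ΔP). Candidate covariates are pruned greedily in
column order when |Pearson r| > 0.9 (mandatory features always win a
clash; constant columns are dropped as undefined), then the top 10 by
impurity-based random-forest importance (fixed seed; permutation
importance available) are added. Class balance is restored inside each
training fold only, by SMOTE-style interpolation between a minority row
and one of its five nearest minority neighbors; test folds are never
touched, and metrics (accuracy, precision, recall, AUROC) are computed on
the original test folds — the leak-free choice where the alternative is
ambiguous. All six models run at library defaults, deliberately untuned.
The boosted-trees model is the configured default for downstream use (a
runtime-economy choice, not re-derived from metrics), and its TreeSHAP
contributions (exactly additive per row up to float32 roundoff) provide
the importance ranking; non-tree models fall back to permutation
importance, flagged.

## Individualization

The closed loop freezes the fitted mortality model and, for each patient
it predicts to die, searches a candidate grid: TV 4–8 mL/kg IBW in 0.5
steps, RR 10–35 /min in steps of 1, ΔP = TV / C with C the median of
recent TV/ΔP pairs, PEEP held fixed (its titration is a separate
workflow). Candidates outside the ΔP (5–25 cmH2O) or VE (2–20 L/min)
safety envelopes are infeasible. Respiratory acidosis (PaCO2 > 45 mmHg
AND pH < 7.35 — the stricter of the two published cues, configurable)
switches the objective to maximizing minute ventilation; otherwise MP is
minimized. The search preserves the active objective: acidotic candidates
may not drop VE below the initial value minus 5% (configurable), and
non-acidotic candidates may not exceed the initial MP. Because candidates
are visited in objective order, the first one the model flips to survival
is the optimum over the feasible grid; if none flips, the settings are
left unchanged. "Flip" means predicted death probability falls below the
0.5 cut (configurable). Non-ventilation covariates are frozen during the
search. The case-study summary reports the flip percentage to one
decimal.

## Synthetic cohort generator

The generator emulates the post-extraction analysis table, not the source
database schema. Defaults are the study conditions: stratum mix
(26.3 / 31.5 / 35.9 / 6.3%), 2:1 male ratio, heights ~N(175, 10²) clipped
to 150–200 cm, per-admission compliance ~N(35, 10²) mL/cmH2O, ventilation
settings piecewise-constant with Poisson setting changes (mean one per
12 h), TV = C·ΔP clipped to 0.2–0.9 L, per-stratum PFR/FiO2/PEEP bands
that make severity and support co-vary, and labs with lognormal/normal
marginals on adult-ICU scales. Death is Bernoulli with logit
`−4.56 + 1.4·(MP/IBW)₄₈ + 0.035·age + 0.1526·lactate` — slopes matched to
published effect sizes (1.4 ≈ 70.57·ln 1.02; 0.1526 = ln 1.165; 0.035/yr
spans the published young-to->80 odds gradient), baseline centring
marginal mortality near 29%. The latent uniform draw per admission is
stored so that threshold-injection experiments (a log-odds jump above a
chosen MP/IBW level) re-realize outcomes deterministically against the
same randomness — a jump of zero is an exact identity.

What the generator does **not** emulate: inter-variable correlation
structure beyond the severity bands (the source data's covariance is
unpublished), informative missingness (MCAR only), waveform-level
dynamics, treatment feedback (settings do not respond to gases), and the
case-mix of a cardiothoracic-surgery-heavy ICU. Passing tests therefore
demonstrate procedural correctness and statistical calibration of the
pipeline, not transportability of any fitted model to real patients.

## Problem sizes and numerical choices

Monte-Carlo checks run at sizes chosen so the estimator noise is well
inside each property's tolerance: 2,000 null replicates at 200/arm for
type-I control of the limit gate (3 binomial SEs), 500 replicates at
~400/arm for gate power, 200 replicates at n=20,000 for odds-ratio CI
coverage, and n=2,000 with 5 folds for the permuted-label AUROC check —
the last because discrete-score classifiers (AdaBoost) produce null-AUROC
estimates with spread well above the rank-statistic bound at smaller n.
Percentiles interpolate linearly; rank tests switch from exact
enumeration to the tie-corrected normal approximation above 8 per arm;
odds-ratio CIs are Wald; complete separation is screened before fitting
and flagged instead of estimated.

## Known limitations

The generator's covariance choices are stated defaults, not inferences
from the restricted source data; dataset-bound published values (absolute
safe limits, hazard ratios, model AUROCs) are consequently not
reproduction targets — the pipeline reproduces the procedures and their
unit-conversion arithmetic. The individualizer is a retrospective what-if
engine: it has no bedside-safety logic and holds PEEP and all non-
ventilation covariates fixed during the search.
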