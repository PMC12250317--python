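# Methods

This note documents the models, numerical choices and known limitations
of `anthroagree`: what the equations compute, how the agreement battery
is defined, what the synthetic cohort generator does and does not
emulate, and where the design was genuinely open.

## Units and data model

All measurements live on one canonical unit system: skinfolds in mm,
circumferences/diameters/height in cm, masses in kg, ages in years.
Equations that were published with other units (the Lee RC pair and
Poortmans use height in metres; the De Rose bone-mass term uses metres
for height and diameters) convert *inside* the evaluator; profiles are
never stored in mixed units. Missing measurement sites are absent keys,
never zeros — a zero skinfold is a validation error, and an equation
that needs an absent site raises an error naming the site and the
requesting equation.

BMI is recomputed from weight and height by default. An input file may
carry an explicit `bmi` column that overrides the computed value, and
the provenance (given vs computed) is tracked: pooled descriptive
tables in the source literature report a mean BMI that is *not* the BMI
of the mean weight and height (24.6 vs 24.74 here), so a cohort-level
BMI can never be treated as derivable.

Subjects carry sex either as a category or as a male-fraction float in
[0, 1]. The float form exists for "mean subject" evaluations: equations
with a linear sex *term* code it as the mixed numeric value, and
equations with separate male/female *formulas* evaluate both branches
and mix them by the fraction. Equations never receive a silent default
sex.

Corrected girths (`c = girth − skinfold·π/10`) use π = 3.141 by
default, reproducing the printed arithmetic of the source compendium;
`EquationOptions(full_precision_pi=True)` switches to machine π. The
difference is below 0.01 cm for physiological folds.

## The equation compendium

Each equation is registered with its output variable (BD, FP, FM, LP,
LM), required skinfolds/circumferences/diameters/demographics, and its
own sex and race codings — the sources disagree (men are coded 1 in
Hastuti but 0 in Gómez-Ambrosi, and Minematsu codes men 1 / women 2),
so codings are per-equation metadata, never stored on the profile.
Race offsets are applied only where the source printed them; categories
the source did not mention fall back to a printed "others" offset when
one exists and otherwise raise. Two special cases: Evans prints only an
Afro-descendant offset against a white reference, so all other
categories take the reference value 0; the Lee RC equations print
offsets for Asians and African-Americans with whites/Hispanics as
reference and genuinely have no "others" class, so e.g. a Mexican
profile is rejected rather than silently coded.

The family counts mirror the comparison counts of a validation study on
this registry: 34 FP comparisons (8 BD equations × 2 converters + 18
direct equations), 6 FM, 3 LP, 13 LM. The two amputee-specific Cavedon
equations are registered but flagged as not exercisable without
axillary/chest folds, and are excluded from family counts by default.

### Printed-formula literalism

The compendium this registry transcribes contains several printed forms
that are dimensionally broken or internally degenerate. The policy is:
reproduce printed arithmetic wherever it is physically meaningful;
where it is nonphysical, implement the only physically consistent
reading and keep the literal form available behind
`EquationOptions(as_printed=True)` for audit. Concretely:

* **Kerr/ISAK adipose mass.** The printed form plugs the raw
  six-skinfold sum (mm) directly into the phantom adipose model and
  returns ~600 kg. The implementation standardizes the height-scaled
  sum into an adipose Z-score,
  `Z = (Σ6SK·(170.18/H) − 116.41)/34.79`, mirroring the muscle-mass
  formula's explicit Z-score, then applies
  `FM = (Z·5.85 + 25.6)/(170.18/H)³`. The constants are the phantom
  mean and SD of the height-scaled sum and are configurable.
* **De Rose bone mass.** Implemented as
  `3.02·((H/100)²·(WD/100)·(FD/100)·400)^0.712` (metres), which gives
  plausible bone masses (~10 kg); the printed `H²/100` variant is 100×
  larger inside the power and yields ~270 kg.
* **O'Connor.** The printed second term `0.0005·(TR+SI+TH)` is linear
  and therefore collapses into the first coefficient; it is implemented
  as printed, with a squared variant (`oconnor_squared=True`) provided
  because the degenerate pair is almost certainly a transcription
  artefact.
* **Heymsfield.** The printed leading coefficient 0.284 is the default;
  the widely published 0.0264 — which is also the only value consistent
  with plausible arm-muscle-area lean masses — is selectable via
  `heymsfield_coefficient`.
* **Slaughter (male).** The printed squared term uses the supraspinal
  fold, `(TR+SSP)²`, where the canonical equation uses `(TR+SS)²`;
  implemented as printed with `slaughter_ss_squared=True` for the
  conventional form.
* **Kulkarni.** The printed "log Σ4SK" is implemented as the natural
  logarithm: base-10 overestimates lean mass by ~11 kg at typical adult
  inputs, while ln reproduces the magnitudes the equations were
  published with. (The Lean skinfold equation explicitly prints
  `log10` and uses base-10.)
* **Doupe.** Implemented exactly as printed (height in cm). The printed
  coefficients are one to two orders of magnitude away from producing
  kg-scale lean masses under any height unit; since no downstream
  decision depends on Doupe, the literal form is kept and this caveat
  documented rather than guessing an unprintable correction.
* **Poortmans.** Printed with raw girths and no height unit; height
  enters in metres (the only reading that keeps the girth-squared term
  on a percent scale).

The Siri (`100·(4.95/BD − 4.5)`) and Brozek (`100·(4.57/BD − 4.142)`)
converters return percent on the 0–100 scale; body densities outside
(0.9, 1.2) trigger a warning but still convert. The two converters
cross at BD = 0.38/0.358 ≈ 1.0615 (FP ≈ 16.3 %): Siri reads higher in
fatter subjects, Brozek in leaner ones.

## The agreement battery

Sign convention: every difference is `reference − estimate`, so a
positive bias means the equation underestimates the reference. This is
stated in every exported manifest.

* **Normality gate.** Shapiro–Wilk at α = 0.05, applied per variable;
  a pair is treated as normal only if both the estimate and the
  reference vectors pass. The gate decision is recorded in each report
  row. Constant vectors are routed to the non-parametric branch with a
  warning.
* **Paired test.** Paired *t* on the normal branch (identical to a
  one-sample *t* on the differences — implemented once); Wilcoxon
  signed-rank otherwise, exact for n ≤ 25 without ties or zeros,
  asymptotic with continuity correction at the n ≈ 27 study scale.
  All-zero differences short-circuit to p = 1. Bonferroni families
  default to the registry sizes {FP: 34, FM: 6, LP: 3, LM: 13} and are
  overridable.
* **Bias.** `SED = SD_d/√n`; the CI of the mean difference uses the
  t quantile with n − 1 df. The Bland–Altman LoA use the conventional
  1.96 multiplier (not 2.0, not t-based) — the combination that
  reproduces reconstructed published LoA/CI pairs exactly.
* **RMA regression.** Slope `sign(r)·SD_y/SD_x` with the reference as
  the dependent variable; scale-equivariant and symmetric under axis
  exchange (slope → 1/slope).
* **ICC.** Two-way, single-measurement, McGraw–Wong definitions:
  consistency = ICC(C,1), absolute = ICC(A,1), computed from the ANOVA
  mean squares (between-subjects MS_R, between-methods MS_C, residual
  MS_E). CIs use the standard F construction; the absolute CI uses
  Satterthwaite degrees of freedom. Negative ICCs are returned as
  computed. One deliberate choice: the between-method
  variance-component estimate `(MS_C − MS_E)` is truncated at zero by
  default (variance components are non-negative in the population),
  which guarantees ICC(A,1) ≤ ICC(C,1) whenever ICC(C,1) ≥ 0; the raw
  untruncated formula — the one pingouin and R's irr report — is
  available via `truncate_method_variance=False`. Note the inequality
  genuinely reverses for negative ICCs (a published lean-percentage row
  with ICCa −0.27 and ICCc −0.35 is arithmetically correct): with a
  negative numerator, the larger absolute-agreement denominator pulls
  the coefficient toward zero.
* **Correlation bands** (on |r|): > 0.7 very strong, 0.4–0.7 strong,
  0.3–0.4 moderate, 0.2–0.3 weak, below none. **ICC bands**: ≤ 0 poor,
  then slight/fair/moderate/substantial at 0.2 steps, 0.81–1.00 almost
  perfect.
* **TEM** `= √(Σd²/2n)` over duplicate pairs, relative TEM as percent
  of the grand mean. **Fisher-z CI** for inter-rater ICCs:
  `tanh(atanh(r) ± z/√(n−3))`. **Paired sample size**: two-sided normal
  approximation, clamped at a minimum of 2; (Δ = 1, SD = 1.8,
  α = 0.05, power = 0.8) gives n = 26, the design premise of a 27-subject
  validation study.

## The synthetic cohort generator

The generator emulates the *statistical shape* of a small
amputee-athlete validation cohort, not any real subjects: n = 27 with a
22:5 male:female split and an amputation mix of 15 transtibial /
9 transfemoral / 3 hip-disarticulation (metadata only — measurements
are taken on the intact side, so the data model carries one value per
site).

Structure: a standard-normal *adiposity* factor and a correlated
(ρ = 0.3) *frame* factor. Skinfolds load 0.75 on adiposity and are
drawn log-normally (moment-matched per site, positive, right-skewed);
girths and body weight load 0.55/0.5 on frame/adiposity; height and
bone diameters load on frame only; age is independent and truncated at
18 by resampling. Sex offsets (women: thicker triceps/thigh folds,
smaller girths, shorter/lighter) are mean-centred across the sexes so
pooled moments stay on target. The per-variable pooled means/SDs
default to a published 27-athlete descriptive table; forearm and hip
circumference and the wrist/femur diameters are *not* in that table, so
their defaults (26 ± 2.5 cm, 98 ± 6 cm, 5.5 ± 0.35 cm, 9.4 ± 0.6 cm)
are synthetic stand-ins chosen as realistic adult values. Race defaults
to all-Hispanic; equations needing other offsets are exercised via
config.

The DXA-style reference is simulated as
`reference = equation(profile) + bias + N(0, noise_sd²)` for one
configurable anchor family (default: the Hastuti FP equation with bias
0.7 % and noise SD 4.55 %, the agreement level a validation study at
this scale reports), then the remaining compartments are filled
consistently (FM = FP·BW/100, LM = BW − FM − BMC, LP = LM/BW·100),
clipping only at physical impossibility. This makes the generator's
bias and noise *known ground truth* that the pipeline must recover —
the basis of the end-to-end calibration tests.

`fixture_cohort` additionally standardizes every targeted variable
affinely so the 27-subject sample means and (ddof = 1) SDs hit the
configured targets *exactly*, preserving the correlation structure
approximately; the reference variables are standardized the same way
and are then no longer an exact function of the anchor equation. Draws
that standardization would push out of physical range are rejected and
redrawn deterministically.

What passing tests do **not** show about real data: the generator's
correlation structure is a free choice (the source table reports no
covariances), real residual-limb asymmetries and sport-specific
physiques are not modelled, and the reference noise is homoscedastic
Gaussian whereas real DXA-vs-anthropometry differences are often
proportional to adiposity. Recovery results therefore validate the
*software chain*, not the field validity of any equation.

## Pipeline and recommendation labels

`run_validation` evaluates every registered equation of each requested
family on every subject, skipping (with a logged reason) equations the
cohort cannot satisfy — mirroring how a study skips equations whose
folds were never collected — and runs the full battery per equation.
Skip accounting is exact: reported + skipped = family registry size.

The `recommend` cascade is an explicit codification of an informal
published decision narrative, and is labelled as such: *recommended*
requires no significant Bonferroni-adjusted difference, |bias| within
the clinical limit ({FP: 1.0 %, FM: 1.0 kg, LM: 1.5 kg, LP: 1.0 %},
configurable — the LP limit is this package's own choice, parallel to
FP), and an almost-perfect absolute-agreement ICC;
*acceptable_with_caution* requires at least substantial ICCa and
|bias| ≤ 2× the limit; everything else is *not_recommended*. Every
fired rule is reported alongside the label.

Exports are tidy CSV/JSON per family plus per-equation Bland–Altman
pair files, the registry dump, and a manifest (config, seed, version,
sign convention) sufficient to reproduce a run bit-for-bit. Rendered
tables round to 2 decimals; underlying CSVs keep full precision.

## Problem sizes in tests

The Monte-Carlo suites use 500 Shapiro–Wilk draws, 2,000 replicates for
the paired-test type-I/power calibrations, 1,000 random samples for the
ICC ordering property, and 500 27-subject cohorts for end-to-end
bias/LoA recovery — sizes at which binomial/standard errors are small
enough to detect real miscalibration while the whole suite stays in the
tens of seconds on one CPU.
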