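# Methods

`dietval` implements the full computational chain of a dietary-assessment
validation study in pregnancy: aggregation of repeated 24 h recalls from two
self-report methods, diet-quality scoring against Swedish food-based dietary
guidelines, total energy expenditure (TEE) from doubly labelled water (DLW),
and the agreement/association statistics that compare them.  Because the
underlying per-participant study data are not openly available, a synthetic
cohort generator with stored ground truth stands in for the raw data; every
number the analysis scripts print is computed from generated inputs at run
time.

## Recall aggregation

A recall day is a list of (food code, grams) items.  Linking items to a
per-100 g food-composition table gives daily energy (kJ) and nutrient grams;
a food-group map (a food may belong to several groups) gives grams per day
for nine groups.  Energy shares (E%) use metabolisable-energy factors of
17 kJ/g for protein and carbohydrate (sucrose included) and 37 kJ/g for fat
and the fatty-acid classes; fibre carries no energy under this convention.
All factors are configuration, since national composition databases differ.

Daily energy is screened against 800 and 3500 kcal bounds (strict
inequalities, thresholds stored in kcal and compared after conversion at
4.184 kJ/kcal).  Flagged days are *retained* by default — in the emulated
protocol such days were manually checked and kept — with a switch to exclude
them.  Participant-level intake is the arithmetic field-wise mean over the
available days (2-3 in a conformant dataset); red + processed meat is
additionally expressed as 7 × the daily mean, in g/week.

Degenerate inputs: an empty day is a valid all-zero day flagged low; E% and
nutrient densities are missing (NaN), never a division by zero, when daily
energy is zero; an unknown food code is a hard error naming the code.

## Diet-quality score (SHEI)

Nine components — fruit & vegetables (g/day), wholegrain (g/10 MJ), fibre
(g/MJ), PUFA, MUFA, SFA (E%), fish & shellfish (g/day), red + processed meat
(g/week), added sugar (E%) — are each scored on [0, 1] and summed to [0, 9].
Scoring is continuous piecewise-linear: encouraged components ramp from 0 at
the lower reference to 1 at the upper; discouraged components are mirrored;
the unsaturated-fat shares score 1 inside a reference band and ramp to 0 at
outer bounds (defaults: PUFA band 5–10 E% with outer bounds 2.5/12.5; MUFA
10–20 E% with 5/25, i.e. outer bounds half a band-width out).

**The default cut-offs are working placeholders.**  The published index's
verbatim reference values are not reproduced here; the defaults (fruit & veg
0→500 g/day, wholegrain 0→75 g/10 MJ, fibre 2→3 g/MJ, fish 0→35 g/day,
meat 500→700 g/week reversed, added sugar 10→20 E% reversed, SFA 10→17 E%
reversed) encode the guideline targets and live entirely in configuration
(`shei.default_config()`, replaceable by YAML), so the published values can
be dropped in without code changes.  Two deliberate choices: the meat
component scores *combined* red + processed meat per week (the quantity the
validation tables report), and "added sugar" is backed by the sucrose E%
column by default — both switchable.

A missing component makes the total missing by default (an optional policy
rescales the remaining components to 0–9).  Monotonicity holds component-wise
except inside the two range-scored components, whose score by construction
falls beyond the upper band edge; the property tests therefore assert
monotonicity for the seven one-sided components and for PUFA below its band.

On simulated cohorts under the default calibration the mean total is ≈ 5.9,
at the lower edge of the emulated population's 6.6 ± 1.0 envelope.  Two
causes, both expected: the placeholder cut-offs are stricter than the
published ones for this population (saturated fat at ~16 E% scores near
zero under a 10→17 ramp), and the clipped concave ramps make the mean of
scores sit below the score of the mean intake (Jensen).  The envelope test
asserts the population band, not the point value.

## Doubly labelled water

Protocol emulated: weighed doses of 0.08 g ²H₂O and 0.15 g H₂¹⁸O per kg body
weight; two pre-dose urine samples and post-dose samples on days 1, 5, 8, 12
and 15.  The chain is the classic slope-intercept (multipoint) method:

1. **Elimination rates.**  Baseline (mean of the pre-dose samples) is
   subtracted; ordinary least squares of ln(excess) on time gives
   k = −slope (per day) and the zero-time excess exp(intercept).  Any
   non-positive excess is an error naming the sample.
2. **Dilution spaces.**  N = (dose g / MW) × dose enrichment / zero-time
   excess, with MW 18.02 (²H₂O as water equivalent) and 20.02 (H₂¹⁸O).
   Dose and sample enrichments must share one unit; the unit cancels in k
   and in N only under that condition, which is validated at load.  The
   ²H/¹⁸O space ratio is a QC quantity with default acceptance band
   [1.00, 1.07] around the physiological ≈1.035.
3. **CO₂ production.**  Two-pool equation
   rCO₂ = (N/2.078)·(1.007·k_O − 1.041·k_d) − 0.0246·(1.05·N·(1.007·k_O − 1.041·k_d)),
   with N = (N_d/1.041 + N_O/1.007)/2.  All coefficients (pool divisor,
   per-isotope fractionation multipliers, fractionated-water fraction and
   coefficient, 22.4 L/mol molar volume) are named configuration in
   `config.DLWConstants`.  A negative fractionation-weighted rate difference
   is an error (not NaN); exact cancellation yields zero production.
4. **Energy equivalent.**  Weir-derived (3.941/FQ + 1.106) kcal per litre
   CO₂, converted at 4.184 kJ/kcal; food quotient fixed at 0.86 by default
   (the emulated cohort's estimated diet FQ), restricted to [0.7, 1.0].
   TEE (kJ/day) = rCO₂ (L/day) × energy equivalent (kJ/L).

Noise-free simulated participants round-trip exactly (rates and pools to
≤0.1%, TEE to ≤0.5%; in practice machine precision), because the generator
inverts the same model — the round trip checks the chain's internal
consistency, not the model's truth.  Error propagation is steep: the TEE
numerator is the small difference 1.007·k_O − 1.041·k_d, so 1%
multiplicative enrichment noise on the five-point schedule yields a median
absolute TEE error of ≈4.5%, and 2% noise ≈9%.  The default measurement
noise is 1% (typical isotope-ratio mass-spectrometry precision relative to
the excess), and the noisy-recovery test runs at that default.  Plateau and
single-sample protocols, three-pool models and BMR partitioning are out of
scope.

## Method comparison

Differences are a − b, averages (a + b)/2.  Limits of agreement are the mean
difference ± **2 SD** exactly (not 1.96 SD), matching the convention of the
emulated study; SD uses the n−1 denominator.  Proportional bias is the OLS
regression of difference on average with Pearson r and two-sided p.  The
percentage mean difference is relative to the reference method's mean
(TEE when intake is compared against DLW) or to the pooled average,
per configuration.

Location tests are two-sided paired t or Wilcoxon signed ranks (zero
differences dropped, mid-ranks for ties, exact signed-rank distribution up
to n = 25 untied non-zero differences, normal approximation without
continuity correction above); correlations are Pearson or Spearman
(Pearson on mid-ranks).  Because the emulated analysis never states its
parametric/non-parametric criterion, the default rule is explicit:
Shapiro–Wilk on the differences at α = 0.05, overridable per variable, and
every reported statistic records which family produced it.  α = 0.05
throughout; no multiple-testing correction by default (a Bonferroni option
exists but is off, matching the emulated analysis).  All-zero differences
return p = 1 by convention; degenerate averages report the regression as
missing.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are pinned once to
the emulated cohort's printed summary statistics and are not tuned per run:

| parameter | default | basis |
|---|---|---|
| participants / isotope sub-sample | 52 / 24 | study design |
| TEE | Normal(10252, 1197) kJ/day | cohort TEE |
| body weight | Normal(67.1, 7.6) kg | cohort weight |
| intake bias vs TEE | −237/10252 ≈ −2.3% | observed mean difference |
| bias slope | 0.10 | induces the observed proportional bias |
| day-to-day CV of intake | 0.23 | typical within-person variation (no printed value exists; sensitivity parameter, not a claim) |
| per-method reporting error SD / shared correlation | 0.18 / 0.3 | chosen once so intake SD (~1900–2000 kJ) and between-method r (~0.8) land near the cohort's |
| food-group means/SDs | printed cohort means/SDs | see `default_food_groups()` |
| dilution-space ratio | Normal(1.035, 0.010) | cohort QC value |
| body-water fraction | 0.55 | early-pregnancy total body water |
| k_d | Normal(0.09, 0.008) /day | physiological water turnover |
| enrichment noise CV | 0.01 | IRMS precision |

Habitual intake is TEE·(1 + bias) + slope·(TEE − μ), so the expected cohort
mean difference equals bias·μ exactly while the slope term adds
level-dependent bias.  Both methods observe the *same* true days (the
telephone recalls covered the days registered in the web tool), so
between-method agreement is inflated by shared day-to-day variance as well
as by the explicit shared-error correlation.  One consequence worth noting:
even with bias slope 0, the difference-on-average regression slope is
positive, because the intake side carries more noise than TEE — the
well-known artefact of regressing differences on averages when variances
differ.  The calibration check therefore verifies that the slope is
*inducible and monotone* in the bias-slope parameter, not that it vanishes
at zero.

Food-group participant means are zero-truncated Gaussian (fruit &
vegetables) or moment-matched zero-inflated lognormal (episodic groups whose
SDs exceed their means: fish, nuts, both beverage classes, juice).  Group
grams decompose into 2-3 synthetic food codes with fixed per-participant
Dirichlet splits; four macronutrient staples are then solved in closed form
per day so the aggregated record reproduces the reported energy exactly and
the configured E% split (protein 15, fat 41, carbohydrate 44 incl. sucrose
9) exactly whenever group foods alone do not already exceed a target
(staple amounts are floored at zero, so targets can only be overshot, on
low-energy days with large group draws).  The composition table's energy
column is macro-consistent by construction (17p + 37f + 17c).

What the generator does **not** emulate: meal-level eating patterns,
seasonal or gestational-week trends, under-reporting that depends on food
type, participant-level heteroscedasticity of reporting error, or
correlation between food-group intake and total energy.  Passing tests
therefore demonstrate that the pipeline computes its statistics correctly
under realistic marginal distributions — not that any real instrument has a
particular accuracy.

All randomness flows from one seeded `numpy.random.default_rng` (PCG64);
equal seeds give byte-identical CSV bundles.

## Problem sizes

The shipped analysis uses the study-sized cohort (n = 52, isotope n = 24,
seed 1).  Property and recovery tests use 6–200 simulated participants,
oracle checks 20 random fixtures per statistic, coverage checks 500
replicate difference-cohorts of n = 52, and the calibration check 200
replicates of n = 24 — sizes at which Monte-Carlo error is well below every
asserted tolerance.

## Known limitations

- The SHEI cut-offs are placeholders pending the published index's exact
  values (see above); totals shift if they are replaced, the machinery does
  not.
- The DLW chain is validated against its own forward model and internal
  oracles; per-participant laboratory TEE values are not public, so no
  external numeric anchor exists beyond the cohort-level summary statistics.
- The Wilcoxon exact path requires untied non-zero differences; ties fall
  back to the normal approximation regardless of n.
- `aggregate_day` trusts the composition table after a single validation
  pass; energy/macronutrient inconsistency is a warning, not an error,
  because real composition databases include non-macronutrient energy.
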