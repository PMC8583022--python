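# Methods

## Study design emulated

The package implements a repeated cross-sectional cohort analysis over
eight three-yearly surveys (S1–S8). Dietary intake is measured once, at the
baseline survey S3, by an FFQ converted upstream to daily-equivalent
servings, grams, milligrams and percent-of-energy variables (the intake
table is this package's input boundary; FFQ item weights and nutrient
composition tables are out of scope). Diet quality is assumed stable over
follow-up, so the S3 exposure is held constant and used to predict outcomes
at S4–S8, one logistic model per outcome × survey × index × adjustment.

Eligibility mirrors a baseline-free-of-disease design: response at S3,
response at ≥ 1 survey of S4–S8, complete dietary data, and none of the
five enduring conditions (diabetes, coronary heart disease, hypertension,
asthma, non-skin cancer) reported at or before S3. A history of depression
and/or anxiety does **not** exclude. Exclusion counts are tallied
sequentially in that order for the flow diagram.

## Index scoring

### HEIFA-2013 (0–100, 11 components)

Core foods are scored in bands against guideline serving targets: zero
strictly below the minimum serving bound, the maximum at/above the target,
and the range between split into three equal bands worth ¼, ½ and ¾ of the
component maximum. This generalises the only fully printed band table
(discretionary foods: 10 / 7.5 / 5 / 2.5 / 0 points for < 2.5 / 2.5–3.4 /
3.5–4.4 / 4.5–5.4 / ≥ 5.5 servings) to every component; band edges are
closed on the side nearer the full score, matching that table. Bounds:
total grains 1–6, wholegrains 1–3, vegetables 1–5, fruit 0.5–2, dairy
0.5–2.5, meat/protein 0.5–2.5 servings/day. Grains, vegetables and fruit
split 5 + 5 points (servings + wholegrains/variety). Vegetable variety
gives 1 point per group at threshold (green, orange, cruciferous,
tuber/bulb at ≥ 1 serving; legumes at ≥ 0.5); fruit variety gives 5 points
at ≥ 2 distinct fruits, else 0. Nutrients: saturated fat ≤ 10 %E → 5,
(10, 12] → 2.5, > 12 → 0; MUFA/PUFA linear 0 → 5 over 0–2 servings; sodium
< 1610 mg → 10, [1610, 2300] → 5, > 2300 → 0; total sugar < 5 %E → 10,
[5, 10] → 5, > 10 → 0; alcohol ≤ 2 standard drinks → 5, else 0. Water
scores ⌊10 × proportion⌋ capped at 5, so > 50% (and exactly 50%) scores 5 —
the 50.0% vs 50.1% distinction is below FFQ precision.

Interval-boundary conventions follow the literal printed inequalities and
are encoded in the cut-point functions; band boundaries at non-representable
thirds (e.g. 1 + 4/3 servings) are resolved by the floor rule and are not
meaningful beyond one float ulp.

### MDS (0–9, 9 binary components)

Six beneficial components (vegetables, legumes, fruits, cereals, fish,
lipid ratio) score 1 at/above the analysis-sample median; red/processed
meat and dairy score 1 *below* the median; alcohol scores 1 in the closed
moderate window 5–25 g/day. The lipid ratio is (MUFA + PUFA)/SFA per
participant, requiring SFA > 0 (violations raise with the participant id).
The median is the conventional interpolated 50th percentile (mean of the
middle two for even n), so the reference is reproducible; it is serialised
with the sample size into the output bundle.

### AHEI-2010 (0–110, 11 components, each 0–10)

Proportional (linear, clamped) scoring between printed anchors: vegetables
0–5 servings, fruit 0–4, whole grains 0–75 g, nuts/legumes 0–1 serving,
long-chain omega-3 0–250 mg, PUFA 2–10 %E (increasing); SSBs + fruit juice
1 → 0 servings, red/processed meat 1.5 → 0, trans fat 4 → 0.5 %E
(decreasing). Sodium is scored by analysis-sample decile, 10 × (10 − d)/9,
giving 10 in the lowest and 0 in the highest decile. Alcohol in women: 10
points on 0.5–1.5 drinks/day, linear to 0 at ≥ 2.5; non-drinkers score 2.5
(the published abstainer convention) and (0, 0.5) interpolates 2.5 → 10.
The intake table carries a separate `wholegrain_g` field because the
whole-grain anchor is in grams while the guideline-index component is in
servings; either convention can be fed independently.

### Quantile references and exposure

Sodium decile cut points and score quintile cut points are interpolated
quantiles; a value exactly at a cut point falls in the lower bin, so tied
scores always share a bin and an all-tied sample sits in bin 1. This makes
assignment deterministic and checkable against a rank oracle
(ceil(k·rank/n)) whenever n splits evenly. Quintile assignment requires
≥ 5 distinct totals; coarse integer indices (MDS) therefore yield unequal
but deterministic quintile sizes with ties never split. Quintiles 4 and 5
collapse to one high-diet-quality category for the sparse mortality
outcome.

## Outcomes

Five conditions are *enduring*: status at wave w is 1 if reported at any
wave ≤ w, regardless of later reports. Depression and/or anxiety is a
single combined group re-evaluated per wave. Incident outcomes at S4–S8
are the cumulative enduring status among that wave's respondents (everyone
in the sample was condition-free at S3). Multimorbidity is ≥ 2 of the six
groups co-existing at a wave. Deaths are assigned to between-survey
intervals: the outcome at wave w is death in the interval ending at w, and
the denominator drops deaths from earlier intervals; an `ncd_subset` scope
restricts to women who ever had any NCD. Enduring status carries through
non-response waves, but outcomes are only evaluated among respondents at
the outcome wave (mortality excepted — its denominator is the surviving
sample regardless of response).

## Covariates

Ten time-varying covariates (age; area, marital status, education,
occupation, income management; smoking, physical activity in four
MET·min/week bands 0–39 / 40–599 / 600–1199 / ≥ 1200, prescribed and OTC
medication as harmonised binaries). Education, measured only at S1 and S6,
is anchored: S3–S5 take the S1 value (S6 as fallback), S7–S8 take S6 (S1
as fallback). Remaining item missingness at S4–S7 borrows from the nearest
*subsequent observed* wave and S8 from the preceding wave; a
`--fill-direction conventional` switch carries the last prior observation
forward instead. Chained (nearest-observed) borrowing was chosen over
strict one-step borrowing so that filling is idempotent; fills never alter
observed values, never touch education, and unfilled gaps are logged.
Adjusted models are complete-case per wave. Mortality models use each
woman's last observed covariates at or before the outcome wave, since
women dying in the interval cannot report covariates at that wave. Age
enters continuously, centred.

## Models

Maximum-likelihood logistic regression (statsmodels), exposure dummies
against Q1, 95% Wald intervals on the log-odds scale — the standard
epidemiological presentation. Degenerate cells are surfaced, not hidden:
zero cases or an all-case/no-case exposure level yields an explicit
"inestimable" result, separation is flagged per level, a singular design
raises naming the collinear columns, and a failed cell never aborts the
grid. Baseline descriptives compare exposure groups with one-way ANOVA
(continuous) and chi-squared tests (categorical), two-sided, flagging
p < 0.05 point-wise with no multiplicity correction; low expected counts
are recorded as warnings.

## Synthetic cohort generator

The generator emulates the *structure* of the restricted data, with no
claim of matching its distributions. Per woman, a socioeconomic latent
u ~ N(0, 1) and a diet latent z = 0.4u + √0.84·ε drive:

- **Intake:** gamma families for servings/grams (mean m·exp(λz), fixed
  shape), lognormal sodium (median ≈ 2000 mg/day), beta water proportion,
  zero-inflated gamma alcohol (30% non-drinkers); gram amounts are tied to
  their serving counterparts via guideline serving sizes with lognormal
  noise. Loadings λ were set once so that pairwise index correlations fall
  in 0.3–0.7 (moderately concordant DQIs, asserted as a range property).
- **Conditions:** per-wave onset logit = baseline + effect·z + ses·u
  (+ a current-smoker term); onset persists for the five enduring
  conditions, depression/anxiety is redrawn per wave. Default per-wave
  baselines give cumulative burdens over five follow-up waves of roughly
  10% (DM, CHD, asthma), 36% (HT), 14% (cancer) and ~14% per-wave
  depression/anxiety; default diet effects are modest protective log-ORs
  per SD of z (−0.35 for DM down to 0 for cancer).
- **Attrition:** deaths per interval (p = 0.008, optionally diet-linked),
  absorbing dropout (4%/wave) plus intermittent skipping (3%/wave) so
  respondents can return, small early non-response at S2/S3, an 11%
  incomplete-FFQ rate and 3% item missingness on covariates.

Everything flows from a single seed; identical configs reproduce
byte-identical cohorts, and each config is content-hashed into the run
manifest. The generator records the latent factors, which serve as
bookkeeping oracles for parameter-recovery tests: the fitted Q5-vs-Q1
log-odds is compared with the log odds-ratio computed from each woman's
true onset probability (this exact oracle absorbs cumulative-incidence
and within-quintile-mixing effects that a naive `exp(β·Δz)` approximation
does not).

What the generator does *not* emulate: FFQ measurement error and
energy-adjustment structure, item-level correlations beyond the single
latent factor, informative (health-related) dropout, and recall/reporting
biases. Passing tests therefore demonstrate the pipeline's correctness and
calibration under a known data-generating process, not the epidemiological
findings themselves.

## Validation sizes and numerical choices

Null calibration uses 500 cohorts of n = 2000 (no diet effects, no
confounding paths) and checks 95% CI coverage of OR = 1 within 95% ± 2%;
parameter recovery uses 100 cohorts of n = 20 000 with an injected
diabetes effect of −0.6 per SD and requires |bias| < 0.05 on the log scale
against the bookkeeping oracle. Oracle equivalence uses 100 random 2×2
tables (|OR − ad/bc| < 1e-6) and 200-record rank-oracle checks. Scoring is
pure and bit-stable; totals equal component sums to 1e-9.

## Known limitations

- HEIFA intermediate bands for components other than discretionary foods
  are a documented generalisation of the printed band table; published
  component-level scorings differ in fine structure.
- No penalty for over-consumption of beneficial core foods (e.g. meat
  above 2.5 servings scores the maximum); the guideline source is
  ambiguous here and the choice is flagged rather than guessed.
- Fruit-variety counting uses a distinct-fruit count with no per-fruit
  minimum serving.
- The AHEI non-drinker score (2.5) is a convention, exposed as a module
  constant.
- Wald intervals can undercover in very sparse cells; those cells are
  usually flagged inestimable first.
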