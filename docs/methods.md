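# Methods

This note documents the models, parameter choices and numerical
conventions behind `mhfii_foodsec`, and what the synthetic-data tests do
and do not demonstrate about real survey data.

## Instruments

### FFQ frequency coding

The food-frequency questionnaire records, for 52 food items, how often
each was consumed in the past month on a 7-level ordinal scale.  Levels
map to fixed weekly frequencies (times/week):

| level | label | weekly |
|---|---|---|
| 0 | not at all | 0 |
| 1 | less than once a month | 0.12 |
| 2 | 1–3 d per month | 0.47 |
| 3 | 1–2 d per week | 1.5 |
| 4 | 3–5 d per week | 4 |
| 5 | daily or almost daily | 6 |
| 6 | more than once a day | 8 |

Food-group frequencies are sums of member-item weekly values.  Summation
is the aggregation convention of the index's validation lineage and makes
group frequency additive in its items.  Portion sizes and energy intake
are outside the instrument's reach and are not modelled.

### mHFII scoring

The modified Healthy Food Intake Index awards points for 11 food groups:
8 favourable (vegetables; fruits and berries; fibre-rich grains; fish;
milk; vegetable oil; nuts and seeds; fat spreads) and 3 limiting (red and
processed meat; sugar-sweetened beverages; snacks).  Seven groups carry a
maximum of 2 points, four a maximum of 1, so totals span 0–18.  For
favourable groups the score is the number of thresholds at or below the
weekly frequency; for limiting groups the number of thresholds at or
above it.  A frequency exactly at a threshold always earns the point
("at least"/"at most" convention) — the boundary rule is stated in the
scoring-table schema because prose descriptions of such indices rarely
pin down open/closed boundaries.

Thresholds, member items, directions and point maxima are configuration
(`ScoringTable` YAML), not code.  **The bundled default table is a
synthetic stand-in**: the published cut-off table for the study index is
not available in machine-readable form, so the shipped thresholds were
constructed once to satisfy every documented structural constraint
(component identities, 7×2 + 4×1 point budget, thresholds reachable from
the 7-level grid, orientation on Nordic food-based dietary guidelines)
and are clearly labelled `*_synthetic.yaml`.  Analyses that only depend
on the structure (total range, component count, ordinal score levels)
are unaffected by the exact cut-offs.

Missing data: a component whose member items are all missing leaves the
participant incomplete (total `NA`, excluded listwise downstream); a
partially answered component is scored on its observed items.  The
alternative — treating unanswered items as zero intake — would bias
favourable components downward and was rejected.

### HFIAS categorisation

Nine occurrence questions with never/rarely/sometimes/often follow-ups
collapse into four ordered categories by the standard HFIA-category
decision rules (most severe triggered condition wins):

* severe — Q5 or Q6 often, or any of Q7–Q9 at least rarely;
* moderate — Q3 or Q4 at least sometimes, or Q5/Q6 rarely or sometimes;
* mild — Q1 at least sometimes, Q2 at least rarely, or Q3/Q4 rarely;
* food secure — otherwise.

The individual-level (rather than household-level) wording used in the
target survey changes the questions, not the scoring; the assumption
that no trigger thresholds were altered is recorded in the cohort
provenance block.  The map is total, unique, and monotone in every item
(verified exhaustively over all 4⁹ patterns against an independent
trigger-table oracle).  The continuous 0–27 sum score is exported for
convenience but unused by the analyses.

## Inference

* **One-way ANOVA** of the mHFII total on the four FI categories, with
  pairwise contrasts against the food-secure reference.  Contrast CIs and
  p-values are Bonferroni-corrected over the 3 reported contrasts (family
  size configurable).
* **Adjusted contrasts** come from a main-effects linear model (FI +
  categorical covariates, no interactions) — the single-adjusted-contrast
  reporting convention implies no FI×covariate interactions.  Age enters
  as the grouped categorical variable, not continuous.
* **Confounder screening** uses three criteria: (i) association with
  both exposure (chi-square, p < 0.05) and outcome (one-way ANOVA,
  p < 0.05); (ii) change-in-estimate — adding the candidate moves the
  severe-FI coefficient by > 10% (relative; configurable, a convention
  rather than an identified study value); (iii) non-redundancy —
  Cramér's V < 0.6 with every already-selected confounder, candidates
  entered in decreasing change-in-estimate order.
* **Proportional-odds models**: per food group, the ordinal component
  score (2 or 3 levels) is regressed on severe-FI vs food-secure
  exposure (mild/moderate participants excluded) plus the selected
  confounders, by maximum likelihood (cumulative logit,
  `statsmodels` `OrderedModel`, L-BFGS; default projected-gradient
  tolerance 1e-7, tightened where exactness is asserted).  Wald 95% CIs
  on the log-odds scale; a binary outcome reduces the model to logistic
  regression, where the no-covariate MLE equals the 2×2 cross-product
  ratio (tested to 1e-6 over a grid of tables).  Quasi-separated fits
  (non-convergence, |log OR| > 10 or SE > 10) are flagged and their CI
  reported as unavailable.
* Degenerate ANOVA inputs (zero residual variance with zero difference)
  report difference 0, p = 1 rather than NaN.
* Ordinal levels unobserved in a given draw are dropped with a dense
  recode rather than raising.

## Synthetic cohort generator

The generator emulates the kind of cross-sectional sample the pipeline
targets: n 6435; 80% women; age groups 18–29/30–44/45–59/60+ at
17/34/37/12%; education comprehensive / upper-secondary-vocational /
lower-tertiary / postgraduate at 8/72/13/7%; FI categories food-secure /
mild / moderate / severe at 35/14.5/14.5/36%.  The mild/moderate split
of the combined 29% is not separately documented and defaults to an even
split (configurable).  Age and education shares not individually pinned
down were fixed once at values realistic for a service-sector workforce.

Two deliberately independent sub-generators:

1. **Total-score generator.**  Confounders are drawn from a one-factor
   Gaussian copula (pairwise latent correlation 0.35) over the
   protective orderings of age, sex and education — sociodemographic
   advantage clusters, which both mirrors real cohorts and gives each
   confounder genuine incremental confounding; marginals are preserved
   exactly.  FI is drawn from a cumulative-logit model tilted by the
   confounders (older/female/higher-educated → less insecure).  The
   total is a linear predictor — confounder effects +1.9 oldest-vs-
   youngest age (monotone within), +0.4 female, +0.8 postgraduate vs
   vocational; latent severe-FI effect ≈ −0.81 — plus Gaussian noise
   (SD 3.0), rounded and clamped to [0, 18].  Within-group dispersion is
   not documented anywhere; SD 3.0 was fixed once as a free calibration
   parameter consistent with the reported CI widths at the study sample
   size, and is flagged in the provenance block.
2. **Component generator.**  Each of the 11 ordinal component scores is
   drawn from a proportional-odds model whose severe-FI log-odds default
   to the log odds ratios the analysis should recover (vegetables 0.54,
   fruits/berries 0.61, fibre-rich grains 0.79, fish 0.65, milk 0.89,
   SSB 0.67, vegetable oil 0.80, nuts/seeds 0.66, red/processed meat
   1.15, fat spreads and snacks 1.0), with graded multipliers
   (0/0.4/0.7/1) across FI levels and mild confounder effects so that
   adjusted fits are the correct analysis.

No analytic link between group means of the total and the component ORs
is imposed, because none is documented; each sub-generator serves its own
estimand and the provenance block says so.

HFIAS answer patterns are sampled uniformly from the pre-enumerated set
of patterns consistent with the drawn category, so re-categorising a
cohort reproduces its FI column exactly.  FFQ item responses (optional)
are sampled uniformly from the level combinations whose group frequency
falls in the drawn score's band (exact round-trip by construction);
unscored items follow a fixed background distribution.  Each block draws
from its own named RNG substream, so enabling a block never perturbs the
others, and identical (config, seed) reproduce cohorts byte-for-byte.

### Calibration

`calibrate_generator` tunes four things — FI cumulative thresholds,
outcome intercept, latent severe effect, and a global confounder-tilt
scale — by iterative stochastic approximation against the target margins
(food-secure mean 9.1, unadjusted severe gap −1.1, adjusted gap −0.8,
the FI prevalences), simulating a large cohort per sweep and applying
logit-difference / mean-difference / ratio updates.  The shipped
defaults were produced by this routine with margins averaged over
multiple 300k–400k cohorts and then frozen; under them, study-sized
replicates average food-secure mean ≈ 9.10, severe mean ≈ 8.0,
unadjusted gap ≈ −1.11, adjusted gap ≈ −0.81 and severe prevalence
≈ 36.2%.  The latent severe effect (−0.8146) differs slightly from the
target adjusted gap because rounding and clamping attenuate fitted
coefficients; calibration absorbs that attenuation.  Infeasible target
combinations raise a calibration-failure error carrying the search
trace; targets with equal adjusted and unadjusted gaps short-circuit to
a zero tilt.

## Problem sizes in the test suite

Simulation-backed checks use sizes chosen to give tight Monte-Carlo
error while keeping the suite practical: 200 study-sized replicates for
the mean-gap margins, 100 replicates × 11 proportional-odds fits for OR
recovery (pooled CI coverage ≥ 90%), 500 replicates of a 600-person
null cohort for the familywise type-I error bound, and full enumeration
(4⁹ patterns; 5⁴ contingency tables) for the exact oracles.

## What passing tests do and do not show

The generator produces clean categorical confounders, logistic-family
ordinal scores, and exactly consistent HFIAS/FFQ patterns.  Real FFQ
data have correlated item-level measurement error, informative
missingness, portion-size variation and survey non-response — none of
which are modelled (missingness injection is available but is
missing-completely-at-random).  Parameter-recovery results therefore
validate the *pipeline arithmetic and inference machinery*, not the
epidemiological robustness of any particular survey's estimates.

## Known limitations

* The shipped scoring thresholds are synthetic stand-ins (above); users
  with the authoritative cut-off table should supply it as YAML.
* Proportional-odds fits assume the common-slopes (proportionality)
  assumption; no score test for it is provided.
* Survey weights, multiple imputation and energy-intake adjustment are
  out of scope.
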