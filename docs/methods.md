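# Methods

## Scope and data model

The unit of analysis is one NICU admission with day-granular order
streams. Length of stay (LOS) is a positive whole number of days; day 1 is
the admission day, and a stay must exceed 24 h (`los_days >= 1`) with at
least one nutrition order to enter the analysis. Admissions flagged for
congenital anomaly, palliative care, discharge on request, transfer or
death are excluded up front and logged with their reason.

All modelling is stratified into four gestation strata with left-closed,
right-open boundaries at 26, 32, 34 and 37 weeks, so 32.0 weeks falls in
the 32–34 stratum. The interval convention resolves the ambiguity of
overlapping textual labels ("26–32", "32–34") in favour of the "< 32 / ≥ 32
weeks" reading. Ages in [22, 26) are folded into the first stratum with a
warning rather than rejected, since simulated tails can fall below 26
weeks; ages outside [22, 45] are data errors.

## Missing-data protocol

Three mechanisms, applied in order:

1. **Forward filling** of daily nutrition orders: a day without an order
   inherits the most recent prior order (marked `filled_forward`). Days
   before the first recorded order cannot be filled; they are flagged and
   excluded from scoring. The operation is idempotent.
2. **Population-mean imputation** of continuous covariates (gestational
   age, birth weight). A field whose imputed fraction exceeds 10%
   (configurable) — or that is entirely missing — is dropped from
   modelling. The cutoff is applied cohort-wide, not per stratum: the
   decision of whether a covariate is trustworthy should not differ
   between strata measured by the same process.
3. Missing **categorical** covariates are recoded to an explicit `unknown`
   level, never mean-imputed (a mean of categories is undefined).

## Deviation scoring

Nutrition orders are compared per day against a table-driven reference:
per-kg energy (kcal/kg/day) and protein (g/kg/day) recommendations by
feeding mode (enteral EN / parenteral PN), birth-weight class (≤ 2500 g vs
> 2500 g, boundary inclusive on the lighter side) and day-of-life band. A
combined EN+PN day is scored against the *highest* of the two single-mode
recommendations; withheld-feeds days recorded as PN-only are scored against
the PN table. Birth weight stands in for daily weight throughout: daily
weights are outside the data model, and orders are recorded per kg.

The shipped reference tables are **editable placeholders** with plausible
neonatal ranges; a deployment should load its unit's own references. No
result in this package depends on the default numbers — only on lookup and
classification behaviour, which the tests sweep exhaustively.

The per-patient **deviation factor** is `sqrt(Σ_d gap_d²)/n`: the L2 norm
of the daily gaps normalised over the `n`-day stay. Two readings of the
source procedure — a raw Euclidean norm versus daily sums averaged over
the stay — conflict; `l2_over_n` keeps both the Euclidean form and the
LOS normalisation and is the default, with `l2_raw` and `mean_abs`
available behind a config switch. Signed gaps enter squared, so over- and
under-prescription count alike. Within each stratum, patients strictly
above the nearest-rank 75th percentile form `Q4`; ties at the cutpoint go
to `remaining`, keeping Q4 strictly the maximum-deviation group. Quartile
coding is computed within stratum (the unit of all modelling), and the
validation split is coded against cutpoints learned on the training split,
which avoids leakage and keeps small validation strata codable.

Medication orders deviate when dose per kg or daily frequency differs from
the drug reference by ≥ 10% (inclusive, per the "≥" convention; a 1e-12
slack keeps orders constructed as exactly 110% on the deviating side of
the float boundary). All deviations count equally regardless of severity.
Frequency deviations are classified and reported but only dose deviations
feed the LOS model and the deviation-day count, mirroring the finding that
frequency trends track dose trends. Patients with only vitamin/iron
supplement orders are `medication not required`; supplements never deviate.

## LOS regression

Per stratum, OLS on a transformed response with four candidate families:
identity, log, square root, reciprocal. Family comparison repeats a random
80/20 construction/test split once per patient in the stratum and averages:
AIC/BIC computed on the **day scale** (the transform Jacobian `log|dz/dy|`
is added to the transformed-scale Gaussian log-likelihood, making criteria
comparable across families — without this, a variance-shrinking transform
like log would win on any data), transformed-scale R², and back-transformed
RMSE in days on the held-out 20%. Ranking is by mean AIC, ties by mean test
RMSE; the procedure is deterministic given a seed and invariant to row
order (rows are sorted by patient id before splitting).

Variable selection keeps terms with Wald p < 0.05 (any coefficient, for
multi-level factors, via an F-test on the term's coefficients) and refits
on the retained set; no multiplicity correction, matching the procedure
being reproduced. Terms constant within a stratum are dropped with a log
entry; a rank-deficient design raises with the aliased columns named. With
no significant term the stratum gets an intercept-only model plus warning.

**Ordinary marginal means** are implemented directly on the reference grid
(all level combinations of modelled categorical factors, continuous
covariates pinned at their fitting means): the OMM of level L averages
grid predictions with factor = L, weighting every other factor's levels by
observed frequency. A grid-size cap (default 100,000 rows) guards against
factor explosions. Day effects anchor each level to the frequency-weighted
grand OMM on the transformed scale, back-transform both, difference, and
round half away from zero — the anchor is a documented choice (the source
tables show paired +/− level effects without stating their baseline) and
is covered by parameter-recovery tests rather than by reproducing printed
tables. Back-transformation uses plain inversion clamped to ≥ 1 day; Duan
smearing is available behind a flag but off by default so effects read as
simple day differences. The day-scale decomposition "median + Σ level
effects ≈ prediction" is exact on the transformed scale and first-order on
the day scale; it degrades for long-stay strata with several large effects,
which is why the payload test asserts it only where curvature is small.

Validation reports per-stratum RMSE (days), R² of predicted vs observed,
and mean ± SD of both; empty strata yield NaN, never zero. A seven-row
grid refits models on every combination of risk-factor sets (antenatal/
perinatal always; nutrition, medication, diagnoses toggled) and reports
|mean observed − mean predicted| per stratum.

## Synthetic cohort generator

The generator emulates a two-site cohort: ~1,050 admissions over 16 months
(12 train + 4 validation, split by admission date), stratum mix
(0.102, 0.252, 0.319, 0.327), and per-stratum covariate and diagnosis
prevalences, gestation and birth-weight moments taken from the published
baseline table of the study population it models. Sepsis probability is
raised by 0.15 among medication-deviating patients, reproducing the
observed deviation–sepsis association; severe RDS is drawn as a subset of
RDS. LOS follows

```
log(LOS) = baseline(stratum) + Σ_k β_k x_k + Normal(0, σ),  σ = 0.3,
```

ceiled to ≥ 1 day. Default baselines (2.78, 1.48, 1.00, 0.98) put the
stratum medians near 25/6/4/4 days after average covariate effects.
Nonzero defaults (log scale): sepsis 0.35, medication dose deviation 0.30,
severe RDS 0.30, male 0.08, protein-Q4 0.10, and a per-stratum energy-Q4
coefficient (0.24, 0.80, 1.05, 1.04) calibrated **analytically** — from
`exp(m+β) − exp(m+wβ)` with stratum mean log-LOS `m` and Q4 frequency
`w≈0.25` — so the injected top-quartile energy effect is ≈ +5 days in
every stratum. Cesarean delivery, maternal disease and TTNB carry explicit
zero coefficients as designed nulls for type-I checks. A config switch
generates additive day-scale LOS instead (`response_scale="identity"`,
noise SD 2 days), giving family selection a case where identity is the
right answer.

Two constructions make ground truth exact rather than approximate:

- **Deviation scales.** Each patient draws a target deviation factor from
  a stratum lognormal profile; the daily gap pattern (random magnitudes,
  random zero days, random signs) is rescaled so its L2-over-n norm equals
  the target *exactly*, and gap signs are flipped where an order would go
  negative (signs vanish in the squares). The analyzer therefore recomputes
  the drawn scale to machine precision, and top-quartile membership —
  assigned with the same quartile coder the analyzer uses — matches
  perfectly.
- **Medication status.** Deviating patients get at least one order at
  ≥ 110% or ≤ 90% of the reference dose; non-deviating orders stay within
  ±7%, a safety margin off the 10% boundary.

What the generator does **not** emulate: vital signs, growth curves,
culture results, site-level random effects, gestation–weight correlation
within stratum, daily weight change, or any real deviation distribution
beyond the quartile summaries that informed the profiles. Passing tests
therefore demonstrate that the pipeline recovers what this generative
family encodes — not fidelity to any particular hospital's data. Order
streams are complete by default (a profile option drops days to exercise
forward filling); covariate missingness is off by default and injectable
per field.

## Numerical choices and problem sizes

- Inclusive thresholds: ≥ 10% medication deviation; ≤ 2500 g weight class.
- Quartile cutpoint: nearest-rank 75th percentile; Q4 strictly above it;
  at least 8 patients per stratum to derive a cutpoint (external cutpoints
  may code smaller batches).
- Effects rounded half away from zero to whole days.
- Back-transform guards: log clipped at e^±20, sqrt at 0, reciprocal at
  1e-6; predictions clamped to ≥ 1 day.
- Degenerate responses (zero variance) yield NaN R² silently.
- Test and acceptance workloads use cohorts of 200–1,600 patients and
  10–50 replicate seeds — large enough that binomial noise on coverage and
  selection rates sits well inside the asserted margins, small enough to
  keep the full suite around a minute of compute.

## Known limitations

- Associational, not causal: deviations may be deliberate responses to the
  clinical condition actually driving the stay.
- The log-of-ceiled-days response slightly inflates short stays; its
  differential effect on coefficients is negligible in the long-stay
  stratum (where coefficient recovery is scored) but visible in short-stay
  strata.
- No severity grading of morbidities or deviations; no per-drug effects;
  no micronutrient scoring.
- Bedside highlighting compares against the immediately previous payload
  only, not full history; predicted LOS comes from the fixed trained model
  with updated covariates, not a daily refit.
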