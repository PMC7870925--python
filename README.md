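# nicu-los

Gestation-stratified length-of-stay (LOS) modelling for neonatal intensive
care, driven by how far daily nutrition and medication orders deviate from
clinical guideline recommendations.

## The problem

LOS in a NICU is the outcome clinicians use to counsel families and plan
resources. Beyond antenatal and perinatal covariates and clinical
diagnoses, day-to-day care itself carries signal: prescriptions that stray
from nutrition references (per-kg energy and protein targets by feeding
mode, birth-weight class and day of life) or from drug references
(recommended dose per kg and daily frequency) are associated with longer
stays. This package turns per-day order streams into per-patient risk
factors and fits interpretable per-stratum LOS models whose effects read as
whole days at the bedside.

## The statistic and the model

For each nutrient, a patient's daily gaps between the guideline
recommendation `x_d` and the prescribed order `x'_d` over an `n`-day stay
are condensed into a **deviation factor**

```
DF = sqrt( Σ_d (x_d − x'_d)² ) / n
```

— the Euclidean (L2) norm of the daily gaps normalised over the stay.
Within each gestation stratum (26–32, 32–34, 34–37, ≥37 weeks) patients
strictly above the 75th percentile of DF form the top-quartile risk group
(`Q4`) against the pooled `remaining` three quartiles. A medication order
deviates when its dose per kg (or daily frequency) differs from the
reference by ≥ 10%; patients are coded `not_required` / `no_deviation` /
`deviation`, with vitamin and iron supplements excluded.

Per stratum, LOS is fitted by OLS on a transformed response `g(y)` with the
family `g` ∈ {identity, log, sqrt, inverse} chosen by repeated random 80/20
splits — one iteration per patient — ranked by mean AIC on the day scale
(the transform's Jacobian is folded into the likelihood so AICs are
comparable across families), ties broken by held-out RMSE. Terms with Wald
p < 0.05 are kept and refitted. Each significant factor level is then
expressed in days via **ordinary marginal means** (OMM): model predictions
averaged over the reference grid with *observed-frequency* weights on the
other factors — better suited to unbalanced strata than uniformly weighted
marginal means — and anchored to the frequency-weighted grand mean:

```
effect_days(level) = round( g⁻¹(OMM(level)) − g⁻¹(Σ_L w_L · OMM(L)) )
```

A per-patient bedside payload (JSON or text) carries the predicted LOS, the
stratum median/IQR, every modelled risk factor with its day weight, and
highlight flags for factors whose level or effect changed since the
previous payload.

Because no patient-level data ship with the package, a synthetic cohort
generator emulates the target population (two sites, ~1,050 admissions over
16 months, published stratum mix and prevalences) with LOS drawn from a
known multiplicative model — so every stage is testable against ground
truth.

## Worked example

```python
import nicu_los as nl
from nicu_los.pipeline import run_pipeline

guidelines = nl.load_default_guidelines()
config = nl.SimulationConfig(n_patients=1047, seed=1)
cohort, truth = nl.simulate_cohort(config, guidelines)
result = run_pipeline(cohort, guidelines, seed=1)

print(result.family_rankings[">=37"].head(2).round(2))
print(result.day_tables[">=37"].effects)
print(result.validation_metrics.round(2))
```

prints (abridged):

```
family  mean_aic  mean_bic  mean_r2  mean_test_rmse  mean_train_rmse  n_iterations
   log    809.19    860.23     0.67            2.13             2.01           278
  sqrt    856.48    907.52     0.68            2.11             1.99           278

             factor        level  effect_days  p_value
             sepsis         True            2   0.0000
    energy_quartile    remaining           -1   0.0000
    energy_quartile           Q4            5   0.0000
medication_category    deviation            1   0.0042
...

gestation_category   n  rmse_days  r_squared  mean_observed  mean_predicted
             26-32  21       7.67       0.30          25.57           24.44
             32-34  60       2.35       0.60           7.73            7.34
             34-37  76       1.92       0.67           5.43            4.94
              >=37  74       2.66       0.63           6.07            5.52
```

Reading: in the ≥37-week stratum the log family wins the AIC ranking over
278 resampled splits; landing in the top energy-deviation quartile adds
about five days to the predicted stay (the generator injected a ~+5-day
effect, so the pipeline recovered it); and on the held-out four months of
admissions the model predicts stays within ~2–8 days RMSE depending on
stratum. `result.payloads` holds one bedside payload per validation
patient; `nicu_los.render_report(result.payloads, "text")` renders the
four-stratum grid with the patient's own stratum zoomed.

A CLI wraps the same stages:

```sh
nicu-los simulate --seed 1 --out scratch/cohort
nicu-los fit --cohort scratch/cohort --seed 1 --out scratch/reports
nicu-los report --cohort scratch/cohort --seed 1 --out scratch/payloads.json
```

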