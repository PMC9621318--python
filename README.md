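# vpaml

Integrating population-pharmacokinetic (popPK) covariate models with machine
learning, using valproic acid (VPA) as the worked example.

Published popPK models of the same drug rarely agree on which patient
covariates drive its pharmacokinetics: one VPA model explains clearance with
serum albumin (ALB) and CYP2C19 genotype, another with body weight, daily
dose and co-therapy with enzyme-inducing antiepileptics (carbamazepine,
phenytoin, phenobarbital).  `vpaml` fuses such models by Monte-Carlo
simulating a virtual patient population from each, merging the simulated
records into one supervised dataset, and training a gradient-boosted
regressor of the steady-state concentration that sees *all* covariates at
once.  The result is a single predictive model — interpretable through
Shapley attributions and usable for exposure simulation — for audiences in
pharmacometrics, therapeutic drug monitoring (TDM) and model-informed
precision dosing.

## The model

Each virtual patient j follows a one-compartment oral model at steady state:

```
Css(t) = ka·F·X0 / (Vd·ka − CL) · [ e^(−CL·t/Vd) / (1 − e^(−CL·τ/Vd))
                                    − e^(−ka·t)  / (1 − e^(−ka·τ)) ]
```

with single dose X0 (mg), dosing interval τ (h), sampling time t ∈ [0, τ],
bioavailability F = 1, and typical-value parameters from two covariate
submodels (no inter-individual random effects):

| | Model A (ka = 2.38 h⁻¹) | Model B (ka = 1.90 h⁻¹) |
|---|---|---|
| CL (L/h) | 0.64·(ALB/38.7)^(−1.06), ×e^(−0.45) for CYP2C19 \*2/\*3 carriers | 0.1·(BW/60)^0.7·DailyDose^0.2, ×1.36 (CBZ), ×1.25 (PHT), ×1.11 (PB) |
| Vd (L) | 22.15 (female), 22.15·e^0.78 (male) | 0.14·BW |

20,000 Model-A patients (4 genotype × gender scenarios) and 14,000 Model-B
patients (7 co-medication combinations) are simulated, concentrations above
150 mg/L filtered out, and the remainder fused into a 16-feature table
(doses, BW, ALB, t, τ, genotype / gender / co-medication indicators).
Gender and ALB — absent from Model-B records — are imputed by k-nearest
neighbours.  Seven regressors are benchmarked by 10-fold cross-validated MAE;
the winning gradient-boosted tree model is interpreted with exact
interventional Shapley values (computed natively for tree ensembles and
verified against an exhaustive coalition-enumeration oracle) and applied to
genotype × co-medication exposure scenarios via trapezoidal AUC over a
12-hour dosing interval.

## Worked example

```python
from vpaml import vpop_sim, fusion, ml_bench, exposure
from vpaml.vpop_sim import SimConfig

a, b = vpop_sim.simulate_filtered(SimConfig(seed=1))
print(f"retained: Dataset-A {len(a)}/20000, Dataset-B {len(b)}/14000")

table = fusion.build_feature_table(a, b, seed=1)
print(f"fused table: {len(table.df)} rows, "
      f"mean Css {table.df['Css'].mean():.1f} mg/L")

bundle = ml_bench.fit_final(table, ml_bench.ModelSpec("xgboost"), seed=1)
Xv, yv = table.validation
m = ml_bench.evaluate(bundle.predict(Xv), yv.to_numpy())
print(f"validation: MAE {m.mae:.1f} mg/L, RMSE {m.rmse:.1f} mg/L, "
      f"MRE {m.mre:.1f}%, IR {m.ir:.2f}%")

results, summary = exposure.run_scenarios(bundle, seed=1)
for r in results:
    print(f"{r.name}: AUC0-12h {r.auc_mean:.1f} +/- {r.auc_sd:.1f} mg.h/L, "
          f"Css_avg {r.css_mean:.1f} +/- {r.css_sd:.1f} mg/L")
print(f"scenario 3 vs 2 AUC ratio: "
      f"{summary['auc_ratio_scenario3_vs_scenario2']:.2f}")
```

prints (seed 1):

```
retained: Dataset-A 14442/20000, Dataset-B 11694/14000
fused table: 26136 rows, mean Css 73.8 mg/L
validation: MAE 2.5 mg/L, RMSE 3.4 mg/L, MRE -0.0%, IR 98.93%
scenario_1: AUC0-12h 1026.4 +/- 136.0 mg.h/L, Css_avg 85.5 +/- 11.3 mg/L
scenario_2: AUC0-12h 616.5 +/- 74.5 mg.h/L, Css_avg 51.4 +/- 6.2 mg/L
scenario_3: AUC0-12h 1174.4 +/- 187.6 mg.h/L, Css_avg 97.9 +/- 15.6 mg/L
scenario_4: AUC0-12h 747.2 +/- 122.3 mg.h/L, Css_avg 62.3 +/- 10.2 mg/L
scenario 3 vs 2 AUC ratio: 1.90
```

Reading the numbers: the retention filter keeps ~72% / ~84% of the two
cohorts; the full 16-feature model predicts held-out simulated
concentrations to within 2.5 mg/L on average, with 98.9% of predictions
inside ±20% of the actual value (the "ideal rate", IR).  In the exposure
scenarios (500 mg twice daily), CYP2C19 variant carriers without
enzyme-inducing co-medication (scenario 3) accumulate roughly 1.9× the
exposure of wild-type patients co-medicated with all three inducers
(scenario 2), whose average steady-state concentration (~51 mg/L) sits near
the lower edge of the usual 50–100 mg/L therapeutic range.

## Command line

```
vpaml all --seed 1 --outdir run1          # simulate → fuse → train →
                                          # evaluate → explain → scenarios →
                                          # external, with artifacts
vpaml predict --bundle run1/bundle_full --input patients.csv --output out.csv
vpaml grid --outdir run1                  # hyperparameter grid search
```

Every stage writes CSV/JSON artifacts stamped with the seed and a config
hash; a YAML file passed via `--config` overrides any default (simulation
sizes, k-NN settings, model zoo, scenario sizes — see
`vpaml.config.PipelineConfig`).

A simplified 12-feature model (dropping Single Dose, ALB, t and τ, which are
often unavailable or unreliable in routine TDM) is trained alongside the
full model, and a synthetic external TDM cohort — generated from published
summary statistics, since the original records are not public — exercises
the external-validation path end to end.

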