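# Methods

## Structural model

Concentrations are generated from the standard one-compartment oral model at
steady state (first-order absorption and elimination, repeated dosing every
τ hours):

Css(t) = ka·F·X0 / (Vd·ka − CL) · [ e^(−ke·t) / (1 − e^(−ke·τ)) −
e^(−ka·t) / (1 − e^(−ka·τ)) ],  ke = CL/Vd.

Assumptions worth keeping in mind:

* **Typical values only.** Each virtual patient's CL and Vd are the
  population values implied by their covariates; inter-individual and
  residual random effects are deliberately excluded so the
  covariate-to-concentration mapping the regressor must learn is noise-free.
  Real TDM data are far noisier; the external-cohort generator (below) is
  where variability is modelled.
* **F = 1** for all valproic-acid formulations (complete oral
  availability); F is kept as a parameter but never varied by the
  simulators.
* The prefactor is singular at Vd·ka = CL.  The implementation rejects that
  case rather than switching to the limiting expression: a bounds check
  (tested) shows no covariate combination reachable by either submodel comes
  near it (Vd·ka exceeds CL by more than 2× everywhere on the covariate
  envelope).
* Mean-value identity: the average of Css over one interval is F·X0/(CL·τ),
  so the steady-state AUC over an interval is F·X0/CL independent of ka, Vd
  and τ.  This closed form is the oracle for both the simulator and the
  trapezoidal integrator (tests require agreement to 1e−6 relative under
  dense quadrature, 0.1% for the trapezoid at 10,001 points).

## Covariate submodels

Model A (ka = 2.38 h⁻¹): CL = 0.64·(ALB/38.7)^(−1.06), multiplied by
e^(−0.45) for carriers of CYP2C19 \*2 and/or \*3 loss-of-function alleles;
Vd = 22.15 L for females, ×e^0.78 for males.  Model B (ka = 1.90 h⁻¹):
CL = 0.1·(BW/60)^0.7·DailyDose^0.2 with multiplicative co-therapy factors
1.36 (carbamazepine), 1.25 (phenytoin), 1.11 (phenobarbital); Vd = 0.14·BW.
Units are fixed throughout: mg, L, h, g/L for ALB, kg for BW.

## Virtual populations

* Dataset A: 4 scenarios (wildtype/variant × male/female) × 5,000 patients;
  BW ~ N(66.5, 12.1) kg, ALB ~ N(38.9, 6.4) g/L.
* Dataset B: 7 co-medication combinations × 2,000 patients;
  BW ~ N(60.2, 12.5) kg; genotype unknown, gender/ALB missing by design.
* Shared dosing design: X0 uniform over {125, 250, 300, …, 900} mg (15
  values), τ uniform over {6, 8, 12, 24} h, t ~ Uniform(0, τ), and
  daily dose = X0·24/τ (equal divided doses — this mapping makes the daily
  dose range exactly 125–3,600 mg, matching the dose lattice times 1–4
  administrations per day).
* Non-positive Normal draws of BW/ALB are redrawn; at these moments the
  probability is below 1e−7 per draw, so the truncation bias is negligible.
* Retention filter: records with Css > 150 mg/L are removed (strictly
  "higher than": 150.0 is retained), keeping the simulated range compatible
  with observed TDM data.  No lower filter is needed — the model cannot
  produce negative concentrations.
* Each dataset consumes its own RNG stream spawned deterministically from
  the config seed (`default_rng([seed, k])`), so A and B are independently
  reproducible and every stage of the pipeline is bit-stable under a fixed
  seed.

What the generator does *not* emulate: between-subject variability around
the typical values, correlation between ALB and BW (the two submodels were
estimated on different cohorts, so the joint distribution is unknown and
independence is assumed), assay error, and non-adherence.  Green tests
therefore certify the pipeline's internal consistency and its agreement
with the published simulation study — not performance on real patients.

## Fusion into the ML table

Merging order: concatenate → impute → one-hot encode → min-max scale →
split.  The 16 features are Single Dose, BW, ALB, t, τ, Daily Dose, the two
genotype indicators, Male, and the 7 co-medication-combination indicators;
reference levels (genotype Unknown, co-medication None, gender Female) are
dropped to avoid redundant columns, and the latent ka/Vd/CL are discarded as
clinically unobservable.

k-NN imputation of gender and ALB (the fields Model-B rows lack) uses k = 5
Euclidean neighbours among complete rows, on min-max-scaled BW, Single
Dose, Daily Dose, t, τ, the co-medication indicators — and, by default, the
simulated concentration itself.  Including the target mirrors how an
off-the-shelf numeric k-NN imputer applied to the whole matrix behaves (the
donor pool becomes concentration-matched) and reproduces the published
behaviour of this pipeline, at the price of target leakage into two imputed
covariates of the co-medicated rows; `include_css=False` gives the
leakage-free variant.  Validation metrics are indistinguishable between the
two (the affected rows' genotype/gender features carry little signal for
the model); the choice mainly moves the extrapolation corner discussed
under "Exposure scenarios".  ALB is the unweighted neighbour mean; gender
the neighbour majority, ties (even k) to female.

Min-max bounds are fitted on the full merged table before the 8:2
derivation/validation split, mirroring the published order of operations;
this leaks the validation range into the scaler (bounds only), and a
fit-on-derivation-only mode is provided (`scaler_mode="derivation"`).

## Regression benchmark and metrics

Seven regressors — XGBoost-style gradient-boosted trees, random forest,
bagging, sklearn gradient boosting, a single decision tree, AdaBoost,
linear regression — are compared by 10-fold cross-validated MAE on the
derivation cohort, each at its implementation defaults.  Library defaults
drift across versions, so printed-performance comparisons are
tolerance-banded and the hyperparameters actually in force are logged into
the ModelBundle.  Fold-mean 95% CIs use the normal approximation
(1.96·SD/√10).

Validation metrics: MAE, RMSE, signed MRE (a bias measure — near zero means
over- and under-prediction cancel), and IR, the share of predictions within
±20% of the actual value (boundary inclusive).

The simplified model drops Single Dose, ALB, t and τ (the inputs most often
missing or unreliable in routine TDM) and retrains on the same derivation
rows.  The default hyperparameter grid for optimizing it brackets each
coordinate of the known good operating point with one smaller and one
larger candidate (648 points); the search minimizes 10-fold CV MAE with
ties broken by lexicographic lattice order.  The full grid is a CLI stage;
tests exercise the search on small sub-grids.

## Shapley attributions

`shap`-style attributions are computed natively.  The value function is
interventional: v(S) = E_z[f(x_S, z_∖S)] with z ranging over a fixed-seed
background subsample of the derivation cohort (default 512 rows).  For a
tree ensemble this expectation is exact, and the per-(x, z) pair game has a
closed-form Shapley value per leaf: collapsing the path conditions per
distinct feature, a leaf with a features satisfied only by x and b only by
z contributes +v·(a−1)!·b!/(a+b)! to each x-only feature and
−v·a!·(b−1)!/(a+b)! to each z-only feature.  Averaging over the background
gives attributions that satisfy local accuracy exactly in float64
(base value + Σφ = prediction; inputs are quantized through float32 first,
replicating how xgboost and sklearn compare features to thresholds).
Thresholds and leaf values are extracted from the booster's JSON dump — the
tabular dump truncates splits to six significant digits, which mis-routes
samples lying near a threshold.

An independent oracle, `exhaustive_shapley`, evaluates the defining sum
over all 2^p coalitions (p ≤ 12) through the model's own predict function;
tests require agreement to 1e−6 on depth-≤2 trees for single trees, random
forests and boosters, plus the null-player, symmetry and efficiency axioms.
Global importance is mean |φ| per feature.  Because the explainer variant
behind the published rankings is not documented, rankings are asserted at
the top-k set level, not position by position (Daily Dose first is the
exception — its dominance is unambiguous).

## Exposure scenarios

Four cohorts at 500 mg twice daily (Daily Dose 1,000 mg, τ = 12 h):
genotype (variant/wildtype) × co-medication (CBZ+PHT+PB combination flag
set, or none).  Each cohort: 1,000 patients, BW ~ N(64.3, 12.4) kg and
ALB ~ N(37.9, 5.6) g/L (the fused-dataset moments), gender Bernoulli(0.5),
and 200 per-patient sampling times drawn uniform on [0, 12] h and sorted
(an even-grid mode is available; whether the original 200 times were shared
across patients is unknowable, so per-patient draws were chosen and made
configurable).  The trained bundle predicts Css at each time; per-patient
AUC0→12h is the trapezoid over the sampled range without endpoint
extrapolation (expected truncation bias < 1% at 200 points), and
C̄ss = AUC/12 exactly.

Scenarios combining a known genotype with active co-medication flags never
occur in the training data (genotype comes from Model-A rows, co-medication
from Model-B rows), so predictions there are an extrapolation of the tree
ensemble, not an interpolation of either popPK model — the point of the
fusion, but also its least-constrained corner.  Empirically this corner is
the only quantity sensitive to implementation details (booster era,
imputation distance): cohort means for the no-co-medication scenarios
reproduce the analytic F·X0/CL values within a few percent, while the
co-medicated corner sits roughly 7–10% below the originally reported
exposures under the default configuration.  The scenario-3 AUC is
additionally cross-checked against the analytic Model-A value at
cohort-mean covariates (agreement within 15% required).

## Synthetic external cohort

The real external TDM dataset (105 measurements, 56 patients) is not
public.  The generator reproduces its published summary statistics —
genotype counts (22 wildtype, 34 variant carriers), 42 male/14 female,
BW ~ N(63.82, 11.48) kg, daily dose on a 250–2,000 mg lattice with weights
giving median 1,000 mg, no enzyme-inducing co-medication, measurements per
patient averaging 105/56 ≈ 1.88 — and simulates observed concentrations
from Model-A at a trough-like regime (t = τ = 12 h) with lognormal
between-subject clearance variability (default 30% CV) and lognormal
residual error (default 20% CV), magnitudes typical of valproic-acid popPK
studies.  ALB is drawn internally to evaluate Model-A clearance but never
emitted: the simplified model deliberately does not consume it.  With both
CVs at zero the observations equal the analytic model exactly (tested).
Published external-validation numbers depend on the real records and are
not reproduction targets; this cohort exists so the evaluation path is
fully testable offline.

## Problem sizes and numerical choices

Tests run the full published sizes once per session (20,000 + 14,000
simulated patients, 10-fold CV of all seven models, 1,000 × 200 scenario
predictions); attribution rankings use 400 foreground rows against a
128-row background, which reproduces the stable top-of-ranking structure at
a fraction of the cost of the full 1,000 × 512 configuration used by the
CLI `explain` stage.  The acceptance script skips the model-zoo CV (no
reported quantity depends on it) and completes in well under a minute.
Degenerate inputs are rejected loudly everywhere (singular PK parameters,
empty grids, k exceeding donors, non-ascending time vectors, schema
mismatches); no silent clipping or coercion is performed anywhere in the
pipeline.

## Known limitations

* The gender column of the fused table is not faithful to the original
  study, whose imputation left Model-B rows essentially all female; here a
  majority vote over ~50/50 donors yields ~50% males in those rows.  The
  effect on every measured quantity is negligible (verified), but the
  per-category counts of the fused table differ.
* Attribution extraction supports xgboost boosters, sklearn decision trees
  and random forests; other estimators (e.g. sklearn gradient boosting,
  AdaBoost) can be benchmarked but not attributed.
* The exposure corner combining genotype and co-medication inherits the
  extrapolation behaviour of whatever booster version is installed; see
  above.
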