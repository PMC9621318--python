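"""Synthetic external therapeutic-drug-monitoring cohort.

The real external validation set (105 steady-state VPA measurements from 56
patients collected in routine TDM) is not publicly available.  This module
generates a synthetic stand-in that matches its published summary
statistics — patient counts, genotype distribution, body weight moments,
gender split, daily-dose range and median, no enzyme-inducing co-medication
— so the simplified-model evaluation path is fully testable offline.

The latent truth is the Model-A population model evaluated at a trough-like
sampling regime (t = tau = 12 h), perturbed by lognormal between-subject
variability on clearance and lognormal residual error.  Serum albumin is
drawn internally to evaluate Model-A clearance but is never emitted as a
feature: the simplified model deliberately does not consume it, matching
what the clinic can measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

from . import ppk_core
from .fusion import FEATURES, SIMPLIFIED_DROP, TARGET
from .ml_bench import ModelBundle, evaluate

#: simplified feature schema (12 features)
SIMPLIFIED_FEATURES = tuple(f for f in FEATURES if f not in SIMPLIFIED_DROP)

#: published genotype distribution of the external cohort (patients)
GENOTYPE_COUNTS = {"*1/*1": 22, "*1/*2": 26, "*1/*3": 4, "*2/*2": 1, "*2/*3": 3}


@dataclass(frozen=True)
class ExternalCohortSpec:
    """Summary statistics the synthetic cohort is generated from."""

    n_patients: int = 56
    n_measurements: int = 105
    n_male: int = 42
    bw_mean: float = 63.82           # kg
    bw_sd: float = 11.48
    alb_mean: float = 38.9           # g/L, latent only (Model-A clearance)
    alb_sd: float = 6.4
    daily_doses: Tuple[float, ...] = (250, 500, 750, 1000, 1250, 1500, 1750, 2000)
    #: weights concentrated at 1,000 mg so the median matches the published one
    dose_weights: Tuple[float, ...] = (0.06, 0.14, 0.14, 0.36, 0.12, 0.10, 0.05, 0.03)
    genotype_counts: Tuple[Tuple[str, int], ...] = tuple(GENOTYPE_COUNTS.items())
    bsv_cl_cv: float = 0.30          # between-subject clearance variability
    residual_cv: float = 0.20        # residual (measurement) error
    tau: float = 12.0                # trough-like sampling: t = tau = 12 h

    def __post_init__(self) -> None:
        if sum(n for _, n in self.genotype_counts) != self.n_patients:
            raise ValueError("genotype counts must sum to the patient count")
        if self.n_measurements < self.n_patients:
            raise ValueError("need at least one measurement per patient")
        if abs(sum(self.dose_weights) - 1.0) > 1e-9 or \
                len(self.dose_weights) != len(self.daily_doses):
            raise ValueError("dose weights must match doses and sum to 1")


def _variant(genotype: str) -> bool:
    """Collapse diplotypes: any *2 or *3 allele counts as a variant carrier."""
    return genotype != "*1/*1"


def generate_external_cohort(spec: ExternalCohortSpec = ExternalCohortSpec(),
                             seed: int = 0) -> pd.DataFrame:
    """Generate the synthetic TDM records (one row per measurement).

    Columns: patient_id, the 12 simplified features (unscaled), and the
    observed Css.  With both variability CVs set to zero the observed Css
    equals the Model-A analytic value exactly.
    """
    rng = np.random.default_rng([seed, 5])
    n = spec.n_patients

    genotype = np.concatenate([[g] * c for g, c in spec.genotype_counts])
    male = np.zeros(n, dtype=bool)
    male[: spec.n_male] = True
    perm = rng.permutation(n)
    genotype, male = genotype[perm], male[rng.permutation(n)]

    bw = rng.normal(spec.bw_mean, spec.bw_sd, n)
    alb = rng.normal(spec.alb_mean, spec.alb_sd, n)
    while np.any(bw <= 0) or np.any(alb <= 0):
        bw[bw <= 0] = rng.normal(spec.bw_mean, spec.bw_sd, int((bw <= 0).sum()))
        alb[alb <= 0] = rng.normal(spec.alb_mean, spec.alb_sd,
                                   int((alb <= 0).sum()))
    daily = rng.choice(spec.daily_doses, n, p=spec.dose_weights)

    # one measurement each, extras distributed at random (mean 105/56 = 1.88)
    n_meas = np.ones(n, dtype=int)
    extra = rng.choice(n, spec.n_measurements - n, replace=True)
    np.add.at(n_meas, extra, 1)

    rows = []
    for j in range(n):
        geno = "variant" if _variant(genotype[j]) else "wildtype"
        cl_pop = ppk_core.clearance_model_a(alb[j], geno)
        vd = ppk_core.volume_model_a("male" if male[j] else "female")
        eta = rng.normal(0.0, 1.0)
        cl = cl_pop * np.exp(eta * np.sqrt(np.log(1 + spec.bsv_cl_cv ** 2))) \
            if spec.bsv_cl_cv > 0 else cl_pop
        x0 = daily[j] * spec.tau / 24.0
        params = ppk_core.PopPKParams(ka=ppk_core.KA_MODEL_A, F=1.0,
                                      Vd=vd, CL=cl)
        reg = ppk_core.DoseRegimen(X0=x0, tau=spec.tau, t=spec.tau)
        css_true = ppk_core.css_steady_state(params, reg)
        for _ in range(n_meas[j]):
            eps = rng.normal(0.0, 1.0)
            css = css_true * np.exp(
                eps * np.sqrt(np.log(1 + spec.residual_cv ** 2))) \
                if spec.residual_cv > 0 else css_true
            rows.append({
                "patient_id": j,
                "BW": bw[j],
                "Daily Dose": float(daily[j]),
                "CYP2C19*1/*1": 0.0 if _variant(genotype[j]) else 1.0,
                "CYP2C19*2 and/or *3 variants": 1.0 if _variant(genotype[j]) else 0.0,
                "Male": 1.0 if male[j] else 0.0,
                **{f: 0.0 for f in SIMPLIFIED_FEATURES if f.startswith("Co-")},
                TARGET: float(css),
            })
    df = pd.DataFrame(rows)
    return df[["patient_id"] + list(SIMPLIFIED_FEATURES) + [TARGET]]


def evaluate_simplified(bundle: ModelBundle, cohort: pd.DataFrame):
    """Score a simplified-model bundle on a TDM cohort.

    Returns (MetricsReport, per-genotype observed mean/SD frame) — the
    latter supports the wildtype-vs-variant observed-concentration contrast.
    """
    if set(bundle.feature_names) != set(SIMPLIFIED_FEATURES):
        raise ValueError("bundle schema does not match the simplified features")
    preds = bundle.predict_from_raw(cohort[list(bundle.feature_names)])
    report = evaluate(preds, cohort[TARGET].to_numpy())
    group = np.where(cohort["CYP2C19*2 and/or *3 variants"] == 1.0,
                     "variant", "wildtype")
    by_geno = (cohort.assign(genotype=group)
               .groupby("genotype")[TARGET].agg(["mean", "std", "count"]))
    return report, by_geno
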