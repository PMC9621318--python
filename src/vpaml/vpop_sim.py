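"""Monte-Carlo simulation of virtual patient populations.

Dataset-A: 4 scenarios (CYP2C19 wildtype/variant x male/female), 5,000 virtual
patients each, covariates BW ~ N(66.5, 12.1) kg and ALB ~ N(38.9, 6.4) g/L,
concentrations from the Model-A covariate submodel (ka = 2.38 /h).

Dataset-B: 7 co-medication combinations (CBZ, PHT, PB, CBZ+PHT, CBZ+PB,
PHT+PB, CBZ+PHT+PB), 2,000 virtual patients each, BW ~ N(60.2, 12.5) kg,
concentrations from Model-B (ka = 1.90 /h).  Genotype is unknown and
gender/ALB are missing by construction (they are not Model-B covariates).

Both datasets share the dosing design: single dose drawn uniformly from a
15-value lattice, dosing interval tau uniform over {6, 8, 12, 24} h, sampling
time t ~ Uniform(0, tau), and daily dose = X0 * 24 / tau (equal divided
doses).  A retention filter removes records with Css > 150 mg/L to keep the
simulated range compatible with observed therapeutic-drug-monitoring data.

Each dataset gets its own RNG stream derived deterministically from the
config seed, so the two are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ppk_core
from .ppk_core import DoseRegimen, PopPKParams

#: single-dose lattice (mg) and dosing-interval set (h) shared by both designs
DOSE_SET = (125, 250, 300, 350, 400, 450, 500, 550, 600,
            650, 700, 750, 800, 850, 900)
TAU_SET = (6, 8, 12, 24)

#: Dataset-A scenario order: (genotype, gender)
SCENARIOS_A = (("wildtype", "male"), ("wildtype", "female"),
               ("variant", "male"), ("variant", "female"))

#: Dataset-B co-medication combinations, in the published order
COMED_COMBOS_B = (("CBZ",), ("PHT",), ("PB",), ("CBZ", "PHT"),
                  ("CBZ", "PB"), ("PHT", "PB"), ("CBZ", "PHT", "PB"))

BW_A = (66.5, 12.1)   # mean, SD (kg)
ALB_A = (38.9, 6.4)   # mean, SD (g/L)
BW_B = (60.2, 12.5)   # mean, SD (kg)

#: column order of the simulation tables
COLUMNS = ["source", "genotype", "gender", "comeds", "BW", "ALB",
           "single_dose", "tau", "t", "daily_dose", "ka", "Vd", "CL", "css"]


@dataclass(frozen=True)
class SimConfig:
    """Simulation sizes and the concentration retention bound."""

    seed: int = 0
    n_per_scenario_a: int = 5000
    n_per_combo_b: int = 2000
    css_max: float = 150.0

    def __post_init__(self) -> None:
        if self.n_per_scenario_a <= 0 or self.n_per_combo_b <= 0:
            raise ValueError("per-scenario counts must be positive")
        if self.css_max <= 0:
            raise ValueError("css_max must be positive")


def _positive_normal(rng: np.random.Generator, mean: float, sd: float,
                     n: int) -> np.ndarray:
    """Normal draws with non-positive values redrawn (P < 1e-7 at our moments)."""
    x = rng.normal(mean, sd, n)
    while np.any(x <= 0):
        bad = x <= 0
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
    return x


def _draw_regimen(rng: np.random.Generator, n: int):
    x0 = rng.choice(DOSE_SET, n).astype(float)
    tau = rng.choice(TAU_SET, n).astype(float)
    t = rng.uniform(0.0, tau)
    daily = x0 * (24.0 / tau)
    return x0, tau, t, daily


def simulate_dataset_a(config: SimConfig) -> pd.DataFrame:
    """Simulate Dataset-A: 4 genotype x gender scenarios from Model-A."""
    rng = np.random.default_rng([config.seed, 0])
    frames = []
    for genotype, gender in SCENARIOS_A:
        n = config.n_per_scenario_a
        bw = _positive_normal(rng, *BW_A, n)
        alb = _positive_normal(rng, *ALB_A, n)
        x0, tau, t, daily = _draw_regimen(rng, n)
        cl = ppk_core.clearance_model_a(alb, genotype)
        vd = np.full(n, ppk_core.volume_model_a(gender))
        params = PopPKParams(ka=ppk_core.KA_MODEL_A, F=1.0, Vd=vd, CL=cl)
        css = ppk_core.css_steady_state(params, DoseRegimen(x0, tau, t))
        frames.append(pd.DataFrame({
            "source": "A", "genotype": genotype, "gender": gender,
            "comeds": "None", "BW": bw, "ALB": alb, "single_dose": x0,
            "tau": tau, "t": t, "daily_dose": daily,
            "ka": ppk_core.KA_MODEL_A, "Vd": vd, "CL": cl, "css": css,
        }))
    return pd.concat(frames, ignore_index=True)[COLUMNS]


def simulate_dataset_b(config: SimConfig) -> pd.DataFrame:
    """Simulate Dataset-B: 7 co-medication combinations from Model-B."""
    rng = np.random.default_rng([config.seed, 1])
    frames = []
    for combo in COMED_COMBOS_B:
        n = config.n_per_combo_b
        bw = _positive_normal(rng, *BW_B, n)
        x0, tau, t, daily = _draw_regimen(rng, n)
        cl = ppk_core.clearance_model_b(bw, daily, combo)
        vd = ppk_core.volume_model_b(bw)
        params = PopPKParams(ka=ppk_core.KA_MODEL_B, F=1.0, Vd=vd, CL=cl)
        css = ppk_core.css_steady_state(params, DoseRegimen(x0, tau, t))
        frames.append(pd.DataFrame({
            "source": "B", "genotype": "unknown", "gender": np.nan,
            "comeds": "+".join(combo), "BW": bw, "ALB": np.nan,
            "single_dose": x0, "tau": tau, "t": t, "daily_dose": daily,
            "ka": ppk_core.KA_MODEL_B, "Vd": vd, "CL": cl, "css": css,
        }))
    return pd.concat(frames, ignore_index=True)[COLUMNS]


def apply_css_filter(records: pd.DataFrame, css_max: float = 150.0) -> pd.DataFrame:
    """Retain records with Css <= css_max (strict 'higher than' is removed).

    Order is preserved; the index is reset.  Only the upper bound is applied:
    the steady-state equation cannot produce negative concentrations.
    """
    return records.loc[records["css"] <= css_max].reset_index(drop=True)


def simulate_filtered(config: SimConfig):
    """Convenience: both datasets, filtered; returns (a, b) DataFrames."""
    a = apply_css_filter(simulate_dataset_a(config), config.css_max)
    b = apply_css_filter(simulate_dataset_b(config), config.css_max)
    return a, b
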