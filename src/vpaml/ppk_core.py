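"""Analytic one-compartment oral steady-state model for valproic acid.

This module holds the structural pharmacokinetic model and the two published
covariate submodels it is parameterized from:

* **Model-A** — clearance driven by serum albumin (ALB) and CYP2C19 genotype,
  volume of distribution driven by gender; absorption rate fixed at
  ``ka = 2.38 /h``.
* **Model-B** — allometric clearance driven by body weight, total daily dose
  and co-therapy with the enzyme-inducing antiepileptics carbamazepine (CBZ),
  phenytoin (PHT) and phenobarbital (PB); ``Vd = 0.14 * BW``;
  ``ka = 1.90 /h``.

Inter-individual and residual random effects are deliberately excluded: each
virtual patient's parameters are the typical (population) values given their
covariates, so the simulated concentration is a deterministic function of the
covariates and the dosing regimen.

All functions are vectorized over their numeric arguments (plain floats or
NumPy arrays broadcast together); categorical arguments (gender, genotype,
co-medication set) are scalars per call.  Units are fixed: mg, L, h.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np

ArrayLike = Union[float, np.ndarray]

#: absorption rate constants (1/h) fixed by the two source models
KA_MODEL_A = 2.38
KA_MODEL_B = 1.90

#: Model-A volume of distribution (L): 22.15 for females, x e^0.78 for males
VD_FEMALE_A = 22.15
VD_MALE_LOG_FACTOR = 0.78

#: Model-A clearance: 0.64 * (ALB / 38.7)^(-1.06), x e^(-0.45) for CYP2C19
#: *2 and/or *3 variant carriers
CL_BASE_A = 0.64
ALB_REF_A = 38.7
ALB_EXP_A = -1.06
VARIANT_LOG_FACTOR = -0.45

#: Model-B: CL = 0.1 * (BW/60)^0.7 * DailyDose^0.2 * comedication multipliers
CL_BASE_B = 0.1
BW_REF_B = 60.0
BW_EXP_B = 0.7
DOSE_EXP_B = 0.2
COMED_MULTIPLIERS = {"CBZ": 1.36, "PHT": 1.25, "PB": 1.11}

GENDERS = ("male", "female")
GENOTYPES = ("wildtype", "variant")


@dataclass(frozen=True)
class PopPKParams:
    """Structural PK parameters for one (or a vector of) virtual patient(s).

    ka : absorption rate constant (1/h)
    F  : absolute bioavailability (fraction, 1.0 for valproic acid)
    Vd : apparent volume of distribution (L)
    CL : total clearance (L/h)
    """

    ka: ArrayLike
    F: ArrayLike
    Vd: ArrayLike
    CL: ArrayLike

    def __post_init__(self) -> None:
        for name in ("ka", "Vd", "CL"):
            if not np.all(np.asarray(getattr(self, name)) > 0):
                raise ValueError(f"{name} must be strictly positive")
        F = np.asarray(self.F)
        if not (np.all(F > 0) and np.all(F <= 1)):
            raise ValueError("F must lie in (0, 1]")
        if np.any(np.isclose(np.asarray(self.Vd) * np.asarray(self.ka),
                             np.asarray(self.CL))):
            raise ValueError("singular parameter set: Vd*ka == CL")


@dataclass(frozen=True)
class DoseRegimen:
    """Repeated oral dosing: single dose X0 (mg) every tau (h), sampled at t.

    ``t`` is the time since the last dose, 0 <= t <= tau.  Membership of X0
    and tau in the simulation dose lattice is enforced by the simulator, not
    here: the steady-state equation is valid for any positive dose.
    """

    X0: ArrayLike
    tau: ArrayLike
    t: ArrayLike

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.X0) < 0):
            raise ValueError("X0 must be non-negative")
        if not np.all(np.asarray(self.tau) > 0):
            raise ValueError("tau must be strictly positive")
        t, tau = np.asarray(self.t), np.asarray(self.tau)
        if np.any(t < 0) or np.any(t > tau):
            raise ValueError("t must lie in [0, tau]")


def css_steady_state(params: PopPKParams, reg: DoseRegimen) -> ArrayLike:
    """Steady-state concentration (mg/L) at time ``t`` within a dosing interval.

    For first-order absorption and elimination under repeated dosing every
    ``tau`` hours::

        Css = ka*F*X0 / (Vd*ka - CL)
              * [ exp(-CL*t/Vd) / (1 - exp(-CL*tau/Vd))
                  - exp(-ka*t)  / (1 - exp(-ka*tau)) ]

    The value is periodic in ``t`` with period ``tau`` (trough at t=0 equals
    trough at t=tau) and non-negative throughout the interval.
    """
    ka, F, Vd, CL = (np.asarray(x, dtype=float)
                     for x in (params.ka, params.F, params.Vd, params.CL))
    X0, tau, t = (np.asarray(x, dtype=float)
                  for x in (reg.X0, reg.tau, reg.t))
    ke = CL / Vd  # elimination rate constant (1/h)
    prefactor = ka * F * X0 / (Vd * ka - CL)
    accumulation = (np.exp(-ke * t) / -np.expm1(-ke * tau)
                    - np.exp(-ka * t) / -np.expm1(-ka * tau))
    out = prefactor * accumulation
    return float(out) if out.ndim == 0 else out


def clearance_model_a(ALB: ArrayLike, genotype: str) -> ArrayLike:
    """Model-A clearance (L/h) from serum albumin (g/L) and CYP2C19 genotype.

    CL = 0.64 * (ALB/38.7)^(-1.06), reduced by e^(-0.45) in carriers of the
    loss-of-function *2 and/or *3 alleles ("variant"); Model-A requires a
    known genotype.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"Model-A requires genotype in {GENOTYPES}, "
                         f"got {genotype!r}")
    ALB = np.asarray(ALB, dtype=float)
    if not np.all(ALB > 0):
        raise ValueError("ALB must be strictly positive")
    cl = CL_BASE_A * (ALB / ALB_REF_A) ** ALB_EXP_A
    if genotype == "variant":
        cl = cl * np.exp(VARIANT_LOG_FACTOR)
    return float(cl) if cl.ndim == 0 else cl


def volume_model_a(gender: str) -> float:
    """Model-A volume of distribution (L): 22.15 (female), 22.15*e^0.78 (male)."""
    if gender not in GENDERS:
        raise ValueError(f"Model-A requires gender in {GENDERS}, got {gender!r}")
    vd = VD_FEMALE_A
    if gender == "male":
        vd *= np.exp(VD_MALE_LOG_FACTOR)
    return float(vd)


def clearance_model_b(BW: ArrayLike, daily_dose: ArrayLike,
                      comeds: Iterable[str] = ()) -> ArrayLike:
    """Model-B clearance (L/h) from body weight, daily dose and co-medication.

    CL = 0.1 * (BW/60)^0.7 * DailyDose^0.2, multiplied by 1.36 / 1.25 / 1.11
    for co-therapy with CBZ / PHT / PB respectively (multiplicative and
    order-independent).
    """
    comeds = frozenset(comeds)
    unknown = comeds - COMED_MULTIPLIERS.keys()
    if unknown:
        raise ValueError(f"unknown co-medication(s): {sorted(unknown)}")
    BW = np.asarray(BW, dtype=float)
    dd = np.asarray(daily_dose, dtype=float)
    if not np.all(BW > 0):
        raise ValueError("BW must be strictly positive")
    if not np.all(dd > 0):
        raise ValueError("daily_dose must be strictly positive")
    cl = CL_BASE_B * (BW / BW_REF_B) ** BW_EXP_B * dd ** DOSE_EXP_B
    for drug in comeds:
        cl = cl * COMED_MULTIPLIERS[drug]
    return float(cl) if cl.ndim == 0 else cl


def volume_model_b(BW: ArrayLike) -> ArrayLike:
    """Model-B volume of distribution (L): 0.14 * BW."""
    BW = np.asarray(BW, dtype=float)
    if not np.all(BW > 0):
        raise ValueError("BW must be strictly positive")
    vd = 0.14 * BW
    return float(vd) if vd.ndim == 0 else vd


def steady_state_auc_analytic(X0: ArrayLike, F: ArrayLike,
                              CL: ArrayLike) -> ArrayLike:
    """Closed-form steady-state AUC over one dosing interval: F*X0/CL (mg.h/L).

    At steady state the amount absorbed per interval equals the amount
    eliminated, so the integral of Css over [0, tau] is F*X0/CL regardless of
    ka, Vd or tau.  Serves as the independent oracle for the trapezoidal
    integrator and the simulator.
    """
    CL = np.asarray(CL, dtype=float)
    if not np.all(CL > 0):
        raise ValueError("CL must be strictly positive")
    out = np.asarray(F, dtype=float) * np.asarray(X0, dtype=float) / CL
    return float(out) if out.ndim == 0 else out
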