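"""Analytic one-compartment model and the two covariate submodels."""

import math

import numpy as np
import pytest

from vpaml import ppk_core
from vpaml.ppk_core import (DoseRegimen, PopPKParams, clearance_model_a,
                            clearance_model_b, css_steady_state,
                            steady_state_auc_analytic, volume_model_a,
                            volume_model_b)

REF_A_FEMALE = dict(ka=2.38, F=1.0, Vd=22.15, CL=0.64)


def _css_oracle(ka, F, Vd, CL, X0, tau, t):
    """Independent term-by-term evaluation of the steady-state equation."""
    pre = ka * F * X0 / (Vd * ka - CL)
    acc = (math.exp(-CL * t / Vd) / (1 - math.exp(-CL * tau / Vd))
           - math.exp(-ka * t) / (1 - math.exp(-ka * tau)))
    return pre * acc


class TestCssSteadyState:
    def test_zero_dose_gives_zero(self):
        params = PopPKParams(**REF_A_FEMALE)
        assert css_steady_state(params, DoseRegimen(0.0, 12.0, 2.0)) == 0.0

    def test_reference_regimen_matches_term_by_term_evaluation(self):
        # 500 mg every 12 h, sampled 2 h post dose, Model-A female wildtype
        params = PopPKParams(**REF_A_FEMALE)
        value = css_steady_state(params, DoseRegimen(500.0, 12.0, 2.0))
        oracle = _css_oracle(2.38, 1.0, 22.15, 0.64, 500.0, 12.0, 2.0)
        assert value == pytest.approx(oracle, rel=1e-12)
        assert value == pytest.approx(73.4, abs=0.05)

    def test_periodicity_trough_equals_next_trough(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            params = PopPKParams(ka=rng.uniform(0.5, 3.0), F=1.0,
                                 Vd=rng.uniform(5.0, 60.0),
                                 CL=rng.uniform(0.1, 1.5))
            tau = float(rng.choice([6.0, 8.0, 12.0, 24.0]))
            x0 = float(rng.choice([125.0, 500.0, 900.0]))
            c0 = css_steady_state(params, DoseRegimen(x0, tau, 0.0))
            c1 = css_steady_state(params, DoseRegimen(x0, tau, tau))
            assert c0 == pytest.approx(c1, rel=1e-9)

    def test_nonnegative_over_interval(self):
        params = PopPKParams(**REF_A_FEMALE)
        t = np.linspace(0.0, 12.0, 501)
        c = css_steady_state(params, DoseRegimen(500.0, 12.0, t))
        assert np.all(c >= 0)

    def test_mean_value_identity_integral_equals_analytic_auc(self):
        # (1/tau) * integral of Css = F*X0/(CL*tau) on fine grids
        rng = np.random.default_rng(12)
        for _ in range(100):
            ka = rng.uniform(0.5, 3.0)
            vd = rng.uniform(5.0, 60.0)
            cl = rng.uniform(0.1, 1.5)
            tau = float(rng.choice([6.0, 8.0, 12.0, 24.0]))
            x0 = float(rng.choice([125.0, 500.0, 900.0]))
            params = PopPKParams(ka=ka, F=1.0, Vd=vd, CL=cl)
            t = np.linspace(0.0, tau, 10001)
            auc = np.trapezoid(
                css_steady_state(params, DoseRegimen(x0, tau, t)), t)
            assert auc == pytest.approx(steady_state_auc_analytic(x0, 1.0, cl),
                                        rel=1e-6)

    def test_monotone_increasing_in_dose(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            params = PopPKParams(ka=rng.uniform(0.5, 3.0), F=1.0,
                                 Vd=rng.uniform(5.0, 60.0),
                                 CL=rng.uniform(0.1, 1.5))
            tau = 12.0
            t = rng.uniform(0.0, tau)
            lo = css_steady_state(params, DoseRegimen(250.0, tau, t))
            hi = css_steady_state(params, DoseRegimen(500.0, tau, t))
            assert hi > lo

    def test_monotone_decreasing_in_clearance_accumulation_regime(self):
        # with ka*tau >> 1 the accumulation term is clearance-dominated
        rng = np.random.default_rng(14)
        for _ in range(100):
            tau = 24.0
            ka = rng.uniform(0.5, 3.0)
            if ka * tau <= 10:
                continue
            vd = rng.uniform(5.0, 60.0)
            cl = rng.uniform(0.1, 1.2)
            t = rng.uniform(0.0, tau)
            c_lo = css_steady_state(PopPKParams(ka, 1.0, vd, cl),
                                    DoseRegimen(500.0, tau, t))
            c_hi = css_steady_state(PopPKParams(ka, 1.0, vd, cl * 1.2),
                                    DoseRegimen(500.0, tau, t))
            assert c_hi < c_lo

    def test_peak_time_between_one_and_two_hours(self):
        # dense grid argmax for the Model-A reference parameter set
        params = PopPKParams(**REF_A_FEMALE)
        t = np.linspace(0.0, 12.0, 20001)
        c = css_steady_state(params, DoseRegimen(500.0, 12.0, t))
        assert 1.0 <= t[np.argmax(c)] <= 2.0

    def test_singular_and_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            PopPKParams(ka=1.0, F=1.0, Vd=2.0, CL=2.0)
        with pytest.raises(ValueError):
            PopPKParams(ka=-1.0, F=1.0, Vd=2.0, CL=0.5)
        with pytest.raises(ValueError):
            PopPKParams(ka=1.0, F=1.5, Vd=2.0, CL=0.5)
        with pytest.raises(ValueError):
            DoseRegimen(500.0, 12.0, 13.0)  # t beyond tau

    def test_covariate_submodels_never_reach_singularity(self):
        # Vd*ka stays far above CL across extreme covariate combinations
        for alb in (5.0, 38.7, 80.0):
            for geno in ("wildtype", "variant"):
                cl = clearance_model_a(alb, geno)
                assert ppk_core.VD_FEMALE_A * ppk_core.KA_MODEL_A > 2 * cl
        for bw in (20.0, 60.0, 150.0):
            for dd in (125.0, 3600.0):
                cl = clearance_model_b(bw, dd, ("CBZ", "PHT", "PB"))
                assert volume_model_b(bw) * ppk_core.KA_MODEL_B > 2 * cl


class TestCovariateSubmodels:
    @pytest.mark.parametrize("alb, genotype, expected", [
        (38.7, "wildtype", 0.64),
        (38.7, "variant", 0.64 * math.exp(-0.45)),       # 0.40808
        (30.0, "wildtype", 0.64 * (30 / 38.7) ** -1.06),  # 0.8383
    ])
    def test_clearance_model_a(self, alb, genotype, expected):
        assert clearance_model_a(alb, genotype) == pytest.approx(expected,
                                                                 rel=1e-12)

    def test_clearance_model_a_reference_magnitudes(self):
        assert clearance_model_a(38.7, "variant") == pytest.approx(0.40808,
                                                                   abs=1e-5)
        assert clearance_model_a(30.0, "wildtype") == pytest.approx(0.8383,
                                                                    abs=1e-4)

    def test_clearance_model_a_requires_genotype(self):
        with pytest.raises(ValueError):
            clearance_model_a(38.7, "unknown")
        with pytest.raises(ValueError):
            clearance_model_a(-1.0, "wildtype")

    def test_volume_model_a(self):
        assert volume_model_a("female") == 22.15
        assert volume_model_a("male") == pytest.approx(48.32, abs=0.01)
        assert volume_model_a("male") / volume_model_a("female") == \
            pytest.approx(math.exp(0.78), rel=1e-12)
        with pytest.raises(ValueError):
            volume_model_a("missing")

    def test_clearance_model_b(self):
        base = clearance_model_b(60.0, 1000.0)
        assert base == pytest.approx(0.1 * 1000 ** 0.2, rel=1e-12)  # 0.39811
        assert base == pytest.approx(0.39811, abs=1e-5)
        full = clearance_model_b(60.0, 1000.0, ("CBZ", "PHT", "PB"))
        assert full == pytest.approx(base * 1.36 * 1.25 * 1.11, rel=1e-12)
        assert clearance_model_b(60.0, 1000.0, ("CBZ",)) == \
            pytest.approx(base * 1.36, rel=1e-12)
        # multipliers commute
        assert clearance_model_b(70.0, 500.0, ("PB", "CBZ")) == \
            pytest.approx(clearance_model_b(70.0, 500.0, ("CBZ", "PB")),
                          rel=1e-15)
        with pytest.raises(ValueError):
            clearance_model_b(60.0, 1000.0, ("CBZ", "VPA"))

    def test_volume_model_b_linear_in_weight(self):
        assert volume_model_b(60.0) == pytest.approx(8.4)
        assert volume_model_b(100.0) == pytest.approx(14.0)
        assert volume_model_b(144.0) == pytest.approx(2 * volume_model_b(72.0))


class TestAnalyticAuc:
    def test_reference_value(self):
        assert steady_state_auc_analytic(500.0, 1.0, 0.64) == \
            pytest.approx(781.25)
        assert steady_state_auc_analytic(0.0, 1.0, 0.64) == 0.0

    def test_matches_quadrature_of_concentration_curve(self):
        params = PopPKParams(**REF_A_FEMALE)
        t = np.linspace(0.0, 12.0, 10001)
        auc = np.trapezoid(css_steady_state(params, DoseRegimen(500.0, 12.0, t)),
                           t)
        assert auc == pytest.approx(781.25, rel=1e-6)

    def test_rejects_nonpositive_clearance(self):
        with pytest.raises(ValueError):
            steady_state_auc_analytic(500.0, 1.0, 0.0)
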