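"""Shared fixtures.

``small_*`` fixtures run a scaled-down simulation (4 x 400 + 7 x 160 virtual
patients) for fast unit tests.  ``full_run`` executes the complete pipeline
once per session at the published study sizes (20,000 + 14,000 patients,
10-fold CV of all seven regressors) and is shared by the acceptance tests
and the stochastic ranking/ordering checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from vpaml import exposure, fusion, interpret, ml_bench, vpop_sim
from vpaml.fusion import FeatureTable, SIMPLIFIED_DROP
from vpaml.ml_bench import ModelBundle, ModelSpec
from vpaml.vpop_sim import SimConfig

SMALL_CONFIG = SimConfig(seed=7, n_per_scenario_a=400, n_per_combo_b=160)


@pytest.fixture(scope="session")
def small_sim():
    return vpop_sim.simulate_filtered(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_table(small_sim) -> FeatureTable:
    a, b = small_sim
    return fusion.build_feature_table(a, b, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_table) -> ModelBundle:
    return ml_bench.fit_final(small_table, ModelSpec("xgboost"), seed=7)


@pytest.fixture(scope="session")
def small_simplified_bundle(small_table) -> ModelBundle:
    simplified = ml_bench.ablate(small_table, SIMPLIFIED_DROP)
    return ml_bench.fit_final(simplified, ModelSpec("xgboost"), seed=7)


@dataclass
class FullRun:
    seed: int
    n_a_raw: int
    n_b_raw: int
    a: pd.DataFrame
    b: pd.DataFrame
    table: FeatureTable
    cv: pd.DataFrame
    bundle: ModelBundle
    bundle_simplified: ModelBundle
    metrics_full: ml_bench.MetricsReport
    metrics_simplified: ml_bench.MetricsReport
    importance: pd.Series
    scenario_results: list
    scenario_summary: dict


@pytest.fixture(scope="session")
def full_run() -> FullRun:
    seed = 0
    cfg = SimConfig(seed=seed)
    a_raw = vpop_sim.simulate_dataset_a(cfg)
    b_raw = vpop_sim.simulate_dataset_b(cfg)
    a = vpop_sim.apply_css_filter(a_raw, cfg.css_max)
    b = vpop_sim.apply_css_filter(b_raw, cfg.css_max)
    table = fusion.build_feature_table(a, b, seed=seed)

    X, y = table.derivation
    specs = [ModelSpec(name) for name in ml_bench.MODEL_REGISTRY]
    cv = ml_bench.crossval_compare(X, y, specs, folds=10, seed=seed)

    bundle = ml_bench.fit_final(table, ModelSpec("xgboost"), seed=seed)
    simplified = ml_bench.ablate(table, SIMPLIFIED_DROP)
    bundle_simplified = ml_bench.fit_final(simplified, ModelSpec("xgboost"),
                                           seed=seed)
    Xv, yv = table.validation
    metrics_full = ml_bench.evaluate(bundle.predict(Xv), yv.to_numpy())
    Xvs, yvs = simplified.validation
    metrics_simplified = ml_bench.evaluate(bundle_simplified.predict(Xvs),
                                           yvs.to_numpy())

    background = interpret.subsample_background(X, 128, seed=seed)
    rng = np.random.default_rng([seed, 8])
    rows = X.iloc[rng.choice(len(X), 400, replace=False)]
    attr = interpret.attribute(bundle, rows, background)
    importance = interpret.global_importance(attr)

    results, summary = exposure.run_scenarios(bundle, seed=seed)

    return FullRun(seed=seed, n_a_raw=len(a_raw), n_b_raw=len(b_raw), a=a,
                   b=b, table=table, cv=cv, bundle=bundle,
                   bundle_simplified=bundle_simplified,
                   metrics_full=metrics_full,
                   metrics_simplified=metrics_simplified,
                   importance=importance, scenario_results=results,
                   scenario_summary=summary)
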