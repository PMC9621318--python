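"""End-to-end orchestration: each stage reads upstream artifacts, writes its
own, and logs one structured line with row counts, seed and timing.

Artifact layout under the output directory::

    dataset_a.csv / dataset_b.csv      filtered simulation tables
    simulation_summary.json            pre/post-filter counts
    features.csv                       fused 16-feature table + Css + split
    scaler.json                        min-max bounds
    bundle_full/ bundle_simplified/    ModelBundle directories
    cv_report.csv                      10-fold CV model comparison
    metrics.json                       validation metrics, full + simplified
    shap_importance.json               global mean-|phi| ranking
    attributions.csv                   per-sample Shapley matrix
    exposure_per_patient.csv           per-patient AUC and average Css
    exposure_summary.json              cohort mean +/- SD per scenario + ratio
    external_cohort.csv                synthetic TDM records
    external_metrics.json              simplified-model metrics on that cohort
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path


import numpy as np
import pandas as pd

from . import exposure, external_cohort, fusion, interpret, ml_bench, vpop_sim
from .config import PipelineConfig
from .fusion import FeatureTable, ScalerSpec, SIMPLIFIED_DROP
from .ml_bench import ModelBundle, ModelSpec

log = logging.getLogger("vpaml")

STAGES = ("simulate", "fuse", "train", "evaluate", "explain", "scenarios",
          "external")


def _stamp(outdir: Path, cfg: PipelineConfig) -> None:
    (outdir / "run_info.json").write_text(json.dumps(
        {"seed": cfg.seed, "config_hash": cfg.config_hash(),
         "config": cfg.model_dump(mode="json")}, indent=1))


def _log(stage: str, start: float, **counts) -> None:
    extras = " ".join(f"{k}={v}" for k, v in counts.items())
    log.info("stage=%s elapsed=%.1fs %s", stage, time.time() - start, extras)


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    t0 = time.time()
    sim_cfg = vpop_sim.SimConfig(seed=cfg.seed,
                                 n_per_scenario_a=cfg.sim.n_per_scenario_a,
                                 n_per_combo_b=cfg.sim.n_per_combo_b,
                                 css_max=cfg.sim.css_max)
    a_raw = vpop_sim.simulate_dataset_a(sim_cfg)
    b_raw = vpop_sim.simulate_dataset_b(sim_cfg)
    a = vpop_sim.apply_css_filter(a_raw, sim_cfg.css_max)
    b = vpop_sim.apply_css_filter(b_raw, sim_cfg.css_max)
    a.to_csv(outdir / "dataset_a.csv", index=False)
    b.to_csv(outdir / "dataset_b.csv", index=False)
    (outdir / "simulation_summary.json").write_text(json.dumps({
        "seed": cfg.seed, "config_hash": cfg.config_hash(),
        "n_a_simulated": len(a_raw), "n_a_retained": len(a),
        "n_b_simulated": len(b_raw), "n_b_retained": len(b),
        "n_merged": len(a) + len(b),
    }, indent=1))
    _log("simulate", t0, a=len(a), b=len(b))


def _load_table(outdir: Path) -> FeatureTable:
    df = pd.read_csv(outdir / "features.csv")
    scaler = ScalerSpec.from_json((outdir / "scaler.json").read_text())
    split = df.pop("split")
    return FeatureTable(df=df, scaler=scaler, split=split)


def stage_fuse(cfg: PipelineConfig, outdir: Path) -> None:
    t0 = time.time()
    # keep_default_na=False: the co-medication level "None" is a real
    # category, not a missing value; blanks still read as NaN
    read = lambda p: pd.read_csv(p, keep_default_na=False, na_values=[""])
    a = read(outdir / "dataset_a.csv")
    b = read(outdir / "dataset_b.csv")
    table = fusion.build_feature_table(
        a, b, k=cfg.fusion.k_neighbors, seed=cfg.seed,
        fraction=cfg.fusion.split_fraction, scaler_mode=cfg.fusion.scaler_mode,
        impute_include_css=cfg.fusion.impute_include_css)
    out = table.df.copy()
    out["split"] = table.split
    out.to_csv(outdir / "features.csv", index=False)
    (outdir / "scaler.json").write_text(table.scaler.to_json())
    _log("fuse", t0, rows=len(out))


def stage_train(cfg: PipelineConfig, outdir: Path) -> None:
    t0 = time.time()
    table = _load_table(outdir)
    specs = [ModelSpec(name) for name in cfg.training.models]
    X, y = table.derivation
    cv = ml_bench.crossval_compare(X, y, specs, folds=cfg.training.folds,
                                   seed=cfg.seed)
    cv.to_csv(outdir / "cv_report.csv", index=False)
    final_spec = ModelSpec(cfg.training.final_model,
                           dict(cfg.training.hyperparams))
    bundle = ml_bench.fit_final(table, final_spec, seed=cfg.seed)
    bundle.save(outdir / "bundle_full")
    simplified = ml_bench.ablate(table, SIMPLIFIED_DROP)
    ml_bench.fit_final(simplified, final_spec, seed=cfg.seed).save(
        outdir / "bundle_simplified")
    _log("train", t0, best=cv.iloc[0]["model"])


def stage_evaluate(cfg: PipelineConfig, outdir: Path) -> None:
    t0 = time.time()
    table = _load_table(outdir)
    Xv, yv = table.validation
    metrics = {}
    for name, drop in (("full", ()), ("simplified", SIMPLIFIED_DROP)):
        bundle = ModelBundle.load(outdir / f"bundle_{name}")
        keep = [f for f in table.feature_names if f not in set(drop)]
        preds = bundle.predict(Xv[keep])
        metrics[name] = ml_bench.evaluate(preds, yv.to_numpy()).as_dict()
        metrics[name]["n"] = int(len(yv))
    (outdir / "metrics.json").write_text(json.dumps(
        {"seed": cfg.seed, "config_hash": cfg.config_hash(), **metrics},
        indent=1))
    _log("evaluate", t0, **{k: round(v["mae"], 2) for k, v in metrics.items()})


def stage_explain(cfg: PipelineConfig, outdir: Path) -> None:
    t0 = time.time()
    table = _load_table(outdir)
    bundle = ModelBundle.load(outdir / "bundle_full")
    Xd, _ = table.derivation
    background = interpret.subsample_background(
        Xd, cfg.interpret.background_size, seed=cfg.seed)
    rng = np.random.default_rng([cfg.seed, 6])
    rows = Xd.iloc[rng.choice(len(Xd), min(cfg.interpret.n_samples, len(Xd)),
                              replace=False)]
    attr = interpret.attribute(bundle, rows, background)
    attr.to_frame().to_csv(outdir / "attributions.csv", index=False)
    importance = interpret.global_importance(attr)
    (outdir / "shap_importance.json").write_text(json.dumps({
        "seed": cfg.seed, "config_hash": cfg.config_hash(),
        "base_value": attr.base_value,
        "ranking": [{"feature": f, "mean_abs_phi": float(v)}
                    for f, v in importance.items()],
    }, indent=1))
    _log("explain", t0, top=importance.index[0])


def stage_scenarios(cfg: PipelineConfig, outdir: Path) -> None:
    t0 = time.time()
    bundle = ModelBundle.load(outdir / "bundle_full")
    specs = exposure.default_scenarios(cfg.scenarios.n_patients,
                                      cfg.scenarios.n_times)
    results, summary = exposure.run_scenarios(bundle, specs, seed=cfg.seed)
    pd.concat([r.per_patient.assign(scenario=r.name) for r in results],
              ignore_index=True).to_csv(
        outdir / "exposure_per_patient.csv", index=False)
    (outdir / "exposure_summary.json").write_text(json.dumps(
        {"seed": cfg.seed, "config_hash": cfg.config_hash(), **summary},
        indent=1))
    _log("scenarios", t0,
         ratio=round(summary["auc_ratio_scenario3_vs_scenario2"], 3))


def stage_external(cfg: PipelineConfig, outdir: Path) -> None:
    t0 = time.time()
    spec = external_cohort.ExternalCohortSpec(
        bsv_cl_cv=cfg.external.bsv_cl_cv,
        residual_cv=cfg.external.residual_cv)
    cohort = external_cohort.generate_external_cohort(spec, seed=cfg.seed)
    cohort.to_csv(outdir / "external_cohort.csv", index=False)
    bundle = ModelBundle.load(outdir / "bundle_simplified")
    report, by_geno = external_cohort.evaluate_simplified(bundle, cohort)
    (outdir / "external_metrics.json").write_text(json.dumps({
        "seed": cfg.seed, "config_hash": cfg.config_hash(),
        "metrics": report.as_dict(),
        "observed_by_genotype": by_geno.to_dict(orient="index"),
    }, indent=1))
    _log("external", t0, mae=round(report.mae, 2))


_STAGE_FN = {
    "simulate": stage_simulate, "fuse": stage_fuse, "train": stage_train,
    "evaluate": stage_evaluate, "explain": stage_explain,
    "scenarios": stage_scenarios, "external": stage_external,
}

_UPSTREAM = {
    "fuse": ["dataset_a.csv", "dataset_b.csv"],
    "train": ["features.csv", "scaler.json"],
    "evaluate": ["features.csv", "bundle_full", "bundle_simplified"],
    "explain": ["features.csv", "bundle_full"],
    "scenarios": ["bundle_full"],
    "external": ["bundle_simplified"],
}


def run(command: str, cfg: PipelineConfig, outdir) -> None:
    """Run one stage or the whole chain; validates upstream artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _stamp(outdir, cfg)
    stages = STAGES if command == "all" else (command,)
    for stage in stages:
        if stage not in _STAGE_FN:
            raise ValueError(f"unknown stage {stage!r}")
        for artifact in _UPSTREAM.get(stage, []):
            if not (outdir / artifact).exists():
                raise FileNotFoundError(
                    f"stage {stage!r} needs missing upstream artifact "
                    f"{artifact!r}; run earlier stages first")
        _STAGE_FN[stage](cfg, outdir)


def predict(bundle_dir, input_csv, output_csv) -> pd.DataFrame:
    """Score a user CSV of raw feature rows with a saved bundle.

    The CSV must contain the bundle's feature columns on the raw (unscaled)
    scale; rows violating the schema are reported with their indices.
    """
    bundle = ModelBundle.load(bundle_dir)
    df = pd.read_csv(input_csv)
    missing = set(bundle.feature_names) - set(df.columns)
    if missing:
        raise ValueError(f"input lacks column(s) {sorted(missing)}")
    bad = df[list(bundle.feature_names)].isna().any(axis=1)
    if bad.any():
        raise ValueError("rows with missing feature values: "
                         f"{list(df.index[bad])[:20]}")
    out = df.copy()
    out["predicted_css"] = bundle.predict_from_raw(df)
    out.to_csv(output_csv, index=False)
    return out
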