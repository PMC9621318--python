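"""Benchmarking, training and evaluation of concentration regressors.

Seven regressors are compared by 10-fold cross-validated mean absolute error
on the derivation cohort: XGBoost-style gradient-boosted trees, random
forest, bagging, (sklearn) gradient boosting, a single decision tree,
AdaBoost, and multiple linear regression — each with its implementation's
default hyperparameters unless overridden.

Evaluation metrics (concentration units mg/L):

* MAE  = mean |pred - actual|
* RMSE = sqrt(mean (pred - actual)^2)
* MRE  = mean (pred - actual)/actual * 100   (signed: measures bias)
* IR   = 100 * fraction of predictions with |pred - actual|/actual <= 0.20
         (the "ideal rate": share within +/-20% of the actual value)
"""

from __future__ import annotations

import itertools
import json
import math
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Sequence, Tuple

import joblib
import numpy as np
import pandas as pd
import sklearn
import xgboost
from sklearn.ensemble import (AdaBoostRegressor, BaggingRegressor,
                              GradientBoostingRegressor, RandomForestRegressor)
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

from .fusion import FeatureTable, ScalerSpec, TARGET


def _make_xgb(seed: int, **hp):
    hp.setdefault("random_state", seed)
    hp.setdefault("n_jobs", 1)  # reproducibility; CPU budget is one core
    return xgboost.XGBRegressor(**hp)


#: registry of the seven benchmark regressors
MODEL_REGISTRY = {
    "xgboost": _make_xgb,
    "random_forest": lambda seed, **hp: RandomForestRegressor(
        random_state=seed, **hp),
    "bagging": lambda seed, **hp: BaggingRegressor(random_state=seed, **hp),
    "gradient_boosting": lambda seed, **hp: GradientBoostingRegressor(
        random_state=seed, **hp),
    "decision_tree": lambda seed, **hp: DecisionTreeRegressor(
        random_state=seed, **hp),
    "adaboost": lambda seed, **hp: AdaBoostRegressor(random_state=seed, **hp),
    "linear": lambda seed, **hp: LinearRegression(**hp),
}


@dataclass(frozen=True)
class ModelSpec:
    """A named regressor plus hyperparameter overrides (empty = defaults)."""

    name: str
    hyperparams: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in MODEL_REGISTRY:
            raise ValueError(f"unknown model {self.name!r}; choose from "
                             f"{sorted(MODEL_REGISTRY)}")

    def build(self, seed: int):
        return MODEL_REGISTRY[self.name](seed, **self.hyperparams)


@dataclass(frozen=True)
class MetricsReport:
    """The four printed evaluation metrics."""

    mae: float    # mg/L
    rmse: float   # mg/L
    mre: float    # %, signed
    ir: float     # %, share of predictions within +/-20% of actual

    def as_dict(self) -> Dict[str, float]:
        return asdict(self)


def evaluate(predicted: np.ndarray, actual: np.ndarray) -> MetricsReport:
    """Compute MAE, RMSE, signed MRE and IR for a prediction vector."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape or predicted.ndim != 1:
        raise ValueError("predicted and actual must be equal-length 1-D arrays")
    if predicted.size == 0:
        raise ValueError("empty input")
    if np.any(actual <= 0):
        raise ValueError("actual values must be positive for relative metrics")
    err = predicted - actual
    rel = err / actual
    return MetricsReport(
        mae=float(np.mean(np.abs(err))),
        rmse=float(np.sqrt(np.mean(err ** 2))),
        mre=float(np.mean(rel) * 100.0),
        ir=float(np.mean(np.abs(rel) <= 0.20) * 100.0),
    )


def crossval_compare(X: pd.DataFrame, y: pd.Series,
                     specs: Sequence[ModelSpec], folds: int = 10,
                     seed: int = 0) -> pd.DataFrame:
    """K-fold CV MAE comparison on the derivation cohort.

    For each model and fold, fit on the other folds and score MAE on both the
    held-out fold and the training folds.  Returns one row per model with
    fold means and normal-approximation 95% CI half-widths (1.96 * SD/sqrt(K)),
    sorted ascending by test MAE.
    """
    if len(X) < folds:
        raise ValueError("fewer rows than folds")
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(Xv))
    rows = []
    for spec in specs:
        train_mae, test_mae = [], []
        for tr, te in splits:
            model = spec.build(seed)
            model.fit(Xv[tr], yv[tr])
            train_mae.append(float(np.mean(np.abs(model.predict(Xv[tr]) - yv[tr]))))
            test_mae.append(float(np.mean(np.abs(model.predict(Xv[te]) - yv[te]))))
        rows.append({
            "model": spec.name,
            "train_mae": float(np.mean(train_mae)),
            "train_mae_ci95": float(1.96 * np.std(train_mae, ddof=1) / math.sqrt(folds)),
            "test_mae": float(np.mean(test_mae)),
            "test_mae_ci95": float(1.96 * np.std(test_mae, ddof=1) / math.sqrt(folds)),
        })
    return (pd.DataFrame(rows)
            .sort_values("test_mae", kind="stable")
            .reset_index(drop=True))


@dataclass
class ModelBundle:
    """The unit shipped between training, interpretation and exposure stages.

    Holds the trained regressor together with the scaler and ordered feature
    schema it was trained under, plus seed/version metadata, so downstream
    stages cannot silently feed it inconsistently prepared inputs.
    """

    model: object
    model_name: str
    feature_names: Tuple[str, ...]
    scaler: ScalerSpec
    seed: int
    hyperparams: Dict[str, object] = field(default_factory=dict)
    versions: Dict[str, str] = field(default_factory=dict)

    def _check(self, X: pd.DataFrame) -> np.ndarray:
        missing = set(self.feature_names) - set(X.columns)
        if missing:
            raise ValueError(f"input lacks feature(s) {sorted(missing)}")
        return X[list(self.feature_names)].to_numpy(dtype=float)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predict Css (mg/L) from an already-scaled feature frame."""
        return np.asarray(self.model.predict(self._check(X)), dtype=float)

    def predict_from_raw(self, X: pd.DataFrame) -> np.ndarray:
        """Predict from unscaled features: applies the stored scaler first."""
        return self.predict(self.scaler.transform(X))

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        if isinstance(self.model, xgboost.XGBRegressor):
            # save at booster level: the sklearn-wrapper save path expects
            # estimator-type tags that newer sklearn no longer defines
            self.model.get_booster().save_model(path / "model.json")
            model_file = "model.json"
        else:
            joblib.dump(self.model, path / "model.joblib")
            model_file = "model.joblib"
        (path / "scaler.json").write_text(self.scaler.to_json())
        meta = {
            "model_name": self.model_name,
            "model_file": model_file,
            "feature_names": list(self.feature_names),
            "seed": self.seed,
            "hyperparams": {k: v for k, v in self.hyperparams.items()
                            if isinstance(v, (int, float, str, bool, type(None)))},
            "versions": self.versions,
        }
        (path / "metadata.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "ModelBundle":
        path = Path(path)
        meta = json.loads((path / "metadata.json").read_text())
        if meta["model_file"].endswith(".json"):
            model = xgboost.XGBRegressor()
            model.load_model(path / meta["model_file"])
        else:
            model = joblib.load(path / meta["model_file"])
        return cls(model=model, model_name=meta["model_name"],
                   feature_names=tuple(meta["feature_names"]),
                   scaler=ScalerSpec.from_json((path / "scaler.json").read_text()),
                   seed=meta["seed"], hyperparams=meta["hyperparams"],
                   versions=meta["versions"])


def fit_final(table: FeatureTable, spec: ModelSpec, seed: int = 0) -> ModelBundle:
    """Train a final model on the derivation cohort and package it."""
    X, y = table.derivation
    model = spec.build(seed)
    model.fit(X.to_numpy(dtype=float), y.to_numpy(dtype=float))
    return ModelBundle(
        model=model, model_name=spec.name,
        feature_names=tuple(table.feature_names), scaler=table.scaler,
        seed=seed, hyperparams=dict(model.get_params()),
        versions={"python": platform.python_version(),
                  "sklearn": sklearn.__version__,
                  "xgboost": xgboost.__version__},
    )


def ablate(table: FeatureTable, drop: Sequence[str]) -> FeatureTable:
    """Drop named features (rows and target unchanged) for a simplified model."""
    unknown = set(drop) - set(table.feature_names)
    if unknown:
        raise ValueError(f"unknown feature(s): {sorted(unknown)}")
    kept = tuple(f for f in table.feature_names if f not in set(drop))
    return FeatureTable(df=table.df[list(kept) + [TARGET]], scaler=table.scaler,
                        split=table.split, feature_names=kept)


def grid_search(X: pd.DataFrame, y: pd.Series, grid: Dict[str, Sequence],
                folds: int = 10, seed: int = 0,
                model_name: str = "xgboost") -> Tuple[ModelSpec, pd.DataFrame]:
    """Exhaustive lattice search minimizing mean K-fold CV MAE.

    Ties are broken by lexicographic order of the lattice (keys sorted,
    candidate values iterated in the given order, first strict minimum
    wins).  Returns the winning ModelSpec and the per-point results.
    """
    if not grid:
        raise ValueError("empty grid")
    keys = sorted(grid)
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(Xv))
    best_spec, best_mae, records = None, np.inf, []
    for values in itertools.product(*(grid[k] for k in keys)):
        hp = dict(zip(keys, values))
        spec = ModelSpec(model_name, hp)
        maes = []
        for tr, te in splits:
            model = spec.build(seed)
            model.fit(Xv[tr], yv[tr])
            maes.append(float(np.mean(np.abs(model.predict(Xv[te]) - yv[te]))))
        mean_mae = float(np.mean(maes))
        records.append({**hp, "cv_mae": mean_mae})
        if mean_mae < best_mae:
            best_spec, best_mae = spec, mean_mae
    return best_spec, pd.DataFrame(records)


#: default grid: brackets the published optimum point with one smaller and
#: one larger candidate per hyperparameter (648 points; CLI `grid` stage)
DEFAULT_GRID = {
    "n_estimators": [10, 20, 40],
    "max_depth": [4, 6, 8],
    "min_child_weight": [3, 5, 7],
    "gamma": [0, 0.1],
    "colsample_bytree": [0.8, 1.0],
    "subsample": [0.8, 1.0],
    "learning_rate": [0.1, 0.3, 0.5],
}

#: the published optimum for the simplified model
OPTIMIZED_SIMPLIFIED_SPEC = ModelSpec("xgboost", {
    "n_estimators": 20, "max_depth": 6, "min_child_weight": 5, "gamma": 0,
    "colsample_bytree": 1.0, "subsample": 1.0, "learning_rate": 0.3,
})
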