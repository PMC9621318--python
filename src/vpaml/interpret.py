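"""Shapley-value interpretation of the trained concentration regressor.

Attributions use the interventional value function: the payoff of a feature
coalition S for sample x is the model's expected output when the features in
S take x's values and the rest are marginalized over a background sample
(by default a fixed-seed subsample of the derivation cohort).  Attributions
are on the model-output scale (mg/L) and satisfy local accuracy:
``base_value + sum(phi) = prediction`` for every sample.

`exhaustive_shapley` evaluates the defining combinatorial sum directly
(all 2^p coalitions) and serves as the independent oracle for the fast
tree-path computation in `attribute`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _treeshap
from .ml_bench import ModelBundle

#: default background subsample size for attribution
DEFAULT_BACKGROUND_SIZE = 512


@dataclass
class Attributions:
    """Per-sample Shapley attributions for a set of rows.

    base_value + values[i].sum() equals the model prediction for row i.
    Indexing returns the (phi, prediction) pair for one sample.
    """

    base_value: float
    values: np.ndarray                 # (n_samples, n_features), mg/L
    feature_names: Tuple[str, ...]
    X: pd.DataFrame                    # the attributed rows (model scale)
    predictions: np.ndarray            # model output per row

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, i):
        return self.values[i], float(self.predictions[i])

    def additivity_gap(self) -> np.ndarray:
        """|base + sum(phi) - prediction| per sample (should be ~0)."""
        return np.abs(self.base_value + self.values.sum(axis=1)
                      - self.predictions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.feature_names),
                            index=self.X.index)


def _resolve(model_or_bundle, X, feature_names):
    if isinstance(model_or_bundle, ModelBundle):
        bundle = model_or_bundle
        names = tuple(bundle.feature_names)
        if isinstance(X, pd.DataFrame):
            missing = set(names) - set(X.columns)
            if missing:
                raise ValueError(f"rows lack feature(s) {sorted(missing)}")
            X = X[list(names)]
        return bundle.model, X, names
    if feature_names is None:
        if isinstance(X, pd.DataFrame):
            feature_names = tuple(X.columns)
        else:
            feature_names = tuple(f"x{i}" for i in range(np.shape(X)[1]))
    return model_or_bundle, X, tuple(feature_names)


def attribute(model_or_bundle, rows, background,
              feature_names: Optional[Sequence[str]] = None) -> Attributions:
    """Exact interventional Shapley attributions for tree models.

    ``rows`` and ``background`` must be on the scale the model was trained
    on (for a ModelBundle: the min-max-scaled feature frame).  The base
    value is the mean model prediction over the background, so local
    accuracy holds for every attributed sample.
    """
    model, rows, names = _resolve(model_or_bundle, rows, feature_names)
    Xr = rows[list(names)] if isinstance(rows, pd.DataFrame) else \
        pd.DataFrame(np.asarray(rows, dtype=float), columns=list(names))
    Zr = background[list(names)].to_numpy(dtype=float) \
        if isinstance(background, pd.DataFrame) \
        else np.asarray(background, dtype=float)
    leaves = _treeshap.extract_ensemble(model, len(names))
    phi = _treeshap.interventional_shapley(leaves, Xr.to_numpy(dtype=float), Zr)
    # base/predictions from the extracted representation keep local accuracy
    # exact in float64; the representation itself matches model.predict to
    # float32 round-off for xgboost and exactly for sklearn trees.
    offset = _margin_offset(model, leaves, Zr)
    predictions = leaves.margin(Xr.to_numpy(dtype=float)) + offset
    base_value = float(leaves.margin(Zr).mean() + offset)
    return Attributions(base_value=base_value, values=phi,
                        feature_names=names, X=Xr, predictions=predictions)


def _margin_offset(model, leaves, Z: np.ndarray) -> float:
    """Constant offset (e.g. xgboost base_score) between leaf sums and predict."""
    probe = Z[: min(len(Z), 32)]
    return float(np.mean(np.asarray(model.predict(probe), dtype=float)
                         - leaves.margin(probe)))


def subsample_background(X: pd.DataFrame, size: int = DEFAULT_BACKGROUND_SIZE,
                         seed: int = 0) -> pd.DataFrame:
    """Fixed-seed background subsample (without replacement when possible)."""
    if len(X) <= size:
        return X
    rng = np.random.default_rng([seed, 3])
    return X.iloc[rng.choice(len(X), size, replace=False)]


def exhaustive_shapley(predictor: Callable[[np.ndarray], np.ndarray],
                       x: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Exact Shapley values by enumerating all 2^p coalitions (p <= 12).

    Implements the defining sum phi_i = sum over S not containing i of
    |S|! (p-|S|-1)! / p! * (v(S+i) - v(S)) with the interventional value
    function v(S) = mean over background of predictor(x_S, z_rest).
    Independent of the tree-path algorithm; used as its oracle.
    """
    x = np.asarray(x, dtype=float).ravel()
    Z = np.asarray(background, dtype=float)
    p = x.size
    if p > 12:
        raise ValueError("exhaustive enumeration limited to p <= 12 features")
    n_b = len(Z)
    # value of every coalition, batched through the predictor
    masks = np.arange(2 ** p)
    member = ((masks[:, None] >> np.arange(p)) & 1).astype(bool)  # (2^p, p)
    mixed = np.where(member[:, None, :], x[None, None, :], Z[None, :, :])
    preds = np.asarray(predictor(mixed.reshape(-1, p)), dtype=float)
    v = preds.reshape(2 ** p, n_b).mean(axis=1)

    import math
    fact = [math.factorial(i) for i in range(p + 1)]
    phi = np.zeros(p)
    sizes = member.sum(axis=1)
    for i in range(p):
        without = ~member[:, i]
        s = sizes[without]
        w = np.array([fact[k] * fact[p - k - 1] / fact[p] for k in s])
        gain = v[masks[without] | (1 << i)] - v[masks[without]]
        phi[i] = float(np.sum(w * gain))
    return phi


def global_importance(attr: Attributions) -> pd.Series:
    """Mean |phi| per feature over all attributed samples, sorted descending."""
    if len(attr) == 0:
        raise ValueError("no attributions")
    imp = pd.Series(np.abs(attr.values).mean(axis=0),
                    index=list(attr.feature_names), name="mean_abs_phi")
    return imp.sort_values(ascending=False, kind="stable")


def dependence_profile(attr: Attributions, feature: str) -> pd.DataFrame:
    """Per-sample (feature value, phi) pairs for one feature, no aggregation."""
    if feature not in attr.feature_names:
        raise ValueError(f"unknown feature {feature!r}")
    j = list(attr.feature_names).index(feature)
    return pd.DataFrame({"value": attr.X[feature].to_numpy(),
                         "phi": attr.values[:, j]})
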