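"""Fuse the two simulated datasets into the 16-feature ML table.

Pipeline order (mirroring the preprocessing narrative): merge with
placeholder levels -> k-nearest-neighbour imputation of the missing gender
and ALB of Model-B rows -> one-hot encoding with reference-level drops
(Unknown / None / Female) and removal of the latent ka/Vd/CL columns ->
min-max scaling of the continuous features -> random 8:2
derivation/validation split.

The genotype level "Unknown" and the co-medication level "None" are
legitimate categories, not missing data; only gender and ALB are imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .vpop_sim import COLUMNS, COMED_COMBOS_B

#: the 16 model features, in fixed column order
FEATURES = (
    "Single Dose", "BW", "ALB", "t", "tau", "Daily Dose",
    "CYP2C19*1/*1", "CYP2C19*2 and/or *3 variants", "Male",
    "Co-administered CBZ", "Co-administered PHT", "Co-administered PB",
    "Co-administered CBZ+PHT", "Co-administered CBZ+PB",
    "Co-administered PHT+PB", "Co-administered CBZ+PHT+PB",
)
CONTINUOUS_FEATURES = FEATURES[:6]
TARGET = "Css"

#: features omitted for the simplified (clinic-friendly) model
SIMPLIFIED_DROP = ("Single Dose", "ALB", "t", "tau")

_COMED_FEATURE = {"+".join(c): f"Co-administered {'+'.join(c)}"
                  for c in COMED_COMBOS_B}

#: default covariate distance features for k-NN imputation
IMPUTE_DISTANCE_FEATURES = ("BW", "single_dose", "daily_dose", "t", "tau")


@dataclass
class ScalerSpec:
    """Per-feature (min, max) observed on the fitting data, for min-max scaling."""

    bounds: Dict[str, Tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not hi > lo:
                raise ValueError(f"degenerate feature {name!r}: max == min")

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for name, (lo, hi) in self.bounds.items():
            if name in out.columns:
                out[name] = (out[name] - lo) / (hi - lo)
        return out

    def inverse_transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for name, (lo, hi) in self.bounds.items():
            if name in out.columns:
                out[name] = out[name] * (hi - lo) + lo
        return out

    def to_json(self) -> str:
        return json.dumps({k: list(v) for k, v in self.bounds.items()}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ScalerSpec":
        return cls({k: (float(v[0]), float(v[1]))
                    for k, v in json.loads(text).items()})


@dataclass
class FeatureTable:
    """The fused ML-ready table: 16 scaled features + Css target + split."""

    df: pd.DataFrame                      # FEATURES + TARGET, scaled
    scaler: ScalerSpec
    split: pd.Series                      # "derivation" / "validation" per row
    feature_names: Tuple[str, ...] = FEATURES

    def _part(self, which: str):
        mask = (self.split == which).to_numpy()
        X = self.df.loc[mask, list(self.feature_names)]
        y = self.df.loc[mask, TARGET]
        return X, y

    @property
    def derivation(self):
        return self._part("derivation")

    @property
    def validation(self):
        return self._part("validation")


def merge_with_placeholders(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Concatenate filtered Dataset-A and Dataset-B with placeholder levels.

    Source-A rows carry the co-medication level "None"; source-B rows carry
    genotype "unknown" and missing gender/ALB.  Schemas must match.
    """
    for name, df in (("a", a), ("b", b)):
        missing = set(COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"dataset {name} lacks columns {sorted(missing)}")
    merged = pd.concat([a[COLUMNS], b[COLUMNS]], ignore_index=True)
    bad_a = merged.eval("source == 'A' and comeds != 'None'")
    bad_b = merged.eval("source == 'B' and genotype != 'unknown'")
    if bad_a.any() or bad_b.any():
        raise ValueError("placeholder levels inconsistent with source tags")
    return merged


def knn_impute(table: pd.DataFrame, k: int = 5,
               distance_features: Sequence[str] = IMPUTE_DISTANCE_FEATURES,
               include_css: bool = True) -> pd.DataFrame:
    """Impute missing gender and ALB from the k nearest complete rows.

    Distance is Euclidean on min-max-scaled continuous dosing/covariate
    features plus the one-hot co-medication indicators.  By default the
    concentration column joins the distance, mirroring how an off-the-shelf
    k-NN imputer applied to the whole numeric matrix behaves: the donor pool
    for a row is then concentration-matched, which couples the imputed ALB
    of co-medicated rows to their Css.  Set ``include_css=False`` for a
    strictly leakage-free distance (covariates and dosing only).

    ALB is imputed as the unweighted mean of the k neighbours' ALB; gender
    as the majority vote among those same neighbours, ties (possible only
    for even k) broken to female.  Complete rows are returned unchanged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    complete = table["gender"].notna() & table["ALB"].notna()
    if not complete.any():
        raise ValueError("no complete donor rows available")
    n_donors = int(complete.sum())
    if k > n_donors:
        raise ValueError(f"k={k} exceeds donor count {n_donors}")
    if complete.all():
        return table.copy()

    cols = list(distance_features) + (["css"] if include_css else [])
    dist = table[cols].astype(float).copy()
    for col in cols:
        lo, hi = dist[col].min(), dist[col].max()
        if hi > lo:
            dist[col] = (dist[col] - lo) / (hi - lo)
    comed_dummies = pd.get_dummies(table["comeds"]).astype(float)
    X = np.hstack([dist.to_numpy(), comed_dummies.to_numpy()])

    nn = NearestNeighbors(n_neighbors=k)
    nn.fit(X[complete.to_numpy()])
    query = ~complete.to_numpy()
    _, idx = nn.kneighbors(X[query])

    donor_alb = table.loc[complete, "ALB"].to_numpy()
    donor_male = (table.loc[complete, "gender"] == "male").to_numpy()

    out = table.copy()
    out.loc[query, "ALB"] = donor_alb[idx].mean(axis=1)
    male_votes = donor_male[idx].sum(axis=1)
    # strict majority required for "male"; ties go to "female"
    out.loc[query, "gender"] = np.where(male_votes * 2 > k, "male", "female")
    return out


def encode_and_drop(table: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode with reference drops; keep the 16 features + Css.

    Reference levels Unknown (genotype), None (co-medication) and Female
    (gender) are dropped, as are the latent pharmacokinetic columns
    (ka, Vd, CL) that are not clinically observable.
    """
    bad_geno = ~table["genotype"].isin(["wildtype", "variant", "unknown"])
    if bad_geno.any():
        raise ValueError("unexpected genotype level(s): "
                         f"{sorted(table.loc[bad_geno, 'genotype'].unique())}")
    bad_com = ~table["comeds"].isin(list(_COMED_FEATURE) + ["None"])
    if bad_com.any():
        raise ValueError("unexpected co-medication level(s): "
                         f"{sorted(table.loc[bad_com, 'comeds'].unique())}")
    if table["gender"].isna().any():
        raise ValueError("gender must be imputed before encoding")

    out = pd.DataFrame(index=table.index)
    out["Single Dose"] = table["single_dose"].astype(float)
    out["BW"] = table["BW"].astype(float)
    out["ALB"] = table["ALB"].astype(float)
    out["t"] = table["t"].astype(float)
    out["tau"] = table["tau"].astype(float)
    out["Daily Dose"] = table["daily_dose"].astype(float)
    out["CYP2C19*1/*1"] = (table["genotype"] == "wildtype").astype(float)
    out["CYP2C19*2 and/or *3 variants"] = (
        table["genotype"] == "variant").astype(float)
    out["Male"] = (table["gender"] == "male").astype(float)
    for level, feature in _COMED_FEATURE.items():
        out[feature] = (table["comeds"] == level).astype(float)
    out[TARGET] = table["css"].astype(float)
    return out[list(FEATURES) + [TARGET]]


def minmax_scale(table: pd.DataFrame,
                 scaler: Optional[ScalerSpec] = None,
                 features: Sequence[str] = CONTINUOUS_FEATURES,
                 ) -> Tuple[pd.DataFrame, ScalerSpec]:
    """Min-max scale continuous features; fit bounds unless a spec is given.

    With a supplied ScalerSpec (prediction time) the stored bounds are
    reused, so outputs may fall outside [0, 1] for out-of-range inputs.
    """
    if scaler is None:
        scaler = ScalerSpec({f: (float(table[f].min()), float(table[f].max()))
                             for f in features})
    return scaler.transform(table), scaler


def split_derivation_validation(n: int, fraction: float = 0.8,
                                seed: int = 0) -> np.ndarray:
    """Uniformly random per-row assignment to derivation/validation cohorts."""
    if n <= 0:
        raise ValueError("empty table")
    n_deriv = int(np.floor(fraction * n + 0.5))
    rng = np.random.default_rng([seed, 2])
    order = rng.permutation(n)
    out = np.empty(n, dtype=object)
    out[order[:n_deriv]] = "derivation"
    out[order[n_deriv:]] = "validation"
    return out


def build_feature_table(a: pd.DataFrame, b: pd.DataFrame, k: int = 5,
                        seed: int = 0, fraction: float = 0.8,
                        scaler_mode: str = "full",
                        impute_include_css: bool = True) -> FeatureTable:
    """Full fusion chain: merge -> impute -> encode -> scale -> split.

    ``scaler_mode='full'`` fits the min-max bounds on the whole merged table
    before splitting (the published order of operations, which leaks the
    validation range into the scaler); ``'derivation'`` fits on the
    derivation rows only.
    """
    merged = merge_with_placeholders(a, b)
    encoded = encode_and_drop(
        knn_impute(merged, k=k, include_css=impute_include_css))
    split = pd.Series(split_derivation_validation(len(encoded), fraction, seed),
                      index=encoded.index, name="split")
    if scaler_mode == "full":
        scaled, scaler = minmax_scale(encoded)
    elif scaler_mode == "derivation":
        _, scaler = minmax_scale(encoded.loc[(split == "derivation").to_numpy()])
        scaled = scaler.transform(encoded)
    else:
        raise ValueError(f"unknown scaler_mode {scaler_mode!r}")
    return FeatureTable(df=scaled, scaler=scaler, split=split)
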