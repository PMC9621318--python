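"""Exact interventional Shapley values for tree ensembles.

The attribution game for a sample ``x`` under a background distribution is
``v(S) = E_z[ f(x_S, z_{~S}) ]`` with ``z`` drawn from the background rows
(features outside the coalition S are replaced by background values).  For a
tree ensemble this expectation is exact by averaging over the background
sample, and the per-pair game ``(x, z)`` admits a closed form:

Each leaf contributes its value whenever the mixed point reaches it.  Along
the path to a leaf, collapse the split conditions per distinct feature into
an interval; a feature is then either satisfied by x only (must be *in* S),
by z only (must be *out* of S), by both (irrelevant), or by neither (leaf
unreachable for this pair).  With ``a`` x-only and ``b`` z-only features the
leaf's game is a conjunction of literals whose Shapley values are::

    phi_i = +v * (a-1)! b! / (a+b)!   for i among the a x-only features
    phi_i = -v * a! (b-1)! / (a+b)!   for i among the b z-only features

(dummy features get zero and can be dropped without changing the values).
Averaging the per-pair values over the background yields the interventional
Shapley values; their sum telescopes to ``f(x) - mean_z f(z)`` exactly.

Complexity is O(samples * leaves * path-length * background); the inner
loops are compiled with numba.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from numba import njit

try:  # xgboost is an optional input format here
    import xgboost
except ImportError:  # pragma: no cover
    xgboost = None


def _quantize(X) -> np.ndarray:
    """Round inputs through float32, replicating how both xgboost and
    sklearn cast feature matrices before threshold comparisons."""
    return np.asarray(X, dtype=np.float32).astype(np.float64)


@dataclass
class LeafConditions:
    """Flattened per-leaf path conditions for an additive tree ensemble.

    ``leaf_value[l]`` is added to the prediction when every condition in
    ``slice(ptr[l], ptr[l+1])`` holds: ``lo < x[feat] <= hi`` when
    ``upper_inclusive`` (sklearn convention) else ``lo <= x[feat] < hi``
    (xgboost convention).
    """

    leaf_value: np.ndarray      # (L,) float64
    ptr: np.ndarray             # (L+1,) int64
    feat: np.ndarray            # (M,) int64
    lo: np.ndarray              # (M,) float64
    hi: np.ndarray              # (M,) float64
    upper_inclusive: bool
    n_features: int

    @property
    def max_path(self) -> int:
        return int(np.max(np.diff(self.ptr))) if len(self.leaf_value) else 0

    def margin(self, X: np.ndarray) -> np.ndarray:
        """Sum of reached leaf values per row (no intercept/base score)."""
        passes = self._passes(_quantize(X))
        out = np.zeros(len(X))
        for l in range(len(self.leaf_value)):
            sl = slice(self.ptr[l], self.ptr[l + 1])
            out += self.leaf_value[l] * passes[:, sl].all(axis=1)
        return out

    def _passes(self, X: np.ndarray) -> np.ndarray:
        """(n, M) boolean matrix: row i satisfies condition m."""
        V = X[:, self.feat]
        if self.upper_inclusive:
            return (V > self.lo) & (V <= self.hi)
        return (V >= self.lo) & (V < self.hi)


def _collapse_path(path: List[Tuple[int, float, bool]], n_features: int):
    """Combine (feature, threshold, is_upper) conditions into intervals."""
    lo = {}
    hi = {}
    for f, thr, is_upper in path:
        if is_upper:
            hi[f] = min(hi.get(f, np.inf), thr)
        else:
            lo[f] = max(lo.get(f, -np.inf), thr)
    feats = sorted(set(lo) | set(hi))
    return [(f, lo.get(f, -np.inf), hi.get(f, np.inf)) for f in feats]


def from_sklearn_tree(tree, n_features: int, scale: float = 1.0) -> LeafConditions:
    """Extract a fitted sklearn decision tree (left branch: x <= threshold)."""
    t = tree.tree_
    leaf_value, ptr, feat, lo, hi = [], [0], [], [], []

    def walk(node: int, path):
        if t.children_left[node] == -1:
            for f, l, h in _collapse_path(path, n_features):
                feat.append(f)
                lo.append(l)
                hi.append(h)
            leaf_value.append(float(t.value[node].ravel()[0]) * scale)
            ptr.append(len(feat))
            return
        f, thr = int(t.feature[node]), float(t.threshold[node])
        walk(t.children_left[node], path + [(f, thr, True)])
        walk(t.children_right[node], path + [(f, thr, False)])

    walk(0, [])
    return LeafConditions(np.array(leaf_value), np.array(ptr, dtype=np.int64),
                          np.array(feat, dtype=np.int64), np.array(lo),
                          np.array(hi), upper_inclusive=True,
                          n_features=n_features)


def _merge(parts: List[LeafConditions]) -> LeafConditions:
    first = parts[0]
    ptrs = [first.ptr]
    offset = first.ptr[-1]
    for p in parts[1:]:
        ptrs.append(p.ptr[1:] + offset)
        offset += p.ptr[-1]
    return LeafConditions(
        leaf_value=np.concatenate([p.leaf_value for p in parts]),
        ptr=np.concatenate(ptrs),
        feat=np.concatenate([p.feat for p in parts]),
        lo=np.concatenate([p.lo for p in parts]),
        hi=np.concatenate([p.hi for p in parts]),
        upper_inclusive=first.upper_inclusive,
        n_features=first.n_features)


def from_xgboost(model, n_features: int) -> LeafConditions:
    """Extract an XGBRegressor/Booster (yes branch: x < threshold).

    Trees are read from the JSON dump, whose split thresholds round-trip the
    stored float32 values exactly (the tabular dump truncates to six
    significant digits, which mis-routes points near a threshold).
    """
    import json as _json

    booster = model.get_booster() if hasattr(model, "get_booster") else model
    names = booster.feature_names or [f"f{i}" for i in range(n_features)]
    findex = {name: i for i, name in enumerate(names)}
    leaf_value, ptr, feat, lo, hi = [], [0], [], [], []
    for dump in booster.get_dump(dump_format="json"):
        def walk(node, path):
            if "leaf" in node:
                for f, l, h in _collapse_path(path, n_features):
                    feat.append(f)
                    lo.append(l)
                    hi.append(h)
                leaf_value.append(float(np.float32(node["leaf"])))
                ptr.append(len(feat))
                return
            f = findex[node["split"]]
            thr = float(np.float32(node["split_condition"]))
            kids = {c["nodeid"]: c for c in node["children"]}
            walk(kids[node["yes"]], path + [(f, thr, True)])
            walk(kids[node["no"]], path + [(f, thr, False)])

        walk(_json.loads(dump), [])
    return LeafConditions(np.array(leaf_value), np.array(ptr, dtype=np.int64),
                          np.array(feat, dtype=np.int64), np.array(lo),
                          np.array(hi), upper_inclusive=False,
                          n_features=n_features)


def extract_ensemble(model, n_features: int) -> LeafConditions:
    """Dispatch on supported model types."""
    if xgboost is not None and isinstance(
            model, (xgboost.XGBRegressor, xgboost.Booster)):
        return from_xgboost(model, n_features)
    if hasattr(model, "tree_"):
        return from_sklearn_tree(model, n_features)
    if hasattr(model, "estimators_") and hasattr(model, "n_estimators") and \
            model.__class__.__name__ == "RandomForestRegressor":
        n = len(model.estimators_)
        return _merge([from_sklearn_tree(t, n_features, scale=1.0 / n)
                       for t in model.estimators_])
    raise TypeError(f"unsupported model type {type(model).__name__}: "
                    "expected an XGBoost model, a sklearn decision tree, "
                    "or a random forest")


def _weight_tables(max_m: int):
    """Wplus[a,b] = (a-1)! b!/(a+b)!; Wminus[a,b] = a! (b-1)!/(a+b)!."""
    wp = np.zeros((max_m + 1, max_m + 1))
    wm = np.zeros((max_m + 1, max_m + 1))
    for a in range(max_m + 1):
        for b in range(max_m + 1):
            if a >= 1:
                wp[a, b] = math.exp(math.lgamma(a) + math.lgamma(b + 1)
                                    - math.lgamma(a + b + 1))
            if b >= 1:
                wm[a, b] = math.exp(math.lgamma(a + 1) + math.lgamma(b)
                                    - math.lgamma(a + b + 1))
    return wp, wm


@njit(cache=True)
def _phi_kernel(leaf_value, ptr, feat, lo, hi, upper_inc, X, zpass,
                wplus, wminus, phi):  # pragma: no cover - compiled
    n_samples = X.shape[0]
    n_leaves = leaf_value.shape[0]
    n_background = zpass.shape[1]
    xp = np.zeros(64, dtype=np.bool_)
    for s in range(n_samples):
        for l in range(n_leaves):
            st = ptr[l]
            en = ptr[l + 1]
            m = en - st
            for j in range(m):
                v = X[s, feat[st + j]]
                if upper_inc:
                    xp[j] = (v > lo[st + j]) and (v <= hi[st + j])
                else:
                    xp[j] = (v >= lo[st + j]) and (v < hi[st + j])
            vleaf = leaf_value[l]
            for z in range(n_background):
                a = 0
                b = 0
                dead = False
                for j in range(m):
                    zp = zpass[st + j, z]
                    if xp[j]:
                        if not zp:
                            a += 1
                    elif zp:
                        b += 1
                    else:
                        dead = True
                        break
                if dead:
                    continue
                if a > 0:
                    w = wplus[a, b] * vleaf
                    for j in range(m):
                        if xp[j] and not zpass[st + j, z]:
                            phi[s, feat[st + j]] += w
                if b > 0:
                    w = wminus[a, b] * vleaf
                    for j in range(m):
                        if zpass[st + j, z] and not xp[j]:
                            phi[s, feat[st + j]] -= w


def interventional_shapley(leaves: LeafConditions, X: np.ndarray,
                           background: np.ndarray) -> np.ndarray:
    """Exact interventional Shapley values, (n_samples, n_features)."""
    X = np.ascontiguousarray(_quantize(X))
    Z = _quantize(background)
    if X.ndim != 2 or Z.ndim != 2 or X.shape[1] != Z.shape[1]:
        raise ValueError("X and background must be 2-D with equal width")
    if X.shape[1] != leaves.n_features:
        raise ValueError("feature count does not match the extracted model")
    if leaves.max_path > 64:
        raise ValueError("tree paths deeper than 64 distinct features")
    zpass = np.ascontiguousarray(leaves._passes(Z).T)  # (M, nB)
    wplus, wminus = _weight_tables(max(leaves.max_path, 1))
    phi = np.zeros((X.shape[0], leaves.n_features))
    _phi_kernel(leaves.leaf_value, leaves.ptr, leaves.feat, leaves.lo,
                leaves.hi, leaves.upper_inclusive, X, zpass,
                wplus, wminus, phi)
    return phi / Z.shape[0]
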