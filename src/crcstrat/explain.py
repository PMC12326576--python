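"""Per-subject Shapley explanations.

Three attribution routes live here:

* :func:`exact_shapley` — the brute-force oracle: enumerate every feature
  subset ``F`` and weight marginal contributions by
  ``|F|! (|S|-|F|-1)! / |S|!``. The value function is the interventional
  (background-marginal) expectation: features outside the coalition are
  replaced by a background row's values and the prediction averaged over the
  background set. Exponential in ``|S|``; capped at 15 features.
* :func:`tree_shap_interventional` — exact interventional Shapley values for
  scikit-learn tree ensembles in polynomial time. For a single background row
  ``z``, a leaf is reached under coalition ``S`` iff every path feature where
  only ``x`` satisfies the path lies in ``S`` (the set ``U``) and every path
  feature where only ``z`` satisfies it lies outside (the set ``V``); the
  Shapley value of such a conjunction game has the closed form
  ``phi_j = +c (k-1)! m! / (k+m)!`` for ``j in U`` and
  ``phi_j = -c k! (m-1)! / (k+m)!`` for ``j in V`` (``k = |U|``, ``m = |V|``,
  leaf value ``c``), averaged over background rows and trees.
* :func:`out_of_fold_shap` — the pipeline route: each training subject is
  explained by the cross-validation model that held it out, using the
  backend's fast tree-path SHAP values, then averaged across repeats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .containers import FeatureMatrix
from .modeling import CVResult

MAX_EXACT_FEATURES = 15


# ---------------------------------------------------------------------------
# exact enumeration oracle


def exact_shapley(predict_fn, instance, background, feature_indices=None) -> np.ndarray:
    """Exact Shapley values by subset enumeration (interventional value function).

    ``v(F)`` is the mean of ``predict_fn`` over rows built by taking the
    instance's values on ``F`` (and on any feature outside ``feature_indices``,
    which are treated as fixed context) and the background row's values
    elsewhere. Returns one phi per entry of ``feature_indices``.
    """
    x = np.asarray(instance, dtype=float).ravel()
    bg = np.atleast_2d(np.asarray(background, dtype=float))
    if bg.shape[0] == 0:
        raise ValueError("background set must be nonempty")
    if feature_indices is None:
        feature_indices = list(range(x.size))
    players = list(feature_indices)
    s = len(players)
    if s > MAX_EXACT_FEATURES:
        raise ValueError(
            f"exact enumeration over {s} features exceeds the {MAX_EXACT_FEATURES}-feature "
            "limit; pass a feature_indices subset"
        )

    value_cache: dict[int, float] = {}

    def v(mask: int) -> float:
        if mask not in value_cache:
            rows = np.tile(x, (bg.shape[0], 1))
            for pos, j in enumerate(players):
                if not (mask >> pos) & 1:
                    rows[:, j] = bg[:, j]
            value_cache[mask] = float(np.mean(predict_fn(rows)))
        return value_cache[mask]

    fact = [math.factorial(k) for k in range(s + 1)]
    phi = np.zeros(s)
    others = list(range(s))
    for pos in range(s):
        rest = [p for p in others if p != pos]
        for size in range(s):
            w = fact[size] * fact[s - size - 1] / fact[s]
            for subset in combinations(rest, size):
                mask = 0
                for p in subset:
                    mask |= 1 << p
                phi[pos] += w * (v(mask | (1 << pos)) - v(mask))
    return phi


# ---------------------------------------------------------------------------
# exact interventional TreeSHAP for scikit-learn tree ensembles


def _leaf_conditions(tree, class_index: int = 1):
    """Collect every leaf of an sklearn ``tree_`` as (value, conditions).

    ``conditions`` maps feature index -> (lo, hi] interval obtained by
    intersecting all splits on the root-to-leaf path (left child: x <= t).
    """
    t = tree.tree_
    leaves = []

    def walk(node: int, conds: dict):
        if t.children_left[node] == -1:
            val = t.value[node].ravel()
            if val.size > 1:  # classifier node: probability of the positive class
                total = val.sum()
                leaf_value = float(val[class_index] / total) if total > 0 else 0.0
            else:
                leaf_value = float(val[0])
            leaves.append((leaf_value, dict(conds)))
            return
        f, thr = int(t.feature[node]), float(t.threshold[node])
        lo, hi = conds.get(f, (-np.inf, np.inf))
        if thr < hi:  # left: x[f] <= thr
            conds[f] = (lo, min(hi, thr))
            walk(t.children_left[node], conds)
        if thr > lo:  # right: x[f] > thr
            conds[f] = (max(lo, thr), hi)
            walk(t.children_right[node], conds)
        conds[f] = (lo, hi)

    walk(0, {})
    return leaves


def _ensemble_trees(model):
    """Yield (tree, weight) pairs whose weighted leaf sum is the model output."""
    if isinstance(model, (RandomForestClassifier, RandomForestRegressor)):
        n = len(model.estimators_)
        return [(est, 1.0 / n) for est in model.estimators_]
    if isinstance(model, (DecisionTreeClassifier, DecisionTreeRegressor)):
        return [(model, 1.0)]
    raise TypeError(
        "interventional TreeSHAP supports sklearn decision trees and random "
        f"forests; got {type(model).__name__}"
    )


def tree_shap_interventional(model, X, background) -> tuple[np.ndarray, float]:
    """Exact interventional Shapley values for an sklearn tree ensemble.

    Output scale: positive-class probability for classifiers, raw value for
    regressors. Returns ``(phi, base)`` with ``base = mean model output over
    the background`` so that ``phi.sum(1) + base == model(X)`` exactly.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    bg = np.atleast_2d(np.asarray(background, dtype=float))
    n, n_features = X.shape
    phi = np.zeros((n, n_features))

    tree_leaves = [(weight, _leaf_conditions(est))
                   for est, weight in _ensemble_trees(model)]
    max_path = max(
        (len(conds) for _, leaves in tree_leaves for _, conds in leaves),
        default=0,
    )
    fact = np.array([math.factorial(k) for k in range(max_path + 1)], dtype=float)

    for weight, leaves in tree_leaves:
        for leaf_value, conds in leaves:
            if not conds or leaf_value == 0.0:
                continue
            feats = np.fromiter(conds.keys(), dtype=int)
            lo = np.array([conds[f][0] for f in feats])
            hi = np.array([conds[f][1] for f in feats])
            # satisfaction of each path condition, per explained row / bg row
            x_sat = (X[:, feats] > lo) & (X[:, feats] <= hi)      # (n, c)
            z_sat = (bg[:, feats] > lo) & (bg[:, feats] <= hi)    # (B, c)
            for i in range(n):
                xs = x_sat[i]
                dead = ~xs & ~z_sat                               # (B, c)
                alive = ~dead.any(axis=1)
                if not alive.any():
                    continue
                u = xs[None, :] & ~z_sat[alive]                   # x-only conditions
                vmask = ~xs[None, :] & z_sat[alive]               # z-only conditions
                k = u.sum(axis=1)
                m = vmask.sum(axis=1)
                tot = k + m
                c = weight * leaf_value / bg.shape[0]
                with np.errstate(divide="ignore", invalid="ignore"):
                    w_u = np.where(k > 0, c * fact[np.maximum(k - 1, 0)] * fact[m] / fact[tot], 0.0)
                    w_v = np.where(m > 0, c * fact[k] * fact[np.maximum(m - 1, 0)] / fact[tot], 0.0)
                np.add.at(phi[i], feats, (u * w_u[:, None]).sum(axis=0))
                np.add.at(phi[i], feats, -(vmask * w_v[:, None]).sum(axis=0))

    if isinstance(model, (RandomForestClassifier, DecisionTreeClassifier)):
        base = float(model.predict_proba(bg)[:, 1].mean())
    else:
        base = float(model.predict(bg).mean())
    return phi, base


# ---------------------------------------------------------------------------
# pipeline explanations


@dataclass
class ShapMatrix:
    """Subject x feature Shapley values with per-subject baselines.

    ``local_accuracy_residual`` is the largest |sum(phi) + baseline - model
    output| observed over every contributing model while the matrix was
    assembled (SHAP efficiency check, on the model-output scale).
    """

    phi: pd.DataFrame
    baseline: pd.Series
    provenance: str
    local_accuracy_residual: float = 0.0

    @property
    def subject_ids(self) -> list[str]:
        return list(self.phi.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.phi.columns)

    def to_tsv(self, path) -> None:
        self.phi.to_csv(path, sep="\t", index_label="subject_id")


def _backend_explain(backend, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(phi, per-row base, raw output) from a fitted backend."""
    if hasattr(backend, "explain"):
        return backend.explain(X)
    phi, base = backend.shap_values(X)
    if np.ndim(base) == 0:
        base = np.full(phi.shape[0], float(base))
    return phi, base, backend.raw_output(X)


def out_of_fold_shap(cv: CVResult, features: FeatureMatrix,
                     *, residual_tol: float = 1e-6) -> ShapMatrix:
    """Per-subject SHAP values averaged across CV repeats.

    For each repeat, a subject's phi comes from the single model that held it
    out; the final phi is the mean over repeats, the baseline the mean of the
    contributing models' expected outputs. Local accuracy is asserted for
    every contributing model.
    """
    if features.sample_ids != list(cv.fold_map.index):
        raise ValueError("feature matrix samples do not match the CV fold map")
    X = features.values.to_numpy(dtype=float)
    n, p = X.shape
    phi_sum = np.zeros((n, p))
    base_sum = np.zeros(n)
    seen = np.zeros(n, dtype=int)
    max_resid = 0.0
    n_repeats = cv.fold_map.shape[1]
    for r in range(n_repeats):
        assignments = cv.fold_map.iloc[:, r].to_numpy()
        for f in np.unique(assignments):
            idx = np.flatnonzero(assignments == f)
            backend = cv.registry[(r, int(f))]
            phi, base, raw = _backend_explain(backend, X[idx])
            resid = float(np.abs(phi.sum(axis=1) + base - raw).max())
            max_resid = max(max_resid, resid)
            phi_sum[idx] += phi
            base_sum[idx] += base
            seen[idx] += 1
    if (seen != n_repeats).any():
        missing = [features.sample_ids[i] for i in np.flatnonzero(seen == 0)]
        raise ValueError(f"subjects absent from every test fold: {missing}")
    if max_resid > residual_tol:
        raise AssertionError(
            f"SHAP local accuracy violated: residual {max_resid:.3g} > {residual_tol:g}"
        )
    return ShapMatrix(
        phi=pd.DataFrame(phi_sum / n_repeats, index=features.sample_ids,
                         columns=features.feature_names),
        baseline=pd.Series(base_sum / n_repeats, index=features.sample_ids),
        provenance="out_of_fold",
        local_accuracy_residual=max_resid,
    )


def external_shap(cv: CVResult, features_ext: FeatureMatrix,
                  *, residual_tol: float = 1e-6) -> ShapMatrix:
    """External-cohort phi: mean over every model in the registry."""
    if features_ext.feature_names != cv.feature_names:
        raise ValueError("external features do not match the training feature set")
    X = features_ext.values.to_numpy(dtype=float)
    phi_sum = np.zeros((X.shape[0], X.shape[1]))
    base_sum = np.zeros(X.shape[0])
    max_resid = 0.0
    for backend in cv.registry.values():
        phi, base, raw = _backend_explain(backend, X)
        max_resid = max(max_resid, float(np.abs(phi.sum(axis=1) + base - raw).max()))
        phi_sum += phi
        base_sum += base
    k = len(cv.registry)
    if max_resid > residual_tol:
        raise AssertionError(
            f"SHAP local accuracy violated: residual {max_resid:.3g} > {residual_tol:g}"
        )
    return ShapMatrix(
        phi=pd.DataFrame(phi_sum / k, index=features_ext.sample_ids,
                         columns=features_ext.feature_names),
        baseline=pd.Series(base_sum / k, index=features_ext.sample_ids),
        provenance="external_mean",
        local_accuracy_residual=max_resid,
    )


# ---------------------------------------------------------------------------
# global importance


@dataclass
class GlobalImportance:
    """Features ranked by mean |phi| with cumulative importance shares."""

    importance: pd.Series   # sorted descending, ties broken by feature name
    top_k: int

    @property
    def ranking(self) -> list[str]:
        return list(self.importance.index)

    def cumulative_share(self, k: int | None = None) -> float:
        k = self.top_k if k is None else k
        total = float(self.importance.sum())
        if total == 0:
            return 0.0
        return float(self.importance.iloc[:k].sum() / total)


def global_importance(shap: ShapMatrix, top_k: int = 20) -> GlobalImportance:
    if shap.phi.empty:
        raise ValueError("empty SHAP matrix")
    imp = shap.phi.abs().mean(axis=0)
    order = np.lexsort((np.array(imp.index, dtype=object), -imp.to_numpy()))
    return GlobalImportance(importance=imp.iloc[order], top_k=top_k)


def shap_summary_records(shap: ShapMatrix, features: FeatureMatrix,
                         top_k: int = 20) -> pd.DataFrame:
    """Long-format (feature, subject, phi, feature value, rank) records for
    beeswarm-style summary plots of the ``top_k`` features."""
    if shap.subject_ids != features.sample_ids:
        raise ValueError("SHAP matrix and feature matrix subjects are misaligned")
    ranking = global_importance(shap, top_k=top_k).ranking[:top_k]
    records = []
    for rank, feat in enumerate(ranking, start=1):
        records.append(pd.DataFrame({
            "feature": feat,
            "subject": shap.subject_ids,
            "phi": shap.phi[feat].to_numpy(),
            "feature_value": features.values[feat].to_numpy(),
            "rank": rank,
        }))
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# double-precision path-dependent TreeSHAP for XGBoost boosters
#
# Per leaf L with leaf value c and unique path features f_1..f_d, the
# cover-weighted descent value function factorises as
#   v_L(S) = c * prod_f (a_f if f in S else b_f),
# where a_f indicates the instance satisfies every split of f on the path and
# b_f is the product of the child-cover fractions of f's splits. The Shapley
# value of this multilinear game is
#   phi_j = c (a_j - b_j) * sum_s s!(d-1-s)!/d! * e_s,
# with e_s the degree-s coefficient of prod_{f != j} (b_f + a_f z). Summed
# over leaves and trees this reproduces the tree-path SHAP values the booster
# itself computes, but accumulated in float64, so local accuracy holds to
# ~1e-12 instead of float32 rounding.


def _parse_xgb_leaves(booster):
    """Leaves of every tree: (value, feature idx array, intervals, cover fracs).

    Parsed from the full-precision JSON model (``save_raw``); the text dump
    rounds thresholds and would misroute instances near a split. Intervals
    use the XGBoost split convention ``lo <= x < hi`` (the yes branch takes
    ``x < threshold``). Intervals may be empty: path-dependent descent enters
    branches no single consistent instance could reach, and such leaves still
    carry cover weight.
    """
    import json as _json

    raw = _json.loads(bytearray(booster.save_raw(raw_format="json")))
    trees = []
    for tree in raw["learner"]["gradient_booster"]["model"]["trees"]:
        split_idx = tree["split_indices"]
        split_cond = tree["split_conditions"]
        left = tree["left_children"]
        right = tree["right_children"]
        hess = tree["sum_hessian"]
        leaves = []

        def walk(node, conds, covers):
            if left[node] == -1:
                feats = np.fromiter(conds.keys(), dtype=int)
                # float32 thresholds: xgboost routes by float32 comparisons,
                # so interval checks must not promote to float64
                lo = np.array([conds[f][0] for f in feats], dtype=np.float32)
                hi = np.array([conds[f][1] for f in feats], dtype=np.float32)
                b = np.array([covers[f] for f in feats])
                leaves.append((float(split_cond[node]), feats, lo, hi, b))
                return
            f = int(split_idx[node])
            thr = float(split_cond[node])
            lo, hi = conds.get(f, (-np.inf, np.inf))
            bf = covers.get(f, 1.0)
            for child, new_iv in ((left[node], (lo, min(hi, thr))),
                                  (right[node], (max(lo, thr), hi))):
                conds2 = dict(conds)
                covers2 = dict(covers)
                conds2[f] = new_iv
                covers2[f] = bf * hess[child] / hess[node]
                walk(child, conds2, covers2)

        walk(0, {}, {})
        trees.append(leaves)
    return trees


def _shapley_poly_weights(d: int) -> np.ndarray:
    """w_s = s! (d-1-s)! / d! for s = 0..d-1."""
    s = np.arange(d)
    from scipy.special import gammaln as _gammaln

    return np.exp(_gammaln(s + 1) + _gammaln(d - s) - _gammaln(d + 1))


def xgb_tree_shap(booster, X: np.ndarray,
                  trees=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Float64 path-dependent SHAP values for a binary XGBoost booster.

    Returns ``(phi, base, raw)`` on the margin (log-odds) scale with
    ``phi.sum(1) + base == raw`` to double precision; ``raw`` is the margin
    recomputed from the parsed trees (it matches the booster's own margin to
    float32 rounding).
    """
    import xgboost as xgb

    X = np.atleast_2d(np.asarray(X, dtype=float))
    # xgboost stores features and thresholds in float32 and compares on that
    # scale; evaluating path conditions in float64 would misroute instances
    # whose value collides with a threshold
    X32 = X.astype(np.float32)
    n, n_features = X.shape
    if trees is None:
        trees = _parse_xgb_leaves(booster)
    phi = np.zeros((n, n_features))
    raw = np.zeros(n)
    expected = 0.0
    weight_cache: dict[int, np.ndarray] = {}

    for leaves in trees:
        for c, feats, lo, hi, b in leaves:
            if feats.size == 0:  # stump tree: constant contribution
                expected += c
                raw += c
                continue
            a = ((X32[:, feats] >= lo) & (X32[:, feats] < hi)).astype(float)  # (n, d)
            d = feats.size
            expected += c * float(b.prod())
            raw += c * a.prod(axis=1)
            w = weight_cache.setdefault(d, _shapley_poly_weights(d))
            for jpos in range(d):
                # e_s coefficients of prod_{f != j} (b_f + a_f z)
                coef = np.zeros((n, d))
                coef[:, 0] = 1.0
                deg = 0
                for fpos in range(d):
                    if fpos == jpos:
                        continue
                    upper = coef[:, : deg + 1].copy()
                    coef[:, : deg + 1] *= b[fpos]
                    coef[:, 1: deg + 2] += upper * a[:, fpos: fpos + 1]
                    deg += 1
                phi[:, feats[jpos]] += c * (a[:, jpos] - b[jpos]) * (coef @ w)

    # intercept: probe the booster once so base matches its margin convention
    probe = xgb.DMatrix(X[:1])
    margin0 = float(booster.predict(probe, output_margin=True)[0])
    intercept = margin0 - raw[0]
    return phi, expected + intercept, raw + intercept
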