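"""Tree-ensemble classification under repeated stratified cross-validation.

Three pluggable backends sit behind one interface: a bagged random forest
(scikit-learn), and two gradient-boosting machines (XGBoost and LightGBM).
Each exposes ``fit`` / ``predict_proba`` plus SHAP attribution hooks used by
the explanation stages: the boosting backends return their native tree-path
SHAP values (log-odds scale), the random forest is explained with the exact
interventional TreeSHAP in :mod:`crcstrat.explain` (probability scale).

CRC is the positive class throughout. All randomness (fold shuffling, model
seeds) derives from one master seed via a NumPy seed-sequence spawn, so a run
is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .containers import FeatureMatrix

BACKENDS = ("random_forest", "xgboost", "lightgbm")

#: backends whose boosters expose SHAP interaction tensors
INTERACTION_BACKENDS = ("xgboost",)


class BackendError(ValueError):
    pass


def _spawn_int(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


class _XGBBackend:
    """XGBoost classifier; SHAP via the booster's pred_contribs (log-odds)."""

    name = "xgboost"
    supports_interactions = True
    output_scale = "log_odds"

    def __init__(self, seed: int, params: dict):
        import xgboost as xgb

        defaults = dict(n_estimators=100, tree_method="hist", n_jobs=1,
                        random_state=seed, eval_metric="logloss")
        defaults.update(params)
        self.model = xgb.XGBClassifier(**defaults)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_XGBBackend":
        self.model.fit(X, y)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(X)[:, 1]

    def raw_output(self, X: np.ndarray) -> np.ndarray:
        import xgboost as xgb

        d = xgb.DMatrix(np.asarray(X))
        return self.model.get_booster().predict(d, output_margin=True)

    def explain(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Double-precision tree-path SHAP values: (phi, base, raw margin).

        Local accuracy (sum phi + base = raw) holds to ~1e-12; the booster's
        own pred_contribs agree to float32 rounding.
        """
        from .explain import _parse_xgb_leaves, xgb_tree_shap

        if getattr(self, "_parsed_trees", None) is None:
            self._parsed_trees = _parse_xgb_leaves(self.model.get_booster())
        phi, base, raw = xgb_tree_shap(self.model.get_booster(), np.asarray(X),
                                       trees=self._parsed_trees)
        return phi, np.full(phi.shape[0], base), raw

    def shap_values(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        phi, base, _raw = self.explain(X)
        return phi, base

    def shap_values_native(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """The booster's own pred_contribs (float32; fast path for
        consistency checks against the interaction tensor)."""
        import xgboost as xgb

        d = xgb.DMatrix(np.asarray(X))
        contrib = self.model.get_booster().predict(d, pred_contribs=True)
        return contrib[:, :-1].astype(float), contrib[:, -1].astype(float)

    def shap_interactions(self, X: np.ndarray) -> np.ndarray:
        import xgboost as xgb

        d = xgb.DMatrix(np.asarray(X))
        tensor = self.model.get_booster().predict(d, pred_interactions=True)
        return tensor[:, :-1, :-1].astype(float)  # drop the bias row/column


class _LGBMBackend:
    """LightGBM classifier; SHAP via pred_contrib (log-odds scale)."""

    name = "lightgbm"
    supports_interactions = False
    output_scale = "log_odds"

    def __init__(self, seed: int, params: dict):
        import lightgbm as lgb

        defaults = dict(n_estimators=100, n_jobs=1, random_state=seed,
                        verbose=-1, deterministic=True, force_row_wise=True)
        defaults.update(params)
        self.model = lgb.LGBMClassifier(**defaults)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_LGBMBackend":
        self.model.fit(np.asarray(X), np.asarray(y))
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(np.asarray(X))[:, 1]

    def raw_output(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(np.asarray(X), raw_score=True).ravel()

    def shap_values(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        contrib = np.asarray(self.model.predict_proba(np.asarray(X), pred_contrib=True))
        return contrib[:, :-1].astype(float), contrib[:, -1].astype(float)

    def shap_interactions(self, X: np.ndarray) -> np.ndarray:
        raise BackendError(
            "lightgbm exposes no SHAP interaction tensor; "
            f"supported backends: {INTERACTION_BACKENDS}"
        )


class _RFBackend:
    """Random forest; explained with exact interventional TreeSHAP
    (probability scale), against a background sampled from its training fold.
    """

    name = "random_forest"
    supports_interactions = False
    output_scale = "probability"

    def __init__(self, seed: int, params: dict):
        params = dict(params)
        self.background_size = int(params.pop("background_size", 50))
        defaults = dict(n_estimators=100, n_jobs=1, random_state=seed)
        defaults.update(params)
        self.model = RandomForestClassifier(**defaults)
        self._rng = np.random.default_rng(seed)
        self.background: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_RFBackend":
        X = np.asarray(X)
        self.model.fit(X, np.asarray(y))
        k = min(self.background_size, X.shape[0])
        idx = self._rng.choice(X.shape[0], size=k, replace=False)
        self.background = X[np.sort(idx)]
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(np.asarray(X))[:, 1]

    def raw_output(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X)

    def shap_values(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        from .explain import tree_shap_interventional

        phi, base = tree_shap_interventional(self.model, np.asarray(X), self.background)
        return phi, np.full(phi.shape[0], base)

    def shap_interactions(self, X: np.ndarray) -> np.ndarray:
        raise BackendError(
            "random_forest exposes no SHAP interaction tensor; "
            f"supported backends: {INTERACTION_BACKENDS}"
        )


_BACKEND_CLASSES = {
    "xgboost": _XGBBackend,
    "lightgbm": _LGBMBackend,
    "random_forest": _RFBackend,
}


def make_backend(name: str, seed: int, params: dict | None = None):
    if name not in _BACKEND_CLASSES:
        raise BackendError(f"unknown backend {name!r}; available: {BACKENDS}")
    return _BACKEND_CLASSES[name](seed, dict(params or {}))


@dataclass
class CVConfig:
    n_folds: int = 5
    n_repeats: int = 20
    seed: int = 0
    backend: str = "xgboost"
    params: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_folds < 2:
            raise ValueError(f"n_folds must be >= 2, got {self.n_folds}")
        if self.n_repeats < 1:
            raise ValueError(f"n_repeats must be >= 1, got {self.n_repeats}")
        if self.backend not in BACKENDS:
            raise BackendError(f"unknown backend {self.backend!r}; available: {BACKENDS}")


@dataclass
class CVResult:
    """Per-(repeat, fold) metrics, model registry, out-of-fold probabilities."""

    metrics: pd.DataFrame           # index (repeat, fold)
    registry: dict                  # (repeat, fold) -> fitted backend
    fold_map: pd.DataFrame          # samples x repeats -> test-fold index
    oof_prob: pd.DataFrame          # samples x repeats -> held-out CRC probability
    labels: pd.Series
    feature_names: list[str]
    config: CVConfig

    def summary(self) -> pd.DataFrame:
        return self.metrics.agg(["mean", "std"]).T

    def mean_oof_probability(self) -> pd.Series:
        """Per-subject CRC probability averaged over all repeats."""
        return self.oof_prob.mean(axis=1)


def compute_binary_metrics(labels, scores, threshold: float = 0.5) -> dict:
    """Accuracy / AU-ROC / AU-PRC with CRC as the positive class.

    AU-ROC is the Mann-Whitney concordance (ties count one half); AU-PRC is
    average precision (precision-weighted recall increments, no trapezoidal
    interpolation). Accuracy thresholds the score at ``threshold`` with >=
    mapping to the positive class.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present to compute ranking metrics")
    pred = (scores >= threshold).astype(int)
    return {
        "accuracy": float((pred == labels).mean()),
        "auroc": float(roc_auc_score(labels, scores)),
        "auprc": float(average_precision_score(labels, scores)),
    }


def run_repeated_cv(features: FeatureMatrix, labels: pd.Series, config: CVConfig) -> CVResult:
    """Stratified K-fold cross-validation repeated ``n_repeats`` times.

    Folds are re-randomised each repeat; every fitted model is retained in the
    registry (keyed by ``(repeat, fold)``) for the explanation and external
    ensembling stages, together with the held-out probabilities.
    """
    config.validate()
    labels = labels.loc[features.sample_ids]
    y = labels.to_numpy(dtype=int)
    if min((y == 0).sum(), (y == 1).sum()) < config.n_folds:
        raise ValueError("each class must contain at least n_folds samples")
    X = features.values.to_numpy(dtype=float)

    master = np.random.SeedSequence(config.seed)
    repeat_seqs = master.spawn(config.n_repeats)
    records, registry = [], {}
    fold_map = pd.DataFrame(index=features.sample_ids, columns=range(config.n_repeats), dtype=int)
    oof = pd.DataFrame(index=features.sample_ids, columns=range(config.n_repeats), dtype=float)

    for r, seq in enumerate(repeat_seqs):
        fold_seed, *model_seqs = seq.spawn(config.n_folds + 1)
        skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                              random_state=_spawn_int(fold_seed))
        for f, (train_idx, test_idx) in enumerate(skf.split(X, y)):
            if np.unique(y[test_idx]).size < 2 or np.unique(y[train_idx]).size < 2:
                raise ValueError(f"fold {(r, f)} lost a class; check stratification inputs")
            backend = make_backend(config.backend, _spawn_int(model_seqs[f]), config.params)
            backend.fit(X[train_idx], y[train_idx])
            prob = backend.predict_proba(X[test_idx])
            m = compute_binary_metrics(y[test_idx], prob)
            records.append({"repeat": r, "fold": f, **m})
            registry[(r, f)] = backend
            fold_map.iloc[test_idx, r] = f
            oof.iloc[test_idx, r] = prob

    metrics = pd.DataFrame(records).set_index(["repeat", "fold"])[
        ["accuracy", "auroc", "auprc"]
    ]
    return CVResult(metrics=metrics, registry=registry, fold_map=fold_map,
                    oof_prob=oof, labels=labels, feature_names=features.feature_names,
                    config=config)


@dataclass
class EnsemblePrediction:
    """Majority-vote label and mean CRC probability over all registry models."""

    votes_crc: pd.Series        # fraction of models voting CRC per sample
    mean_probability: pd.Series
    labels: pd.Series           # 0/1 with the documented tie rule
    n_models: int


def predict_external_ensemble(cv: CVResult, features_ext: FeatureMatrix,
                              *, threshold: float = 0.5) -> EnsemblePrediction:
    """Aggregate all stored CV models over an external cohort.

    Label = class with more than half the votes; an exact 50/50 tie resolves
    to CRC when the mean probability is >= 0.5. Feature names must match the
    training matrix exactly (order included).
    """
    if features_ext.feature_names != cv.feature_names:
        missing = sorted(set(cv.feature_names) - set(features_ext.feature_names))
        extra = sorted(set(features_ext.feature_names) - set(cv.feature_names))
        raise ValueError(
            f"external features do not match training features; "
            f"missing={missing[:10]}, unexpected={extra[:10]}"
        )
    X = features_ext.values.to_numpy(dtype=float)
    probs = np.vstack([b.predict_proba(X) for b in cv.registry.values()])
    votes = (probs >= threshold).mean(axis=0)
    mean_prob = probs.mean(axis=0)
    labels = np.where(votes > 0.5, 1, np.where(votes < 0.5, 0, (mean_prob >= 0.5).astype(int)))
    idx = features_ext.sample_ids
    return EnsemblePrediction(
        votes_crc=pd.Series(votes, index=idx),
        mean_probability=pd.Series(mean_prob, index=idx),
        labels=pd.Series(labels, index=idx),
        n_models=len(cv.registry),
    )


def align_external_features(features_ext: FeatureMatrix, train_names: list[str],
                            *, fill_value: float = 0.0) -> FeatureMatrix:
    """Reindex an external feature matrix onto the training feature set.

    Taxa absent from the external cohort are filled with ``fill_value`` (the
    CLR of a pseudocount-only taxon is approximately the negative mean log,
    but 0 — the CLR grand mean — is the neutral default); extra features are
    dropped. Intended for cohorts profiled against a narrower taxonomy.
    """
    vals = features_ext.values.reindex(columns=train_names)
    vals = vals.fillna(fill_value)
    kind = pd.Series(
        [features_ext.feature_kind.get(c, "taxon_clr") for c in train_names],
        index=train_names,
    )
    return FeatureMatrix(values=vals, feature_kind=kind, encodings=features_ext.encodings)
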