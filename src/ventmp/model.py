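"""Mortality-prediction model suite.

Recipe: ventilation-related features enter the model by default
(MP, MP/IBW, TV per kg IBW, 48 h SD of MP, PEEP, respiratory rate,
driving pressure); remaining candidates are pruned at |r| > 0.90
cross-correlation and the top 10 by random-forest importance are added;
minority oversampling balances the training folds only; six classifiers
(logistic regression, random forest, SVM, AdaBoost, XGBoost, stacking)
run under stratified 5-fold cross-validation at library defaults, scored
by accuracy, precision, recall and AUROC on the untouched test folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

MANDATORY_FEATURES = [
    "twa_mp", "twa_mp_ibw", "twa_tv_mlkg", "sd48_mp", "twa_peep", "twa_rr", "twa_dp",
]

MODEL_NAMES = ["logistic_regression", "random_forest", "svm",
               "ada_boost", "xgboost", "stacking"]


@dataclass
class FeatureSpec:
    mandatory: list[str]
    selected: list[str] = field(default_factory=list)
    pruned: list[tuple[str, str]] = field(default_factory=list)  # (dropped, kept partner)
    notes: list[str] = field(default_factory=list)

    @property
    def all_features(self) -> list[str]:
        return [*self.mandatory, *self.selected]

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class ModelReport:
    model_name: str
    accuracy: float
    precision: float
    recall: float
    auroc: float
    per_fold: dict[str, list[float]]
    seed: int
    features: list[str]

    def as_dict(self) -> dict:
        return asdict(self)


def prune_correlated(
    feature_table: pd.DataFrame,
    threshold: float = 0.90,
    mandatory: list[str] | None = None,
) -> FeatureSpec:
    """Drop the later column of every pair with |Pearson r| > threshold.

    Greedy scan in column order; mandatory features are never dropped (the
    non-mandatory partner goes instead). Constant columns, whose
    correlation is undefined, are dropped with a note. Deterministic for a
    fixed column order.
    """
    mandatory = MANDATORY_FEATURES if mandatory is None else mandatory
    cols = [c for c in feature_table.columns
            if pd.api.types.is_numeric_dtype(feature_table[c])]
    spec = FeatureSpec(mandatory=[c for c in cols if c in mandatory])

    keep: list[str] = []
    dropped: set[str] = set()
    for col in cols:
        if feature_table[col].nunique(dropna=True) <= 1:
            dropped.add(col)
            spec.notes.append(f"{col}: constant, correlation undefined, dropped")
            continue
        clash = None
        for prev in keep:
            r = feature_table[col].corr(feature_table[prev])
            if np.isfinite(r) and abs(r) > threshold:
                clash = prev
                break
        if clash is None:
            keep.append(col)
        elif col in mandatory and clash not in mandatory:
            # mandatory wins over the earlier non-mandatory partner
            keep.remove(clash)
            dropped.add(clash)
            spec.pruned.append((clash, col))
            keep.append(col)
        else:
            dropped.add(col)
            spec.pruned.append((col, clash))
    spec.selected = [c for c in keep if c not in spec.mandatory]
    return spec


def select_top_features(
    feature_table: pd.DataFrame,
    outcome,
    k: int = 10,
    spec: FeatureSpec | None = None,
    seed: int = 0,
    method: str = "impurity",
) -> FeatureSpec:
    """Keep the k most important non-mandatory features by random forest.

    ``method="impurity"`` ranks by the forest's impurity-based importance
    (default); ``"permutation"`` by sklearn permutation importance. The
    mandatory ventilation features always stay. Fewer than k candidates →
    all are kept, with a note.
    """
    from sklearn.ensemble import RandomForestClassifier

    if spec is None:
        spec = FeatureSpec(
            mandatory=[c for c in feature_table.columns if c in MANDATORY_FEATURES],
            selected=[c for c in feature_table.columns
                      if c not in MANDATORY_FEATURES
                      and pd.api.types.is_numeric_dtype(feature_table[c])],
        )
    candidates = spec.selected
    if len(candidates) <= k:
        if len(candidates) < k:
            spec.notes.append(f"only {len(candidates)} candidates for top-{k}")
        return spec
    X = feature_table[candidates].to_numpy(dtype=float)
    y = np.asarray(outcome)
    rf = RandomForestClassifier(random_state=seed)
    rf.fit(X, y)
    if method == "impurity":
        imp = rf.feature_importances_
    elif method == "permutation":
        from sklearn.inspection import permutation_importance

        imp = permutation_importance(rf, X, y, random_state=seed).importances_mean
    else:
        raise ValueError(f"unknown method {method!r}")
    order = np.argsort(imp)[::-1][:k]
    spec.selected = [candidates[i] for i in sorted(order)]
    return spec


def balance_minority(train_X, train_y, seed: int = 0, k_neighbors: int = 5):
    """SMOTE-style minority oversampling.

    Synthetic rows are convex combinations of a minority row and one of its
    ``k_neighbors`` nearest minority neighbors (Euclidean), with a uniform
    interpolation weight. Returns arrays with equal class counts; an
    already-balanced input is returned unchanged. Apply to training folds
    only.
    """
    from sklearn.neighbors import NearestNeighbors

    X = np.asarray(train_X, dtype=float)
    y = np.asarray(train_y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    if counts[0] == counts[1]:
        return X, y
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    X_min = X[y == minority]
    if len(X_min) < 2:
        raise ValueError("minority class needs at least 2 rows")

    k = min(k_neighbors, len(X_min) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    _, idx = nn.kneighbors(X_min)  # column 0 is the point itself

    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(X_min), size=n_needed)
    pick = rng.integers(1, k + 1, size=n_needed)
    lam = rng.random(size=n_needed)[:, None]
    neighbors = X_min[idx[base, pick]]
    synth = X_min[base] + lam * (neighbors - X_min[base])

    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return X_out, y_out


def _make_models(seed: int) -> dict:
    from sklearn.ensemble import (AdaBoostClassifier, RandomForestClassifier,
                                  StackingClassifier)
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC
    from xgboost import XGBClassifier

    scaled = lambda est: make_pipeline(StandardScaler(), est)  # noqa: E731
    base = {
        "logistic_regression": scaled(LogisticRegression(max_iter=1000, random_state=seed)),
        "random_forest": RandomForestClassifier(random_state=seed),
        "svm": scaled(SVC(probability=True, random_state=seed)),
        "ada_boost": AdaBoostClassifier(random_state=seed),
        "xgboost": XGBClassifier(random_state=seed, eval_metric="logloss"),
    }
    base["stacking"] = StackingClassifier(
        estimators=[(n, m) for n, m in list(base.items())],
        final_estimator=LogisticRegression(max_iter=1000, random_state=seed),
    )
    return base


def run_suite(
    feature_table: pd.DataFrame,
    outcome,
    folds: int = 5,
    seed: int = 0,
    feature_spec: FeatureSpec | None = None,
    oversample: bool = True,
    models: list[str] | None = None,
) -> list[ModelReport]:
    """Stratified k-fold evaluation of the six-model suite.

    Oversampling (and the scalers inside each pipeline) are fit on the
    training fold only; metrics are computed on the original, untouched
    test folds. Deterministic for a fixed seed.
    """
    from sklearn.metrics import (accuracy_score, precision_score, recall_score,
                                 roc_auc_score)
    from sklearn.model_selection import StratifiedKFold

    if folds < 2:
        raise ValueError("folds must be >= 2")
    cols = feature_spec.all_features if feature_spec else [
        c for c in feature_table.columns
        if pd.api.types.is_numeric_dtype(feature_table[c])]
    X = feature_table[cols].to_numpy(dtype=float)
    y = np.asarray(outcome).astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("outcome must be binary with both classes present")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    for _, test_idx in splits:
        if len(np.unique(y[test_idx])) < 2:
            raise ValueError("a fold is missing a class; reduce folds or rebalance")

    wanted = models or MODEL_NAMES
    reports = []
    for name in wanted:
        per_fold = {"accuracy": [], "precision": [], "recall": [], "auroc": []}
        for fold_i, (tr, te) in enumerate(splits):
            X_tr, y_tr = X[tr], y[tr]
            if oversample:
                X_tr, y_tr = balance_minority(X_tr, y_tr, seed=seed * 1000 + fold_i)
            model = _make_models(seed)[name]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X_tr, y_tr)
                y_hat = model.predict(X[te])
                y_prob = model.predict_proba(X[te])[:, 1]
            per_fold["accuracy"].append(accuracy_score(y[te], y_hat))
            per_fold["precision"].append(precision_score(y[te], y_hat, zero_division=0))
            per_fold["recall"].append(recall_score(y[te], y_hat, zero_division=0))
            per_fold["auroc"].append(roc_auc_score(y[te], y_prob))
        reports.append(ModelReport(
            model_name=name,
            accuracy=float(np.mean(per_fold["accuracy"])),
            precision=float(np.mean(per_fold["precision"])),
            recall=float(np.mean(per_fold["recall"])),
            auroc=float(np.mean(per_fold["auroc"])),
            per_fold={k: [float(v) for v in vs] for k, vs in per_fold.items()},
            seed=seed,
            features=cols,
        ))
    return reports


def fit_final_model(
    feature_table: pd.DataFrame,
    outcome,
    feature_spec: FeatureSpec | None = None,
    model_name: str = "xgboost",
    seed: int = 0,
    oversample: bool = True,
):
    """Fit the chosen model (boosted trees by default, for its runtime
    economy) on the full table for downstream individualization."""
    cols = feature_spec.all_features if feature_spec else [
        c for c in feature_table.columns
        if pd.api.types.is_numeric_dtype(feature_table[c])]
    X = feature_table[cols].to_numpy(dtype=float)
    y = np.asarray(outcome).astype(int)
    if oversample:
        X, y = balance_minority(X, y, seed=seed)
    model = _make_models(seed)[model_name]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    model.feature_names_ventmp_ = cols
    return model


def importance_ranking(fitted_model, feature_table: pd.DataFrame,
                       feature_names: list[str] | None = None) -> pd.DataFrame:
    """Rank features by mean |additive attribution| (TreeSHAP).

    For boosted-trees models, XGBoost's built-in TreeSHAP contributions
    are used; per-row attributions plus the bias term sum to the margin
    prediction exactly. Models without additive-attribution support fall
    back to permutation importance, flagged in the ``method`` column.
    """
    names = feature_names or getattr(fitted_model, "feature_names_ventmp_",
                                     list(feature_table.columns))
    X = feature_table[names].to_numpy(dtype=float)
    try:
        import xgboost as xgb

        booster = fitted_model.get_booster()
        contribs = booster.predict(xgb.DMatrix(X), pred_contribs=True)
        mean_abs = np.abs(contribs[:, :-1]).mean(axis=0)  # last column is bias
        method = "treeshap"
    except (AttributeError, ImportError):
        from sklearn.inspection import permutation_importance

        y_hat = fitted_model.predict(X)
        imp = permutation_importance(fitted_model, X, y_hat, random_state=0)
        mean_abs = imp.importances_mean
        method = "permutation_fallback"
    out = pd.DataFrame({"feature": names, "mean_abs_attribution": mean_abs,
                        "method": method})
    return out.sort_values("mean_abs_attribution", ascending=False,
                           kind="stable").reset_index(drop=True)


def shap_values(fitted_model, feature_table: pd.DataFrame,
                feature_names: list[str] | None = None):
    """Raw per-row TreeSHAP contributions (columns: features + bias)."""
    import xgboost as xgb

    names = feature_names or getattr(fitted_model, "feature_names_ventmp_",
                                     list(feature_table.columns))
    X = feature_table[names].to_numpy(dtype=float)
    return fitted_model.get_booster().predict(xgb.DMatrix(X), pred_contribs=True)
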