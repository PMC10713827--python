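"""Treated-versus-control well classification.

Three classifier kinds — a linear discriminant (LDA), level-wise boosted
trees (XGBoost) and leaf-wise boosted trees (LightGBM) — are tuned by
5-fold grid-search cross-validation on a stratified 90/10 split, evaluated
on the held-out test wells (confusion matrix + accuracy + per-row control
probability) and interrogated for their ten most important features.

Wells are labelled control (0) for vehicle and treated (1) for any
compound at any dose.  Feature scaling is fit on the training split only
by default; ``scale_before_split=True`` reproduces the scale-before-split
ordering instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import accuracy_score, confusion_matrix
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedKFold,
    cross_val_score,
    train_test_split,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import RobustScaler

from .catalogue import FEATURE_NAMES
from .plate import COMPOUNDS, VEHICLE

KINDS = ("lda", "lgbm", "xgb")

CONTROL, TREATED = 0, 1

DEFAULT_GRIDS: dict[str, list[dict] | dict] = {
    "lda": [
        {"clf__solver": ["svd"]},
        {"clf__solver": ["lsqr"], "clf__shrinkage": ["auto"]},
    ],
    "lgbm": {
        "clf__n_estimators": [100, 300],
        "clf__learning_rate": [0.05, 0.1],
        "clf__num_leaves": [15, 31],
    },
    "xgb": {
        "clf__n_estimators": [100, 300],
        "clf__learning_rate": [0.05, 0.1],
        "clf__max_depth": [3, 6],
    },
}


@dataclass
class SplitSpec:
    test_fraction: float = 0.10
    seed: int = 0
    stratify: bool = True


@dataclass
class ClassifierReport:
    kind: str
    best_params: dict
    cv_scores: list[float]
    cv_summary: dict[str, float]
    confusion: dict[str, int]        # TN, FP, FN, TP (control = negative)
    test_accuracy: float
    control_probabilities: list[float]
    importances: pd.DataFrame        # all features, normalized, descending
    grid_scores: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def top10(self) -> pd.DataFrame:
        return self.importances.head(10)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "best_params": self.best_params,
            "cv_scores": self.cv_scores,
            "cv_summary": self.cv_summary,
            "confusion": self.confusion,
            "test_accuracy": self.test_accuracy,
            "control_probabilities": self.control_probabilities,
            "top10_features": self.top10.to_dict(orient="records"),
        }


def label_wells(table: pd.DataFrame) -> pd.Series:
    """Vehicle -> control (0); any compound at any dose -> treated (1)."""
    known = set(COMPOUNDS) | {VEHICLE}
    unknown = set(table["compound"]) - known
    if unknown:
        raise ValueError(f"unknown conditions: {sorted(unknown)}")
    return (table["compound"] != VEHICLE).astype(int).rename("label")


def split_train_test(
    table: pd.DataFrame, labels: pd.Series, spec: SplitSpec = SplitSpec()
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series]:
    """Stratified split with ``test_fraction`` held out, per well row."""
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("both classes must be present to split")
    tr, te, ytr, yte = train_test_split(
        table,
        labels,
        test_size=spec.test_fraction,
        random_state=spec.seed,
        stratify=labels if spec.stratify else None,
    )
    return tr, te, ytr, yte


def make_estimator(kind: str, seed: int = 0, scale: bool = True) -> Pipeline:
    if kind == "lda":
        clf = LinearDiscriminantAnalysis()
    elif kind == "lgbm":
        import lightgbm as lgb

        clf = lgb.LGBMClassifier(
            random_state=seed, verbose=-1, importance_type="gain",
            n_jobs=1, min_child_samples=5,
        )
    elif kind == "xgb":
        import xgboost as xgb

        clf = xgb.XGBClassifier(
            random_state=seed,
            importance_type="gain",
            eval_metric="logloss",
            n_jobs=1,
            verbosity=0,
        )
    else:
        raise ValueError(f"unknown classifier kind {kind!r}; choose from {KINDS}")
    steps = [("scale", RobustScaler())] if scale else []
    steps.append(("clf", clf))
    return Pipeline(steps)


def tune_and_train(
    kind: str,
    X_train: pd.DataFrame,
    y_train: pd.Series,
    grid: dict | list | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    scale: bool = True,
) -> tuple[Pipeline, dict, pd.DataFrame]:
    """Exhaustive grid search (stratified ``cv_folds``-fold CV, accuracy),
    then refit on the full training set with the best point.

    Returns (fitted pipeline, best hyperparameters, per-point CV scores).
    """
    if grid is None:
        grid = DEFAULT_GRIDS[kind]
    est = make_estimator(kind, seed=seed, scale=scale)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    gs = GridSearchCV(est, grid, scoring="accuracy", cv=cv, refit=True)
    gs.fit(X_train[list(FEATURE_NAMES)].to_numpy(), np.asarray(y_train))
    scores = pd.DataFrame(
        {
            "params": [str(p) for p in gs.cv_results_["params"]],
            "mean_cv_accuracy": gs.cv_results_["mean_test_score"],
            "std_cv_accuracy": gs.cv_results_["std_test_score"],
        }
    )
    return gs.best_estimator_, dict(gs.best_params_), scores


def cross_validate(
    model: Pipeline,
    X: pd.DataFrame,
    y: pd.Series,
    k: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, dict[str, float]]:
    """Stratified k-fold accuracies with min/median/max summary."""
    n_min = int(y.value_counts().min())
    if k > len(y):
        raise ValueError(f"k={k} exceeds n={len(y)}")
    folds = k
    if n_min < k:
        import warnings

        folds = max(2, n_min)
        warnings.warn(
            f"minority class has {n_min} rows < k={k}; using {folds} folds"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = cross_val_score(
        clone(model), X[list(FEATURE_NAMES)].to_numpy(), np.asarray(y), cv=cv,
        scoring="accuracy",
    )
    summary = {
        "min": float(scores.min()),
        "median": float(np.median(scores)),
        "max": float(scores.max()),
    }
    return scores, summary


def evaluate(
    model: Pipeline, X_test: pd.DataFrame, y_test: pd.Series
) -> tuple[dict[str, int], float, np.ndarray]:
    """Confusion matrix (control = negative class), accuracy = trace/total,
    and the probability of the control class per test row."""
    if len(X_test) == 0:
        raise ValueError("empty test set")
    Xa = X_test[list(FEATURE_NAMES)].to_numpy()
    pred = model.predict(Xa)
    cm = confusion_matrix(y_test, pred, labels=[CONTROL, TREATED])
    tn, fp, fn, tp = cm.ravel()
    acc = accuracy_score(y_test, pred)
    proba = model.predict_proba(Xa)
    classes = list(model.classes_)
    p_control = proba[:, classes.index(CONTROL)]
    return (
        {"TN": int(tn), "FP": int(fp), "FN": int(fn), "TP": int(tp)},
        float(acc),
        p_control,
    )


def feature_importance(
    model: Pipeline, kind: str, feature_names: tuple[str, ...] = FEATURE_NAMES
) -> pd.DataFrame:
    """Normalized importances, descending.

    LDA: absolute coefficients on the (robust-scaled) features; boosted
    trees: gain-based importances.  Weights are fractions summing to 1.
    """
    clf = model.named_steps["clf"]
    if kind == "lda":
        if not hasattr(clf, "coef_"):
            raise ValueError("model is not fitted")
        raw = np.abs(np.ravel(clf.coef_))
    elif kind == "lgbm":
        raw = clf.booster_.feature_importance(importance_type="gain").astype(float)
    elif kind == "xgb":
        raw = np.asarray(clf.feature_importances_, dtype=float)
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    total = raw.sum()
    weights = raw / total if total > 0 else raw
    df = pd.DataFrame({"feature": list(feature_names), "weight": weights})
    return df.sort_values("weight", ascending=False, ignore_index=True)


def run_classification(
    table: pd.DataFrame,
    kinds: tuple[str, ...] = KINDS,
    seed: int = 0,
    spec: SplitSpec | None = None,
    cv_folds: int = 5,
    cv_k: int = 10,
    scale_before_split: bool = False,
) -> dict[str, ClassifierReport]:
    """End-to-end procedure for each classifier kind.

    ``scale_before_split=True`` robust-scales the whole table before splitting
    (scale-then-split); the default fits the scaler inside the pipeline on
    training folds only, which avoids information leakage.
    """
    from .profiling import robust_scale

    # drop wells that failed featurization entirely; median-impute isolated
    # missing composites (e.g. no TH-positive cell in a well)
    feat = table[list(FEATURE_NAMES)]
    valid = ~feat.isna().all(axis=1)
    table = table.loc[valid].copy()
    table[list(FEATURE_NAMES)] = feat.loc[valid].fillna(feat.loc[valid].median())

    y = label_wells(table)
    spec = spec or SplitSpec(seed=seed)
    data = table
    scale_in_pipeline = True
    if scale_before_split:
        data = robust_scale(table).table
        scale_in_pipeline = False
    X_train, X_test, y_train, y_test = split_train_test(data, y, spec)
    reports: dict[str, ClassifierReport] = {}
    for kind in kinds:
        model, best, grid_scores = tune_and_train(
            kind, X_train, y_train, cv_folds=cv_folds, seed=seed,
            scale=scale_in_pipeline,
        )
        cv_scores, cv_summary = cross_validate(
            model, X_train, y_train, k=cv_k, seed=seed
        )
        confusion, acc, p_control = evaluate(model, X_test, y_test)
        imp = feature_importance(model, kind)
        reports[kind] = ClassifierReport(
            kind=kind,
            best_params=best,
            cv_scores=[float(s) for s in cv_scores],
            cv_summary=cv_summary,
            confusion=confusion,
            test_accuracy=acc,
            control_probabilities=[float(p) for p in p_control],
            importances=imp,
            grid_scores=grid_scores,
        )
    return reports
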