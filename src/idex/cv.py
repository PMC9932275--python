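"""Repeated stratified cross-validation over the four classifier families.

Produces an out-of-fold score tensor (classifier x round x patient) in which
all classifiers share the same fold split within a round, plus per-round
performance distributions (AUC, accuracy, sensitivity, specificity, F1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .feature_selection import boruta_select
from .preprocessing import DecisionThreshold, EncodedMatrix

__all__ = [
    "ModelSpec",
    "CVPlan",
    "ScoreTensor",
    "PerformanceDistribution",
    "make_model",
    "run_repeated_cv",
    "compute_performance",
    "FAMILIES",
]

FAMILIES = ("RF", "SVM", "XGB", "NB")

#: Published per-family defaults. XGB keys use the boosting parameter names
#: they were reported under; the backend translates them.
_DEFAULTS: dict[str, dict] = {
    "RF": {"n_estimators": 500, "min_samples_leaf": 5},
    "SVM": {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
    "XGB": {
        "eta": 0.1,
        "n_estimators": 100,
        "max_depth": 5,
        "min_child_weight": 2,
        "subsample": 0.9,
        "colsample_bytree": 1.0,
    },
    "NB": {},
}


@dataclass(frozen=True)
class ModelSpec:
    family: str
    hyperparameters: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}")
        unknown = set(self.hyperparameters) - set(_DEFAULTS[self.family])
        if unknown:
            raise ValueError(f"unknown hyperparameters for {self.family}: {sorted(unknown)}")

    def resolved(self) -> dict:
        params = dict(_DEFAULTS[self.family])
        params.update(self.hyperparameters)
        return params


class _Model:
    """fit/score wrapper putting every family on a [0,1] probability scale."""

    def __init__(self, family: str, estimator):
        self.family = family
        self._est = estimator

    def fit(self, X, y) -> "_Model":
        self._est.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
        return self

    def score(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        proba = self._est.predict_proba(X)
        pos = list(self._est.classes_).index(1) if 1 in self._est.classes_ else -1
        return proba[:, pos]


class _PlattSVC:
    """RBF SVC with a sigmoid map fit on training decision values.

    Puts the SVM on the same probability scale as the other families so one
    shared prevalence threshold applies; the sigmoid is a 1-D logistic
    regression on the decision function, fit on the training fold itself.
    """

    def __init__(self, kernel: str, C: float, gamma, seed: int):
        self._svc = SVC(kernel=kernel, C=C, gamma=gamma, random_state=seed)
        self._platt = None

    def fit(self, X, y):
        from sklearn.linear_model import LogisticRegression

        self._svc.fit(X, y)
        d = self._svc.decision_function(X).reshape(-1, 1)
        self._platt = LogisticRegression(C=1e6).fit(d, y)
        self.classes_ = self._platt.classes_
        return self

    def predict_proba(self, X):
        d = self._svc.decision_function(X).reshape(-1, 1)
        return self._platt.predict_proba(d)


def make_model(spec: ModelSpec, seed: int = 0) -> _Model:
    """Instantiate a scoring model for a family with its default parameters.

    SVM scores come from Platt-style probability calibration fit on the
    training data so every family shares one probability scale. The gradient
    boosting family accepts the published boosting parameter names
    (``eta``, ``min_child_weight``, ``colsample_bytree``) and maps them onto
    the scikit-learn implementation.
    """
    p = spec.resolved()
    if spec.family == "RF":
        est = RandomForestClassifier(
            n_estimators=p["n_estimators"],
            min_samples_leaf=p["min_samples_leaf"],
            random_state=seed,
            n_jobs=1,
        )
    elif spec.family == "SVM":
        est = _PlattSVC(kernel=p["kernel"], C=p["C"], gamma=p["gamma"], seed=seed)
    elif spec.family == "XGB":
        colsample = p["colsample_bytree"]
        est = GradientBoostingClassifier(
            learning_rate=p["eta"],
            n_estimators=p["n_estimators"],
            max_depth=p["max_depth"],
            min_samples_leaf=max(1, int(p["min_child_weight"])),
            subsample=p["subsample"],
            max_features=None if colsample >= 1.0 else colsample,
            random_state=seed,
        )
    elif spec.family == "NB":
        est = GaussianNB()
    else:  # pragma: no cover - guarded by ModelSpec
        raise ValueError(spec.family)
    return _Model(spec.family, est)


@dataclass(frozen=True)
class CVPlan:
    n_rounds: int = 20
    n_folds: int = 5
    stratified: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rounds < 1 or self.n_folds < 2:
            raise ValueError("need n_rounds >= 1 and n_folds >= 2")


@dataclass
class ScoreTensor:
    """Out-of-fold scores: ``scores[classifier]`` is (n_rounds, n_patients)."""

    scores: dict
    fold_assignment: np.ndarray  # (n_rounds, n_patients) fold index
    patient_ids: np.ndarray
    selected_features: dict  # (round, fold) -> list of feature names

    @property
    def classifiers(self) -> list[str]:
        return list(self.scores)

    @property
    def n_rounds(self) -> int:
        return self.fold_assignment.shape[0]

    @property
    def n_patients(self) -> int:
        return self.fold_assignment.shape[1]

    def validate(self) -> None:
        for name, arr in self.scores.items():
            if arr.shape != self.fold_assignment.shape:
                raise ValueError(f"tensor shape mismatch for {name}")
            if np.isnan(arr).any():
                raise ValueError(f"unfilled cells in tensor for {name}")
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError(f"scores outside [0,1] for {name}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for clf, arr in self.scores.items():
            for r in range(self.n_rounds):
                rows.append(
                    pd.DataFrame(
                        {
                            "classifier": clf,
                            "round": r,
                            "patient_id": self.patient_ids,
                            "score": arr[r],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


@dataclass
class PerformanceDistribution:
    """Per-round metric values for one classifier (NaN marks undefined)."""

    metrics: dict  # metric name -> list of per-round values

    def summary(self) -> pd.DataFrame:
        rows = []
        for m, vals in self.metrics.items():
            arr = np.asarray(vals, dtype=float)
            ok = arr[~np.isnan(arr)]
            rows.append(
                {
                    "metric": m,
                    "median": float(np.median(ok)) if ok.size else np.nan,
                    "mean": float(ok.mean()) if ok.size else np.nan,
                    "sd": float(ok.std(ddof=1)) if ok.size > 1 else np.nan,
                    "n_rounds": len(vals),
                }
            )
        return pd.DataFrame(rows)


def run_repeated_cv(
    X: EncodedMatrix,
    y,
    specs: Sequence[ModelSpec],
    plan: CVPlan,
    selection: Mapping | Sequence | None = None,
    patient_ids: Sequence | None = None,
) -> ScoreTensor:
    """Out-of-fold scores for every classifier under a shared fold plan.

    Per round one stratified split is drawn (seed = master_seed + round) and
    shared by all classifiers. ``selection`` is either a fixed feature list,
    a dict of Boruta parameters for nested per-training-fold selection, or
    None (all features). If nested selection confirms nothing for a fold, all
    features are used for that fold (recorded as such).
    """
    y = np.asarray(y, dtype=int)
    df = X.values
    if df.isna().any().any():
        raise ValueError("matrix contains missing values; impute first")
    if patient_ids is None:
        patient_ids = np.arange(len(df))

    nested = isinstance(selection, Mapping)
    fixed = list(selection) if (selection is not None and not nested) else None

    scores = {s.family: np.full((plan.n_rounds, len(df)), np.nan) for s in specs}
    folds = np.full((plan.n_rounds, len(df)), -1, dtype=int)
    selected: dict = {}

    for r in range(plan.n_rounds):
        seed_r = plan.master_seed + r
        if plan.stratified:
            splitter = StratifiedKFold(n_splits=plan.n_folds, shuffle=True, random_state=seed_r)
        else:
            from sklearn.model_selection import KFold

            splitter = KFold(n_splits=plan.n_folds, shuffle=True, random_state=seed_r)
        for k, (train_idx, test_idx) in enumerate(splitter.split(df, y)):
            y_train = y[train_idx]
            if len(np.unique(y_train)) < 2:
                raise ValueError(f"single-class training fold (round {r}, fold {k})")
            if nested:
                res = boruta_select(
                    df.iloc[train_idx], y_train, seed=seed_r * 97 + k, **dict(selection)
                )
                # the confirmed set is what selection-frequency reporting uses;
                # an empty confirmation falls back to all features for fitting only
                selected[(r, k)] = sorted(res.confirmed)
                feats = sorted(res.confirmed) or list(df.columns)
            elif fixed is not None:
                selected[(r, k)] = feats = fixed
            else:
                selected[(r, k)] = feats = list(df.columns)
            X_train = df.iloc[train_idx][feats].to_numpy(dtype=float)
            X_test = df.iloc[test_idx][feats].to_numpy(dtype=float)
            folds[r, test_idx] = k
            for spec in specs:
                model = make_model(spec, seed=seed_r * 131 + k)
                model.fit(X_train, y_train)
                scores[spec.family][r, test_idx] = model.score(X_test)

    tensor = ScoreTensor(
        scores=scores,
        fold_assignment=folds,
        patient_ids=np.asarray(patient_ids),
        selected_features=selected,
    )
    tensor.validate()
    return tensor


def _round_metrics(y_true: np.ndarray, s: np.ndarray, threshold: DecisionThreshold) -> dict:
    pred = threshold.apply(s)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    out = {
        "accuracy": (tp + tn) / len(y_true),
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
        "F1": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else np.nan,
    }
    out["AUC"] = roc_auc_score(y_true, s) if len(np.unique(y_true)) == 2 else np.nan
    return out


def compute_performance(
    tensor: ScoreTensor, y, threshold: DecisionThreshold
) -> dict[str, PerformanceDistribution]:
    """Per-classifier per-round metric distributions from an OOF tensor."""
    tensor.validate()
    y = np.asarray(y, dtype=int)
    out = {}
    for clf, arr in tensor.scores.items():
        metrics: dict[str, list] = {m: [] for m in ("AUC", "accuracy", "sensitivity", "specificity", "F1")}
        for r in range(tensor.n_rounds):
            vals = _round_metrics(y, arr[r], threshold)
            for m in metrics:
                metrics[m].append(vals[m])
        out[clf] = PerformanceDistribution(metrics=metrics)
    return out
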