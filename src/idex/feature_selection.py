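"""Boruta-style all-relevant feature selection and nested selection frequency.

Each iteration appends permuted (shadow) copies of every still-active
feature, fits a random-forest ensemble, and scores a "hit" for a real
feature whose importance exceeds the maximum shadow importance. Features are
confirmed/rejected by a binomial test of the hit count against p = 0.5 with
Bonferroni correction over the original feature count; rejected features are
dropped from subsequent iterations.

The default importance measure is held-out permutation importance on the
Brier score: the ensemble is fit on a fresh random 60% of the rows each
iteration and the importance of a column is the increase in Brier score on
the remaining 40% when that column is permuted. In-sample impurity
importance ("mdi") systematically inflates the apparent relevance of noise
features with lucky sample correlations and is kept only as an option.
Several shadow copies per feature (default 16) raise the null bar to the
maximum of many permuted draws, which is what keeps the false-confirmation
rate near zero on pure-noise labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .preprocessing import EncodedMatrix

__all__ = [
    "BorutaResult",
    "SelectionFrequency",
    "boruta_select",
    "nested_selection_frequency",
    "selection_frequency_from_tensor",
    "select_features",
]


@dataclass
class BorutaResult:
    confirmed: set
    rejected: set
    tentative: set
    hit_counts: dict
    n_iterations_run: int

    def __post_init__(self) -> None:
        overlap = (self.confirmed & self.rejected) | (self.confirmed & self.tentative) | (
            self.rejected & self.tentative
        )
        if overlap:
            raise ValueError(f"feature sets must partition the input: overlap {overlap}")


@dataclass
class SelectionFrequency:
    frequency: dict  # feature -> fraction of fits confirmed
    n_fits: int

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.frequency.items() if not 0.0 <= v <= 1.0}
        if bad:
            raise ValueError(f"frequencies outside [0,1]: {bad}")

    def to_frame(self) -> pd.DataFrame:
        items = sorted(self.frequency.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(
            {
                "feature": [k for k, _ in items],
                "frequency": [v for _, v in items],
                "rank": np.arange(1, len(items) + 1),
            }
        )


def heldout_brier_importance(
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    n_estimators: int = 100,
    repeats: int = 3,
    test_frac: float = 0.4,
) -> np.ndarray:
    """Permutation importance on a held-out split, measured by Brier score.

    Fits a forest on a random (1 - test_frac) subset, then for each column
    permutes the held-out values ``repeats`` times and returns the mean
    increase in Brier score (predict on all permuted variants in one batch).
    """
    n = len(X)
    perm = rng.permutation(n)
    cut = int(round((1.0 - test_frac) * n))
    tr, te = perm[:cut], perm[cut:]
    rf = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features="sqrt",
        random_state=int(rng.integers(0, 2**31 - 1)),
        n_jobs=1,
    )
    rf.fit(X[tr], y[tr])
    X_te, y_te = X[te], y[te]
    pos = int(np.where(rf.classes_ == 1)[0][0]) if 1 in rf.classes_ else -1
    base = float(((rf.predict_proba(X_te)[:, pos] - y_te) ** 2).mean())
    m = X.shape[1]
    big = np.repeat(X_te[None], m * repeats, axis=0)
    for rep in range(repeats):
        for j in range(m):
            big[rep * m + j, :, j] = X_te[rng.permutation(len(te)), j]
    proba = rf.predict_proba(big.reshape(-1, m))[:, pos].reshape(repeats, m, len(te))
    brier = ((proba - y_te[None, None, :]) ** 2).mean(axis=2).mean(axis=0)
    return brier - base


def _mdi_importance(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator, n_estimators: int
) -> np.ndarray:
    rf = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features="sqrt",
        random_state=int(rng.integers(0, 2**31 - 1)),
        n_jobs=1,
    )
    rf.fit(X, y)
    return rf.feature_importances_


def make_shadow(real: np.ndarray, rng: np.random.Generator, copies: int) -> np.ndarray:
    """``copies`` independently permuted copies of every column of ``real``."""
    shadow = np.tile(real, (1, copies))
    for j in range(shadow.shape[1]):
        shadow[:, j] = shadow[rng.permutation(len(shadow)), j]
    return shadow


def boruta_select(
    X: EncodedMatrix | pd.DataFrame,
    y,
    max_iterations: int = 100,
    alpha: float = 0.01,
    seed: int = 0,
    n_estimators: int = 100,
    importance: str = "heldout_brier",
    shadow_copies: int = 16,
) -> BorutaResult:
    """Run shadow-feature all-relevant selection on an encoded matrix.

    Parameters
    ----------
    X:
        Encoded (no-missing) feature matrix.
    y:
        Binary labels; must contain both classes.
    max_iterations:
        Iteration cap; features still undecided stay tentative.
    alpha:
        Significance level of the hit-count binomial test against p = 0.5,
        Bonferroni-corrected over the number of input features.
    importance:
        ``"heldout_brier"`` (default) or ``"mdi"``.
    shadow_copies:
        Permuted copies per active feature forming the null reference.
    """
    df = X.values if isinstance(X, EncodedMatrix) else pd.DataFrame(X)
    y = np.asarray(y, dtype=int)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if len(np.unique(y)) < 2:
        raise ValueError("constant labels: selection undefined")
    if importance not in {"heldout_brier", "mdi"}:
        raise ValueError(f"unknown importance measure {importance!r}")

    rng = np.random.default_rng(seed)
    features = list(df.columns)
    corrected = alpha / len(features)

    confirmed: set = set()
    rejected: set = set()
    tentative: set = set(features)
    hits = {f: 0 for f in features}
    n_iter = 0

    while tentative and n_iter < max_iterations:
        n_iter += 1
        active = [f for f in features if f not in rejected]
        real = df[active].to_numpy(dtype=float)
        shadow = make_shadow(real, rng, shadow_copies)
        both = np.hstack([real, shadow])
        if importance == "heldout_brier":
            imp = heldout_brier_importance(both, y, rng, n_estimators)
        else:
            imp = _mdi_importance(both, y, rng, n_estimators)
        real_imp, shadow_max = imp[: len(active)], imp[len(active):].max()
        for f, v in zip(active, real_imp):
            if f in tentative and v > shadow_max:
                hits[f] += 1
        for f in sorted(tentative):
            k = hits[f]
            if binomtest(k, n_iter, 0.5, alternative="greater").pvalue < corrected:
                confirmed.add(f)
            elif binomtest(k, n_iter, 0.5, alternative="less").pvalue < corrected:
                rejected.add(f)
        tentative -= confirmed | rejected

    return BorutaResult(
        confirmed=confirmed,
        rejected=rejected,
        tentative=tentative,
        hit_counts=hits,
        n_iterations_run=n_iter,
    )


def nested_selection_frequency(
    X: EncodedMatrix | pd.DataFrame,
    y,
    n_rounds: int = 20,
    n_folds: int = 5,
    master_seed: int = 0,
    boruta_params: Mapping | None = None,
) -> SelectionFrequency:
    """Selection frequency over every training fold of a repeated-CV plan.

    ``boruta_select`` runs on each of the ``n_rounds * n_folds`` training
    folds; a feature's frequency is the fraction of fits in which it was
    confirmed (tentative at termination counts as not selected).
    """
    if n_rounds * n_folds < 1:
        raise ValueError("plan must contain at least one fit")
    df = X.values if isinstance(X, EncodedMatrix) else pd.DataFrame(X)
    y = np.asarray(y, dtype=int)
    params = dict(boruta_params or {})
    counts = {f: 0 for f in df.columns}
    n_fits = 0
    for r in range(n_rounds):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=master_seed + r)
        for k, (train_idx, _) in enumerate(skf.split(df, y)):
            res = boruta_select(
                df.iloc[train_idx],
                y[train_idx],
                seed=master_seed * 1_000_003 + r * 101 + k,
                **params,
            )
            n_fits += 1
            for f in res.confirmed:
                counts[f] += 1
    return SelectionFrequency(
        frequency={f: c / n_fits for f, c in counts.items()}, n_fits=n_fits
    )


def selection_frequency_from_tensor(tensor, feature_names: Sequence) -> SelectionFrequency:
    """Selection frequency from the per-fit feature records of a score tensor.

    Lets the nested-selection frequency and the classification share a single
    repeated-CV pass.
    """
    records = tensor.selected_features
    if not records:
        raise ValueError("tensor carries no per-fit selection records")
    counts = {f: 0 for f in feature_names}
    for feats in records.values():
        for f in feats:
            if f in counts:
                counts[f] += 1
    n_fits = len(records)
    return SelectionFrequency(
        frequency={f: c / n_fits for f, c in counts.items()}, n_fits=n_fits
    )


def select_features(freq: SelectionFrequency, cutoff: float = 0.60) -> list:
    """Features at or above the frequency cutoff, ranked descending."""
    kept = [(f, v) for f, v in freq.frequency.items() if v >= cutoff]
    kept.sort(key=lambda kv: (-kv[1], kv[0]))
    return [f for f, _ in kept]
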