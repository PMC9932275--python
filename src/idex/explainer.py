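"""From-scratch Shapley-value attribution for fitted scoring models.

Two routes are provided and kept independent of each other:

* :func:`exact_shapley` — direct coalition enumeration of the Shapley
  formula with marginal masking against a weighted background set;
* :func:`kernel_shap` — a kernel-weighted linear surrogate fitted by
  constrained weighted least squares over coalition indicator vectors, in
  "full" (all coalitions) or sampled mode.

Both satisfy local accuracy: base value plus the attribution vector sums to
the model score for the explained instance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, factorial
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cv import ModelSpec, make_model
from .preprocessing import EncodedMatrix

__all__ = [
    "BackgroundSet",
    "Explanation",
    "GlobalSummary",
    "base_value",
    "exact_shapley",
    "kernel_shap",
    "explain_patients",
    "explain_confounders",
    "global_summary",
    "explanations_to_frame",
]

EXACT_LIMIT = 16


@dataclass
class BackgroundSet:
    """Reference rows (and weights) defining the no-information expectation."""

    rows: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rows = np.atleast_2d(np.asarray(self.rows, dtype=float))
        if self.rows.size == 0:
            raise ValueError("background set must be non-empty")
        if self.weights is None:
            self.weights = np.full(len(self.rows), 1.0 / len(self.rows))
        else:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (len(self.rows),) or (w < 0).any() or w.sum() <= 0:
                raise ValueError("weights must be non-negative, one per row")
            self.weights = w / w.sum()

    @classmethod
    def summarize(cls, rows: np.ndarray, k: int, seed: int = 0) -> "BackgroundSet":
        """k weighted medoids (nearest actual rows to k-means centers)."""
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        if k >= len(rows):
            return cls(rows)
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, random_state=seed, n_init=4).fit(rows)
        medoids, weights = [], []
        for c in range(k):
            members = rows[km.labels_ == c]
            if len(members) == 0:
                continue
            d = np.linalg.norm(members - km.cluster_centers_[c], axis=1)
            medoids.append(members[int(d.argmin())])
            weights.append(len(members) / len(rows))
        return cls(np.vstack(medoids), np.asarray(weights))


@dataclass
class Explanation:
    patient_id: object
    base_value: float
    phi: np.ndarray
    feature_names: list
    model_score: float
    method: str
    n_coalitions_used: int

    @property
    def local_accuracy_gap(self) -> float:
        return abs(self.base_value + float(self.phi.sum()) - self.model_score)


def _as_fn(model) -> Callable[[np.ndarray], np.ndarray]:
    if callable(model) and not hasattr(model, "score"):
        return lambda X: np.asarray(model(np.atleast_2d(X)), dtype=float)
    return lambda X: np.asarray(model.score(np.atleast_2d(X)), dtype=float)


def base_value(model, background: BackgroundSet) -> float:
    """Weighted mean model score over the background rows."""
    fn = _as_fn(model)
    return float(np.dot(background.weights, fn(background.rows)))


def _coalition_values(fn, x: np.ndarray, background: BackgroundSet, masks: np.ndarray) -> np.ndarray:
    """v(S) for each mask row: background rows with S-columns fixed to x."""
    n_bg, m = background.rows.shape
    out = np.empty(len(masks))
    chunk = max(1, 262_144 // max(n_bg, 1))
    for start in range(0, len(masks), chunk):
        sub = masks[start : start + chunk]
        big = np.repeat(background.rows[None, :, :], len(sub), axis=0)  # (c, n_bg, m)
        sel = np.broadcast_to(sub[:, None, :], big.shape)
        big = np.where(sel, x[None, None, :], big)
        scores = fn(big.reshape(-1, m)).reshape(len(sub), n_bg)
        out[start : start + chunk] = scores @ background.weights
    return out


def _all_masks(m: int) -> np.ndarray:
    ints = np.arange(2**m, dtype=np.uint32)
    return (ints[:, None] >> np.arange(m)[None, :]) & 1 == 1


def exact_shapley(
    model, x, background: BackgroundSet, patient_id=None,
    feature_names: Sequence | None = None, exact_limit: int = EXACT_LIMIT,
) -> Explanation:
    """Exact Shapley values by full coalition enumeration.

    ``phi_j = sum_{S not containing j} |S|!(M-|S|-1)!/M! [v(S+j) - v(S)]``
    with v the background-weighted mean score under marginal masking.
    """
    x = np.asarray(x, dtype=float).ravel()
    m = x.size
    if m > exact_limit:
        raise ValueError(
            f"{m} features exceeds the exact enumeration limit {exact_limit}; "
            "use kernel_shap"
        )
    fn = _as_fn(model)
    masks = _all_masks(m)
    v = _coalition_values(fn, x, background, masks)
    sizes = masks.sum(axis=1)
    # weight by coalition size: |S|!(M-|S|-1)!/M!
    w = np.array([factorial(s) * factorial(m - s - 1) / factorial(m) for s in range(m)])
    phi = np.zeros(m)
    mask_index = {tuple(row): i for i, row in enumerate(masks.astype(int))}
    for i, row in enumerate(masks):
        for j in range(m):
            if row[j]:
                continue
            with_j = row.copy()
            with_j[j] = True
            phi[j] += w[sizes[i]] * (v[mask_index[tuple(with_j.astype(int))]] - v[i])
    names = list(feature_names) if feature_names is not None else [f"f{j}" for j in range(m)]
    return Explanation(
        patient_id=patient_id,
        base_value=float(v[0]),
        phi=phi,
        feature_names=names,
        model_score=float(v[-1]),
        method="exact",
        n_coalitions_used=2**m,
    )


def _kernel_weight(m: int, s: int) -> float:
    return (m - 1) / (comb(m, s) * s * (m - s))


def _sample_masks(m: int, n: int, rng: np.random.Generator) -> np.ndarray:
    sizes = np.arange(1, m)
    p = np.array([_kernel_weight(m, s) * comb(m, s) for s in sizes])
    p /= p.sum()
    seen: set = set()
    rows = []
    attempts = 0
    while len(rows) < n and attempts < 50 * n:
        attempts += 1
        s = int(rng.choice(sizes, p=p))
        idx = tuple(sorted(rng.choice(m, size=s, replace=False).tolist()))
        if idx in seen:
            continue
        seen.add(idx)
        row = np.zeros(m, dtype=bool)
        row[list(idx)] = True
        rows.append(row)
    return np.array(rows)


def kernel_shap(
    model, x, background: BackgroundSet, n_coalitions: int | str = "full",
    seed: int = 0, patient_id=None, feature_names: Sequence | None = None,
) -> Explanation:
    """Kernel-weighted linear surrogate Shapley values.

    Fits the linear explanation model by weighted least squares over coalition
    indicator vectors with the Shapley kernel weight, constrained so the
    coefficients plus the base value reproduce the model score (local
    accuracy). ``"full"`` enumerates all coalitions; an integer samples that
    many distinct non-trivial coalitions by kernel weight (the two trivial
    coalitions enter through the constraints).
    """
    x = np.asarray(x, dtype=float).ravel()
    m = x.size
    if m < 1:
        raise ValueError("need at least one feature")
    fn = _as_fn(model)
    base = base_value(model, background)
    fx = float(fn(x[None, :])[0])
    delta = fx - base
    names = list(feature_names) if feature_names is not None else [f"f{j}" for j in range(m)]

    if m == 1:
        return Explanation(patient_id, base, np.array([delta]), names, fx, "kernel", 2)

    full = n_coalitions == "full" or (
        isinstance(n_coalitions, (int, np.integer)) and n_coalitions >= 2**m - 2
    )
    if full:
        masks = _all_masks(m)
        masks = masks[(masks.sum(axis=1) > 0) & (masks.sum(axis=1) < m)]
        used = 2**m
    else:
        n_coalitions = int(n_coalitions)
        if n_coalitions < m + 2:
            raise ValueError(f"n_coalitions must be >= M+2 = {m + 2}")
        rng = np.random.default_rng(seed)
        masks = _sample_masks(m, n_coalitions, rng)
        used = len(masks) + 2

    v = _coalition_values(fn, x, background, masks)
    z = masks.astype(float)
    pi = np.array([_kernel_weight(m, int(s)) for s in masks.sum(axis=1)])
    # eliminate phi_m via the efficiency constraint
    zt = z[:, :-1] - z[:, -1:]
    target = (v - base) - z[:, -1] * delta
    sw = np.sqrt(pi)
    beta, *_ = np.linalg.lstsq(zt * sw[:, None], target * sw, rcond=None)
    phi = np.append(beta, delta - beta.sum())
    return Explanation(patient_id, base, phi, names, fx, "kernel", used)


# --------------------------------------------------------------------------
# Cohort-level drivers

def explain_patients(
    model,
    train_matrix,
    test_matrix,
    method: str = "kernel",
    n_coalitions: int | str = "full",
    background_size: int | None = None,
    patient_ids: Sequence | None = None,
    feature_names: Sequence | None = None,
    seed: int = 0,
) -> list[Explanation]:
    """One explanation per test row, with the training matrix as background."""
    if method not in {"exact", "kernel"}:
        raise ValueError(f"unknown method {method!r}")
    train = _matrix_values(train_matrix)
    test = _matrix_values(test_matrix)
    if feature_names is None:
        feature_names = _matrix_names(test_matrix, test.shape[1])
    if train.shape[1] != test.shape[1]:
        raise ValueError("train/test feature count mismatch")
    if background_size is not None and background_size < len(train):
        background = BackgroundSet.summarize(train, background_size, seed=seed)
    else:
        background = BackgroundSet(train)
    ids = list(patient_ids) if patient_ids is not None else list(range(len(test)))
    out = []
    for i, row in enumerate(test):
        if method == "exact":
            exp = exact_shapley(model, row, background, ids[i], feature_names)
        else:
            exp = kernel_shap(
                model, row, background, n_coalitions, seed=seed + i,
                patient_id=ids[i], feature_names=feature_names,
            )
        out.append(exp)
    return out


def _matrix_values(mat) -> np.ndarray:
    if isinstance(mat, EncodedMatrix):
        return mat.to_numpy()
    if isinstance(mat, pd.DataFrame):
        return mat.to_numpy(dtype=float)
    return np.atleast_2d(np.asarray(mat, dtype=float))


def _matrix_names(mat, n: int) -> list:
    if isinstance(mat, EncodedMatrix):
        return mat.columns
    if isinstance(mat, pd.DataFrame):
        return list(mat.columns)
    return [f"f{j}" for j in range(n)]


def explain_confounders(
    report,
    cohort,
    spec: ModelSpec,
    method: str = "kernel",
    features: Sequence | None = None,
    n_coalitions: int | str = "full",
    background_size: int | None = None,
    seed: int = 0,
) -> list[Explanation]:
    """Explain every confounding patient with the included patients as training set."""
    from .preprocessing import encode, impute

    if not report.included_ids:
        raise ValueError("consensus report has an empty included set")
    if not report.confounding_ids:
        return []
    included = cohort.subset(report.included_ids)
    confounders = cohort.subset(sorted(report.confounding_ids))
    mat_in = impute(encode(included), included)
    mat_out = impute(encode(confounders), confounders)
    cols = features if features is not None else mat_in.columns
    train = mat_in.values[list(cols)]
    test = mat_out.values[list(cols)]
    model = make_model(spec, seed=seed).fit(train.to_numpy(), included.labels)
    return explain_patients(
        model, train, test, method=method, n_coalitions=n_coalitions,
        background_size=background_size, patient_ids=confounders.patient_ids.tolist(),
        feature_names=list(cols), seed=seed,
    )


@dataclass
class GlobalSummary:
    """Mean |phi| ranking plus per-feature (phi, value) scatter data."""

    mean_abs_phi: pd.Series
    ranks: pd.Series
    beeswarm: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.mean_abs_phi.index, "mean_abs_phi": self.mean_abs_phi.values,
             "rank": self.ranks.loc[self.mean_abs_phi.index].values}
        )


def global_summary(
    explanations: Sequence[Explanation], feature_values: pd.DataFrame | None = None
) -> GlobalSummary:
    """Aggregate per-patient explanations into a ranked global view."""
    if not explanations:
        raise ValueError("need at least one explanation")
    names = explanations[0].feature_names
    phis = np.vstack([e.phi for e in explanations])
    mean_abs = pd.Series(np.abs(phis).mean(axis=0), index=names).sort_values(
        ascending=False, kind="stable"
    )
    ranks = pd.Series(np.arange(1, len(names) + 1), index=mean_abs.index)
    rows = []
    for i, e in enumerate(explanations):
        for j, f in enumerate(names):
            val = np.nan
            if feature_values is not None and f in feature_values.columns:
                val = feature_values.iloc[i][f]
            rows.append({"patient_id": e.patient_id, "feature": f, "phi": e.phi[j], "value": val})
    return GlobalSummary(mean_abs_phi=mean_abs, ranks=ranks, beeswarm=pd.DataFrame(rows))


def explanations_to_frame(explanations: Sequence[Explanation]) -> pd.DataFrame:
    """Tidy export: one row per (patient, feature)."""
    rows = []
    for e in explanations:
        for j, f in enumerate(e.feature_names):
            rows.append(
                {
                    "patient_id": e.patient_id,
                    "feature": f,
                    "phi": float(e.phi[j]),
                    "base_value": e.base_value,
                    "model_score": e.model_score,
                    "method": e.method,
                }
            )
    return pd.DataFrame(rows)
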