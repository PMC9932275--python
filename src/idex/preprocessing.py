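"""Feature encoding, imputation and the prevalence-derived decision threshold."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import Cohort

__all__ = ["EncodedMatrix", "DecisionThreshold", "encode", "impute", "prevalence_threshold"]


@dataclass
class EncodedMatrix:
    """Numeric patients x features matrix with an imputation log."""

    values: pd.DataFrame
    imputation_log: dict = field(default_factory=dict)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_patients(self) -> int:
        return len(self.values)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def write_csv(self, path) -> None:
        self.values.to_csv(path, index=False)
        Path(path).with_suffix(".imputation.json").write_text(
            json.dumps(self.imputation_log, indent=1)
        )


@dataclass(frozen=True)
class DecisionThreshold:
    """Positive-class fraction used as the score cut-off.

    A score is called positive iff ``score > value`` (strict, configurable at
    the call sites that apply it).
    """

    value: float
    n_positive: int
    n_total: int

    def __post_init__(self) -> None:
        if not 0.0 < self.value < 1.0:
            raise ValueError("threshold must lie strictly inside (0,1)")

    def apply(self, scores: np.ndarray, strict: bool = True) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        return (scores > self.value).astype(int) if strict else (scores >= self.value).astype(int)


def encode(cohort: Cohort) -> EncodedMatrix:
    """Encode a cohort into a numeric matrix.

    Coded (ordinal/categorical) features keep their schema integer codes as a
    single column each — no one-hot expansion; continuous features pass
    through. Column order follows the schema and is deterministic. Missing
    values are preserved (NaN) for :func:`impute`.
    """
    order = [fs.name for fs in cohort.schema]
    out = cohort.features[order].astype(float).reset_index(drop=True)
    for fs in cohort.schema:
        if fs.kind == "continuous":
            continue
        col = out[fs.name]
        bad = col.dropna()[~col.dropna().isin(fs.codes)]
        if len(bad):
            pid = cohort.patient_ids[bad.index[0]]
            raise ValueError(
                f"patient {pid!r}: value {bad.iloc[0]!r} outside schema codes "
                f"for feature {fs.name!r}"
            )
    return EncodedMatrix(values=out, imputation_log={})


def impute(matrix: EncodedMatrix, cohort: Cohort, policy: str = "median_mode") -> EncodedMatrix:
    """Fill missing entries: median for continuous, mode for coded features.

    ``policy="indicator"`` additionally appends one binary missing-indicator
    column per feature that actually had missing entries. Every fill is
    recorded in the imputation log.
    """
    if policy not in {"median_mode", "indicator"}:
        raise ValueError(f"unknown imputation policy {policy!r}")
    kinds = {fs.name: fs.kind for fs in cohort.schema}
    values = matrix.values.copy()
    log: dict[str, dict] = {}
    indicators: dict[str, np.ndarray] = {}
    for name in matrix.columns:
        col = values[name]
        n_missing = int(col.isna().sum())
        if n_missing == 0:
            continue
        if n_missing == len(col):
            raise ValueError(f"feature {name!r} entirely missing; cannot impute")
        if kinds.get(name) == "continuous":
            fill = float(col.median())
            method = "median"
        else:
            # mode; ties broken by smallest code for determinism
            fill = float(col.mode().min())
            method = "mode"
        if policy == "indicator":
            indicators[f"{name}_missing"] = col.isna().to_numpy(dtype=float)
        values[name] = col.fillna(fill)
        log[name] = {"method": method, "fill": fill, "n_filled": n_missing}
    for ind_name, ind in indicators.items():
        values[ind_name] = ind
    return EncodedMatrix(values=values, imputation_log=log)


def prevalence_threshold(labels) -> DecisionThreshold:
    """Positive-class fraction of ``labels`` as a decision threshold."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("labels empty")
    n_pos = int(labels.sum())
    n_tot = int(labels.size)
    if n_pos in (0, n_tot):
        raise ValueError("single-class labels: prevalence threshold degenerate")
    return DecisionThreshold(value=n_pos / n_tot, n_positive=n_pos, n_total=n_tot)
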