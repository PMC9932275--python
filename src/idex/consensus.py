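"""Iterative multi-classifier consensus filtering of label-inconsistent patients.

Counts per-patient misclassifications over repeated-CV rounds, flags patients
misclassified in at least ``round_threshold`` rounds by every classifier,
removes them, iterates, and quantifies inter-classifier agreement via Cohen's
kappa and pairwise concordance tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .cv import CVPlan, ModelSpec, ScoreTensor, run_repeated_cv
from .preprocessing import DecisionThreshold, encode, impute, prevalence_threshold
from .synthetic import Cohort

__all__ = [
    "MisclassCount",
    "KappaStat",
    "ConsensusReport",
    "cohens_kappa",
    "kappa_band",
    "count_misclassifications",
    "identify_confounders",
    "pairwise_kappa",
    "concordance_table",
    "iterate_consensus",
    "default_round_threshold",
    "exclusion_percent",
    "retained_count",
]


# --------------------------------------------------------------------------
# Cohen's kappa

def cohens_kappa(labels_a, labels_b) -> float:
    """Chance-corrected agreement ``(p_o - p_e) / (1 - p_e)``.

    ``p_e`` is computed from the two marginal label distributions. When both
    vectors are identical and constant (``p_e = 1``), 1.0 is returned.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("label vectors must be equal-length, non-empty 1-D")
    n = a.size
    p_o = float((a == b).mean())
    classes = np.union1d(a, b)
    p_e = sum(float((a == c).mean()) * float((b == c).mean()) for c in classes)
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


_BANDS = [(-1.01, 0.0, "none"), (0.0, 0.4, "poor"), (0.4, 0.6, "moderate"),
          (0.6, 0.8, "good"), (0.8, 1.0 + 1e-12, "great")]


def kappa_band(kappa: float) -> str:
    """Concordance band: none (<0), poor, moderate, good, great."""
    for lo, hi, name in _BANDS:
        if lo <= kappa < hi or (name == "great" and kappa == 1.0):
            return name
    raise ValueError(f"kappa {kappa} outside [-1, 1]")


@dataclass(frozen=True)
class KappaStat:
    pair: tuple
    mean: float
    sd: float

    @property
    def band(self) -> str:
        return kappa_band(self.mean)


# --------------------------------------------------------------------------
# Misclassification counting and confounder identification

@dataclass
class MisclassCount:
    """``counts[classifier]`` is an int array over patients, 0..n_rounds."""

    counts: dict
    n_rounds: int
    patient_ids: np.ndarray

    def __post_init__(self) -> None:
        for clf, arr in self.counts.items():
            arr = np.asarray(arr)
            if arr.min() < 0 or arr.max() > self.n_rounds:
                raise ValueError(f"counts outside 0..n_rounds for {clf}")


def _hard_labels(tensor: ScoreTensor, threshold: DecisionThreshold) -> dict:
    return {clf: threshold.apply(arr) for clf, arr in tensor.scores.items()}


def count_misclassifications(
    tensor: ScoreTensor, labels, threshold: DecisionThreshold
) -> MisclassCount:
    """Rounds in which each classifier's out-of-fold call disagrees with truth."""
    tensor.validate()
    y = np.asarray(labels, dtype=int)
    counts = {}
    for clf, hard in _hard_labels(tensor, threshold).items():
        counts[clf] = (hard != y[None, :]).sum(axis=0).astype(int)
    return MisclassCount(counts=counts, n_rounds=tensor.n_rounds, patient_ids=tensor.patient_ids)


def default_round_threshold(n_rounds: int) -> int:
    """15 for the 20-round plan; otherwise ceil(0.75 * n_rounds)."""
    return 15 if n_rounds == 20 else math.ceil(0.75 * n_rounds)


def identify_confounders(
    counts: MisclassCount, round_threshold: int | None = None, require_all: bool = True
) -> set:
    """Patients misclassified in >= round_threshold rounds.

    With ``require_all`` (default) a patient must cross the threshold for
    EVERY classifier; otherwise the union over classifiers is returned.
    """
    if not counts.counts:
        raise ValueError("no classifiers in counts")
    if round_threshold is None:
        round_threshold = default_round_threshold(counts.n_rounds)
    per_clf = [np.asarray(arr) >= round_threshold for arr in counts.counts.values()]
    stacked = np.vstack(per_clf)
    flagged = stacked.all(axis=0) if require_all else stacked.any(axis=0)
    return set(np.asarray(counts.patient_ids)[flagged].tolist())


# --------------------------------------------------------------------------
# Agreement statistics

def pairwise_kappa(tensor: ScoreTensor, threshold: DecisionThreshold) -> list[KappaStat]:
    """Per-round kappa between each classifier pair, summarized mean +- sd."""
    if len(tensor.scores) < 2:
        raise ValueError("need at least two classifiers")
    hard = _hard_labels(tensor, threshold)
    stats = []
    for a, b in combinations(tensor.classifiers, 2):
        ks = [cohens_kappa(hard[a][r], hard[b][r]) for r in range(tensor.n_rounds)]
        ks = np.asarray(ks)
        sd = float(ks.std(ddof=1)) if len(ks) > 1 else 0.0
        stats.append(KappaStat(pair=(a, b), mean=float(ks.mean()), sd=sd))
    return stats


def concordance_table(
    tensor: ScoreTensor,
    threshold: DecisionThreshold,
    pair: tuple,
    n_bins: int = 20,
) -> dict:
    """Joint predicted-label percentages plus the score-pair histogram.

    The 2x2 table averages, over rounds, the joint distribution of the two
    classifiers' hard calls (cells: pos/pos, pos/neg, neg/pos, neg/neg as
    percentages summing to 100). The histogram aggregates score pairs over
    all rounds with the decision threshold position recorded.
    """
    a, b = pair
    if a not in tensor.scores or b not in tensor.scores:
        raise ValueError(f"unknown classifier pair {pair}")
    ha, hb = threshold.apply(tensor.scores[a]), threshold.apply(tensor.scores[b])
    table = np.zeros((2, 2))
    for r in range(tensor.n_rounds):
        for i in (0, 1):
            for j in (0, 1):
                table[i, j] += float(((ha[r] == i) & (hb[r] == j)).mean())
    table = table / tensor.n_rounds * 100.0
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    hist, _, _ = np.histogram2d(
        tensor.scores[a].ravel(), tensor.scores[b].ravel(), bins=[edges, edges]
    )
    return {
        "pair": (a, b),
        "percent": {
            "neg_neg": table[0, 0],
            "neg_pos": table[0, 1],
            "pos_neg": table[1, 0],
            "pos_pos": table[1, 1],
        },
        "histogram": hist,
        "bin_edges": edges,
        "threshold": threshold.value,
    }


# --------------------------------------------------------------------------
# The iterative procedure

@dataclass
class ConsensusIteration:
    index: int
    confounding_ids: set
    included_ids: list
    removed_by_class: dict  # {"positive": int, "negative": int}
    threshold: float
    kappa: list  # KappaStat list on this iteration's input cohort


@dataclass
class ConsensusReport:
    iterations: list
    included_ids: list
    confounding_ids: set
    kappa_before: list
    kappa_after: list | None
    threshold: DecisionThreshold
    tensors: dict = field(default_factory=dict, repr=False)

    def kappa_table(self) -> pd.DataFrame:
        rows = []
        after = {k.pair: k for k in (self.kappa_after or [])}
        for k in self.kappa_before:
            row = {
                "pair": f"{k.pair[0]}-{k.pair[1]}",
                "before_mean": k.mean,
                "before_sd": k.sd,
                "before_band": k.band,
            }
            ka = after.get(k.pair)
            if ka is not None:
                row.update(after_mean=ka.mean, after_sd=ka.sd, after_band=ka.band)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "threshold": self.threshold.value,
            "included_ids": [str(i) for i in self.included_ids],
            "confounding_ids": sorted(str(i) for i in self.confounding_ids),
            "iterations": [
                {
                    "index": it.index,
                    "confounding_ids": sorted(str(i) for i in it.confounding_ids),
                    "n_removed": len(it.confounding_ids),
                    "removed_by_class": it.removed_by_class,
                    "n_included_after": len(it.included_ids),
                    "threshold": it.threshold,
                    "kappa": [
                        {"pair": list(k.pair), "mean": k.mean, "sd": k.sd, "band": k.band}
                        for k in it.kappa
                    ],
                }
                for it in self.iterations
            ],
            "kappa_before": [
                {"pair": list(k.pair), "mean": k.mean, "sd": k.sd, "band": k.band}
                for k in self.kappa_before
            ],
            "kappa_after": [
                {"pair": list(k.pair), "mean": k.mean, "sd": k.sd, "band": k.band}
                for k in (self.kappa_after or [])
            ],
        }
        return json.dumps(payload, indent=1)


def _prepare(cohort: Cohort):
    mat = impute(encode(cohort), cohort)
    return mat


def iterate_consensus(
    cohort: Cohort,
    specs: Sequence[ModelSpec],
    plan: CVPlan,
    n_iterations: int = 2,
    round_threshold: int | None = None,
    selection=None,
    recompute_threshold: bool = False,
    final_eval: bool = True,
    auto_stop: bool = True,
) -> ConsensusReport:
    """Run the full consensus loop.

    Each iteration: repeated CV on the current cohort -> misclassification
    counts -> all-classifier flagging at ``round_threshold`` -> removal. The
    decision threshold is computed from the labels of the iteration-1 input
    cohort and held fixed unless ``recompute_threshold``. With ``final_eval``
    a last CV pass on the included cohort provides the "after" kappa values.
    """
    threshold = prevalence_threshold(cohort.labels)
    current = cohort
    iterations: list[ConsensusIteration] = []
    all_confounders: set = set()
    kappa_before: list[KappaStat] | None = None
    tensors: dict = {}

    for it in range(n_iterations):
        if current.n_patients == 0 or len(np.unique(current.labels)) < 2:
            break
        thr = prevalence_threshold(current.labels) if recompute_threshold else threshold
        mat = _prepare(current)
        tensor = run_repeated_cv(
            mat, current.labels, specs, plan, selection=selection,
            patient_ids=current.patient_ids,
        )
        kappas = pairwise_kappa(tensor, thr)
        if it == 0:
            kappa_before = kappas
            tensors["before"] = tensor
        counts = count_misclassifications(tensor, current.labels, thr)
        flagged = identify_confounders(counts, round_threshold)
        label_of = dict(zip(current.patient_ids.tolist(), current.labels.tolist()))
        removed_by_class = {
            "positive": sum(1 for pid in flagged if label_of[pid] == 1),
            "negative": sum(1 for pid in flagged if label_of[pid] == 0),
        }
        included = [pid for pid in current.patient_ids.tolist() if pid not in flagged]
        iterations.append(
            ConsensusIteration(
                index=it,
                confounding_ids=flagged,
                included_ids=included,
                removed_by_class=removed_by_class,
                threshold=thr.value,
                kappa=kappas,
            )
        )
        all_confounders |= flagged
        current = current.subset(included)
        if auto_stop and not flagged:
            break

    if kappa_before is None:
        # n_iterations == 0: baseline kappa only
        mat = _prepare(current)
        tensor = run_repeated_cv(
            mat, current.labels, specs, plan, selection=selection,
            patient_ids=current.patient_ids,
        )
        kappa_before = pairwise_kappa(tensor, threshold)
        tensors["before"] = tensor

    kappa_after = None
    if final_eval and iterations:
        thr = prevalence_threshold(current.labels) if recompute_threshold else threshold
        mat = _prepare(current)
        tensor_after = run_repeated_cv(
            mat, current.labels, specs, plan, selection=selection,
            patient_ids=current.patient_ids,
        )
        kappa_after = pairwise_kappa(tensor_after, thr)
        tensors["after"] = tensor_after

    return ConsensusReport(
        iterations=iterations,
        included_ids=current.patient_ids.tolist(),
        confounding_ids=all_confounders,
        kappa_before=kappa_before,
        kappa_after=kappa_after,
        threshold=threshold,
        tensors=tensors,
    )


# --------------------------------------------------------------------------
# Cohort bookkeeping arithmetic

def exclusion_percent(n_initial: int, n_excluded: int) -> float:
    """Percentage of the initial cohort that was excluded."""
    if n_initial <= 0 or not 0 <= n_excluded <= n_initial:
        raise ValueError("invalid cohort counts")
    return 100.0 * n_excluded / n_initial


def retained_count(n_initial: int, n_excluded: int) -> int:
    """Patients retained after exclusion."""
    if n_initial <= 0 or not 0 <= n_excluded <= n_initial:
        raise ValueError("invalid cohort counts")
    return n_initial - n_excluded
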