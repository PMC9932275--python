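"""Synthetic cohort generation.

Builds patient-level tabular cohorts with the statistical structure the
downstream analysis assumes: mixed continuous/ordinal/categorical clinical
features with integer level encodings, a minority positive (IDE) class whose
prevalence is controlled through a logistic latent model, MCAR missingness,
correlated lymph-node count features, a near-constant binary feature, and a
planted fraction of label-flipped ("confounding") patients recorded as ground
truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureSchema",
    "CohortConfig",
    "Cohort",
    "GroundTruth",
    "default_paper_schema",
    "generate_cohort",
    "plant_confounders",
    "write_cohort",
    "read_cohort",
]

LABEL_COLUMN = "ide_label"
ID_COLUMN = "patient_id"


@dataclass(frozen=True)
class FeatureSchema:
    """Description of a single clinical feature.

    Parameters
    ----------
    name:
        Column name.
    kind:
        One of ``"continuous"``, ``"ordinal"``, ``"categorical"``.
    levels:
        Integer code -> label map for coded features; empty for continuous.
    missing_rate:
        Default MCAR missingness fraction in ``[0, 1]``.
    """

    name: str
    kind: str
    levels: Mapping[int, str] = field(default_factory=dict)
    missing_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in {"continuous", "ordinal", "categorical"}:
            raise ValueError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"missing_rate out of [0,1] for {self.name!r}")
        if self.kind == "continuous":
            if self.levels:
                raise ValueError(f"continuous feature {self.name!r} cannot have levels")
            return
        codes = sorted(self.levels)
        if not codes:
            raise ValueError(f"coded feature {self.name!r} needs levels")
        if codes[0] not in (0, 1):
            raise ValueError(f"{self.name!r}: codes must start at 0 or 1")
        if codes != list(range(codes[0], codes[0] + len(codes))):
            raise ValueError(f"{self.name!r}: codes must be consecutive integers")
        labels = list(self.levels.values())
        if len(set(labels)) != len(labels):
            raise ValueError(f"{self.name!r}: duplicate level labels")

    @property
    def codes(self) -> list[int]:
        return sorted(self.levels)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "levels": {str(k): v for k, v in self.levels.items()},
            "missing_rate": self.missing_rate,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeatureSchema":
        return cls(
            name=d["name"],
            kind=d["kind"],
            levels={int(k): v for k, v in d.get("levels", {}).items()},
            missing_rate=float(d.get("missing_rate", 0.05)),
        )


def _binary(name: str, labels=("no", "yes"), missing_rate: float = 0.05) -> FeatureSchema:
    return FeatureSchema(name, "ordinal", {0: labels[0], 1: labels[1]}, missing_rate)


def default_paper_schema(missing_rate: float = 0.05) -> list[FeatureSchema]:
    """The default 28-feature clinical schema with its integer level encodings.

    Contains the coded treatment/pathology variables with their published
    integer encodings (surgery type, CT/HT schemes, therapy combination,
    in situ component, LVI, sentinel lymph node), the continuous tumor and
    therapy measurements, and a near-constant binary HER2 feature.
    """
    mr = missing_rate
    cont = lambda n: FeatureSchema(n, "continuous", {}, mr)  # noqa: E731
    schema = [
        cont("age"),
        cont("diameter"),
        _binary("multiplicity", missing_rate=mr),
        FeatureSchema("grading", "ordinal", {1: "G1", 2: "G2", 3: "G3"}, mr),
        cont("er"),
        cont("pgr"),
        cont("ki67"),
        _binary("her2", missing_rate=mr),
        FeatureSchema(
            "in_situ_component",
            "ordinal",
            {0: "not present", 1: "present, not typed", 2: "G1", 3: "G2", 4: "G3"},
            mr,
        ),
        FeatureSchema(
            "lvi",
            "ordinal",
            {0: "not present", 1: "present, not typed", 2: "focal", 3: "extended"},
            mr,
        ),
        cont("eradicated_lymph_nodes"),
        cont("metastatic_lymph_nodes"),
        _binary("lymph_node_status", ("negative", "positive"), mr),
        FeatureSchema(
            "sentinel_lymph_node",
            "categorical",
            {0: "negative", 1: "not done", 2: "positive"},
            mr,
        ),
        _binary("lymph_node_dissection", missing_rate=mr),
        FeatureSchema(
            "surgery_type", "categorical", {1: "quadrantectomy", 2: "mastectomy"}, mr
        ),
        _binary("ct", missing_rate=mr),
        FeatureSchema(
            "ct_scheme",
            "categorical",
            {
                0: "absent",
                1: "anthracycline + taxanes",
                2: "antracycline",
                3: "taxanes",
                4: "CMF",
                5: "other",
            },
            mr,
        ),
        cont("ct_months"),
        _binary("ht", missing_rate=mr),
        FeatureSchema(
            "ht_scheme",
            "categorical",
            {
                0: "absent",
                1: "Tamoxifen",
                2: "LHRHa",
                3: "Tamoxifen + LHRHa",
                4: "Aromatase Inhibitors",
                5: "Tamoxifen + Aromatase Inhibitors",
                6: "LHRHa + Aromatase Inhibitors",
                7: "other",
            },
            mr,
        ),
        _binary("trastuzumab", missing_rate=mr),
        FeatureSchema(
            "therapy_combination",
            "categorical",
            {
                0: "No",
                1: "HT",
                2: "CT",
                3: "CT + HT",
                4: "CT + trastuzumab",
                5: "CT + HT + trastuzumab",
            },
            mr,
        ),
        _binary("radiotherapy", missing_rate=mr),
        _binary("menopausal_status", ("pre", "post"), mr),
        FeatureSchema(
            "histology",
            "categorical",
            {0: "ductal", 1: "lobular", 2: "other"},
            mr,
        ),
        FeatureSchema("pt_stage", "ordinal", {1: "pT1", 2: "pT2", 3: "pT3", 4: "pT4"}, mr),
        FeatureSchema("pn_stage", "ordinal", {0: "pN0", 1: "pN1", 2: "pN2", 3: "pN3"}, mr),
    ]
    assert len(schema) == 28
    return schema


#: Default nonzero effects on the label log-odds (standardized feature scale).
DEFAULT_EFFECTS: dict[str, float] = {
    "age": -0.8,
    "diameter": 0.9,
    "multiplicity": 0.6,
    "er": 0.7,
    "ki67": 0.9,
    "grading": 0.6,
    "metastatic_lymph_nodes": 0.8,
    "eradicated_lymph_nodes": -0.6,
    "lymph_node_status": 0.7,
    "surgery_type": 0.6,
}


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int
    horizon: str = "5y"
    target_prevalence: float = 0.29
    effect_vector: Mapping[str, float] | None = None
    confounder_fraction: float = 0.0
    missingness: Mapping[str, float] | None = None
    seed: int = 0
    schema: Sequence[FeatureSchema] | None = None
    lymph_node_correlation: float = 0.6
    continuous_ranges: Mapping[str, tuple[float, float, float, float]] | None = None

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.horizon not in {"5y", "10y"}:
            raise ValueError("horizon must be '5y' or '10y'")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must be in (0,1)")
        if not 0.0 <= self.confounder_fraction <= 0.5:
            raise ValueError("confounder_fraction must be in [0, 0.5]")


@dataclass
class Cohort:
    """A patient table plus labels, schema and horizon tag."""

    patient_ids: np.ndarray
    features: pd.DataFrame
    labels: np.ndarray
    schema: list[FeatureSchema]
    horizon: str

    def __post_init__(self) -> None:
        self.patient_ids = np.asarray(self.patient_ids)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.patient_ids) != len(set(self.patient_ids.tolist())):
            raise ValueError("duplicated patient_ids")
        if len(self.labels) != len(self.patient_ids):
            raise ValueError("one label per patient required")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be 0/1")
        if len(self.features) != len(self.patient_ids):
            raise ValueError("feature row count mismatch")
        self._validate_codes()

    def _validate_codes(self) -> None:
        for fs in self.schema:
            if fs.kind == "continuous":
                continue
            col = self.features[fs.name]
            vals = col.dropna().unique()
            bad = set(int(v) for v in vals) - set(fs.codes)
            if bad:
                raise ValueError(f"feature {fs.name!r} holds codes outside schema: {bad}")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def prevalence(self) -> float:
        return float(self.labels.mean())

    @property
    def feature_names(self) -> list[str]:
        return [fs.name for fs in self.schema]

    def subset(self, patient_ids: Sequence) -> "Cohort":
        """Cohort restricted to the given patient ids (order preserved)."""
        keep = np.isin(self.patient_ids, np.asarray(list(patient_ids)))
        return Cohort(
            patient_ids=self.patient_ids[keep],
            features=self.features.loc[keep].reset_index(drop=True),
            labels=self.labels[keep],
            schema=list(self.schema),
            horizon=self.horizon,
        )

    def with_labels(self, labels: np.ndarray) -> "Cohort":
        return Cohort(
            patient_ids=self.patient_ids.copy(),
            features=self.features.copy(),
            labels=np.asarray(labels, dtype=int),
            schema=list(self.schema),
            horizon=self.horizon,
        )


@dataclass
class GroundTruth:
    confounder_ids: set
    informative_features: set


# clinically plausible truncated-normal ranges: (mean, sd, low, high)
_DEFAULT_RANGES: dict[str, tuple[float, float, float, float]] = {
    "age": (55.0, 12.0, 25.0, 90.0),
    "diameter": (20.0, 10.0, 1.0, 80.0),
    "er": (60.0, 35.0, 0.0, 100.0),
    "pgr": (45.0, 35.0, 0.0, 100.0),
    "ki67": (25.0, 18.0, 0.0, 95.0),
    "ct_months": (4.0, 2.0, 0.0, 6.0),
    "eradicated_lymph_nodes": (12.0, 7.0, 0.0, 35.0),
    "metastatic_lymph_nodes": (2.0, 3.0, 0.0, 20.0),
}

_CATEGORICAL_PROBS: dict[str, Sequence[float]] = {
    "her2": (0.97, 0.03),  # near-constant by construction
    "grading": (0.2, 0.5, 0.3),
    "in_situ_component": (0.55, 0.15, 0.1, 0.12, 0.08),
    "lvi": (0.6, 0.15, 0.15, 0.1),
    "sentinel_lymph_node": (0.45, 0.35, 0.2),
    "surgery_type": (0.65, 0.35),
    "ct_scheme": (0.35, 0.2, 0.15, 0.1, 0.1, 0.1),
    "ht_scheme": (0.3, 0.25, 0.1, 0.1, 0.12, 0.05, 0.04, 0.04),
    "therapy_combination": (0.1, 0.3, 0.15, 0.3, 0.08, 0.07),
    "histology": (0.75, 0.15, 0.1),
    "pt_stage": (0.45, 0.4, 0.1, 0.05),
    "pn_stage": (0.5, 0.3, 0.12, 0.08),
}


def _truncnorm(rng: np.random.Generator, mean, sd, low, high, size) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < low) | (out > high)
    return out


def _draw_features(
    schema: Sequence[FeatureSchema],
    n: int,
    rng: np.random.Generator,
    ln_corr: float,
    ranges: Mapping[str, tuple[float, float, float, float]],
) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    # shared latent severity drives the two lymph-node counts
    severity = rng.normal(size=n)
    ln_names = {"eradicated_lymph_nodes", "metastatic_lymph_nodes"}
    for fs in schema:
        if fs.kind == "continuous":
            mean, sd, low, high = ranges.get(fs.name, (0.0, 1.0, -4.0, 4.0))
            if fs.name in ln_names:
                # correlated via shared latent: x = corr*sev + sqrt(1-corr^2)*eps
                z = ln_corr * severity + np.sqrt(1 - ln_corr**2) * rng.normal(size=n)
                raw = mean + sd * z
                cols[fs.name] = np.clip(raw, low, high).round(0)
            else:
                cols[fs.name] = _truncnorm(rng, mean, sd, low, high, n).round(1)
        else:
            codes = np.array(fs.codes)
            probs = _CATEGORICAL_PROBS.get(fs.name)
            if probs is None or len(probs) != len(codes):
                probs = np.full(len(codes), 1.0 / len(codes))
            cols[fs.name] = codes[rng.choice(len(codes), size=n, p=np.asarray(probs))]
    return pd.DataFrame({fs.name: cols[fs.name] for fs in schema}).astype(float)


def _solve_intercept(eta: np.ndarray, target: float, tol: float = 1e-10) -> float:
    """Bisect beta0 so that mean(logistic(beta0 + eta)) == target."""

    def mean_p(b0: float) -> float:
        return float((1.0 / (1.0 + np.exp(-(b0 + eta)))).mean())

    lo, hi = -60.0, 60.0
    if not mean_p(lo) < target < mean_p(hi):
        raise ValueError(
            "cannot solve intercept: target prevalence unreachable for this "
            "effect vector (degenerate linear predictor)"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def generate_cohort(config: CohortConfig) -> tuple[Cohort, GroundTruth]:
    """Draw a cohort under a logistic latent label model.

    The latent positive-class probability is ``logistic(b0 + sum_j b_j z_ij)``
    on standardized features, with the intercept solved by bisection so the
    mean probability matches ``config.target_prevalence``. Labels are Bernoulli
    draws; a ``confounder_fraction`` of patients then have labels flipped and
    are recorded in the returned :class:`GroundTruth`. Missingness is applied
    MCAR per feature afterwards. Identical config (including seed) reproduces
    the cohort exactly.
    """
    rng = np.random.default_rng(config.seed)
    schema = list(config.schema) if config.schema is not None else default_paper_schema()
    ranges = dict(_DEFAULT_RANGES)
    if config.continuous_ranges:
        ranges.update(config.continuous_ranges)
    feats = _draw_features(
        schema, config.n_patients, rng, config.lymph_node_correlation, ranges
    )

    effects = dict(DEFAULT_EFFECTS) if config.effect_vector is None else dict(config.effect_vector)
    unknown = set(effects) - set(feats.columns)
    if unknown:
        raise ValueError(f"effect_vector names unknown features: {sorted(unknown)}")

    eta = np.zeros(config.n_patients)
    for name, beta in effects.items():
        if beta == 0:
            continue
        col = feats[name].to_numpy(dtype=float)
        sd = col.std()
        if sd == 0:
            continue
        eta += beta * (col - col.mean()) / sd
    b0 = _solve_intercept(eta, config.target_prevalence)
    p = 1.0 / (1.0 + np.exp(-(b0 + eta)))
    latent_labels = (rng.random(config.n_patients) < p).astype(int)

    ids = np.array([f"P{i:05d}" for i in range(config.n_patients)])
    cohort = Cohort(
        patient_ids=ids,
        features=feats,
        labels=latent_labels,
        schema=schema,
        horizon=config.horizon,
    )

    flip_seed = int(rng.integers(0, 2**31 - 1))
    cohort, flipped = plant_confounders(cohort, config.confounder_fraction, flip_seed)

    # MCAR missingness, applied after label generation
    miss = {fs.name: fs.missing_rate for fs in schema}
    if config.missingness:
        miss.update(config.missingness)
    feats = cohort.features
    for name, rate in miss.items():
        if rate <= 0:
            continue
        mask = rng.random(config.n_patients) < rate
        feats.loc[mask, name] = np.nan

    truth = GroundTruth(
        confounder_ids=flipped,
        informative_features={k for k, v in effects.items() if v != 0},
    )
    return cohort, truth


def plant_confounders(
    cohort: Cohort, fraction: float, seed: int
) -> tuple[Cohort, set]:
    """Flip the labels of ``round(fraction * n)`` uniformly chosen patients.

    Returns a new cohort (input untouched) and the set of flipped patient ids.
    """
    if not 0.0 <= fraction <= 0.5:
        raise ValueError("confounder fraction must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    n_flip = int(round(fraction * cohort.n_patients))
    if n_flip == 0:
        return cohort.with_labels(cohort.labels), set()
    idx = rng.choice(cohort.n_patients, size=n_flip, replace=False)
    labels = cohort.labels.copy()
    labels[idx] = 1 - labels[idx]
    return cohort.with_labels(labels), set(cohort.patient_ids[idx].tolist())


# ---------------------------------------------------------------------------
# CSV / JSON round-trip

def write_cohort(cohort: Cohort, csv_path, truth: GroundTruth | None = None) -> None:
    """Write cohort CSV (+ schema JSON sidecar, + optional ground-truth JSON)."""
    csv_path = Path(csv_path)
    df = cohort.features.copy()
    df.insert(0, ID_COLUMN, cohort.patient_ids)
    df[LABEL_COLUMN] = cohort.labels
    df.to_csv(csv_path, index=False)
    sidecar = {
        "horizon": cohort.horizon,
        "schema": [fs.to_dict() for fs in cohort.schema],
    }
    csv_path.with_suffix(".schema.json").write_text(json.dumps(sidecar, indent=1))
    if truth is not None:
        payload = {
            "confounder_ids": sorted(truth.confounder_ids),
            "informative_features": sorted(truth.informative_features),
        }
        csv_path.with_suffix(".truth.json").write_text(json.dumps(payload, indent=1))


def read_cohort(csv_path) -> Cohort:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    sidecar = json.loads(csv_path.with_suffix(".schema.json").read_text())
    schema = [FeatureSchema.from_dict(d) for d in sidecar["schema"]]
    return Cohort(
        patient_ids=df[ID_COLUMN].to_numpy(),
        features=df[[fs.name for fs in schema]].astype(float),
        labels=df[LABEL_COLUMN].to_numpy(dtype=int),
        schema=schema,
        horizon=sidecar["horizon"],
    )
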