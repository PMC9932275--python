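"""End-to-end orchestration: generate -> select -> classify -> consensus -> explain.

Every stage writes its artifact to disk (CSV/JSON) so runs are reproducible
from the archived config + seed and stages can be inspected individually.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .consensus import concordance_table, iterate_consensus
from .cv import CVPlan, FAMILIES, ModelSpec, compute_performance
from .explainer import (
    explain_confounders,
    explain_patients,
    explanations_to_frame,
    global_summary,
)
from .feature_selection import select_features, selection_frequency_from_tensor
from .preprocessing import encode, impute, prevalence_threshold
from .synthetic import Cohort, CohortConfig, generate_cohort, read_cohort, write_cohort

__all__ = ["RunConfig", "RunManifest", "validate_config", "run_pipeline"]

_DEFAULT_CONFIG: dict = {
    "cohort": {
        "source": "synthetic",
        "path": None,
        "n_patients": 486,
        "horizon": "5y",
        "target_prevalence": 0.29,
        "confounder_fraction": 0.12,
    },
    "plan": {"n_rounds": 20, "n_folds": 5, "stratified": True},
    "models": list(FAMILIES),
    "model_overrides": {},
    "selection": {
        "mode": "none",  # none | fixed | nested
        "features": None,
        "cutoff": 0.60,
        "boruta": {"max_iterations": 100, "alpha": 0.01, "n_estimators": 100},
    },
    "consensus": {"n_iterations": 2, "round_threshold": None},
    "explainer": {
        "method": "kernel",
        "n_coalitions": "full",
        "background_size": 25,
        "max_features": 12,
        "max_patients": 25,
    },
    "output_dir": "idex_run",
    "seed": 0,
}


@dataclass(frozen=True)
class RunConfig:
    """Validated, fully-defaulted pipeline configuration."""

    data: dict

    def __getitem__(self, key):
        return self.data[key]

    def hash(self) -> str:
        canon = json.dumps(self.data, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _merge(defaults: dict, given: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, val in given.items():
        if key not in defaults:
            raise ValueError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            if defaults[key]:
                out[key] = _merge(defaults[key], val, path + key + ".")
            else:  # open mapping (e.g. per-family overrides); validated downstream
                out[key] = dict(val)
        else:
            out[key] = val
    return out


def validate_config(source) -> RunConfig:
    """Parse and validate a config mapping or YAML/JSON file path.

    Missing keys take the published defaults (20 rounds, 5 folds, 15/20 rule,
    2 iterations, 60% selection cutoff); unknown keys are rejected with the
    offending key name.
    """
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text()) or {}
    else:
        raw = dict(source or {})
    data = _merge(_DEFAULT_CONFIG, raw)
    plan = data["plan"]
    if plan["n_rounds"] < 1:
        raise ValueError("plan.n_rounds must be >= 1")
    if plan["n_folds"] < 2:
        raise ValueError("plan.n_folds must be >= 2")
    if data["consensus"]["n_iterations"] < 0:
        raise ValueError("consensus.n_iterations must be >= 0")
    if not 0 <= data["selection"]["cutoff"] <= 1:
        raise ValueError("selection.cutoff must be in [0,1]")
    for fam in data["models"]:
        if fam not in FAMILIES:
            raise ValueError(f"models: unknown family {fam!r}")
    if data["cohort"]["source"] not in {"synthetic", "csv"}:
        raise ValueError("cohort.source must be 'synthetic' or 'csv'")
    if data["cohort"]["source"] == "csv" and not data["cohort"]["path"]:
        raise ValueError("cohort.path required when cohort.source is 'csv'")
    return RunConfig(data=data)


@dataclass
class RunManifest:
    config_hash: str
    outputs: list = field(default_factory=list)
    timings: dict = field(default_factory=dict)
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "version": self.version,
                "outputs": self.outputs,
                "timings_s": self.timings,
            },
            indent=1,
        )


def _load_cohort(cfg: RunConfig):
    c = cfg["cohort"]
    if c["source"] == "csv":
        return read_cohort(c["path"]), None
    config = CohortConfig(
        n_patients=c["n_patients"],
        horizon=c["horizon"],
        target_prevalence=c["target_prevalence"],
        confounder_fraction=c["confounder_fraction"],
        seed=cfg["seed"],
    )
    return generate_cohort(config)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute every stage in order and emit the tables behind the analysis.

    Outputs (all CSV/JSON under ``output_dir``): cohort + schema, encoded
    matrix + imputation log, selection frequencies, consensus report with the
    pairwise kappa table and concordance tables, per-classifier performance
    distributions, per-patient and confounder explanations, global summary,
    and the run manifest.
    """
    out_dir = Path(config["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.hash())
    t_all = time.perf_counter()

    def _emit(name: str, writer) -> None:
        path = out_dir / name
        writer(path)
        manifest.outputs.append(str(path))

    def _stage(name):
        manifest.timings[name] = time.perf_counter() - _stage.t
        _stage.t = time.perf_counter()

    _stage.t = time.perf_counter()

    # -- stage: cohort -----------------------------------------------------
    cohort, truth = _load_cohort(config)
    _emit("cohort.csv", lambda p: write_cohort(cohort, p, truth))
    manifest.outputs.append(str(out_dir / "cohort.schema.json"))
    if truth is not None:
        manifest.outputs.append(str(out_dir / "cohort.truth.json"))
    _stage("cohort")

    # -- stage: preprocessing ---------------------------------------------
    matrix = impute(encode(cohort), cohort)
    _emit("encoded.csv", matrix.write_csv)
    manifest.outputs.append(str(out_dir / "encoded.imputation.json"))
    threshold = prevalence_threshold(cohort.labels)
    _emit(
        "threshold.json",
        lambda p: Path(p).write_text(
            json.dumps(
                {"value": threshold.value, "n_positive": threshold.n_positive,
                 "n_total": threshold.n_total},
                indent=1,
            )
        ),
    )
    _stage("preprocessing")

    # -- stage: consensus (shares its CV pass with selection frequencies) --
    sel_cfg = config["selection"]
    if sel_cfg["mode"] == "nested":
        selection = dict(sel_cfg["boruta"])
    elif sel_cfg["mode"] == "fixed":
        selection = list(sel_cfg["features"] or matrix.columns)
    else:
        selection = None
    specs = [
        ModelSpec(fam, config["model_overrides"].get(fam, {})) for fam in config["models"]
    ]
    plan = CVPlan(
        n_rounds=config["plan"]["n_rounds"],
        n_folds=config["plan"]["n_folds"],
        stratified=config["plan"]["stratified"],
        master_seed=config["seed"],
    )
    report = iterate_consensus(
        cohort, specs, plan,
        n_iterations=config["consensus"]["n_iterations"],
        round_threshold=config["consensus"]["round_threshold"],
        selection=selection,
    )
    _emit("consensus_report.json", lambda p: Path(p).write_text(report.to_json()))
    _emit("kappa_table.csv", lambda p: report.kappa_table().to_csv(p, index=False))
    tensor = report.tensors.get("after") or report.tensors["before"]
    _emit("scores.csv", lambda p: tensor.to_frame().to_csv(p, index=False))

    conc_rows = []
    from itertools import combinations

    for pair in combinations(tensor.classifiers, 2):
        tab = concordance_table(tensor, threshold, pair)
        conc_rows.append({"pair": f"{pair[0]}-{pair[1]}", **tab["percent"]})
    import pandas as pd

    _emit(
        "concordance_tables.csv",
        lambda p: pd.DataFrame(conc_rows).to_csv(p, index=False),
    )
    _stage("consensus")

    # -- stage: selection frequency ---------------------------------------
    freq = selection_frequency_from_tensor(report.tensors["before"], matrix.columns)
    _emit("selection_frequency.csv", lambda p: freq.to_frame().to_csv(p, index=False))
    if sel_cfg["mode"] == "nested":
        selected = select_features(freq, sel_cfg["cutoff"])
    else:
        selected = list(matrix.columns)
    _stage("selection")

    # -- stage: performance ------------------------------------------------
    included = cohort.subset(report.included_ids)
    mat_inc = impute(encode(included), included)
    perf = compute_performance(tensor, included.labels, threshold)
    perf_frames = []
    for clf, dist in perf.items():
        frame = dist.summary()
        frame.insert(0, "classifier", clf)
        perf_frames.append(frame)
    _emit(
        "performance.csv",
        lambda p: pd.concat(perf_frames, ignore_index=True).to_csv(p, index=False),
    )
    _stage("performance")

    # -- stage: explanation ------------------------------------------------
    exp_cfg = config["explainer"]
    feats = selected[: exp_cfg["max_features"]] or list(matrix.columns)[: exp_cfg["max_features"]]
    best_spec = specs[[s.family for s in specs].index("XGB")] if any(
        s.family == "XGB" for s in specs
    ) else specs[0]
    from .cv import make_model

    model = make_model(best_spec, seed=config["seed"]).fit(
        mat_inc.values[feats].to_numpy(), included.labels
    )
    n_exp = min(exp_cfg["max_patients"], included.n_patients)
    exps = explain_patients(
        model,
        mat_inc.values[feats],
        mat_inc.values[feats].iloc[:n_exp],
        method=exp_cfg["method"],
        n_coalitions=exp_cfg["n_coalitions"],
        background_size=exp_cfg["background_size"],
        patient_ids=included.patient_ids[:n_exp].tolist(),
        feature_names=feats,
        seed=config["seed"],
    )
    _emit(
        "explanations.csv", lambda p: explanations_to_frame(exps).to_csv(p, index=False)
    )
    summary = global_summary(exps, mat_inc.values[feats].iloc[:n_exp])
    _emit("global_summary.csv", lambda p: summary.to_frame().to_csv(p, index=False))
    _emit(
        "beeswarm.csv", lambda p: summary.beeswarm.to_csv(p, index=False)
    )

    if report.confounding_ids:
        conf_exps = explain_confounders(
            report, cohort, best_spec,
            method=exp_cfg["method"], features=feats,
            n_coalitions=exp_cfg["n_coalitions"],
            background_size=exp_cfg["background_size"], seed=config["seed"],
        )
        _emit(
            "confounder_explanations.csv",
            lambda p: explanations_to_frame(conf_exps).to_csv(p, index=False),
        )
    _stage("explanation")

    manifest.timings["total"] = time.perf_counter() - t_all
    _emit("config.json", lambda p: Path(p).write_text(json.dumps(config.data, indent=1)))
    (out_dir / "manifest.json").write_text(manifest.to_json())
    manifest.outputs.append(str(out_dir / "manifest.json"))
    for f in manifest.outputs:
        if not Path(f).exists():  # pragma: no cover - manifest invariant
            raise RuntimeError(f"declared output missing: {f}")
    return manifest
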