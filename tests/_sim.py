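"""Shared simulation setups used by the acceptance suite.

These define the synthetic scenarios (schemas, effect vectors, classifier
settings) under which the statistical acceptance criteria are evaluated.
"""

from __future__ import annotations

import numpy as np

from idex.consensus import iterate_consensus
from idex.cv import CVPlan, ModelSpec, make_model
from idex.explainer import explain_patients
from idex.preprocessing import encode, impute, prevalence_threshold
from idex.synthetic import CohortConfig, FeatureSchema, generate_cohort

#: Cheap classifier settings for repeated-consensus simulations (small
#: ensembles; the procedure's behavior, not raw accuracy, is under test).
FAST_SPECS = [
    ModelSpec("RF", {"n_estimators": 30}),
    ModelSpec("SVM"),
    ModelSpec("XGB", {"n_estimators": 30, "max_depth": 3}),
    ModelSpec("NB"),
]


def separable_cohort(seed: int, n: int = 450, flip: float = 0.12):
    """Cohort with a bimodal latent structure and planted label flips.

    A dominant binary risk feature plus moderate continuous markers makes the
    latent labels near-deterministic, so the planted flips are (almost) the
    only label-inconsistent patients — the ground truth the consensus
    procedure is supposed to recover.
    """
    schema = [
        FeatureSchema("risk_group", "ordinal", {0: "low", 1: "high"}, 0.0),
        FeatureSchema("marker_a", "continuous", {}, 0.0),
        FeatureSchema("marker_b", "continuous", {}, 0.0),
        FeatureSchema("marker_c", "continuous", {}, 0.0),
        FeatureSchema("noise_a", "continuous", {}, 0.0),
        FeatureSchema("noise_b", "continuous", {}, 0.0),
    ]
    effects = {"risk_group": 5.0, "marker_a": 0.6, "marker_b": 0.5, "marker_c": 0.4}
    return generate_cohort(
        CohortConfig(
            n_patients=n,
            target_prevalence=0.49,
            confounder_fraction=flip,
            effect_vector=effects,
            schema=schema,
            seed=seed,
        )
    )


def consensus_recovery_run(seed: int, n: int = 450, flip: float = 0.12):
    """One consensus-recovery replicate: returns (recall, fpr, kappa_up)."""
    cohort, truth = separable_cohort(seed, n=n, flip=flip)
    plan = CVPlan(n_rounds=20, n_folds=5, master_seed=1000 + seed)
    report = iterate_consensus(cohort, FAST_SPECS, plan, n_iterations=2)
    planted, flagged = truth.confounder_ids, report.confounding_ids
    recall = len(planted & flagged) / len(planted)
    fpr = len(flagged - planted) / (cohort.n_patients - len(planted))
    before = {k.pair: k.mean for k in report.kappa_before}
    after = {k.pair: k.mean for k in report.kappa_after}
    kappa_up = all(after[p] > before[p] for p in before)
    return recall, fpr, kappa_up


def informative_noise_cohort(seed: int, n: int = 500, n_inf: int = 5, n_noise: int = 15):
    """Continuous cohort: ``n_inf`` strongly informative + ``n_noise`` noise."""
    schema = [
        FeatureSchema(f"inf_{i}", "continuous", {}, 0.0) for i in range(n_inf)
    ] + [FeatureSchema(f"noise_{i}", "continuous", {}, 0.0) for i in range(n_noise)]
    effects = {f"inf_{i}": 0.9 for i in range(n_inf)}
    cohort, truth = generate_cohort(
        CohortConfig(
            n_patients=n,
            target_prevalence=0.4,
            effect_vector=effects,
            schema=schema,
            seed=seed,
        )
    )
    return impute(encode(cohort), cohort), cohort.labels


def confounder_sign_run(seed: int, n: int = 800, flip: float = 0.25) -> bool:
    """One replicate of the confounder-explanation sign property.

    Fits an additive boosted model on non-flipped patients, explains flipped
    and correctly classified patients, and checks that per-feature mean
    attributions of confounders with observed class c share the sign of those
    of correctly classified class-(1-c) patients on the top-5 features.
    """
    schema = [
        FeatureSchema(f"marker_{i}", "continuous", {}, 0.0) for i in range(5)
    ] + [FeatureSchema(f"noise_{i}", "continuous", {}, 0.0) for i in range(3)]
    effects = {f"marker_{i}": (2.5 if i != 2 else -2.5) for i in range(5)}
    cohort, truth = generate_cohort(
        CohortConfig(
            n_patients=n,
            target_prevalence=0.49,
            confounder_fraction=flip,
            effect_vector=effects,
            schema=schema,
            seed=seed,
        )
    )
    mat = impute(encode(cohort), cohort)
    thr = prevalence_threshold(cohort.labels)
    conf_mask = np.isin(cohort.patient_ids, sorted(truth.confounder_ids))
    model = make_model(ModelSpec("XGB", {"n_estimators": 100, "max_depth": 1}), seed=seed)
    model.fit(mat.to_numpy()[~conf_mask], cohort.labels[~conf_mask])
    calls = thr.apply(model.score(mat.to_numpy()))
    correct = (calls == cohort.labels) & ~conf_mask

    explain_idx = np.where(conf_mask | correct)[0]
    exps = explain_patients(
        model,
        mat.values[~conf_mask],
        mat.values.iloc[explain_idx],
        method="kernel",
        background_size=20,
        feature_names=mat.columns,
        seed=seed,
    )
    phis_sub = np.vstack([e.phi for e in exps])
    phis = np.full((cohort.n_patients, phis_sub.shape[1]), np.nan)
    phis[explain_idx] = phis_sub
    top5 = np.argsort(-np.abs(phis_sub).mean(axis=0))[:5]
    ok = True
    for c in (0, 1):
        conf_c = conf_mask & (cohort.labels == c)
        corr_opp = correct & (cohort.labels == 1 - c)
        if conf_c.sum() < 3 or corr_opp.sum() < 3:
            continue
        s_conf = np.sign(np.nanmean(phis[conf_c], axis=0)[top5])
        s_corr = np.sign(np.nanmean(phis[corr_opp], axis=0)[top5])
        ok &= bool((s_conf == s_corr).all())
    return ok
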