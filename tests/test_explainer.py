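import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from idex.explainer import (
    BackgroundSet,
    base_value,
    exact_shapley,
    explain_patients,
    explanations_to_frame,
    global_summary,
    kernel_shap,
)


def linear_model(w, b=0.0):
    w = np.asarray(w, dtype=float)
    return lambda X: np.atleast_2d(X) @ w + b


def tanh_model(W, scale=0.125, shift=0.5):
    return lambda X: np.tanh(np.atleast_2d(X) @ W).sum(axis=1) * scale + shift


small_floats = st.floats(-3, 3, allow_nan=False, width=32)


class TestBackgroundSet:
    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            BackgroundSet(np.empty((0, 3)))

    def test_weights_normalized(self):
        bg = BackgroundSet(np.zeros((4, 2)), weights=[1, 1, 1, 1])
        assert bg.weights.sum() == pytest.approx(1.0)

    def test_bad_weights(self):
        with pytest.raises(ValueError):
            BackgroundSet(np.zeros((2, 2)), weights=[1.0])

    def test_summarize_weights_sum_to_one(self, rng):
        bg = BackgroundSet.summarize(rng.normal(size=(60, 3)), k=5, seed=0)
        assert len(bg.rows) == 5
        assert bg.weights.sum() == pytest.approx(1.0)

    def test_summarize_small_input_passthrough(self, rng):
        rows = rng.normal(size=(3, 2))
        bg = BackgroundSet.summarize(rows, k=10)
        assert len(bg.rows) == 3


class TestBaseValue:
    def test_constant_model(self, rng):
        bg = BackgroundSet(rng.normal(size=(7, 2)))
        assert base_value(lambda X: np.full(len(np.atleast_2d(X)), 0.42), bg) == pytest.approx(0.42)

    def test_identity_two_rows(self):
        bg = BackgroundSet(np.array([[0.2], [0.8]]))
        assert base_value(lambda X: np.atleast_2d(X)[:, 0], bg) == pytest.approx(0.5)

    def test_duplication_with_halved_weights_invariant(self, rng):
        rows = rng.normal(size=(5, 2))
        f = linear_model([1.0, -2.0])
        b1 = base_value(f, BackgroundSet(rows))
        b2 = base_value(
            f, BackgroundSet(np.vstack([rows, rows]), weights=np.full(10, 0.1))
        )
        assert b1 == pytest.approx(b2)


class TestExactShapley:
    def test_dummy_axiom(self, rng):
        f = linear_model([1.5, 0.0, -2.0])  # feature 1 ignored
        bg = BackgroundSet(rng.normal(size=(9, 3)))
        e = exact_shapley(f, rng.normal(size=3), bg)
        assert e.phi[1] == pytest.approx(0.0, abs=1e-12)

    def test_additive_closed_form(self, rng):
        bg = BackgroundSet(rng.normal(size=(15, 4)))
        x = rng.normal(size=4)
        e = exact_shapley(lambda X: np.atleast_2d(X).sum(axis=1), x, bg)
        np.testing.assert_allclose(e.phi, x - bg.rows.mean(axis=0), atol=1e-10)

    def test_symmetry_axiom(self, rng):
        f = lambda X: np.atleast_2d(X)[:, 0] * np.atleast_2d(X)[:, 1]  # symmetric
        rows = rng.normal(size=(8, 1))
        bg = BackgroundSet(np.hstack([rows, rows]))  # identical background columns
        x = np.array([1.3, 1.3])
        e = exact_shapley(f, x, bg)
        assert e.phi[0] == pytest.approx(e.phi[1], abs=1e-10)

    def test_efficiency(self, rng):
        W = rng.normal(size=(5, 3))
        f = tanh_model(W)
        bg = BackgroundSet(rng.normal(size=(11, 5)))
        x = rng.normal(size=5)
        e = exact_shapley(f, x, bg)
        assert e.local_accuracy_gap < 1e-9

    def test_linearity_axiom(self, rng):
        bg_rows = rng.normal(size=(7, 3))
        bg = BackgroundSet(bg_rows)
        x = rng.normal(size=3)
        f1 = linear_model(rng.normal(size=3))
        f2 = tanh_model(rng.normal(size=(3, 2)))
        a, b = 2.0, -0.7
        combo = lambda X: a * f1(X) + b * f2(X)
        e = exact_shapley(combo, x, bg)
        e1 = exact_shapley(f1, x, bg)
        e2 = exact_shapley(f2, x, bg)
        np.testing.assert_allclose(e.phi, a * e1.phi + b * e2.phi, atol=1e-10)

    def test_over_limit_directs_to_kernel(self, rng):
        f = linear_model(np.ones(18))
        bg = BackgroundSet(rng.normal(size=(3, 18)))
        with pytest.raises(ValueError, match="kernel_shap"):
            exact_shapley(f, rng.normal(size=18), bg)

    @given(
        m=st.integers(2, 5),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=25, deadline=None)
    def test_axioms_random_models(self, m, seed):
        rng = np.random.default_rng(seed)
        W = rng.normal(size=(m, 2))
        f = tanh_model(W)
        bg = BackgroundSet(rng.normal(size=(6, m)))
        x = rng.normal(size=m)
        e = exact_shapley(f, x, bg)
        # efficiency
        assert e.local_accuracy_gap < 1e-9
        # dummy: appended ignored feature gets zero
        f_aug = lambda X: f(np.atleast_2d(X)[:, :m])
        bg_aug = BackgroundSet(np.hstack([bg.rows, rng.normal(size=(6, 1))]))
        e_aug = exact_shapley(f_aug, np.append(x, 0.3), bg_aug)
        assert e_aug.phi[-1] == pytest.approx(0.0, abs=1e-10)


class TestKernelShap:
    def test_full_mode_matches_exact(self, rng):
        for _ in range(10):
            m = 6
            f = tanh_model(rng.normal(size=(m, 3)))
            bg = BackgroundSet(rng.normal(size=(10, m)))
            x = rng.normal(size=m)
            e_exact = exact_shapley(f, x, bg)
            e_kernel = kernel_shap(f, x, bg, "full")
            np.testing.assert_allclose(e_kernel.phi, e_exact.phi, atol=1e-6)

    def test_full_mode_local_accuracy(self, rng):
        f = tanh_model(rng.normal(size=(4, 2)))
        bg = BackgroundSet(rng.normal(size=(8, 4)))
        e = kernel_shap(f, rng.normal(size=4), bg, "full")
        assert e.local_accuracy_gap < 1e-9

    def test_single_feature(self, rng):
        bg = BackgroundSet(rng.normal(size=(5, 1)))
        x = np.array([2.0])
        f = linear_model([3.0])
        e = kernel_shap(f, x, bg, "full")
        assert e.phi[0] == pytest.approx(3.0 * (2.0 - bg.rows.mean()), abs=1e-9)

    def test_underdetermined_sampling_rejected(self, rng):
        f = linear_model(np.ones(6))
        bg = BackgroundSet(rng.normal(size=(4, 6)))
        with pytest.raises(ValueError, match="M\\+2"):
            kernel_shap(f, rng.normal(size=6), bg, n_coalitions=6)

    def test_sampled_mode_deterministic(self, rng):
        f = tanh_model(rng.normal(size=(7, 2)))
        bg = BackgroundSet(rng.normal(size=(6, 7)))
        x = rng.normal(size=7)
        e1 = kernel_shap(f, x, bg, n_coalitions=40, seed=9)
        e2 = kernel_shap(f, x, bg, n_coalitions=40, seed=9)
        np.testing.assert_array_equal(e1.phi, e2.phi)

    def test_sampled_mode_converges_to_exact(self, rng):
        m = 7
        f = tanh_model(rng.normal(size=(m, 3)))
        bg = BackgroundSet(rng.normal(size=(8, m)))
        x = rng.normal(size=m)
        target = exact_shapley(f, x, bg).phi
        errs = []
        for n_co in (16, 40, 90, 2**m - 2):
            err = [
                np.abs(kernel_shap(f, x, bg, n_co, seed=s).phi - target).max()
                for s in range(5)
            ]
            errs.append(np.mean(err))
        assert errs[-1] < 1e-9  # full coverage -> exact
        assert errs[-1] <= errs[0]  # decreasing in expectation

    def test_saturated_sample_size_is_full(self, rng):
        m = 4
        f = tanh_model(rng.normal(size=(m, 2)))
        bg = BackgroundSet(rng.normal(size=(5, m)))
        x = rng.normal(size=m)
        e = kernel_shap(f, x, bg, n_coalitions=2**m, seed=0)
        np.testing.assert_allclose(e.phi, exact_shapley(f, x, bg).phi, atol=1e-9)


class TestExplainPatients:
    def test_constant_model_zero_phi(self, rng):
        train = rng.normal(size=(10, 3))
        test = rng.normal(size=(1, 3))
        exps = explain_patients(lambda X: np.full(len(np.atleast_2d(X)), 0.3), train, test)
        assert len(exps) == 1
        np.testing.assert_allclose(exps[0].phi, 0.0, atol=1e-12)

    def test_row_permutation_permutes_outputs(self, rng):
        f = linear_model([1.0, -1.0])
        train = rng.normal(size=(12, 2))
        test = rng.normal(size=(4, 2))
        perm = [2, 0, 3, 1]
        a = explain_patients(f, train, test, method="exact")
        b = explain_patients(f, train, test[perm], method="exact")
        for i, j in enumerate(perm):
            np.testing.assert_allclose(b[i].phi, a[j].phi, atol=1e-12)

    def test_positive_phi_pushes_above_base(self, rng):
        # additive model: positive phi iff feature value above background mean
        f = linear_model([2.0])
        train = rng.normal(size=(30, 1))
        x_hi = train.mean(axis=0) + 1.0
        exps = explain_patients(f, train, x_hi[None, :], method="exact")
        assert exps[0].phi[0] > 0
        assert exps[0].model_score > exps[0].base_value

    def test_feature_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            explain_patients(linear_model([1.0]), rng.normal(size=(5, 1)), rng.normal(size=(2, 3)))

    def test_unknown_method(self, rng):
        with pytest.raises(ValueError):
            explain_patients(linear_model([1.0]), rng.normal(size=(5, 1)),
                             rng.normal(size=(1, 1)), method="tree")


class TestExplainConfounders:
    def _report(self, included, confounders):
        from idex.consensus import ConsensusReport
        from idex.preprocessing import DecisionThreshold

        return ConsensusReport(
            iterations=[],
            included_ids=included,
            confounding_ids=set(confounders),
            kappa_before=[],
            kappa_after=None,
            threshold=DecisionThreshold(0.4, 2, 5),
        )

    def test_zero_confounders_empty_list(self, tiny_cohort):
        from idex.cv import ModelSpec
        from idex.explainer import explain_confounders

        report = self._report(tiny_cohort.patient_ids.tolist(), [])
        assert explain_confounders(report, tiny_cohort, ModelSpec("NB")) == []

    def test_one_explanation_per_confounder(self, tiny_cohort):
        from idex.cv import ModelSpec
        from idex.explainer import explain_confounders

        ids = tiny_cohort.patient_ids.tolist()
        report = self._report(ids[6:], ids[:6])
        feats = tiny_cohort.feature_names[:5]
        exps = explain_confounders(
            report, tiny_cohort, ModelSpec("NB"), features=feats, background_size=10
        )
        assert len(exps) == 6
        assert sorted(e.patient_id for e in exps) == sorted(ids[:6])
        for e in exps:
            assert e.local_accuracy_gap < 1e-6

    def test_empty_included_fails(self, tiny_cohort):
        from idex.cv import ModelSpec
        from idex.explainer import explain_confounders

        report = self._report([], tiny_cohort.patient_ids.tolist()[:3])
        with pytest.raises(ValueError, match="included"):
            explain_confounders(report, tiny_cohort, ModelSpec("NB"))


class TestGlobalSummary:
    def _exps(self, rng, n=6, m=4):
        f = linear_model(rng.normal(size=m))
        train = rng.normal(size=(15, m))
        test = pd.DataFrame(rng.normal(size=(n, m)), columns=[f"f{j}" for j in range(m)])
        return explain_patients(f, train, test, method="exact",
                                feature_names=list(test.columns)), test

    def test_rank_is_permutation(self, rng):
        exps, test = self._exps(rng)
        summary = global_summary(exps, test)
        assert sorted(summary.ranks) == list(range(1, 5))
        mean_abs = summary.mean_abs_phi.values
        assert (np.diff(mean_abs) <= 1e-12).all()

    def test_single_explanation_ranking(self, rng):
        exps, test = self._exps(rng, n=1)
        summary = global_summary(exps, test)
        order = np.argsort(-np.abs(exps[0].phi), kind="stable")
        assert list(summary.mean_abs_phi.index) == [exps[0].feature_names[i] for i in order]

    def test_zero_phi_feature_ranks_last(self, rng):
        w = np.array([1.0, 2.0, 0.0])
        f = linear_model(w)
        train = rng.normal(size=(10, 3))
        test = pd.DataFrame(rng.normal(size=(5, 3)), columns=["a", "b", "c"])
        exps = explain_patients(f, train, test, method="exact", feature_names=["a", "b", "c"])
        summary = global_summary(exps, test)
        assert summary.mean_abs_phi.index[-1] == "c"

    def test_additive_ranking_matches_coef_times_sd(self, rng):
        w = np.array([0.5, 3.0, 1.5])
        sds = np.array([2.0, 0.2, 1.0])
        f = linear_model(w)
        train = rng.normal(size=(2000, 3)) * sds
        test = pd.DataFrame(train[:200], columns=["a", "b", "c"])
        exps = explain_patients(f, train, test, method="exact", feature_names=["a", "b", "c"])
        summary = global_summary(exps, test)
        expected = np.argsort(-np.abs(w) * sds, kind="stable")
        assert list(summary.mean_abs_phi.index) == [["a", "b", "c"][i] for i in expected]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            global_summary([])

    def test_tidy_export_columns(self, rng):
        exps, _ = self._exps(rng, n=2)
        frame = explanations_to_frame(exps)
        assert set(frame.columns) == {
            "patient_id", "feature", "phi", "base_value", "model_score", "method",
        }
        assert len(frame) == 2 * 4
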