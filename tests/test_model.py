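"""Thermodynamic regression: forward model, objective, fitting, CV, sMAPE."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import approx_fprime

from tfregnet.containers import CandidateNetwork, ExpressionMatrix, FValueMatrix
from tfregnet.model import (
    FitConfig,
    cross_validate_lambda,
    fit_subtype_model,
    gene_objective_and_grad,
    inter_subtype_prediction_matrix,
    objective,
    per_gene_smape,
    predict_expression,
    smape,
)
from tfregnet.synthetic import simulate_cohort

from .conftest import backbone_of


def single_edge_fvals(F, basal=10.0):
    idx = pd.MultiIndex.from_tuples([("T", "g")], names=["tf", "gene"])
    return FValueMatrix(f=pd.Series([F], index=idx), basal=pd.Series({"g": basal}))


class TestPredictExpression:
    def test_f_one_returns_basal(self):
        fv = single_edge_fvals(1.0, basal=7.0)
        tf_expr = pd.DataFrame({"s1": [0.5], "s2": [100.0]}, index=["T"])
        pred = predict_expression(fv, tf_expr)
        assert np.allclose(pred.loc["g"], 7.0)

    def test_hand_evaluated_activation(self):
        # basal 10, x=1, F=4 -> 10 * (1+4)/(1+1) = 25
        fv = single_edge_fvals(4.0, basal=10.0)
        pred = predict_expression(fv, pd.DataFrame({"s": [1.0]}, index=["T"]))
        assert pred.loc["g", "s"] == pytest.approx(25.0, rel=1e-12)

    def test_repression_saturates_at_basal_over_four(self):
        fv = single_edge_fvals(0.25, basal=8.0)
        pred = predict_expression(fv, pd.DataFrame({"s": [1e9]}, index=["T"]))
        assert pred.loc["g", "s"] == pytest.approx(2.0, rel=1e-6)

    def test_missing_tf_row_names_the_tf(self):
        fv = single_edge_fvals(2.0)
        with pytest.raises(KeyError, match="T"):
            predict_expression(fv, pd.DataFrame({"s": [1.0]}, index=["OTHER"]))


class TestObjective:
    def test_perfect_fit_all_f_one_is_zero(self):
        fv = single_edge_fvals(1.0, basal=5.0)
        expr = ExpressionMatrix(pd.DataFrame({"s1": [2.0, 5.0], "s2": [3.0, 5.0]}, index=["T", "g"]))
        assert objective(fv, expr, lam=0.5) == pytest.approx(0.0, abs=1e-20)

    def test_hand_computed_two_gene_case_lambda_zero(self):
        idx = pd.MultiIndex.from_tuples([("T", "g1"), ("T", "g2")], names=["tf", "gene"])
        fv = FValueMatrix(f=pd.Series([4.0, 1.0], index=idx), basal=pd.Series({"g1": 10.0, "g2": 6.0}))
        # x=1 -> g1 predicts 25, g2 predicts 6; observe 50 and 3
        expr = ExpressionMatrix(pd.DataFrame({"s": [1.0, 50.0, 3.0]}, index=["T", "g1", "g2"]))
        expected = (np.log2(25) - np.log2(50)) ** 2 + (np.log2(6) - np.log2(3)) ** 2
        assert objective(fv, expr, lam=0.0) == pytest.approx(expected, rel=1e-12)

    def test_penalty_strictly_increases_with_lambda_when_f_not_one(self):
        fv = single_edge_fvals(4.0, basal=10.0)
        expr = ExpressionMatrix(pd.DataFrame({"s": [1.0, 25.0]}, index=["T", "g"]))
        assert objective(fv, expr, 1.0) > objective(fv, expr, 0.1) > objective(fv, expr, 0.0)


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            r, K = int(rng.integers(1, 4)), 12
            x = 2.0 ** rng.normal(0, 1, size=(r, K))
            logy = rng.normal(3, 1, size=K)
            theta = rng.normal(0, 1, size=r + 1)
            lam = float(rng.uniform(0, 1))
            _, grad = gene_objective_and_grad(theta, logy, x, lam)
            num = approx_fprime(theta, lambda th: gene_objective_and_grad(th, logy, x, lam)[0], 1e-7)
            assert np.allclose(grad, num, rtol=1e-5, atol=1e-5)


class TestFit:
    def test_null_system_recovers_f_one(self):
        cohort = simulate_cohort(
            n_tfs=3, n_genes=8, subtypes=("A",), samples_per_subtype=50, noise_sd=0.0, seed=13
        )
        cohort.truth.f_true = {k: 1.0 for k in cohort.truth.f_true}
        samples = [f"A_{i:03d}" for i in range(50)]
        from tfregnet.synthetic import sample_tf_expression, simulate_expression

        tf_expr = sample_tf_expression(cohort.truth, samples, seed=14)
        expr = simulate_expression(cohort.truth, tf_expr, 50)
        res = fit_subtype_model(backbone_of(cohort.truth), expr, "A", FitConfig(lam=0.1))
        assert np.abs(res.fvals.log2_f).max() < 0.05

    def test_parameter_recovery_on_synthetic_truth(self, recovery_cohort):
        res = fit_subtype_model(
            backbone_of(recovery_cohort.truth), recovery_cohort.expression, "A", FitConfig(lam=0.1)
        )
        truth_log2 = pd.Series(
            {
                (tf, g): np.log2(recovery_cohort.truth.f_true[(tf, g, "A")])
                for tf, g in recovery_cohort.truth.backbone
            }
        )
        fitted = res.fvals.log2_f.reindex(truth_log2.index)
        r = np.corrcoef(truth_log2, fitted)[0, 1]
        assert r >= 0.9

    def test_shrinkage_is_monotone_in_lambda(self, recovery_cohort):
        bb = backbone_of(recovery_cohort.truth)
        means = [
            np.abs(
                fit_subtype_model(bb, recovery_cohort.expression, "A", FitConfig(lam=lam)).fvals.log2_f
            ).mean()
            for lam in (0.01, 0.1, 1.0, 10.0)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(means, means[1:]))

    def test_too_few_samples_rejected(self, recovery_cohort):
        sub = recovery_cohort.expression.subset_samples(["A_000"])
        with pytest.raises(ValueError):
            fit_subtype_model(backbone_of(recovery_cohort.truth), sub, "A", FitConfig())


class TestSmape:
    def test_perfect_prediction_is_zero(self):
        assert smape([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_evaluated_value(self):
        assert smape([1.0], [3.0]) == pytest.approx(1.0)

    def test_zero_zero_counts_as_zero(self):
        assert smape([0.0, 1.0], [0.0, 1.0]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            smape([1.0], [1.0, 2.0])

    def test_bounded_by_two(self):
        rng = np.random.default_rng(0)
        y, yhat = rng.uniform(0, 10, 50), rng.uniform(0, 10, 50)
        assert 0.0 <= smape(y, yhat) <= 2.0


class TestCrossValidation:
    def test_noiseless_data_prefers_smallest_lambda(self):
        cohort = simulate_cohort(
            n_tfs=3, n_genes=8, subtypes=("A",), samples_per_subtype=40, noise_sd=0.0, seed=21
        )
        table = cross_validate_lambda(
            backbone_of(cohort.truth), cohort.expression, "A", [0.01, 1.0, 10.0], folds=3, seed=0
        )
        assert table.attrs["best_lambda_smape"] == 0.01

    def test_more_folds_than_samples_rejected(self, two_subtype_cohort):
        with pytest.raises(ValueError):
            cross_validate_lambda(
                backbone_of(two_subtype_cohort.truth),
                two_subtype_cohort.expression,
                "A",
                [0.1],
                folds=1000,
                seed=0,
            )


class TestInterSubtypeMatrix:
    @staticmethod
    def _models_and_cohorts(cohort, subtypes, lam=0.1):
        bb = backbone_of(cohort.truth)
        models, cohorts = {}, {}
        for s in subtypes:
            models[s] = fit_subtype_model(bb, cohort.expression, s, FitConfig(lam=lam)).fvals
            cohorts[s] = cohort.expression.subset_samples(cohort.expression.samples_of(s))
        return models, cohorts

    def test_single_subtype_scales_to_zero(self, recovery_cohort):
        models, cohorts = self._models_and_cohorts(recovery_cohort, ["A"])
        M = inter_subtype_prediction_matrix(models, cohorts, top_n_variable=10)
        assert M.shape == (1, 1) and M.iloc[0, 0] == 0.0

    def test_matched_model_is_row_minimum(self, two_subtype_cohort):
        models, cohorts = self._models_and_cohorts(two_subtype_cohort, ["A", "B"])
        M = inter_subtype_prediction_matrix(models, cohorts, top_n_variable=15)
        raw = M.attrs["raw"]
        for s in ("A", "B"):
            assert raw.loc[s, s] == raw.loc[s].min()

    def test_relabeling_permutes_consistently(self, two_subtype_cohort):
        models, cohorts = self._models_and_cohorts(two_subtype_cohort, ["A", "B"])
        M1 = inter_subtype_prediction_matrix(models, cohorts, top_n_variable=15)
        ren_models = {"Z" if s == "A" else s: v for s, v in models.items()}
        ren_cohorts = {"Z" if s == "A" else s: v for s, v in cohorts.items()}
        M2 = inter_subtype_prediction_matrix(ren_models, ren_cohorts, top_n_variable=15)
        assert M2.loc["Z", "Z"] == M1.loc["A", "A"]
        assert M2.loc["B", "Z"] == M1.loc["B", "A"]

    def test_missing_cohort_rejected(self, two_subtype_cohort):
        models, cohorts = self._models_and_cohorts(two_subtype_cohort, ["A", "B"])
        del cohorts["B"]
        with pytest.raises(ValueError):
            inter_subtype_prediction_matrix(models, cohorts)
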