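"""Scheffé fitting, pseudo coding, diagnostics and the printed-model oracles."""

import numpy as np
import pytest

from conftest import PUBLISHED_EE_COEFFS, PUBLISHED_SIZE_COEFFS
from formulab import datasets
from formulab.design import DesignMatrix, scheffe_terms
from formulab.scheffe import (
    CodingDomainError,
    LeverageError,
    PseudoCoding,
    ResponseTable,
    SingularFitError,
    entrapment_metrics,
    fit_scheffe,
    predict,
    press_and_predicted_r2,
    select_model,
    to_pseudo,
)


class TestPseudoCoding:
    @pytest.mark.parametrize(
        "composition,expected",
        [
            ((0.70, 0.20, 0.10), (2 / 3, 0.0, 1 / 3)),
            ((0.60, 0.30, 0.10), (0.0, 2 / 3, 1 / 3)),
            ((0.60, 0.20, 0.05), (0.0, 0.0, 0.0)),  # the lower-bound vector
        ],
    )
    def test_transform(self, coding, composition, expected):
        assert np.allclose(to_pseudo(np.array(composition), coding), expected)

    def test_simplex_preserved(self, coding):
        rng = np.random.default_rng(0)
        lo = np.array(coding.lower)
        for _ in range(50):
            x = lo + rng.dirichlet(np.ones(3)) * coding.span
            p = to_pseudo(x, coding)
            assert np.all(p >= -1e-12) and abs(p.sum() - 1.0) < 1e-12

    def test_below_lower_bound_rejected(self, coding):
        with pytest.raises(CodingDomainError):
            to_pseudo(np.array([0.55, 0.35, 0.10]), coding)

    def test_invalid_coding_rejected(self):
        with pytest.raises(ValueError):
            PseudoCoding((0.6, 0.3, 0.2))

    def test_printed_coefficients_reproduce_printed_predictions(
        self, coding, optimum_fraction
    ):
        """The pseudo-coding validation oracle: evaluating the PUBLISHED
        coefficient vectors (not a refit) at the pseudo-coded optimum must
        reproduce the published predictions to the last printed digit."""
        p = to_pseudo(optimum_fraction, coding)
        X = scheffe_terms(p, "scheffe-quadratic")[0]
        # one unit in the last printed digit: the published coefficients are
        # themselves rounded to two decimals
        assert X @ PUBLISHED_SIZE_COEFFS == pytest.approx(37.53, abs=0.01)
        assert X @ PUBLISHED_EE_COEFFS == pytest.approx(80.55, abs=0.01)

    def test_vertex_predictions_match_replicated_observations(self, coding):
        """Published-equation values at the design's replicated vertex points
        sit next to the observed responses (≈47.5 nm at 70/20/10, ≈40.1 nm
        at 60/30/10)."""
        X = scheffe_terms(to_pseudo(np.array([0.70, 0.20, 0.10]), coding),
                          "scheffe-quadratic")[0]
        assert X @ PUBLISHED_SIZE_COEFFS == pytest.approx(47.5, abs=0.3)
        X = scheffe_terms(to_pseudo(np.array([0.60, 0.30, 0.10]), coding),
                          "scheffe-quadratic")[0]
        assert X @ PUBLISHED_SIZE_COEFFS == pytest.approx(40.1, abs=0.3)


class TestFit:
    @pytest.mark.parametrize(
        "response,published",
        [("size_nm", PUBLISHED_SIZE_COEFFS), ("ee_pct", PUBLISHED_EE_COEFFS)],
    )
    def test_refit_recovers_published_coefficients(self, coding, response, published):
        fit = fit_scheffe(datasets.response_table(response), coding)
        assert np.allclose(fit.coefficients, published, rtol=0.01, atol=0.01)

    def test_noiseless_recovery_is_exact(self, coding):
        beta = np.array([50.0, 40.0, 90.0, -30.0, -70.0, -80.0])
        design = datasets.design_matrix()
        y = scheffe_terms(to_pseudo(design.runs, coding), "scheffe-quadratic") @ beta
        fit = fit_scheffe(ResponseTable(design, y), coding)
        assert np.allclose(fit.coefficients, beta, atol=1e-9)
        assert fit.press == pytest.approx(0.0, abs=1e-12)
        assert fit.pred_r2 == pytest.approx(1.0, abs=1e-10)
        assert np.isinf(fit.adequate_precision)

    def test_rank_deficiency_raises(self, coding):
        design = DesignMatrix(
            runs=np.tile([0.65, 0.25, 0.10], (8, 1)), names=datasets.COMPONENTS,
            model_order="scheffe-quadratic")
        with pytest.raises(SingularFitError):
            fit_scheffe(ResponseTable(design, np.ones(8)), coding)

    def test_residuals_orthogonal_to_model_columns(self, size_fit):
        X = scheffe_terms(size_fit.design_points, "scheffe-quadratic")
        assert np.allclose(X.T @ size_fit.residuals, 0.0, atol=1e-8)

    def test_coefficient_estimates_unbiased(self, coding):
        """β̂ is unbiased on y = Xβ + N(0, 1) across 500 replicates: each mean
        error is within 4 Monte-Carlo standard errors of zero."""
        beta = PUBLISHED_SIZE_COEFFS
        design = datasets.design_matrix()
        X = scheffe_terms(to_pseudo(design.runs, coding), "scheffe-quadratic")
        rng = np.random.default_rng(42)
        est = np.array([
            np.linalg.lstsq(X, X @ beta + rng.normal(0, 1, len(X)), rcond=None)[0]
            for _ in range(500)
        ])
        se = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        assert np.all(np.abs(est.mean(axis=0) - beta) < 4 * se)


class TestDiagnostics:
    def test_press_equals_explicit_loo_refit(self, size_fit, ee_fit, coding):
        """Hat-matrix PRESS must equal the literal n-refit leave-one-out sum
        of squared prediction errors (independent oracle) to 1e-8 relative."""
        for response in ("size_nm", "ee_pct"):
            table = datasets.response_table(response)
            fit = fit_scheffe(table, coding)
            P = to_pseudo(table.design.runs, coding)
            X = scheffe_terms(P, "scheffe-quadratic")
            y = np.asarray(table.y, float)
            press_loo = 0.0
            for i in range(len(y)):
                keep = np.arange(len(y)) != i
                b = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
                press_loo += (y[i] - X[i] @ b) ** 2
            assert fit.press == pytest.approx(press_loo, rel=1e-8)

    def test_diagnostic_orderings(self, size_fit, ee_fit):
        for fit in (size_fit, ee_fit):
            assert fit.adj_r2 <= fit.r2
            assert fit.pred_r2 <= fit.r2
            assert fit.press >= fit.anova["ss_residual"]

    def test_adjusted_vs_predicted_gap_below_criterion(self, size_fit, ee_fit):
        assert size_fit.adj_r2 - size_fit.pred_r2 < 0.2
        assert ee_fit.adj_r2 - ee_fit.pred_r2 < 0.2

    def test_adequate_precision_above_four(self, size_fit, ee_fit):
        assert size_fit.adequate_precision > 4
        assert ee_fit.adequate_precision > 4

    def test_fit_r2_equals_squared_correlation_at_design_points(self, size_fit):
        X = scheffe_terms(size_fit.design_points, "scheffe-quadratic")
        yhat = X @ size_fit.coefficients
        corr2 = np.corrcoef(yhat, size_fit.y)[0, 1] ** 2
        assert corr2 == pytest.approx(size_fit.r2, abs=1e-10)

    def test_saturated_fit_reports_leverage_error(self, coding):
        """Six runs for six terms interpolate every point (h=1): PRESS is
        undefined and the leverage error must name the situation."""
        runs = np.array([
            [0.70, 0.20, 0.10], [0.60, 0.30, 0.10], [0.70, 0.25, 0.05],
            [0.65, 0.30, 0.05], [0.65, 0.25, 0.10], [0.70, 0.225, 0.075]])
        design = DesignMatrix(runs=runs, names=datasets.COMPONENTS,
                              model_order="scheffe-quadratic")
        fit = fit_scheffe(ResponseTable(design, np.arange(6.0)), coding)
        with pytest.raises(LeverageError):
            press_and_predicted_r2(fit)


class TestPredictAndSelect:
    def test_prediction_at_published_optimum(self, size_fit, ee_fit, optimum_fraction):
        assert predict(size_fit, optimum_fraction) == pytest.approx(37.53, abs=0.01)
        assert predict(ee_fit, optimum_fraction) == pytest.approx(80.55, abs=0.01)

    def test_vertex_prediction_equals_linear_coefficient(self, size_fit, coding):
        """Scheffé property: at a pseudo-simplex vertex the polynomial equals
        that component's linear coefficient."""
        from formulab.scheffe import from_pseudo

        for i in range(3):
            vertex = np.zeros(3)
            vertex[i] = 1.0
            comp = from_pseudo(vertex, coding)
            assert predict(size_fit, comp) == pytest.approx(
                size_fit.coefficients[i], abs=1e-9)

    def test_select_model_prefers_quadratic_on_study_data(self, coding):
        fit = select_model(datasets.response_table("size_nm"), coding)
        assert fit.model_order == "scheffe-quadratic"


class TestEntrapmentMetrics:
    def test_worked_example(self):
        ee, dl = entrapment_metrics(8.215, 10.0, 100.0)
        assert ee == pytest.approx(82.15)
        assert dl == pytest.approx(8.215)

    @pytest.mark.parametrize("loaded,expected_ee", [(0.0, 0.0), (10.0, 100.0)])
    def test_boundaries(self, loaded, expected_ee):
        ee, _ = entrapment_metrics(loaded, 10.0, 50.0)
        assert ee == pytest.approx(expected_ee)

    def test_mass_balance_violation(self):
        with pytest.raises(ValueError):
            entrapment_metrics(11.0, 10.0, 50.0)
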