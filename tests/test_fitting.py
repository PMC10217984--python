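"""Nonlinear least-squares fitting, initialization and model selection."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.exceptions import NotFittedError

from goosegrowth import (
    GrowthCurveRegressor,
    ModelParams,
    TraitSeries,
    evaluate,
    fit_all_models,
    fit_model,
    initial_guess,
    select_best,
)
from goosegrowth.fitting import InitializationError, SelectionError
from goosegrowth.models import MODEL_NAMES

TRUTH = {
    "logistic": ModelParams(5000.0, 30.0, 0.6),
    "gompertz": ModelParams(5000.0, 5.0, 0.35),
    "von_bertalanffy": ModelParams(5000.0, 0.6, 0.25),
}


class TestInitialGuess:
    def test_noiseless_logistic_guess_near_truth(self, make_noiseless_series):
        series = make_noiseless_series("logistic", 5000.0, 30.0, 0.6)
        g = initial_guess("logistic", series)
        assert g.A == pytest.approx(1.05 * series.values.max())
        # linearisation with a slightly wrong A still lands close
        assert g.B == pytest.approx(30.0, rel=0.25)
        assert g.k == pytest.approx(0.6, rel=0.25)

    def test_constant_series_is_degenerate(self):
        series = TraitSeries("x", "t", "g", np.arange(6.0), np.full(6, 42.0))
        with pytest.raises(InitializationError):
            initial_guess("logistic", series)

    def test_observed_means_give_valid_params(self, shitou):
        g = initial_guess("logistic", shitou)
        assert g.A > shitou.values.max() == 5289.92


class TestFit:
    @pytest.mark.parametrize("model", MODEL_NAMES)
    def test_noiseless_recovery_to_machine_precision(self, model, make_noiseless_series):
        truth = TRUTH[model]
        series = make_noiseless_series(model, truth.A, truth.B, truth.k)
        res = fit_model(model, series)
        assert res.converged
        assert res.params.A == pytest.approx(truth.A, rel=1e-6)
        assert res.params.B == pytest.approx(truth.B, rel=1e-6)
        assert res.params.k == pytest.approx(truth.k, rel=1e-6)
        assert res.r_squared >= 1 - 1e-12

    @pytest.mark.parametrize("model", MODEL_NAMES)
    def test_refit_stability(self, model):
        """Fitting the curve's own predictions returns the same parameters."""
        truth = TRUTH[model]
        rng = np.random.default_rng(21)
        weeks = np.arange(13.0)
        noisy = evaluate(model, truth, weeks) * np.exp(rng.normal(0, 0.03, weeks.size))
        first = fit_model(model, TraitSeries("sim", "w", "g", weeks, noisy))
        refit_series = TraitSeries("sim", "w", "g", weeks, first.predict(weeks))
        second = fit_model(model, refit_series)
        for name in ("A", "B", "k"):
            assert getattr(second.params, name) == pytest.approx(
                getattr(first.params, name), rel=1e-8
            )

    @pytest.mark.parametrize("model", ["logistic", "gompertz"])
    def test_r_squared_invariant_under_unit_rescaling(self, model, shitou):
        grams = fit_model(model, shitou)
        kg_series = TraitSeries(
            shitou.breed, shitou.trait, "kg", shitou.weeks, shitou.values / 1000.0
        )
        kg = fit_model(model, kg_series)
        assert kg.r_squared == pytest.approx(grams.r_squared, abs=1e-9)
        assert kg.params.A == pytest.approx(grams.params.A / 1000.0, rel=1e-6)
        assert kg.params.B == pytest.approx(grams.params.B, rel=1e-6)
        assert kg.params.k == pytest.approx(grams.params.k, rel=1e-6)

    def test_sse_not_worse_than_initial_guess(self, shitou):
        for model in MODEL_NAMES:
            g = initial_guess(model, shitou)
            sse0 = float(np.sum((evaluate(model, g, shitou.weeks) - shitou.values) ** 2))
            assert fit_model(model, shitou).sse <= sse0 + 1e-9

    def test_beats_brute_force_grid(self, make_noiseless_series):
        """Fitted SSE matches or beats a dense 40^3 parameter grid."""
        rng = np.random.default_rng(7)
        weeks = np.arange(8.0)
        y = evaluate("logistic", (800.0, 12.0, 0.7), weeks) * np.exp(
            rng.normal(0, 0.03, weeks.size)
        )
        series = TraitSeries("sim", "w", "g", weeks, y)
        res = fit_model("logistic", series)
        A = np.linspace(y.max(), 3 * y.max(), 40)
        B = np.linspace(1.0, 60.0, 40)
        k = np.linspace(0.05, 2.0, 40)
        Ag, Bg, kg = np.meshgrid(A, B, k, indexing="ij")
        pred = Ag[..., None] / (1 + Bg[..., None] * np.exp(-kg[..., None] * weeks))
        grid_min = float(np.min(np.sum((pred - y) ** 2, axis=-1)))
        assert res.sse <= grid_min * 1.001

    def test_short_or_degenerate_series_rejected(self):
        reg = GrowthCurveRegressor()
        with pytest.raises(ValueError, match="at least 5"):
            reg.fit(np.arange(4.0), np.array([1.0, 2.0, 3.0, 4.0]))
        with pytest.raises(ValueError, match="zero variance"):
            reg.fit(np.arange(6.0), np.full(6, 5.0))

    def test_non_convergence_is_reported_not_silent(self, shitou):
        res = fit_model("logistic", shitou, max_iter=3)
        assert res.converged is False
        assert res.message


class TestEstimatorAPI:
    def test_get_set_params_and_clone(self):
        reg = GrowthCurveRegressor(model="gompertz", max_iter=100)
        assert clone(reg).get_params()["model"] == "gompertz"
        reg.set_params(model="logistic")
        assert reg.get_params()["max_iter"] == 100

    def test_predict_requires_fit(self):
        with pytest.raises(NotFittedError):
            GrowthCurveRegressor().predict([1.0, 2.0])

    def test_column_vector_input_and_score(self, shitou):
        X = shitou.weeks.reshape(-1, 1)
        reg = GrowthCurveRegressor().fit(X, shitou.values)
        assert reg.predict(X).shape == (len(shitou),)
        # RegressorMixin.score on the training data equals the stored R^2
        assert reg.score(X, shitou.values) == pytest.approx(reg.r_squared_, abs=1e-12)


class TestSelectBest:
    def _result(self, model, r2, sse, converged=True):
        series = TraitSeries(
            "x", "t", "g", np.arange(6.0), evaluate("logistic", (10.0, 5.0, 0.5), np.arange(6.0))
        )
        res = fit_model(model, series)
        return res.__class__(
            model=model,
            params=res.params,
            r_squared=r2,
            sse=sse,
            n_iter=res.n_iter,
            converged=converged,
            inflection=res.inflection,
        )

    def test_argmax_r_squared(self):
        results = [
            self._result("logistic", 0.999, 1.0),
            self._result("gompertz", 0.995, 2.0),
            self._result("von_bertalanffy", 0.990, 3.0),
        ]
        assert select_best(results).r_squared == 0.999

    def test_tie_breaks_by_sse_then_model_order(self):
        by_sse = [self._result("gompertz", 0.99, 1.0), self._result("logistic", 0.99, 2.0)]
        assert select_best(by_sse).model == "gompertz"
        full_tie = [self._result("von_bertalanffy", 0.99, 1.0), self._result("logistic", 0.99, 1.0)]
        assert select_best(full_tie).model == "logistic"

    def test_non_converged_excluded_with_warning(self):
        results = [
            self._result("logistic", 0.999, 1.0, converged=False),
            self._result("gompertz", 0.9, 5.0),
        ]
        with pytest.warns(UserWarning, match="non-converged"):
            assert select_best(results).model == "gompertz"

    def test_empty_and_all_failed(self):
        with pytest.raises(ValueError):
            select_best([])
        with pytest.raises(SelectionError), pytest.warns(UserWarning):
            select_best([self._result("logistic", 0.9, 1.0, converged=False)])


def test_fit_all_models_covers_requested_models(shitou):
    fits = fit_all_models(shitou)
    assert [f.model for f in fits] == list(MODEL_NAMES)
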