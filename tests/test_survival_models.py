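"""Parametric forms, censored MLE, information criteria and Akaike
weighting, with lifelines as the independent fitting oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from lifelines import LogLogisticFitter, LogNormalFitter, WeibullFitter

from psmcea import distributions as dist
from psmcea.errors import ConfigurationError, FittingError
from psmcea.survfit import (
    BMAEnsemble,
    ParametricModel,
    akaike_weights,
    bma_survival,
    fit_parametric,
    goodness_of_fit_report,
    survival_function,
    survivor_grid,
)


class TestSurvivalFunction:
    def test_exponential_median_identity(self):
        assert survival_function("exponential", {"rate": math.log(2) / 12}, 12.0) == \
            pytest.approx(0.5)

    @pytest.mark.parametrize("shape", [0.5, 1.0, 2.7])
    def test_weibull_at_scale(self, shape):
        s = survival_function("weibull", {"shape": shape, "scale": 9.0}, 9.0)
        assert s == pytest.approx(math.exp(-1.0))

    def test_loglogistic_median(self):
        assert survival_function("loglogistic", {"shape": 1.0, "scale": 10.0}, 10.0) == \
            pytest.approx(0.5)

    @pytest.mark.parametrize("family,params", [
        ("exponential", {"rate": 0.05}),
        ("weibull", {"shape": 1.3, "scale": 20.0}),
        ("gompertz", {"shape": 0.04, "rate": 0.02}),
        ("lognormal", {"mu": 3.0, "sigma": 0.8}),
        ("loglogistic", {"shape": 1.6, "scale": 18.0}),
    ])
    def test_proper_survivor(self, family, params):
        t = np.linspace(0, 120, 500)
        s = dist.survival(family, params, t)
        assert s[0] == pytest.approx(1.0)
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all((s >= 0) & (s <= 1))
        # quantile inverts the survivor
        u = np.array([0.9, 0.5, 0.1])
        tq = dist.survival_quantile(family, params, u)
        np.testing.assert_allclose(dist.survival(family, params, tq), u, rtol=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ConfigurationError):
            survival_function("weibull", {"shape": -1.0, "scale": 2.0}, 1.0)
        with pytest.raises(ConfigurationError):
            survival_function("exponential", {"rate": 0.1}, -1.0)


TRUE_PARAMS = {
    "exponential": {"rate": 0.06},
    "weibull": {"shape": 1.4, "scale": 20.0},
    "gompertz": {"shape": 0.05, "rate": 0.02},
    "lognormal": {"mu": 2.9, "sigma": 0.7},
    "loglogistic": {"shape": 1.8, "scale": 16.0},
}


def _simulate_censored(family, params, n, seed, censor_quantile=0.25):
    """Event times from the family; administrative censoring at the time
    where the survivor equals ``censor_quantile`` (so ~25% censored)."""
    rng = np.random.default_rng(seed)
    t = dist.survival_quantile(family, params, rng.uniform(1e-12, 1.0, size=n))
    cutoff = dist.survival_quantile(family, params, censor_quantile)
    event = (t <= cutoff).astype(int)
    return pd.DataFrame({"time_months": np.minimum(t, cutoff), "event": event})


class TestFitParametric:
    def test_exponential_closed_form(self):
        ipd = pd.DataFrame({"time_months": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 1, 0]})
        model = fit_parametric(ipd, "exponential")
        assert model.params["rate"] == 3.0 / 10.0  # d / sum(t), exact
        assert model.k == 1
        # AIC/BIC identities
        assert model.aic == pytest.approx(2 * 1 - 2 * model.loglik)
        assert model.bic == pytest.approx(math.log(4) - 2 * model.loglik)

    def test_aic_identity(self):
        model = ParametricModel("exponential", {"rate": 0.1}, loglik=-100.0, n=50, k=1)
        assert model.aic == 202.0

    def test_all_censored_exponential_is_boundary_error(self):
        ipd = pd.DataFrame({"time_months": [5.0, 6.0], "event": [0, 0]})
        with pytest.raises(FittingError, match="boundary"):
            fit_parametric(ipd, "exponential")

    @pytest.mark.parametrize("family", sorted(TRUE_PARAMS))
    def test_parameter_recovery(self, family):
        """n=5,000 self-simulated, ~25% censoring: estimates within 5%
        relative error (10% for the Gompertz shape)."""
        params = TRUE_PARAMS[family]
        ipd = _simulate_censored(family, params, 5000, seed=2024)
        model = fit_parametric(ipd, family)
        for name, true in params.items():
            tol = 0.10 if (family == "gompertz" and name == "shape") else 0.05
            assert model.params[name] == pytest.approx(true, rel=tol), (family, name)

    @pytest.mark.parametrize("family,fitter,mapping", [
        ("weibull", WeibullFitter, {"shape": "rho_", "scale": "lambda_"}),
        ("lognormal", LogNormalFitter, {"mu": "mu_", "sigma": "sigma_"}),
        ("loglogistic", LogLogisticFitter, {"shape": "beta_", "scale": "alpha_"}),
    ])
    def test_matches_lifelines(self, family, fitter, mapping):
        ipd = _simulate_censored(family, TRUE_PARAMS[family], 800, seed=77)
        ours = fit_parametric(ipd, family)
        theirs = fitter().fit(ipd["time_months"], ipd["event"])
        for name, attr in mapping.items():
            assert ours.params[name] == pytest.approx(getattr(theirs, attr), rel=1e-3)
        assert ours.loglik == pytest.approx(theirs.log_likelihood_, rel=1e-6)


class TestAkaikeWeights:
    def _model(self, loglik, k=1, n=100):
        return ParametricModel("exponential", {"rate": 0.1}, loglik, n=n, k=k)

    def test_equal_aics_give_uniform_weights(self):
        ens = akaike_weights([self._model(-50.0) for _ in range(5)])
        np.testing.assert_allclose(ens.weights, 0.2)

    def test_two_point_delta_two(self):
        # AICs {100, 102}: weights e^0 and e^-1 normalised
        models = [self._model(-49.0), self._model(-50.0)]
        ens = akaike_weights(models)
        assert ens.weights[0] == pytest.approx(0.7311, abs=1e-4)
        assert ens.weights[1] == pytest.approx(0.2689, abs=1e-4)

    def test_translation_invariance(self):
        base = [self._model(-40.0), self._model(-42.5), self._model(-45.0)]
        shifted = [self._model(m.loglik - 500.0) for m in base]
        w0 = akaike_weights(base).weights
        w1 = akaike_weights(shifted).weights
        np.testing.assert_allclose(w0, w1, atol=1e-12)

    def test_huge_delta_collapses(self):
        ens = akaike_weights([self._model(-50.0), self._model(-150.0)])
        assert ens.weights[1] < 1e-40

    def test_weights_sum_to_one(self, itt_stage):
        for arm, eps in itt_stage.ensembles.items():
            for ens in eps.values():
                assert ens.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_nonfinite_aic_rejected(self):
        bad = ParametricModel("exponential", {"rate": 0.1}, float("nan"), n=10, k=1)
        with pytest.raises(ConfigurationError):
            akaike_weights([bad])


class TestBMASurvival:
    def test_single_model_identity(self):
        m = ParametricModel("exponential", {"rate": 0.08}, -10.0, n=10, k=1)
        ens = BMAEnsemble([m], np.array([1.0]))
        t = np.linspace(0, 60, 61)
        np.testing.assert_allclose(bma_survival(ens, t), m.survival(t))

    def test_two_exponential_closed_form(self):
        models = [
            ParametricModel("exponential", {"rate": 0.05}, -10.0, n=10, k=1),
            ParametricModel("exponential", {"rate": 0.10}, -10.0, n=10, k=1),
        ]
        ens = BMAEnsemble(models, np.array([0.5, 0.5]))
        expected = 0.5 * math.exp(-0.5) + 0.5 * math.exp(-1.0)
        assert bma_survival(ens, 10.0) == pytest.approx(expected, abs=1e-9)
        assert bma_survival(ens, 0.0) == 1.0

    def test_bounded_by_components_and_monotone(self, itt_stage):
        t = np.arange(0.0, 241.0)
        for arm, eps in itt_stage.ensembles.items():
            for ens in eps.values():
                s = bma_survival(ens, t)
                comps = np.array([m.survival(t) for m in ens.models])
                assert np.all(s <= comps.max(axis=0) + 1e-12)
                assert np.all(s >= comps.min(axis=0) - 1e-12)
                assert np.all(np.diff(s) <= 1e-12)


class TestGoodnessOfFit:
    def test_zero_deviation_on_self_curve(self):
        m = ParametricModel("exponential", {"rate": 0.07}, -10.0, n=10, k=1)
        ens = BMAEnsemble([m], np.array([1.0]))
        from psmcea.reconstruct import DigitizedCurve

        t = np.arange(0.0, 36.0, 3.0)
        curve = DigitizedCurve(t, m.survival(t))
        report = goodness_of_fit_report(ens, curve)
        assert report["sup_norm"] == pytest.approx(0.0, abs=1e-12)

    def test_five_family_report_tracks_km(self, itt_stage):
        for arm, eps in itt_stage.gof.items():
            for endpoint, report in eps.items():
                assert len(report["table"]) == 5
                assert report["sup_norm"] < 0.05

    def test_grid_covers_horizon(self, itt_stage):
        ens = itt_stage.ensembles[next(iter(itt_stage.ensembles))]["OS"]
        grid = survivor_grid(ens, 240)
        assert len(grid) == 241 and grid[0] == pytest.approx(1.0)
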