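"""Calibration: LM fitting, closed-form oracle agreement, inference, prediction."""

import dataclasses
import warnings

import numpy as np
import pytest
import statsmodels.api as sm

from aquasorb import (
    DomainError,
    FitOptions,
    IdentifiabilityError,
    InsufficientDataError,
    ModelFamily,
    ModelSpec,
    SimulationDesign,
    SorptionDataset,
    default_initial_parameters,
    evaluate,
    fit,
    generate,
    predict,
)
from aquasorb.fitting import initial_sse, linear_least_squares
from aquasorb.models import design_matrix, design_to_canonical


class TestDefaults:
    def test_generalized_dlp_defaults(self):
        got = default_initial_parameters(ModelSpec("dlp")).values
        assert got == pytest.approx(
            (-0.033, 13.309, -0.014, 1.719, -0.0157, 5.803, 5.712e-3, -1.721)
        )

    def test_generalized_peleg_defaults(self):
        got = default_initial_parameters(ModelSpec("peleg")).values
        assert got == pytest.approx(
            (-0.083, 30.046, 3.611e-3, -0.615, -0.143, 54.315, -0.067, 24.034)
        )

    def test_single_temperature_defaults_are_offsets(self):
        got = default_initial_parameters(ModelSpec("dlp", generalized=False)).values
        assert got == pytest.approx((13.309, 1.719, 5.803, -1.721))


class TestFit:
    def test_noiseless_dlp_matches_linear_oracle(self, dlp_spec, dlp_truth):
        design = SimulationDesign(
            spec=dlp_spec, true_parameters=dlp_truth, noise_sd=0.0,
            temperatures=(25.0, 45.0), n_points=12, replicates=1, seed=0,
        )
        ds = generate(design)
        res = fit(ds, dlp_spec)
        beta_oracle, sse_oracle = linear_least_squares(ds, dlp_spec)
        assert res.sse == pytest.approx(sse_oracle, abs=1e-10)
        pred = evaluate(dlp_spec, res.parameters, ds.water_activity, ds.temperatures_kelvin())
        truth = evaluate(dlp_spec, dlp_truth, ds.water_activity, ds.temperatures_kelvin())
        assert np.max(np.abs(pred - truth)) < 1e-6

    def test_constant_response_polynomial(self):
        """A flat dataset is interpolated exactly by the intercept alone."""
        aw = np.tile(np.linspace(0.2, 0.7, 5), 2)
        temp = np.repeat([25.0, 45.0], 5)
        c = 7.3
        ds = SorptionDataset(np.ones(10), temp, aw, np.full(10, c))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # R2 undefined for constant data
            res = fit(ds, ModelSpec("polynomial"))
        expected = np.zeros(8)
        expected[1] = c  # b01
        np.testing.assert_allclose(res.parameters.as_array(), expected, atol=1e-6)
        assert np.isnan(res.goodness.r_squared)

    def test_objective_never_inflates(self, dlp_dataset, dlp_spec, dlp_truth):
        options = FitOptions(initial_parameters=dlp_truth.as_array() * 1.5)
        res = fit(dlp_dataset, dlp_spec, options)
        assert res.sse <= initial_sse(dlp_dataset, dlp_spec, options) + 1e-12

    def test_pooling_is_permutation_invariant(self, dlp_dataset, dlp_spec, rng):
        res = fit(dlp_dataset, dlp_spec)
        res2 = fit(dlp_dataset.permuted(rng.permutation(len(dlp_dataset))), dlp_spec)
        np.testing.assert_allclose(
            res.parameters.as_array(), res2.parameters.as_array(), rtol=1e-9
        )
        assert res.goodness.rmse == pytest.approx(res2.goodness.rmse, abs=1e-10)
        np.testing.assert_allclose(res.standard_errors, res2.standard_errors, rtol=1e-6)

    def test_generalized_needs_two_temperatures(self, dlp_truth, dlp_spec):
        design = SimulationDesign(
            spec=dlp_spec, true_parameters=dlp_truth, temperatures=(25.0, 45.0),
            n_points=10, replicates=1, seed=1,
        )
        ds = generate(design)
        single = SorptionDataset(
            ds.replicate[ds.temperature == 25.0],
            ds.temperature[ds.temperature == 25.0],
            ds.water_activity[ds.temperature == 25.0],
            ds.moisture[ds.temperature == 25.0],
        )
        with pytest.raises(IdentifiabilityError):
            fit(single, dlp_spec)

    def test_more_parameters_than_points(self):
        ds = SorptionDataset([1, 1, 1], [25, 35, 45], [0.2, 0.4, 0.6], [1, 2, 3])
        with pytest.raises(InsufficientDataError):
            fit(ds, ModelSpec("dlp"))

    def test_nonconvergence_is_flagged_not_raised(self, dlp_dataset):
        truth = default_initial_parameters(ModelSpec("peleg")).as_array()
        options = FitOptions(
            max_function_evaluations=10, initial_parameters=truth * 3
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit(dlp_dataset, ModelSpec("peleg"), options)
        assert not res.converged
        assert "initial values" in res.message


class TestInference:
    def test_matches_statsmodels_ols(self, dlp_dataset, dlp_spec, dlp_fit):
        """For the linear-in-parameter families, LM inference must agree
        with ordinary least-squares inference on the design matrix."""
        X = design_matrix(dlp_spec, dlp_dataset)
        ols = sm.OLS(dlp_dataset.moisture, X).fit()
        np.testing.assert_allclose(
            design_to_canonical(ols.params), dlp_fit.parameters.as_array(), rtol=1e-8
        )
        np.testing.assert_allclose(
            design_to_canonical(ols.bse), dlp_fit.standard_errors, rtol=1e-8
        )
        ci = ols.conf_int(alpha=0.05)
        np.testing.assert_allclose(design_to_canonical(ci[:, 0]), dlp_fit.ci_lower, rtol=1e-8)
        np.testing.assert_allclose(design_to_canonical(ci[:, 1]), dlp_fit.ci_upper, rtol=1e-8)
        np.testing.assert_allclose(
            design_to_canonical(ols.tvalues), dlp_fit.t_statistics, rtol=1e-8
        )
        np.testing.assert_allclose(
            design_to_canonical(ols.pvalues), dlp_fit.p_values, rtol=1e-6, atol=1e-12
        )

    def test_zero_residual_fit_has_zero_ci_width(self, dlp_spec, dlp_truth):
        design = SimulationDesign(
            spec=dlp_spec, true_parameters=dlp_truth, noise_sd=0.0,
            temperatures=(25.0, 35.0, 45.0), n_points=15, replicates=1, seed=0,
        )
        res = fit(generate(design), dlp_spec)
        np.testing.assert_allclose(res.ci_upper - res.ci_lower, 0.0, atol=1e-8)

    def test_ci_brackets_estimate(self, dlp_fit):
        beta = dlp_fit.parameters.as_array()
        assert np.all(dlp_fit.ci_lower <= beta) and np.all(beta <= dlp_fit.ci_upper)


class TestPredict:
    def test_composition_identity_at_training_points(self, dlp_dataset, dlp_fit):
        pred, flag = predict(dlp_fit, dlp_dataset.water_activity, dlp_dataset.temperature)
        direct = evaluate(
            dlp_fit.spec, dlp_fit.parameters,
            dlp_dataset.water_activity, dlp_dataset.temperatures_kelvin(),
        )
        np.testing.assert_array_equal(pred, direct)
        assert not np.any(flag)

    def test_in_bounds_query_not_flagged(self, dlp_fit):
        value, flagged = predict(dlp_fit, 0.55, 28.0)
        assert not flagged
        assert 0 < value < 50

    def test_out_of_bounds_query_flagged_and_warns(self, dlp_fit):
        with pytest.warns(UserWarning, match="inaccuracies"):
            _, flagged = predict(dlp_fit, 0.95, 50.0)
        assert flagged

    def test_invalid_water_activity_raises(self, dlp_fit):
        with pytest.raises(DomainError):
            predict(dlp_fit, 1.0, 30.0)


@pytest.mark.parametrize("family", [ModelFamily.PELEG, ModelFamily.POLYNOMIAL, ModelFamily.DLP])
def test_noiseless_recovery_each_family(family):
    """Data generated without noise is refit to the generating curve;
    the Peleg search starts near (not at) the truth."""
    spec = ModelSpec(family, True)
    truth = default_initial_parameters(spec)
    design = SimulationDesign(
        spec=spec, true_parameters=truth, noise_sd=0.0,
        temperatures=(25.0, 35.0, 45.0), n_points=20, replicates=1, seed=0,
    )
    ds = generate(design)
    options = FitOptions(initial_parameters=truth.as_array() * 1.1) \
        if family is ModelFamily.PELEG else None
    res = fit(ds, spec, options)
    pred = evaluate(spec, res.parameters, ds.water_activity, ds.temperatures_kelvin())
    clean = evaluate(spec, truth, ds.water_activity, ds.temperatures_kelvin())
    assert np.max(np.abs(pred - clean)) < 1e-6
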