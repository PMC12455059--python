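"""Levenberg-Marquardt calibration of isotherm models with inference.

The objective is the mean squared error between observed and predicted
equilibrium moisture content over all pooled replicate records (replicates
enter individually; they are never averaged before fitting).  Optimization
uses the Levenberg-Marquardt method with a 1e-6 tolerance and caps of 600
function evaluations / 400 iterations by default, mirroring a typical
curve-fitting configuration for this problem.

After the fit, parameter inference is frequentist nonlinear least squares:
``cov = s^2 (J'J)^-1`` with ``s^2 = SSE/(N-M)`` and J the Jacobian of the
predictions at the optimum (the exact design matrix for the families that
are linear in their parameters), Student-t confidence intervals and
two-sided t-tests on N-M degrees of freedom.

Shipped default initial values are the calibrated parameters for Achira
biscuit adsorption data; they transfer reasonably to other low-moisture
products and can always be overridden.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import optimize, stats

from . import validation as _validation
from .models import (
    CELSIUS_OFFSET,
    DomainError,
    IdentifiabilityError,
    InsufficientDataError,
    ModelFamily,
    ModelSpec,
    ParameterSet,
    SorptionDataset,
    design_matrix,
    design_to_canonical,
    evaluate,
)

__all__ = [
    "DEFAULT_GENERALIZED_PARAMETERS",
    "FitOptions",
    "FitBounds",
    "FitResult",
    "default_initial_parameters",
    "fit",
    "parameter_inference",
    "predict",
]

#: Calibrated generalized parameters for Achira biscuits (Kelvin coupling),
#: canonical order (b0, b01, b1, b11, b2, b21, b3, b31).  Shipped as the
#: predefined initial values for each family.
DEFAULT_GENERALIZED_PARAMETERS: dict[ModelFamily, tuple[float, ...]] = {
    ModelFamily.PELEG: (-0.083, 30.046, 3.611e-3, -0.615, -0.143, 54.315, -0.067, 24.034),
    ModelFamily.POLYNOMIAL: (-0.051, 16.516, 6.411e-3, 10.753, 0.294, -103.131, -0.381, 135.904),
    ModelFamily.DLP: (-0.033, 13.309, -0.014, 1.719, -0.0157, 5.803, 5.712e-3, -1.721),
}


@dataclasses.dataclass(frozen=True)
class FitOptions:
    """Optimizer and inference configuration.

    ``tolerance`` is applied to both the step-size and objective-change
    convergence tests.  ``initial_parameters=None`` selects the shipped
    family defaults.  Parameters are unbounded (no box constraints).
    """

    tolerance: float = 1e-6
    max_function_evaluations: int = 600
    max_iterations: int = 400
    initial_parameters: ParameterSet | tuple | list | np.ndarray | None = None
    confidence_level: float = 0.95

    def __post_init__(self) -> None:
        if not self.tolerance > 0:
            raise ValueError("tolerance must be > 0")
        if self.max_function_evaluations < 1 or self.max_iterations < 1:
            raise ValueError("evaluation/iteration limits must be >= 1")
        if not 0 < self.confidence_level < 1:
            raise ValueError("confidence_level must lie in (0, 1)")


@dataclasses.dataclass(frozen=True)
class FitBounds:
    """Training-data envelope used by the extrapolation guard."""

    aw_min: float
    aw_max: float
    t_min: float
    t_max: float
    temperature_unit: str

    def contains(self, water_activity, temperature=None):
        aw = np.asarray(water_activity, dtype=float)
        inside = (aw >= self.aw_min) & (aw <= self.aw_max)
        if temperature is not None:
            T = np.asarray(temperature, dtype=float)
            inside = inside & (T >= self.t_min) & (T <= self.t_max)
        return inside


@dataclasses.dataclass
class FitResult:
    """Calibrated model: parameters, inference, goodness, convergence."""

    spec: ModelSpec
    parameters: ParameterSet
    residuals: np.ndarray
    covariance: np.ndarray
    standard_errors: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    t_statistics: np.ndarray
    p_values: np.ndarray
    goodness: _validation.GoodnessOfFit
    converged: bool
    n_function_evaluations: int
    n_iterations: int | None
    fit_bounds: FitBounds
    n_observations: int
    n_parameters: int
    temperature_unit: str
    options: FitOptions
    message: str = ""
    jacobian: np.ndarray | None = dataclasses.field(default=None, repr=False)

    @property
    def sse(self) -> float:
        return float(np.sum(self.residuals**2))

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return self.spec.parameter_names


def default_initial_parameters(spec: ModelSpec) -> ParameterSet:
    """Shipped starting values for a family (Achira-derived; overridable).

    Single-temperature specs get the temperature-independent entries
    (b01, b11, b21, b31) of the generalized defaults, i.e. the b_i = 0
    reduction.
    """
    g = DEFAULT_GENERALIZED_PARAMETERS[spec.family]
    if spec.generalized:
        return ParameterSet(g)
    return ParameterSet(g[1::2])


def _initial_vector(spec: ModelSpec, options: FitOptions) -> np.ndarray:
    init = options.initial_parameters
    if init is None:
        return default_initial_parameters(spec).as_array()
    p = init.as_array() if isinstance(init, ParameterSet) else np.asarray(init, float)
    if p.shape != (spec.n_parameters,):
        raise ValueError(
            f"initial parameters must have length {spec.n_parameters}, got {p.shape}"
        )
    return p


def fit(dataset: SorptionDataset, spec: ModelSpec, options: FitOptions | None = None) -> FitResult:
    """Calibrate ``spec`` to ``dataset`` by Levenberg-Marquardt least squares.

    All replicate records enter the objective individually.  Temperatures
    are converted to Kelvin internally.  Non-convergence within the
    evaluation/iteration caps returns the best-so-far parameters flagged
    ``converged=False`` together with a feedback message; it does not raise.
    """
    options = options or FitOptions()
    spec = ModelSpec(spec.family, spec.generalized) if not isinstance(spec, ModelSpec) else spec
    n, m = len(dataset), spec.n_parameters
    if n <= m:
        raise InsufficientDataError(f"need more observations than parameters (N={n}, M={m})")
    if spec.generalized and dataset.n_temperatures < 2:
        raise IdentifiabilityError(
            "a temperature-generalized model needs >= 2 distinct temperatures; "
            "fit the single-temperature form instead"
        )

    aw = dataset.water_activity
    t_kelvin = dataset.temperatures_kelvin() if spec.generalized else None
    obs = dataset.moisture
    x0 = _initial_vector(spec, options)

    def residual_fun(beta: np.ndarray) -> np.ndarray:
        return obs - evaluate(spec, beta, aw, t_kelvin, check=False)

    linear = spec.family is not ModelFamily.PELEG
    if linear:
        design = _prediction_jacobian_linear(spec, aw, t_kelvin)

        def jac_fun(beta: np.ndarray) -> np.ndarray:
            return -design

        jac = jac_fun
    else:
        jac = "2-point"

    sol = optimize.least_squares(
        residual_fun,
        x0,
        jac=jac,
        method="lm",
        ftol=options.tolerance,
        xtol=options.tolerance,
        # the configured tolerance governs the objective-change and step-size
        # tests; the gradient test is kept tight so badly scaled problems are
        # not cut off before reaching the least-squares optimum
        gtol=1e-12,
        max_nfev=min(options.max_function_evaluations, options.max_iterations * (m + 1)),
    )
    converged = bool(sol.status > 0)
    message = sol.message if converged else (
        f"{sol.message} — returning best parameters found so far; "
        "consider revising the initial values or relaxing the evaluation limits"
    )

    params = ParameterSet(tuple(sol.x))
    residuals = obs - evaluate(spec, sol.x, aw, t_kelvin, check=False)
    jac_pred = design if linear else -np.asarray(sol.jac)
    goodness = _validation.GoodnessOfFit.from_predictions(obs, obs - residuals, m)
    if not np.isfinite(goodness.r_squared):
        warnings.warn(
            "R2 is undefined for constant observations; goodness recorded as NaN",
            stacklevel=2,
        )

    bounds = FitBounds(
        aw_min=float(aw.min()),
        aw_max=float(aw.max()),
        t_min=float(dataset.temperature.min()),
        t_max=float(dataset.temperature.max()),
        temperature_unit=dataset.temperature_unit,
    )
    result = FitResult(
        spec=spec,
        parameters=params,
        residuals=residuals,
        covariance=np.full((m, m), np.nan),
        standard_errors=np.full(m, np.nan),
        ci_lower=np.full(m, np.nan),
        ci_upper=np.full(m, np.nan),
        t_statistics=np.full(m, np.nan),
        p_values=np.full(m, np.nan),
        goodness=goodness,
        converged=converged,
        n_function_evaluations=int(sol.nfev),
        n_iterations=None,
        fit_bounds=bounds,
        n_observations=n,
        n_parameters=m,
        temperature_unit=dataset.temperature_unit,
        options=options,
        message=message,
        jacobian=jac_pred,
    )
    return parameter_inference(result)


def _prediction_jacobian_linear(spec: ModelSpec, aw: np.ndarray, t_kelvin) -> np.ndarray:
    """d(prediction)/d(parameters), canonical column order, linear families."""
    u = np.log(-np.log(aw)) if spec.family is ModelFamily.DLP else aw
    powers = [np.ones_like(u), u, u**2, u**3]
    if not spec.generalized:
        return np.column_stack(powers)
    cols = []
    for pk in powers:
        cols.append(t_kelvin * pk)  # b_i slope
        cols.append(pk)  # b_i1 offset
    return np.column_stack(cols)


def parameter_inference(result: FitResult) -> FitResult:
    """Augment a fit with covariance, standard errors, CIs and t-tests.

    Uses ``cov = s^2 (J'J)^-1`` with N-M degrees of freedom.  A singular
    J'J yields infinite standard errors and a collinearity warning rather
    than an exception.
    """
    n, m = result.n_observations, result.n_parameters
    dof = n - m
    if dof <= 0:
        raise InsufficientDataError("inference requires N > M")
    J = result.jacobian
    if J is None:
        raise ValueError("fit result carries no Jacobian; re-run fit()")
    s2 = result.sse / dof
    jtj = J.T @ J
    try:
        jtj_inv = np.linalg.inv(jtj)
        if not np.all(np.isfinite(jtj_inv)):
            raise np.linalg.LinAlgError
        cov = s2 * jtj_inv
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        warnings.warn(
            "J'J is singular (collinear parameters); standard errors are infinite",
            stacklevel=2,
        )
        cov = np.full((m, m), np.inf)
        se = np.full(m, np.inf)

    beta = result.parameters.as_array()
    alpha = 1.0 - result.options.confidence_level
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, dof)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.where(beta != 0, np.inf * np.sign(beta), 0.0))
        tstat = np.where(np.isfinite(se), tstat, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)

    result.covariance = cov
    result.standard_errors = se
    half = np.where(np.isfinite(se), tcrit * se, np.inf)
    result.ci_lower = beta - half
    result.ci_upper = beta + half
    result.t_statistics = tstat
    result.p_values = pvals
    return result


_EXTRAPOLATION_NOTE = (
    "query falls outside the calibration bounds "
    "(a_w [{0.aw_min:g}, {0.aw_max:g}], T [{0.t_min:g}, {0.t_max:g}] {0.temperature_unit}); "
    "beyond these limits the model predictions are subject to inaccuracies"
)


def predict(result: FitResult, water_activity, temperature=None, *, warn: bool = True):
    """Predict X_e (% d.b.) from a calibrated model, with an extrapolation flag.

    ``temperature`` is interpreted in the unit the training dataset
    declared (Kelvin conversion happens internally).  Returns
    ``(prediction, extrapolation_flag)``; the flag marks queries outside
    the (a_w, T) envelope of the training data, which also triggers a
    warning.  Water activity outside (0, 1) raises regardless of the flag.
    """
    aw = np.asarray(water_activity, dtype=float)
    if np.any(~np.isfinite(aw)) or np.any(aw <= 0) or np.any(aw >= 1):
        raise DomainError("water activity must lie strictly in (0, 1)")
    if result.spec.generalized:
        if temperature is None:
            raise ValueError("this calibrated model requires a temperature")
        T = np.asarray(temperature, dtype=float)
        t_kelvin = T + CELSIUS_OFFSET if result.temperature_unit == "celsius" else T
    else:
        T = None
        t_kelvin = None
    value = evaluate(result.spec, result.parameters, aw, t_kelvin, check=False)
    inside = result.fit_bounds.contains(aw, T)
    flag = ~np.asarray(inside)
    if warn and np.any(flag):
        warnings.warn(_EXTRAPOLATION_NOTE.format(result.fit_bounds), stacklevel=2)
    if np.ndim(value) == 0:
        return float(value), bool(flag)
    return value, flag


def linear_least_squares(dataset: SorptionDataset, spec: ModelSpec) -> tuple[np.ndarray, float]:
    """Closed-form generalized Polynomial/DLP solution (canonical order, SSE).

    Solves the normal equations through a QR-based ``lstsq`` on the
    design matrix; serves as the independent oracle for the iterative fit.
    """
    X = design_matrix(spec, dataset)
    y = dataset.moisture
    beta_design, *_ = np.linalg.lstsq(X, y, rcond=None)
    sse = float(np.sum((y - X @ beta_design) ** 2))
    return design_to_canonical(beta_design), sse


def initial_sse(dataset: SorptionDataset, spec: ModelSpec, options: FitOptions | None = None) -> float:
    """Objective value at the starting parameters (for monotonicity checks)."""
    options = options or FitOptions()
    x0 = _initial_vector(spec, options)
    t_kelvin = dataset.temperatures_kelvin() if spec.generalized else None
    pred = evaluate(spec, x0, dataset.water_activity, t_kelvin, check=False)
    return float(np.sum((dataset.moisture - pred) ** 2))
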