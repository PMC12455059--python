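"""Goodness-of-fit metrics, residual diagnostics and the validation verdict.

The metrics are the usual calibration bundle: MSE, RMSE, the coefficient
of determination expressed in percent, and its adjusted form
``R2_adj(%) = 100 - ((N-1)/(N-M)) * (100 - R2)``.  A calibrated model is
accepted when R2_adj exceeds a threshold (98 % by default, strictly);
otherwise the verdict carries feedback pointing at the usual suspects
(initial values, model choice).

Residuals are screened for serial correlation with the Ljung-Box
portmanteau test and for normality with the Lilliefors test.  Lilliefors
p-values come from a seeded Monte-Carlo simulation of the null (normal
samples of the same size, mean and variance re-estimated each draw), so
they are deterministic given the seed and free of table interpolation.
"""

from __future__ import annotations

import dataclasses
import functools

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import acorr_ljungbox

from .models import DomainError, InsufficientDataError

__all__ = [
    "GoodnessOfFit",
    "LjungBoxTest",
    "LillieforsTest",
    "ResidualDiagnostics",
    "ValidationVerdict",
    "mse",
    "rmse",
    "r_squared",
    "r_squared_adj",
    "ljung_box_test",
    "lilliefors_test",
    "diagnose_residuals",
    "validate",
]

DEFAULT_R2ADJ_THRESHOLD = 98.0


def _paired(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.ndim != 1 or pred.ndim != 1:
        raise ValueError("observed and predicted must be 1-d")
    if len(obs) != len(pred):
        raise ValueError(f"length mismatch: {len(obs)} observed vs {len(pred)} predicted")
    if len(obs) == 0:
        raise InsufficientDataError("empty input")
    if not (np.all(np.isfinite(obs)) and np.all(np.isfinite(pred))):
        raise ValueError("non-finite values in observed/predicted")
    return obs, pred


def mse(observed, predicted) -> float:
    """Mean squared error, (% d.b.)^2."""
    obs, pred = _paired(observed, predicted)
    return float(np.mean((obs - pred) ** 2))


def rmse(observed, predicted) -> float:
    """Root mean squared error, % d.b."""
    return float(np.sqrt(mse(observed, predicted)))


def r_squared(observed, predicted, *, printed_form: bool = False) -> float:
    """Coefficient of determination in percent.

    The default is the conventional ``100 * (1 - SS_res / SS_tot)`` with
    ``SS_tot = sum((X_e - mean(X_e))**2)``; it can be negative for fits
    worse than the mean.  ``printed_form=True`` switches to the variant
    ``100 - SS_res / sum((mean(X_e) - X_e_pred)**2)``, kept only for
    comparison — it is not on a percent scale and is not used anywhere
    else in the package.
    """
    obs, pred = _paired(observed, predicted)
    if len(obs) < 2:
        raise InsufficientDataError("r_squared needs at least 2 observations")
    ss_res = float(np.sum((obs - pred) ** 2))
    if printed_form:
        denom = float(np.sum((np.mean(obs) - pred) ** 2))
        if denom == 0.0:
            raise DomainError("printed-form denominator is zero")
        return 100.0 - ss_res / denom
    ss_tot = float(np.sum((obs - np.mean(obs)) ** 2))
    if ss_tot == 0.0:
        raise DomainError("r_squared is undefined for constant observations (zero total variance)")
    return 100.0 * (1.0 - ss_res / ss_tot)


def r_squared_adj(r_squared_pct: float, n: int, m: int) -> float:
    """Adjusted R2 in percent: ``100 - ((N-1)/(N-M)) * (100 - R2)``."""
    if n <= m:
        raise InsufficientDataError(f"adjusted R2 requires N > M (got N={n}, M={m})")
    return 100.0 - ((n - 1) / (n - m)) * (100.0 - float(r_squared_pct))


@dataclasses.dataclass(frozen=True)
class GoodnessOfFit:
    """MSE/RMSE/R2/R2_adj bundle for a calibrated model."""

    mse: float
    rmse: float
    r_squared: float
    r_squared_adj: float
    n_observations: int
    n_parameters: int

    @classmethod
    def from_predictions(cls, observed, predicted, n_parameters: int) -> "GoodnessOfFit":
        obs, pred = _paired(observed, predicted)
        m = mse(obs, pred)
        try:
            r2 = r_squared(obs, pred)
            r2a = r_squared_adj(r2, len(obs), n_parameters)
        except DomainError:
            r2 = r2a = float("nan")
        return cls(
            mse=m,
            rmse=float(np.sqrt(m)),
            r_squared=r2,
            r_squared_adj=r2a,
            n_observations=len(obs),
            n_parameters=n_parameters,
        )


@dataclasses.dataclass(frozen=True)
class LjungBoxTest:
    statistic: float  # Q
    lags: int
    p_value: float
    reject: bool
    alpha: float


@dataclasses.dataclass(frozen=True)
class LillieforsTest:
    statistic: float  # D = sup |ECDF - fitted normal CDF|
    p_value: float
    reject: bool
    alpha: float
    n_monte_carlo: int
    seed: int


def default_ljung_box_lags(n: int) -> int:
    return min(20, n - 1)


def ljung_box_test(residuals, lags: int | None = None, alpha: float = 0.05) -> LjungBoxTest:
    """Ljung-Box portmanteau test for residual autocorrelation up to lag h.

    ``Q = N(N+2) * sum_{k<=h} rho_k^2 / (N-k)`` is referred to a
    chi-square distribution with h degrees of freedom.
    """
    x = np.asarray(residuals, dtype=float)
    if x.ndim != 1:
        raise ValueError("residuals must be 1-d")
    h = default_ljung_box_lags(len(x)) if lags is None else int(lags)
    if h < 1 or len(x) <= h:
        raise ValueError(f"need length > lags >= 1 (got N={len(x)}, lags={h})")
    if np.ptp(x) == 0.0:
        raise DomainError("autocorrelation is undefined for constant residuals")
    table = acorr_ljungbox(x, lags=[h], return_df=True)
    q = float(table["lb_stat"].iloc[0])
    p = float(table["lb_pvalue"].iloc[0])
    return LjungBoxTest(statistic=q, lags=h, p_value=p, reject=bool(p < alpha), alpha=alpha)


def _lilliefors_statistic_rows(x: np.ndarray) -> np.ndarray:
    """Row-wise Lilliefors D for a 2-d array of samples."""
    n = x.shape[1]
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    z = np.sort((x - mu) / sd, axis=1)
    cdf = stats.norm.cdf(z)
    i = np.arange(1, n + 1)
    d_plus = (i / n - cdf).max(axis=1)
    d_minus = (cdf - (i - 1) / n).max(axis=1)
    return np.maximum(d_plus, d_minus)


def lilliefors_statistic(sample) -> float:
    """Kolmogorov-Smirnov distance to the normal fitted to the sample."""
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise InsufficientDataError("lilliefors test needs a 1-d sample of length >= 4")
    if np.std(x, ddof=1) == 0.0:
        raise DomainError("lilliefors test is undefined for a zero-variance sample")
    return float(_lilliefors_statistic_rows(x[None, :])[0])


@functools.lru_cache(maxsize=16)
def _null_distribution(n: int, reps: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((reps, n))
    return np.sort(_lilliefors_statistic_rows(draws))


def lilliefors_test(
    residuals,
    alpha: float = 0.05,
    *,
    n_monte_carlo: int = 5000,
    seed: int = 20_250_908,
) -> LillieforsTest:
    """Lilliefors normality test with a seeded Monte-Carlo p-value.

    The null distribution of D (normal samples of the same size, mean and
    SD re-estimated) is simulated once per (n, reps, seed) and cached; the
    p-value is ``(1 + #{D_null >= D}) / (reps + 1)``.
    """
    d = lilliefors_statistic(residuals)
    null = _null_distribution(len(np.asarray(residuals)), int(n_monte_carlo), int(seed))
    n_ge = len(null) - np.searchsorted(null, d, side="left")
    p = (1.0 + n_ge) / (len(null) + 1.0)
    return LillieforsTest(
        statistic=d,
        p_value=float(p),
        reject=bool(p < alpha),
        alpha=alpha,
        n_monte_carlo=int(n_monte_carlo),
        seed=int(seed),
    )


@dataclasses.dataclass(frozen=True)
class ResidualDiagnostics:
    residuals: np.ndarray
    ljung_box: LjungBoxTest
    lilliefors: LillieforsTest
    alpha: float


def diagnose_residuals(
    residuals,
    lags: int | None = None,
    alpha: float = 0.05,
    *,
    n_monte_carlo: int = 5000,
    seed: int = 20_250_908,
) -> ResidualDiagnostics:
    """Run both residual screens (independence and normality) on one vector."""
    x = np.asarray(residuals, dtype=float)
    return ResidualDiagnostics(
        residuals=x,
        ljung_box=ljung_box_test(x, lags=lags, alpha=alpha),
        lilliefors=lilliefors_test(x, alpha=alpha, n_monte_carlo=n_monte_carlo, seed=seed),
        alpha=alpha,
    )


@dataclasses.dataclass(frozen=True)
class ValidationVerdict:
    validated: bool
    r_squared_adj: float
    threshold: float
    feedback: tuple[str, ...]

    @property
    def verdict(self) -> str:
        return "validated" if self.validated else "revisit"


def validate(fit, threshold_r2adj: float = DEFAULT_R2ADJ_THRESHOLD) -> ValidationVerdict:
    """Accept a calibrated model iff R2_adj strictly exceeds the threshold.

    A failing fit gets structured feedback mirroring the calibration
    feedback loop: retry with different initial values, or reformulate
    with another model family.
    """
    r2a = float(fit.goodness.r_squared_adj)
    if np.isfinite(r2a) and r2a > threshold_r2adj:
        return ValidationVerdict(True, r2a, threshold_r2adj, ())
    feedback = (
        f"adjusted R2 = {r2a:.3f} % does not exceed the {threshold_r2adj:g} % acceptance threshold",
        "revisit the initial parameter values (the optimizer may have stalled in a poor basin)",
        "consider reformulating with a different model family for this product",
    )
    return ValidationVerdict(False, r2a, threshold_r2adj, feedback)
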