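"""Synthetic sorption datasets with known truth, and recovery experiments.

The generator emulates a dynamic dewpoint isotherm (DDI) acquisition: a
dense, regular water-activity grid (0.10-0.80, 76 points by default) per
replicate, three replicates, storage temperatures of 25/35/45 degC, and
additive homoscedastic Gaussian noise on the equilibrium moisture content
at the 0.15 % d.b. scale.  Everything is seeded and reproducible.

``recovery_experiment`` repeats generate -> fit -> inference and
summarizes per-parameter bias, estimation RMSE, confidence-interval
coverage of the truth, and the mean fitted RMSE — the simulation-based
evidence that the calibration machinery behaves as advertised.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .fitting import FitOptions, FitResult, fit
from .models import CELSIUS_OFFSET, ModelSpec, ParameterSet, SorptionDataset, evaluate

__all__ = ["SimulationDesign", "RecoverySummary", "generate", "recovery_experiment"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class SimulationDesign:
    """Study design for one synthetic acquisition campaign.

    Defaults mirror the DDI campaign the package targets: a_w 0.10-0.80
    at 76 grid points (>75 per replicate), replicates n=3, temperatures
    25/35/45 degC, noise SD 0.15 % d.b.
    """

    spec: ModelSpec
    true_parameters: ParameterSet | tuple | list
    temperatures: tuple[float, ...] = (25.0, 35.0, 45.0)
    aw_min: float = 0.10
    aw_max: float = 0.80
    n_points: int = 76
    replicates: int = 3
    noise_sd: float = 0.15
    seed: int = 0
    temperature_unit: str = "celsius"

    def __post_init__(self) -> None:
        if not (0.0 < self.aw_min < self.aw_max < 1.0):
            raise ValueError("a_w grid must satisfy 0 < min < max < 1")
        if self.n_points < self.spec.n_parameters + 1:
            raise ValueError("grid must have more points than model parameters")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.spec.generalized and len(self.temperatures) < 2:
            raise ValueError("a generalized design needs >= 2 temperatures")

    @property
    def n_records(self) -> int:
        return self.replicates * len(self.temperatures) * self.n_points

    def truth_array(self) -> np.ndarray:
        p = self.true_parameters
        return p.as_array() if isinstance(p, ParameterSet) else np.asarray(p, dtype=float)

    def aw_grid(self) -> np.ndarray:
        return np.linspace(self.aw_min, self.aw_max, self.n_points)


def generate(design: SimulationDesign) -> SorptionDataset:
    """Simulate one dataset: truth + seeded Gaussian noise, replicate by
    replicate.  Negative moisture draws are clipped to 0 (count logged)."""
    rng = np.random.default_rng(design.seed)
    grid = design.aw_grid()
    truth = design.truth_array()
    to_kelvin = CELSIUS_OFFSET if design.temperature_unit == "celsius" else 0.0

    rep_col, t_col, aw_col, xe_col = [], [], [], []
    for rep in range(1, design.replicates + 1):
        for temp in design.temperatures:
            t_internal = temp + to_kelvin
            clean = evaluate(
                design.spec, truth, grid, t_internal if design.spec.generalized else None
            )
            clean = np.atleast_1d(np.asarray(clean, dtype=float))
            if not np.all(np.isfinite(clean)):
                bad = np.flatnonzero(~np.isfinite(clean))[0]
                raise ValueError(
                    f"true model is non-finite at a_w={grid[bad]:.4f}, T={temp:g} "
                    f"{design.temperature_unit}"
                )
            noisy = clean + rng.normal(0.0, design.noise_sd, size=len(grid)) \
                if design.noise_sd > 0 else clean.copy()
            n_clip = int(np.sum(noisy < 0))
            if n_clip:
                logger.info(
                    "clipped %d negative moisture draw(s) to 0 (replicate %d, T=%g)",
                    n_clip, rep, temp,
                )
                noisy = np.maximum(noisy, 0.0)
            rep_col.append(np.full(len(grid), rep))
            t_col.append(np.full(len(grid), temp))
            aw_col.append(grid)
            xe_col.append(noisy)

    return SorptionDataset(
        np.concatenate(rep_col),
        np.concatenate(t_col),
        np.concatenate(aw_col),
        np.concatenate(xe_col),
        temperature_unit=design.temperature_unit,
        source=f"synthetic:{design.spec.family.value}:seed={design.seed}",
    )


@dataclasses.dataclass(frozen=True)
class RecoverySummary:
    """Monte-Carlo summary of repeated generate -> fit rounds."""

    parameter_names: tuple[str, ...]
    bias: np.ndarray                 # mean(estimate - truth), per parameter
    estimation_rmse: np.ndarray      # sqrt(mean((estimate - truth)^2))
    ci_coverage: np.ndarray          # fraction of CIs containing the truth
    mean_fitted_rmse: float          # mean of the per-fit RMSE (% d.b.)
    n_replications: int
    n_failed: int


def recovery_experiment(
    design: SimulationDesign,
    n_replications: int,
    seed: int | None = None,
    fit_options: FitOptions | None = None,
) -> RecoverySummary:
    """Repeat generate -> fit -> inference and summarize estimator behavior.

    Per-replication seeds are spawned deterministically from ``seed``
    (defaulting to ``design.seed``).  Replications that raise or fail to
    converge are recorded and excluded from the summary.
    """
    if n_replications < 1:
        raise ValueError("n_replications must be >= 1")
    root = design.seed if seed is None else seed
    child_seeds = np.random.SeedSequence(root).generate_state(n_replications) & 0x7FFFFFFF
    truth = design.truth_array()

    estimates, covered, rmses = [], [], []
    n_failed = 0
    for s in child_seeds:
        sub = dataclasses.replace(design, seed=int(s))
        try:
            result: FitResult = fit(generate(sub), design.spec, fit_options)
            if not result.converged:
                raise RuntimeError("fit did not converge")
        except Exception as exc:  # noqa: BLE001 — failures are data here
            n_failed += 1
            logger.warning("replication seed=%d failed: %s", s, exc)
            continue
        est = result.parameters.as_array()
        estimates.append(est)
        covered.append((result.ci_lower <= truth) & (truth <= result.ci_upper))
        rmses.append(result.goodness.rmse)

    if not estimates:
        raise RuntimeError("all replications failed to fit")
    est = np.asarray(estimates)
    err = est - truth
    return RecoverySummary(
        parameter_names=design.spec.parameter_names,
        bias=err.mean(axis=0),
        estimation_rmse=np.sqrt((err**2).mean(axis=0)),
        ci_coverage=np.asarray(covered, dtype=float).mean(axis=0),
        mean_fitted_rmse=float(np.mean(rmses)),
        n_replications=n_replications,
        n_failed=n_failed,
    )
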