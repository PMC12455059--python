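"""Reading sorption datasets (CSV/XLSX) and writing machine-readable fit reports.

The expected tabular layout has one row per observation with columns for
the replicate label, the temperature, the water activity and the
equilibrium moisture content (% d.b.).  Header matching is
case-insensitive and whitespace/underscore-tolerant, with a small alias
table covering the phrasings these files show up with in practice.

Fit reports are JSON: parameters in canonical order with standard errors,
confidence intervals, t-tests, goodness metrics, residual-test outcomes,
convergence info and the calibration bounds.  ``read_report`` /
``fit_from_report`` round-trip losslessly, so a stored report is enough
to keep predicting.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fitting import FitBounds, FitOptions, FitResult, ParameterSet
from .models import ModelSpec, SorptionDataset
from .validation import GoodnessOfFit, ResidualDiagnostics, ValidationVerdict

__all__ = [
    "ColumnMapping",
    "read_dataset",
    "write_dataset",
    "write_report",
    "read_report",
    "fit_from_report",
    "write_residuals",
]

_ALIASES: dict[str, tuple[str, ...]] = {
    "replicate": ("replicate", "replicates", "rep"),
    "temperature": ("temperature", "temp", "t"),
    "water_activity": ("aw", "wateractivity", "activity"),
    "moisture": ("xe", "moisture", "moisturecontent", "equilibriummoisturecontent", "emc"),
}


def _normalize(header: str) -> str:
    return "".join(ch for ch in str(header).strip().lower() if ch.isalnum())


@dataclasses.dataclass(frozen=True)
class ColumnMapping:
    """Explicit column names; any left as None is resolved via aliases."""

    replicate_column: str | None = None
    temperature_column: str | None = None
    water_activity_column: str | None = None
    moisture_column: str | None = None
    temperature_unit: str = "celsius"

    def resolve(self, headers) -> dict[str, str]:
        headers = list(headers)
        normalized = {_normalize(h): h for h in headers}
        explicit = {
            "replicate": self.replicate_column,
            "temperature": self.temperature_column,
            "water_activity": self.water_activity_column,
            "moisture": self.moisture_column,
        }
        resolved: dict[str, str] = {}
        for field, given in explicit.items():
            if given is not None:
                if given not in headers:
                    raise ValueError(
                        f"column {given!r} (for {field}) not found; available headers: {headers}"
                    )
                resolved[field] = given
                continue
            for alias in _ALIASES[field]:
                if alias in normalized:
                    resolved[field] = normalized[alias]
                    break
            else:
                raise ValueError(
                    f"could not locate a column for {field!r}; available headers: {headers} "
                    f"(recognized aliases: {_ALIASES[field]})"
                )
        if len(set(resolved.values())) != 4:
            raise ValueError(f"column mapping is not one-to-one: {resolved}")
        return resolved


def _coerce_numeric(series: pd.Series, column: str) -> np.ndarray:
    numeric = pd.to_numeric(series, errors="coerce")
    bad = series.notna() & numeric.isna()
    if bad.any():
        rows = (series.index[bad] + 2).tolist()[:5]  # +2: header line + 1-based
        offenders = series[bad].astype(str).tolist()[:5]
        if any("," in v for v in offenders):
            raise ValueError(
                f"column {column!r} contains comma decimal separators (e.g. {offenders[0]!r}) "
                f"at file row(s) {rows}; use a dot decimal separator"
            )
        raise ValueError(
            f"column {column!r} contains non-numeric value(s) {offenders} at file row(s) {rows}"
        )
    if numeric.isna().any():
        rows = (series.index[numeric.isna()] + 2).tolist()[:5]
        raise ValueError(f"column {column!r} has missing values at file row(s) {rows}")
    return numeric.to_numpy(dtype=float)


def read_dataset(
    path,
    mapping: ColumnMapping | None = None,
    *,
    sheet: int | str = 0,
) -> SorptionDataset:
    """Load a sorption dataset from CSV or XLSX.

    Rows failing the domain checks (a_w outside (0,1), negative moisture,
    non-numeric cells) are rejected with row-indexed messages; row order
    is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mapping = mapping or ColumnMapping()
    if path.suffix.lower() in (".xlsx", ".xlsm", ".xls"):
        frame = pd.read_excel(path, sheet_name=sheet, dtype=object)
    else:
        frame = pd.read_csv(path, dtype=object)
    if frame.empty:
        raise ValueError(f"{path} contains no data rows")
    cols = mapping.resolve(frame.columns)
    frame = frame.reset_index(drop=True)

    rep = _coerce_numeric(frame[cols["replicate"]], cols["replicate"])
    temp = _coerce_numeric(frame[cols["temperature"]], cols["temperature"])
    aw = _coerce_numeric(frame[cols["water_activity"]], cols["water_activity"])
    xe = _coerce_numeric(frame[cols["moisture"]], cols["moisture"])

    bad_aw = np.flatnonzero((aw <= 0) | (aw >= 1))
    if bad_aw.size:
        rows = (bad_aw + 2).tolist()[:5]
        raise ValueError(
            f"water activity must lie strictly in (0, 1); violated at file row(s) {rows} "
            f"with value(s) {aw[bad_aw[:5]].tolist()}"
        )
    bad_xe = np.flatnonzero(xe < 0)
    if bad_xe.size:
        rows = (bad_xe + 2).tolist()[:5]
        raise ValueError(f"moisture content must be >= 0; violated at file row(s) {rows}")

    return SorptionDataset(
        rep.astype(int),
        temp,
        aw,
        xe,
        temperature_unit=mapping.temperature_unit,
        source=str(path),
    )


def write_dataset(dataset: SorptionDataset, path) -> Path:
    """Write a dataset as CSV or XLSX (by extension) in the canonical layout."""
    path = Path(path)
    frame = dataset.to_frame()
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        frame.to_excel(path, index=False)
    else:
        frame.to_csv(path, index=False)
    return path


def _listify(x) -> list:
    return np.asarray(x, dtype=float).tolist()


def report_dict(
    result: FitResult,
    diagnostics: ResidualDiagnostics | None = None,
    verdict: ValidationVerdict | None = None,
) -> dict:
    """Assemble the JSON-serializable report for a calibrated model."""
    g = result.goodness
    doc = {
        "software": {"name": "aquasorb", "version": __version__},
        "model": {"family": result.spec.family.value, "generalized": result.spec.generalized},
        "parameter_names": list(result.parameter_names),
        "parameters": _listify(result.parameters.as_array()),
        "standard_errors": _listify(result.standard_errors),
        "ci_lower": _listify(result.ci_lower),
        "ci_upper": _listify(result.ci_upper),
        "t_statistics": _listify(result.t_statistics),
        "p_values": _listify(result.p_values),
        "covariance": [
            _listify(row) for row in np.atleast_2d(np.asarray(result.covariance, dtype=float))
        ],
        "goodness": {
            "mse": g.mse,
            "rmse": g.rmse,
            "r_squared": g.r_squared,
            "r_squared_adj": g.r_squared_adj,
        },
        "residuals": _listify(result.residuals),
        "convergence": {
            "converged": result.converged,
            "n_function_evaluations": result.n_function_evaluations,
            "message": result.message,
        },
        "fit_bounds": dataclasses.asdict(result.fit_bounds),
        "n_observations": result.n_observations,
        "n_parameters": result.n_parameters,
        "temperature_unit": result.temperature_unit,
        "options": {
            "tolerance": result.options.tolerance,
            "max_function_evaluations": result.options.max_function_evaluations,
            "max_iterations": result.options.max_iterations,
            "confidence_level": result.options.confidence_level,
        },
    }
    if diagnostics is not None:
        doc["residual_tests"] = {
            "ljung_box": {
                "statistic": diagnostics.ljung_box.statistic,
                "lags": diagnostics.ljung_box.lags,
                "p_value": diagnostics.ljung_box.p_value,
                "reject_independence": diagnostics.ljung_box.reject,
            },
            "lilliefors": {
                "statistic": diagnostics.lilliefors.statistic,
                "p_value": diagnostics.lilliefors.p_value,
                "reject_normality": diagnostics.lilliefors.reject,
                "n_monte_carlo": diagnostics.lilliefors.n_monte_carlo,
                "seed": diagnostics.lilliefors.seed,
            },
            "alpha": diagnostics.alpha,
        }
    if verdict is not None:
        doc["validation"] = {
            "verdict": verdict.verdict,
            "validated": verdict.validated,
            "r_squared_adj": verdict.r_squared_adj,
            "threshold": verdict.threshold,
            "feedback": list(verdict.feedback),
        }
    return doc


def write_report(
    result: FitResult,
    path,
    diagnostics: ResidualDiagnostics | None = None,
    verdict: ValidationVerdict | None = None,
) -> Path:
    """Serialize a fit report as deterministic, sorted-key JSON."""
    path = Path(path)
    doc = report_dict(result, diagnostics=diagnostics, verdict=verdict)
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path


def read_report(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def fit_from_report(doc: dict) -> FitResult:
    """Reconstruct a predict-capable :class:`FitResult` from a report."""
    spec = ModelSpec(doc["model"]["family"], doc["model"]["generalized"])
    opts = FitOptions(**doc["options"])
    residuals = np.asarray(doc["residuals"], dtype=float)
    g = doc["goodness"]
    goodness = GoodnessOfFit(
        mse=g["mse"],
        rmse=g["rmse"],
        r_squared=g["r_squared"],
        r_squared_adj=g["r_squared_adj"],
        n_observations=doc["n_observations"],
        n_parameters=doc["n_parameters"],
    )
    return FitResult(
        spec=spec,
        parameters=ParameterSet(tuple(doc["parameters"])),
        residuals=residuals,
        covariance=np.asarray(doc["covariance"], dtype=float),
        standard_errors=np.asarray(doc["standard_errors"], dtype=float),
        ci_lower=np.asarray(doc["ci_lower"], dtype=float),
        ci_upper=np.asarray(doc["ci_upper"], dtype=float),
        t_statistics=np.asarray(doc["t_statistics"], dtype=float),
        p_values=np.asarray(doc["p_values"], dtype=float),
        goodness=goodness,
        converged=doc["convergence"]["converged"],
        n_function_evaluations=doc["convergence"]["n_function_evaluations"],
        n_iterations=None,
        fit_bounds=FitBounds(**doc["fit_bounds"]),
        n_observations=doc["n_observations"],
        n_parameters=doc["n_parameters"],
        temperature_unit=doc["temperature_unit"],
        options=opts,
        message=doc["convergence"]["message"],
        jacobian=None,
    )


def write_residuals(result: FitResult, path) -> Path:
    """Export the residual vector as CSV (index, residual in % d.b.)."""
    path = Path(path)
    pd.DataFrame({"residual": result.residuals}).to_csv(path, index_label="record")
    return path
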