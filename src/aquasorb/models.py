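"""Isotherm model families and their temperature-generalized forms.

Three empirical equations describe the equilibrium moisture content
``X_e`` (% dry basis) of a low-moisture food as a function of water
activity ``a_w`` and, in the generalized forms, absolute temperature
``T`` (K):

* **Peleg** — double power law ``X_e = b0*a_w**b1 + b2*a_w**b3``.
* **Polynomial** — cubic in ``a_w``.
* **DLP** (double log polynomial) — cubic in ``x = ln(-ln a_w)``.

The temperature-generalized variant replaces each parameter ``b_i`` by
the affine function ``b_i*T + b_i1``, giving eight parameters in the
canonical order ``(b0, b01, b1, b11, b2, b21, b3, b31)``.

All evaluation happens in Kelvin internally; datasets carry their
declared unit and are converted on the way in.
"""

from __future__ import annotations

import dataclasses
import enum
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CELSIUS_OFFSET",
    "DomainError",
    "IdentifiabilityError",
    "InsufficientDataError",
    "ModelFamily",
    "ModelSpec",
    "ParameterSet",
    "SorptionRecord",
    "SorptionDataset",
    "dlp_transform",
    "evaluate",
    "design_matrix",
    "DESIGN_COLUMN_ORDER",
    "design_to_canonical",
    "canonical_to_design",
]

CELSIUS_OFFSET = 273.15

#: Parameter names, canonical order.
GENERALIZED_PARAMETER_NAMES = ("b0", "b01", "b1", "b11", "b2", "b21", "b3", "b31")
SINGLE_PARAMETER_NAMES = ("b0", "b1", "b2", "b3")

#: Column order of :func:`design_matrix`; the intercept-like b_i1 entries
#: come first in each (constant, temperature-slope) pair.
DESIGN_COLUMN_ORDER = ("b01", "b0", "b11", "b1", "b21", "b2", "b31", "b3")

# canonical index i holds the parameter named GENERALIZED_PARAMETER_NAMES[i];
# its position in the design column order:
_CANONICAL_TO_DESIGN = np.array([1, 0, 3, 2, 5, 4, 7, 6])


class DomainError(ValueError):
    """An input falls outside the mathematical domain of an operation."""


class InsufficientDataError(ValueError):
    """Fewer observations than parameters (or empty input)."""


class IdentifiabilityError(ValueError):
    """The requested model cannot be identified from the data provided."""


class ModelFamily(str, enum.Enum):
    PELEG = "peleg"
    POLYNOMIAL = "polynomial"
    DLP = "dlp"

    @classmethod
    def coerce(cls, value: "ModelFamily | str | int") -> "ModelFamily":
        """Accept a member, a name, or the 1/2/3 menu aliases."""
        if isinstance(value, cls):
            return value
        aliases = {"1": cls.PELEG, "2": cls.POLYNOMIAL, "3": cls.DLP}
        key = str(value).strip().lower()
        if key in aliases:
            return aliases[key]
        try:
            return cls(key)
        except ValueError:
            raise ValueError(
                f"unknown model family {value!r}; expected one of "
                f"{[m.value for m in cls]} or the numeric aliases 1/2/3"
            ) from None


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """A model family plus whether temperature is coupled in."""

    family: ModelFamily
    generalized: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", ModelFamily.coerce(self.family))

    @property
    def n_parameters(self) -> int:
        return 8 if self.generalized else 4

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return GENERALIZED_PARAMETER_NAMES if self.generalized else SINGLE_PARAMETER_NAMES


@dataclasses.dataclass(frozen=True)
class ParameterSet:
    """Ordered parameter vector: 8 entries (generalized, canonical order
    ``b0, b01, b1, b11, b2, b21, b3, b31``) or 4 (single temperature)."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if len(vals) not in (4, 8):
            raise ValueError(f"parameter vector must have length 4 or 8, got {len(vals)}")
        if not all(np.isfinite(vals)):
            raise ValueError("parameter vector contains non-finite entries")
        object.__setattr__(self, "values", vals)

    @property
    def generalized(self) -> bool:
        return len(self.values) == 8

    @property
    def names(self) -> tuple[str, ...]:
        return GENERALIZED_PARAMETER_NAMES if self.generalized else SINGLE_PARAMETER_NAMES

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


def _as_parameter_array(params, spec: ModelSpec) -> np.ndarray:
    p = params.as_array() if isinstance(params, ParameterSet) else np.asarray(params, float)
    if p.shape != (spec.n_parameters,):
        raise ValueError(
            f"expected {spec.n_parameters} parameters for {spec.family.value} "
            f"(generalized={spec.generalized}), got shape {p.shape}"
        )
    return p


def _check_water_activity(aw: np.ndarray) -> None:
    if not np.all(np.isfinite(aw)):
        raise DomainError("water activity must be finite")
    if np.any(aw <= 0.0) or np.any(aw >= 1.0):
        bad = np.asarray(aw)[(np.asarray(aw) <= 0) | (np.asarray(aw) >= 1)]
        raise DomainError(
            f"water activity must lie strictly in (0, 1); offending value(s): {bad[:5]}"
        )


def dlp_transform(water_activity):
    """Variable transform ``x = ln(-ln a_w)`` used by the DLP equation.

    Strictly decreasing in ``a_w`` on (0, 1); raises :class:`DomainError`
    outside the open interval.
    """
    aw = np.asarray(water_activity, dtype=float)
    _check_water_activity(aw)
    out = np.log(-np.log(aw))
    return float(out) if np.isscalar(water_activity) or out.ndim == 0 else out


def _coefficients(spec: ModelSpec, p: np.ndarray, temperature) -> tuple:
    """The four working coefficients c0..c3 (affine in T when generalized)."""
    if spec.generalized:
        if temperature is None:
            raise ValueError("generalized model evaluation requires a temperature")
        T = np.asarray(temperature, dtype=float)
        if not np.all(np.isfinite(T)):
            raise DomainError("temperature must be finite")
        return tuple(p[2 * i] * T + p[2 * i + 1] for i in range(4))
    return tuple(p[i] for i in range(4))


def evaluate(spec: ModelSpec, params, water_activity, temperature=None, *, check: bool = True):
    """Predicted equilibrium moisture content (% d.b.).

    Parameters
    ----------
    spec
        Model family and generalization flag.
    params
        :class:`ParameterSet` or array-like in canonical order.
    water_activity
        Scalar or array, strictly inside (0, 1).
    temperature
        Absolute temperature in Kelvin; required iff ``spec.generalized``.
    check
        Disable domain validation (internal fast path).
    """
    p = _as_parameter_array(params, spec)
    aw = np.asarray(water_activity, dtype=float)
    if check:
        _check_water_activity(aw)
    c0, c1, c2, c3 = _coefficients(spec, p, temperature)
    if spec.family is ModelFamily.PELEG:
        out = c0 * aw**c1 + c2 * aw**c3
    else:
        u = np.log(-np.log(aw)) if spec.family is ModelFamily.DLP else aw
        out = c0 + u * (c1 + u * (c2 + u * c3))
    out = np.asarray(out, dtype=float)
    return float(out) if out.ndim == 0 else out


def design_matrix(spec: ModelSpec, dataset: "SorptionDataset") -> np.ndarray:
    """N x 8 regressor matrix for the linear-in-parameter generalized families.

    Columns are ``[1, T, u, T*u, u**2, T*u**2, u**3, T*u**3]`` with
    ``u = a_w`` (Polynomial) or ``u = ln(-ln a_w)`` (DLP) and T in Kelvin,
    matching the parameter order :data:`DESIGN_COLUMN_ORDER`
    ``(b01, b0, b11, b1, b21, b2, b31, b3)``.  ``X @ beta_design``
    reproduces :func:`evaluate` exactly.
    """
    if spec.family is ModelFamily.PELEG:
        raise ValueError("design_matrix is undefined for the Peleg family (nonlinear in parameters)")
    if not spec.generalized:
        raise ValueError("design_matrix is defined for generalized specs only")
    aw = dataset.water_activity
    T = dataset.temperatures_kelvin()
    u = np.log(-np.log(aw)) if spec.family is ModelFamily.DLP else aw
    ones = np.ones_like(u)
    cols = [ones, T, u, T * u, u**2, T * u**2, u**3, T * u**3]
    return np.column_stack(cols)


def design_to_canonical(beta_design: np.ndarray) -> np.ndarray:
    """Reorder a design-order solution to the canonical parameter order."""
    beta = np.asarray(beta_design, float)
    return beta[_CANONICAL_TO_DESIGN]


def canonical_to_design(beta_canonical: np.ndarray) -> np.ndarray:
    """Reorder canonical parameters to the design column order."""
    beta = np.asarray(beta_canonical, float)
    out = np.empty_like(beta)
    out[_CANONICAL_TO_DESIGN] = beta
    return out


@dataclasses.dataclass(frozen=True)
class SorptionRecord:
    """One (replicate, temperature, water activity, moisture) observation."""

    replicate: int
    temperature: float
    water_activity: float
    moisture: float


class SorptionDataset:
    """Replicate-tagged sorption observations with unit metadata.

    Parameters
    ----------
    replicate, temperature, water_activity, moisture
        Equal-length 1-d array-likes; ``water_activity`` strictly in
        (0, 1), ``moisture`` (% d.b.) non-negative.
    temperature_unit
        ``"celsius"`` (default) or ``"kelvin"`` — the unit of the
        ``temperature`` column as given.
    source
        Free-text provenance.
    """

    def __init__(
        self,
        replicate,
        temperature,
        water_activity,
        moisture,
        temperature_unit: str = "celsius",
        source: str = "",
    ) -> None:
        self.replicate = np.asarray(replicate, dtype=int)
        self.temperature = np.asarray(temperature, dtype=float)
        self.water_activity = np.asarray(water_activity, dtype=float)
        self.moisture = np.asarray(moisture, dtype=float)
        unit = str(temperature_unit).strip().lower()
        if unit not in ("celsius", "kelvin"):
            raise ValueError(f"temperature_unit must be 'celsius' or 'kelvin', got {temperature_unit!r}")
        self.temperature_unit = unit
        self.source = source
        self._validate()

    def _validate(self) -> None:
        n = len(self.water_activity)
        if n == 0:
            raise InsufficientDataError("dataset is empty")
        for name in ("replicate", "temperature", "water_activity", "moisture"):
            arr = getattr(self, name)
            if arr.ndim != 1 or len(arr) != n:
                raise ValueError(f"column {name!r} must be 1-d of length {n}")
        if not np.all(np.isfinite(self.temperature)):
            bad = np.flatnonzero(~np.isfinite(self.temperature))
            raise ValueError(f"non-finite temperature at record(s) {bad[:5].tolist()}")
        bad_aw = np.flatnonzero(
            ~np.isfinite(self.water_activity)
            | (self.water_activity <= 0)
            | (self.water_activity >= 1)
        )
        if bad_aw.size:
            raise DomainError(
                f"water activity must lie strictly in (0, 1); offending record(s) "
                f"{bad_aw[:5].tolist()} with value(s) {self.water_activity[bad_aw[:5]]}"
            )
        bad_xe = np.flatnonzero(~np.isfinite(self.moisture) | (self.moisture < 0))
        if bad_xe.size:
            raise ValueError(
                f"moisture content must be finite and >= 0; offending record(s) "
                f"{bad_xe[:5].tolist()}"
            )

    def __len__(self) -> int:
        return len(self.water_activity)

    @property
    def n_temperatures(self) -> int:
        return len(np.unique(self.temperature))

    def temperatures_kelvin(self) -> np.ndarray:
        if self.temperature_unit == "kelvin":
            return self.temperature.copy()
        return self.temperature + CELSIUS_OFFSET

    def records(self) -> list[SorptionRecord]:
        return [
            SorptionRecord(int(r), float(t), float(a), float(x))
            for r, t, a, x in zip(
                self.replicate, self.temperature, self.water_activity, self.moisture
            )
        ]

    @classmethod
    def from_records(
        cls,
        records: Iterable[SorptionRecord],
        temperature_unit: str = "celsius",
        source: str = "",
    ) -> "SorptionDataset":
        recs = list(records)
        return cls(
            [r.replicate for r in recs],
            [r.temperature for r in recs],
            [r.water_activity for r in recs],
            [r.moisture for r in recs],
            temperature_unit=temperature_unit,
            source=source,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": self.replicate,
                "temperature": self.temperature,
                "water_activity": self.water_activity,
                "moisture": self.moisture,
            }
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, temperature_unit: str = "celsius", source: str = ""
    ) -> "SorptionDataset":
        return cls(
            frame["replicate"].to_numpy(),
            frame["temperature"].to_numpy(),
            frame["water_activity"].to_numpy(),
            frame["moisture"].to_numpy(),
            temperature_unit=temperature_unit,
            source=source,
        )

    def permuted(self, order: Sequence[int]) -> "SorptionDataset":
        idx = np.asarray(order, dtype=int)
        return SorptionDataset(
            self.replicate[idx],
            self.temperature[idx],
            self.water_activity[idx],
            self.moisture[idx],
            temperature_unit=self.temperature_unit,
            source=self.source,
        )
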