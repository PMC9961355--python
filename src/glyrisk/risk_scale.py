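"""The Kovatchev blood-glucose risk transform and its standardized variable.

Glucose x (mg/dL) maps to the risk variable

    y = gamma * ((ln x)**alpha - beta)

with fitted constants alpha=1.084, beta=5.381, gamma=1.509.  The map is
strictly increasing and crosses zero at x* = exp(beta**(1/alpha)) ≈ 112.5.
Over the CGM-valid range [39, 400] the realized span of y is roughly
[-1.95, 2.39]; dividing by 10 gives the standardized variable xi used as the
network scale.  The risk *score* is 10*y**2 and its normalized form y**2/10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cgm_io import CGMSeries, GLUCOSE_MAX, GLUCOSE_MIN
from .errors import DomainError

XI_DIVISOR = 10.0


@dataclass(frozen=True)
class RiskScaleParams:
    alpha: float = 1.084
    beta: float = 5.381
    gamma: float = 1.509

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma) <= 0:
            raise ValueError("risk-scale parameters must be strictly positive")


DEFAULT_PARAMS = RiskScaleParams()


def glucose_to_risk(x, params: RiskScaleParams = DEFAULT_PARAMS):
    """Map glucose (mg/dL, must exceed 1) to the risk variable y."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 1):
        raise DomainError("glucose must exceed 1 mg/dL for the risk transform")
    y = params.gamma * (np.log(x) ** params.alpha - params.beta)
    return y if y.ndim else float(y)


def risk_to_glucose(y, params: RiskScaleParams = DEFAULT_PARAMS):
    """Exact inverse of :func:`glucose_to_risk`."""
    y = np.asarray(y, dtype=float)
    base = y / params.gamma + params.beta
    if np.any(base <= 0):
        raise DomainError("risk value below the invertible range")
    x = np.exp(base ** (1.0 / params.alpha))
    return x if x.ndim else float(x)


def zero_risk_glucose(params: RiskScaleParams = DEFAULT_PARAMS) -> float:
    """Glucose level at which the risk variable is exactly zero."""
    return float(np.exp(params.beta ** (1.0 / params.alpha)))


def risk_bounds(params: RiskScaleParams = DEFAULT_PARAMS) -> tuple[float, float]:
    """Realized (min, max) of y over the CGM-valid glucose range [39, 400]."""
    return (
        float(glucose_to_risk(GLUCOSE_MIN, params)),
        float(glucose_to_risk(GLUCOSE_MAX, params)),
    )


def bg_risk_score(y):
    """Risk score 10*y**2 — symmetric, non-negative, zero only at y=0."""
    y = np.asarray(y, dtype=float)
    s = 10.0 * y**2
    return s if s.ndim else float(s)


def normalized_bg_risk(y):
    """Normalized risk score y**2/10, used as an error weight."""
    y = np.asarray(y, dtype=float)
    s = y**2 / 10.0
    return s if s.ndim else float(s)


@dataclass
class RiskSeries:
    """A fully-valid series on the risk scale; ``xi`` is always ``y / 10``."""

    individual_id: str
    t0: pd.Timestamp
    dt: float
    y: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)

    @property
    def xi(self) -> np.ndarray:
        return self.y / XI_DIVISOR

    def __len__(self) -> int:
        return len(self.y)


def standardize(y, individual_id: str = "", t0=None, dt: float = 5.0) -> RiskSeries:
    """Wrap a risk-variable sequence into a RiskSeries (xi derived as y/10)."""
    return RiskSeries(individual_id, t0 if t0 is not None else pd.Timestamp(0), dt, y)


def destandardize(xi) -> np.ndarray:
    return np.asarray(xi, dtype=float) * XI_DIVISOR


def to_risk_series(series: CGMSeries, params: RiskScaleParams = DEFAULT_PARAMS) -> RiskSeries:
    """Convert a fully-imputed glucose series to the risk scale."""
    if not series.valid.all():
        raise DomainError("to_risk_series requires a fully-valid (imputed) series")
    return RiskSeries(
        series.individual_id, series.t0, series.dt, glucose_to_risk(series.values, params)
    )
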