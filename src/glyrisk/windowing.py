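"""Supervised window construction for the two model families.

Recurrent-family windows take 10 input points spaced one horizon apart
(indices t, t+h, ..., t+9h) with the target one further horizon ahead at
t+10h.  Lattice (CNN) windows take 16 consecutive points t..t+15, arranged
row-major into a 4x4 grid, with the target at t+15+h.  In both families the
target therefore sits exactly ``horizon_minutes`` after the most recent
input observation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .cgm_io import CGMSeries
from .errors import ConfigError
from .risk_scale import RiskSeries

logger = logging.getLogger(__name__)

RECURRENT_INPUT_LEN = 10
LATTICE_INPUT_LEN = 16
LATTICE_SHAPE = (4, 4)
DEFAULT_MAX_LEN = 10_000


@dataclass(frozen=True)
class WindowSpec:
    family: str  # "recurrent" | "lattice"
    horizon_minutes: int
    dt: float = 5.0
    stride: int = 1
    scale: str = "xi"  # "xi" | "glucose"
    lattice_order: str = "row"  # "row" | "column"

    def __post_init__(self):
        if self.family not in ("recurrent", "lattice"):
            raise ConfigError(f"unknown window family {self.family!r}")
        if self.scale not in ("xi", "glucose"):
            raise ConfigError(f"unknown scale {self.scale!r}")
        if self.horizon_minutes % self.dt != 0:
            raise ConfigError("horizon_minutes must be divisible by dt")
        if self.stride < 1:
            raise ConfigError("stride must be >= 1")

    @property
    def horizon_steps(self) -> int:
        return int(self.horizon_minutes / self.dt)

    @property
    def input_len(self) -> int:
        return RECURRENT_INPUT_LEN if self.family == "recurrent" else LATTICE_INPUT_LEN


@dataclass
class WindowSet:
    inputs: np.ndarray  # (n, 10) or (n, 4, 4)
    targets: np.ndarray  # (n,)
    spec: WindowSpec
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.targets)


def _series_values(series, scale: str) -> np.ndarray:
    if isinstance(series, RiskSeries):
        if scale != "xi":
            raise ConfigError("RiskSeries windows must use scale='xi'")
        return series.xi
    if isinstance(series, CGMSeries):
        if scale != "glucose":
            raise ConfigError("CGMSeries windows must use scale='glucose'")
        if not series.valid.all():
            raise ConfigError("windowing requires a fully-imputed series")
        return series.values
    return np.asarray(series, dtype=float)


def make_recurrent_windows(series, spec: WindowSpec) -> WindowSet:
    """Windows of 10 points spaced one horizon apart, target one horizon on."""
    x = _series_values(series, spec.scale)
    h = spec.horizon_steps
    L = len(x)
    n = max(0, L - RECURRENT_INPUT_LEN * h)
    bases = np.arange(0, n, spec.stride)
    if bases.size == 0:
        logger.warning("series too short for recurrent windows (L=%d, h=%d)", L, h)
        return WindowSet(
            np.empty((0, RECURRENT_INPUT_LEN)), np.empty(0), spec, _sid(series)
        )
    offsets = np.arange(RECURRENT_INPUT_LEN) * h
    inputs = x[bases[:, None] + offsets[None, :]]
    targets = x[bases + RECURRENT_INPUT_LEN * h]
    return WindowSet(inputs, targets, spec, _sid(series))


def make_lattice_windows(series, spec: WindowSpec) -> WindowSet:
    """Windows of 16 consecutive points as a 4x4 lattice, target a horizon on."""
    x = _series_values(series, spec.scale)
    h = spec.horizon_steps
    L = len(x)
    n = max(0, L - (LATTICE_INPUT_LEN - 1) - h)
    bases = np.arange(0, n, spec.stride)
    if bases.size == 0:
        logger.warning("series too short for lattice windows (L=%d, h=%d)", L, h)
        return WindowSet(np.empty((0, *LATTICE_SHAPE)), np.empty(0), spec, _sid(series))
    offsets = np.arange(LATTICE_INPUT_LEN)
    flat = x[bases[:, None] + offsets[None, :]]
    lat = flat.reshape(-1, *LATTICE_SHAPE)
    if spec.lattice_order == "column":
        lat = np.transpose(lat, (0, 2, 1))
    targets = x[bases + (LATTICE_INPUT_LEN - 1) + h]
    return WindowSet(lat, targets, spec, _sid(series))


def make_windows(series, spec: WindowSpec) -> WindowSet:
    if spec.family == "recurrent":
        return make_recurrent_windows(series, spec)
    return make_lattice_windows(series, spec)


def truncate_series(series, max_len: int = DEFAULT_MAX_LEN):
    """Keep the first ``max_len`` grid points (default 10^4 ≈ 34 days at 5 min)."""
    if len(series) <= max_len:
        return series
    if isinstance(series, RiskSeries):
        return replace(series, y=series.y[:max_len].copy())
    return replace(
        series, values=series.values[:max_len].copy(), valid=series.valid[:max_len].copy()
    )


def _sid(series) -> str:
    return getattr(series, "individual_id", "")
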