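"""Reading and writing CGM series on a regular sampling grid.

A series is stored as a dense grid of slots spaced ``dt`` minutes apart,
starting at ``t0``.  Each slot holds a glucose reading in mg/dL (NaN when
nothing was recorded) and a validity flag.  Raw (pre-clean) series may carry
finite but invalid readings; canonical series use NaN for every invalid slot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientDataError

logger = logging.getLogger(__name__)

GLUCOSE_MIN = 39.0
GLUCOSE_MAX = 400.0

_DT_COMMENT = "# dt_minutes="


@dataclass
class CGMSeries:
    """A glucose series aligned on a regular ``dt``-minute grid.

    Parameters
    ----------
    individual_id : str
        Identifier of the person the series belongs to.
    t0 : pd.Timestamp
        Timestamp of slot 0 (timezone-naive; only relative time matters).
    dt : float
        Grid spacing in minutes (default 5).
    values : np.ndarray
        Glucose readings in mg/dL, NaN where missing.
    valid : np.ndarray
        Boolean mask, same length as ``values``.
    """

    individual_id: str
    t0: pd.Timestamp
    dt: float
    values: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must have equal length")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return len(self.values)

    def validate(self) -> None:
        """Check the clean-series invariants; raise ValueError on violation."""
        if len(self) < 2:
            raise ValueError("series must have length >= 2")
        v = self.values[self.valid]
        if not np.all(np.isfinite(v)):
            raise ValueError("valid entries must be finite")
        if v.size and (v.min() < GLUCOSE_MIN or v.max() > GLUCOSE_MAX):
            raise ValueError(
                f"valid entries must lie in [{GLUCOSE_MIN:g}, {GLUCOSE_MAX:g}]"
            )

    def copy(self) -> "CGMSeries":
        return replace(self, values=self.values.copy(), valid=self.valid.copy())

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.t0 + pd.to_timedelta(np.arange(len(self)) * self.dt, unit="m")


def read_cgm_csv(path, dt: float = 5.0, individual_id: str | None = None) -> CGMSeries:
    """Read a ``timestamp,glucose`` CSV and snap it to a regular grid.

    Readings map to slot ``round((t - t0) / dt)`` from the first timestamp;
    when two rows land on the same slot the first is kept and a warning is
    logged.  Slots with no reading, or with a non-numeric glucose field, are
    marked invalid.
    """
    header_dt = _read_dt_comment(path)
    if header_dt is not None:
        dt = header_dt
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas raises various types
        raise FormatError(f"could not parse {path}: {exc}") from exc
    cols = {c.strip().lower(): c for c in df.columns}
    if "timestamp" not in cols or "glucose" not in cols:
        raise FormatError(f"{path}: expected header columns 'timestamp,glucose'")
    try:
        ts = pd.to_datetime(df[cols["timestamp"]])
    except Exception as exc:
        raise FormatError(f"{path}: unparseable timestamps: {exc}") from exc
    glucose = pd.to_numeric(df[cols["glucose"]], errors="coerce").to_numpy(float)
    if len(df) < 2:
        raise InsufficientDataError(f"{path}: need at least 2 rows, got {len(df)}")

    t0 = ts.iloc[0]
    minutes = (ts - t0).dt.total_seconds().to_numpy() / 60.0
    slots = np.rint(minutes / dt).astype(int)
    if slots.min() < 0:
        order = np.argsort(slots, kind="stable")
        slots, glucose = slots[order], glucose[order]
        t0 = t0 + pd.to_timedelta(slots[0] * dt, unit="m")
        slots = slots - slots[0]

    n = int(slots.max()) + 1
    values = np.full(n, np.nan)
    filled = np.zeros(n, dtype=bool)
    for s, g in zip(slots, glucose):
        if filled[s]:
            logger.warning("%s: duplicate reading for grid slot %d dropped", path, s)
            continue
        values[s] = g
        filled[s] = True

    if individual_id is None:
        individual_id = _stem(path)
    return CGMSeries(individual_id, pd.Timestamp(t0), dt, values)


def write_cgm_csv(series: CGMSeries, path) -> None:
    """Write a series as ``timestamp,glucose`` CSV with a ``# dt_minutes`` header.

    Slots whose value is NaN are written with an empty glucose field.  Finite
    values are written as-is, so a raw series roundtrips its readings; the
    validity mask is recomputed on read (invalid ⇔ missing field).
    """
    ts = series.timestamps
    with open(path, "w") as fh:
        fh.write(f"{_DT_COMMENT}{series.dt:g}\n")
        fh.write("timestamp,glucose\n")
        for t, v in zip(ts, series.values):
            g = "" if not np.isfinite(v) else f"{v:g}"
            fh.write(f"{t.isoformat()},{g}\n")


def _read_dt_comment(path) -> float | None:
    try:
        with open(path) as fh:
            first = fh.readline()
    except OSError as exc:
        raise FormatError(f"cannot open {path}: {exc}") from exc
    if first.startswith(_DT_COMMENT):
        try:
            return float(first[len(_DT_COMMENT):])
        except ValueError as exc:
            raise FormatError(f"{path}: bad dt header {first!r}") from exc
    return None


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]
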