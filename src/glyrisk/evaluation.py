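"""Forecast metrics: plain RMSE, risk-weighted RMSE, LM ratio, Clarke grid.

The risk-weighted RMSE weights each squared error by the normalized BG-risk
score of the *truth* point and normalizes by the weight sum:
sqrt(sum(w_i e_i^2) / sum(w_i)).  Clarke error-grid zones follow the
canonical published inequalities, evaluated in A, E, C, D order with B as
the fall-through.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, UndefinedMetricError
from .risk_scale import (
    DEFAULT_PARAMS,
    RiskScaleParams,
    destandardize,
    glucose_to_risk,
    normalized_bg_risk,
    risk_to_glucose,
)

ZONES = ("A", "B", "C", "D", "E")


@dataclass
class ForecastResult:
    """Aligned (truth, prediction) pairs on one scale."""

    truth: np.ndarray
    prediction: np.ndarray
    scale: str  # "xi" | "glucose"
    horizon_minutes: int
    model_name: str = ""
    individual_id: str = ""

    def __post_init__(self):
        self.truth = np.asarray(self.truth, dtype=float)
        self.prediction = np.asarray(self.prediction, dtype=float)
        if self.truth.shape != self.prediction.shape or self.truth.size < 1:
            raise ValueError("truth and prediction must be equal-length, non-empty")
        if not (np.all(np.isfinite(self.truth)) and np.all(np.isfinite(self.prediction))):
            raise ValueError("truth and prediction must be finite")

    def __len__(self) -> int:
        return len(self.truth)

    def to_glucose(self, params: RiskScaleParams = DEFAULT_PARAMS) -> "ForecastResult":
        """Convert a xi-scale result to glucose via the inverse risk map.

        Predictions are clipped to the glucose-representable risk range
        before inversion (tanh outputs can stray outside it early in
        training).
        """
        if self.scale == "glucose":
            return self
        lo = glucose_to_risk(39.0, params)
        hi = glucose_to_risk(400.0, params)
        y_t = np.clip(destandardize(self.truth), lo, hi)
        y_p = np.clip(destandardize(self.prediction), lo, hi)
        return ForecastResult(
            risk_to_glucose(y_t, params),
            risk_to_glucose(y_p, params),
            "glucose",
            self.horizon_minutes,
            self.model_name,
            self.individual_id,
        )


def rmse(result: ForecastResult) -> float:
    """Root mean squared error over the aligned pairs."""
    e = result.prediction - result.truth
    return float(np.sqrt(np.mean(e**2)))


def weighted_rmse(
    result: ForecastResult,
    weights: np.ndarray | None = None,
    params: RiskScaleParams = DEFAULT_PARAMS,
    weight_on: str = "truth",
) -> float:
    """Risk-weighted RMSE: sqrt(sum(w e^2) / sum(w)).

    By default weights are the normalized BG-risk scores of the truth
    points (``weight_on="prediction"`` uses predicted risk instead); an
    explicit ``weights`` array overrides both.
    """
    if weights is None:
        if result.scale != "glucose":
            raise DomainError("risk weights require a glucose-scale result")
        ref = result.truth if weight_on == "truth" else result.prediction
        weights = normalized_bg_risk(glucose_to_risk(ref, params))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != result.truth.shape:
        raise ValueError("weights must align with the pairs")
    wsum = weights.sum()
    if wsum <= 0:
        raise UndefinedMetricError("all weights are zero; weighted RMSE undefined")
    e = result.prediction - result.truth
    return float(np.sqrt(np.sum(weights * e**2) / wsum))


def lm_ratio(model_rmse: float, lm_rmse: float) -> float:
    """Model RMSE divided by the persistence-baseline RMSE (< 1 is better)."""
    if lm_rmse <= 0:
        raise DomainError("LM RMSE must be positive to form a ratio")
    return model_rmse / lm_rmse


# --- Clarke error grid ----------------------------------------------------

def clarke_zone(reference: float, prediction: float) -> str:
    """Classify one (reference, prediction) glucose pair into zones A-E."""
    r, p = float(reference), float(prediction)
    if r <= 0 or p <= 0:
        raise DomainError("Clarke grid requires positive glucose values")
    if (r <= 70 and p <= 70) or abs(p - r) <= 0.2 * r:
        return "A"
    if (r >= 180 and p <= 70) or (r <= 70 and p >= 180):
        return "E"
    if (70 <= r <= 290 and p >= r + 110) or (130 <= r <= 180 and p <= (7 / 5) * r - 182):
        return "C"
    if (
        (r >= 240 and 70 <= p <= 180)
        or (r <= 175 / 3 and 70 <= p <= 180)
        or (175 / 3 <= r <= 70 and p >= (6 / 5) * r)
    ):
        return "D"
    return "B"


def clarke_zones(reference: np.ndarray, prediction: np.ndarray) -> np.ndarray:
    """Vectorized zone classification; returns an array of 'A'..'E'."""
    r = np.asarray(reference, dtype=float)
    p = np.asarray(prediction, dtype=float)
    if np.any(r <= 0) or np.any(p <= 0):
        raise DomainError("Clarke grid requires positive glucose values")
    out = np.full(r.shape, "B", dtype="U1")
    d = (
        ((r >= 240) & (70 <= p) & (p <= 180))
        | ((r <= 175 / 3) & (70 <= p) & (p <= 180))
        | ((175 / 3 <= r) & (r <= 70) & (p >= (6 / 5) * r))
    )
    out[d] = "D"
    c = ((70 <= r) & (r <= 290) & (p >= r + 110)) | (
        (130 <= r) & (r <= 180) & (p <= (7 / 5) * r - 182)
    )
    out[c] = "C"
    e = ((r >= 180) & (p <= 70)) | ((r <= 70) & (p >= 180))
    out[e] = "E"
    a = ((r <= 70) & (p <= 70)) | (np.abs(p - r) <= 0.2 * r)
    out[a] = "A"
    return out


@dataclass
class ClarkeZoneCounts:
    counts: dict[str, int] = field(default_factory=lambda: {z: 0 for z in ZONES})

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        n = self.total
        return {z: (self.counts[z] / n if n else 0.0) for z in ZONES}


def clarke_analysis(result: ForecastResult) -> ClarkeZoneCounts:
    """Per-zone counts and fractions for a glucose-scale result."""
    if result.scale != "glucose":
        raise DomainError("Clarke analysis requires glucose-scale values")
    zones = clarke_zones(result.truth, result.prediction)
    labels, counts = np.unique(zones, return_counts=True)
    out = ClarkeZoneCounts()
    for z, c in zip(labels, counts):
        out.counts[str(z)] = int(c)
    return out


def zone_ratio(
    model_counts: ClarkeZoneCounts, lm_counts: ClarkeZoneCounts
) -> dict[str, float | None]:
    """Elementwise model/LM count ratio per zone; 0/0 zones reported as None."""
    out: dict[str, float | None] = {}
    for z in ZONES:
        m, l = model_counts.counts[z], lm_counts.counts[z]
        out[z] = None if l == 0 else m / l
    return out


# --- report assembly ------------------------------------------------------

REPORT_COLUMNS = [
    "individual_id",
    "model_name",
    "arch",
    "horizon",
    "replica",
    "xi_rmse",
    "cgm_rmse",
    "weighted_cgm_rmse",
    "lm_ratio",
]


@dataclass
class EvaluationReport:
    """Tidy per-individual metric rows plus cohort quartile summaries."""

    rows: pd.DataFrame

    @classmethod
    def from_records(cls, records: list[dict]) -> "EvaluationReport":
        df = pd.DataFrame.from_records(records, columns=REPORT_COLUMNS)
        return cls(df)

    def summary(self) -> pd.DataFrame:
        metrics = ["xi_rmse", "cgm_rmse", "weighted_cgm_rmse", "lm_ratio"]
        return (
            self.rows.groupby(["model_name", "horizon"])[metrics]
            .quantile([0.25, 0.5, 0.75])
            .unstack(level=-1)
        )

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)
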