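"""Persistence baseline and training-cohort selection."""

from __future__ import annotations

import numpy as np

from ..cgm_io import CGMSeries
from ..errors import InsufficientDataError
from ..evaluation import ForecastResult
from ..risk_scale import RiskSeries


def lm_predict(series, horizon_steps: int, dt: float = 5.0) -> ForecastResult:
    """Sample-and-hold forecast: predict x[t - h] for every t >= h."""
    if isinstance(series, RiskSeries):
        x, scale, sid, dt = series.xi, "xi", series.individual_id, series.dt
    elif isinstance(series, CGMSeries):
        x, scale, sid, dt = series.values, "glucose", series.individual_id, series.dt
    else:
        x, scale, sid = np.asarray(series, dtype=float), "glucose", ""
    if len(x) <= horizon_steps:
        raise InsufficientDataError(
            f"series length {len(x)} <= horizon {horizon_steps} steps"
        )
    return ForecastResult(
        truth=x[horizon_steps:],
        prediction=x[:-horizon_steps],
        scale=scale,
        horizon_minutes=int(horizon_steps * dt),
        model_name="LM",
        individual_id=sid,
    )


def coefficient_of_variation(series: CGMSeries) -> float:
    """std/mean of the valid glucose readings."""
    v = series.values[series.valid]
    if v.size == 0:
        return float("nan")
    return float(np.std(v) / np.mean(v))


def select_training_individuals(
    cohort: list[CGMSeries], k: int, seed: int
) -> list[str]:
    """The highest-CV individual plus k-1 uniformly sampled others (seeded)."""
    if k > len(cohort):
        raise ValueError(f"k={k} exceeds cohort size {len(cohort)}")
    cvs = {s.individual_id: coefficient_of_variation(s) for s in cohort}
    top = max(cvs, key=lambda i: cvs[i])
    rest = [s.individual_id for s in cohort if s.individual_id != top]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E1]))
    extra = list(rng.choice(rest, size=k - 1, replace=False)) if k > 1 else []
    return [top] + [str(i) for i in extra]
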