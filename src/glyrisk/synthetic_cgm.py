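"""Synthetic CGM cohorts with realistic structure for end-to-end testing.

The latent trajectory is a mean-reverting first-order process in risk space
around the basal glucose level, with Gaussian innovations; meal excursions
arrive as a Poisson process and add a linear-rise / exponential-decay bump
in glucose space.  Simulating in risk space and inverting the transform
yields the right-skewed glucose distribution characteristic of CGM data.
Sensor artifacts (error codes, out-of-range readings, dropouts) are injected
afterwards in runs with geometric lengths so multi-point gaps occur.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cgm_io import CGMSeries, GLUCOSE_MAX, GLUCOSE_MIN, write_cgm_csv
from .errors import ConfigError
from .risk_scale import glucose_to_risk, risk_to_glucose


@dataclass(frozen=True)
class SimConfig:
    n_individuals: int = 1
    series_len: int = 10_000
    dt: float = 5.0
    basal_glucose: float = 120.0
    reversion_rate: float = 0.05
    noise_sd: float = 3.0  # mg/dL-equivalent innovation scale near basal
    meal_rate: float = 4.0  # events per day
    meal_amplitude: tuple[float, float] = (40.0, 120.0)
    meal_rise_steps: int = 4
    meal_decay_steps: int = 12
    invalid_frac: float = 0.03
    # proportions of (non-positive codes, below-39, above-400, missing)
    artifact_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1 or self.series_len < 2:
            raise ConfigError("need at least 1 individual and 2 grid points")
        if not (0.0 <= self.invalid_frac <= 0.3):
            raise ConfigError("invalid_frac must lie in [0, 0.3]")
        if not (0.0 < self.reversion_rate <= 1.0):
            raise ConfigError("reversion_rate must lie in (0, 1]")
        if min(self.meal_rate, self.noise_sd) < 0 or self.dt <= 0:
            raise ConfigError("rates and dt must be non-negative / positive")
        if abs(sum(self.artifact_mix) - 1.0) > 1e-9:
            raise ConfigError("artifact_mix proportions must sum to 1")


def _meal_bump(amplitude: float, rise: int, decay: int, length: int) -> np.ndarray:
    """Linear rise over ``rise`` steps then exponential decay (time const ``decay``)."""
    t = np.arange(length, dtype=float)
    up = np.minimum(t / max(rise, 1), 1.0)
    down = np.exp(-np.maximum(t - rise, 0.0) / max(decay, 1))
    return amplitude * up * down


def simulate_individual(
    config: SimConfig, individual_id: str = "sim-000", rng: np.random.Generator | None = None
) -> CGMSeries:
    """Generate one raw series (artifacts included) per the config."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x51D]))
    n = config.series_len
    # offset the baseline by the expected meal contribution so the realized
    # mean stays near basal_glucose
    p_step = config.meal_rate * config.dt / 1440.0
    bump_len = config.meal_rise_steps + 6 * config.meal_decay_steps
    shape_sum = _meal_bump(1.0, config.meal_rise_steps, config.meal_decay_steps, bump_len).sum()
    meal_mean = p_step * np.mean(config.meal_amplitude) * shape_sum
    baseline = max(config.basal_glucose - meal_mean, 60.0)
    y_basal = glucose_to_risk(baseline)
    sigma_y = glucose_to_risk(baseline + config.noise_sd) - y_basal

    # mean-reverting walk in risk space
    y = np.empty(n)
    y[0] = y_basal
    eps = rng.normal(0.0, sigma_y, size=n)
    theta = config.reversion_rate
    for t in range(1, n):
        y[t] = y[t - 1] + theta * (y_basal - y[t - 1]) + eps[t]

    glucose = risk_to_glucose(y)

    # meal excursions as Poisson arrivals in glucose space
    starts = np.flatnonzero(rng.random(n) < p_step)
    for s in starts:
        amp = rng.uniform(*config.meal_amplitude)
        seg = min(bump_len, n - s)
        glucose[s : s + seg] += _meal_bump(
            amp, config.meal_rise_steps, config.meal_decay_steps, seg
        )

    # keep the clean trajectory within the sensor-valid range so that with
    # invalid_frac=0 the preprocessing chain is an identity
    glucose = np.clip(glucose, GLUCOSE_MIN, GLUCOSE_MAX)

    values = glucose.copy()
    _inject_artifacts(values, config, rng)
    return CGMSeries(individual_id, pd.Timestamp("2020-01-01"), config.dt, values)


def _inject_artifacts(values: np.ndarray, config: SimConfig, rng: np.random.Generator) -> None:
    """Overwrite ~invalid_frac of slots with artifacts, in geometric runs (mean 2)."""
    n = len(values)
    needed = int(round(config.invalid_frac * n))
    if needed == 0:
        return
    hit = np.zeros(n, dtype=bool)
    kinds = ("nonpositive", "low", "high", "missing")
    placed = 0
    attempts = 0
    while placed < needed and attempts < 50 * needed:
        attempts += 1
        start = int(rng.integers(1, n - 1))  # keep both ends clean-ish
        length = min(int(rng.geometric(0.5)), needed - placed, n - 1 - start)
        if length < 1 or hit[start : start + length].any():
            continue
        kind = kinds[int(rng.choice(4, p=config.artifact_mix))]
        sl = slice(start, start + length)
        if kind == "nonpositive":
            values[sl] = rng.choice([0.0, -1.0], size=length)
        elif kind == "low":
            values[sl] = rng.uniform(15.0, GLUCOSE_MIN - 1e-6, size=length)
        elif kind == "high":
            values[sl] = rng.uniform(GLUCOSE_MAX + 1e-6, 500.0, size=length)
        else:
            values[sl] = np.nan
        hit[sl] = True
        placed += length


def simulate_cohort(config: SimConfig) -> list[CGMSeries]:
    """n_individuals independent series with jittered per-individual dynamics."""
    config.validate()
    ss = np.random.SeedSequence([config.seed, 0xC00])
    children = ss.spawn(config.n_individuals)
    cohort = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        jittered = replace(
            config,
            basal_glucose=float(np.clip(config.basal_glucose + rng.normal(0, 12), 90, 180)),
            noise_sd=float(config.noise_sd * rng.uniform(0.6, 1.6)),
            meal_rate=float(config.meal_rate * rng.uniform(0.5, 1.5)),
        )
        cohort.append(simulate_individual(jittered, f"sim-{i:03d}", rng))
    return cohort


def write_cohort(cohort: list[CGMSeries], out_dir, config: SimConfig | None = None) -> Path:
    """Emit one CSV per individual plus a manifest JSON; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in cohort:
        fname = f"{s.individual_id}.csv"
        write_cgm_csv(s, out / fname)
        entries.append({"individual_id": s.individual_id, "file": fname, "n_points": len(s)})
    manifest = {
        "n_individuals": len(cohort),
        "dt_minutes": cohort[0].dt if cohort else None,
        "individuals": entries,
    }
    if config is not None:
        manifest["config"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in config.__dict__.items()
        }
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
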