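"""End-to-end experiment orchestration: simulate/load → preprocess →
transform → train replicas → evaluate against the persistence baseline.

Single-individual models (RNN0/RNN/GRU/LSTM/CNN) train on the highest-CV
individual; CNN10 trains on the full ``train_k``-individual selection.  All
remaining individuals form the test set.  Every model row carries an
``lm_ratio`` computed against the persistence baseline evaluated on exactly
the same (input, target) pairs.
"""

from __future__ import annotations

import glob
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .cgm_io import CGMSeries, read_cgm_csv
from .errors import ConfigError, EmptySeriesError, GlyriskError
from .evaluation import EvaluationReport, ForecastResult, rmse, weighted_rmse
from .forecasters import (
    ModelSpec,
    build_model,
    lm_predict,
    predict,
    select_training_individuals,
    train,
)
from .preprocessing import IMPUTE_MODES, preprocess
from .risk_scale import to_risk_series
from .synthetic_cgm import SimConfig, simulate_cohort
from .windowing import WindowSpec, WindowSet, make_windows, truncate_series

logger = logging.getLogger(__name__)

DEFAULT_ARCHES = ("RNN0", "RNN", "GRU", "LSTM", "CNN", "CNN10")


@dataclass
class ExperimentConfig:
    sim: SimConfig | None = None
    data_dir: str | None = None
    horizons: tuple[int, ...] = (15, 30, 60)
    arches: tuple[str, ...] = DEFAULT_ARCHES
    replicas: int = 5
    train_k: int = 10
    seed: int = 0
    impute_mode: str = "recursive_floor"
    max_len: int = 10_000
    epochs: int = 50
    hidden_size: int = 16
    out_dir: str | None = None

    def validate(self) -> None:
        if (self.sim is None) == (self.data_dir is None):
            raise ConfigError("exactly one of sim / data_dir must be given")
        if self.impute_mode not in IMPUTE_MODES:
            raise ConfigError(f"unknown impute mode {self.impute_mode!r}")
        for a in self.arches:
            if a not in DEFAULT_ARCHES:
                raise ConfigError(f"unknown architecture {a!r}")
        if self.replicas < 1 or self.train_k < 1:
            raise ConfigError("replicas and train_k must be >= 1")


def load_cohort(config: ExperimentConfig) -> list[CGMSeries]:
    if config.sim is not None:
        return simulate_cohort(config.sim)
    files = sorted(glob.glob(str(Path(config.data_dir) / "*.csv")))
    if not files:
        raise ConfigError(f"no CSV files in {config.data_dir}")
    return [read_cgm_csv(f) for f in files]


def _windows_for(series: CGMSeries, arch: str, horizon: int) -> WindowSet:
    family = "lattice" if arch.startswith("CNN") else "recurrent"
    scale = "glucose" if arch == "RNN0" else "xi"
    spec = WindowSpec(family=family, horizon_minutes=horizon, dt=series.dt, scale=scale)
    src = series if scale == "glucose" else to_risk_series(series)
    return make_windows(src, spec)


def _concat_windows(sets: list[WindowSet]) -> WindowSet:
    nonempty = [w for w in sets if len(w)]
    if not nonempty:
        raise GlyriskError("no training windows available")
    return WindowSet(
        np.concatenate([w.inputs for w in nonempty]),
        np.concatenate([w.targets for w in nonempty]),
        nonempty[0].spec,
        source_id="+".join(w.source_id for w in nonempty),
    )


def _last_input(windows: WindowSet) -> np.ndarray:
    """The most recent observation in each window (the LM forecast)."""
    if windows.inputs.ndim == 2:
        return windows.inputs[:, -1]
    return windows.inputs[:, -1, -1]


def _pair_metrics(result: ForecastResult, lm_result: ForecastResult) -> dict:
    """xi/cgm/weighted RMSEs plus the LM ratio on identical pairs."""
    cgm = result.to_glucose()
    lm_cgm = lm_result.to_glucose()
    if result.scale == "xi":
        xi_rmse = rmse(result)
    else:  # glucose-scale model: report the xi-equivalent error too
        xi_rmse = rmse(_glucose_result_to_xi(result))
    lm_cgm_rmse = rmse(lm_cgm)
    return {
        "xi_rmse": xi_rmse,
        "cgm_rmse": rmse(cgm),
        "weighted_cgm_rmse": weighted_rmse(cgm),
        "lm_ratio": rmse(cgm) / lm_cgm_rmse if lm_cgm_rmse > 0 else float("nan"),
    }


def _glucose_result_to_xi(result: ForecastResult) -> ForecastResult:
    from .risk_scale import glucose_to_risk

    t = np.clip(result.truth, 39.0, 400.0)
    p = np.clip(result.prediction, 39.0, 400.0)
    return ForecastResult(
        glucose_to_risk(t) / 10.0,
        glucose_to_risk(p) / 10.0,
        "xi",
        result.horizon_minutes,
        result.model_name,
        result.individual_id,
    )


def run_experiment(config: ExperimentConfig) -> EvaluationReport:
    """Run the full protocol and return (optionally also write) the report."""
    config.validate()
    raw = load_cohort(config)

    processed: list[CGMSeries] = []
    for s in raw:
        try:
            p = truncate_series(preprocess(s, config.impute_mode), config.max_len)
        except EmptySeriesError:
            logger.warning("%s: no valid data, dropped from cohort", s.individual_id)
            continue
        processed.append(p)
    if len(processed) <= config.train_k:
        raise ConfigError("cohort too small for the requested train_k")

    train_ids = select_training_individuals(processed, config.train_k, config.seed)
    by_id = {s.individual_id: s for s in processed}
    test_series = [s for s in processed if s.individual_id not in set(train_ids)]
    logger.info("training on %s; %d held-out individuals", train_ids, len(test_series))

    records: list[dict] = []
    for horizon in config.horizons:
        # persistence-baseline rows, one per held-out individual
        for s in test_series:
            h_steps = int(horizon / s.dt)
            lm_cgm = lm_predict(s, h_steps)
            lm_xi = lm_predict(to_risk_series(s), h_steps)
            records.append(
                {
                    "individual_id": s.individual_id,
                    "model_name": "LM",
                    "arch": "LM",
                    "horizon": horizon,
                    "replica": 0,
                    "xi_rmse": rmse(lm_xi),
                    "cgm_rmse": rmse(lm_cgm),
                    "weighted_cgm_rmse": weighted_rmse(lm_cgm),
                    "lm_ratio": 1.0,
                }
            )

        for arch in config.arches:
            train_members = train_ids if arch == "CNN10" else train_ids[:1]
            train_windows = _concat_windows(
                [_windows_for(by_id[i], arch, horizon) for i in train_members]
            )
            for replica in range(config.replicas):
                sub = np.random.SeedSequence(
                    [config.seed, DEFAULT_ARCHES.index(arch), horizon, replica]
                )
                mspec = ModelSpec(
                    arch=arch,
                    horizon_minutes=horizon,
                    hidden_size=config.hidden_size,
                    seed=int(sub.generate_state(1)[0]),
                    epochs=config.epochs,
                )
                trained = train(build_model(mspec), train_windows, mspec)
                model_name = f"{arch}_{replica + 1}"
                for s in test_series:
                    windows = _windows_for(s, arch, horizon)
                    if len(windows) == 0:
                        logger.warning("%s: too short for %s@%d", s.individual_id, arch, horizon)
                        continue
                    result = predict(trained, windows)
                    lm_result = ForecastResult(
                        windows.targets,
                        _last_input(windows),
                        windows.spec.scale,
                        horizon,
                        "LM",
                        s.individual_id,
                    )
                    row = {
                        "individual_id": s.individual_id,
                        "model_name": model_name,
                        "arch": arch,
                        "horizon": horizon,
                        "replica": replica + 1,
                    }
                    row.update(_pair_metrics(result, lm_result))
                    records.append(row)

    report = EvaluationReport.from_records(records)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "report.csv")
        report.summary().to_csv(out / "summary.csv")
        with open(out / "experiment.json", "w") as fh:
            json.dump(_config_dict(config, train_ids), fh, indent=2, default=str)
    return report


def _config_dict(config: ExperimentConfig, train_ids: list[str]) -> dict:
    d = asdict(config)
    d["train_ids"] = train_ids
    return d
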