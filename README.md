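# glyrisk

Short-horizon blood-glucose forecasting on the Kovatchev risk scale.

The package takes continuous glucose monitor (CGM) time series at a nominal
5-minute cadence and provides the full experimental pipeline:

1. **I/O & gridding** (`glyrisk.cgm_io`) — read/write `timestamp,glucose`
   CSVs, snapped onto a regular grid with a validity mask.
2. **Preprocessing** (`glyrisk.preprocessing`) — remove non-positive/missing
   entries, trim out-of-range ends, and fill gaps with floor-mean imputation
   (literal right-to-left recursion by default; a floored linear
   interpolation is available via `--impute-mode linear_floor`).
3. **Risk transform** (`glyrisk.risk_scale`) — glucose → risk variable
   `y = γ((ln x)^α − β)` (α=1.084, β=5.381, γ=1.509), its exact inverse,
   the risk score `10·y²`, its normalized form `y²/10`, and the
   standardized variable `ξ = y/10` used as the network scale.
4. **Windowing** (`glyrisk.windowing`) — supervised pairs for recurrent
   models (10 points spaced one horizon apart) and for the CNN (16
   consecutive points in a 4×4 lattice), at 15/30/60-minute horizons.
5. **Forecasters** (`glyrisk.forecasters`) — RNN / GRU / LSTM / CNN built on
   a small numpy reverse-mode autodiff engine (no deep-learning framework
   required), trained 50 epochs with Adam; MAE loss on the ξ scale, MSE for
   the glucose-scale RNN0 variant; plus the last-measurement (sample-and-
   hold) baseline and the CV-based training-cohort selector.
6. **Evaluation** (`glyrisk.evaluation`) — ξ RMSE, CGM RMSE, risk-weighted
   RMSE, model/LM RMSE ratio, and Clarke error-grid zone analysis.
7. **Synthetic cohorts** (`glyrisk.synthetic_cgm`) — mean-reverting risk-
   space simulator with meal excursions and realistic sensor artifacts, so
   the whole pipeline is testable without any restricted dataset.
8. **Orchestration** (`glyrisk.pipeline`, CLI `glyrisk`) — end-to-end
   simulate → preprocess → train replicas → evaluate experiments from a
   single YAML config.

## CLI

```bash
# generate a synthetic cohort
glyrisk simulate --n 12 --length 2000 --seed 1 --out data/

# clean + impute one series
glyrisk preprocess data/sim-000.csv clean.csv --impute-mode recursive_floor

# train a single model and evaluate it
glyrisk train data/sim-000.csv --arch GRU --horizon 30 --out gru.json
glyrisk evaluate gru.json data/sim-001.csv

# full experiment from YAML
glyrisk run --config experiment.yaml --seed 7 --out results/
```

Example `experiment.yaml`:

```yaml
sim: {n_individuals: 12, series_len: 2000, invalid_frac: 0.03, seed: 1}
horizons: [30]
arches: [RNN, GRU, CNN, CNN10]
replicas: 1
train_k: 10
epochs: 50
```

`run` writes `report.csv` (one row per individual × model × horizon, with
ξ/CGM/weighted RMSEs and the LM ratio), `summary.csv` (cohort quartiles),
and `experiment.json` (provenance: config + training selection).

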