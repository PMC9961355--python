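"""Small forecasting networks, the training loop, and prediction.

Four architecture families are available: vanilla RNN, GRU, LSTM (each a
single recurrent layer over the 10-step strided input followed by a dense
readout to one scalar), and an encoder-like CNN (4x4x1 input, three 2x2
valid convolutions with 4/8/16 channels and tanh, then a 16→1 dense layer
with tanh).  Risk-scale models use tanh outputs and MAE loss; the
glucose-scale variant (RNN0) uses an identity readout and MSE loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ..errors import ConfigError, ContractError, DivergenceError
from ..evaluation import ForecastResult
from ..windowing import WindowSet
from ._autograd import Adam, Tensor

ARCHES = ("RNN0", "RNN", "GRU", "LSTM", "CNN", "CNN10")
RECURRENT_ARCHES = ("RNN0", "RNN", "GRU", "LSTM")

# Optimizer defaults (unstated upstream, declared here). The glucose-scale
# model needs a larger step because its targets live on [39, 400] while
# Adam steps are bounded by ~lr regardless of gradient magnitude.
DEFAULT_LR_XI = 1e-3
DEFAULT_LR_GLUCOSE = 0.1
DEFAULT_BATCH = 64
DEFAULT_EPOCHS = 50
DEFAULT_HIDDEN = 16


@dataclass(frozen=True)
class ModelSpec:
    arch: str
    horizon_minutes: int
    hidden_size: int = DEFAULT_HIDDEN
    seed: int = 0
    epochs: int = DEFAULT_EPOCHS
    lr: float | None = None
    batch_size: int = DEFAULT_BATCH

    def __post_init__(self):
        if self.arch not in ARCHES:
            raise ConfigError(f"unknown architecture {self.arch!r}")

    @property
    def scale(self) -> str:
        return "glucose" if self.arch == "RNN0" else "xi"

    @property
    def activation(self) -> str:
        return "identity" if self.arch == "RNN0" else "tanh"

    @property
    def loss(self) -> str:
        return "MSE" if self.scale == "glucose" else "MAE"

    @property
    def family(self) -> str:
        return "recurrent" if self.arch in RECURRENT_ARCHES else "lattice"

    @property
    def learning_rate(self) -> float:
        if self.lr is not None:
            return self.lr
        return DEFAULT_LR_GLUCOSE if self.scale == "glucose" else DEFAULT_LR_XI


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class _Model:
    """Base: a named-parameter container with a batched forward pass."""

    def __init__(self):
        self.weights: dict[str, Tensor] = {}

    def _param(self, name: str, data: np.ndarray) -> Tensor:
        t = Tensor(data, name=name)
        self.weights[name] = t
        return t

    def parameters(self) -> list[Tensor]:
        return list(self.weights.values())

    def forward(self, x: np.ndarray) -> Tensor:
        raise NotImplementedError

    def predict_values(self, x: np.ndarray) -> np.ndarray:
        return self.forward(np.asarray(x, dtype=float)).data.ravel()


class RNNModel(_Model):
    def __init__(self, hidden: int, activation: str, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        self.activation = activation
        self.Wx = self._param("Wx", _glorot(rng, 1, hidden, (1, hidden)))
        self.Wh = self._param("Wh", _glorot(rng, hidden, hidden, (hidden, hidden)))
        self.b = self._param("b", np.zeros((1, hidden)))
        self.Wo = self._param("Wo", _glorot(rng, hidden, 1, (hidden, 1)))
        self.bo = self._param("bo", np.zeros((1, 1)))

    def forward(self, x: np.ndarray) -> Tensor:
        B, T = x.shape
        h: Tensor | np.ndarray = np.zeros((B, self.hidden))
        for t in range(T):
            xt = Tensor(x[:, t : t + 1])
            h = (xt @ self.Wx + _hmat(h, self.Wh) + self.b).tanh()
        out = h @ self.Wo + self.bo
        return out.tanh() if self.activation == "tanh" else out


class GRUModel(_Model):
    def __init__(self, hidden: int, activation: str, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        self.activation = activation
        for gate in ("z", "r", "h"):
            self._param(f"Wx{gate}", _glorot(rng, 1, hidden, (1, hidden)))
            self._param(f"Wh{gate}", _glorot(rng, hidden, hidden, (hidden, hidden)))
            self._param(f"b{gate}", np.zeros((1, hidden)))
        self._param("Wo", _glorot(rng, hidden, 1, (hidden, 1)))
        self._param("bo", np.zeros((1, 1)))

    def forward(self, x: np.ndarray) -> Tensor:
        w = self.weights
        B, T = x.shape
        h: Tensor | np.ndarray = np.zeros((B, self.hidden))
        for t in range(T):
            xt = Tensor(x[:, t : t + 1])
            z = (xt @ w["Wxz"] + _hmat(h, w["Whz"]) + w["bz"]).sigmoid()
            r = (xt @ w["Wxr"] + _hmat(h, w["Whr"]) + w["br"]).sigmoid()
            rh = r * h if isinstance(h, Tensor) else r * Tensor(h)
            cand = (xt @ w["Wxh"] + rh @ w["Whh"] + w["bh"]).tanh()
            h = _as_t(h) + z * (cand - _as_t(h))
        out = h @ w["Wo"] + w["bo"]
        return out.tanh() if self.activation == "tanh" else out


class LSTMModel(_Model):
    FORGET_BIAS = 1.0

    def __init__(self, hidden: int, activation: str, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        self.activation = activation
        for gate in ("i", "f", "o", "g"):
            self._param(f"Wx_{gate}", _glorot(rng, 1, hidden, (1, hidden)))
            self._param(f"Wh_{gate}", _glorot(rng, hidden, hidden, (hidden, hidden)))
            bias = np.full((1, hidden), self.FORGET_BIAS) if gate == "f" else np.zeros((1, hidden))
            self._param(f"b_{gate}", bias)
        self._param("Wo", _glorot(rng, hidden, 1, (hidden, 1)))
        self._param("bo", np.zeros((1, 1)))

    def forward(self, x: np.ndarray) -> Tensor:
        w = self.weights
        B, T = x.shape
        h: Tensor | np.ndarray = np.zeros((B, self.hidden))
        c: Tensor | np.ndarray = np.zeros((B, self.hidden))
        for t in range(T):
            xt = Tensor(x[:, t : t + 1])
            i = (xt @ w["Wx_i"] + _hmat(h, w["Wh_i"]) + w["b_i"]).sigmoid()
            f = (xt @ w["Wx_f"] + _hmat(h, w["Wh_f"]) + w["b_f"]).sigmoid()
            o = (xt @ w["Wx_o"] + _hmat(h, w["Wh_o"]) + w["b_o"]).sigmoid()
            g = (xt @ w["Wx_g"] + _hmat(h, w["Wh_g"]) + w["b_g"]).tanh()
            c = f * _as_t(c) + i * g
            h = o * c.tanh()
        out = h @ w["Wo"] + w["bo"]
        return out.tanh() if self.activation == "tanh" else out


class CNNModel(_Model):
    """4x4x1 → conv2x2(4) → conv2x2(8) → conv2x2(16) → dense 16→1, all tanh."""

    CHANNELS = (1, 4, 8, 16)

    def __init__(self, activation: str, rng: np.random.Generator):
        super().__init__()
        self.activation = activation
        for layer in range(3):
            cin, cout = self.CHANNELS[layer], self.CHANNELS[layer + 1]
            fan_in, fan_out = 4 * cin, 4 * cout
            self._param(f"K{layer}", _glorot(rng, fan_in, fan_out, (2, 2, cin, cout)))
            self._param(f"c{layer}", np.zeros(cout))
        self._param("Wo", _glorot(rng, 16, 1, (16, 1)))
        self._param("bo", np.zeros((1, 1)))

    def forward(self, x: np.ndarray) -> Tensor:
        B = x.shape[0]
        t = Tensor(np.asarray(x, dtype=float).reshape(B, 4, 4, 1))
        size = 4
        for layer in range(3):
            size -= 1
            t = _conv2x2(t, self.weights[f"K{layer}"], self.weights[f"c{layer}"], size).tanh()
        flat = t.reshape(B, 16)
        out = flat @ self.weights["Wo"] + self.weights["bo"]
        return out.tanh() if self.activation == "tanh" else out


def _conv2x2(x: Tensor, K: Tensor, bias: Tensor, out_size: int) -> Tensor:
    """Valid 2x2 convolution via four shifted matmuls (NHWC layout)."""
    B, _, _, cin = x.shape
    cout = K.shape[3]
    total = None
    for di in range(2):
        for dj in range(2):
            patch = x[:, di : di + out_size, dj : dj + out_size, :]
            term = patch.reshape(B * out_size * out_size, cin) @ K[di, dj]
            total = term if total is None else total + term
    return total.reshape(B, out_size, out_size, cout) + bias


def _as_t(h):
    return h if isinstance(h, Tensor) else Tensor(h)


def _hmat(h, W: Tensor):
    return (h if isinstance(h, Tensor) else Tensor(h)) @ W


def build_model(spec: ModelSpec) -> _Model:
    """Instantiate an untrained network with seed-deterministic weights."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xA11]))
    if spec.arch in ("CNN", "CNN10"):
        return CNNModel(spec.activation, rng)
    cls = {"RNN0": RNNModel, "RNN": RNNModel, "GRU": GRUModel, "LSTM": LSTMModel}[spec.arch]
    return cls(spec.hidden_size, spec.activation, rng)


def parameter_count(model: _Model) -> int:
    return sum(p.data.size for p in model.parameters())


@dataclass
class TrainedModel:
    spec: ModelSpec
    model: _Model
    training_log: list[float] = field(default_factory=list)


def train(model: _Model, windows: WindowSet, spec: ModelSpec) -> TrainedModel:
    """Run ``spec.epochs`` of shuffled mini-batch Adam on the spec's loss."""
    n = len(windows)
    if n == 0:
        raise ContractError("cannot train on an empty WindowSet")
    if windows.spec.scale != spec.scale:
        raise ConfigError(
            f"window scale {windows.spec.scale!r} does not match model scale {spec.scale!r}"
        )
    X = np.asarray(windows.inputs, dtype=float)
    ty = np.asarray(windows.targets, dtype=float).reshape(-1, 1)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x7EA1]))
    opt = Adam(model.parameters(), lr=spec.learning_rate)
    log: list[float] = []
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        total, count = 0.0, 0
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            pred = model.forward(X[idx])
            err = pred - Tensor(ty[idx])
            loss = err.abs().mean() if spec.loss == "MAE" else err.square().mean()
            if not np.isfinite(loss.data):
                raise DivergenceError(epoch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
            count += len(idx)
        log.append(total / count)
    return TrainedModel(spec, model, log)


def predict(trained: TrainedModel, windows: WindowSet) -> ForecastResult:
    """One prediction per window, aligned to targets, on the window scale."""
    preds = trained.model.predict_values(windows.inputs)
    return ForecastResult(
        truth=np.asarray(windows.targets, dtype=float),
        prediction=preds,
        scale=windows.spec.scale,
        horizon_minutes=windows.spec.horizon_minutes,
        model_name=trained.spec.arch,
        individual_id=windows.source_id,
    )


# --- checkpoints ----------------------------------------------------------

def save_checkpoint(trained: TrainedModel, path) -> None:
    blob = {
        "spec": {
            "arch": trained.spec.arch,
            "horizon_minutes": trained.spec.horizon_minutes,
            "hidden_size": trained.spec.hidden_size,
            "seed": trained.spec.seed,
            "epochs": trained.spec.epochs,
            "lr": trained.spec.lr,
            "batch_size": trained.spec.batch_size,
        },
        "training_log": trained.training_log,
        "weights": {k: v.data.tolist() for k, v in trained.model.weights.items()},
    }
    with open(path, "w") as fh:
        json.dump(blob, fh)


def load_checkpoint(path) -> TrainedModel:
    with open(path) as fh:
        blob = json.load(fh)
    spec = ModelSpec(**blob["spec"])
    model = build_model(spec)
    for k, v in blob["weights"].items():
        model.weights[k].data = np.asarray(v, dtype=float)
    return TrainedModel(spec, model, list(blob["training_log"]))
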