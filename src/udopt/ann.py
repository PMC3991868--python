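"""Feed-forward neural-network surrogate trained by Levenberg-Marquardt.

The surrogate is a single-hidden-layer perceptron: inputs and the response
are min-max scaled to [0, 1], the hidden layer uses the log-sigmoid
activation 1/(1 + exp(-net)) and the output neuron is linear.  Training
minimizes the mean squared error on scaled data with a damped Gauss-Newton
(Levenberg-Marquardt) loop using the analytic Jacobian of the per-sample
errors; a step is accepted only if it lowers the MSE, so the recorded
training history is monotone non-increasing.

The architecture search mirrors cut-and-try practice: hidden sizes over a
range, several random restarts each, selection by test-set scaled MSE.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .data import Dataset

__all__ = [
    "Scaler",
    "MLPTopology",
    "MLPParameters",
    "TrainingConfig",
    "MLPSurrogate",
    "fit_scaler",
    "scale",
    "unscale",
    "mse",
    "forward",
    "gradient_jacobian",
    "train_lm",
    "train",
    "select_architecture",
    "NATIVE_ALGORITHM",
    "FALLBACK_ALGORITHMS",
]

NATIVE_ALGORITHM = "levenberg-marquardt"
#: Algorithm names accepted as aliases for the gradient-descent fallback.
FALLBACK_ALGORITHMS = (
    "fletcher-reeves-cg",
    "polak-ribiere-cg",
    "powell-beale-cg",
    "bfgs-quasi-newton",
    "one-step-secant",
    "resilient-gradient-descent",
    "gradient-descent",
    "gradient-descent-momentum",
    "gradient-descent-adaptive",
)


@dataclass(frozen=True)
class Scaler:
    """Columnwise min-max map onto [0, 1] over the fitted range."""

    x_min: np.ndarray
    x_max: np.ndarray

    def transform(self, data: np.ndarray) -> np.ndarray:
        return (np.asarray(data, dtype=float) - self.x_min) / (self.x_max - self.x_min)

    def inverse(self, data: np.ndarray) -> np.ndarray:
        return np.asarray(data, dtype=float) * (self.x_max - self.x_min) + self.x_min


def fit_scaler(data: np.ndarray) -> Scaler:
    data = np.atleast_2d(np.asarray(data, dtype=float))
    x_min, x_max = data.min(axis=0), data.max(axis=0)
    if np.any(x_max <= x_min):
        bad = np.nonzero(x_max <= x_min)[0].tolist()
        raise ValueError(f"constant column(s) {bad}: zero range, cannot min-max scale")
    return Scaler(x_min=x_min, x_max=x_max)


def scale(scaler: Scaler, data: np.ndarray) -> np.ndarray:
    return scaler.transform(data)


def unscale(scaler: Scaler, data: np.ndarray) -> np.ndarray:
    return scaler.inverse(data)


def mse(predicted: np.ndarray, actual: np.ndarray) -> float:
    predicted = np.asarray(predicted, dtype=float).ravel()
    actual = np.asarray(actual, dtype=float).ravel()
    if predicted.size == 0 or actual.size == 0:
        raise ValueError("mse of empty vectors is undefined")
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must have equal length")
    return float(np.mean((predicted - actual) ** 2))


@dataclass(frozen=True)
class MLPTopology:
    n_in: int = 3
    n_hidden: int = 7
    n_out: int = 1

    def __post_init__(self) -> None:
        if min(self.n_in, self.n_hidden, self.n_out) < 1:
            raise ValueError("layer sizes must be positive")

    @property
    def n_params(self) -> int:
        return self.n_hidden * self.n_in + self.n_hidden + self.n_out * self.n_hidden + self.n_out


@dataclass
class MLPParameters:
    w_hidden: np.ndarray  # (n_hidden, n_in)
    b_hidden: np.ndarray  # (n_hidden,)
    w_out: np.ndarray     # (n_out, n_hidden)
    b_out: np.ndarray     # (n_out,)

    def pack(self) -> np.ndarray:
        return np.concatenate([self.w_hidden.ravel(), self.b_hidden,
                               self.w_out.ravel(), self.b_out])

    @classmethod
    def unpack(cls, vec: np.ndarray, topo: MLPTopology) -> "MLPParameters":
        h, i, o = topo.n_hidden, topo.n_in, topo.n_out
        k = 0
        w_hidden = vec[k:k + h * i].reshape(h, i); k += h * i
        b_hidden = vec[k:k + h]; k += h
        w_out = vec[k:k + o * h].reshape(o, h); k += o * h
        b_out = vec[k:k + o]
        return cls(w_hidden.copy(), b_hidden.copy(), w_out.copy(), b_out.copy())


@dataclass
class TrainingConfig:
    algorithm: str = NATIVE_ALGORITHM
    learning_rate: float = 0.01  # used by the gradient-descent fallback
    goal_mse: float = 1e-5       # on scaled data
    max_epochs: int = 1000
    mu_init: float = 1e-3
    mu_inc: float = 10.0
    mu_dec: float = 0.1
    mu_max: float = 1e10
    seed: int = 0
    init: Literal["nguyen-widrow", "uniform"] = "nguyen-widrow"
    restarts: int = 5  # seeds per cell in the architecture search

    def __post_init__(self) -> None:
        if self.goal_mse <= 0:
            raise ValueError("goal_mse must be positive")
        if not (0 < self.mu_dec < 1 < self.mu_inc):
            raise ValueError("need 0 < mu_dec < 1 < mu_inc")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class MLPSurrogate:
    """A trained network with its scalers; callable on raw factor values."""

    topology: MLPTopology
    parameters: MLPParameters
    x_scaler: Scaler
    y_scaler: Scaler
    history: list[float] = field(default_factory=list)
    status: str = "untrained"
    seed: int = 0

    def forward_scaled(self, Xs: np.ndarray) -> np.ndarray:
        Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
        hidden = _sigmoid(Xs @ self.parameters.w_hidden.T + self.parameters.b_hidden)
        return hidden @ self.parameters.w_out.T + self.parameters.b_out

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.topology.n_in:
            raise ValueError(f"expected {self.topology.n_in} inputs, got {X.shape[1]}")
        ys = self.forward_scaled(self.x_scaler.transform(X))
        return self.y_scaler.inverse(ys).ravel()

    __call__ = predict

    def to_json(self, path) -> None:
        p = self.parameters
        payload = {
            "topology": [self.topology.n_in, self.topology.n_hidden, self.topology.n_out],
            "w_hidden": p.w_hidden.tolist(), "b_hidden": p.b_hidden.tolist(),
            "w_out": p.w_out.tolist(), "b_out": p.b_out.tolist(),
            "x_min": self.x_scaler.x_min.tolist(), "x_max": self.x_scaler.x_max.tolist(),
            "y_min": self.y_scaler.x_min.tolist(), "y_max": self.y_scaler.x_max.tolist(),
            "history": self.history, "status": self.status, "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "MLPSurrogate":
        with open(path) as fh:
            d = json.load(fh)
        topo = MLPTopology(*d["topology"])
        params = MLPParameters(
            np.array(d["w_hidden"]), np.array(d["b_hidden"]),
            np.array(d["w_out"]), np.array(d["b_out"]),
        )
        return cls(
            topology=topo, parameters=params,
            x_scaler=Scaler(np.array(d["x_min"]), np.array(d["x_max"])),
            y_scaler=Scaler(np.array(d["y_min"]), np.array(d["y_max"])),
            history=list(d["history"]), status=d["status"], seed=int(d["seed"]),
        )


def forward(model: MLPSurrogate, x: np.ndarray) -> np.ndarray:
    """Raw-unit prediction: scale input, sigmoid hidden layer, linear output, unscale."""
    return model.predict(x)


def gradient_jacobian(params: MLPParameters, topo: MLPTopology, Xs: np.ndarray) -> np.ndarray:
    """Analytic Jacobian d(prediction)/d(parameters) on scaled inputs.

    Rows are samples, columns follow :meth:`MLPParameters.pack` order.  For
    e = prediction - target this equals the error Jacobian used by LM.
    """
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
    n = len(Xs)
    hidden = _sigmoid(Xs @ params.w_hidden.T + params.b_hidden)  # (n, h)
    dh = hidden * (1.0 - hidden)                                  # sigmoid'
    # output neuron: d/dw_out = hidden, d/db_out = 1
    # hidden weights: d/dW1[h,i] = w_out[h] * dh[:,h] * Xs[:,i]
    back = params.w_out.ravel() * dh                              # (n, h)
    j_w_hidden = (back[:, :, None] * Xs[:, None, :]).reshape(n, -1)
    j_b_hidden = back
    j_w_out = hidden
    j_b_out = np.ones((n, 1))
    return np.hstack([j_w_hidden, j_b_hidden, j_w_out, j_b_out])


def _init_params(topo: MLPTopology, rng: np.random.Generator,
                 method: str) -> MLPParameters:
    h, i, o = topo.n_hidden, topo.n_in, topo.n_out
    if method == "uniform":
        vec = rng.uniform(-0.5, 0.5, topo.n_params)
        return MLPParameters.unpack(vec, topo)
    # Nguyen-Widrow-style: random directions, norms set to 0.7 h^(1/i),
    # biases spread so the active regions tile the [0,1] input cube.
    w = rng.uniform(-1.0, 1.0, (h, i))
    norms = np.linalg.norm(w, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    beta = 0.7 * h ** (1.0 / i)
    w = beta * w / norms
    b = beta * np.linspace(-1.0, 1.0, h) * np.sign(w[:, 0] + (w[:, 0] == 0))
    w_out = rng.uniform(-0.5, 0.5, (o, h))
    b_out = rng.uniform(-0.5, 0.5, o)
    return MLPParameters(w, b, w_out, b_out)


def _prepare(train: Dataset):
    x_scaler = fit_scaler(train.X)
    y_scaler = fit_scaler(train.y[:, None])
    Xs = x_scaler.transform(train.X)
    ys = y_scaler.transform(train.y[:, None]).ravel()
    return x_scaler, y_scaler, Xs, ys


def train_lm(topology: MLPTopology, train: Dataset, config: TrainingConfig) -> MLPSurrogate:
    """Levenberg-Marquardt training on min-max scaled data.

    Each epoch solves (J'J + mu I) dw = -J'e; the step is accepted only if it
    lowers the scaled MSE (mu shrinks), otherwise mu grows and the step is
    retried.  Stops at goal_mse, max_epochs, or mu overflow (best-so-far
    parameters are kept and the status flags the overflow).
    """
    if len(train) == 0:
        raise ValueError("training dataset is empty")
    x_scaler, y_scaler, Xs, ys = _prepare(train)
    rng = np.random.default_rng(config.seed)
    params = _init_params(topology, rng, config.init)
    vec = params.pack()
    model = MLPSurrogate(topology, params, x_scaler, y_scaler, seed=config.seed)
    err = model.forward_scaled(Xs).ravel() - ys
    current = float(np.mean(err**2))
    history = [current]
    mu = config.mu_init
    status = "max_epochs"
    eye = np.eye(topology.n_params)
    for _ in range(config.max_epochs):
        if current <= config.goal_mse:
            status = "goal_reached"
            break
        J = gradient_jacobian(model.parameters, topology, Xs)
        g = J.T @ err
        JtJ = J.T @ J
        accepted = False
        while mu <= config.mu_max:
            try:
                step = np.linalg.solve(JtJ + mu * eye, -g)
            except np.linalg.LinAlgError:
                mu *= config.mu_inc
                continue
            cand = MLPParameters.unpack(vec + step, topology)
            trial_model = MLPSurrogate(topology, cand, x_scaler, y_scaler)
            trial_err = trial_model.forward_scaled(Xs).ravel() - ys
            trial = float(np.mean(trial_err**2))
            if trial < current:
                vec = vec + step
                model.parameters = cand
                err, current = trial_err, trial
                mu = max(mu * config.mu_dec, 1e-20)
                accepted = True
                history.append(current)
                break
            mu *= config.mu_inc
        if not accepted:
            status = "mu_overflow"
            break
    else:
        if current <= config.goal_mse:
            status = "goal_reached"
    model.history = history
    model.status = status
    return model


def _train_gd(topology: MLPTopology, train: Dataset, config: TrainingConfig) -> MLPSurrogate:
    """Plain batch gradient descent; fallback for the non-native algorithm names."""
    x_scaler, y_scaler, Xs, ys = _prepare(train)
    rng = np.random.default_rng(config.seed)
    model = MLPSurrogate(topology, _init_params(topology, rng, config.init),
                         x_scaler, y_scaler, seed=config.seed)
    vec = model.parameters.pack()
    err = model.forward_scaled(Xs).ravel() - ys
    current = float(np.mean(err**2))
    history = [current]
    for _ in range(config.max_epochs):
        if current <= config.goal_mse:
            break
        J = gradient_jacobian(model.parameters, topology, Xs)
        grad = 2.0 * J.T @ err / len(ys)
        cand_vec = vec - config.learning_rate * grad
        cand = MLPParameters.unpack(cand_vec, topology)
        trial_model = MLPSurrogate(topology, cand, x_scaler, y_scaler)
        trial_err = trial_model.forward_scaled(Xs).ravel() - ys
        trial = float(np.mean(trial_err**2))
        if trial >= current:  # keep the history monotone; plain GD stalls here
            break
        vec, err, current = cand_vec, trial_err, trial
        model.parameters = cand
        history.append(current)
    model.history = history
    model.status = "gd_fallback"
    return model


def train(topology: MLPTopology, train_data: Dataset, config: TrainingConfig) -> MLPSurrogate:
    """Dispatch on config.algorithm: native LM or the gradient-descent fallback."""
    name = config.algorithm.lower().replace("_", "-").replace(" ", "-")
    if name in (NATIVE_ALGORITHM, "lm", "levenberg-marquardt-backpropagation"):
        return train_lm(topology, train_data, config)
    if name in FALLBACK_ALGORITHMS:
        return _train_gd(topology, train_data, config)
    raise NotImplementedError(f"training algorithm {config.algorithm!r} is not implemented")


def select_architecture(
    train_data: Dataset,
    test_data: Dataset,
    hidden_range: Sequence[int] = range(3, 13),
    algorithms: Sequence[str] = (NATIVE_ALGORITHM,),
    config: TrainingConfig | None = None,
) -> tuple[MLPSurrogate, pd.DataFrame]:
    """Cut-and-try search over hidden sizes and algorithms.

    Each (hidden size, algorithm) cell is trained from ``config.restarts``
    seeds; the candidate with minimum test-set scaled MSE wins, ties breaking
    toward fewer hidden neurons and then the lower seed.  Returns the winner
    and the full selection report.
    """
    if len(train_data) == 0 or len(test_data) == 0:
        raise ValueError("train and test datasets must be nonempty")
    config = config or TrainingConfig()
    rows = []
    best = None  # (test_mse, n_hidden, seed, model)
    for n_hidden in hidden_range:
        for algo in algorithms:
            for r in range(config.restarts):
                seed = (config.seed + 10007 * r) % (2**31 - 1)
                cfg = replace(config, algorithm=algo, seed=seed)
                try:
                    model = train(MLPTopology(train_data.space.n_factors, n_hidden, 1),
                                  train_data, cfg)
                except NotImplementedError as exc:
                    rows.append({"n_hidden": n_hidden, "algorithm": algo, "seed": seed,
                                 "train_mse_scaled": math.nan, "test_mse_scaled": math.nan,
                                 "status": f"skipped: {exc}"})
                    continue
                ys_test = model.y_scaler.transform(test_data.y[:, None]).ravel()
                pred_test = model.forward_scaled(model.x_scaler.transform(test_data.X)).ravel()
                test_mse = mse(pred_test, ys_test)
                rows.append({"n_hidden": n_hidden, "algorithm": algo, "seed": seed,
                             "train_mse_scaled": model.history[-1],
                             "test_mse_scaled": test_mse, "status": model.status})
                key = (test_mse, n_hidden, seed)
                if math.isfinite(test_mse) and (best is None or key < best[:3]):
                    best = (test_mse, n_hidden, seed, model)
    report = pd.DataFrame(rows)
    if best is None:
        raise RuntimeError(f"all architecture cells failed to train:\n{report}")
    return best[3], report
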