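"""Feed-forward backpropagation network mapping CARs (66) to voxels (396).

The mapping network is a classic three-layer perceptron: 66 logistic hidden
units between a 66-unit input (one CAR vector) and a 396-unit logistic
output (one SynthWord pattern). Training is online (per-pattern) gradient
descent on half the squared error, with heavy-ball momentum (alpha = 0.3)
and a learning rate starting at eta = 0.3 that decays multiplicatively by
0.001 per epoch down to a floor of 1e-6. Weights and biases initialize
i.i.d. uniform on [-0.5, 0.5]. Voxel targets scaled to [0.2, 0.8] keep the
logistic outputs away from saturation.

The network is written in-package (rather than wrapping a generic MLP)
because the interpretation stage needs exact analytic gradients with
respect to the *inputs* under frozen weights, which generic regressors do
not expose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

N_INPUT = 66
N_HIDDEN = 66
N_OUTPUT = 396
INIT_LO = -0.5
INIT_HI = 0.5


@dataclass
class NetworkParams:
    """Weights and biases of the two affine layers."""

    w_in: np.ndarray   # (n_input, n_hidden)
    b_hidden: np.ndarray  # (n_hidden,)
    w_out: np.ndarray  # (n_hidden, n_output)
    b_out: np.ndarray  # (n_output,)

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.w_in.copy(), self.b_hidden.copy(),
            self.w_out.copy(), self.b_out.copy(),
        )

    @property
    def shapes(self):
        return (self.w_in.shape, self.b_hidden.shape,
                self.w_out.shape, self.b_out.shape)

    def allclose(self, other: "NetworkParams", atol: float = 0.0) -> bool:
        return (
            np.array_equal(self.w_in, other.w_in)
            and np.array_equal(self.b_hidden, other.b_hidden)
            and np.array_equal(self.w_out, other.w_out)
            and np.array_equal(self.b_out, other.b_out)
        ) if atol == 0.0 else all(
            np.allclose(a, b, atol=atol)
            for a, b in (
                (self.w_in, other.w_in), (self.b_hidden, other.b_hidden),
                (self.w_out, other.w_out), (self.b_out, other.b_out),
            )
        )


@dataclass
class TrainingConfig:
    eta_init: float = 0.3
    eta_floor: float = 1e-6
    eta_decay: float = 0.001
    momentum: float = 0.3
    max_epochs: int = 10_000
    target_mse: float = 1e-3
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self):
        if not 0 < self.eta_floor <= self.eta_init:
            raise ValueError("need 0 < eta_floor <= eta_init")
        if not 0 <= self.momentum < 1:
            raise ValueError("need 0 <= momentum < 1")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")


def init_network(
    seed: int,
    n_input: int = N_INPUT,
    n_hidden: int = N_HIDDEN,
    n_output: int = N_OUTPUT,
) -> NetworkParams:
    """Uniform [-0.5, 0.5] initialization of all weights and biases."""
    rng = np.random.default_rng(seed)
    return NetworkParams(
        w_in=rng.uniform(INIT_LO, INIT_HI, size=(n_input, n_hidden)),
        b_hidden=rng.uniform(INIT_LO, INIT_HI, size=n_hidden),
        w_out=rng.uniform(INIT_LO, INIT_HI, size=(n_hidden, n_output)),
        b_out=rng.uniform(INIT_LO, INIT_HI, size=n_output),
    )


def forward(
    params: NetworkParams,
    x: np.ndarray,
    output_activation: str = "logistic",
) -> tuple[np.ndarray, np.ndarray]:
    """Hidden and output activations for one CAR vector or a batch.

    ``output_activation`` is ``"logistic"`` (default) or ``"linear"``; the
    linear variant exists for analytically solvable test harnesses.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite network input")
    hidden = expit(x @ params.w_in + params.b_hidden)
    pre = hidden @ params.w_out + params.b_out
    if output_activation == "logistic":
        output = expit(pre)
    elif output_activation == "linear":
        output = pre
    else:
        raise ValueError(f"unknown output activation {output_activation!r}")
    return hidden, output


def pattern_gradients(
    params: NetworkParams,
    x: np.ndarray,
    y: np.ndarray,
    output_activation: str = "logistic",
):
    """Analytic gradients of L = 0.5 * sum((output - y)^2) for one pattern.

    Returns ``(grads, input_grad, output, loss)`` with grads a NetworkParams
    of like-shaped gradient arrays.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    hidden, output = forward(params, x, output_activation)
    err = output - y
    loss = 0.5 * float(err @ err)
    if output_activation == "logistic":
        delta_out = err * output * (1.0 - output)
    else:
        delta_out = err
    g_w_out = np.outer(hidden, delta_out)
    g_b_out = delta_out
    delta_hidden = (delta_out @ params.w_out.T) * hidden * (1.0 - hidden)
    g_w_in = np.outer(x, delta_hidden)
    g_b_hidden = delta_hidden
    input_grad = delta_hidden @ params.w_in.T
    grads = NetworkParams(g_w_in, g_b_hidden, g_w_out, g_b_out)
    return grads, input_grad, output, loss


def train(
    X: np.ndarray,
    Y: np.ndarray,
    config: TrainingConfig,
    params: NetworkParams | None = None,
    output_activation: str = "logistic",
) -> tuple[NetworkParams, np.ndarray]:
    """Online backprop with momentum and per-epoch learning-rate decay.

    Patterns are presented in a freshly shuffled order every epoch (seeded).
    The per-epoch curve records the mean per-pattern MSE (mean over output
    units) measured on the forward pass before each update. Training stops
    at ``target_mse`` or ``max_epochs``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0] or X.shape[0] < 1:
        raise ValueError("X and Y must be 2-D with matching, nonzero row counts")
    rng = np.random.default_rng(config.seed)
    if params is None:
        params = init_network(
            config.seed, n_input=X.shape[1], n_output=Y.shape[1]
        )
    else:
        params = params.copy()
    n, n_out = Y.shape
    vel = NetworkParams(
        np.zeros_like(params.w_in), np.zeros_like(params.b_hidden),
        np.zeros_like(params.w_out), np.zeros_like(params.b_out),
    )
    alpha = config.momentum
    curve = []
    for epoch in range(config.max_epochs):
        eta = max(config.eta_floor,
                  config.eta_init * (1.0 - config.eta_decay) ** epoch)
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        sse = 0.0
        for i in order:
            grads, _, _, loss = pattern_gradients(
                params, X[i], Y[i], output_activation
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch}"
                )
            sse += loss
            vel.w_in = alpha * vel.w_in - eta * grads.w_in
            vel.b_hidden = alpha * vel.b_hidden - eta * grads.b_hidden
            vel.w_out = alpha * vel.w_out - eta * grads.w_out
            vel.b_out = alpha * vel.b_out - eta * grads.b_out
            params.w_in += vel.w_in
            params.b_hidden += vel.b_hidden
            params.w_out += vel.w_out
            params.b_out += vel.b_out
        epoch_mse = 2.0 * sse / (n * n_out)  # undo the 1/2 loss factor
        curve.append(epoch_mse)
        if epoch_mse <= config.target_mse:
            break
    return params, np.asarray(curve)


def gradient_check(
    params: NetworkParams,
    x: np.ndarray,
    y: np.ndarray,
    step: float = 1e-5,
    output_activation: str = "logistic",
    rng: np.random.Generator | None = None,
    max_entries_per_array: int | None = None,
) -> float:
    """Max |analytic - central finite difference| over weights AND inputs.

    ``max_entries_per_array`` optionally subsamples coordinates (seeded via
    ``rng``) to keep the check fast on the full-size architecture.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def loss_fn(p: NetworkParams, xv: np.ndarray) -> float:
        _, out = forward(p, xv, output_activation)
        e = out - y
        return 0.5 * float(e @ e)

    grads, input_grad, _, _ = pattern_gradients(params, x, y, output_activation)
    worst = 0.0
    work = params.copy()
    arrays = [
        (work.w_in, grads.w_in), (work.b_hidden, grads.b_hidden),
        (work.w_out, grads.w_out), (work.b_out, grads.b_out),
    ]
    for arr, g in arrays:
        flat, gflat = arr.ravel(), g.ravel()
        idx = np.arange(flat.size)
        if max_entries_per_array is not None and flat.size > max_entries_per_array:
            r = rng if rng is not None else np.random.default_rng(0)
            idx = r.choice(flat.size, size=max_entries_per_array, replace=False)
        for j in idx:
            orig = flat[j]
            flat[j] = orig + step
            up = loss_fn(work, x)
            flat[j] = orig - step
            down = loss_fn(work, x)
            flat[j] = orig
            worst = max(worst, abs((up - down) / (2 * step) - gflat[j]))
    xv = x.copy()
    for j in range(xv.size):
        orig = xv[j]
        xv[j] = orig + step
        up = loss_fn(params, xv)
        xv[j] = orig - step
        down = loss_fn(params, xv)
        xv[j] = orig
        worst = max(worst, abs((up - down) / (2 * step) - input_grad[j]))
    return worst


class CerebraNetwork(BaseEstimator, RegressorMixin):
    """sklearn-style estimator around the CAR-to-voxel backprop network.

    Parameters mirror :class:`TrainingConfig`; fitted state lives in
    ``params_`` (weights/biases) and ``learning_curve_`` (per-epoch MSE).
    """

    def __init__(
        self,
        eta_init: float = 0.3,
        eta_floor: float = 1e-6,
        eta_decay: float = 0.001,
        momentum: float = 0.3,
        max_epochs: int = 10_000,
        target_mse: float = 1e-3,
        output_activation: str = "logistic",
        shuffle: bool = True,
        random_state: int = 0,
    ):
        self.eta_init = eta_init
        self.eta_floor = eta_floor
        self.eta_decay = eta_decay
        self.momentum = momentum
        self.max_epochs = max_epochs
        self.target_mse = target_mse
        self.output_activation = output_activation
        self.shuffle = shuffle
        self.random_state = random_state

    def _config(self) -> TrainingConfig:
        return TrainingConfig(
            eta_init=self.eta_init, eta_floor=self.eta_floor,
            eta_decay=self.eta_decay, momentum=self.momentum,
            max_epochs=self.max_epochs, target_mse=self.target_mse,
            seed=self.random_state, shuffle=self.shuffle,
        )

    def fit(self, X, y):
        X = check_array(X)
        y = check_array(y)
        self.params_, self.learning_curve_ = train(
            X, y, self._config(), output_activation=self.output_activation
        )
        self.n_features_in_ = X.shape[1]
        self.n_outputs_ = y.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "params_")
        X = check_array(X)
        _, out = forward(self.params_, X, self.output_activation)
        return out


def save_checkpoint(path, params: NetworkParams, config: TrainingConfig,
                    curve: np.ndarray) -> None:
    """Round-trippable model container (npz)."""
    np.savez(
        path,
        w_in=params.w_in, b_hidden=params.b_hidden,
        w_out=params.w_out, b_out=params.b_out,
        curve=np.asarray(curve),
        config=np.array(
            [config.eta_init, config.eta_floor, config.eta_decay,
             config.momentum, config.max_epochs, config.target_mse,
             config.seed, float(config.shuffle)]
        ),
    )


def load_checkpoint(path) -> tuple[NetworkParams, TrainingConfig, np.ndarray]:
    data = np.load(path)
    params = NetworkParams(
        data["w_in"], data["b_hidden"], data["w_out"], data["b_out"]
    )
    c = data["config"]
    config = TrainingConfig(
        eta_init=float(c[0]), eta_floor=float(c[1]), eta_decay=float(c[2]),
        momentum=float(c[3]), max_epochs=int(c[4]), target_mse=float(c[5]),
        seed=int(c[6]), shuffle=bool(c[7]),
    )
    return params, config, data["curve"]
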