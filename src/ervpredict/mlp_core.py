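"""The 4-3-1 multilayer perceptron and its back-propagation trainer.

Architecture: 4 input nodes, one hidden layer of 3 neurons, a single output
neuron; logistic sigmoid activation on both the hidden and output layers, so
the output lies in (0, 1) and reads as a likelihood of transcriptional
disruption. The loss is the sum of squared errors E = sum_i (y_i - t_i)^2 / 2,
minimized by plain full-batch gradient descent. Each network has exactly
3*4 + 3 + 3 + 1 = 19 parameters.

Internally, training is vectorized over a *stack* of independently
initialized networks sharing one training set; gradient descent steps for
different members never interact, so stacked training is equivalent to
training each member alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

N_INPUT, N_HIDDEN = 4, 3
N_PARAMS = N_HIDDEN * N_INPUT + N_HIDDEN + N_HIDDEN + 1  # 19


@dataclass
class MlpModel:
    hidden_weights: np.ndarray  # (3, 4)
    hidden_bias: np.ndarray  # (3,)
    output_weights: np.ndarray  # (3,)
    output_bias: float

    def pack(self) -> np.ndarray:
        """Flatten to the canonical 19-vector: W_hid (row-major), b_hid, w_out, b_out."""
        return np.concatenate(
            [
                np.ravel(self.hidden_weights),
                np.asarray(self.hidden_bias, dtype=float),
                np.asarray(self.output_weights, dtype=float),
                [self.output_bias],
            ]
        )

    @classmethod
    def unpack(cls, theta: np.ndarray) -> "MlpModel":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (N_PARAMS,):
            raise ValueError(f"expected {N_PARAMS} parameters, got shape {theta.shape}")
        return cls(
            hidden_weights=theta[:12].reshape(N_HIDDEN, N_INPUT).copy(),
            hidden_bias=theta[12:15].copy(),
            output_weights=theta[15:18].copy(),
            output_bias=float(theta[18]),
        )


# Resilient-propagation constants (iRprop- variant): per-parameter step sizes
# grow by ETA_PLUS while the gradient keeps its sign and shrink by ETA_MINUS on
# a sign flip, bounded to [DELTA_MIN, DELTA_MAX]; DELTA0 is the initial step.
RPROP_DELTA0 = 0.1
RPROP_ETA_PLUS = 1.2
RPROP_ETA_MINUS = 0.5
RPROP_DELTA_MIN = 1e-6
RPROP_DELTA_MAX = 50.0


@dataclass(frozen=True)
class TrainConfig:
    """Back-propagation hyperparameters.

    ``stop_threshold`` bounds the largest absolute component of the loss
    gradient: training stops once every partial derivative is smaller in
    magnitude, or after ``max_epochs`` full-batch steps.

    ``algorithm`` selects the weight-update rule: resilient propagation
    ("rprop", the default — scale-free per-parameter steps, converges in
    hundreds rather than tens of thousands of epochs on this architecture)
    or plain gradient descent ("gd") with the fixed ``learning_rate``.
    """

    learning_rate: float = 0.05
    max_epochs: int = 5_000
    stop_threshold: float = 0.001
    init_range: float = 0.5
    seed: int = 0
    algorithm: str = "rprop"

    def __post_init__(self):
        if self.learning_rate <= 0 or self.max_epochs <= 0 or self.stop_threshold <= 0 or self.init_range <= 0:
            raise ValueError("learning_rate, max_epochs, stop_threshold and init_range must all be positive")
        if self.algorithm not in ("rprop", "gd"):
            raise ValueError(f"algorithm must be 'rprop' or 'gd', got {self.algorithm!r}")


@dataclass
class TrainResult:
    model: "MlpModel"
    final_error: float
    converged: bool
    epochs: int


def sigmoid(z):
    """Logistic 1/(1+exp(-z)), stable on both tails."""
    from scipy.special import expit

    return expit(np.asarray(z, dtype=float))


def init_model(seed: int, init_range: float = 0.5) -> MlpModel:
    """Draw all 19 parameters i.i.d. uniform on (-init_range, +init_range)."""
    if init_range <= 0:
        raise ValueError("init_range must be positive")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(-init_range, init_range, size=N_PARAMS)
    return MlpModel.unpack(theta)


# ---------------------------------------------------------------------------
# Stacked representation: R independent networks as arrays with a leading
# member axis. stack_params = (W1 (R,3,4), b1 (R,3), w2 (R,3), b2 (R,)).
# ---------------------------------------------------------------------------


def init_stack(seeds: Sequence[int], init_range: float = 0.5):
    """Initialize one network per seed; member r is exactly init_model(seeds[r])."""
    thetas = np.stack([init_model(int(s), init_range).pack() for s in seeds])
    return _unpack_stack(thetas)


def _unpack_stack(thetas: np.ndarray):
    R = thetas.shape[0]
    return (
        thetas[:, :12].reshape(R, N_HIDDEN, N_INPUT).copy(),
        thetas[:, 12:15].copy(),
        thetas[:, 15:18].copy(),
        thetas[:, 18].copy(),
    )


def pack_stack(stack) -> np.ndarray:
    W1, b1, w2, b2 = stack
    R = W1.shape[0]
    return np.concatenate([W1.reshape(R, 12), b1, w2, b2[:, None]], axis=1)


def stack_from_models(models: Sequence[MlpModel]):
    return _unpack_stack(np.stack([m.pack() for m in models]))


def stack_member(stack, r: int) -> MlpModel:
    W1, b1, w2, b2 = stack
    return MlpModel(W1[r].copy(), b1[r].copy(), w2[r].copy(), float(b2[r]))


def _forward_hidden(stack, Xt: np.ndarray):
    """Hidden activations H (R, 3, n) and outputs Y (R, n) for Xt = X.T (4, n)."""
    from scipy.special import expit

    W1, b1, w2, b2 = stack
    R = W1.shape[0]
    n = Xt.shape[1]
    Z1 = (np.asarray(W1).reshape(R * N_HIDDEN, N_INPUT) @ Xt).reshape(R, N_HIDDEN, n)
    Z1 += np.asarray(b1)[:, :, None]
    H = expit(Z1)
    Z2 = np.matmul(np.asarray(w2)[:, None, :], H)[:, 0, :] + np.asarray(b2)[:, None]
    return H, expit(Z2)


def forward_stack(stack, X: np.ndarray) -> np.ndarray:
    """Outputs of every stacked network on every row of X; shape (R, n)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    _, Y = _forward_hidden(stack, np.ascontiguousarray(X.T))
    return Y


def _grad_stack(stack, X, t):
    """SSE loss over one stack: flat gradient (R, 19) and per-member error (R,)."""
    thetas = pack_stack(stack)[None]
    X = np.atleast_2d(np.asarray(X, dtype=float))
    G = np.empty_like(thetas)
    err = _grad_grouped(thetas, X[None], np.ascontiguousarray(X.T)[None], np.asarray(t, dtype=float)[None], G)
    return G[0], err[0]


def _grad_grouped(thetas: np.ndarray, X: np.ndarray, Xt: np.ndarray, t: np.ndarray, G: np.ndarray):
    """Grouped SSE gradient: S groups of R members, each group with its own data.

    thetas (S, R, 19), X (S, n, 4), Xt (S, 4, n), t (S, n); writes the flat
    gradient into G (S, R, 19) and returns the per-member error (S, R).
    """
    from scipy.special import expit

    S, R, _ = thetas.shape
    n = t.shape[1]
    W1 = thetas[:, :, :12].reshape(S, R * N_HIDDEN, N_INPUT)
    b1 = thetas[:, :, 12:15]
    w2 = thetas[:, :, 15:18]
    b2 = thetas[:, :, 18]
    Z1 = np.matmul(W1, Xt).reshape(S, R, N_HIDDEN, n)
    Z1 += b1[:, :, :, None]
    H = expit(Z1)
    Y = expit(np.matmul(w2[:, :, None, :], H)[:, :, 0, :] + b2[:, :, None])  # (S, R, n)
    resid = Y - t[:, None, :]
    err = 0.5 * np.einsum("srn,srn->sr", resid, resid)
    d2 = resid * Y
    d2 *= 1.0 - Y
    G[:, :, 15:18] = np.matmul(H, d2[:, :, :, None])[:, :, :, 0]
    G[:, :, 18] = d2.sum(axis=2)
    d1 = H * (1.0 - H)
    d1 *= d2[:, :, None, :]
    d1 *= w2[:, :, :, None]  # (S, R, 3, n)
    G[:, :, :12] = np.matmul(d1.reshape(S, R * N_HIDDEN, n), X).reshape(S, R, 12)
    G[:, :, 12:15] = d1.sum(axis=3)
    return err


def train_grouped(thetas: np.ndarray, X: np.ndarray, t: np.ndarray, cfg: TrainConfig):
    """Train S groups of R networks, each group full-batch on its own data.

    thetas (S, R, 19), X (S, n, 4), t (S, n). Members never interact: the
    result is identical to training each member alone. A member freezes once
    the largest absolute component of its loss gradient drops below
    ``cfg.stop_threshold``; the loop ends when all members are frozen or
    ``max_epochs`` is reached. Returns (thetas, err, converged, epochs_run)
    with err and converged shaped (S, R).

    Raises FloatingPointError if any member's error becomes non-finite.
    """
    thetas = np.array(thetas, dtype=float)
    X = np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=float)
    if thetas.ndim != 3 or X.ndim != 3 or t.ndim != 2:
        raise ValueError("train_grouped expects thetas (S,R,19), X (S,n,4), t (S,n)")
    if X.shape[2] != N_INPUT or X.shape[1] == 0:
        raise ValueError(f"each group needs a non-empty (n, {N_INPUT}) design")
    if np.any(~np.isfinite(t)):
        raise ValueError("every training record needs a finite target")
    S, R, _ = thetas.shape
    Xt = np.ascontiguousarray(np.swapaxes(X, 1, 2))
    G = np.empty_like(thetas)
    active = np.ones((S, R), dtype=bool)
    rprop = cfg.algorithm == "rprop"
    if rprop:
        delta = np.full_like(thetas, RPROP_DELTA0)
        g_prev = np.zeros_like(thetas)
    epochs = 0
    err = np.empty((S, R))
    for epoch in range(cfg.max_epochs):
        err = _grad_grouped(thetas, X, Xt, t, G)
        if not np.all(np.isfinite(err)):
            bad = np.argwhere(~np.isfinite(err))
            raise FloatingPointError(f"non-finite training error for member(s) {bad.tolist()} at epoch {epoch}")
        active &= np.abs(G).max(axis=2) >= cfg.stop_threshold
        if not active.any():
            epochs = epoch
            break
        if rprop:
            sign_change = g_prev * G
            delta *= np.where(sign_change > 0, RPROP_ETA_PLUS, np.where(sign_change < 0, RPROP_ETA_MINUS, 1.0))
            np.clip(delta, RPROP_DELTA_MIN, RPROP_DELTA_MAX, out=delta)
            G[sign_change < 0] = 0.0  # iRprop-: no step and no sign memory after a flip
            thetas -= np.sign(G) * delta * active[:, :, None]
            g_prev, G = G, g_prev
        else:
            thetas -= cfg.learning_rate * G * active[:, :, None]
        epochs = epoch + 1
    return thetas, err, ~active, epochs


def train_stack(stack, X: np.ndarray, t: np.ndarray, cfg: TrainConfig):
    """Train every member of the stack on (X, t); single-group wrapper.

    Returns (stack, final_errors, converged_mask, epochs_run).
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_INPUT:
        raise ValueError(f"X must have shape (n, {N_INPUT})")
    if len(t) != len(X) or len(X) == 0:
        raise ValueError("dataset must be non-empty with one target per row")
    thetas, err, conv, epochs = train_grouped(pack_stack(stack)[None], X[None], t[None], cfg)
    return _unpack_stack(thetas[0]), err[0], conv[0], epochs


# ---------------------------------------------------------------------------
# Single-model interface.
# ---------------------------------------------------------------------------


def _as_xy(dataset) -> tuple[np.ndarray, np.ndarray]:
    """Accept a (X, t) pair or a sequence of FeatureVector with targets."""
    if isinstance(dataset, tuple) and len(dataset) == 2:
        return np.asarray(dataset[0], dtype=float), np.asarray(dataset[1], dtype=float)
    X = np.array([v.as_array() for v in dataset], dtype=float)
    t = np.array([np.nan if v.target is None else v.target for v in dataset], dtype=float)
    return X, t


def forward(model: MlpModel, x) -> Union[float, np.ndarray]:
    """Predicted likelihood in (0, 1); accepts a FeatureVector, a 4-vector, or (n, 4)."""
    if hasattr(x, "as_array"):
        x = x.as_array()
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    out = forward_stack(stack_from_models([model]), np.atleast_2d(x))[0]
    return float(out[0]) if single else out


def gradient(model: MlpModel, dataset) -> np.ndarray:
    """Analytic gradient of the SSE loss as the canonical 19-vector."""
    X, t = _as_xy(dataset)
    G, _ = _grad_stack(stack_from_models([model]), X, t)
    return G[0]


def loss(model: MlpModel, dataset) -> float:
    X, t = _as_xy(dataset)
    _, err = _grad_stack(stack_from_models([model]), X, t)
    return float(err[0])


def train(model: MlpModel, dataset, cfg: TrainConfig) -> TrainResult:
    """Train one network; a thin wrapper over the stacked trainer."""
    X, t = _as_xy(dataset)
    stack, err, converged, epochs = train_stack(stack_from_models([model]), X, t, cfg)
    return TrainResult(model=stack_member(stack, 0), final_error=float(err[0]), converged=bool(converged[0]), epochs=epochs)
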