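"""Stack LSTM force decoder, implemented from first principles in NumPy.

The recurrent cell follows the bias-free formulation used for this decoder
rather than the textbook LSTM: with ``z = [y<t-1>, x<t>]``,

    C~  = tanh(Wc z)
    G_u = sigmoid(Wu z),  G_f = sigmoid(Wf z),  G_o = sigmoid(Wo z)
    C<t> = G_u * C~ + G_f * C<t-1>
    y<t> = G_o * C<t>

— no bias terms and no tanh on the cell output.  A ``variant="standard"``
flag restores the textbook form (biases on, ``y = G_o * tanh(C)``) for
comparison.

The network stacks two such layers (30 then 15 units) over the 96
band-power features and reads out each time step through a single fully
connected neuron with ReLU activation, so predicted force is non-negative
by construction — the zero floor a force sensor imposes.  Training
minimizes mean absolute error (plus an L2 penalty on the readout weights)
with Adam (beta1 = 0.9, beta2 = 0.999), batching whole trials, with
variational (per-sequence) dropout masks on the forward and recurrent
paths of both layers.  Gradients are exact backpropagation through time,
derived by hand for this cell; a finite-difference check lives in the test
suite.

Hyper-parameters are drawn from a fixed discrete grid (dropouts, readout
L2, learning rate, batch size, epochs) and selected by seeded random
search scored on a held-out 20% validation split of the training trials.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "LSTMLayerWeights",
    "NetworkParams",
    "CellState",
    "HyperParams",
    "HYPERPARAM_GRID",
    "ForceLSTM",
    "LSTMResults",
    "lstm_cell_forward",
    "lstm_layer_forward",
    "network_forward",
    "train_network",
    "tune_hyperparameters",
    "save_params",
    "load_params",
]

#: Discrete search space for every tunable of the network.
HYPERPARAM_GRID: dict[str, tuple] = {
    "dropout_l1_forward": (0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    "dropout_l1_recurrent": (0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    "dropout_l2_forward": (0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    "dropout_l2_recurrent": (0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    "l2_lambda": (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    "learning_rate": (0.001, 0.0015, 0.002, 0.0025, 0.003),
    "batch_size": (5, 10, 15, 20, 30),
    "n_epochs": (30, 50, 70, 100, 120),
}


@dataclass
class HyperParams:
    """One point of the hyper-parameter grid."""

    dropout_l1_forward: float = 0.1
    dropout_l1_recurrent: float = 0.1
    dropout_l2_forward: float = 0.1
    dropout_l2_recurrent: float = 0.1
    l2_lambda: float = 0.0
    learning_rate: float = 0.002
    batch_size: int = 10
    n_epochs: int = 70

    def to_dict(self) -> dict:
        return asdict(self)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class LSTMLayerWeights:
    """Gate weight matrices of one layer.

    Each matrix has shape ``(units, units + input_dim [+ 1])`` and acts on
    the concatenation ``[y<t-1>, x<t>]`` (with a trailing constant 1 when
    ``use_bias`` — the bias column — in the standard variant).
    """

    W_c: np.ndarray
    W_u: np.ndarray
    W_f: np.ndarray
    W_o: np.ndarray
    use_bias: bool = False

    def __post_init__(self) -> None:
        shapes = {w.shape for w in (self.W_c, self.W_u, self.W_f, self.W_o)}
        if len(shapes) != 1:
            raise ValueError("the four gate matrices must share one shape")

    @property
    def units(self) -> int:
        return self.W_c.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_c.shape[1] - self.units - (1 if self.use_bias else 0)

    def stacked(self) -> np.ndarray:
        return np.concatenate([self.W_c, self.W_u, self.W_f, self.W_o], axis=0)


@dataclass
class CellState:
    """Output and carry vectors of one layer at one time step."""

    y: np.ndarray
    C: np.ndarray


@dataclass
class NetworkParams:
    """All trainable weights: two LSTM layers plus the ReLU readout neuron."""

    layer1: LSTMLayerWeights
    layer2: LSTMLayerWeights
    dense_w: np.ndarray
    dense_b: float
    l2_lambda: float = 0.0
    variant: str = "paper"

    def __post_init__(self) -> None:
        if self.layer2.input_dim != self.layer1.units:
            raise ValueError("layer2 input dimension must equal layer1 units")
        if self.dense_w.shape != (self.layer2.units,):
            raise ValueError("dense_w must match layer2 units")


def _glorot(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (rows + cols))
    return rng.uniform(-limit, limit, size=(rows, cols))


def _init_layer(
    units: int, input_dim: int, rng: np.random.Generator, use_bias: bool
) -> LSTMLayerWeights:
    cols = units + input_dim + (1 if use_bias else 0)
    return LSTMLayerWeights(
        W_c=_glorot(rng, units, cols),
        W_u=_glorot(rng, units, cols),
        W_f=_glorot(rng, units, cols),
        W_o=_glorot(rng, units, cols),
        use_bias=use_bias,
    )


def init_params(
    n_features: int = 96,
    units: tuple[int, int] = (30, 15),
    seed: int = 0,
    variant: str = "paper",
    l2_lambda: float = 0.0,
) -> NetworkParams:
    """Seeded Glorot-uniform initialization of the whole network."""
    if variant not in ("paper", "standard"):
        raise ValueError("variant must be 'paper' or 'standard'")
    rng = np.random.default_rng(seed)
    use_bias = variant == "standard"
    u1, u2 = units
    return NetworkParams(
        layer1=_init_layer(u1, n_features, rng, use_bias),
        layer2=_init_layer(u2, u1, rng, use_bias),
        dense_w=_glorot(rng, 1, u2)[0],
        dense_b=0.0,
        l2_lambda=l2_lambda,
        variant=variant,
    )


# ---------------------------------------------------------------------------
# forward pass


def lstm_cell_forward(
    x_t: np.ndarray,
    state: CellState,
    w: LSTMLayerWeights,
    variant: str = "paper",
) -> CellState:
    """One step of the recurrence for a single sample (no dropout)."""
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape[-1] != w.input_dim or state.y.shape[-1] != w.units:
        raise ValueError("input/state dimensions do not match the layer weights")
    parts = [state.y, x_t]
    if w.use_bias:
        parts.append(np.ones(x_t.shape[:-1] + (1,)))
    z = np.concatenate(parts, axis=-1)
    a = z @ w.stacked().T
    u = w.units
    c_til = np.tanh(a[..., :u])
    g_u = _sigmoid(a[..., u : 2 * u])
    g_f = _sigmoid(a[..., 2 * u : 3 * u])
    g_o = _sigmoid(a[..., 3 * u :])
    C = g_u * c_til + g_f * state.C
    y = g_o * (np.tanh(C) if variant == "standard" else C)
    return CellState(y=y, C=C)


def _layer_forward(
    X: np.ndarray,
    w: LSTMLayerWeights,
    variant: str,
    mx: np.ndarray | None = None,
    mh: np.ndarray | None = None,
    want_cache: bool = False,
):
    """Run a layer over a batch of sequences.

    X is ``(batch, T, input_dim)``; ``mx``/``mh`` are per-sequence
    (variational) dropout masks of shape ``(batch, input_dim)`` and
    ``(batch, units)``, already inverted-scaled.  Returns ``(batch, T,
    units)`` outputs and, optionally, the cache needed for BPTT.
    """
    B, T, d = X.shape
    u = w.units
    Ws = w.stacked()
    y = np.zeros((B, u))
    C = np.zeros((B, u))
    outputs = np.empty((B, T, u))
    cache = [] if want_cache else None
    ones = np.ones((B, 1))
    for t in range(T):
        xt = X[:, t] if mx is None else X[:, t] * mx
        yp = y if mh is None else y * mh
        parts = [yp, xt] + ([ones] if w.use_bias else [])
        z = np.concatenate(parts, axis=1)
        a = z @ Ws.T
        c_til = np.tanh(a[:, :u])
        g_u = _sigmoid(a[:, u : 2 * u])
        g_f = _sigmoid(a[:, 2 * u : 3 * u])
        g_o = _sigmoid(a[:, 3 * u :])
        C_prev = C
        C = g_u * c_til + g_f * C_prev
        if variant == "standard":
            tC = np.tanh(C)
            y = g_o * tC
        else:
            tC = None
            y = g_o * C
        outputs[:, t] = y
        if want_cache:
            cache.append((z, c_til, g_u, g_f, g_o, C_prev, C, tC))
        if not np.isfinite(y).all():
            raise FloatingPointError(f"non-finite LSTM activation at step {t}")
    return outputs, cache


def _layer_backward(
    dY: np.ndarray,
    cache: list,
    w: LSTMLayerWeights,
    variant: str,
    mx: np.ndarray | None,
    mh: np.ndarray | None,
):
    """Exact BPTT through one layer; returns (dWs, dX)."""
    B, T, u = dY.shape
    d = w.input_dim
    Ws = w.stacked()
    dWs = np.zeros_like(Ws)
    dX = np.empty((B, T, d))
    dy_rec = np.zeros((B, u))
    dC_next = np.zeros((B, u))
    for t in range(T - 1, -1, -1):
        z, c_til, g_u, g_f, g_o, C_prev, C, tC = cache[t]
        dy = dY[:, t] + dy_rec
        if variant == "standard":
            dg_o = dy * tC
            dC = dC_next + dy * g_o * (1.0 - tC * tC)
        else:
            dg_o = dy * C
            dC = dC_next + dy * g_o
        dc_til = dC * g_u
        dg_u = dC * c_til
        dg_f = dC * C_prev
        dC_next = dC * g_f
        da = np.concatenate(
            [
                dc_til * (1.0 - c_til * c_til),
                dg_u * g_u * (1.0 - g_u),
                dg_f * g_f * (1.0 - g_f),
                dg_o * g_o * (1.0 - g_o),
            ],
            axis=1,
        )
        dWs += da.T @ z
        dz = da @ Ws
        dy_rec = dz[:, :u] if mh is None else dz[:, :u] * mh
        dxt = dz[:, u : u + d]
        dX[:, t] = dxt if mx is None else dxt * mx
    return dWs, dX


def lstm_layer_forward(
    sequence: np.ndarray,
    w: LSTMLayerWeights,
    dropout_masks: tuple[np.ndarray, np.ndarray] | None = None,
    variant: str = "paper",
) -> np.ndarray:
    """Apply one layer to a single ``(T, input_dim)`` sequence.

    State starts at zero; one output per input step.  ``dropout_masks`` is an
    optional ``(forward_mask, recurrent_mask)`` pair (training only).
    """
    seq = np.asarray(sequence, dtype=float)
    if seq.ndim != 2:
        raise ValueError("expected a (T, input_dim) sequence")
    mx = mh = None
    if dropout_masks is not None:
        mx = np.atleast_2d(dropout_masks[0])
        mh = np.atleast_2d(dropout_masks[1])
    out, _ = _layer_forward(seq[None], w, variant, mx=mx, mh=mh)
    return out[0]


def _network_forward_batch(
    X: np.ndarray,
    params: NetworkParams,
    masks: dict | None = None,
    want_cache: bool = False,
):
    m = masks or {}
    h1, c1 = _layer_forward(
        X, params.layer1, params.variant, m.get("mx1"), m.get("mh1"), want_cache
    )
    h2, c2 = _layer_forward(
        h1, params.layer2, params.variant, m.get("mx2"), m.get("mh2"), want_cache
    )
    s = h2 @ params.dense_w + params.dense_b
    yhat = np.maximum(s, 0.0)
    caches = {"c1": c1, "c2": c2, "h1": h1, "h2": h2, "s": s} if want_cache else None
    return yhat, caches


def network_forward(
    features: np.ndarray,
    params: NetworkParams,
    train_mode: bool = False,
    dropout_masks: dict | None = None,
) -> np.ndarray:
    """Full forward pass for one trial's ``(T, n_features)`` matrix.

    Output is one non-negative force prediction per time step; ReLU on the
    readout clamps negatives to exactly zero, matching a resting force
    sensor.  Dropout masks are only honored in ``train_mode``.
    """
    f = np.asarray(features, dtype=float)
    if f.ndim != 2:
        raise ValueError("expected a (T, n_features) matrix")
    masks = dropout_masks if train_mode else None
    yhat, _ = _network_forward_batch(f[None], params, masks)
    return yhat[0]


# ---------------------------------------------------------------------------
# training


def _draw_masks(rng, B: int, params: NetworkParams, hp: HyperParams) -> dict:
    def mask(p: float, dim: int) -> np.ndarray | None:
        if p <= 0:
            return None
        return rng.binomial(1, 1.0 - p, size=(B, dim)) / (1.0 - p)

    return {
        "mx1": mask(hp.dropout_l1_forward, params.layer1.input_dim),
        "mh1": mask(hp.dropout_l1_recurrent, params.layer1.units),
        "mx2": mask(hp.dropout_l2_forward, params.layer2.input_dim),
        "mh2": mask(hp.dropout_l2_recurrent, params.layer2.units),
    }


def _loss_and_grads(X, Y, params: NetworkParams, masks: dict):
    B, T, _ = X.shape
    yhat, cache = _network_forward_batch(X, params, masks, want_cache=True)
    resid = yhat - Y
    loss = np.mean(np.abs(resid)) + params.l2_lambda * np.sum(params.dense_w**2)

    ds = np.sign(resid) / (B * T)
    ds = ds * (cache["s"] > 0)  # ReLU gate
    d_dense_w = np.einsum("bt,btu->u", ds, cache["h2"]) + 2.0 * params.l2_lambda * params.dense_w
    d_dense_b = float(ds.sum())
    dh2 = ds[..., None] * params.dense_w
    m = masks or {}
    dW2, dh1 = _layer_backward(
        dh2, cache["c2"], params.layer2, params.variant, m.get("mx2"), m.get("mh2")
    )
    dW1, _ = _layer_backward(
        dh1, cache["c1"], params.layer1, params.variant, m.get("mx1"), m.get("mh1")
    )
    return loss, {"W1": dW1, "W2": dW2, "dense_w": d_dense_w, "dense_b": d_dense_b}


class _Adam:
    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_network(
    trials: Sequence[tuple[np.ndarray, np.ndarray]],
    hp: HyperParams | None = None,
    seed: int = 0,
    *,
    variant: str = "paper",
    units: tuple[int, int] = (30, 15),
    epoch_cap: int | None = None,
) -> tuple[NetworkParams, list[float]]:
    """Train the stack LSTM on a list of (features, target) trials.

    Batches are whole trials; dropout masks are redrawn per batch with one
    mask per sequence (variational dropout).  Loss is mean absolute error
    plus the L2 penalty on the readout weights.  Fully deterministic given
    ``seed``.  Returns the trained weights and the per-epoch loss trace.
    """
    if not trials:
        raise ValueError("need at least one training trial")
    hp = hp or HyperParams()
    X = np.stack([np.asarray(f, dtype=float) for f, _ in trials])
    Y = np.stack([np.asarray(y, dtype=float).ravel() for _, y in trials])
    n_features = X.shape[2]

    rng = np.random.default_rng(seed)
    params = init_params(
        n_features,
        units=units,
        seed=int(rng.integers(2**31)),
        variant=variant,
        l2_lambda=hp.l2_lambda,
    )
    # flat view of the trainable arrays; dense_b handled as a 1-element array
    dense_b = np.array([params.dense_b])
    flat = (
        [params.layer1.W_c, params.layer1.W_u, params.layer1.W_f, params.layer1.W_o]
        + [params.layer2.W_c, params.layer2.W_u, params.layer2.W_f, params.layer2.W_o]
        + [params.dense_w, dense_b]
    )
    opt = _Adam([p.shape for p in flat], lr=hp.learning_rate)

    n_epochs = hp.n_epochs if epoch_cap is None else min(hp.n_epochs, epoch_cap)
    loss_trace: list[float] = []
    N = X.shape[0]
    for _ in range(n_epochs):
        order = rng.permutation(N)
        epoch_losses = []
        for start in range(0, N, hp.batch_size):
            idx = order[start : start + hp.batch_size]
            masks = _draw_masks(rng, len(idx), params, hp)
            params.dense_b = float(dense_b[0])
            loss, grads = _loss_and_grads(X[idx], Y[idx], params, masks)
            if not np.isfinite(loss):
                raise FloatingPointError("training diverged: non-finite loss")
            g1 = np.split(grads["W1"], 4, axis=0)
            g2 = np.split(grads["W2"], 4, axis=0)
            opt.step(flat, g1 + g2 + [grads["dense_w"], np.array([grads["dense_b"]])])
            epoch_losses.append(loss)
        loss_trace.append(float(np.mean(epoch_losses)))
    params.dense_b = float(dense_b[0])
    return params, loss_trace


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    sst = np.sum((y - y.mean()) ** 2)
    return 1.0 - float(np.sum((y - yhat) ** 2) / sst)


def _grid_size(grid: dict) -> int:
    n = 1
    for v in grid.values():
        n *= len(v)
    return n


def tune_hyperparameters(
    trials: Sequence[tuple[np.ndarray, np.ndarray]],
    grid: dict | None = None,
    budget: int = 30,
    seed: int = 0,
    *,
    val_frac: float = 0.2,
    variant: str = "paper",
    units: tuple[int, int] = (30, 15),
    epoch_cap: int | None = None,
) -> tuple[HyperParams, list[dict]]:
    """Seeded random search over the hyper-parameter grid.

    Holds out ``val_frac`` of the trials (trial-level, seeded) for
    validation, trains each sampled configuration on the rest, and scores
    validation R^2 on the concatenated predictions.  Returns the best
    configuration and the full search log.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    grid = dict(grid or HYPERPARAM_GRID)
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty hyper-parameter grid")
    if _grid_size(grid) == 1:
        hp = HyperParams(**{k: v[0] for k, v in grid.items()})
        return hp, []

    rng = np.random.default_rng(seed)
    n = len(trials)
    n_val = max(1, int(round(val_frac * n)))
    if n_val >= n:
        raise ValueError("not enough trials to hold out a validation split")
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    train = [trials[i] for i in train_idx]
    val = [trials[i] for i in val_idx]
    y_val = np.concatenate([y for _, y in val])

    seen: set[tuple] = set()
    log: list[dict] = []
    best_hp, best_score = None, -np.inf
    attempts = 0
    while len(log) < budget and attempts < 20 * budget:
        attempts += 1
        choice = {k: v[rng.integers(len(v))] for k, v in grid.items()}
        key = tuple(sorted(choice.items()))
        if key in seen and _grid_size(grid) > budget:
            continue
        seen.add(key)
        hp = HyperParams(**choice)
        train_seed = int(rng.integers(2**31))
        params, _ = train_network(
            train, hp, seed=train_seed, variant=variant, units=units, epoch_cap=epoch_cap
        )
        pred = np.concatenate([network_forward(f, params) for f, _ in val])
        score = _r_squared(y_val, pred)
        log.append({"hp": hp.to_dict(), "val_r2": score, "train_seed": train_seed})
        if score > best_score:
            best_hp, best_score = hp, score
    return best_hp, log


# ---------------------------------------------------------------------------
# model / results objects


class ForceLSTM:
    """Stack LSTM decoder over per-trial feature/target pairs.

    Parameters
    ----------
    features : sequence of (T, n_features) arrays (normalized)
    targets : sequence of (T,) force targets (newtons)
    variant : "paper" (bias-free, no output tanh) or "standard"
    units : layer widths, default (30, 15)
    """

    def __init__(
        self,
        features: Sequence[np.ndarray],
        targets: Sequence[np.ndarray],
        *,
        variant: str = "paper",
        units: tuple[int, int] = (30, 15),
    ):
        if len(features) != len(targets) or not features:
            raise ValueError("features and targets must be equal-length, non-empty")
        self.trials = [
            (np.asarray(f, dtype=float), np.asarray(y, dtype=float).ravel())
            for f, y in zip(features, targets)
        ]
        self.variant = variant
        self.units = units

    def tune(
        self,
        budget: int = 30,
        seed: int = 0,
        grid: dict | None = None,
        epoch_cap: int | None = None,
    ) -> tuple[HyperParams, list[dict]]:
        return tune_hyperparameters(
            self.trials,
            grid=grid,
            budget=budget,
            seed=seed,
            variant=self.variant,
            units=self.units,
            epoch_cap=epoch_cap,
        )

    def fit(
        self,
        hyperparams: HyperParams | None = None,
        seed: int = 0,
        epoch_cap: int | None = None,
    ) -> "LSTMResults":
        hp = hyperparams or HyperParams()
        params, trace = train_network(
            self.trials,
            hp,
            seed=seed,
            variant=self.variant,
            units=self.units,
            epoch_cap=epoch_cap,
        )
        return LSTMResults(model=self, params=params, hyperparams=hp, loss_trace=trace, seed=seed)


@dataclass
class LSTMResults:
    """Trained decoder: weights, training trace and prediction interface."""

    model: ForceLSTM
    params: NetworkParams
    hyperparams: HyperParams
    loss_trace: list[float]
    seed: int

    def predict(self, features: np.ndarray) -> np.ndarray:
        return network_forward(features, self.params)

    @property
    def fittedvalues(self) -> list[np.ndarray]:
        return [self.predict(f) for f, _ in self.model.trials]

    @property
    def train_rsquared(self) -> float:
        y = np.concatenate([t for _, t in self.model.trials])
        yhat = np.concatenate(self.fittedvalues)
        return _r_squared(y, yhat)

    def summary(self) -> str:
        p = self.params
        n_weights = sum(
            w.size
            for layer in (p.layer1, p.layer2)
            for w in (layer.W_c, layer.W_u, layer.W_f, layer.W_o)
        ) + p.dense_w.size + 1
        lines = [
            "Stack LSTM force decoder",
            "=" * 40,
            f"variant             {p.variant}",
            f"architecture        {p.layer1.input_dim} -> {p.layer1.units} -> "
            f"{p.layer2.units} -> 1 (ReLU)",
            f"trainable weights   {n_weights}",
            f"trials              {len(self.model.trials)}",
            f"epochs run          {len(self.loss_trace)}",
            f"final train MAE     {self.loss_trace[-1]: .5f}" if self.loss_trace else "",
            f"train R^2           {self.train_rsquared: .4f}",
            f"hyper-parameters    {self.hyperparams.to_dict()}",
        ]
        return "\n".join(line for line in lines if line)

    def plot_loss(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.loss_trace)
        ax.set_xlabel("epoch")
        ax.set_ylabel("training MAE (N)")
        return ax


# ---------------------------------------------------------------------------
# serialization


def save_params(path, params: NetworkParams, hyperparams: HyperParams | None = None) -> None:
    """Serialize network weights plus a JSON manifest into one .npz archive."""
    meta = {
        "variant": params.variant,
        "l2_lambda": params.l2_lambda,
        "use_bias": params.layer1.use_bias,
        "hyperparams": hyperparams.to_dict() if hyperparams else None,
    }
    arrays = {"dense_w": params.dense_w, "dense_b": np.array([params.dense_b])}
    for i, layer in enumerate((params.layer1, params.layer2), start=1):
        for gate in ("c", "u", "f", "o"):
            arrays[f"l{i}_W_{gate}"] = getattr(layer, f"W_{gate}")
    np.savez(path, manifest=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_params(path) -> tuple[NetworkParams, dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["manifest"]).decode())
        layers = []
        for i in (1, 2):
            layers.append(
                LSTMLayerWeights(
                    W_c=z[f"l{i}_W_c"],
                    W_u=z[f"l{i}_W_u"],
                    W_f=z[f"l{i}_W_f"],
                    W_o=z[f"l{i}_W_o"],
                    use_bias=meta["use_bias"],
                )
            )
        params = NetworkParams(
            layer1=layers[0],
            layer2=layers[1],
            dense_w=z["dense_w"],
            dense_b=float(z["dense_b"][0]),
            l2_lambda=meta["l2_lambda"],
            variant=meta["variant"],
        )
    return params, meta
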