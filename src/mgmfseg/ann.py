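"""Pixel-wise fusion of multiscale matched-filter responses by a small MLP.

Each pixel of an angiogram carries an n-scale feature vector (its matched
filter responses at every Gaussian scale).  A feed-forward network with two
hidden layers maps that vector to a single vessel-likelihood score in (0, 1):

    F(x) = h(W3 . g(W2 . g(W1 . x~ + b1) + b2) + b3)

with logistic g and h, and x~ the per-scale z-scored feature vector.  The
network is trained on pixels sampled from a set of training images (all
vessel pixels plus a balanced draw of background pixels) to minimize the
mean squared error against the {0, 1} ground-truth labels.  Applied to every
pixel of a response stack, the network yields a gray-scale vessel detection
map that a thresholding method then binarizes.

The two hidden-layer widths are the only architectural freedom; an
exhaustive grid search over (n_1st, n_2nd) scored by training-set ROC area
selects them.  The default (3, 8) is the optimum reported for 11-scale
angiogram features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import expit

from .gmf import ResponseStack
from .metrics import roc, auc

__all__ = [
    "NetworkArchitecture",
    "NetworkModel",
    "TrainingConfig",
    "TrainingError",
    "DivergenceError",
    "init_network",
    "forward",
    "train",
    "predict_image",
    "architecture_search",
    "save_model",
    "load_model",
]


class TrainingError(ValueError):
    """Raised when the training set or the optimization is unusable."""


class DivergenceError(TrainingError):
    """Raised when the loss becomes non-finite; carries the offending epoch."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"training loss became non-finite at epoch {epoch}")


_ACTIVATIONS = {"logistic"}


@dataclass(frozen=True)
class NetworkArchitecture:
    """Four-layer feed-forward topology: inputs, two hidden layers, one output."""

    n_inputs: int
    hidden_sizes: tuple[int, int] = (3, 8)
    activation_hidden: str = "logistic"
    activation_output: str = "logistic"

    def __post_init__(self) -> None:
        if self.n_inputs < 1:
            raise ValueError("n_inputs must be >= 1")
        hs = tuple(int(h) for h in self.hidden_sizes)
        if len(hs) != 2 or any(h < 1 for h in hs):
            raise ValueError("hidden_sizes must be a pair of positive integers")
        object.__setattr__(self, "hidden_sizes", hs)
        for a in (self.activation_hidden, self.activation_output):
            if a not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {a!r}")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.n_inputs, *self.hidden_sizes, 1)


@dataclass
class NetworkModel:
    """Weights, biases and input-normalization constants of a fusion MLP.

    ``weights[i]``/``biases[i]`` map layer ``i`` activations to layer
    ``i + 1`` pre-activations (shapes ``fan_out x fan_in`` and ``fan_out``).
    ``input_mean``/``input_scale`` are the per-scale z-scoring constants
    frozen at training time.
    """

    architecture: NetworkArchitecture
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    input_mean: np.ndarray
    input_scale: np.ndarray
    seed: int | None = None

    def __call__(self, features: np.ndarray) -> np.ndarray:
        return forward(self, features)


@dataclass(frozen=True)
class TrainingConfig:
    """Hyper-parameters of the pixel-sampling and MSE training loop.

    ``class_balance`` is the background-to-vessel pixel sampling ratio (1.0
    draws as many background pixels as there are vessel pixels per image).
    ``optimizer`` is ``"sgd"`` (mini-batch gradient descent with momentum,
    default) or ``"lm"`` (full-batch Levenberg-Marquardt; memory scales with
    n_samples x n_parameters, intended for small sample sets).
    """

    loss: str = "mse"
    optimizer: str = "sgd"
    learning_rate: float = 0.5
    momentum: float = 0.9
    epochs: int = 200
    batch_size: int = 256
    seed: int = 0
    class_balance: float = 1.0
    validation_fraction: float = 0.0
    patience: int = 20
    normalize_inputs: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss != "mse":
            raise ValueError("only squared-error loss is supported")
        if self.optimizer not in ("sgd", "lm"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def init_network(arch: NetworkArchitecture, seed: int) -> NetworkModel:
    """Seeded Glorot-uniform initialization: W ~ U(-r, r), r = sqrt(6/(fan_in+fan_out)); zero biases."""
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    sizes = arch.layer_sizes
    for fan_in, fan_out in zip(sizes, sizes[1:]):
        r = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-r, r, size=(fan_out, fan_in)))
        biases.append(np.zeros(fan_out))
    m = arch.n_inputs
    return NetworkModel(
        architecture=arch,
        weights=weights,
        biases=biases,
        input_mean=np.zeros(m),
        input_scale=np.ones(m),
        seed=int(seed),
    )


def _forward_layers(model: NetworkModel, x: np.ndarray) -> list[np.ndarray]:
    """Activations of every layer for a (n, m) feature matrix (x already normalized)."""
    acts = [x]
    for W, b in zip(model.weights, model.biases):
        acts.append(expit(acts[-1] @ W.T + b))
    return acts


def forward(model: NetworkModel, features: np.ndarray) -> np.ndarray:
    """Vessel-likelihood score(s) in (0, 1) for one feature vector or a matrix of them."""
    x = np.asarray(features, dtype=np.float64)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != model.architecture.n_inputs:
        raise ValueError(
            f"expected {model.architecture.n_inputs} features, got {x.shape[1]}"
        )
    x = (x - model.input_mean) / model.input_scale
    out = _forward_layers(model, x)[-1][:, 0]
    return out[0] if single else out


@dataclass
class TrainingHistory:
    """Per-epoch mean training loss (and validation A_z when a split is used)."""

    loss: list[float] = field(default_factory=list)
    val_az: list[float] = field(default_factory=list)
    stopped_epoch: int | None = None


def _sample_pixels(
    stacks: list[ResponseStack],
    masks: list[np.ndarray],
    class_balance: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    if len(stacks) != len(masks) or not stacks:
        raise TrainingError("stacks and masks must be non-empty and aligned")
    X_parts, y_parts = [], []
    for stack, mask in zip(stacks, masks):
        mask = np.asarray(mask).astype(bool)
        if mask.shape != stack.image_shape:
            raise TrainingError(
                f"mask shape {mask.shape} does not match stack {stack.image_shape}"
            )
        feats = stack.features()
        flat = mask.ravel()
        vessel_idx = np.flatnonzero(flat)
        bg_idx = np.flatnonzero(~flat)
        if vessel_idx.size and bg_idx.size:
            n_bg = min(bg_idx.size, int(round(class_balance * vessel_idx.size)))
            bg_idx = rng.choice(bg_idx, size=n_bg, replace=False)
        idx = np.concatenate([vessel_idx, bg_idx])
        X_parts.append(feats[idx])
        y_parts.append(flat[idx].astype(np.float64))
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)
    if y.min() == y.max():
        raise TrainingError("training sample contains a single class")
    return X, y


def _backprop_grads(model, X, y):
    acts = _forward_layers(model, X)
    out = acts[-1][:, 0]
    # d(MSE)/d(pre-activation) for logistic output under squared error
    delta = ((out - y) * out * (1.0 - out))[:, None] * (2.0 / len(y))
    gW, gb = [], []
    for i in range(len(model.weights) - 1, -1, -1):
        gW.append(delta.T @ acts[i])
        gb.append(delta.sum(axis=0))
        if i > 0:
            delta = (delta @ model.weights[i]) * acts[i] * (1.0 - acts[i])
    return gW[::-1], gb[::-1], out


def _sgd(model, X, y, cfg, history, X_val=None, y_val=None):
    vel_W = [np.zeros_like(W) for W in model.weights]
    vel_b = [np.zeros_like(b) for b in model.biases]
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5D]))
    n = len(y)
    best_val, since_best = -np.inf, 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            gW, gb, out = _backprop_grads(model, X[sel], y[sel])
            epoch_loss += float(np.sum((out - y[sel]) ** 2))
            for i in range(len(model.weights)):
                vel_W[i] = cfg.momentum * vel_W[i] - cfg.learning_rate * gW[i]
                vel_b[i] = cfg.momentum * vel_b[i] - cfg.learning_rate * gb[i]
                model.weights[i] += vel_W[i]
                model.biases[i] += vel_b[i]
        epoch_loss /= n
        if not np.isfinite(epoch_loss):
            raise DivergenceError(epoch)
        history.loss.append(epoch_loss)
        if X_val is not None:
            scores = _forward_layers(model, X_val)[-1][:, 0]
            val_az = auc(roc(scores, y_val > 0.5))
            history.val_az.append(val_az)
            if val_az > best_val + 1e-6:
                best_val, since_best = val_az, 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    history.stopped_epoch = epoch
                    break


def _flatten_params(model):
    return np.concatenate([a.ravel() for a in (*model.weights, *model.biases)])


def _unflatten_params(model, vec):
    pos = 0
    for group in (model.weights, model.biases):
        for i, a in enumerate(group):
            group[i] = vec[pos : pos + a.size].reshape(a.shape)
            pos += a.size


def _lm_jacobian(model, X):
    """Per-sample Jacobian of the network output w.r.t. all parameters."""
    acts = _forward_layers(model, X)
    out = acts[-1][:, 0]
    n = len(X)
    deltas = [None] * len(model.weights)
    deltas[-1] = (out * (1.0 - out))[:, None]
    for i in range(len(model.weights) - 2, -1, -1):
        deltas[i] = (deltas[i + 1] @ model.weights[i + 1]) * acts[i + 1] * (1.0 - acts[i + 1])
    JW = [
        (d[:, :, None] * a[:, None, :]).reshape(n, -1)
        for d, a in zip(deltas, acts[:-1])
    ]
    return np.concatenate(JW + deltas, axis=1), out


def _levenberg_marquardt(model, X, y, cfg, history):
    lam = 1e-2
    theta = _flatten_params(model)
    _, out = _lm_jacobian(model, X)
    loss = float(np.mean((out - y) ** 2))
    for epoch in range(cfg.epochs):
        J, out = _lm_jacobian(model, X)
        r = out - y
        A = J.T @ J
        g = J.T @ r
        accepted = False
        for _ in range(12):
            try:
                step = np.linalg.solve(A + lam * np.eye(A.shape[0]), g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            trial = theta - step
            _unflatten_params(model, trial)
            trial_out = _forward_layers(model, X)[-1][:, 0]
            trial_loss = float(np.mean((trial_out - y) ** 2))
            if np.isfinite(trial_loss) and trial_loss < loss:
                theta, loss, lam = trial, trial_loss, max(lam / 10.0, 1e-12)
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            _unflatten_params(model, theta)
        if not np.isfinite(loss):
            raise DivergenceError(epoch)
        history.loss.append(loss)
        if not accepted and lam > 1e10:
            break
    _unflatten_params(model, theta)


def train(
    stacks: list[ResponseStack],
    masks: list[np.ndarray],
    arch: NetworkArchitecture | None = None,
    cfg: TrainingConfig | None = None,
) -> tuple[NetworkModel, TrainingHistory]:
    """Fit the fusion MLP on pixels sampled from (stack, mask) pairs.

    All vessel pixels of every image enter the sample, together with
    ``class_balance`` times as many uniformly drawn background pixels.
    Features are z-scored per scale with constants frozen into the model.
    Returns the trained model and the per-epoch loss history.
    """
    cfg = cfg or TrainingConfig()
    if arch is None:
        arch = NetworkArchitecture(n_inputs=stacks[0].n_scales)
    if arch.n_inputs != stacks[0].n_scales:
        raise TrainingError(
            f"architecture expects {arch.n_inputs} scales, stacks carry {stacks[0].n_scales}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA1]))
    X, y = _sample_pixels(stacks, masks, cfg.class_balance, rng)

    model = init_network(arch, cfg.seed)
    if cfg.normalize_inputs:
        model.input_mean = X.mean(axis=0)
        scale = X.std(axis=0)
        model.input_scale = np.where(scale > 0, scale, 1.0)
    Xn = (X - model.input_mean) / model.input_scale

    X_val = y_val = None
    if cfg.validation_fraction > 0:
        n_val = int(round(cfg.validation_fraction * len(y)))
        perm = rng.permutation(len(y))
        val_sel, tr_sel = perm[:n_val], perm[n_val:]
        X_val, y_val = Xn[val_sel], y[val_sel]
        Xn, y = Xn[tr_sel], y[tr_sel]

    history = TrainingHistory()
    if cfg.optimizer == "sgd":
        _sgd(model, Xn, y, cfg, history, X_val, y_val)
    else:
        _levenberg_marquardt(model, Xn, y, cfg, history)
    return model, history


def predict_image(model: NetworkModel, stack: ResponseStack) -> np.ndarray:
    """Per-pixel forward score arranged as an image in (0, 1)."""
    if stack.n_scales != model.architecture.n_inputs:
        raise ValueError(
            f"model expects {model.architecture.n_inputs} scales, stack has {stack.n_scales}"
        )
    scores = forward(model, stack.features())
    return scores.reshape(stack.image_shape)


def architecture_search(
    stacks: list[ResponseStack],
    masks: list[np.ndarray],
    grid_max: int = 10,
    cfg: TrainingConfig | None = None,
) -> tuple[NetworkArchitecture, np.ndarray]:
    """Exhaustive search over the two hidden-layer widths in [1, grid_max]^2.

    Trains one model per (n_1st, n_2nd) cell and scores it by the pooled
    training-set ROC area of its pixel scores.  Returns the best architecture
    and the full grid of A_z values (NaN where training failed).  Exact A_z
    ties break toward the smaller total neuron count, then the smaller first
    hidden layer.
    """
    if grid_max < 1:
        raise ValueError("grid_max must be >= 1")
    cfg = cfg or TrainingConfig()
    labels = np.concatenate([np.asarray(m).astype(bool).ravel() for m in masks])
    feats = np.concatenate([s.features() for s in stacks])
    table = np.full((grid_max, grid_max), np.nan)
    for n1 in range(1, grid_max + 1):
        for n2 in range(1, grid_max + 1):
            arch = NetworkArchitecture(n_inputs=stacks[0].n_scales, hidden_sizes=(n1, n2))
            cell_seed = int(np.random.SeedSequence([cfg.seed, n1, n2]).generate_state(1)[0] % (2**31))
            cell_cfg = TrainingConfig(**{**asdict(cfg), "seed": cell_seed})
            try:
                model, _ = train(stacks, masks, arch, cell_cfg)
            except TrainingError:
                continue
            scores = forward(model, feats)
            table[n1 - 1, n2 - 1] = auc(roc(scores, labels))
    if np.all(np.isnan(table)):
        raise TrainingError("every architecture-search cell failed to train")
    best_az = np.nanmax(table)
    candidates = [
        (n1 + n2, n1, n2)
        for n1 in range(1, grid_max + 1)
        for n2 in range(1, grid_max + 1)
        if table[n1 - 1, n2 - 1] == best_az
    ]
    _, n1, n2 = min(candidates)
    best = NetworkArchitecture(n_inputs=stacks[0].n_scales, hidden_sizes=(n1, n2))
    return best, table


def save_model(model: NetworkModel, path, training_config: TrainingConfig | None = None) -> None:
    """Serialize a model to a self-describing JSON file (bit-exact round-trip)."""
    payload = {
        "format": "mgmfseg-model-v1",
        "architecture": {
            "n_inputs": model.architecture.n_inputs,
            "hidden_sizes": list(model.architecture.hidden_sizes),
            "activation_hidden": model.architecture.activation_hidden,
            "activation_output": model.architecture.activation_output,
        },
        "weights": [W.tolist() for W in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "input_mean": model.input_mean.tolist(),
        "input_scale": model.input_scale.tolist(),
        "seed": model.seed,
        "training_config": asdict(training_config) if training_config else None,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_model(path) -> NetworkModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "mgmfseg-model-v1":
        raise ValueError(f"{path} is not a recognized model file")
    a = payload["architecture"]
    arch = NetworkArchitecture(
        n_inputs=a["n_inputs"],
        hidden_sizes=tuple(a["hidden_sizes"]),
        activation_hidden=a["activation_hidden"],
        activation_output=a["activation_output"],
    )
    return NetworkModel(
        architecture=arch,
        weights=[np.array(W, dtype=np.float64) for W in payload["weights"]],
        biases=[np.array(b, dtype=np.float64) for b in payload["biases"]],
        input_mean=np.array(payload["input_mean"], dtype=np.float64),
        input_scale=np.array(payload["input_scale"], dtype=np.float64),
        seed=payload["seed"],
    )
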