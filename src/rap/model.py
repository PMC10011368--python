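"""Multioutput fully connected network for missed-meal detection.

Architecture: three shared hidden layers (512, 32, 16 units) feeding two
branches, each with a 16-unit hidden layer — a single logistic unit for
meal detection and a 5-way softmax for carbohydrate-class estimation.
Hidden activations are ReLU; weights are Xavier-uniform initialised with
zero biases; training minimises binary cross-entropy (all samples) plus
weighted categorical cross-entropy (meal-positive samples only) plus an L1
penalty, with Adam at a constant learning rate, mini-batches of 128, and
early stopping on a stratified validation split.

The network is small enough that forward/backward passes are plain numpy
matrix products; training the in-silico experiment takes minutes on one
CPU core and is bit-reproducible given the config seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .errors import RapError, ValidationError
from .features import N_CARB_CLASSES, N_FEATURES, SCHEMA_VERSION

_EPS = 1e-12


class TrainingError(RapError, RuntimeError):
    """Optimisation produced a non-finite loss."""


@dataclass(frozen=True)
class MealNetConfig:
    """Hyperparameters of the detection/estimation network.

    The architecture and optimiser settings are fixed defaults of the
    method.  ``pos_weight`` re-weights meal-positive samples in the
    detection loss; the default 1.0 (no re-weighting) keeps the detection
    output an approximately calibrated posterior probability, which is what
    an absolute alert threshold like 0.86 presumes.  Set it to a number > 1
    or "auto" (negative/positive ratio, capped at 50) to trade false alarms
    for sensitivity.
    """

    input_dim: int = N_FEATURES
    shared_layers: tuple[int, ...] = (512, 32, 16)
    branch_hidden: int = 16
    n_classes: int = N_CARB_CLASSES
    l1_penalty: float = 1e-6
    learning_rate: float = 1e-4
    batch_size: int = 128
    loss_weights: tuple[float, float] = (1.0, 1.0)
    pos_weight: float | str = 1.0
    val_fraction: float = 0.15
    patience: int = 10
    max_epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim != N_FEATURES:
            raise ValidationError(
                f"MealNetConfig.input_dim must equal the feature schema length {N_FEATURES}")
        if self.l1_penalty < 0:
            raise ValidationError("MealNetConfig.l1_penalty must be >= 0")
        if self.learning_rate <= 0:
            raise ValidationError("MealNetConfig.learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValidationError("MealNetConfig.batch_size must be >= 1")
        if not 0.0 < self.val_fraction < 0.5:
            raise ValidationError("MealNetConfig.val_fraction must lie in (0, 0.5)")
        if any(w < 0 for w in self.loss_weights):
            raise ValidationError("MealNetConfig.loss_weights must be >= 0")


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


_WEIGHT_KEYS = ("W1", "W2", "W3", "Wd", "wd_out", "Wc", "Wc_out")
_BIAS_KEYS = ("b1", "b2", "b3", "bd", "bd_out", "bc", "bc_out")


class MealNet:
    """Network state: config, parameter tensors, feature scaler, history."""

    def __init__(self, config: MealNetConfig, params: dict[str, np.ndarray]):
        self.config = config
        self.params = params
        self.scaler_mean: np.ndarray | None = None
        self.scaler_std: np.ndarray | None = None
        self.training_history: list[dict] = []

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Single-archive model artifact: config, weights, scaler, schema."""
        meta = {"config": asdict(self.config), "schema_version": SCHEMA_VERSION}
        arrays = dict(self.params)
        if self.scaler_mean is not None:
            arrays["scaler_mean"] = self.scaler_mean
            arrays["scaler_std"] = self.scaler_std
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "MealNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg = meta["config"]
            for key in ("shared_layers", "loss_weights"):
                cfg[key] = tuple(cfg[key])
            net = cls(MealNetConfig(**cfg),
                      {k: data[k] for k in data.files
                       if k in _WEIGHT_KEYS or k in _BIAS_KEYS})
            if "scaler_mean" in data.files:
                net.scaler_mean = data["scaler_mean"]
                net.scaler_std = data["scaler_std"]
        return net


def build(config: MealNetConfig) -> MealNet:
    """Construct an untrained network: Xavier-uniform weights, zero biases."""
    rng = np.random.default_rng(config.seed)
    h1, h2, h3 = config.shared_layers
    hb = config.branch_hidden
    params = {
        "W1": _xavier(rng, config.input_dim, h1), "b1": np.zeros(h1),
        "W2": _xavier(rng, h1, h2), "b2": np.zeros(h2),
        "W3": _xavier(rng, h2, h3), "b3": np.zeros(h3),
        "Wd": _xavier(rng, h3, hb), "bd": np.zeros(hb),
        "wd_out": _xavier(rng, hb, 1), "bd_out": np.zeros(1),
        "Wc": _xavier(rng, h3, hb), "bc": np.zeros(hb),
        "Wc_out": _xavier(rng, hb, config.n_classes), "bc_out": np.zeros(config.n_classes),
    }
    return MealNet(config, params)


def compute_sample_weights(meal_flag: np.ndarray, carb_class: np.ndarray,
                           asymmetry: float = 0.25) -> np.ndarray:
    """Per-sample weights for the classification loss.

    Class weight is proportional to inverse class frequency among positive
    samples (imbalance correction), multiplied by ``1 + asymmetry * class``
    so that mass sits on larger-carb truths — misclassifying a large meal
    as small costs more than the reverse, discouraging overestimation of
    small meals.  Weights are normalised to mean 1 over positives; negative
    samples get weight 0 (they never enter the classification loss).
    """
    meal_flag = np.asarray(meal_flag)
    carb_class = np.asarray(carb_class)
    pos = meal_flag == 1
    if not pos.any():
        raise ValidationError("compute_sample_weights: no positive samples")
    counts = np.bincount(carb_class[pos], minlength=N_CARB_CLASSES)
    class_w = np.zeros(N_CARB_CLASSES)
    present = counts > 0
    if not present.all():
        warnings.warn(
            f"carb classes {np.flatnonzero(~present).tolist()} absent from training data; "
            "their weights are computed from the remaining classes", stacklevel=2)
    class_w[present] = counts[present].sum() / counts[present]
    class_w[~present] = class_w[present].mean() if present.any() else 0.0
    class_w *= 1.0 + asymmetry * np.arange(N_CARB_CLASSES)

    weights = np.zeros(len(meal_flag))
    weights[pos] = class_w[carb_class[pos]]
    weights[pos] /= weights[pos].mean()
    return weights


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------

def _forward(params: dict, X: np.ndarray) -> dict:
    z1 = X @ params["W1"] + params["b1"]; a1 = np.maximum(z1, 0.0)
    z2 = a1 @ params["W2"] + params["b2"]; a2 = np.maximum(z2, 0.0)
    z3 = a2 @ params["W3"] + params["b3"]; a3 = np.maximum(z3, 0.0)
    zd = a3 @ params["Wd"] + params["bd"]; ad = np.maximum(zd, 0.0)
    logit = (ad @ params["wd_out"] + params["bd_out"])[:, 0]
    p = 1.0 / (1.0 + np.exp(-logit))
    zc = a3 @ params["Wc"] + params["bc"]; ac = np.maximum(zc, 0.0)
    class_logits = ac @ params["Wc_out"] + params["bc_out"]
    shifted = class_logits - class_logits.max(axis=1, keepdims=True)
    expd = np.exp(shifted)
    probs = expd / expd.sum(axis=1, keepdims=True)
    return {"X": X, "a1": a1, "a2": a2, "a3": a3, "ad": ad, "ac": ac,
            "p": p, "probs": probs}


def _loss_terms(cache: dict, y_flag: np.ndarray, y_class: np.ndarray,
                weights: np.ndarray, params: dict, config: MealNetConfig,
                pos_weight: float) -> tuple[float, float, float]:
    p = np.clip(cache["p"], _EPS, 1.0 - _EPS)
    bce = -np.mean(pos_weight * y_flag * np.log(p) + (1 - y_flag) * np.log(1 - p))
    pos = y_flag == 1
    if pos.any():
        logp = np.log(np.clip(cache["probs"][pos, y_class[pos]], _EPS, None))
        cce = -np.mean(weights[pos] * logp)
    else:
        cce = 0.0
    l1 = config.l1_penalty * sum(np.abs(params[k]).sum() for k in _WEIGHT_KEYS)
    return float(bce), float(cce), float(l1)


def _backward(cache: dict, y_flag: np.ndarray, y_class: np.ndarray,
              weights: np.ndarray, params: dict, config: MealNetConfig,
              pos_weight: float) -> dict:
    n = len(y_flag)
    w_det, w_cls = config.loss_weights
    p = cache["p"]
    # d(BCE)/d(logit) with positive-class re-weighting
    dlogit = (w_det / n) * (pos_weight * y_flag * (p - 1.0) + (1 - y_flag) * p)

    pos = y_flag == 1
    n_pos = max(int(pos.sum()), 1)
    dclass = np.zeros_like(cache["probs"])
    if pos.any():
        dclass[pos] = cache["probs"][pos]
        dclass[pos, y_class[pos]] -= 1.0
        dclass[pos] *= (w_cls * weights[pos, None]) / n_pos

    grads: dict[str, np.ndarray] = {}
    # detection branch
    d_ad = dlogit[:, None] @ params["wd_out"].T
    grads["wd_out"] = cache["ad"].T @ dlogit[:, None]
    grads["bd_out"] = np.array([dlogit.sum()])
    d_zd = d_ad * (cache["ad"] > 0)
    grads["Wd"] = cache["a3"].T @ d_zd
    grads["bd"] = d_zd.sum(axis=0)
    # classification branch
    d_ac = dclass @ params["Wc_out"].T
    grads["Wc_out"] = cache["ac"].T @ dclass
    grads["bc_out"] = dclass.sum(axis=0)
    d_zc = d_ac * (cache["ac"] > 0)
    grads["Wc"] = cache["a3"].T @ d_zc
    grads["bc"] = d_zc.sum(axis=0)
    # shared trunk
    d_a3 = d_zd @ params["Wd"].T + d_zc @ params["Wc"].T
    d_z3 = d_a3 * (cache["a3"] > 0)
    grads["W3"] = cache["a2"].T @ d_z3
    grads["b3"] = d_z3.sum(axis=0)
    d_z2 = (d_z3 @ params["W3"].T) * (cache["a2"] > 0)
    grads["W2"] = cache["a1"].T @ d_z2
    grads["b2"] = d_z2.sum(axis=0)
    d_z1 = (d_z2 @ params["W2"].T) * (cache["a1"] > 0)
    grads["W1"] = cache["X"].T @ d_z1
    grads["b1"] = d_z1.sum(axis=0)

    for k in _WEIGHT_KEYS:
        grads[k] = grads[k] + config.l1_penalty * np.sign(params[k])
    return grads


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _stratified_split(y_flag: np.ndarray, val_fraction: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for flag in (0, 1):
        idx = np.flatnonzero(y_flag == flag)
        rng.shuffle(idx)
        n_val = max(1, int(round(val_fraction * len(idx)))) if len(idx) else 0
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def train(net: MealNet, X: np.ndarray, y_flag: np.ndarray, y_class: np.ndarray,
          sample_weights: np.ndarray | None = None) -> MealNet:
    """Fit the network in place and return it.

    Features are z-scored with statistics of the training split (persisted
    with the model); optimisation is Adam with the configured constant
    learning rate; early stopping restores the best-validation-loss
    parameters after ``patience`` epochs without improvement.
    """
    config = net.config
    X = np.asarray(X, dtype=float)
    y_flag = np.asarray(y_flag, dtype=int)
    y_class = np.asarray(y_class, dtype=int)
    if X.ndim != 2 or X.shape[1] != config.input_dim:
        raise ValidationError(f"train: X must be (n, {config.input_dim})")
    if not (len(X) == len(y_flag) == len(y_class)):
        raise ValidationError("train: features and labels misaligned")
    if not (y_flag == 1).any():
        raise ValidationError("train: empty positive set")
    if sample_weights is None:
        sample_weights = compute_sample_weights(y_flag, y_class)
    sample_weights = np.asarray(sample_weights, dtype=float)
    if not np.all(np.isfinite(sample_weights)) or (sample_weights < 0).any():
        raise ValidationError("train: sample weights must be finite and >= 0")

    rng = np.random.default_rng(config.seed + 1)
    train_idx, val_idx = _stratified_split(y_flag, config.val_fraction, rng)

    mean = X[train_idx].mean(axis=0)
    std = X[train_idx].std(axis=0)
    std[std < 1e-8] = 1.0
    net.scaler_mean, net.scaler_std = mean, std
    Xs = (X - mean) / std

    if config.pos_weight == "auto":
        n_pos = int((y_flag[train_idx] == 1).sum())
        n_neg = len(train_idx) - n_pos
        pos_weight = min(n_neg / max(n_pos, 1), 50.0)
    else:
        pos_weight = float(config.pos_weight)

    params = net.params
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v_) for k, v_ in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    best_val = np.inf
    best_params = {k: p.copy() for k, p in params.items()}
    epochs_since_best = 0
    net.training_history = []

    Xv, yv, cv, wv = Xs[val_idx], y_flag[val_idx], y_class[val_idx], sample_weights[val_idx]
    Xt, yt, ct, wt = Xs[train_idx], y_flag[train_idx], y_class[train_idx], sample_weights[train_idx]

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(Xt))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            cache = _forward(params, Xt[batch])
            bce, cce, l1 = _loss_terms(cache, yt[batch], ct[batch], wt[batch],
                                       params, config, pos_weight)
            loss = config.loss_weights[0] * bce + config.loss_weights[1] * cce + l1
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite training loss at epoch {epoch}, batch offset {start}")
            grads = _backward(cache, yt[batch], ct[batch], wt[batch],
                              params, config, pos_weight)
            step += 1
            lr_t = config.learning_rate * np.sqrt(1 - beta2 ** step) / (1 - beta1 ** step)
            for k in params:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                params[k] -= lr_t * m[k] / (np.sqrt(v[k]) + eps)
            epoch_loss += loss
            n_batches += 1

        val_cache = _forward(params, Xv)
        vb, vc, vl = _loss_terms(val_cache, yv, cv, wv, params, config, pos_weight)
        val_loss = config.loss_weights[0] * vb + config.loss_weights[1] * vc + vl
        net.training_history.append({
            "epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1),
            "val_loss": val_loss,
        })
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_params = {k: p.copy() for k, p in params.items()}
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= config.patience:
                break

    net.params = best_params
    return net


def predict(net: MealNet, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Detection probability and 5-way class probabilities per row.

    Accepts one feature vector or a batch; row order is preserved.
    """
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != net.config.input_dim:
        raise ValidationError(
            f"predict: expected {net.config.input_dim} features, got {X.shape[1]}")
    if net.scaler_mean is not None:
        X = (X - net.scaler_mean) / net.scaler_std
    cache = _forward(net.params, X)
    p, probs = cache["p"], cache["probs"]
    if single:
        return float(p[0]), probs[0]
    return p, probs
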