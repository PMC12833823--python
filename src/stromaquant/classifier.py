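"""Ten-class convolutional patch classifier.

A compact CNN — three 3x3 convolution blocks with 2x2 max pooling, global
average pooling, and a linear softmax head — trained from scratch with
plain stochastic gradient descent under a per-batch exponential
learning-rate decay. The network is small enough to train on one CPU in
minutes on the synthetic patch benchmark while exercising the same
mechanism as a full-scale backbone: tile-level tissue classification with
confidence scores, confusion-matrix/kappa evaluation, and penultimate-layer
embeddings.

All tensors are float32 numpy arrays; convolutions are im2col matrix
products, so the heavy lifting runs in BLAS and training is bit-for-bit
reproducible for a fixed seed on one machine.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .synthetic import CLASS_NAMES


@dataclass(frozen=True)
class ClassifierConfig:
    preset: str = "compact"  # "backbone-transfer" is a documented extension point
    input_size: int = 64
    channels: tuple[int, ...] = (8, 16, 32)
    batch_size: int = 160
    learning_rate: float = 0.01
    lr_decay_per_batch: float = 0.9999
    epochs: int = 50
    momentum: float = 0.9
    seed: int = 0
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not 0 < self.lr_decay_per_batch <= 1:
            raise ValueError("lr decay must lie in (0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


# ---------------------------------------------------------------- layers

def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, H, W, C) -> (N*H*W, 9C) patches of the zero-padded input."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    # win: (N, H, W, C, 3, 3) -> (N*H*W, 3*3*C)
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(n * h * w, 9 * c)


def _col2im(dcols: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    n, h, w, c = shape
    d = dcols.reshape(n, h, w, 3, 3, c)
    dxp = np.zeros((n, h + 2, w + 2, c), dtype=dcols.dtype)
    for ky in range(3):
        for kx in range(3):
            dxp[:, ky : ky + h, kx : kx + w, :] += d[:, :, :, ky, kx, :]
    return dxp[:, 1 : 1 + h, 1 : 1 + w, :]


class _Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        scale = np.sqrt(2.0 / (9 * c_in))  # He initialization
        self.w = (rng.standard_normal((9 * c_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._cols = _im2col(x)
        n, h, w, _ = x.shape
        return (self._cols @ self.w + self.b).reshape(n, h, w, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy_flat = dy.reshape(-1, dy.shape[-1])
        self.dw = self._cols.T @ dy_flat
        self.db = dy_flat.sum(axis=0)
        return _col2im(dy_flat @ self.w.T, self._shape)

    params = ("w", "b")


class _BatchNorm:
    """Per-channel batch normalization over (N, H, W) with running stats."""

    def __init__(self, c: int) -> None:
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self.training = True
        self.frozen = False  # train with running stats (inference normalization)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training and not self.frozen:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.run_mean = 0.9 * self.run_mean + 0.1 * mean.astype(np.float32)
            self.run_var = 0.9 * self.run_var + 0.1 * var.astype(np.float32)
            if getattr(self, "_calibrating", False):
                m = x.shape[0] * x.shape[1] * x.shape[2]
                self._acc_n += m
                self._acc_sum += x.sum(axis=(0, 1, 2))
                self._acc_sumsq += (x.astype(np.float64) ** 2).sum(axis=(0, 1, 2))
        else:
            mean, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + 1e-5).astype(np.float32)
        self._xhat = ((x - mean) / self._std).astype(np.float32)
        return self.gamma * self._xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes = (0, 1, 2)
        m = dy.shape[0] * dy.shape[1] * dy.shape[2]
        self.dgamma = (dy * self._xhat).sum(axis=axes)
        self.dbeta = dy.sum(axis=axes)
        dxhat = dy * self.gamma
        if self.frozen:  # fixed statistics: no batch coupling in the gradient
            return (dxhat / self._std).astype(np.float32)
        dx = (
            dxhat
            - dxhat.mean(axis=axes)
            - self._xhat * (dxhat * self._xhat).sum(axis=axes) / m
        ) / self._std
        return dx.astype(np.float32)

    def start_calibration(self) -> None:
        c = len(self.gamma)
        self._calibrating = True
        self._acc_n = 0
        self._acc_sum = np.zeros(c, dtype=np.float64)
        self._acc_sumsq = np.zeros(c, dtype=np.float64)

    def finish_calibration(self) -> None:
        mean = self._acc_sum / self._acc_n
        self.run_mean = mean.astype(np.float32)
        self.run_var = (self._acc_sumsq / self._acc_n - mean**2).astype(np.float32)
        self._calibrating = False

    params = ("gamma", "beta")


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    params = ()


class _MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        x4 = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        x4 = np.ascontiguousarray(x4).reshape(n, h // 2, w // 2, c, 4)
        self._idx = x4.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(x4, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        d4 = np.zeros((n, h // 2, w // 2, c, 4), dtype=dy.dtype)
        np.put_along_axis(d4, self._idx[..., None], dy[..., None], axis=-1)
        d = d4.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(d).reshape(n, h, w, c)

    params = ()


class _GlobalAvgPool:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :] / (h * w), self._shape).astype(dy.dtype)

    params = ()


class _Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        scale = np.sqrt(2.0 / d_in)
        self.w = (rng.standard_normal((d_in, d_out)) * scale).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.w.T

    params = ("w", "b")


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ----------------------------------------------------------------- model

@dataclass
class TrainedClassifier:
    layers: list
    config: ClassifierConfig
    class_names: tuple[str, ...]
    history: list[dict] = field(default_factory=list)  # per-epoch loss/accuracy
    lr_schedule: list[float] = field(default_factory=list)  # lr at each step

    def _forward(self, x: np.ndarray, upto: int | None = None) -> np.ndarray:
        for layer in self.layers[:upto]:
            x = layer.forward(x)
        return x

    def _set_training(self, training: bool) -> None:
        for layer in self.layers:
            if hasattr(layer, "training"):
                layer.training = training

    def predict_proba(self, patches: np.ndarray, batch_size: int = 256) -> np.ndarray:
        self._set_training(False)
        x = _prepare(patches, self.config.input_size)
        out = [
            _softmax(self._forward(x[i : i + batch_size]))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(out) if out else np.empty((0, len(self.class_names)))

    def embed(self, patches: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Penultimate (global-average-pool) features, one row per patch."""
        self._set_training(False)
        x = _prepare(patches, self.config.input_size)
        out = [
            self._forward(x[i : i + batch_size], upto=-1)
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(out)

    def save(self, path: str) -> None:
        arrays = {}
        for i, layer in enumerate(self.layers):
            for p in layer.params:
                arrays[f"layer{i}_{p}"] = getattr(layer, p)
            for p in ("run_mean", "run_var"):
                if hasattr(layer, p):
                    arrays[f"layer{i}_{p}"] = getattr(layer, p)
        meta = {
            "config": {**asdict(self.config), "channels": list(self.config.channels),
                       "class_names": list(self.config.class_names)},
            "class_names": list(self.class_names),
            "history": self.history,
        }
        np.savez_compressed(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> "TrainedClassifier":
        data = np.load(path)
        meta = json.loads(bytes(data["_meta"]).decode())
        cfg_d = meta["config"]
        cfg_d["channels"] = tuple(cfg_d["channels"])
        cfg_d["class_names"] = tuple(cfg_d["class_names"])
        config = ClassifierConfig(**cfg_d)
        model = _build(config)
        for i, layer in enumerate(model.layers):
            for p in layer.params:
                setattr(layer, p, data[f"layer{i}_{p}"])
            for p in ("run_mean", "run_var"):
                if f"layer{i}_{p}" in data:
                    setattr(layer, p, data[f"layer{i}_{p}"])
        model.history = meta["history"]
        return model


def _prepare(patches: np.ndarray, input_size: int) -> np.ndarray:
    x = np.asarray(patches, dtype=np.float32)
    if x.ndim != 4 or x.shape[3] != 3:
        raise ValueError("patches must have shape (N, H, W, 3)")
    if x.shape[1] != input_size or x.shape[2] != input_size:
        raise ValueError(f"patches must be {input_size}x{input_size}")
    return x / 255.0 - 0.5


def _build(config: ClassifierConfig) -> TrainedClassifier:
    if config.preset != "compact":
        raise NotImplementedError(
            "only the 'compact' preset is implemented; 'backbone-transfer' "
            "(224px input over a pretrained backbone) is an extension point"
        )
    rng = np.random.default_rng(config.seed)
    layers: list = []
    c_in = 3
    for c_out in config.channels:
        layers += [_Conv3x3(c_in, c_out, rng), _BatchNorm(c_out), _ReLU(), _MaxPool2()]
        c_in = c_out
    layers += [_GlobalAvgPool(), _Linear(c_in, len(config.class_names), rng)]
    return TrainedClassifier(layers=layers, config=config, class_names=config.class_names)


def train_classifier(
    patches: np.ndarray, labels: np.ndarray, config: ClassifierConfig
) -> TrainedClassifier:
    """Train the compact CNN by mini-batch SGD with exponential lr decay.

    The learning rate at optimization step t is lr * decay**t. Raises if
    any configured class is absent from the training labels.
    """
    labels = np.asarray(labels, dtype=np.int64)
    present = set(np.unique(labels).tolist())
    missing = [c for i, c in enumerate(config.class_names) if i not in present]
    if missing:
        raise ValueError(f"classes absent from training data: {missing}")

    model = _build(config)
    model._set_training(True)
    x_all = _prepare(patches, config.input_size)
    n = len(x_all)
    rng = np.random.default_rng(config.seed + 1)
    bn_layers = [l for l in model.layers if isinstance(l, _BatchNorm)]

    def calibrate() -> None:
        # replace EMA batch-norm statistics with exact full-pass moments so
        # inference does not depend on how many steps updated the averages
        for layer in bn_layers:
            layer.start_calibration()
        for start in range(0, n, 256):
            model._forward(x_all[start : start + 256])
        for layer in bn_layers:
            layer.finish_calibration()

    velocity = {}
    step = 0
    for epoch in range(config.epochs):
        if config.epochs > 1 and epoch == config.epochs - 1:
            # final epoch trains under inference-time normalization (frozen
            # running statistics), closing the batch-vs-population stats gap
            calibrate()
            for layer in bn_layers:
                layer.frozen = True
        order = rng.permutation(n)
        epoch_loss, epoch_correct = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            x, y = x_all[idx], labels[idx]
            logits = model._forward(x)
            probs = _softmax(logits)
            epoch_loss += -np.log(np.maximum(probs[np.arange(len(y)), y], 1e-12)).sum()
            epoch_correct += int((probs.argmax(axis=1) == y).sum())
            grad = probs.copy()
            grad[np.arange(len(y)), y] -= 1.0
            grad = (grad / len(y)).astype(np.float32)
            for layer in reversed(model.layers):
                grad = layer.backward(grad)
            lr = config.learning_rate * config.lr_decay_per_batch**step
            model.lr_schedule.append(lr)
            for li, layer in enumerate(model.layers):
                for p in layer.params:
                    g = getattr(layer, "d" + p)
                    v = velocity.get((li, p), 0.0)
                    v = config.momentum * v - lr * g
                    velocity[(li, p)] = v
                    setattr(layer, p, getattr(layer, p) + v)
            step += 1
        model.history.append(
            {"epoch": epoch, "loss": float(epoch_loss / n), "accuracy": epoch_correct / n}
        )
    if config.epochs == 1:  # no frozen epoch ran; still fix exact moments
        calibrate()
    for layer in bn_layers:
        layer.frozen = False
    model._set_training(False)
    return model


def predict_patches(
    model: TrainedClassifier, patches: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-patch predicted class index and full confidence vector.

    The class is the argmax of the softmax confidences; ties resolve to the
    lowest class index.
    """
    probs = model.predict_proba(patches)
    return probs.argmax(axis=1), probs


def extract_embeddings(model: TrainedClassifier, patches: np.ndarray) -> np.ndarray:
    return model.embed(patches)


# ------------------------------------------------------------ evaluation

@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # (k, k), rows = truth, cols = prediction
    class_names: tuple[str, ...]
    per_class_accuracy: np.ndarray  # row-normalized diagonal
    accuracy: float  # observed agreement p_o
    p_e: float  # chance agreement from marginal products
    kappa: float  # NaN when p_e == 1 (single class in both margins)


def evaluate(
    truth: np.ndarray, predicted: np.ndarray, class_names: tuple[str, ...] = CLASS_NAMES
) -> ConfusionMatrix:
    """Confusion matrix, per-class accuracy, and Cohen's kappa.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement p_e computed from
    the products of the row and column marginals.
    """
    truth = np.asarray(truth, dtype=np.int64)
    predicted = np.asarray(predicted, dtype=np.int64)
    if truth.shape != predicted.shape:
        raise ValueError("truth and prediction lengths differ")
    k = len(class_names)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (truth, predicted), 1)
    n = counts.sum()
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(row > 0, np.diag(counts) / np.maximum(row, 1), np.nan)
    p_o = counts.trace() / n
    p_e = float((row * col).sum()) / n**2
    kappa = np.nan if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return ConfusionMatrix(
        counts=counts,
        class_names=tuple(class_names),
        per_class_accuracy=per_class,
        accuracy=float(p_o),
        p_e=p_e,
        kappa=float(kappa),
    )
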