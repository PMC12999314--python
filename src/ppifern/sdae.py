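"""Stacked denoising autoencoder (SDAE) representation learning.

Each layer is a denoising autoencoder: the input is stochastically
corrupted, encoded as h = sigmoid(We x + be) and decoded as
y = sigmoid(Wd h + bd), with mean-squared reconstruction error against the
*clean* input as the training objective.  Layers are pretrained greedily
(each on the clean encodings of the previous stack), then a softmax
classification head is attached and the encoder weights are fine-tuned
end-to-end by cross-entropy.  At inference only the encoder path is used,
with no corruption; encodings therefore lie in (0, 1).

Training is plain seeded mini-batch gradient descent with a fixed learning
rate: dependency-light and bitwise-reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # Clipped for overflow safety; keeps outputs strictly inside (0, 1).
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


@dataclass(frozen=True)
class CorruptionSpec:
    """Stochastic input corruption applied before encoding during training.

    ``masking`` zeroes a uniformly random floor(rate * dim) subset of
    coordinates per sample; ``additive_gaussian`` adds i.i.d. Normal(0,
    rate^2) noise (``rate`` is the standard deviation in that case).
    """

    kind: str = "masking"
    rate: float = 0.3

    def __post_init__(self) -> None:
        if self.kind not in ("masking", "additive_gaussian"):
            raise ValueError(f"unknown corruption kind {self.kind!r}")
        if self.kind == "masking" and not 0.0 <= self.rate <= 1.0:
            raise ValueError("masking rate must be in [0, 1]")
        if self.kind == "additive_gaussian" and self.rate < 0:
            raise ValueError("gaussian sigma must be >= 0")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "rate": self.rate}

    @classmethod
    def from_dict(cls, d: Mapping) -> "CorruptionSpec":
        return cls(**dict(d))


@dataclass(frozen=True)
class SDAEConfig:
    layer_dims: tuple[int, ...] = (512, 256, 128)
    corruption: CorruptionSpec = field(default_factory=CorruptionSpec)
    epochs_pretrain: int = 15
    epochs_finetune: int = 100
    learning_rate: float = 0.5
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.layer_dims)
        if not dims or any(d <= 0 for d in dims):
            raise ValueError("layer_dims must be non-empty and strictly positive")
        object.__setattr__(self, "layer_dims", dims)
        if self.epochs_pretrain < 0 or self.epochs_finetune < 0:
            raise ValueError("epoch counts must be >= 0")
        if self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate and batch_size must be positive")

    def to_dict(self) -> dict:
        return {
            "layer_dims": list(self.layer_dims),
            "corruption": self.corruption.to_dict(),
            "epochs_pretrain": self.epochs_pretrain,
            "epochs_finetune": self.epochs_finetune,
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SDAEConfig":
        d = dict(d)
        d["corruption"] = CorruptionSpec.from_dict(d["corruption"])
        d["layer_dims"] = tuple(d["layer_dims"])
        return cls(**d)


@dataclass
class LayerParams:
    """Untied encoder/decoder parameters of one denoising autoencoder."""

    we: np.ndarray  # (out_dim, in_dim)
    be: np.ndarray  # (out_dim,)
    wd: np.ndarray  # (in_dim, out_dim)
    bd: np.ndarray  # (in_dim,)

    def __post_init__(self) -> None:
        out_dim, in_dim = self.we.shape
        if self.be.shape != (out_dim,) or self.wd.shape != (in_dim, out_dim) \
                or self.bd.shape != (in_dim,):
            raise ValueError("inconsistent layer parameter shapes")
        for arr in (self.we, self.be, self.wd, self.bd):
            if not np.isfinite(arr).all():
                raise ValueError("non-finite layer parameters")

    @property
    def in_dim(self) -> int:
        return self.we.shape[1]

    @property
    def out_dim(self) -> int:
        return self.we.shape[0]


@dataclass
class SDAEModel:
    """An ordered encoder stack plus an optional softmax classification head."""

    layers: list[LayerParams]
    config: SDAEConfig
    input_dim: int
    head_w: np.ndarray | None = None  # (2, last_dim)
    head_b: np.ndarray | None = None  # (2,)

    def __post_init__(self) -> None:
        dim = self.input_dim
        for i, layer in enumerate(self.layers):
            if layer.in_dim != dim:
                raise ValueError(
                    f"layer {i}: input dim {layer.in_dim} != expected {dim}"
                )
            dim = layer.out_dim

    @property
    def output_dim(self) -> int:
        return self.layers[-1].out_dim if self.layers else self.input_dim

    def to_dict(self) -> dict:
        return {
            "input_dim": self.input_dim,
            "config": self.config.to_dict(),
            "layers": [
                {
                    "we": layer.we.tolist(),
                    "be": layer.be.tolist(),
                    "wd": layer.wd.tolist(),
                    "bd": layer.bd.tolist(),
                }
                for layer in self.layers
            ],
            "head_w": self.head_w.tolist() if self.head_w is not None else None,
            "head_b": self.head_b.tolist() if self.head_b is not None else None,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SDAEModel":
        layers = [
            LayerParams(
                we=np.asarray(ld["we"], dtype=float),
                be=np.asarray(ld["be"], dtype=float),
                wd=np.asarray(ld["wd"], dtype=float),
                bd=np.asarray(ld["bd"], dtype=float),
            )
            for ld in d["layers"]
        ]
        return cls(
            layers=layers,
            config=SDAEConfig.from_dict(d["config"]),
            input_dim=int(d["input_dim"]),
            head_w=np.asarray(d["head_w"], dtype=float) if d.get("head_w") is not None else None,
            head_b=np.asarray(d["head_b"], dtype=float) if d.get("head_b") is not None else None,
        )


# ---------------------------------------------------------------------------
# Elementary operations


def corrupt(
    x: np.ndarray, spec: CorruptionSpec, rng: np.random.Generator
) -> np.ndarray:
    """Corrupt a vector or a batch of row vectors.

    Masking zeroes exactly floor(rate * dim) uniformly chosen coordinates
    per sample; additive Gaussian adds Normal(0, rate^2) noise.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("input to corrupt() must be finite")
    batch = x if x.ndim == 2 else x[None, :]
    if spec.kind == "masking":
        dim = batch.shape[1]
        n_mask = int(np.floor(spec.rate * dim))
        out = batch.copy()
        if n_mask > 0:
            # Per-row uniformly random subset without replacement.
            order = np.argsort(rng.random(batch.shape), axis=1)
            rows = np.repeat(np.arange(batch.shape[0]), n_mask)
            cols = order[:, :n_mask].ravel()
            out[rows, cols] = 0.0
    else:
        out = batch + rng.normal(0.0, spec.rate, size=batch.shape)
    return out if x.ndim == 2 else out[0]


def encode_layer(x: np.ndarray, layer: LayerParams) -> np.ndarray:
    """h = sigmoid(We x + be); accepts a vector or a batch of rows."""
    x = np.asarray(x, dtype=float)
    return _sigmoid(x @ layer.we.T + layer.be)


def decode_layer(h: np.ndarray, layer: LayerParams) -> np.ndarray:
    """y = sigmoid(Wd h + bd); accepts a vector or a batch of rows."""
    h = np.asarray(h, dtype=float)
    return _sigmoid(h @ layer.wd.T + layer.bd)


def reconstruction_loss(x: np.ndarray, y: np.ndarray) -> float:
    """Mean squared error (1/n) sum (x_i - y_i)^2 over the last axis, averaged
    over the batch if given one."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("shape mismatch in reconstruction_loss")
    return float(np.mean((x - y) ** 2))


def _init_layer(in_dim: int, out_dim: int, rng: np.random.Generator) -> LayerParams:
    # Glorot-style uniform range keeps the sigmoid pre-activations in the
    # responsive region at the start of training.
    r_e = np.sqrt(6.0 / (in_dim + out_dim))
    return LayerParams(
        we=rng.uniform(-r_e, r_e, size=(out_dim, in_dim)),
        be=np.zeros(out_dim),
        wd=rng.uniform(-r_e, r_e, size=(in_dim, out_dim)),
        bd=np.zeros(in_dim),
    )


# ---------------------------------------------------------------------------
# Training


def train_dae(
    data: np.ndarray,
    in_dim: int,
    out_dim: int,
    config: SDAEConfig,
    rng: np.random.Generator,
) -> tuple[LayerParams, list[float]]:
    """Train one denoising autoencoder layer; returns (params, per-epoch loss).

    Minimizes mean reconstruction error of the clean input from the
    corrupted one by mini-batch gradient descent.  Deterministic for a
    given generator state.
    """
    data = np.asarray(data, dtype=float)
    if data.size == 0:
        raise ValueError("training data must be non-empty")
    if data.shape[1] != in_dim:
        raise ValueError(f"data has {data.shape[1]} columns, expected {in_dim}")
    layer = _init_layer(in_dim, out_dim, rng)
    n = data.shape[0]
    lr = config.learning_rate
    epoch_losses: list[float] = []
    for _ in range(config.epochs_pretrain):
        order = rng.permutation(n)
        total, count = 0.0, 0
        for start in range(0, n, config.batch_size):
            X = data[order[start:start + config.batch_size]]
            Xc = corrupt(X, config.corruption, rng)
            H = encode_layer(Xc, layer)
            Y = decode_layer(H, layer)
            B = X.shape[0]
            loss = reconstruction_loss(X, Y)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite reconstruction loss at epoch {len(epoch_losses)}; "
                    f"lr={lr}, batch={B}"
                )
            total += loss * B
            count += B
            # Backprop through decode(encode(corrupt(x))) against clean x.
            dY = 2.0 * (Y - X) / (B * in_dim)
            dZd = dY * Y * (1.0 - Y)
            dWd = dZd.T @ H
            dbd = dZd.sum(axis=0)
            dH = dZd @ layer.wd
            dZe = dH * H * (1.0 - H)
            dWe = dZe.T @ Xc
            dbe = dZe.sum(axis=0)
            layer.we -= lr * dWe
            layer.be -= lr * dbe
            layer.wd -= lr * dWd
            layer.bd -= lr * dbd
        epoch_losses.append(total / count)
    return layer, epoch_losses


def pretrain(
    data: np.ndarray, config: SDAEConfig, rng: np.random.Generator | None = None
) -> SDAEModel:
    """Greedy layer-wise pretraining: layer k trains on the clean encodings
    produced by layers 1..k-1 over the training set."""
    data = np.asarray(data, dtype=float)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    layers: list[LayerParams] = []
    current = data
    in_dim = data.shape[1]
    for out_dim in config.layer_dims:
        layer, _ = train_dae(current, in_dim, out_dim, config, rng)
        layers.append(layer)
        current = encode_layer(current, layer)
        in_dim = out_dim
    return SDAEModel(layers=layers, config=config, input_dim=data.shape[1])


def fine_tune(
    model: SDAEModel,
    data: np.ndarray,
    labels: np.ndarray,
    config: SDAEConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SDAEModel:
    """Attach a softmax head and fine-tune it jointly with every encoder
    layer by cross-entropy gradient descent.  Decoder weights are retained
    untouched.  Returns a new model; the input model is not modified."""
    if config is None:
        config = model.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    data = np.asarray(data, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(
            f"fine-tuning requires both binary classes present, got {classes}"
        )

    layers = [
        LayerParams(
            we=l.we.copy(), be=l.be.copy(), wd=l.wd.copy(), bd=l.bd.copy()
        )
        for l in model.layers
    ]
    d_last = layers[-1].out_dim if layers else model.input_dim
    r = np.sqrt(6.0 / (d_last + 2))
    head_w = rng.uniform(-r, r, size=(2, d_last))
    head_b = np.zeros(2)

    n = data.shape[0]
    lr = config.learning_rate
    onehot = np.eye(2)[labels]
    for _ in range(config.epochs_finetune):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            X = data[idx]
            T = onehot[idx]
            B = X.shape[0]
            # Forward through the encoder stack.
            activations = [X]
            for layer in layers:
                activations.append(encode_layer(activations[-1], layer))
            Z = activations[-1] @ head_w.T + head_b
            Z -= Z.max(axis=1, keepdims=True)
            expZ = np.exp(Z)
            P = expZ / expZ.sum(axis=1, keepdims=True)
            # Softmax + cross-entropy gradient.
            dZ = (P - T) / B
            dW = dZ.T @ activations[-1]
            db = dZ.sum(axis=0)
            dA = dZ @ head_w
            head_w -= lr * dW
            head_b -= lr * db
            for k in range(len(layers) - 1, -1, -1):
                H = activations[k + 1]
                dZe = dA * H * (1.0 - H)
                dWe = dZe.T @ activations[k]
                dbe = dZe.sum(axis=0)
                dA = dZe @ layers[k].we
                layers[k].we -= lr * dWe
                layers[k].be -= lr * dbe
    return SDAEModel(
        layers=layers,
        config=config,
        input_dim=model.input_dim,
        head_w=head_w,
        head_b=head_b,
    )


def encode(model: SDAEModel, x: np.ndarray) -> np.ndarray:
    """Deterministic deep feature: the composition of all encoder layers.

    No corruption is applied and the classification head is NOT applied;
    output dimension equals the last hidden size, entries in (0, 1).
    """
    out = np.asarray(x, dtype=float)
    for layer in model.layers:
        out = encode_layer(out, layer)
    return out


def head_predict_proba(model: SDAEModel, x: np.ndarray) -> np.ndarray:
    """Class probabilities from the fine-tuned softmax head (diagnostic use)."""
    if model.head_w is None:
        raise ValueError("model has no classification head; call fine_tune first")
    h = encode(model, x)
    z = h @ model.head_w.T + model.head_b
    z -= z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
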