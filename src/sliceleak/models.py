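"""Classifier specifications and the desk-scale surrogate CNN.

Three transfer-learning architectures are captured as declarative
:class:`ModelSpec` values (two VGG16 variants differing in freeze policy
and head, and a ResNet-18 with a sigmoid unit appended); building them
requires pretrained backbone weights, which are an optional runtime
dependency — requesting one without weights raises
:class:`~sliceleak.errors.UnavailableWeightsError`.

The ``small_cnn`` family is a self-contained surrogate that trains in
seconds on a CPU: a 2x2 average-pool stem, two 3x3 convolution + ReLU +
2x2 max-pool blocks, global average pooling and one sigmoid unit, written
in NumPy with im2col convolutions, Xavier initialization and an Adam
optimizer.  Its job in the leakage experiments is not to be a good
diagnostic model but to have enough capacity to memorize subject identity
from slice appearance — the capacity that turns a slice-level split into
an inflated score.

Training uses sigmoid cross-entropy loss and the inverse-time learning
rate schedule ``lr_t = lr / (1 + decay * t)`` with ``t`` the 0-based epoch
index, so ``decay = 0`` keeps the rate constant.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, InputError, TrainingError, UnavailableWeightsError
from .preprocess import SliceRecord

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "SmallCNNClassifier",
    "SmallCNNFactory",
    "ConstantClassifier",
    "SubjectLookupClassifier",
    "BaselineFactory",
    "build_model",
    "train",
    "evaluate",
    "save_checkpoint",
    "load_checkpoint",
]

_FAMILY_CONSTRAINTS = {
    # family: (freeze_policy, head); None means unconstrained
    "vgg16_v1": ("freeze_all_but_head", "three_fc_relu"),
    "vgg16_v2": ("finetune_all", "gap_head"),
    "resnet18": ("finetune_all", "fc_sigmoid"),
    "small_cnn": (None, None),
}
_TRANSFER_FAMILIES = ("vgg16_v1", "vgg16_v2", "resnet18")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of a binary slice classifier.

    ``vgg16_v1`` freezes the convolutional backbone and fine-tunes only a
    three-layer ReLU fully-connected head; ``vgg16_v2`` replaces the head
    with global average pooling and fine-tunes everything; ``resnet18``
    appends a single sigmoid unit and fine-tunes all transferred layers.
    Newly added layers are Xavier-initialized in every family.
    """

    family: str = "small_cnn"
    input_size: tuple[int, int] = (64, 64)
    freeze_policy: str = "finetune_all"
    head: str = "gap_head"
    new_layer_init: str = "xavier"
    channels: tuple[int, int] = (8, 32)  # small_cnn only

    def __post_init__(self) -> None:
        if self.family not in _FAMILY_CONSTRAINTS:
            raise ConfigurationError(f"unknown model family {self.family!r}")
        want_freeze, want_head = _FAMILY_CONSTRAINTS[self.family]
        if want_freeze is not None and self.freeze_policy != want_freeze:
            raise ConfigurationError(
                f"{self.family} requires freeze_policy={want_freeze!r}, "
                f"got {self.freeze_policy!r}"
            )
        if want_head is not None and self.head != want_head:
            raise ConfigurationError(
                f"{self.family} requires head={want_head!r}, got {self.head!r}"
            )
        if self.new_layer_init != "xavier":
            raise ConfigurationError("only Xavier initialization is supported")

    @staticmethod
    def vgg16_v1(input_size: tuple[int, int] = (224, 224)) -> "ModelSpec":
        return ModelSpec(
            family="vgg16_v1",
            input_size=input_size,
            freeze_policy="freeze_all_but_head",
            head="three_fc_relu",
        )

    @staticmethod
    def vgg16_v2(input_size: tuple[int, int] = (224, 224)) -> "ModelSpec":
        return ModelSpec(
            family="vgg16_v2",
            input_size=input_size,
            freeze_policy="finetune_all",
            head="gap_head",
        )

    @staticmethod
    def resnet18(input_size: tuple[int, int] = (224, 224)) -> "ModelSpec":
        return ModelSpec(
            family="resnet18",
            input_size=input_size,
            freeze_policy="finetune_all",
            head="fc_sigmoid",
        )

    @staticmethod
    def small_cnn(
        input_size: tuple[int, int] = (64, 64), channels: tuple[int, int] = (8, 32)
    ) -> "ModelSpec":
        return ModelSpec(
            family="small_cnn",
            input_size=input_size,
            freeze_policy="finetune_all",
            head="gap_head",
            channels=channels,
        )


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults mirror the full-scale protocol."""

    batch_size: int = 128
    epochs: int = 50
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    decay: float = 0.0
    weight_seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size <= 0:
            raise ConfigurationError("batch_size must be positive")
        if self.epochs <= 0:
            raise ConfigurationError("epochs must be positive")
        if self.optimizer != "adam":
            raise ConfigurationError("only the adam optimizer is supported")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.decay < 0:
            raise ConfigurationError("decay must be nonnegative")

    def learning_rate_at(self, epoch: int) -> float:
        """Inverse-time schedule: lr / (1 + decay * epoch), epoch 0-based."""
        return self.learning_rate / (1.0 + self.decay * epoch)


# ---------------------------------------------------------------------------
# NumPy small CNN internals


def _im2col3x3(x: np.ndarray) -> np.ndarray:
    """(N, C, h, w) -> (N, C*9, h*w) patch matrix for a padded 3x3 conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((n, c, 9, h * w), dtype=x.dtype)
    for q, (dy, dx) in enumerate((i, j) for i in range(3) for j in range(3)):
        cols[:, :, q] = xp[:, :, dy : dy + h, dx : dx + w].reshape(n, c, h * w)
    return cols.reshape(n, c * 9, h * w)


def _col2im3x3(dcols: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    n, c, h, w = shape
    d = dcols.reshape(n, c, 3, 3, h, w)
    gp = np.zeros((n, c, h + 2, w + 2), dtype=dcols.dtype)
    for dy in range(3):
        for dx in range(3):
            gp[:, :, dy : dy + h, dx : dx + w] += d[:, :, dy, dx]
    return gp[:, :, 1 : 1 + h, 1 : 1 + w]


def _maxpool2(x: np.ndarray) -> np.ndarray:
    """2x2 max pooling over strided views (no window copy)."""
    a = np.maximum(x[:, :, 0::2, 0::2], x[:, :, 0::2, 1::2])
    b = np.maximum(x[:, :, 1::2, 0::2], x[:, :, 1::2, 1::2])
    return np.maximum(a, b)


def _maxpool2_backward(dout: np.ndarray, x: np.ndarray, out: np.ndarray) -> np.ndarray:
    # subgradient: tied maxima each receive the full upstream gradient
    dx = np.zeros_like(x)
    for sy in (0, 1):
        for sx in (0, 1):
            view = x[:, :, sy::2, sx::2]
            dx[:, :, sy::2, sx::2] = np.where(view == out, dout, 0.0)
    return dx


def _xavier(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class _SmallCNNNet:
    """Parameter container and forward/backward pass of the surrogate CNN.

    The head averages the last feature maps over a coarse ``pool_grid`` x
    ``pool_grid`` spatial grid before the sigmoid unit (``pool_grid=1`` is
    plain global average pooling).  The default 4x4 grid keeps some
    spatial layout in the features: with full GAP the net has too little
    representational room to memorize which subject a slice came from,
    which is precisely the capacity the leakage experiments exercise.
    """

    def __init__(
        self,
        input_size: tuple[int, int],
        channels: tuple[int, int],
        seed: int,
        pool_grid: int = 4,
    ):
        h, w = input_size
        if h % 8 or w % 8:
            raise ConfigurationError(
                f"small_cnn input size must be divisible by 8, got {input_size!r}"
            )
        c1, c2 = channels
        hf, wf = h // 8, w // 8  # feature map size after stem + two pool blocks
        pool_grid = min(pool_grid, hf, wf)  # small inputs fall back to coarser heads
        if hf % pool_grid or wf % pool_grid:
            raise ConfigurationError(
                f"head pool grid {pool_grid} must divide the {hf}x{wf} feature map"
            )
        rng = np.random.default_rng(seed)
        self.input_size = (h, w)
        self.channels = (c1, c2)
        self.pool_grid = pool_grid
        n_feat = c2 * pool_grid * pool_grid
        self.params = {
            "W1": _xavier(rng, (c1, 9), fan_in=9, fan_out=c1 * 9),
            "b1": np.zeros(c1, dtype=np.float32),
            "W2": _xavier(rng, (c2, c1 * 9), fan_in=c1 * 9, fan_out=c2 * 9),
            "b2": np.zeros(c2, dtype=np.float32),
            "wd": _xavier(rng, (n_feat,), fan_in=n_feat, fan_out=1),
            "bd": np.zeros((), dtype=np.float32),
        }

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def stem(self, x: np.ndarray) -> np.ndarray:
        """Parameter-free front: 2x2 average pool + layer-1 patch matrix.

        Depends only on the input, so the training loop computes it once
        per dataset and slices batches out of it.
        """
        n, h, w = x.shape
        x0 = x.reshape(n, 1, h // 2, 2, w // 2, 2).mean(axis=(3, 5), dtype=np.float32)
        return _im2col3x3(x0)

    def forward_cols(self, cols1: np.ndarray, want_cache: bool = False):
        p = self.params
        n = cols1.shape[0]
        h1, w1 = self.input_size[0] // 2, self.input_size[1] // 2
        c1, c2 = self.channels
        z1 = (np.matmul(p["W1"][None], cols1) + p["b1"][None, :, None]).reshape(
            n, c1, h1, w1
        )
        a1 = np.maximum(z1, 0.0)
        p1 = _maxpool2(a1)
        cols2 = _im2col3x3(p1)
        h2, w2 = h1 // 2, w1 // 2
        z2 = (np.matmul(p["W2"][None], cols2) + p["b2"][None, :, None]).reshape(
            n, c2, h2, w2
        )
        a2 = np.maximum(z2, 0.0)
        p2 = _maxpool2(a2)
        g = self.pool_grid
        h3, w3 = p2.shape[2:]
        pooled = p2.reshape(n, c2, g, h3 // g, g, w3 // g).mean(
            axis=(3, 5), dtype=np.float32
        )
        feat = pooled.reshape(n, -1)
        logits = feat @ p["wd"] + p["bd"]
        if not want_cache:
            return logits
        cache = dict(
            cols1=cols1, z1=z1, a1=a1, p1=p1, cols2=cols2, z2=z2, a2=a2, p2=p2,
            feat=feat,
        )
        return logits, cache

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: (N, H, W) float32 -> logits (N,), optionally with backprop cache."""
        return self.forward_cols(self.stem(x), want_cache)

    def backward(self, dlogits: np.ndarray, cache: dict) -> dict:
        p = self.params
        n = dlogits.shape[0]
        c1, c2 = self.channels
        feat = cache["feat"]
        grads = {
            "wd": feat.T @ dlogits,
            "bd": np.asarray(dlogits.sum(), dtype=np.float32),
        }
        dfeat = dlogits[:, None] * p["wd"][None, :]
        g = self.pool_grid
        h3, w3 = cache["p2"].shape[2:]
        cell = (h3 // g) * (w3 // g)
        dpooled = (dfeat / cell).reshape(n, c2, g, 1, g, 1).astype(np.float32)
        dp2 = np.broadcast_to(dpooled, (n, c2, g, h3 // g, g, w3 // g)).reshape(
            cache["p2"].shape
        )
        da2 = _maxpool2_backward(dp2, cache["a2"], cache["p2"])
        dz2 = da2 * (cache["z2"] > 0)
        dz2f = dz2.reshape(n, c2, -1)
        grads["W2"] = np.einsum("ncp,nqp->cq", dz2f, cache["cols2"], optimize=True)
        grads["b2"] = dz2f.sum(axis=(0, 2))
        dcols2 = np.matmul(p["W2"].T[None], dz2f)
        dp1 = _col2im3x3(dcols2, cache["p1"].shape)
        da1 = _maxpool2_backward(dp1, cache["a1"], cache["p1"])
        dz1 = da1 * (cache["z1"] > 0)
        dz1f = dz1.reshape(n, c1, -1)
        grads["W1"] = np.einsum("ncp,nqp->cq", dz1f, cache["cols1"], optimize=True)
        grads["b1"] = dz1f.sum(axis=(0, 2))
        return grads


class _Adam:
    def __init__(self, params: dict, beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            g = grads[k].astype(np.float32)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= np.float32(lr) * mhat / (np.sqrt(vhat) + self.eps)


def _records_to_arrays(slices: Sequence[SliceRecord]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([np.asarray(s.pixels, dtype=np.float32) for s in slices])
    y = np.array([s.label for s in slices], dtype=np.float32)
    if not np.all(np.isfinite(x)):
        raise InputError("slice pixels contain non-finite values")
    return x, y


class SmallCNNClassifier:
    """Trainable surrogate CNN with the fit/predict contract of the CV engine.

    After :meth:`fit` (or :func:`train`), ``loss_trace_`` holds the mean
    per-epoch training loss and ``updates_`` the number of optimizer steps
    taken.
    """

    def __init__(self, spec: ModelSpec, config: Optional[TrainConfig] = None, seed: int = 0):
        if spec.family != "small_cnn":
            raise ConfigurationError("SmallCNNClassifier requires a small_cnn spec")
        self.spec = spec
        self.config = config if config is not None else TrainConfig()
        self.seed = seed
        self.net = _SmallCNNNet(spec.input_size, spec.channels, seed=seed)
        self.loss_trace_: list[float] = []
        self.updates_ = 0

    def fit(self, slices: Sequence[SliceRecord]) -> "SmallCNNClassifier":
        train(self, slices, self.config)
        return self

    def predict_proba(self, slices: Sequence[SliceRecord]) -> np.ndarray:
        x, _ = _records_to_arrays(slices)
        out = np.empty(len(slices), dtype=np.float64)
        for start in range(0, len(slices), 512):
            logits = self.net.forward(x[start : start + 512])
            out[start : start + 512] = 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
        return out

    def predict(self, slices: Sequence[SliceRecord]) -> np.ndarray:
        return (self.predict_proba(slices) >= 0.5).astype(int)


def build_model(
    spec: ModelSpec, seed: int = 0, config: Optional[TrainConfig] = None
):
    """Instantiate a classifier from its spec.

    ``small_cnn`` is built from scratch with Xavier-initialized weights
    drawn from ``seed``.  The transfer families need pretrained backbone
    weights, which this package does not bundle or download; requesting
    one raises :class:`UnavailableWeightsError`.
    """
    if spec.family in _TRANSFER_FAMILIES:
        raise UnavailableWeightsError(
            f"model family {spec.family!r} needs pretrained backbone weights, "
            "which are not bundled; use the small_cnn surrogate or provide weights"
        )
    return SmallCNNClassifier(spec, config=config, seed=seed)


def train(
    model: SmallCNNClassifier,
    slices: Sequence[SliceRecord],
    config: Optional[TrainConfig] = None,
) -> tuple[SmallCNNClassifier, list[float]]:
    """Train a surrogate CNN; returns the model and its per-epoch loss trace.

    Runs exactly ``config.epochs`` epochs of mini-batch Adam with sigmoid
    cross-entropy loss at batch size ``config.batch_size``; the learning
    rate at (0-based) epoch ``t`` is ``lr / (1 + decay * t)``.  Batch order
    is shuffled with a generator derived from ``weight_seed``, so identical
    seeds and data give bit-identical trained parameters.
    """
    config = config if config is not None else model.config
    x, y = _records_to_arrays(slices)
    classes = np.unique(y)
    if classes.size < 2:
        raise InputError("training data contains a single class")
    net = model.net
    optimizer = _Adam(net.params)
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=model.seed, spawn_key=(97,))
    )
    n = len(slices)
    cols1_all = net.stem(x)  # parameter-free, so computed once per dataset
    model.loss_trace_ = []
    model.updates_ = 0
    for epoch in range(config.epochs):
        lr = config.learning_rate_at(epoch)
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            yb = y[batch]
            logits, cache = net.forward_cols(cols1_all[batch], want_cache=True)
            # stable sigmoid cross-entropy: softplus(z) - y*z
            loss = float(np.mean(np.logaddexp(0.0, logits) - yb * logits))
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch} "
                    f"(lr={config.learning_rate}, decay={config.decay})"
                )
            prob = 1.0 / (1.0 + np.exp(-logits))
            dlogits = ((prob - yb) / len(batch)).astype(np.float32)
            grads = net.backward(dlogits, cache)
            optimizer.step(net.params, grads, lr)
            epoch_loss += loss * len(batch)
            model.updates_ += 1
        model.loss_trace_.append(epoch_loss / n)
    return model, model.loss_trace_


def evaluate(model, slices: Sequence[SliceRecord]) -> float:
    """Slice-level accuracy: the fraction of slices whose thresholded
    prediction (0.5) equals the label, with no per-subject aggregation."""
    if len(slices) == 0:
        raise InputError("empty evaluation set")
    pred = np.asarray(model.predict(slices)).astype(int)
    truth = np.array([s.label for s in slices], dtype=int)
    return float((pred == truth).mean())


def save_checkpoint(model: SmallCNNClassifier, path) -> None:
    """Write model weights to an .npz container with the spec/config as JSON."""
    import json

    meta = json.dumps(
        {"spec": asdict(model.spec), "config": asdict(model.config), "seed": model.seed}
    )
    np.savez(path, __meta__=np.array(meta), **model.net.params)


def load_checkpoint(path) -> SmallCNNClassifier:
    """Rebuild a classifier from a checkpoint written by :func:`save_checkpoint`."""
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        params = {k: data[k] for k in data.files if k != "__meta__"}
    spec_kw = meta["spec"]
    spec_kw["input_size"] = tuple(spec_kw["input_size"])
    spec_kw["channels"] = tuple(spec_kw["channels"])
    model = SmallCNNClassifier(
        ModelSpec(**spec_kw), config=TrainConfig(**meta["config"]), seed=meta["seed"]
    )
    for key in model.net.params:
        if key not in params or params[key].shape != model.net.params[key].shape:
            raise InputError(f"checkpoint at {path} is missing or misshapes {key!r}")
    model.net.params = {k: v.copy() for k, v in params.items()}
    return model


@dataclass
class SmallCNNFactory:
    """Classifier factory for :func:`sliceleak.folds.nested_cv`."""

    spec: ModelSpec = field(default_factory=ModelSpec.small_cnn)
    base_config: TrainConfig = field(default_factory=TrainConfig)

    def create(self, learning_rate: float, decay: float, seed: int) -> SmallCNNClassifier:
        config = replace(
            self.base_config, learning_rate=learning_rate, decay=decay, weight_seed=seed
        )
        return SmallCNNClassifier(self.spec, config=config, seed=seed)


class ConstantClassifier:
    """Baseline that always predicts one class; chance-level on balanced data."""

    def __init__(self, constant: int = 1):
        self.constant = int(constant)

    def fit(self, slices: Sequence[SliceRecord]) -> "ConstantClassifier":
        return self

    def predict(self, slices: Sequence[SliceRecord]) -> np.ndarray:
        return np.full(len(slices), self.constant, dtype=int)


class SubjectLookupClassifier:
    """Memorizes the subject -> label table from training slices.

    This rule is the leakage mechanism in its purest form: under a
    slice-level split every test slice's subject was seen in training, so
    it scores perfectly; under a subject-level split it has never seen the
    test subjects and falls back to the training majority class.
    """

    def __init__(self) -> None:
        self.table_: dict[str, int] = {}
        self.majority_ = 0

    def fit(self, slices: Sequence[SliceRecord]) -> "SubjectLookupClassifier":
        if len(slices) == 0:
            raise InputError("empty training set")
        votes: dict[str, list[int]] = {}
        for s in slices:
            votes.setdefault(s.subject_id, []).append(s.label)
        self.table_ = {subj: int(round(np.mean(v))) for subj, v in votes.items()}
        self.majority_ = int(np.mean([s.label for s in slices]) >= 0.5)
        return self

    def predict(self, slices: Sequence[SliceRecord]) -> np.ndarray:
        return np.array(
            [self.table_.get(s.subject_id, self.majority_) for s in slices], dtype=int
        )


@dataclass
class BaselineFactory:
    """Wraps a zero-hyperparameter baseline into the factory protocol."""

    constructor: type

    def create(self, learning_rate: float, decay: float, seed: int):
        return self.constructor()
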