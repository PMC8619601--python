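"""The block-wise CNN classifier.

The architecture is four identical blocks — 3x3 convolution, batch
normalization, ReLU, 2x2 stride-2 max pooling, 50% dropout — with channel
widths 8, 16, 32, 64, followed by two tanh fully-connected hidden layers
(512 and 1024 units) and a single sigmoid output unit trained with binary
cross-entropy. On the 64x64x3 wavelet-approximate input the spatial trace
is 64 -> 32 -> 16 -> 8 -> 4, so the flattened feature vector entering the
fully-connected stack has 4*4*64 = 1024 elements.

Convolutions use stride 1 with 'same' padding by default, so all spatial
reduction happens in the pools; stride and which blocks pool are both
configurable, which makes the "pool in blocks 1-3 only" variant (8x8 map
before the FC stack) a one-line change.

Training: Adam at learning rate 1e-3, batch size 16, 35 epochs, with
uniform random rotation augmentation of the training images. Everything is
deterministic given ``NetworkConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import _nn
from .exceptions import ConfigurationError, DataError, TrainingDivergenceError

__all__ = [
    "NetworkConfig",
    "LayerInfo",
    "NetworkSpec",
    "Network",
    "TrainReport",
    "build_network",
    "relu",
    "batch_norm_forward",
    "train",
    "predict",
    "classify",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Declarative description of the block-wise CNN and its training run.

    Defaults reproduce the published architecture and hyperparameters:
    four conv blocks (8/16/32/64 channels, 3x3 kernels), 2x2 stride-2
    pooling in every block, 50% dropout, FC hidden sizes 512 and 1024 with
    tanh, sigmoid output, binary cross-entropy, 35 epochs at learning rate
    0.001, validation every 31 iterations.
    """

    input_shape: tuple[int, int, int] = (64, 64, 3)
    block_channels: tuple[int, ...] = (8, 16, 32, 64)
    kernel: tuple[int, int] = (3, 3)
    conv_stride: int = 1
    pool_blocks: tuple[int, ...] | None = None  # None = pool in every block
    dropout_rate: float = 0.5
    fc_hidden: tuple[int, ...] = (512, 1024)
    hidden_activation: str = "tanh"
    output_activation: str = "sigmoid"
    loss: str = "binary_cross_entropy"
    epochs: int = 35
    learning_rate: float = 0.001
    batch_size: int = 16
    validation_frequency: int = 31
    batch_norm_epsilon: float = 1e-5
    rotation_degrees: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.block_channels) < 1 or any(c < 1 for c in self.block_channels):
            raise ConfigurationError("block_channels must be >= 1 each, nonempty")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.conv_stride < 1:
            raise ConfigurationError("conv_stride must be >= 1")
        if self.epochs < 0 or self.learning_rate <= 0 or self.batch_size < 1:
            raise ConfigurationError("invalid training hyperparameters")


@dataclass(frozen=True)
class LayerInfo:
    """One row of the layer table: role, shapes and parameter count."""

    name: str
    kind: str
    shape_in: tuple[int, ...]
    shape_out: tuple[int, ...]
    n_params: int


@dataclass(frozen=True)
class NetworkSpec:
    """Ordered layer descriptors; shapes chain and the output is one unit.

    Layer counting is ambiguous in the literature (grouped table rows vs
    computational layers vs weighted layers), so both useful conventions
    are exposed: ``n_layers_table`` mirrors the grouped published-table
    convention (input + 5 rows per block + FC/activations/classification/
    loss rows) and ``n_weight_layers`` counts layers holding trainable
    weights (convolutions + dense layers).
    """

    rows: tuple[LayerInfo, ...]

    def __post_init__(self) -> None:
        for prev, cur in zip(self.rows, self.rows[1:]):
            if prev.shape_out != cur.shape_in:
                raise ConfigurationError(
                    f"shape break: {prev.name} emits {prev.shape_out} but "
                    f"{cur.name} expects {cur.shape_in}"
                )
        if self.rows and self.rows[-1].shape_out != (1,):
            raise ConfigurationError("final layer must emit a single probability")

    @property
    def n_params(self) -> int:
        return sum(r.n_params for r in self.rows)

    @property
    def n_weight_layers(self) -> int:
        return sum(1 for r in self.rows if r.kind in ("conv", "dense"))

    @property
    def n_layers_table(self) -> int:
        n_blocks = sum(1 for r in self.rows if r.kind == "conv")
        return 1 + 5 * n_blocks + 4

    def to_table(self) -> str:
        """Plain-text layer table (number, name, kind, shapes, params)."""
        lines = ["Number\tLayer\tKind\tShape in\tShape out\tParams"]
        for i, r in enumerate(self.rows, start=1):
            lines.append(
                f"{i}\t{r.name}\t{r.kind}\t{r.shape_in}\t{r.shape_out}\t{r.n_params}"
            )
        return "\n".join(lines)


@dataclass
class TrainReport:
    """Per-epoch training losses plus interleaved validation checkpoints."""

    epoch_loss: list[float] = field(default_factory=list)
    epoch_accuracy: list[float] = field(default_factory=list)
    val_iterations: list[int] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_error: list[float] = field(default_factory=list)

    @property
    def epochs_completed(self) -> int:
        return len(self.epoch_loss)


class Network:
    """A built (possibly trained) network: layers, spec and RNG streams."""

    def __init__(self, config: NetworkConfig):
        if config.hidden_activation != "tanh":
            raise ConfigurationError("only tanh hidden activation is supported")
        if config.output_activation != "sigmoid":
            raise ConfigurationError("only sigmoid output is supported")
        self.config = config
        ss = np.random.SeedSequence(config.seed)
        init_rng, self.dropout_rng, self.shuffle_rng, self.augment_rng = (
            np.random.default_rng(s) for s in ss.spawn(4)
        )

        h, w, c = config.input_shape
        rows = [LayerInfo("input", "input", (h, w, c), (h, w, c), 0)]
        self.layers: list[_nn.Layer] = []
        pool_blocks = (
            set(range(len(config.block_channels)))
            if config.pool_blocks is None
            else set(config.pool_blocks)
        )
        in_c = c
        for bi, out_c in enumerate(config.block_channels):
            conv = _nn.Conv2D(in_c, out_c, config.kernel, config.conv_stride, init_rng)
            oh, ow = conv.out_shape(h, w)
            if oh < 1 or ow < 1:
                raise ConfigurationError(f"spatial collapse at block {bi + 1}")
            self.layers.append(conv)
            rows.append(
                LayerInfo(f"conv-{bi + 1}", "conv", (h, w, in_c), (oh, ow, out_c),
                          conv.n_params)
            )
            h, w, in_c = oh, ow, out_c
            bn = _nn.BatchNorm2D(out_c, eps=config.batch_norm_epsilon)
            self.layers.append(bn)
            rows.append(LayerInfo(f"batchnorm-{bi + 1}", "batchnorm",
                                  (h, w, out_c), (h, w, out_c), bn.n_params))
            self.layers.append(_nn.ReLU())
            rows.append(LayerInfo(f"relu-{bi + 1}", "relu",
                                  (h, w, out_c), (h, w, out_c), 0))
            if bi in pool_blocks:
                if h < 2 or w < 2 or h % 2 or w % 2:
                    raise ConfigurationError(
                        f"cannot 2x2-pool a {h}x{w} map at block {bi + 1}"
                    )
                self.layers.append(_nn.MaxPool2())
                h, w = h // 2, w // 2
                rows.append(LayerInfo(f"maxpool-{bi + 1}", "maxpool",
                                      (h * 2, w * 2, out_c), (h, w, out_c), 0))
            self.layers.append(_nn.Dropout(config.dropout_rate, self.dropout_rng))
            rows.append(LayerInfo(f"dropout-{bi + 1}", "dropout",
                                  (h, w, out_c), (h, w, out_c), 0))

        n_flat = h * w * in_c
        self.layers.append(_nn.Flatten())
        rows.append(LayerInfo("flatten", "flatten", (h, w, in_c), (n_flat,), 0))
        n_in = n_flat
        for fi, n_out in enumerate(config.fc_hidden):
            dense = _nn.Dense(n_in, n_out, init_rng)
            self.layers.append(dense)
            rows.append(LayerInfo(f"fc-{fi + 1}", "dense", (n_in,), (n_out,),
                                  dense.n_params))
            self.layers.append(_nn.Tanh())
            rows.append(LayerInfo(f"tanh-{fi + 1}", "tanh", (n_out,), (n_out,), 0))
            n_in = n_out
        out = _nn.Dense(n_in, 1, init_rng)
        # zero-init the classification head: training starts from the
        # maximum-entropy prediction 0.5, so no seed-dependent logit offset
        # has to be unlearned by the (short) optimization budget
        out.W[...] = 0.0
        self.layers.append(out)
        rows.append(LayerInfo("fc-out", "dense", (n_in,), (1,), out.n_params))
        rows.append(LayerInfo("sigmoid", "sigmoid", (1,), (1,), 0))
        self.output_layer = out
        self.spec = NetworkSpec(rows=tuple(rows))

    # -- forward passes -------------------------------------------------
    def _logits(self, x_nchw: np.ndarray, train: bool) -> np.ndarray:
        out = x_nchw
        for layer in self.layers:
            out = layer.forward(out, train)
        return out[:, 0]

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Probabilities in (0, 1) for a batch of NHWC images."""
        x = _to_nchw(images, self.config.input_shape)
        return _nn.sigmoid(self._logits(x, train=False))

    def params_grads(self):
        pg = []
        for layer in self.layers:
            pg.extend(layer.params_grads())
        return pg


def build_network(config: NetworkConfig) -> Network:
    """Construct the network (random init) from its declarative config."""
    return Network(config)


def relu(x):
    """Rectified linear unit, elementwise max(0, x)."""
    return np.maximum(0, np.asarray(x))


def batch_norm_forward(x, gamma, beta, eps=1e-5, axis=0):
    """Reference batch-norm forward: standardize over ``axis``, then affine.

    ``(x - mean) / sqrt(var + eps) * gamma + beta`` with the mean/variance
    taken over the mini-batch axis. For a constant batch the standardized
    term is 0 (up to eps regularization) and the output collapses to beta.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0 for numerical stability")
    x = np.asarray(x, dtype=np.float64)
    mu = x.mean(axis=axis, keepdims=True)
    var = x.var(axis=axis, keepdims=True)
    return gamma * (x - mu) / np.sqrt(var + eps) + beta


def _to_nchw(images: np.ndarray, input_shape: tuple[int, int, int]) -> np.ndarray:
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 3:
        images = images[None]
    if images.shape[1:] != tuple(input_shape):
        raise ValueError(
            f"images have shape {images.shape[1:]}, expected {tuple(input_shape)}"
        )
    return np.ascontiguousarray(images.transpose(0, 3, 1, 2))


def _rotate_batch(x_nchw: np.ndarray, max_deg: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Per-image uniform random rotation in [-max_deg, +max_deg], reflect fill."""
    if max_deg <= 0:
        return x_nchw
    out = np.empty_like(x_nchw)
    angles = rng.uniform(-max_deg, max_deg, size=x_nchw.shape[0])
    for i, ang in enumerate(angles):
        out[i] = ndimage.rotate(
            x_nchw[i], ang, axes=(1, 2), reshape=False, order=1, mode="reflect"
        )
    return out


def train(
    net: Network,
    images: np.ndarray,
    labels: np.ndarray,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainReport:
    """Train in place with Adam on binary cross-entropy; returns the report.

    ``images`` is an NHWC float array (values in [0, 1]) matching the
    network's input shape; ``labels`` are 0 (normal) / 1 (abnormal). Both
    classes must be present. Rotation augmentation is applied to every
    training batch. If a validation set is given, loss and error rate are
    recorded every ``validation_frequency`` iterations. Deterministic given
    the network's seed.
    """
    cfg = net.config
    x = _to_nchw(images, cfg.input_shape)
    y = np.asarray(labels, dtype=np.float64)
    if x.shape[0] == 0:
        raise DataError("empty training set")
    if len(np.unique(y)) < 2:
        raise DataError("training set must contain both classes")

    optimizer = _nn.Adam(net.params_grads(), lr=cfg.learning_rate)
    report = TrainReport()
    n = x.shape[0]
    iteration = 0
    for _ in range(cfg.epochs):
        order = net.shuffle_rng.permutation(n)
        losses, n_correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = _rotate_batch(x[idx], cfg.rotation_degrees, net.augment_rng)
            yb = y[idx]
            logits = net._logits(xb, train=True)
            loss, dlogits = _nn.bce_with_logits(logits, yb)
            if not np.isfinite(loss):
                raise TrainingDivergenceError(f"non-finite loss {loss}")
            losses.append(loss * len(idx))
            n_correct += int(np.sum((logits >= 0) == (yb == 1)))
            dout = dlogits[:, None].astype(np.float32)
            for layer in reversed(net.layers):
                dout = layer.backward(dout)
            optimizer.step()
            iteration += 1
            if validation is not None and iteration % cfg.validation_frequency == 0:
                _validate(net, validation, iteration, report)
        report.epoch_loss.append(sum(losses) / n)
        report.epoch_accuracy.append(n_correct / n)
    if report.epochs_completed > 0:
        _finalize_bn_stats(net, x)
    return report


def _finalize_bn_stats(net: Network, x: np.ndarray) -> None:
    """Recompute BN running statistics with dropout off (inference mode).

    Dropout inflates the variance of the activations that downstream
    batch-norm layers see during training (inverted dropout preserves means
    but roughly doubles second moments at rate 0.5), so running statistics
    accumulated during training mis-standardize the dropout-free inference
    activations — the classic dropout/batch-norm variance shift. After the
    last epoch the running mean/variance are therefore re-estimated from
    clean forward passes over the training images: batch norm still uses
    per-batch statistics while every dropout layer is inactive, and the
    running buffers are set to the plain average over batches.
    """
    bn_layers = [l for l in net.layers if isinstance(l, _nn.BatchNorm2D)]
    if not bn_layers:
        return
    sums = {id(l): [np.zeros_like(l.running_mean), np.zeros_like(l.running_var)]
            for l in bn_layers}
    n_batches = 0
    bs = net.config.batch_size
    for start in range(0, x.shape[0], bs):
        out = x[start : start + bs]
        if out.shape[0] < 2:
            continue  # a 1-image batch has degenerate variance
        for layer in net.layers:
            if isinstance(layer, _nn.BatchNorm2D):
                mu = out.mean(axis=(0, 2, 3))
                var = out.var(axis=(0, 2, 3))
                sums[id(layer)][0] += mu
                sums[id(layer)][1] += var
                g = layer.gamma.reshape(1, -1, 1, 1)
                b = layer.beta.reshape(1, -1, 1, 1)
                inv = 1.0 / np.sqrt(var + layer.eps)
                out = (g * (out - mu.reshape(1, -1, 1, 1))
                       * inv.reshape(1, -1, 1, 1) + b).astype(np.float32)
            elif isinstance(layer, _nn.Dropout):
                out = layer.forward(out, train=False)
            else:
                out = layer.forward(out, train=False)
        n_batches += 1
    if n_batches == 0:
        return
    for layer in bn_layers:
        layer.running_mean = (sums[id(layer)][0] / n_batches).astype(np.float32)
        layer.running_var = (sums[id(layer)][1] / n_batches).astype(np.float32)


def _validate(net, validation, iteration, report):
    xv, yv = validation
    probs = net.predict_proba(xv)
    yv = np.asarray(yv, dtype=np.float64)
    eps = 1e-12
    loss = float(
        -np.mean(yv * np.log(probs + eps) + (1 - yv) * np.log(1 - probs + eps))
    )
    err = float(np.mean((probs >= 0.5) != (yv == 1)))
    report.val_iterations.append(iteration)
    report.val_loss.append(loss)
    report.val_error.append(err)


def predict(net: Network, images: np.ndarray) -> np.ndarray:
    """Per-image abnormality probabilities in (0, 1)."""
    return net.predict_proba(images)


def classify(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard labels: 1 (abnormal) where probability >= threshold."""
    return (np.asarray(probs) >= threshold).astype(np.int64)


def variant(config: NetworkConfig, **overrides) -> NetworkConfig:
    """A copy of ``config`` with fields replaced (for sweeps/ablations)."""
    return replace(config, **overrides)
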