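"""Unsupervised CDAE training.

Each presentation of an image runs: normalize -> corrupt with a freshly
drawn mask -> forward pass -> mean-squared reconstruction error against the
*uncorrupted* normalized image -> plain SGD step. The learning rate starts
at 0.05 and is multiplied by 0.9 after every epoch. Encoding for downstream
use never applies corruption.

The module exposes both a scikit-learn style transformer
(:class:`CDAETransformer`) and thin functional wrappers
(:func:`train_cdae`, :func:`lr_schedule`, :func:`reconstruction_loss`).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import _ops
from .cdae import ArchitectureSpec, CDAENetwork, cdae_architecture
from .imageprep import ISHImage, normalize

__all__ = [
    "TrainConfig",
    "TrainReport",
    "lr_schedule",
    "reconstruction_loss",
    "train_cdae",
    "CDAETransformer",
]


@dataclass
class TrainConfig:
    """SGD hyperparameters. Defaults follow the reference training recipe:
    initial learning rate 0.05 decayed by 0.9 per epoch, 20% masking noise,
    mean-squared reconstruction loss."""

    initial_lr: float = 0.05
    lr_decay_per_epoch: float = 0.9
    n_epochs: int = 50
    batch_size: int = 16
    denoising_rate: float = 0.20
    loss: str = "mse"
    seed: int = 0
    normalization_mode: str = "tanh"
    dtype: str = "float32"
    init: str = "identity"
    grad_clip: float | None = 1.0
    """Global gradient-norm ceiling per SGD step (None disables). Guards the
    early high-learning-rate epochs against the gradient spikes that the
    value-duplicating unpooling amplifies into the bottleneck."""

    def __post_init__(self) -> None:
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be > 0")
        if not (0 < self.lr_decay_per_epoch <= 1):
            raise ValueError("lr_decay_per_epoch must be in (0, 1]")
        if not (0 <= self.denoising_rate <= 0.8):
            raise ValueError("denoising_rate must be in [0, 0.8]")
        if self.loss != "mse":
            raise ValueError("only mse loss is supported")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")


@dataclass
class TrainReport:
    epoch_losses: list[float] = field(default_factory=list)
    epoch_lrs: list[float] = field(default_factory=list)
    wall_clock_s: float = 0.0
    checkpoint_path: str | None = None


def lr_schedule(epoch: int, initial_lr: float = 0.05, decay: float = 0.9) -> float:
    """Learning rate at a given 0-based epoch: initial_lr * decay**epoch."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return initial_lr * decay ** epoch


def reconstruction_loss(output: np.ndarray, target: np.ndarray) -> float:
    """Mean squared difference over all pixels; 0 iff identical."""
    output = np.asarray(output, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if output.shape != target.shape:
        raise ValueError(f"shape mismatch: {output.shape} vs {target.shape}")
    d = output - target
    return float(np.mean(d * d))


# --------------------------------------------------------------------- backprop

def _forward_cached(net: CDAENetwork, x: np.ndarray):
    """Forward through all layers keeping what backward needs.

    x: (N, 1, H, W). Returns (output, caches); cache entries are
    (kind, payload) where payload depends on the layer kind.
    """
    a = x
    caches = []
    for layer, p in zip(net.layers, net.params):
        if layer.kind in ("conv", "deconv"):
            z, win = _ops.conv_forward(a, p["weight"], p["bias"])
            y = _ops.activation_forward(z, layer.activation)
            caches.append(("conv", (win, y, layer.activation)))
            a = y
        elif layer.kind == "maxpool":
            y, idx = _ops.maxpool_forward(a)
            caches.append(("maxpool", (idx, a.shape)))
            a = y
        else:
            caches.append(("unpool", None))
            a = _ops.unpool_forward(a)
    return a, caches


def _backward(net: CDAENetwork, dy: np.ndarray, caches):
    """Backward pass; returns per-layer gradients aligned with net.params."""
    grads: list[dict[str, np.ndarray] | None] = [None] * len(net.params)
    for i in range(len(net.params) - 1, -1, -1):
        kind, payload = caches[i]
        if kind == "conv":
            win, y, activation = payload
            dz = _ops.activation_backward(dy, y, activation)
            dy, dw, db = _ops.conv_backward(dz, win, net.params[i]["weight"])
            grads[i] = {"weight": dw, "bias": db}
        elif kind == "maxpool":
            idx, x_shape = payload
            dy = _ops.maxpool_backward(dy, idx, x_shape)
        else:
            dy = _ops.unpool_backward(dy)
    return grads


def sgd_step(net: CDAENetwork, batch_in: np.ndarray, batch_target: np.ndarray,
             lr: float, grad_clip: float | None = None) -> float:
    """One plain-SGD update on a (N, 1, H, W) batch; returns the batch loss."""
    out, caches = _forward_cached(net, batch_in)
    diff = out - batch_target
    loss = float(np.mean(diff * diff))
    if not np.isfinite(loss):
        raise FloatingPointError(
            f"non-finite reconstruction loss ({loss}); training aborted"
        )
    dy = (2.0 / diff.size) * diff
    grads = _backward(net, dy, caches)
    scale = 1.0
    if grad_clip is not None:
        norm_sq = sum(float((g["weight"] ** 2).sum() + (g["bias"] ** 2).sum())
                      for g in grads if g is not None)
        scale = min(1.0, grad_clip / max(np.sqrt(norm_sq), 1e-12))
    for p, g in zip(net.params, grads):
        if p is not None:
            p["weight"] -= lr * scale * g["weight"]
            p["bias"] -= lr * scale * g["bias"]
    return loss


def _as_pixel_stack(images) -> np.ndarray:
    if isinstance(images, np.ndarray):
        if images.ndim == 2:
            images = images[None]
        return np.asarray(images, dtype=np.float64)
    return np.stack(
        [im.pixels if isinstance(im, ISHImage) else np.asarray(im, dtype=np.float64)
         for im in images]
    )


def train_network(net: CDAENetwork, images, config: TrainConfig) -> TrainReport:
    """Run the SGD loop in place on ``net``; images are raw [0, 1] grids."""
    t0 = time.time()
    stack = _as_pixel_stack(images)
    h, w = net.architecture.input_h, net.architecture.input_w
    if stack.shape[1:] != (h, w):
        raise ValueError(
            f"image dims {stack.shape[1:]} do not match architecture {h}x{w}"
        )
    targets = np.stack(
        [normalize(ISHImage(px), config.normalization_mode).pixels for px in stack]
    ).astype(net.dtype)
    rng = np.random.default_rng(config.seed)
    n = len(targets)
    n_pixels = h * w
    n_zero = int(round(config.denoising_rate * n_pixels))
    report = TrainReport()
    for epoch in range(config.n_epochs):
        lr = lr_schedule(epoch, config.initial_lr, config.lr_decay_per_epoch)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch_t = targets[idx]
            # fresh corruption mask for every presentation: exactly
            # round(rate * H * W) pixels zeroed, without replacement
            batch_x = batch_t.reshape(len(idx), -1).copy()
            for r in range(len(idx)):
                batch_x[r, rng.choice(n_pixels, size=n_zero, replace=False)] = 0.0
            batch_x = batch_x.reshape(batch_t.shape)
            loss = sgd_step(net, batch_x[:, None], batch_t[:, None], lr,
                            grad_clip=config.grad_clip)
            losses.append((loss, len(idx)))
        total = sum(l * k for l, k in losses) / sum(k for _, k in losses)
        report.epoch_losses.append(total)
        report.epoch_lrs.append(lr)
    report.wall_clock_s = time.time() - t0
    return report


def train_cdae(images, architecture: ArchitectureSpec,
               config: TrainConfig | None = None) -> tuple[CDAENetwork, TrainReport]:
    """Train a fresh CDAE on raw images; thin wrapper over the SGD loop."""
    config = config or TrainConfig()
    net = CDAENetwork(architecture, seed=config.seed, dtype=config.dtype,
                      init=config.init)
    report = train_network(net, images, config)
    return net, report


class CDAETransformer(TransformerMixin, BaseEstimator):
    """Denoising convolutional autoencoder as an unsupervised transformer.

    ``fit`` trains the encoder/decoder to reconstruct uncorrupted images
    from masked ones; ``transform`` maps each image to the flattened
    bottleneck activations (the gene's representation vector).

    Parameters
    ----------
    n_pool_stages : int, default=4
        Number of 2x2 pooling (and mirrored unpooling) stages. Image dims
        must be divisible by ``2**n_pool_stages``.
    n_filters : int, default=4
        Feature maps per hidden convolution.
    filter_size : int, default=3
        Odd spatial filter extent.
    convs_per_stage : int, default=2
        Convolutions between consecutive poolings.
    denoising_rate : float, default=0.2
        Fraction of pixels zeroed per presentation during training.
    n_epochs, batch_size, learning_rate, lr_decay :
        Plain-SGD schedule; the learning rate is ``learning_rate *
        lr_decay**epoch``.
    normalization : {"tanh", "zscore"}, default="tanh"
        Input normalization; "tanh" maps [0, 1] to [-1, 1].
    random_state : int, default=0
        Seed for weight init, shuffling, and corruption masks.

    Attributes
    ----------
    network_ : CDAENetwork
        The trained network (decoder retained; use
        ``network_.truncate_decoder()`` for an encoder-only copy).
    architecture_ : ArchitectureSpec
    loss_history_ : list of float
        Mean reconstruction loss per epoch.
    n_features_out_ : int
        Representation length (bottleneck height x width).
    """

    def __init__(self, n_pool_stages: int = 4, n_filters: int = 4,
                 filter_size: int = 3, convs_per_stage: int = 2,
                 denoising_rate: float = 0.2, n_epochs: int = 50,
                 batch_size: int = 16, learning_rate: float = 0.05,
                 lr_decay: float = 0.9, normalization: str = "tanh",
                 random_state: int = 0, dtype: str = "float32",
                 init: str = "identity", grad_clip: float | None = 1.0):
        self.n_pool_stages = n_pool_stages
        self.n_filters = n_filters
        self.filter_size = filter_size
        self.convs_per_stage = convs_per_stage
        self.denoising_rate = denoising_rate
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.normalization = normalization
        self.random_state = random_state
        self.dtype = dtype
        self.init = init
        self.grad_clip = grad_clip

    def _config(self) -> TrainConfig:
        return TrainConfig(
            initial_lr=self.learning_rate,
            lr_decay_per_epoch=self.lr_decay,
            n_epochs=self.n_epochs,
            batch_size=self.batch_size,
            denoising_rate=self.denoising_rate,
            seed=self.random_state,
            normalization_mode=self.normalization,
            dtype=self.dtype,
            init=self.init,
            grad_clip=self.grad_clip,
        )

    def fit(self, X, y=None):
        stack = _as_pixel_stack(X)
        if stack.ndim != 3 or stack.shape[0] < 1:
            raise ValueError("X must be a non-empty stack of 2D images")
        h, w = stack.shape[1:]
        self.architecture_ = cdae_architecture(
            h, w, n_pool_stages=self.n_pool_stages, n_filters=self.n_filters,
            filter_size=self.filter_size, convs_per_stage=self.convs_per_stage,
        )
        self.network_ = CDAENetwork(self.architecture_, seed=self.random_state,
                                    dtype=self.dtype, init=self.init)
        self.report_ = train_network(self.network_, stack, self._config())
        self.loss_history_ = self.report_.epoch_losses
        self.n_features_out_ = self.architecture_.representation_length()
        return self

    def transform(self, X) -> np.ndarray:
        """Encode images (uncorrupted) to (n_images, L) representations."""
        check_is_fitted(self, "network_")
        stack = _as_pixel_stack(X)
        norm = np.stack(
            [normalize(ISHImage(px), self.normalization).pixels for px in stack]
        )
        return self.network_.encode_batch(norm)
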