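"""Convolutional denoising autoencoder: layer specifications, shape
calculus, the best-AUC reference architecture, and the network object.

The architecture is a mirror-symmetric encoder/decoder. The encoder stacks
stride-1, size-preserving convolutions with 2x2 max-pooling stages down to a
single-feature-map bottleneck; the decoder upsamples with value-duplicating
2x2 unpooling (each source cell fills its 2x2 output block — no pooling
switches are recorded) followed by deconvolutions, which here are ordinary
size-preserving convolutions with independently learned weights. After
training, the decoder is truncated and the flattened bottleneck activations
serve as the per-gene representation vector.

The reference ("best-AUC") architecture on a 960x480 input uses four
pooling stages and a single bottleneck map, giving a 60x30 = 1800-feature
representation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import _ops
from .imageprep import ISHImage

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "CDAENetwork",
    "RepresentationVector",
    "best_auc_architecture",
    "cdae_architecture",
    "bottleneck_shape",
    "max_pool",
    "unpool",
]

_KINDS = {"conv", "deconv", "maxpool", "unpool"}
_ACTIVATIONS = {"relu", "tanh", "linear"}


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the network.

    ``conv``/``deconv`` layers carry ``n_filters`` filters of odd
    ``filter_size`` (stride fixed at 1, zero padding of ``filter_size // 2``
    so spatial dims are preserved) and an ``activation``. ``maxpool`` /
    ``unpool`` layers use a fixed 2x2 window.
    """

    kind: str
    n_filters: int | None = None
    filter_size: int = 3
    window: int = 2
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown layer kind: {self.kind!r}")
        if self.kind in ("conv", "deconv"):
            if self.n_filters is None or self.n_filters < 1:
                raise ValueError(f"{self.kind} layer needs n_filters >= 1")
            if self.filter_size < 3 or self.filter_size % 2 == 0:
                raise ValueError(
                    f"filter_size must be odd and >= 3, got {self.filter_size}"
                )
            if self.activation not in _ACTIVATIONS:
                raise ValueError(f"unknown activation: {self.activation!r}")
        if self.window != 2:
            raise ValueError("pooling/unpooling window is fixed at 2")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered encoder and decoder layer lists with the symmetry contract.

    Invariants enforced: input dims divisible by 2^(pooling stages); one
    unpool per pool; the final decoder layer has a single filter with tanh
    activation so reconstructions cover the normalized target range.
    """

    input_h: int
    input_w: int
    encoder: tuple[LayerSpec, ...]
    decoder: tuple[LayerSpec, ...]
    tied_weights: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "encoder", tuple(self.encoder))
        object.__setattr__(self, "decoder", tuple(self.decoder))
        n_pool = sum(1 for l in self.encoder if l.kind == "maxpool")
        n_unpool = sum(1 for l in self.decoder if l.kind == "unpool")
        if self.decoder and n_pool != n_unpool:
            raise ValueError(
                f"decoder must mirror encoder: {n_pool} pool vs {n_unpool} unpool stages"
            )
        factor = 2 ** n_pool
        if self.input_h % factor or self.input_w % factor:
            raise ValueError(
                f"input dims {self.input_h}x{self.input_w} not divisible by "
                f"2^{n_pool} = {factor}"
            )
        if any(l.kind in ("deconv", "unpool") for l in self.encoder):
            raise ValueError("encoder may only contain conv/maxpool layers")
        if any(l.kind in ("conv", "maxpool") for l in self.decoder):
            raise ValueError("decoder may only contain deconv/unpool layers")
        if self.decoder:
            last = self.decoder[-1]
            if last.kind != "deconv" or last.n_filters != 1 or last.activation != "tanh":
                raise ValueError(
                    "final decoder layer must be a single-filter deconv with tanh"
                )

    @property
    def n_pool_stages(self) -> int:
        return sum(1 for l in self.encoder if l.kind == "maxpool")

    @property
    def bottleneck_maps(self) -> int:
        convs = [l for l in self.encoder if l.kind == "conv"]
        return convs[-1].n_filters if convs else 1

    def bottleneck_shape(self) -> tuple[int, int]:
        return bottleneck_shape(self.input_h, self.input_w, self.n_pool_stages)

    def representation_length(self) -> int:
        h, w = self.bottleneck_shape()
        return h * w * self.bottleneck_maps

    def encoder_only(self) -> "ArchitectureSpec":
        return ArchitectureSpec(
            input_h=self.input_h,
            input_w=self.input_w,
            encoder=self.encoder,
            decoder=(),
            tied_weights=self.tied_weights,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_h": self.input_h,
                "input_w": self.input_w,
                "tied_weights": self.tied_weights,
                "encoder": [asdict(l) for l in self.encoder],
                "decoder": [asdict(l) for l in self.decoder],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        d = json.loads(text)
        return cls(
            input_h=d["input_h"],
            input_w=d["input_w"],
            encoder=tuple(LayerSpec(**l) for l in d["encoder"]),
            decoder=tuple(LayerSpec(**l) for l in d["decoder"]),
            tied_weights=d.get("tied_weights", False),
        )


@dataclass
class RepresentationVector:
    """Flattened bottleneck activations of one image."""

    values: np.ndarray
    gene_id: str = ""


def bottleneck_shape(input_h: int, input_w: int, n_pool_stages: int) -> tuple[int, int]:
    """Spatial shape after ``n_pool_stages`` 2x2 poolings with size-preserving
    convolutions: (input_h / 2^n, input_w / 2^n)."""
    factor = 2 ** n_pool_stages
    if input_h % factor or input_w % factor:
        raise ValueError(
            f"dims {input_h}x{input_w} not divisible by 2^{n_pool_stages}"
        )
    return input_h // factor, input_w // factor


def cdae_architecture(
    input_h: int,
    input_w: int,
    n_pool_stages: int = 4,
    n_filters: int = 4,
    filter_size: int = 3,
    convs_per_stage: int = 2,
) -> ArchitectureSpec:
    """Build a mirror-symmetric CDAE with the given depth and width.

    Encoder: ``n_pool_stages`` blocks of ``convs_per_stage`` convolutions
    followed by 2x2 max-pooling, then one more convolution and a final
    single-filter bottleneck convolution. Decoder: for every pooling stage an
    unpooling followed by ``convs_per_stage`` deconvolutions, ending in a
    single-filter tanh deconvolution. All hidden activations are ReLU.
    """
    enc: list[LayerSpec] = []
    for _ in range(n_pool_stages):
        enc += [LayerSpec("conv", n_filters, filter_size)] * convs_per_stage
        enc.append(LayerSpec("maxpool"))
    enc.append(LayerSpec("conv", n_filters, filter_size))
    enc.append(LayerSpec("conv", 1, filter_size))

    dec: list[LayerSpec] = []
    for _ in range(n_pool_stages):
        dec.append(LayerSpec("unpool"))
        dec += [LayerSpec("deconv", n_filters, filter_size)] * convs_per_stage
    dec.append(LayerSpec("deconv", 1, filter_size, activation="tanh"))

    return ArchitectureSpec(input_h=input_h, input_w=input_w,
                            encoder=tuple(enc), decoder=tuple(dec))


def best_auc_architecture(input_h: int = 960, input_w: int = 480) -> ArchitectureSpec:
    """The reference architecture: four 2x2 pooling stages, two 3x3
    convolutions of four filters per stage, a four-filter then single-filter
    bottleneck convolution, and a mirrored deconvolution/unpooling decoder
    ending in a single-filter tanh layer. On the default 960x480 input the
    bottleneck is 60x30, i.e. an 1800-feature representation."""
    return cdae_architecture(input_h, input_w, n_pool_stages=4, n_filters=4,
                             filter_size=3, convs_per_stage=2)


def max_pool(grid: np.ndarray) -> np.ndarray:
    """2x2 max-pooling of a 2D grid: each output cell is the maximum of its
    disjoint 2x2 block; dims must be even."""
    grid = np.asarray(grid, dtype=np.float64)
    y, _ = _ops.maxpool_forward(grid[None, None])
    return y[0, 0]


def unpool(grid: np.ndarray) -> np.ndarray:
    """Value-duplicating 2x2 unpooling of a 2D grid: every cell fills a
    constant 2x2 output block."""
    grid = np.asarray(grid, dtype=np.float64)
    return _ops.unpool_forward(grid[None, None])[0, 0]


class CDAENetwork:
    """A CDAE with concrete weights.

    Two seeded random initialization policies are available:

    - ``"identity"`` (default): each filter passes one input channel
      through its centre tap, plus fan-in-scaled uniform noise at a
      quarter of the usual amplitude. At initialization the whole
      encoder/decoder cascade is then close to an information-preserving
      downsampler/upsampler, so every bottleneck unit is active from the
      start — a single-feature-map ReLU bottleneck initialized purely at
      random frequently starts (and stays) mostly dead, because the sign
      of one spatially-correlated map decides the fate of all its units.
    - ``"uniform"``: plain fan-in-scaled uniform init,
      U(-sqrt(6/fan_in), sqrt(6/fan_in)).

    Biases start at zero, one per feature map. ``dtype`` defaults to
    float32 (training is memory-bandwidth bound); pass float64 where
    tighter numerics matter, e.g. finite-difference gradient verification.
    """

    def __init__(self, architecture: ArchitectureSpec, seed: int = 0,
                 dtype: str | np.dtype = "float32", init: str = "identity"):
        if init not in ("identity", "uniform"):
            raise ValueError(f"unknown init policy: {init!r}")
        self.architecture = architecture
        self.rng_seed = seed
        self.init = init
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        self.params: list[dict[str, np.ndarray] | None] = []
        c_in = 1
        for layer in self.layers:
            if layer.kind in ("conv", "deconv"):
                k = layer.filter_size
                fan_in = c_in * k * k
                limit = np.sqrt(6.0 / fan_in)
                w = rng.uniform(-limit, limit, size=(layer.n_filters, c_in, k, k))
                if init == "identity":
                    w *= 0.25
                    for o in range(layer.n_filters):
                        w[o, o % c_in, k // 2, k // 2] += 1.0
                b = np.zeros(layer.n_filters)
                self.params.append({"weight": w.astype(self.dtype),
                                    "bias": b.astype(self.dtype)})
                c_in = layer.n_filters
            else:
                self.params.append(None)

    @property
    def layers(self) -> tuple[LayerSpec, ...]:
        return self.architecture.encoder + self.architecture.decoder

    @property
    def n_encoder_layers(self) -> int:
        return len(self.architecture.encoder)

    # ------------------------------------------------------------------ forward

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        if x.shape[-2:] != (self.architecture.input_h, self.architecture.input_w):
            raise ValueError(
                f"input shape {x.shape[-2:]} does not match architecture "
                f"{self.architecture.input_h}x{self.architecture.input_w}"
            )
        return x[:, None]  # (N, 1, H, W)

    def forward_batch(self, x: np.ndarray, upto: int | None = None) -> np.ndarray:
        """Run a (N, H, W) batch through layers [0, upto); returns (N, C, H', W')."""
        a = self._check_input(x)
        layers = self.layers[:upto] if upto is not None else self.layers
        for layer, p in zip(layers, self.params):
            if layer.kind in ("conv", "deconv"):
                z, _ = _ops.conv_forward(a, p["weight"], p["bias"])
                a = _ops.activation_forward(z, layer.activation)
            elif layer.kind == "maxpool":
                a, _ = _ops.maxpool_forward(a)
            else:
                a = _ops.unpool_forward(a)
        return a

    def forward_full(self, image: ISHImage | np.ndarray) -> ISHImage:
        """Full encoder+decoder pass; the reconstruction has the input dims
        and, through the final tanh, values strictly inside (-1, 1)."""
        if not self.architecture.decoder:
            raise ValueError("network has no decoder (already truncated)")
        pixels = image.pixels if isinstance(image, ISHImage) else np.asarray(image)
        gene_id = image.gene_id if isinstance(image, ISHImage) else ""
        out = self.forward_batch(pixels[None])
        return ISHImage(pixels=out[0, 0], gene_id=gene_id)

    def encode_batch(self, x: np.ndarray) -> np.ndarray:
        """Bottleneck activations for a (N, H, W) batch, flattened to (N, L)."""
        a = self.forward_batch(x, upto=self.n_encoder_layers)
        return a.reshape(a.shape[0], -1)

    def encode(self, image: ISHImage | np.ndarray) -> RepresentationVector:
        """The representation vector: flattened activations of the final
        encoder convolution (never corrupted input — encoding is
        evaluation-time)."""
        pixels = image.pixels if isinstance(image, ISHImage) else np.asarray(image)
        gene_id = image.gene_id if isinstance(image, ISHImage) else ""
        return RepresentationVector(values=self.encode_batch(pixels[None])[0],
                                    gene_id=gene_id)

    def truncate_decoder(self) -> "CDAENetwork":
        """Drop the decoder, keeping encoder weights shared with this network.

        Representations through the truncated network are identical to those
        through the full one; truncating twice is a no-op."""
        if not self.architecture.decoder:
            return self
        out = object.__new__(CDAENetwork)
        out.architecture = self.architecture.encoder_only()
        out.rng_seed = self.rng_seed
        out.dtype = self.dtype
        out.params = self.params[: self.n_encoder_layers]
        return out

    # ---------------------------------------------------------------- storage

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: npz with the architecture JSON embedded."""
        arrays: dict[str, np.ndarray] = {
            "architecture_json": np.frombuffer(
                self.architecture.to_json().encode(), dtype=np.uint8
            ),
            "rng_seed": np.array(self.rng_seed),
            "init": np.array(self.init),
        }
        for i, p in enumerate(self.params):
            if p is not None:
                arrays[f"w{i}"] = p["weight"]
                arrays[f"b{i}"] = p["bias"]
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CDAENetwork":
        with np.load(path) as data:
            arch = ArchitectureSpec.from_json(bytes(data["architecture_json"]).decode())
            dtype = data["w0"].dtype if "w0" in data else np.float32
            init = str(data["init"]) if "init" in data else "identity"
            net = cls(arch, seed=int(data["rng_seed"]), dtype=dtype, init=init)
            for i, p in enumerate(net.params):
                if p is not None:
                    p["weight"] = data[f"w{i}"]
                    p["bias"] = data[f"b{i}"]
        return net
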