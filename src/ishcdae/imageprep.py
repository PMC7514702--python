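"""Image loading, resampling, normalization and masking corruption.

Every image entering the autoencoder passes through this module: grayscale
conversion to [0, 1] floats, antialiased resampling to the training
resolution, normalization to the range the decoder's output activation can
reproduce, and — during training only — masking corruption that zeroes a
fixed fraction of pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "ISHImage",
    "CorruptionSpec",
    "load_grayscale",
    "resample",
    "normalize",
    "denormalize",
    "corrupt",
]


@dataclass
class ISHImage:
    """A single-channel intensity image tied to a gene identifier.

    Parameters
    ----------
    pixels : ndarray of shape (height, width)
        Finite float intensities. Raw images live in [0, 1]; normalized
        images may use other ranges (e.g. [-1, 1]).
    gene_id : str
        Identifier of the gene whose expression the image shows.
    """

    pixels: np.ndarray
    gene_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(
                f"ISHImage requires a 2D pixel grid, got ndim={self.pixels.ndim}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("ISHImage requires height, width >= 1")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("ISHImage intensities must be finite")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class CorruptionSpec:
    """Masking-noise parameters: fraction of pixels forced to zero."""

    rate: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate < 1.0):
            raise ValueError(f"corruption rate must be in [0, 1), got {self.rate}")


def load_grayscale(path: str | Path) -> ISHImage:
    """Load an image file as single-channel float intensities in [0, 1].

    Multi-channel inputs are converted by averaging the channels; integer
    dtypes are scaled by their maximum representable value. The gene id is
    taken from the file stem.
    """
    path = Path(path)
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.size == 0:
        raise ValueError(f"zero-size image: {path}")
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 3:  # channel-mean luminance
        arr = arr.mean(axis=2)
    return ISHImage(pixels=arr, gene_id=path.stem)


def resample(image: ISHImage, target_h: int, target_w: int) -> ISHImage:
    """Resample to exactly (target_h, target_w).

    Downsampling (both dims shrink or stay) uses box/area averaging, which
    antialiases the large reductions typical for ISH scans; any enlargement
    uses bilinear interpolation. Resampling to the current size is the
    identity.
    """
    if target_h < 1 or target_w < 1:
        raise ValueError("target dims must be >= 1")
    if (target_h, target_w) == (image.height, image.width):
        return ISHImage(pixels=image.pixels.copy(), gene_id=image.gene_id)
    shrinking = target_h <= image.height and target_w <= image.width
    resampler = Image.Resampling.BOX if shrinking else Image.Resampling.BILINEAR
    pil = Image.fromarray(image.pixels.astype(np.float32), mode="F")
    out = np.asarray(pil.resize((target_w, target_h), resample=resampler), dtype=np.float64)
    return ISHImage(pixels=out, gene_id=image.gene_id)


def normalize(image: ISHImage, mode: str = "tanh") -> ISHImage:
    """Normalize intensities for autoencoder training.

    ``"tanh"`` linearly maps [0, 1] to [-1, 1] so a tanh output layer can
    cover the target range. ``"zscore"`` subtracts the per-image mean and
    divides by the standard deviation (errors on constant images).
    """
    x = image.pixels
    if mode == "tanh":
        out = 2.0 * x - 1.0
    elif mode == "zscore":
        sd = x.std()
        if sd == 0:
            raise ValueError(
                f"zscore normalization undefined for constant image {image.gene_id!r}"
            )
        out = (x - x.mean()) / sd
    else:
        raise ValueError(f"unknown normalization mode: {mode!r}")
    return ISHImage(pixels=out, gene_id=image.gene_id)


def denormalize(image: ISHImage, mode: str = "tanh", mean: float = 0.0, sd: float = 1.0) -> ISHImage:
    """Invert :func:`normalize` (for zscore, supply the original mean/sd)."""
    x = image.pixels
    if mode == "tanh":
        out = (x + 1.0) / 2.0
    elif mode == "zscore":
        out = x * sd + mean
    else:
        raise ValueError(f"unknown normalization mode: {mode!r}")
    return ISHImage(pixels=out, gene_id=image.gene_id)


def corrupt(image: ISHImage, spec: CorruptionSpec) -> tuple[ISHImage, np.ndarray]:
    """Zero exactly ``round(rate * H * W)`` pixels, chosen uniformly.

    Returns the corrupted image and a boolean mask marking zeroed positions.
    Untouched pixels are bit-identical to the input; the draw is without
    replacement and deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    return _corrupt_with_rng(image.pixels, spec.rate, rng, image.gene_id)


def _corrupt_with_rng(
    pixels: np.ndarray, rate: float, rng: np.random.Generator, gene_id: str = ""
) -> tuple[ISHImage, np.ndarray]:
    n = pixels.size
    n_zero = int(round(rate * n))
    flat = pixels.flatten()
    mask = np.zeros(n, dtype=bool)
    if n_zero > 0:
        idx = rng.choice(n, size=n_zero, replace=False)
        flat[idx] = 0.0
        mask[idx] = True
    shape = pixels.shape
    return (
        ISHImage(pixels=flat.reshape(shape), gene_id=gene_id),
        mask.reshape(shape),
    )
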