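"""Synthetic ISH-like image corpora with planted GO-category structure.

Real ISH sections are large grayscale images: a dark slide background
surrounding an elliptical brain region filled with multi-scale expression
texture. Genes annotated to the same functional category tend to share a
localized spatial or textural expression motif. The generator emulates
exactly that, at desk scale: every gene gets one image; genes positive for
a category carry that category's motif (a Gaussian expression blob, a
horizontal laminar band evoking layered structures such as the cerebellar
cortex, or a directional texture frequency) inside the brain ellipse, with
per-image spatial jitter; negatives carry background texture only.
Category sizes are drawn in a configurable range inside [15, 500], against
a larger negative pool, reproducing the heavy class imbalance of real GO
annotation tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .imageprep import ISHImage

__all__ = [
    "SyntheticSpec",
    "SyntheticCorpus",
    "generate_corpus",
    "write_corpus",
    "read_corpus",
]

_MOTIF_KINDS = {"blob", "layered-band", "texture-frequency"}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic corpus.

    Defaults give a 2:1-aspect 96x48 image (divisible by 2^4, so the
    four-pooling-stage reference architecture applies directly), 200 genes,
    4 non-overlapping categories of 15-25 positives each, strong motifs, and
    mild pixel noise.
    """

    image_height: int = 96
    image_width: int = 48
    n_genes: int = 200
    n_categories: int = 4
    positives_per_category: tuple[int, int] = (15, 25)
    motif_kind: str = "blob"
    motif_strength: float = 1.0
    background_noise_sd: float = 0.05
    brain_ellipse: tuple[float, float, float, float] = (0.5, 0.5, 0.42, 0.40)
    """(center_row, center_col, semi_axis_row, semi_axis_col), relative units."""
    allow_overlap: bool = False
    pool_stages: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.positives_per_category
        if not (15 <= lo <= hi <= 500):
            raise ValueError(
                f"positives_per_category must lie within [15, 500], got ({lo}, {hi})"
            )
        factor = 2 ** self.pool_stages
        if self.image_height % factor or self.image_width % factor:
            raise ValueError(
                f"image dims {self.image_height}x{self.image_width} not divisible "
                f"by 2^{self.pool_stages} = {factor}"
            )
        if hi > self.n_genes:
            raise ValueError("positives_per_category max exceeds n_genes")
        if not self.allow_overlap and self.n_categories * hi > self.n_genes:
            raise ValueError(
                "non-overlapping categories need n_genes >= n_categories * max positives"
            )
        if self.motif_kind not in _MOTIF_KINDS:
            raise ValueError(f"unknown motif_kind: {self.motif_kind!r}")
        if not (0.0 <= self.motif_strength <= 1.0):
            raise ValueError("motif_strength must be in [0, 1]")


@dataclass
class SyntheticCorpus:
    images: list[ISHImage]
    gene_ids: list[str]
    category_ids: list[str]
    annotations: np.ndarray  # (n_genes, n_categories) binary
    ground_truth_motifs: list[dict]
    spec: SyntheticSpec

    def annotation_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.annotations, index=self.gene_ids,
                            columns=self.category_ids, dtype=int)


def _ellipse_mask(h: int, w: int, ellipse: tuple[float, float, float, float]) -> np.ndarray:
    cr, cc, ar, ac = ellipse
    rows = (np.arange(h) + 0.5) / h
    cols = (np.arange(w) + 0.5) / w
    rr, cc_ = np.meshgrid(rows, cols, indexing="ij")
    return ((rr - cr) / ar) ** 2 + ((cc_ - cc) / ac) ** 2 <= 1.0


def _motif_field(kind: str, params: dict, h: int, w: int,
                 jitter_r: float = 0.0, jitter_c: float = 0.0) -> np.ndarray:
    """Unit-amplitude motif pattern on the full grid (masked later)."""
    rows = (np.arange(h) + 0.5) / h
    cols = (np.arange(w) + 0.5) / w
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    if kind == "blob":
        r0 = params["center_row"] + jitter_r
        c0 = params["center_col"] + jitter_c
        s = params["sigma"]
        return np.exp(-(((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * s * s)))
    if kind == "layered-band":
        r0 = params["center_row"] + jitter_r
        half = params["half_width"]
        return np.exp(-(((rr - r0) / half) ** 2))
    if kind == "texture-frequency":
        freq = params["frequency"]
        theta = params["orientation"]
        phase = 2 * np.pi * freq * (rr * np.cos(theta) + cc * np.sin(theta))
        return 0.5 * (1 + np.sin(phase + params.get("phase", 0.0)))
    raise ValueError(f"unknown motif kind: {kind!r}")


def _draw_motif_params(kind: str, index: int, n_categories: int,
                       ellipse: tuple[float, float, float, float],
                       rng: np.random.Generator) -> dict:
    cr, cc, ar, ac = ellipse
    if kind == "blob":
        # spread centres around the ellipse so categories stay distinguishable
        angle = 2 * np.pi * index / max(n_categories, 1) + rng.uniform(-0.2, 0.2)
        rad = rng.uniform(0.35, 0.6)
        return {
            "center_row": cr + rad * ar * np.sin(angle),
            "center_col": cc + rad * ac * np.cos(angle),
            "sigma": rng.uniform(0.06, 0.10),
        }
    if kind == "layered-band":
        return {
            "center_row": cr + (index / max(n_categories - 1, 1) - 0.5) * 1.2 * ar,
            "half_width": rng.uniform(0.04, 0.07),
        }
    return {
        "frequency": 3.0 + 2.5 * index,
        "orientation": rng.uniform(0, np.pi),
        "phase": rng.uniform(0, 2 * np.pi),
    }


def generate_corpus(spec: SyntheticSpec) -> SyntheticCorpus:
    """Generate a corpus deterministically from ``spec.seed``.

    Background: near-black outside the brain ellipse, mid-gray expression
    texture inside, both with Gaussian pixel noise, clipped to [0, 1].
    Positives additionally receive ``motif_strength``-scaled category motifs
    with small per-image translation jitter. At strength 0 positives and
    negatives are drawn from the same distribution.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height, spec.image_width
    gene_ids = [f"gene{i:05d}" for i in range(spec.n_genes)]
    category_ids = [f"GO:{1000 + i}" for i in range(spec.n_categories)]

    lo, hi = spec.positives_per_category
    counts = rng.integers(lo, hi + 1, size=spec.n_categories)
    annotations = np.zeros((spec.n_genes, spec.n_categories), dtype=np.int8)
    if spec.allow_overlap:
        for j, k in enumerate(counts):
            annotations[rng.choice(spec.n_genes, size=k, replace=False), j] = 1
    else:
        order = rng.permutation(spec.n_genes)
        pos = 0
        for j, k in enumerate(counts):
            annotations[order[pos : pos + k], j] = 1
            pos += k

    motifs = [
        {"kind": spec.motif_kind, "category_id": category_ids[j],
         **_draw_motif_params(spec.motif_kind, j, spec.n_categories,
                              spec.brain_ellipse, rng)}
        for j in range(spec.n_categories)
    ]

    mask = _ellipse_mask(h, w, spec.brain_ellipse)
    images: list[ISHImage] = []
    for i, gid in enumerate(gene_ids):
        base = np.where(mask, 0.5, 0.02)
        img = base + rng.normal(0.0, spec.background_noise_sd, size=(h, w))
        for j in np.flatnonzero(annotations[i]):
            m = motifs[j]
            jr, jc = rng.uniform(-0.03, 0.03, size=2)  # ~2-3 px translation jitter
            pattern = _motif_field(m["kind"], m, h, w, jr, jc)
            img = img + spec.motif_strength * 0.45 * pattern * mask
        images.append(ISHImage(pixels=np.clip(img, 0.0, 1.0), gene_id=gid))

    return SyntheticCorpus(images=images, gene_ids=gene_ids,
                           category_ids=category_ids, annotations=annotations,
                           ground_truth_motifs=motifs, spec=spec)


def write_corpus(corpus: SyntheticCorpus, directory: str | Path,
                 bit_depth: int = 16) -> Path:
    """Write PNG images, a TSV annotation table, and a JSON manifest.

    Returns the manifest path. Round-trips losslessly up to PNG
    quantization (1/255 or 1/65535 per pixel).
    """
    import imageio.v3 as iio

    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scale = 2 ** bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    files = {}
    for img in corpus.images:
        fname = f"{img.gene_id}.png"
        quant = np.round(np.clip(img.pixels, 0, 1) * scale).astype(dtype)
        iio.imwrite(directory / fname, quant)
        files[img.gene_id] = fname
    corpus.annotation_frame().to_csv(directory / "annotations.tsv", sep="\t",
                                     index_label="gene_id")
    manifest = {
        "spec": asdict(corpus.spec),
        "bit_depth": bit_depth,
        "seed": corpus.spec.seed,
        "annotations": "annotations.tsv",
        "images": files,
        "ground_truth_motifs": corpus.ground_truth_motifs,
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=float))
    return path


def read_corpus(directory: str | Path) -> SyntheticCorpus:
    """Load a corpus written by :func:`write_corpus`.

    Errors name the missing manifest or the gene whose image file or
    annotation row is absent.
    """
    import imageio.v3 as iio

    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing corpus manifest: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    spec_d = dict(manifest["spec"])
    spec_d["positives_per_category"] = tuple(spec_d["positives_per_category"])
    spec_d["brain_ellipse"] = tuple(spec_d["brain_ellipse"])
    for k in ("image_height", "image_width", "n_genes", "n_categories",
              "pool_stages", "seed"):
        spec_d[k] = int(spec_d[k])
    spec = SyntheticSpec(**spec_d)

    ann = pd.read_csv(directory / manifest["annotations"], sep="\t",
                      index_col="gene_id")
    scale = 2 ** manifest["bit_depth"] - 1
    images = []
    for gid, fname in manifest["images"].items():
        fpath = directory / fname
        if not fpath.exists():
            raise FileNotFoundError(f"missing image for gene {gid!r}: {fpath}")
        if gid not in ann.index:
            raise ValueError(f"gene {gid!r} has an image but no annotation row")
        arr = np.asarray(iio.imread(fpath), dtype=np.float64) / scale
        images.append(ISHImage(pixels=arr, gene_id=gid))
    gene_ids = list(manifest["images"].keys())
    return SyntheticCorpus(
        images=images,
        gene_ids=gene_ids,
        category_ids=list(ann.columns),
        annotations=ann.loc[gene_ids].to_numpy(dtype=np.int8),
        ground_truth_motifs=manifest["ground_truth_motifs"],
        spec=spec,
    )
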