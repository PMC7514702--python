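"""End-to-end driver: generate (or load) a corpus, train the CDAE, truncate
the decoder, extract representations, and classify GO categories — plus the
hyperparameter sweep harness (denoising rate, filter size, representation
size via pooling depth).

A single global seed fans out deterministically to per-stage seeds, and
every artifact is stamped with a hash of the full configuration, so a rerun
with the same config reproduces the summary exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cdae import bottleneck_shape
from .goclass import (AnnotationMatrix, DEFAULT_REG_GRID, EvaluationSummary,
                      evaluate_all)
from .synthetic import SyntheticCorpus, SyntheticSpec, generate_corpus, read_corpus
from .train import CDAETransformer

__all__ = [
    "PipelineConfig",
    "ClassifyConfig",
    "stage_seed",
    "config_hash",
    "run_pipeline",
    "run_sweep",
    "SWEEP_PARAMETERS",
]

log = logging.getLogger("ishcdae")

SWEEP_PARAMETERS = ("denoising_rate", "filter_size", "representation_size")
_VALID_FILTER_SIZES = (3, 5, 7, 9, 11)


@dataclass
class ClassifyConfig:
    k_folds: int = 5
    min_count: int = 15
    max_count: int = 500
    reg_grid: tuple[float, ...] = DEFAULT_REG_GRID


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; YAML-serializable."""

    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    corpus_path: str | None = None  # load instead of generate when set
    generate: bool = True
    n_pool_stages: int = 4
    n_filters: int = 4
    filter_size: int = 3
    convs_per_stage: int = 2
    denoising_rate: float = 0.20
    n_epochs: int = 50
    batch_size: int = 16
    learning_rate: float = 0.05
    lr_decay: float = 0.9
    normalization: str = "tanh"
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.generate and not self.corpus_path:
            raise ValueError("generation disabled but no corpus_path given")
        if not (0.0 <= self.denoising_rate <= 0.8):
            raise ValueError("denoising_rate must be within the sweep range [0, 0.8]")
        if self.filter_size not in _VALID_FILTER_SIZES:
            raise ValueError(f"filter_size must be one of {_VALID_FILTER_SIZES}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            sd = dict(d["synthetic"])
            for key in ("positives_per_category", "brain_ellipse"):
                if key in sd:
                    sd[key] = tuple(sd[key])
            d["synthetic"] = SyntheticSpec(**sd)
        if "classify" in d and isinstance(d["classify"], dict):
            cd = dict(d["classify"])
            if "reg_grid" in cd:
                cd["reg_grid"] = tuple(cd["reg_grid"])
            d["classify"] = ClassifyConfig(**cd)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def config_hash(config: PipelineConfig) -> str:
    """Stable hash of the full configuration; changes when any field does."""
    canon = json.dumps(config.to_dict(), sort_keys=True, default=float)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 from the global seed."""
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _load_or_generate(config: PipelineConfig) -> SyntheticCorpus:
    if config.corpus_path and not config.generate:
        log.info("loading corpus from %s", config.corpus_path)
        return read_corpus(config.corpus_path)
    spec = dataclasses.replace(config.synthetic,
                               seed=stage_seed(config.seed, "generate"),
                               pool_stages=config.n_pool_stages)
    log.info("generating corpus: %d genes, %d categories, seed %d",
             spec.n_genes, spec.n_categories, spec.seed)
    return generate_corpus(spec)


def run_pipeline(config: PipelineConfig,
                 outdir: str | Path | None = None) -> EvaluationSummary:
    """Execute generate/load -> train -> truncate -> extract -> classify.

    When ``outdir`` is given, writes the representation matrix (TSV),
    per-category fold results (CSV), the network checkpoint, the loss
    history, and a summary JSON stamped with the config hash and seed.
    """
    chash = config_hash(config)
    log.info("pipeline start (config %s, seed %d)", chash, config.seed)
    corpus = _load_or_generate(config)
    stack = np.stack([im.pixels for im in corpus.images])

    log.info("training CDAE: %d epochs, denoising rate %.2f",
             config.n_epochs, config.denoising_rate)
    cdae = CDAETransformer(
        n_pool_stages=config.n_pool_stages, n_filters=config.n_filters,
        filter_size=config.filter_size, convs_per_stage=config.convs_per_stage,
        denoising_rate=config.denoising_rate, n_epochs=config.n_epochs,
        batch_size=config.batch_size, learning_rate=config.learning_rate,
        lr_decay=config.lr_decay, normalization=config.normalization,
        random_state=stage_seed(config.seed, "train"),
    ).fit(stack)
    encoder = cdae.network_.truncate_decoder()
    log.info("extracting %d-feature representations", cdae.n_features_out_)
    X = cdae.transform(stack)

    annotations = AnnotationMatrix(gene_ids=corpus.gene_ids,
                                   category_ids=corpus.category_ids,
                                   membership=corpus.annotations)
    log.info("classifying GO categories")
    summary = evaluate_all(
        X, annotations, k=config.classify.k_folds,
        min_count=config.classify.min_count, max_count=config.classify.max_count,
        reg_grid=config.classify.reg_grid,
        seed=stage_seed(config.seed, "classify"),
    )
    log.info("pipeline done: mean AUC %.4f over %d categories",
             summary.mean_auc, len(summary.results))

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rep = pd.DataFrame(X, index=corpus.gene_ids)
        rep.to_csv(outdir / "representations.tsv", sep="\t", index_label="gene_id")
        summary.to_frame().to_csv(outdir / "category_results.csv", index=False)
        cdae.network_.save(outdir / "cdae_checkpoint.npz")
        pd.DataFrame({"epoch": range(len(cdae.loss_history_)),
                      "lr": cdae.report_.epoch_lrs,
                      "mean_loss": cdae.loss_history_}
                     ).to_csv(outdir / "loss_history.csv", index=False)
        payload = {
            "config_hash": chash,
            "seed": config.seed,
            "config": config.to_dict(),
            "mean_auc": summary.mean_auc,
            "n_features": int(cdae.n_features_out_),
            "per_category": {r.category_id: r.mean_auc for r in summary.results},
            "errors": summary.errors,
        }
        (outdir / "summary.json").write_text(json.dumps(payload, indent=1,
                                                        default=float))
    return summary


def _apply_sweep_value(config: PipelineConfig, parameter: str, value):
    if parameter == "denoising_rate":
        return dataclasses.replace(config, denoising_rate=float(value))
    if parameter == "filter_size":
        return dataclasses.replace(config, filter_size=int(value))
    if parameter == "representation_size":
        # realized by varying the pooling-stage count on a fixed input
        n = int(value)
        synthetic = dataclasses.replace(config.synthetic, pool_stages=n)
        return dataclasses.replace(config, n_pool_stages=n, synthetic=synthetic)
    raise ValueError(
        f"unknown sweep parameter {parameter!r}; expected one of {SWEEP_PARAMETERS}"
    )


def run_sweep(config: PipelineConfig, parameter: str, values,
              outdir: str | Path | None = None) -> pd.DataFrame:
    """One full pipeline run per value, everything else fixed.

    Returns a (value, mean_auc, n_features) table; with ``outdir`` also
    writes it as CSV plus an AUC-vs-value plot.
    """
    if parameter not in SWEEP_PARAMETERS:
        raise ValueError(
            f"unknown sweep parameter {parameter!r}; expected one of {SWEEP_PARAMETERS}"
        )
    rows = []
    for v in values:
        cfg = _apply_sweep_value(config, parameter, v)
        summary = run_pipeline(cfg)
        h, w = bottleneck_shape(cfg.synthetic.image_height,
                                cfg.synthetic.image_width, cfg.n_pool_stages)
        rows.append({"value": v, "mean_auc": summary.mean_auc,
                     "n_features": h * w})
        log.info("sweep %s=%s -> mean AUC %.4f", parameter, v, summary.mean_auc)
    table = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / f"sweep_{parameter}.csv", index=False)
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(table["value"], table["mean_auc"], "o-")
        ax.set_xlabel(parameter)
        ax.set_ylabel("mean AUC")
        ax.set_ylim(0.0, 1.05)
        fig.tight_layout()
        fig.savefig(outdir / f"sweep_{parameter}.png", dpi=120)
        plt.close(fig)
    return table
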