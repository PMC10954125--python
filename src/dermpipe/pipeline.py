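"""End-to-end pipeline driver in a fitted-model shape.

``DermoscopyClassifier`` is constructed from images + labels (or from a
manifest / synthetic dataset) with a :class:`PipelineConfig`; ``fit()``
executes denoise -> segment -> HOG + deep descriptors -> fuse -> split
-> entropy selection -> SMOTE-Tomek rebalancing (training rows only) ->
softmax head training, and returns a :class:`DermoscopyResults` carrying
the per-split metrics, the loss trace, the fitted selection/scaler/head
and a ``summary()`` table.

One global seed fans out to per-stage seeds through a fixed stage-name
hash, so each stage is independently reproducible.  Each stage appends a
machine-parseable record (stage, n_in, n_out, seconds, seed) to
``results.stage_log``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as dio
from .backbone import Backbone, BackboneSpec
from .exceptions import DegenerateInputError, DomainError
from .fuse_balance import (
    FUSED_DIM,
    N_SELECT,
    EntropySelection,
    entropy_scores,
    fuse_matrix,
    select_top_k,
    smote_tomek,
)
from .gradcam import SaliencyMap, grad_cam
from .hog import hog_descriptor
from .model_eval import (
    ClassifierHead,
    LossRecord,
    MetricsReport,
    TrainConfig,
    auc_ovr,
    confusion_matrix,
    cross_entropy,
    metrics_from_confusion,
    split_dataset,
    train_head,
)
from .preprocess import DiffusionParams, madf, resize_image, to_grayscale
from .segment import apply_mask, cluster_intensities, lesion_mask
from .synthgen import SyntheticDataset

logger = logging.getLogger("dermpipe")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters with the reference defaults.

    Defaults: 224x224 input, kurtosis tolerance 0.001, 2 intensity
    clusters, 64x128 HOG with 8-px cells / 9 bins, 16-conv backbone with
    a 4096-wide tap, 256 entropy bins, 1186 selected features, learning
    rate 0.001, batch 32, 40 epochs, 70:20:10 split.
    """

    image_size: int = 224
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    n_clusters: int = 2
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    entropy_bins: int = 256
    k_select: int = N_SELECT
    smote_k_neighbors: int = 5
    rebalance: bool = True
    train: TrainConfig = field(default_factory=TrainConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["diffusion"] = DiffusionParams(**d.get("diffusion", {}))
        bb = dict(d.get("backbone", {}))
        if "conv_blocks" in bb:
            bb["conv_blocks"] = tuple(tuple(b) for b in bb["conv_blocks"])
        if "fc_widths" in bb:
            bb["fc_widths"] = tuple(bb["fc_widths"])
        d["backbone"] = BackboneSpec(**bb)
        tr = dict(d.get("train", {}))
        if "split" in tr:
            tr["split"] = tuple(tr["split"])
        d["train"] = TrainConfig(**tr)
        return cls(**d)


@dataclass
class DermoscopyResults:
    """Everything the fit produced: estimates, diagnostics, artifacts."""

    config: PipelineConfig
    seed: int
    class_names: list[str]
    features: np.ndarray  # fused (n, 7876) float32
    splits: dict  # name -> index array
    selection: EntropySelection
    scaler: tuple[np.ndarray, np.ndarray]  # mean, std over selected train columns
    head: ClassifierHead
    backbone: Backbone
    loss_record: LossRecord
    metrics: dict  # split name -> MetricsReport
    rebalance_counts: dict
    stage_log: list[dict] = field(default_factory=list)

    @property
    def metrics_test(self) -> MetricsReport:
        return self.metrics["test"]

    def transform(self, features: np.ndarray) -> np.ndarray:
        mean, std = self.scaler
        return (self.selection.apply(features) - mean) / std

    def predict_from_features(self, features: np.ndarray) -> np.ndarray:
        return self.head.predict(self.transform(features))

    def predict_proba_from_features(self, features: np.ndarray) -> np.ndarray:
        return self.head.predict_proba(self.transform(features))

    def predict(self, images: list[np.ndarray]) -> list[str]:
        """Class names for new RGB images (full featurization path)."""
        feats = _featurize(images, self.config, self.backbone)
        return [self.class_names[i] for i in self.predict_from_features(feats)]

    def explain(self, image: np.ndarray, target_class: str | int | None = None) -> SaliencyMap:
        """Grad-CAM heat map over the backbone for one image."""
        rgb = resize_image(np.asarray(image, dtype=np.float64), self.config.image_size, self.config.image_size)
        if target_class is None:
            probs = self.backbone.predict_proba(rgb.astype(np.float32))
            target = int(np.argmax(probs[0]))
        elif isinstance(target_class, str):
            target = self.class_names.index(target_class)
        else:
            target = int(target_class)
        return grad_cam(self.backbone, rgb.astype(np.float32), target)

    def summary(self) -> str:
        test = self.metrics["test"]
        lines = [
            "Dermoscopy lesion classification results",
            "=" * 44,
            f"images               : {len(self.features)}",
            f"classes              : {', '.join(self.class_names)}",
            f"fused features       : {self.features.shape[1]}",
            f"selected features    : {len(self.selection.selected_idx)}",
            f"head parameters      : {self.head.n_parameters}",
            f"train/test/val sizes : "
            + "/".join(str(len(self.splits[s])) for s in ("train", "test", "val")),
            f"rebalanced train     : {self.rebalance_counts}",
            f"final train loss     : {self.loss_record.cross_entropy[-1]:.4f}",
            "-" * 44,
            "test split:",
            test.summary(),
        ]
        return "\n".join(lines)


def _log_stage(log: list[dict], stage: str, n_in: int, n_out: int, t0: float, seed: int) -> None:
    rec = {"stage": stage, "n_in": n_in, "n_out": n_out, "seconds": round(time.perf_counter() - t0, 3), "seed": seed}
    log.append(rec)
    logger.info("stage=%(stage)s n_in=%(n_in)d n_out=%(n_out)d seconds=%(seconds).3f seed=%(seed)d", rec)


def _featurize(
    images: list[np.ndarray],
    config: PipelineConfig,
    backbone: Backbone,
    stage_log: list[dict] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Denoise, segment and describe each image; returns fused (n, 7876)."""
    log = stage_log if stage_log is not None else []
    size = config.image_size

    t0 = time.perf_counter()
    grays, rgbs = [], []
    for img in images:
        rgb = resize_image(np.asarray(img, dtype=np.float64), size, size)
        rgbs.append(rgb)
        den = madf(to_grayscale(rgb), config.diffusion)
        grays.append(den.filtered)
    _log_stage(log, "preprocess", len(images), len(grays), t0, stage_seed(seed, "preprocess"))

    t0 = time.perf_counter()
    hog_rows = []
    for g in grays:
        seg = cluster_intensities(g, n_clusters=config.n_clusters)
        try:
            mask = lesion_mask(seg)
        except DegenerateInputError:
            logger.warning("degenerate segmentation; using full-image mask")
            mask = np.ones_like(g, dtype=bool)
        hog_rows.append(hog_descriptor(apply_mask(g, mask)).vector)
    _log_stage(log, "segment+hog", len(grays), len(hog_rows), t0, stage_seed(seed, "segment"))

    t0 = time.perf_counter()
    deep = backbone.tap(np.stack(rgbs).astype(np.float32))
    _log_stage(log, "deep", len(rgbs), len(deep), t0, stage_seed(seed, "deep"))

    return fuse_matrix(np.asarray(hog_rows), deep).matrix.astype(np.float32)


class DermoscopyClassifier:
    """Eight-class dermoscopy lesion classifier (fit/results object pair).

    Parameters
    ----------
    images : list of (H, W, 3) arrays on the 0-255 scale.
    labels : list of class-name strings.
    config : PipelineConfig, optional.
    """

    def __init__(self, images: list[np.ndarray], labels: list[str], config: PipelineConfig | None = None):
        if len(images) != len(labels):
            raise DomainError("images and labels differ in length")
        if not images:
            raise DomainError("empty dataset")
        self.images = images
        self.labels = list(labels)
        self.config = config or PipelineConfig()
        self.class_names = sorted(set(self.labels))

    @classmethod
    def from_dataset(cls, dataset: SyntheticDataset, config: PipelineConfig | None = None):
        return cls(dataset.images, dataset.labels, config)

    @classmethod
    def from_manifest(cls, manifest_path: str | Path, config: PipelineConfig | None = None):
        man = dio.read_manifest(manifest_path)
        return cls(dio.load_images(man), man.frame["label"].tolist(), config)

    def fit(self, seed: int = 0, features: np.ndarray | None = None) -> DermoscopyResults:
        """Run the full pipeline; ``features`` may supply a cached fused matrix."""
        cfg = self.config
        stage_log: list[dict] = []
        y = np.asarray([self.class_names.index(l) for l in self.labels], dtype=np.int64)
        if np.min(np.bincount(y)) < 3:
            raise DomainError("every class needs at least 3 samples")

        backbone = Backbone(cfg.backbone, seed=stage_seed(seed, "backbone"))
        if features is None:
            features = _featurize(self.images, cfg, backbone, stage_log, seed)
        features = np.asarray(features)
        if features.shape != (len(y), FUSED_DIM):
            raise DomainError(f"features must be (n, {FUSED_DIM})")

        t0 = time.perf_counter()
        tr, te, va = split_dataset(y, cfg.train.split, seed=stage_seed(seed, "split"))
        splits = {"train": tr, "test": te, "val": va}
        _log_stage(stage_log, "split", len(y), len(tr), t0, stage_seed(seed, "split"))

        t0 = time.perf_counter()
        scores = entropy_scores(features[tr], bins=cfg.entropy_bins)
        selection = select_top_k(scores, k=cfg.k_select, bins=cfg.entropy_bins, n_train=len(tr))
        x_sel = selection.apply(features).astype(np.float64)
        mean = x_sel[tr].mean(axis=0)
        std = x_sel[tr].std(axis=0)
        std[std == 0] = 1.0
        x_std = (x_sel - mean) / std
        _log_stage(stage_log, "select", features.shape[1], len(selection.selected_idx), t0, stage_seed(seed, "select"))

        t0 = time.perf_counter()
        x_fit, y_fit = x_std[tr], y[tr]
        rebalance_counts: dict = {}
        if cfg.rebalance:
            min_count = int(np.min(np.bincount(y_fit, minlength=len(self.class_names))[np.unique(y_fit)]))
            k_nn = min(cfg.smote_k_neighbors, min_count - 1)
            if k_nn >= 1:
                reb = smote_tomek(x_fit, y_fit, k_neighbors=k_nn, seed=stage_seed(seed, "smote"))
                x_fit, y_fit = reb.X, reb.y
                labels_u, counts_u = np.unique(y_fit, return_counts=True)
                rebalance_counts = {self.class_names[int(c)]: int(n) for c, n in zip(labels_u, counts_u)}
        _log_stage(stage_log, "rebalance", len(tr), len(y_fit), t0, stage_seed(seed, "smote"))

        t0 = time.perf_counter()
        head = ClassifierHead(
            n_features=x_fit.shape[1],
            n_classes=len(self.class_names),
            hidden=cfg.train.hidden,
            seed=stage_seed(seed, "head"),
        )
        train_cfg = dataclasses.replace(cfg.train, seed=stage_seed(seed, "train"))
        loss_record = train_head(head, x_fit, y_fit, train_cfg)
        _log_stage(stage_log, "train", len(y_fit), head.n_parameters, t0, stage_seed(seed, "train"))

        metrics: dict[str, MetricsReport] = {}
        for name, idx in splits.items():
            probs = head.predict_proba(x_std[idx])
            pred = probs.argmax(axis=1)
            rep = metrics_from_confusion(confusion_matrix(y[idx], pred, n_classes=len(self.class_names)))
            try:
                rep.auc_macro = auc_ovr(y[idx], probs)
            except DegenerateInputError:
                rep.auc_macro = None
            if len(idx):
                rep.loss_trace = [cross_entropy(probs, y[idx])]
            metrics[name] = rep
        metrics["train"].loss_trace = list(loss_record.cross_entropy)

        return DermoscopyResults(
            config=cfg,
            seed=seed,
            class_names=self.class_names,
            features=features,
            splits=splits,
            selection=selection,
            scaler=(mean, std),
            head=head,
            backbone=backbone,
            loss_record=loss_record,
            metrics=metrics,
            rebalance_counts=rebalance_counts,
            stage_log=stage_log,
        )


def run_pipeline(
    config: PipelineConfig,
    manifest_path: str | Path,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> DermoscopyResults:
    """Fit the pipeline from a manifest, caching artifacts under ``outdir``.

    A cached ``features.npy`` in ``outdir`` (from a previous run with the
    same data) is reused, making re-runs bit-identical without re-running
    the image stages.  Metrics, the confusion matrix and the loss trace
    are written as JSON/CSV.
    """
    model = DermoscopyClassifier.from_manifest(manifest_path, config)
    cached = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cache = outdir / "features.npy"
        if cache.exists():
            cached = np.load(cache)
    results = model.fit(seed=seed, features=cached)
    if outdir is not None:
        np.save(outdir / "features.npy", results.features)
        sidecar = {
            "blocks": {"hog": [0, 3780], "deep": [3780, 7876]},
            "n_images": int(len(results.features)),
            "selected_idx": results.selection.selected_idx.tolist(),
            "entropy_bins": results.selection.bins,
        }
        (outdir / "features.json").write_text(json.dumps(sidecar))
        test = results.metrics["test"]
        payload = {
            name: {
                "accuracy": rep.accuracy,
                "macro_precision": rep.macro_precision,
                "macro_recall": rep.macro_recall,
                "macro_f1": rep.macro_f1,
                "auc_macro": rep.auc_macro,
            }
            for name, rep in results.metrics.items()
        }
        (outdir / "metrics.json").write_text(json.dumps(payload, indent=2))
        np.savetxt(outdir / "confusion_test.csv", test.confusion, fmt="%d", delimiter=",")
        np.savetxt(outdir / "loss_trace.csv", np.asarray(results.loss_record.cross_entropy), delimiter=",")
    return results
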