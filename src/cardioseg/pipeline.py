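"""End-to-end training, prediction and evaluation of the segmenter.

The pipeline freezes a convolutional filter bank, extracts 224x224x64
features per subject, tiles them into 8x8 frames, assembles a labeled
pixel-feature table (optionally subsampled per subject, stratified by
class), fits the three-member voting ensemble, and at prediction time maps
the per-pixel three-class filter to a binary enlarged-region mask: class-2
pixels, with connected components (4-connectivity) smaller than
``min_region_px`` removed.  A subject is diagnosed as enlarged when any
class-2 pixel survives that filter.

Splits are always by subject, never by pixel, and flip augmentation is
applied to training subjects only.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy import ndimage

from .ensemble import (
    EnsembleConfig,
    TrainedEnsemble,
    ensemble_predict,
    fit_ensemble,
)
from .features import (
    FeatureFrame,
    FilterBank,
    extract_features,
    flatten_to_frame,
    make_filter_bank,
    tile_frames,
)
from .imaging import SIDE, Image224, LabelMask
from . import metrics as mx
from .phantoms import augment_flips

logger = logging.getLogger("cardioseg")

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
_PREDICT_CHUNK = 65536


@dataclass
class PipelineConfig:
    """Every knob of the pipeline; fully determines training given data."""

    bank_provenance: str = "seeded_random"
    bank_seed: int = 42
    frame_size: int = 8
    voting_mode: str = "soft"
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    sd_floor: float = 1e-6
    n_trees: int = 25
    n_rounds: int = 30
    learning_rate: float = 0.3
    lambda_reg: float = 1.0
    gamma_penalty: float = 0.0
    max_depth: int = 6
    min_region_px: int = 25
    augment: bool = True
    pixels_per_subject: int = 4000  # 0 = use every pixel
    seed: int = 0

    def __post_init__(self) -> None:
        if SIDE % self.frame_size:
            raise ValueError(f"frame_size must divide {SIDE}")
        if self.min_region_px < 0:
            raise ValueError("min_region_px must be >= 0")

    def ensemble_config(self) -> EnsembleConfig:
        return EnsembleConfig(
            voting_mode=self.voting_mode,
            weights=self.weights,
            sd_floor=self.sd_floor,
            n_trees=self.n_trees,
            forest_seed=self.seed,
            n_rounds=self.n_rounds,
            learning_rate=self.learning_rate,
            lambda_reg=self.lambda_reg,
            gamma_penalty=self.gamma_penalty,
            boost_seed=self.seed,
            max_depth=self.max_depth,
        )

    def make_bank(self, weights_file=None) -> FilterBank:
        return make_filter_bank(
            self.bank_provenance, seed=self.bank_seed,
            weights_file=weights_file,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "weights" in raw:
            raw["weights"] = tuple(raw["weights"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml

        data = asdict(self)
        data["weights"] = list(data["weights"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _subject_frame(
    image: Image224,
    mask: LabelMask,
    bank: FilterBank,
    frame_size: int,
) -> FeatureFrame:
    """Features for one image, assembled frame-by-frame (8x8 tiling)."""
    fmap = extract_features(image, bank)
    blocks, labels = [], []
    mask_arr = mask.classes
    for fr, fc, block in tile_frames(fmap, frame_size):
        blocks.append(block.reshape(-1, fmap.n_channels))
        labels.append(
            mask_arr[
                fr * frame_size : (fr + 1) * frame_size,
                fc * frame_size : (fc + 1) * frame_size,
            ].reshape(-1)
        )
    return FeatureFrame(np.vstack(blocks), np.concatenate(labels))


def _stratified_subsample(
    frame: FeatureFrame, n_pixels: int, rng: np.random.Generator
) -> FeatureFrame:
    """Class-stratified subsample of a labeled table, >= 1 row per class."""
    if n_pixels <= 0 or frame.n_pixels <= n_pixels:
        return frame
    labels = frame.labels
    classes, counts = np.unique(labels, return_counts=True)
    take = np.maximum(
        np.round(counts / counts.sum() * n_pixels).astype(int), 2
    )
    keep = []
    for c, t in zip(classes, take):
        idx = np.flatnonzero(labels == c)
        keep.append(rng.choice(idx, size=min(t, len(idx)), replace=False))
    keep = np.sort(np.concatenate(keep))
    return FeatureFrame(frame.rows[keep], labels[keep])


def build_training_frame(
    dataset: list[tuple[Image224, LabelMask]],
    bank: FilterBank,
    config: PipelineConfig,
) -> FeatureFrame:
    """Labeled pixel table over all (augmented) training subjects."""
    rng = np.random.default_rng(config.seed)
    frames = []
    for image, mask in dataset:
        if mask.shape != image.pixels.shape[:2]:
            raise ValueError(
                f"mask/image shape mismatch for {image.source_id!r}"
            )
        pairs = augment_flips(image, mask) if config.augment else [(image, mask)]
        budget = (
            config.pixels_per_subject // len(pairs)
            if config.pixels_per_subject
            else 0
        )
        for img, msk in pairs:
            frame = _subject_frame(img, msk, bank, config.frame_size)
            frames.append(_stratified_subsample(frame, budget, rng))
    return FeatureFrame.concat(frames)


def stratified_split(subjects, n_train: int):
    """Split a cohort by subject into (train, test), keeping at least one
    enlarged and one healthy subject in the test set when both exist.

    Test quotas per diagnosis group are proportional to group size; within
    a group, the later subjects go to the test set.  Deterministic given
    the cohort order.
    """
    n_test = len(subjects) - n_train
    if not 0 < n_test < len(subjects):
        raise ValueError("n_train must leave a non-empty train and test set")
    enlarged = [s for s in subjects if s.enlarged]
    healthy = [s for s in subjects if not s.enlarged]
    if not enlarged or not healthy:
        return list(subjects[:n_train]), list(subjects[n_train:])
    quota_enl = round(n_test * len(enlarged) / len(subjects))
    quota_enl = min(max(quota_enl, 1), n_test - 1, len(enlarged))
    quota_heal = n_test - quota_enl
    test_ids = {s.subject_id for s in enlarged[-quota_enl:]}
    test_ids |= {s.subject_id for s in healthy[-quota_heal:]}
    train = [s for s in subjects if s.subject_id not in test_ids]
    test = [s for s in subjects if s.subject_id in test_ids]
    return train, test


def train_pipeline(
    dataset: list[tuple[Image224, LabelMask]],
    config: PipelineConfig | None = None,
    bank: FilterBank | None = None,
) -> TrainedEnsemble:
    """Train the ensemble on labeled subjects; deterministic under config."""
    config = config or PipelineConfig()
    if len(dataset) < 2:
        raise ValueError("training needs at least 2 subjects")
    bank = bank or config.make_bank()
    t0 = time.perf_counter()
    frame = build_training_frame(dataset, bank, config)
    logger.info(
        "assembled training table: %d rows x %d features (%.1fs)",
        frame.n_pixels, frame.n_features, time.perf_counter() - t0,
    )
    t0 = time.perf_counter()
    model = fit_ensemble(frame.rows, frame.labels, config.ensemble_config())
    model.bank_fingerprint = bank.fingerprint()
    logger.info("fitted ensemble in %.1fs", time.perf_counter() - t0)
    return model


def _check_bank(model: TrainedEnsemble, bank: FilterBank) -> None:
    if (
        model.bank_fingerprint is not None
        and bank.fingerprint() != model.bank_fingerprint
    ):
        raise ValueError(
            "filter bank does not match the one the model was trained with "
            f"(model: {model.bank_fingerprint}, given: {bank.fingerprint()})"
        )


def predict_image(
    model: TrainedEnsemble, image: Image224, bank: FilterBank
) -> tuple[LabelMask, np.ndarray]:
    """One pass over an image: voted per-pixel classes (224x224) and
    combined class probabilities (224x224xK)."""
    _check_bank(model, bank)
    frame = flatten_to_frame(extract_features(image, bank))
    cls_chunks, prob_chunks = [], []
    for i in range(0, frame.n_pixels, _PREDICT_CHUNK):
        c, p = ensemble_predict(model, frame.rows[i : i + _PREDICT_CHUNK])
        cls_chunks.append(c)
        prob_chunks.append(p)
    h, w = frame.shape
    mask = LabelMask(
        np.concatenate(cls_chunks).reshape(h, w).astype(np.int64), n_classes=3
    )
    return mask, np.vstack(prob_chunks).reshape(h, w, -1)


def predict_proba_mask(
    model: TrainedEnsemble, image: Image224, bank: FilterBank
) -> np.ndarray:
    """Per-pixel combined class probabilities, shape (224, 224, K)."""
    return predict_image(model, image, bank)[1]


def predict_mask(
    model: TrainedEnsemble, image: Image224, bank: FilterBank
) -> LabelMask:
    """Voted per-pixel class, reshaped to the 224x224 three-class filter."""
    return predict_image(model, image, bank)[0]


def to_binary(mask3: LabelMask, min_region_px: int = 25) -> LabelMask:
    """Class-2 indicator with small 4-connected components removed."""
    binary = (mask3.classes == 2).astype(np.int64)
    if min_region_px > 0 and binary.any():
        labeled, n = ndimage.label(binary, structure=_FOUR_CONN)
        sizes = ndimage.sum_labels(binary, labeled, index=np.arange(1, n + 1))
        for comp, size in enumerate(sizes, start=1):
            if size < min_region_px:
                binary[labeled == comp] = 0
    return LabelMask(binary, n_classes=2)


def diagnose_subject(binary_mask: LabelMask) -> bool:
    """Enlarged iff any pixel survives the minimum-area filter."""
    return bool(np.any(binary_mask.classes == 1))


@dataclass
class SubjectResult:
    subject_id: str
    mask3_pred: LabelMask
    mask2_pred: LabelMask
    pixel_accuracy: float
    pixel_sensitivity: float  # NaN when the subject has no class-2 truth
    pixel_specificity: float
    dice_binary: float
    dice_macro: float
    diagnosis: bool
    truth_diagnosis: bool
    enlarged_score: float = field(default=0.0)  # mean class-2 probability


def evaluate_subject(
    model: TrainedEnsemble,
    subject_id: str,
    image: Image224,
    mask3: LabelMask,
    mask2: LabelMask,
    bank: FilterBank,
    config: PipelineConfig,
) -> SubjectResult:
    pred3, probs = predict_image(model, image, bank)
    class2_idx = int(np.searchsorted(model.class_order, 2))
    has_class2 = (
        class2_idx < len(model.class_order)
        and model.class_order[class2_idx] == 2
    )
    pred2 = to_binary(pred3, config.min_region_px)

    c2 = mx.confusion(pred3, mask3, positive_class=2)
    acc = (pred3.classes == mask3.classes).mean()
    sens = mx.sensitivity(c2) if (c2.tp + c2.fn) else float("nan")
    spec = mx.specificity(c2) if (c2.tn + c2.fp) else float("nan")
    return SubjectResult(
        subject_id=subject_id,
        mask3_pred=pred3,
        mask2_pred=pred2,
        pixel_accuracy=float(acc),
        pixel_sensitivity=sens,
        pixel_specificity=spec,
        dice_binary=mx.dice(pred2, mask2, mode="binary"),
        dice_macro=mx.dice(pred3, mask3, mode="macro"),
        diagnosis=diagnose_subject(pred2),
        truth_diagnosis=bool(np.any(mask2.classes == 1)),
        enlarged_score=(
            float(probs[:, :, class2_idx].mean()) if has_class2 else 0.0
        ),
    )


def evaluate_pipeline(
    model: TrainedEnsemble,
    dataset,
    config: PipelineConfig | None = None,
    bank: FilterBank | None = None,
) -> tuple[list[SubjectResult], dict]:
    """Score each subject and aggregate by unweighted means.

    ``dataset`` is a sequence of objects with attributes ``subject_id``,
    ``image``, ``mask3``, ``mask2`` (e.g. phantom subjects) or tuples
    ``(subject_id, image, mask3, mask2)``.
    """
    config = config or PipelineConfig()
    if not dataset:
        raise ValueError("cannot evaluate an empty dataset")
    bank = bank or config.make_bank()
    results = []
    for item in dataset:
        if hasattr(item, "image"):
            sid, image, m3, m2 = item.subject_id, item.image, item.mask3, item.mask2
        else:
            sid, image, m3, m2 = item
        t0 = time.perf_counter()
        results.append(
            evaluate_subject(model, sid, image, m3, m2, bank, config)
        )
        logger.info("evaluated %s in %.1fs", sid, time.perf_counter() - t0)

    diag_pred = np.array([r.diagnosis for r in results])
    diag_true = np.array([r.truth_diagnosis for r in results])
    c = mx.confusion(diag_pred.astype(int), diag_true.astype(int), 1)
    with np.errstate(invalid="ignore"):
        summary = {
            "n_subjects": len(results),
            "pixel_accuracy": float(np.mean([r.pixel_accuracy for r in results])),
            "pixel_sensitivity": float(
                np.nanmean([r.pixel_sensitivity for r in results])
            ),
            "pixel_specificity": float(
                np.nanmean([r.pixel_specificity for r in results])
            ),
            "dice_binary": float(np.mean([r.dice_binary for r in results])),
            "dice_macro": float(np.mean([r.dice_macro for r in results])),
            "subject_accuracy": mx.accuracy(c),
            "subject_sensitivity": (
                mx.sensitivity(c) if (c.tp + c.fn) else float("nan")
            ),
            "subject_specificity": (
                mx.specificity(c) if (c.tn + c.fp) else float("nan")
            ),
            "subject_confusion": {
                "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn
            },
        }
    return results, summary


def results_to_dataframe(results: list[SubjectResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "accuracy": r.pixel_accuracy,
                "sensitivity": r.pixel_sensitivity,
                "specificity": r.pixel_specificity,
                "dice_binary": r.dice_binary,
                "dice_macro": r.dice_macro,
                "diagnosis": r.diagnosis,
                "truth": r.truth_diagnosis,
            }
            for r in results
        ]
    )
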