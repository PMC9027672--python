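"""End-to-end orchestration and the evaluation protocol.

The full pipeline chains: Gabor preprocessing -> EPO-driven multilevel
Otsu segmentation -> feature extraction -> swarm-tuned autoencoder
classification.  Evaluation follows the usual two protocols for a 500-ish
image balanced dataset: stratified train/test splits at several training
fractions (40-80%) and stratified k-fold cross-validation (6-10 folds),
reporting sensitivity, specificity, accuracy and F-score per split plus
their average (tumor is the positive class).

Feature extraction is deterministic per image, so features are computed
once; everything fitted (feature scaling, autoencoder parameters) sees
only the training portion of each split.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .aeclassifier import AEConfig, ClassifierModel, train_mlo
from .features import extract_texture_stats
from .mlt import ThresholdSet, compute_histogram, decode_thresholds, exhaustive_mlt
from .optimizers import EPOParams, MLOParams, epo_optimize, mlt_objective
from .phantoms import GrayImage, LabeledDataset
from .preprocess import GaborParams, default_bank, gabor_filter

logger = logging.getLogger("pentumor")


class EvalError(ValueError):
    """Raised for invalid evaluation plans or datasets."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with tumor (label 1) as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvalError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, predictions, labels) -> "ConfusionMatrix":
        predictions = np.asarray(predictions)
        labels = np.asarray(labels)
        if predictions.shape != labels.shape:
            raise EvalError("predictions and labels must be equal length")
        return cls(
            tp=int(np.sum((predictions == 1) & (labels == 1))),
            fp=int(np.sum((predictions == 1) & (labels == 0))),
            tn=int(np.sum((predictions == 0) & (labels == 0))),
            fn=int(np.sum((predictions == 0) & (labels == 1))),
        )


@dataclass(frozen=True)
class MetricsRow:
    """One evaluation row; undefined metrics are NaN markers, never zeros."""

    split: str
    sensitivity: float
    specificity: float
    accuracy: float
    f_score: float

    def values(self) -> np.ndarray:
        return np.array(
            [self.sensitivity, self.specificity, self.accuracy, self.f_score]
        )


@dataclass
class MetricsReport:
    """Per-split metric rows plus their average (NaN-aware)."""

    rows: list[MetricsRow]

    @property
    def average(self) -> MetricsRow:
        stacked = np.vstack([r.values() for r in self.rows])
        if np.isnan(stacked).any():
            logger.info("undefined metric markers excluded from averages")
        with np.errstate(all="ignore"):
            avg = np.nanmean(stacked, axis=0)
        return MetricsRow("Average", *avg)

    def to_dataframe(self):
        import pandas as pd

        rows = [*self.rows, self.average]
        return pd.DataFrame(
            {
                "split": [r.split for r in rows],
                "sensitivity": [r.sensitivity for r in rows],
                "specificity": [r.specificity for r in rows],
                "accuracy": [r.accuracy for r in rows],
                "f_score": [r.f_score for r in rows],
            }
        )


def compute_metrics(cm: ConfusionMatrix, split: str = "") -> MetricsRow:
    """Sensitivity, specificity, accuracy and F-score from confusion counts.

    Requires at least one positive and one negative ground-truth sample.
    Zero-denominator metrics (e.g. precision with no positive predictions)
    are reported as NaN markers and propagate into the F-score.
    """
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise EvalError(
            "metrics need at least one positive and one negative ground-truth sample"
        )
    sensitivity = cm.tp / (cm.tp + cm.fn)
    specificity = cm.tn / (cm.tn + cm.fp)
    accuracy = (cm.tp + cm.tn) / cm.total
    if cm.tp + cm.fp == 0:
        precision = math.nan
    else:
        precision = cm.tp / (cm.tp + cm.fp)
    if math.isnan(precision) or precision + sensitivity == 0:
        f_score = math.nan
    else:
        f_score = 2 * precision * sensitivity / (precision + sensitivity)
    return MetricsRow(split, sensitivity, specificity, accuracy, f_score)


@dataclass(frozen=True)
class EvalPlan:
    """Which splits to evaluate: training fractions or k-fold fold counts."""

    mode: str = "train_split"  # or "kfold"
    train_fractions: tuple[float, ...] = (0.4, 0.5, 0.6, 0.7, 0.8)
    folds: tuple[int, ...] = (6, 7, 8, 9, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("train_split", "kfold"):
            raise EvalError(f"mode must be 'train_split' or 'kfold', got {self.mode!r}")
        if any(not (0.0 < f < 1.0) for f in self.train_fractions):
            raise EvalError("train fractions must lie in (0, 1)")
        if any(k < 2 for k in self.folds):
            raise EvalError("fold counts must be >= 2")


def split_train_test(
    dataset: LabeledDataset, fraction: float, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified train/test split at a given training fraction."""
    if not (0.0 < fraction < 1.0):
        raise EvalError(f"fraction must lie in (0, 1), got {fraction}")
    labels = dataset.labels
    counts = dataset.class_counts
    if counts[0] < 2 or counts[1] < 2:
        raise EvalError("each class needs at least 2 items to split")
    idx = np.arange(len(dataset))
    train_idx, test_idx = train_test_split(
        idx, train_size=fraction, stratify=labels, random_state=int(seed)
    )
    return dataset.subset(sorted(train_idx)), dataset.subset(sorted(test_idx))


def kfold_plan(
    dataset: LabeledDataset, folds: int, seed: int = 0
) -> list[tuple[LabeledDataset, LabeledDataset]]:
    """Stratified k-fold partition: each item tests exactly once."""
    labels = dataset.labels
    counts = dataset.class_counts
    if folds < 2:
        raise EvalError(f"folds must be >= 2, got {folds}")
    if folds > min(counts.values()):
        raise EvalError(
            f"folds ({folds}) exceeds the smallest class count ({min(counts.values())})"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed))
    return [
        (dataset.subset(sorted(tr)), dataset.subset(sorted(te)))
        for tr, te in skf.split(np.zeros(len(dataset)), labels)
    ]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the end-to-end run.

    Segmentation uses ``n_thresholds`` (K) levels; the default K = 2 yields
    three classes matching the phantoms' background/organ/tumor structure.
    The per-image EPO budget is deliberately small: phantom histograms are
    strongly trimodal and a short search already reaches the exhaustive
    optimum.
    """

    skip_gabor: bool = False
    gabor_bank: Optional[tuple[GaborParams, ...]] = None
    gabor_combine: str = "max"
    n_thresholds: int = 2
    segmentation_method: str = "epo"  # or "exhaustive"
    seg_population: int = 20
    seg_iterations: int = 40
    latent_dim: Optional[int] = None
    activation: str = "sigmoid"
    clf_population: int = 30
    clf_iterations: int = 150
    clf_leaders: int = 3
    search_bound: float = 3.0


def _item_seed(global_seed: int, item_id: int) -> int:
    """Stable per-item sub-seed below 2**31."""
    ss = np.random.SeedSequence([int(global_seed), int(item_id)])
    return int(ss.generate_state(1)[0] % (2**31))


def segment_image(
    image: GrayImage,
    k: int,
    method: str = "epo",
    seed: int = 0,
    population: int = 20,
    iterations: int = 40,
) -> tuple[ThresholdSet, np.ndarray]:
    """Threshold an image into K+1 classes; returns (thresholds, label map)."""
    from .mlt import apply_thresholds

    hist = compute_histogram(image)
    if method == "exhaustive":
        ts, _ = exhaustive_mlt(hist, k)
    elif method == "epo":
        obj = mlt_objective(hist, k)
        result = epo_optimize(
            obj,
            EPOParams(population_size=population, max_iterations=iterations, seed=seed),
        )
        ts = decode_thresholds(result.best_position, hist.levels)
    else:
        raise EvalError(f"unknown segmentation method {method!r}")
    return ts, apply_thresholds(image, ts)


def extract_dataset_features(
    images: LabeledDataset, config: PipelineConfig, seed: int = 0
) -> LabeledDataset:
    """Run preprocessing + segmentation + feature extraction on every image.

    Deterministic: each image's EPO segmentation uses a sub-seed derived
    from the global seed and the item index.
    """
    bank = list(config.gabor_bank) if config.gabor_bank else default_bank()
    items = []
    for i, (img, label) in enumerate(images.items):
        if not isinstance(img, GrayImage):
            raise EvalError(f"item {i} is not an image")
        work = img if config.skip_gabor else gabor_filter(img, bank, config.gabor_combine)
        ts, label_map = segment_image(
            work,
            config.n_thresholds,
            method=config.segmentation_method,
            seed=_item_seed(seed, i),
            population=config.seg_population,
            iterations=config.seg_iterations,
        )
        fv = extract_texture_stats(work, label_map, n_classes=config.n_thresholds + 1)
        items.append((fv, label))
        logger.debug("segmented item %d: thresholds=%s", i, ts.thresholds)
    return LabeledDataset(items)


def _evaluate_split(
    train: LabeledDataset,
    test: LabeledDataset,
    config: PipelineConfig,
    seed: int,
    split_name: str,
) -> tuple[MetricsRow, ClassifierModel]:
    x_train, _ = train.feature_matrix()
    clf_config = AEConfig(
        input_dim=x_train.shape[1],
        latent_dim=config.latent_dim,
        activation=config.activation,
    )
    model, _ = train_mlo(
        train,
        config=clf_config,
        mlo=MLOParams(
            population_size=config.clf_population,
            n_leaders=config.clf_leaders,
            max_iterations=config.clf_iterations,
            seed=seed,
        ),
        search_bound=config.search_bound,
    )
    x_test, y_test = test.feature_matrix()
    preds = model.predict(x_test)
    cm = ConfusionMatrix.from_predictions(preds, y_test)
    return compute_metrics(cm, split=split_name), model


def run_pipeline(
    images: LabeledDataset,
    config: Optional[PipelineConfig] = None,
    plan: Optional[EvalPlan] = None,
) -> MetricsReport:
    """Full evaluation: segment, featurize, then train/test per split.

    For each training fraction (or fold), an autoencoder classifier is
    tuned by MLO on the training portion only and scored on the held-out
    portion; rows mirror the split layout with a trailing average.
    Reruns with identical inputs and seeds produce identical reports.
    """
    if config is None:
        config = PipelineConfig()
    if plan is None:
        plan = EvalPlan()
    if len(images) < 10:
        raise EvalError(f"dataset must hold at least 10 items, got {len(images)}")

    features = extract_dataset_features(images, config, seed=plan.seed)
    rows: list[MetricsRow] = []
    if plan.mode == "train_split":
        for j, fraction in enumerate(plan.train_fractions):
            train, test = split_train_test(features, fraction, seed=plan.seed + j)
            row, _ = _evaluate_split(
                train, test, config, seed=_item_seed(plan.seed, 10_000 + j),
                split_name=f"TS={int(round(fraction * 100))}%",
            )
            rows.append(row)
            logger.info("split %s: accuracy=%.4f", row.split, row.accuracy)
    else:
        for j, k in enumerate(plan.folds):
            cms = []
            for f, (train, test) in enumerate(kfold_plan(features, k, seed=plan.seed + j)):
                row, model = _evaluate_split(
                    train, test, config,
                    seed=_item_seed(plan.seed, 20_000 + 100 * j + f),
                    split_name=f"CV={k}/fold{f}",
                )
                x_test, y_test = test.feature_matrix()
                cms.append(ConfusionMatrix.from_predictions(model.predict(x_test), y_test))
            pooled = ConfusionMatrix(
                tp=sum(c.tp for c in cms), fp=sum(c.fp for c in cms),
                tn=sum(c.tn for c in cms), fn=sum(c.fn for c in cms),
            )
            rows.append(compute_metrics(pooled, split=f"CV={k}"))
            logger.info("fold set %s: accuracy=%.4f", rows[-1].split, rows[-1].accuracy)
    return MetricsReport(rows)
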