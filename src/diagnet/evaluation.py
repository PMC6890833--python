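"""Stratified cross-validation harness and classification metrics.

Each fold runs the full pipeline with strict train/test isolation: the
feature mask, the EROS eigen summaries and weights, the augmentation and
the model are all derived from training-fold subjects only; held-out
subjects are only ever transformed with the training-fold mask and scored
with the trained model.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from diagnet.augmentation import AugmentationConfig, augment_training_set
from diagnet.connectivity import (
    apply_mask,
    compute_mask,
    pearson_matrix,
    upper_triangle_vector,
)
from diagnet.eros import covariance_eigen, eros_weights
from diagnet.io import RoiTimeSeries
from diagnet.model import (
    TrainConfig,
    classify_prob,
    fine_tune_slp,
    init_model,
    predict_label,
    train_joint,
)

logger = logging.getLogger(__name__)


@dataclass
class FeatureConfig:
    """Connectivity feature-extraction knobs."""

    keep_fraction: float = 0.25  # kept from each extreme of the averaged vector
    eros_components: int = 2


@dataclass
class FoldMetrics:
    """Held-out metrics of one cross-validation fold.

    Rates with an empty denominator (e.g. sensitivity when the test fold
    has no patients) are NaN, an explicit undefined marker.
    """

    fold_index: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    roc_points: list[tuple[float, float, float]] = field(default_factory=list)
    test_subjects: list[str] = field(default_factory=list)
    provenance_hash: str = ""


def confusion_metrics(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) from binary labels.

    accuracy = (TP+TN)/N, sensitivity = TP/(TP+FN) over actual patients,
    specificity = TN/(TN+FP) over actual controls. An empty class yields
    NaN for its rate rather than a silent zero.
    """
    y_true = np.asarray(y_true, dtype=int).ravel()
    y_pred = np.asarray(y_pred, dtype=int).ravel()
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("label vectors must be non-empty and aligned")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    accuracy = (tp + tn) / y_true.size
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else math.nan
    specificity = tn / (tn + fp) if (tn + fp) > 0 else math.nan
    return accuracy, sensitivity, specificity


def roc_auc(
    y_true: Sequence[int], scores: Sequence[float]
) -> tuple[float, list[tuple[float, float, float]]]:
    """Trapezoidal AUC and the ROC points (fpr, tpr, threshold).

    The trapezoidal integral over all score thresholds equals the
    tie-aware concordance P(score+ > score-) + 0.5 P(tie).
    """
    y_true = np.asarray(y_true, dtype=int).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if y_true.shape != scores.shape:
        raise ValueError("labels and scores must align")
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC needs at least one positive and one negative")
    fpr, tpr, thresholds = _sk_roc_curve(y_true, scores)
    return float(_sk_auc(fpr, tpr)), list(zip(fpr.tolist(), tpr.tolist(), thresholds.tolist()))


def _connectivity_vectors(dataset: Sequence[RoiTimeSeries]):
    return [upper_triangle_vector(pearson_matrix(ts.data)) for ts in dataset]


def _provenance_hash(train_ids: Sequence[str], mask_indices: np.ndarray) -> str:
    digest = hashlib.sha256()
    digest.update(",".join(sorted(train_ids)).encode())
    digest.update(mask_indices.tobytes())
    return digest.hexdigest()[:16]


def cross_validate(
    dataset: Sequence[RoiTimeSeries],
    k: int = 10,
    train_config: TrainConfig | None = None,
    aug_config: AugmentationConfig | None = None,
    feature_config: FeatureConfig | None = None,
    seed: int = 0,
    augment: bool = True,
) -> tuple[list[FoldMetrics], FoldMetrics]:
    """Stratified k-fold cross-validation of the full pipeline.

    Per fold: (1) feature mask from training connectivity vectors only,
    (2) EROS eigen summaries and Algorithm-style weights from training
    subjects only, (3) optional interpolation augmentation of the training
    features, (4) joint training then SLP fine-tuning, (5) scoring of the
    held-out subjects. Every subject appears in exactly one test fold.

    Returns the per-fold metrics and a mean row (fold_index -1, NaN-aware
    averaging).

    Raises
    ------
    ValueError
        If a class has fewer than k members (stratification impossible).
    """
    if train_config is None:
        train_config = TrainConfig()
    if aug_config is None:
        aug_config = AugmentationConfig(seed=seed)
    if feature_config is None:
        feature_config = FeatureConfig()
    if k < 2:
        raise ValueError("k must be >= 2")

    labels = np.array([ts.label for ts in dataset], dtype=int)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"each class needs >= k={k} members, got counts {counts.tolist()}"
        )

    # per-subject quantities that do not depend on the fold split
    vectors = _connectivity_vectors(dataset)
    eigen = [
        covariance_eigen(ts.data, n=feature_config.eros_components)
        for ts in dataset
    ]

    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_metrics: list[FoldMetrics] = []
    for fold_index, (train_idx, test_idx) in enumerate(
        splitter.split(np.zeros(len(dataset)), labels)
    ):
        mask = compute_mask(
            [vectors[i] for i in train_idx],
            keep_fraction=feature_config.keep_fraction,
        )
        train_features = [apply_mask(vectors[i], mask) for i in train_idx]
        train_labels = labels[train_idx]

        if augment and aug_config.per_sample_count > 0:
            S = np.column_stack([eigen[i].eigenvalues for i in train_idx])
            w = eros_weights(S)
            fold_aug = AugmentationConfig(
                k=aug_config.k,
                per_sample_count=aug_config.per_sample_count,
                same_class_only=aug_config.same_class_only,
                seed=aug_config.seed + fold_index,
            )
            X_train, y_train, _prov = augment_training_set(
                train_features,
                train_labels,
                [eigen[i] for i in train_idx],
                w,
                fold_aug,
            )
        else:
            X_train = np.vstack(train_features)
            y_train = train_labels

        fold_train = TrainConfig(
            bottleneck_dim=train_config.bottleneck_dim,
            joint_epochs=train_config.joint_epochs,
            finetune_epochs=train_config.finetune_epochs,
            learning_rate=train_config.learning_rate,
            batch_size=train_config.batch_size,
            loss_weights=train_config.loss_weights,
            seed=train_config.seed + fold_index,
            finetune_freezes_encoder=train_config.finetune_freezes_encoder,
        )
        params = init_model(
            input_dim=X_train.shape[1],
            bottleneck_dim=fold_train.bottleneck_dim,
            seed=fold_train.seed,
        )
        params, _trajectory = train_joint(params, X_train, y_train, fold_train)
        params = fine_tune_slp(params, X_train, y_train, fold_train)

        X_test = np.vstack([apply_mask(vectors[i], mask) for i in test_idx])
        y_test = labels[test_idx]
        scores = np.atleast_1d(classify_prob(params, X_test))
        preds = np.atleast_1d(predict_label(params, X_test))
        accuracy, sensitivity, specificity = confusion_metrics(y_test, preds)
        try:
            auc_value, roc_points = roc_auc(y_test, scores)
        except ValueError:
            auc_value, roc_points = math.nan, []

        fold_metrics.append(
            FoldMetrics(
                fold_index=fold_index,
                accuracy=accuracy,
                sensitivity=sensitivity,
                specificity=specificity,
                auc=auc_value,
                roc_points=roc_points,
                test_subjects=[dataset[i].subject_id for i in test_idx],
                provenance_hash=_provenance_hash(
                    [dataset[i].subject_id for i in train_idx], mask.indices
                ),
            )
        )
        logger.info(
            "fold %d: accuracy=%.3f auc=%.3f", fold_index, accuracy, auc_value
        )

    mean = FoldMetrics(
        fold_index=-1,
        accuracy=float(np.nanmean([f.accuracy for f in fold_metrics])),
        sensitivity=float(np.nanmean([f.sensitivity for f in fold_metrics])),
        specificity=float(np.nanmean([f.specificity for f in fold_metrics])),
        auc=float(np.nanmean([f.auc for f in fold_metrics])),
    )
    return fold_metrics, mean


def run_site_wise(
    dataset: Sequence[RoiTimeSeries],
    k: int = 5,
    train_config: TrainConfig | None = None,
    aug_config: AugmentationConfig | None = None,
    feature_config: FeatureConfig | None = None,
    seed: int = 0,
    augment: bool = True,
) -> tuple[dict[str, tuple[list[FoldMetrics], FoldMetrics]], FoldMetrics | None]:
    """Independent cross-validation per imaging site.

    Sites too small for stratified k-fold are skipped with a logged
    reason. Returns per-site results and the unweighted cross-site
    average of the per-site mean metrics (None if every site skipped).
    """
    sites: dict[str, list[RoiTimeSeries]] = {}
    for ts in dataset:
        sites.setdefault(ts.site_id or "unknown", []).append(ts)

    results: dict[str, tuple[list[FoldMetrics], FoldMetrics]] = {}
    for site, members in sorted(sites.items()):
        try:
            results[site] = cross_validate(
                members,
                k=k,
                train_config=train_config,
                aug_config=aug_config,
                feature_config=feature_config,
                seed=seed,
                augment=augment,
            )
        except ValueError as exc:
            logger.warning("site %s skipped: %s", site, exc)

    if not results:
        return results, None
    means = [mean for _folds, mean in results.values()]
    average = FoldMetrics(
        fold_index=-1,
        accuracy=float(np.nanmean([m.accuracy for m in means])),
        sensitivity=float(np.nanmean([m.sensitivity for m in means])),
        specificity=float(np.nanmean([m.specificity for m in means])),
        auc=float(np.nanmean([m.auc for m in means])),
    )
    return results, average
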