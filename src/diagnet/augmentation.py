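"""SMOTE-style data augmentation guided by EROS similarity.

For every real training sample p, its k nearest same-class neighbours
(by EROS similarity on the raw time series) are found, one neighbour q is
drawn uniformly, and a synthetic sample

    p' = alpha * p + (1 - alpha) * q,   alpha ~ Uniform[0, 1]

is added with p's label. With one synthetic sample per real sample the
training set doubles. Interpolation happens in masked-correlation feature
space, never on raw time series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from diagnet.eros import EigenSummary, ErosWeights, nearest_neighbors

logger = logging.getLogger(__name__)


@dataclass
class AugmentationConfig:
    """Knobs for EROS-kNN interpolation augmentation.

    k : neighbour count (default 5, the classic SMOTE choice).
    per_sample_count : synthetic samples per real sample (default 1,
        doubling the training set).
    same_class_only : restrict neighbours to the seed sample's class.
    seed : RNG seed; the augmented set is bit-reproducible from it.
    """

    k: int = 5
    per_sample_count: int = 1
    same_class_only: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.per_sample_count < 0:
            raise ValueError("per_sample_count must be >= 0")


class Provenance(NamedTuple):
    """Audit record for one synthetic sample."""

    seed_index: int
    neighbor_index: int
    alpha: float


def interpolate(p: np.ndarray, q: np.ndarray, alpha: float) -> np.ndarray:
    """Convex combination alpha*p + (1-alpha)*q of two feature vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return alpha * p + (1.0 - alpha) * q


def augment_training_set(
    features: Sequence[np.ndarray],
    labels: Sequence[int],
    eigen: Sequence[EigenSummary],
    w: ErosWeights,
    config: AugmentationConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, list[Provenance]]:
    """Augment a training fold by EROS-kNN linear interpolation.

    Returns the stacked real+synthetic feature matrix, the matching label
    vector (real samples first, in input order), and one provenance record
    (seed index, neighbour index, alpha) per synthetic sample. A sample
    with no eligible neighbour is skipped with a warning, relaxing the
    N*(1+per_sample_count) size guarantee.

    Must only ever see training-fold data: augmenting before the
    train/test split would leak test subjects into training.
    """
    if config is None:
        config = AugmentationConfig()
    n = len(features)
    if not (n == len(labels) == len(eigen)) or n == 0:
        raise ValueError("features, labels and eigen summaries must align")

    rng = np.random.default_rng(config.seed)
    features = [np.asarray(f, dtype=float) for f in features]
    labels = np.asarray(labels, dtype=int)

    synthetic: list[np.ndarray] = []
    synthetic_labels: list[int] = []
    provenance: list[Provenance] = []
    neighbour_cache: dict[int, list[int]] = {}

    for _round in range(config.per_sample_count):
        for i in range(n):
            if i not in neighbour_cache:
                try:
                    neighbour_cache[i] = nearest_neighbors(
                        i,
                        eigen,
                        labels,
                        w,
                        k=config.k,
                        same_class_only=config.same_class_only,
                    )
                except ValueError:
                    logger.warning(
                        "sample %d has no eligible neighbour; skipped", i
                    )
                    neighbour_cache[i] = []
            neighbours = neighbour_cache[i]
            if not neighbours:
                continue
            j = int(rng.choice(neighbours))
            alpha = float(rng.uniform(0.0, 1.0))
            synthetic.append(interpolate(features[i], features[j], alpha))
            synthetic_labels.append(int(labels[i]))
            provenance.append(Provenance(i, j, alpha))

    out_features = np.vstack([np.vstack(features)] + ([np.vstack(synthetic)] if synthetic else []))
    out_labels = np.concatenate([labels, np.array(synthetic_labels, dtype=int)])
    return out_features, out_labels, provenance


def provenance_to_csv(provenance: Sequence[Provenance], path) -> None:
    """Export provenance records as seed_index,neighbor_index,alpha CSV."""
    import pandas as pd

    pd.DataFrame(provenance, columns=["seed_index", "neighbor_index", "alpha"]).to_csv(
        path, index=False
    )
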