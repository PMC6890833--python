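"""Pearson functional connectivity and extreme-correlation feature masking.

The functional connectivity of a subject is the m x m matrix of Pearson
correlations between region time series. Only the strictly upper triangle
(q = m(m-1)/2 values) is kept as a feature vector. Feature selection keeps
the indices of the most positive and most negative *training-set-averaged*
correlations (by default the top and bottom quarters, i.e. half of all
pairs), discarding the intermediate ones.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ConnectivityVector:
    """Upper-triangle Pearson correlations of one subject.

    ``values[k]`` is the correlation of region pair (i, j), i < j, in
    row-major pair order; length q = m(m-1)/2.
    """

    values: np.ndarray
    m: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        q = self.m * (self.m - 1) // 2
        if self.values.shape != (q,):
            raise ValueError(
                f"connectivity vector for m={self.m} must have length {q}, "
                f"got {self.values.shape}"
            )


@dataclass
class FeatureMask:
    """Sorted index set into a length-q connectivity vector."""

    indices: np.ndarray
    q: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size and (
            np.any(np.diff(self.indices) <= 0)
            or self.indices[0] < 0
            or self.indices[-1] >= self.q
        ):
            raise ValueError("mask indices must be strictly increasing and < q")

    def __len__(self) -> int:
        return int(self.indices.size)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"q": self.q, "indices": self.indices.tolist()})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureMask":
        payload = json.loads(Path(path).read_text())
        return cls(indices=np.array(payload["indices"]), q=payload["q"])


def pearson_matrix(ts: np.ndarray) -> np.ndarray:
    """Full Pearson correlation matrix of a T x m time-series matrix.

    Zero-variance (constant) columns get correlation 0 with every other
    column by convention — degenerate regions should not abort a fold —
    but keep a unit diagonal.

    Raises
    ------
    ValueError
        If fewer than two timepoints are supplied.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 2:
        raise ValueError(f"need a T x m matrix with T >= 2, got shape {ts.shape}")
    centered = ts - ts.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    degenerate = norms == 0.0
    if degenerate.any():
        logger.warning(
            "%d zero-variance column(s); their correlations set to 0",
            int(degenerate.sum()),
        )
    safe = np.where(degenerate, 1.0, norms)
    unit = centered / safe
    corr = unit.T @ unit
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    # clip round-off excursions outside [-1, 1]
    return np.clip(corr, -1.0, 1.0)


def upper_triangle_vector(corr: np.ndarray) -> ConnectivityVector:
    """Strictly-upper-triangle entries of a symmetric matrix, row-major.

    Pair order: (0,1), (0,2), ..., (0,m-1), (1,2), ... as produced by
    ``numpy.triu_indices``.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {corr.shape}")
    m = corr.shape[0]
    iu = np.triu_indices(m, k=1)
    return ConnectivityVector(values=corr[iu], m=m)


def pair_to_index(i: int, j: int, m: int) -> int:
    """Upper-triangle vector position of region pair (i, j), i < j."""
    if not 0 <= i < j < m:
        raise ValueError(f"need 0 <= i < j < m, got ({i}, {j}) with m={m}")
    return i * m - i * (i + 1) // 2 + (j - i - 1)


def compute_mask(
    training_vectors: Sequence[ConnectivityVector | np.ndarray],
    keep_fraction: float = 0.25,
) -> FeatureMask:
    """Extreme-correlation mask from training-set-averaged connectivity.

    Averages the training vectors element-wise and keeps the indices of
    the ``floor(q * keep_fraction)`` largest and equally many smallest
    averaged values (default quarter each, half of all pairs). Ties are
    broken toward the lower index, so the mask is deterministic.

    Only training-fold vectors may be passed: the mask is the only place
    feature selection sees the data, and computing it from held-out
    subjects would leak test information.
    """
    if len(training_vectors) == 0:
        raise ValueError("cannot compute a mask from zero training vectors")
    arrays = [
        v.values if isinstance(v, ConnectivityVector) else np.asarray(v, dtype=float)
        for v in training_vectors
    ]
    q = arrays[0].shape[0]
    for a in arrays:
        if a.shape != (q,):
            raise ValueError("training vectors have mixed lengths")
    mean = np.mean(arrays, axis=0)

    n_keep = int(np.floor(q * keep_fraction))
    # stable mergesort => ties resolved toward the lower index
    order = np.argsort(mean, kind="stable")
    smallest = order[:n_keep]
    descending = np.lexsort((np.arange(q), -mean))
    # the two arms stay disjoint even under massive ties, so the mask size
    # is always 2*floor(q/4)
    taken = np.zeros(q, dtype=bool)
    taken[smallest] = True
    largest = np.fromiter(
        (i for i in descending if not taken[i]), dtype=int, count=-1
    )[:n_keep]
    indices = np.sort(np.concatenate([smallest, largest]))
    return FeatureMask(indices=indices, q=q)


def apply_mask(
    v: ConnectivityVector | np.ndarray, mask: FeatureMask
) -> np.ndarray:
    """Restrict a connectivity vector to the masked indices (index order)."""
    values = v.values if isinstance(v, ConnectivityVector) else np.asarray(v, float)
    if values.shape != (mask.q,):
        raise ValueError(
            f"vector length {values.shape} does not match mask q={mask.q}"
        )
    return values[mask.indices]
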