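"""EROS (Extended Frobenius Norm) similarity between multivariate time series.

EROS compares two multivariate time series through the eigenstructure of
their region-covariance matrices:

    EROS(A, B, w) = sum_i  w_i * |<a_i, b_i>|

where a_i, b_i are the rank-i unit eigenvectors of the two covariance
matrices and w is a non-negative weight vector, summing to one, derived
from the eigenvalues of *all* items in the collection. Because the
eigenvectors are orthonormal the score lies in [0, 1], equals 1 for
identical eigenbases, and is invariant to eigenvector sign flips.

For speed only the ``n`` leading components are kept (default 2); the
per-subject eigen summary is computed once and cached by subject id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_AGGREGATES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "mean": lambda rows: rows.mean(axis=1),
    "min": lambda rows: rows.min(axis=1),
    "max": lambda rows: rows.max(axis=1),
}


@dataclass
class EigenSummary:
    """Leading eigenpairs of one subject's m x m sample covariance.

    eigenvalues : (n,) descending, signal-units squared.
    eigenvectors : (n, m) rows, each unit-norm; row i pairs with
        eigenvalue i. Signs are canonicalized so the largest-magnitude
        entry of each vector is positive.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        if self.eigenvectors.ndim != 2 or self.eigenvalues.shape != (
            self.eigenvectors.shape[0],
        ):
            raise ValueError("eigenvalues and eigenvector rows must align")
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be sorted descending")

    @property
    def n(self) -> int:
        return int(self.eigenvalues.shape[0])


@dataclass
class ErosWeights:
    """Normalized component weights for the EROS score."""

    w: np.ndarray
    aggregate: str = "mean"

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if np.any(self.w < 0):
            raise ValueError("EROS weights must be non-negative")
        if abs(float(self.w.sum()) - 1.0) > 1e-12:
            raise ValueError("EROS weights must sum to 1")

    @property
    def n(self) -> int:
        return int(self.w.shape[0])


def covariance_eigen(ts, n: int = 2) -> EigenSummary:
    """Leading eigenpairs of the sample covariance of a T x m series.

    The covariance uses column centering and the T-1 divisor. The default
    of two components follows the observation that truncating to the two
    leading eigenvectors leaves nearest-neighbour rankings essentially
    unchanged while making the pairwise similarity much cheaper.

    Parameters
    ----------
    ts : RoiTimeSeries or ndarray of shape (T, m)
    n : int
        Number of leading components, 1 <= n <= m.
    """
    data = getattr(ts, "data", ts)
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError(f"need a T x m matrix with T >= 2, got {data.shape}")
    m = data.shape[1]
    if not 1 <= n <= m:
        raise ValueError(f"component count n={n} must satisfy 1 <= n <= m={m}")

    cov = np.cov(data, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1][:n]
    eigenvalues = evals[order]
    eigenvectors = evecs[:, order].T  # rows
    # canonical sign: the largest-|entry| coordinate is positive
    for row in eigenvectors:
        pivot = np.argmax(np.abs(row))
        if row[pivot] < 0:
            row *= -1.0
    return EigenSummary(eigenvalues=eigenvalues, eigenvectors=eigenvectors)


def eros_weights(S: np.ndarray, aggregate: str = "mean") -> ErosWeights:
    """Component weight vector from the eigenvalue matrix of a collection.

    ``S`` is n x N: column i holds the (retained) eigenvalues of item i.
    Each column is normalized to sum 1, each row is aggregated (default
    mean) across items, and the aggregated vector is renormalized to sum 1.
    When fewer than m components are retained, the per-item normalization
    divides by the sum of the retained eigenvalues only, which keeps the
    final weights summing exactly to one.

    Raises
    ------
    ValueError
        On negative entries or a zero-sum column (a degenerate item whose
        retained eigenvalues all vanish).
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[1] < 1:
        raise ValueError(f"S must be an n x N matrix with N >= 1, got {S.shape}")
    if np.any(S < 0):
        raise ValueError("eigenvalue matrix has negative entries")
    col_sums = S.sum(axis=0)
    if np.any(col_sums <= 0):
        bad = int(np.argmin(col_sums))
        raise ValueError(f"item {bad} has zero-sum eigenvalues (degenerate)")
    if aggregate not in _AGGREGATES:
        raise ValueError(
            f"unknown aggregate {aggregate!r}; choose from {sorted(_AGGREGATES)}"
        )
    normalized = S / col_sums
    w = _AGGREGATES[aggregate](normalized)
    w = w / w.sum()
    return ErosWeights(w=w, aggregate=aggregate)


def eros_similarity(a: EigenSummary, b: EigenSummary, w: ErosWeights) -> float:
    """Weighted sum of absolute cosines between rank-paired eigenvectors.

    Symmetric in its two arguments and bounded in [0, 1]; equals 1 when
    the two eigenbases agree up to sign.
    """
    if not (a.n == b.n == w.n):
        raise ValueError(
            f"component counts differ: A has {a.n}, B has {b.n}, w has {w.n}"
        )
    cosines = np.abs(np.einsum("im,im->i", a.eigenvectors, b.eigenvectors))
    return float(np.dot(w.w, np.minimum(cosines, 1.0)))


def nearest_neighbors(
    target_index: int,
    eigen: Sequence[EigenSummary],
    labels: Sequence[int],
    w: ErosWeights,
    k: int = 5,
    same_class_only: bool = True,
) -> list[int]:
    """Indices of the up-to-k most EROS-similar items to ``eigen[target_index]``.

    Candidates are all other items, restricted to the target's class when
    ``same_class_only`` (SMOTE-style augmentation interpolates within a
    class). Ties in similarity break toward the lower candidate index.
    Returns fewer than k neighbours (with a warning) when the class is
    small; raises if no candidate is eligible.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    target = eigen[target_index]
    target_label = labels[target_index]
    scored: list[tuple[float, int]] = []
    for idx, (summary, label) in enumerate(zip(eigen, labels)):
        if idx == target_index:
            continue
        if same_class_only and label != target_label:
            continue
        scored.append((eros_similarity(target, summary, w), idx))
    if not scored:
        raise ValueError(
            f"no eligible neighbour for item {target_index} "
            f"(class {target_label})"
        )
    scored.sort(key=lambda pair: (-pair[0], pair[1]))
    if len(scored) < k:
        logger.warning(
            "item %d: only %d eligible neighbour(s) for k=%d",
            target_index,
            len(scored),
            k,
        )
    return [idx for _score, idx in scored[:k]]
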