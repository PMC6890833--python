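"""Two-class synthetic multivariate Gaussian time series with known structure.

Both classes draw zero-mean Gaussian time series. Class 0 uses a
background covariance with unit variances and a uniform off-diagonal
``base_correlation``; class 1 shifts the covariance at a known set of
region pairs by +/-delta (signs alternating across pairs so both the
high-correlation and the anti-correlation arms of the feature mask are
exercised). The perturbed pairs are the ground truth a feature-selection
or classification pipeline should recover, which makes every stage
testable without any imaging data.

The series are temporally white by default — Pearson correlation and the
covariance eigenstructure, the only statistics the pipeline consumes, are
then fully controlled by the specified covariance. An optional AR(1)
coefficient adds temporal smoothness while preserving the stationary
cross-covariance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from diagnet.connectivity import FeatureMask, pair_to_index
from diagnet.io import RoiTimeSeries

logger = logging.getLogger(__name__)


def default_perturbed_pairs(m: int, n_pairs: int) -> list[tuple[int, int]]:
    """Deterministic spread of region pairs.

    Vertex-disjoint pairs (0,1), (2,3), ... come first; when more pairs are
    needed, stride-2 pairs are added at positions spread across the
    regions. Spreading keeps the overlap graph sparse (short paths rather
    than cycles), so the perturbed covariance stays close to positive
    definite and needs at most a small ridge.
    """
    pairs: list[tuple[int, int]] = []
    for i in range(0, m - 1, 2):
        pairs.append((i, i + 1))
        if len(pairs) == n_pairs:
            return pairs
    for stride in range(2, m):
        span = m - stride
        half = max(span // 2, 1)
        # interleave the two halves: 0, half, 1, half+1, ...
        order = [
            i
            for pair_pos in range(half)
            for i in (pair_pos, pair_pos + half)
            if i < span
        ] + list(range(2 * half, span))
        for i in order:
            pair = (i, i + stride)
            if pair not in pairs:
                pairs.append(pair)
            if len(pairs) == n_pairs:
                return pairs
    raise ValueError(f"cannot choose {n_pairs} distinct pairs among {m} regions")


@dataclass
class SyntheticSpec:
    """Generator settings; defaults give a clearly separable two-class set.

    delta is the covariance shift at each perturbed pair (sign alternates
    across pairs); base_correlation the uniform background off-diagonal.
    """

    m: int = 20
    T: int = 150
    n_per_class: int = 50
    perturbed_pairs: list[tuple[int, int]] = field(default_factory=list)
    delta: float = 0.6
    base_correlation: float = 0.1
    n_sites: int = 1
    site_shift: float = 0.0
    ar_coefficient: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.perturbed_pairs:
            self.perturbed_pairs = default_perturbed_pairs(self.m, 12)
        seen = set()
        for i, j in self.perturbed_pairs:
            if not 0 <= i < j < self.m:
                raise ValueError(f"invalid region pair ({i}, {j}) for m={self.m}")
            if (i, j) in seen:
                raise ValueError(f"duplicate perturbed pair ({i}, {j})")
            seen.add((i, j))
        if self.m < 2 or self.T < 2 or self.n_per_class < 1:
            raise ValueError("need m >= 2, T >= 2, n_per_class >= 1")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in [0, 1)")


def class_covariances(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """(Sigma0, Sigma1): background and perturbed covariance matrices.

    Both are ridge-adjusted to be symmetric positive definite (minimum
    eigenvalue > 1e-6) when the perturbation pushes them indefinite;
    generation fails with advice if no modest ridge suffices.
    """
    m = spec.m
    sigma0 = np.full((m, m), spec.base_correlation)
    np.fill_diagonal(sigma0, 1.0)
    sigma1 = sigma0.copy()
    for idx, (i, j) in enumerate(spec.perturbed_pairs):
        sign = 1.0 if idx % 2 == 0 else -1.0
        sigma1[i, j] += sign * spec.delta
        sigma1[j, i] += sign * spec.delta

    out = []
    for name, sigma in (("class 0", sigma0), ("class 1", sigma1)):
        min_eig = float(np.linalg.eigvalsh(sigma).min())
        if min_eig <= 1e-6:
            ridge = 1e-5 - min_eig
            if ridge > 0.5:
                raise ValueError(
                    f"{name} covariance is far from positive definite "
                    f"(min eigenvalue {min_eig:.3f}); use a smaller delta"
                )
            logger.warning(
                "%s covariance ridge-adjusted by %.4g to restore SPD", name, ridge
            )
            sigma = sigma + ridge * np.eye(m)
        out.append(sigma)
    return out[0], out[1]


def _draw_series(
    rng: np.random.Generator, cov: np.ndarray, T: int, phi: float
) -> np.ndarray:
    chol = np.linalg.cholesky(cov)
    white = rng.standard_normal((T, cov.shape[0])) @ chol.T
    if phi == 0.0:
        return white
    # AR(1) filter with innovation scaling that preserves the stationary cov
    out = np.empty_like(white)
    out[0] = white[0]
    scale = np.sqrt(1.0 - phi**2)
    for t in range(1, T):
        out[t] = phi * out[t - 1] + scale * white[t]
    return out


def make_dataset(
    spec: SyntheticSpec,
) -> tuple[list[RoiTimeSeries], list[tuple[int, int]]]:
    """Generate the two-class dataset; returns (subjects, ground-truth pairs).

    Subjects alternate class in the output (s0000 patient, s0001 control,
    ...) and are assigned round-robin to ``n_sites`` pseudo-sites. Fully
    reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    sigma0, sigma1 = class_covariances(spec)
    subjects: list[RoiTimeSeries] = []
    counter = 0
    for subject_pair in range(spec.n_per_class):
        # one patient/control pair per iteration, both sent to the same
        # pseudo-site so sites stay class-balanced
        site_index = subject_pair % spec.n_sites
        for label, cov in ((1, sigma1), (0, sigma0)):
            data = _draw_series(rng, cov, spec.T, spec.ar_coefficient)
            if spec.site_shift:
                data = data + spec.site_shift * site_index
            subjects.append(
                RoiTimeSeries(
                    subject_id=f"s{counter:04d}",
                    data=data,
                    label=label,
                    site_id=f"site{site_index}",
                )
            )
            counter += 1
    return subjects, list(spec.perturbed_pairs)


def mask_recovery_rate(
    mask: FeatureMask, truth: list[tuple[int, int]], m: int
) -> float:
    """Fraction of ground-truth perturbed pairs captured by a feature mask.

    An empty truth set is vacuously fully recovered (1.0).
    """
    if not truth:
        return 1.0
    mask_set = set(int(i) for i in mask.indices)
    hits = sum(1 for i, j in truth if pair_to_index(i, j, m) in mask_set)
    return hits / len(truth)


def write_dataset(
    subjects: list[RoiTimeSeries],
    truth: list[tuple[int, int]],
    out_dir: str | Path,
) -> None:
    """Write .1D files, a phenotype CSV and a ground-truth JSON to a directory,
    in exactly the formats the readers consume."""
    import pandas as pd

    from diagnet.io import write_roi_timeseries

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts in subjects:
        write_roi_timeseries(ts, out_dir / f"{ts.subject_id}.1D")
        rows.append(
            {
                "SUB_ID": ts.subject_id,
                # ABIDE convention: 1 = patient, 2 = control
                "DX_GROUP": 1 if ts.label == 1 else 2,
                "SITE_ID": ts.site_id or "site0",
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "phenotypes.csv", index=False)
    (out_dir / "ground_truth.json").write_text(
        json.dumps({"perturbed_pairs": [list(p) for p in truth]})
    )
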