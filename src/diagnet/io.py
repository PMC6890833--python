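"""Readers and writers for ROI time-series files, phenotype tables and metrics.

Time-series files follow the ABIDE ``.1D`` dialect: whitespace-delimited
numeric text, one scan timepoint per row, one region (ROI) per column,
``#`` starting a comment line. Phenotype tables are delimited files with a
subject-id, diagnosis-code and site-id column; diagnosis codes are mapped
to the internal binary convention (1 = patient, 0 = control) at read time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: ABIDE convention: DX_GROUP 1 = patient (here: ASD), 2 = typical control.
DEFAULT_LABEL_MAPPING: dict[int, int] = {1: 1, 2: 0}


class FormatError(ValueError):
    """Raised for ragged, empty or non-numeric time-series files."""


class PhenotypeError(ValueError):
    """Raised for unknown diagnosis codes or duplicate subject ids."""


@dataclass
class RoiTimeSeries:
    """One subject's T x m matrix of region-averaged signals.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    data : ndarray of shape (T, m)
        Signal values; T timepoints, m regions. Must be finite.
    label : int or None
        Binary diagnosis, 1 = patient, 0 = control.
    site_id : str or None
        Imaging-site identifier, when known.
    """

    subject_id: str
    data: np.ndarray
    label: int | None = None
    site_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError(
                f"time series for {self.subject_id!r} must be 2-D, "
                f"got shape {self.data.shape}"
            )
        t, m = self.data.shape
        if t < 2 or m < 2:
            raise FormatError(
                f"time series for {self.subject_id!r} needs T >= 2 and m >= 2, "
                f"got T={t}, m={m}"
            )
        if not np.all(np.isfinite(self.data)):
            raise FormatError(
                f"time series for {self.subject_id!r} contains non-finite entries"
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class PhenotypeTable:
    """Subject-level diagnosis and site assignments with binary labels."""

    records: list[tuple[str, int, str]] = field(default_factory=list)
    label_mapping: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_MAPPING)
    )

    def label_of(self, subject_id: str) -> int:
        for sid, code, _site in self.records:
            if sid == subject_id:
                return self.label_mapping[code]
        raise KeyError(subject_id)

    def site_of(self, subject_id: str) -> str:
        for sid, _code, site in self.records:
            if sid == subject_id:
                return site
        raise KeyError(subject_id)

    @property
    def subject_ids(self) -> list[str]:
        return [sid for sid, _c, _s in self.records]


def read_roi_timeseries(
    path: str | Path,
    subject_id: str | None = None,
    has_header: bool = False,
) -> RoiTimeSeries:
    """Read one subject's ROI time series from a ``.1D``-style text file.

    Rows are timepoints in file order, columns are regions in file order.
    Lines beginning with ``#`` (after optional whitespace) are comments.

    Parameters
    ----------
    path : path-like
        File to read.
    subject_id : str, optional
        Defaults to the file stem.
    has_header : bool
        If true, the first non-comment line is a column-header row and is
        skipped.

    Raises
    ------
    FormatError
        On ragged rows (naming the offending line), non-numeric tokens, or
        an empty / comment-only file.
    """
    path = Path(path)
    if subject_id is None:
        subject_id = path.stem

    rows: list[list[float]] = []
    width: int | None = None
    header_pending = has_header
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if header_pending:
                header_pending = False
                continue
            tokens = stripped.split()
            try:
                values = [float(tok) for tok in tokens]
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric token in {stripped!r}"
                ) from exc
            if width is None:
                width = len(values)
            elif len(values) != width:
                raise FormatError(
                    f"{path}:{lineno}: row has {len(values)} values, "
                    f"expected {width}"
                )
            rows.append(values)

    if not rows:
        raise FormatError(f"{path}: no data rows (empty or comment-only file)")

    return RoiTimeSeries(subject_id=subject_id, data=np.array(rows, dtype=float))


def write_roi_timeseries(ts: RoiTimeSeries, path: str | Path) -> None:
    """Write a time series in the ``.1D`` dialect read by `read_roi_timeseries`."""
    np.savetxt(path, ts.data, fmt="%.10g", header=f"subject {ts.subject_id}")


def read_phenotypes(
    path: str | Path,
    label_mapping: Mapping[int, int] | None = None,
    subject_col: str = "SUB_ID",
    diagnosis_col: str = "DX_GROUP",
    site_col: str = "SITE_ID",
) -> PhenotypeTable:
    """Read a phenotype CSV and map diagnosis codes to binary labels.

    The default column names and code mapping follow the ABIDE phenotype
    file convention (DX_GROUP 1 -> patient/1, 2 -> control/0).

    Raises
    ------
    PhenotypeError
        On an unknown diagnosis code or a duplicate subject id.
    KeyError
        If a required column is missing.
    """
    if label_mapping is None:
        label_mapping = dict(DEFAULT_LABEL_MAPPING)
    df = pd.read_csv(path)
    for col in (subject_col, diagnosis_col, site_col):
        if col not in df.columns:
            raise KeyError(f"phenotype file {path} lacks column {col!r}")

    records: list[tuple[str, int, str]] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = str(row[subject_col])
        code = int(row[diagnosis_col])
        site = str(row[site_col])
        if sid in seen:
            raise PhenotypeError(f"duplicate subject id {sid!r} in {path}")
        if code not in label_mapping:
            raise PhenotypeError(
                f"subject {sid!r}: diagnosis code {code} not in label mapping "
                f"{sorted(label_mapping)}"
            )
        seen.add(sid)
        records.append((sid, code, site))
    return PhenotypeTable(records=records, label_mapping=dict(label_mapping))


def write_metrics(results: Sequence, path: str | Path) -> None:
    """Write per-fold metrics plus a mean row; ROC points go to a sibling file.

    Produces ``path`` with columns fold, accuracy, sensitivity, specificity,
    auc (one row per fold, final row ``mean``) and ``<stem>_roc.csv`` with
    per-fold (fpr, tpr, threshold) triples.

    Raises
    ------
    ValueError
        If `results` is empty.
    """
    if not results:
        raise ValueError("cannot write a metrics report for zero folds")
    path = Path(path)

    rows = []
    for fm in results:
        rows.append(
            {
                "fold": fm.fold_index,
                "accuracy": fm.accuracy,
                "sensitivity": fm.sensitivity,
                "specificity": fm.specificity,
                "auc": fm.auc,
            }
        )
    df = pd.DataFrame(rows)
    mean_row = df.drop(columns="fold").mean(numeric_only=True)
    mean_row["fold"] = "mean"
    df = pd.concat([df, mean_row.to_frame().T], ignore_index=True)
    df = df[["fold", "accuracy", "sensitivity", "specificity", "auc"]]
    df.to_csv(path, index=False)

    roc_rows = []
    for fm in results:
        for fpr, tpr, thr in fm.roc_points:
            roc_rows.append(
                {"fold": fm.fold_index, "fpr": fpr, "tpr": tpr, "threshold": thr}
            )
    roc_path = path.with_name(path.stem + "_roc.csv")
    pd.DataFrame(roc_rows, columns=["fold", "fpr", "tpr", "threshold"]).to_csv(
        roc_path, index=False
    )
    logger.info("wrote metrics to %s and ROC points to %s", path, roc_path)
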