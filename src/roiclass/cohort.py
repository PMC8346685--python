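"""Cohort container and delimited-table IO for ROI feature tables.

A cohort table is a flat CSV/TSV with one row per subject: the metadata
columns ``subject_id, group, site, age, sex`` followed by one column per
schema feature. Columns may appear in any order in the file; on load they
are reordered to schema order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .schemas import FeatureSchema, SchemaError

logger = logging.getLogger(__name__)

GROUPS: tuple[str, ...] = ("HC", "TLE-HS-L", "TLE-HS-R", "TLE-NS-L", "TLE-NS-R")
META_COLUMNS: tuple[str, ...] = ("subject_id", "group", "site", "age", "sex")

#: Cell contents treated as missing, besides the empty cell.
NA_MARKERS: tuple[str, ...] = ("NA", "NaN", "nan")


class CohortError(ValueError):
    """Raised for malformed cohorts or invalid selections."""


@dataclass(frozen=True)
class ROICohort:
    """Subject metadata plus an M x N feature matrix aligned to a schema."""

    subjects: pd.DataFrame  # columns META_COLUMNS, M rows
    X: np.ndarray  # M x N float matrix in schema order
    schema: FeatureSchema

    def __post_init__(self) -> None:
        if list(self.subjects.columns) != list(META_COLUMNS):
            raise CohortError(f"metadata columns must be {META_COLUMNS}")
        if self.X.ndim != 2:
            raise CohortError("feature matrix must be 2-D")
        if self.X.shape[0] != len(self.subjects):
            raise CohortError("metadata row count does not match feature matrix")
        if self.X.shape[1] != len(self.schema):
            raise CohortError(
                f"matrix has {self.X.shape[1]} columns, schema expects {len(self.schema)}"
            )
        sites = self.subjects["site"].astype(str)
        if (sites.str.len() == 0).any():
            raise CohortError("every site label must be non-empty")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def groups(self) -> np.ndarray:
        return self.subjects["group"].to_numpy()

    @property
    def sites(self) -> np.ndarray:
        return self.subjects["site"].astype(str).to_numpy()

    def take(self, idx: np.ndarray) -> "ROICohort":
        """Row subset (positional indices), metadata and matrix together."""
        return replace(
            self,
            subjects=self.subjects.iloc[idx].reset_index(drop=True),
            X=self.X[np.asarray(idx)],
        )

    def with_matrix(self, X: np.ndarray) -> "ROICohort":
        return replace(self, X=np.asarray(X, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        frame = self.subjects.copy()
        feat = pd.DataFrame(self.X, columns=self.schema.names, index=frame.index)
        return pd.concat([frame, feat], axis=1)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _detect_separator(path: Path) -> str:
    header = path.open("r", encoding="utf-8").readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def load_cohort(
    path: str | Path,
    schema: FeatureSchema,
    extra_columns: str = "ignore",
) -> ROICohort:
    """Read a delimited cohort table and align it to ``schema``.

    Parameters
    ----------
    path:
        CSV or TSV file (delimiter auto-detected from the header line).
    extra_columns:
        ``"ignore"`` drops unknown columns, ``"error"`` rejects the file.
    """
    if extra_columns not in ("ignore", "error"):
        raise ValueError("extra_columns must be 'ignore' or 'error'")
    path = Path(path)
    sep = _detect_separator(path)
    raw = pd.read_csv(
        path,
        sep=sep,
        dtype=str,
        na_values=list(NA_MARKERS),
        keep_default_na=False,
        skipinitialspace=True,
    )

    missing = [c for c in (*META_COLUMNS, *schema.names) if c not in raw.columns]
    if missing:
        raise SchemaError(f"table is missing required columns: {missing[:10]}")
    unknown = [c for c in raw.columns if c not in META_COLUMNS and c not in schema.names]
    if unknown and extra_columns == "error":
        raise SchemaError(f"table has unexpected columns: {unknown[:10]}")

    subjects = raw[list(META_COLUMNS)].copy()
    for col in ("age", "sex"):
        try:
            subjects[col] = pd.to_numeric(subjects[col])
        except (ValueError, TypeError) as exc:
            raise CohortError(f"column {col!r} is not numeric: {exc}") from exc

    feat = raw[schema.names]
    X = np.empty((len(raw), len(schema)), dtype=float)
    for j, col in enumerate(schema.names):
        converted = pd.to_numeric(feat[col].replace("", np.nan), errors="coerce")
        bad = converted.isna() & feat[col].notna() & (feat[col] != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortError(
                f"unparseable value {feat[col].iloc[row]!r} in column {col!r}, row {row}"
            )
        X[:, j] = converted.to_numpy(dtype=float)

    return ROICohort(subjects=subjects, X=X, schema=schema)


def filter_complete_cases(cohort: ROICohort) -> ROICohort:
    """Drop every row with a missing feature value. Idempotent."""
    keep = ~np.isnan(cohort.X).any(axis=1)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_complete_cases: removed %d of %d rows", n_removed, cohort.n_subjects)
    if not keep.any():
        raise CohortError("complete-case filtering removed every row")
    if n_removed == 0:
        return cohort
    return cohort.take(np.flatnonzero(keep))


def filter_site_outliers(cohort: ROICohort, k: float = 1.5) -> ROICohort:
    """Optional QC rule: within each site, drop rows holding any feature value
    outside ``[Q1 - k*IQR, Q3 + k*IQR]`` for that site. Off by default in every
    pipeline entry point."""
    keep = np.ones(cohort.n_subjects, dtype=bool)
    sites = cohort.sites
    for site in np.unique(sites):
        rows = np.flatnonzero(sites == site)
        block = cohort.X[rows]
        q1 = np.nanpercentile(block, 25, axis=0)
        q3 = np.nanpercentile(block, 75, axis=0)
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        with np.errstate(invalid="ignore"):
            out = (block < lo) | (block > hi)
        keep[rows[out.any(axis=1)]] = False
    if not keep.any():
        raise CohortError("outlier filtering removed every row")
    return cohort.take(np.flatnonzero(keep))


def _as_group_set(value: str | Iterable[str]) -> frozenset:
    groups = frozenset([value]) if isinstance(value, str) else frozenset(value)
    bad = groups - set(GROUPS)
    if bad:
        raise CohortError(f"unknown group label(s): {sorted(bad)}")
    return groups


def select_binary_groups(
    cohort: ROICohort,
    positive: str | Sequence[str],
    negative: str | Sequence[str],
) -> tuple[ROICohort, np.ndarray]:
    """Restrict to two (possibly pooled) group sets and return 0/1 labels.

    Rows from ``negative`` get label 0, rows from ``positive`` label 1; the
    original row order and feature values are preserved exactly.
    """
    pos = _as_group_set(positive)
    neg = _as_group_set(negative)
    if not pos or not neg:
        raise CohortError("both group sets must be non-empty")
    if pos & neg:
        raise CohortError(f"group sets overlap: {sorted(pos & neg)}")

    groups = cohort.groups
    is_pos = np.isin(groups, list(pos))
    is_neg = np.isin(groups, list(neg))
    if not is_pos.any():
        raise CohortError(f"no subjects in positive set {sorted(pos)}")
    if not is_neg.any():
        raise CohortError(f"no subjects in negative set {sorted(neg)}")

    idx = np.flatnonzero(is_pos | is_neg)
    labels = is_pos[idx].astype(int)
    return cohort.take(idx), labels
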