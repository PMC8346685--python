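"""ROI importance maps aggregated across trained pipelines.

SVC importance is the mean absolute weight per feature; dense-net importance
backtracks relevance from the output contrast through both hidden layers as
a sum over paths of absolute weight products. Both maps are min-max
normalized to [0, 1]; an all-equal map normalizes to all ones with a
warning, since flat maps accompany near-chance classifiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pipeline import PipelineModel
from .schemas import FeatureSchema


class ImportanceError(ValueError):
    pass


@dataclass(frozen=True)
class ImportanceMap:
    feature_names: tuple[str, ...]
    values: np.ndarray  # normalized to [0, 1]
    kind: str
    n_models: int

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.feature_names),):
            raise ImportanceError("one importance value required per feature")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ImportanceError("importance values must lie in [0, 1]")


def normalize_importance(raw: np.ndarray) -> np.ndarray:
    """Min-max normalize; a constant vector maps to all ones."""
    raw = np.asarray(raw, dtype=float)
    span = raw.max() - raw.min()
    if span == 0:
        warnings.warn(
            "importance map is constant across features (flat maps typically "
            "accompany near-chance classifiers); normalizing to all ones",
            stacklevel=2,
        )
        return np.ones_like(raw)
    return (raw - raw.min()) / span


def _check_models(models: Sequence[PipelineModel], kind: str, n_features: int) -> None:
    if not models:
        raise ImportanceError("at least one fitted model is required")
    for m in models:
        if m.kind != kind:
            raise ImportanceError(f"expected {kind!r} pipelines, got {m.kind!r}")
        n = m.classifier.coef.size if kind == "svc" else m.classifier.W1.shape[0]
        if n != n_features:
            raise ImportanceError(
                f"model input dimension {n} does not match schema length {n_features}"
            )


def svc_importance(models: Sequence[PipelineModel], schema: FeatureSchema) -> ImportanceMap:
    """Mean |weight| per feature over iterations, min-max normalized."""
    _check_models(models, "svc", len(schema))
    raw = np.mean([np.abs(m.classifier.coef) for m in models], axis=0)
    return ImportanceMap(
        feature_names=tuple(schema.names),
        values=normalize_importance(raw),
        kind="svc",
        n_models=len(models),
    )


def dlc_backtrack_relevance(model: PipelineModel) -> np.ndarray:
    """Per-input relevance: sum over hidden paths of |W1|·|W2|·|contrast|,
    where the contrast is the difference of the two output nodes' incoming
    weights."""
    clf = model.classifier
    contrast = clf.W3[:, 1] - clf.W3[:, 0]
    return np.abs(clf.W1) @ np.abs(clf.W2) @ np.abs(contrast)


def dlc_importance(models: Sequence[PipelineModel], schema: FeatureSchema) -> ImportanceMap:
    """Connection-weight backtracking relevance averaged over iterations."""
    _check_models(models, "dlc", len(schema))
    raw = np.mean([dlc_backtrack_relevance(m) for m in models], axis=0)
    return ImportanceMap(
        feature_names=tuple(schema.names),
        values=normalize_importance(raw),
        kind="dlc",
        n_models=len(models),
    )


def export_importance(imap: ImportanceMap, schema: FeatureSchema) -> pd.DataFrame:
    """Long table (roi_name, measure, hemisphere, importance), descending."""
    if tuple(schema.names) != imap.feature_names:
        raise ImportanceError("schema does not match the importance map")
    frame = pd.DataFrame(
        {
            "roi_name": [f.roi_name for f in schema],
            "measure": [f.measure.value for f in schema],
            "hemisphere": [f.hemisphere.value for f in schema],
            "importance": imap.values,
        }
    )
    return frame.sort_values("importance", ascending=False, kind="stable").reset_index(drop=True)


def write_importance(imap: ImportanceMap, schema: FeatureSchema, path: str | Path) -> None:
    export_importance(imap, schema).to_csv(path, index=False)
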