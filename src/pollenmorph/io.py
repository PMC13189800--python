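"""Dataset manifests and feature-table serialization.

A manifest is a CSV with columns ``path,label,slide_id,source_image_id``
(the last two optional) listing one particle crop per row; labels must be
drawn from the five analysis classes. Feature tables are CSV with the
descriptor columns in canonical order followed by ``label`` and
``slide_id``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import CORE9, FEATURES_11
from .synthscene import CLASS_LABELS

__all__ = ["DatasetManifest", "load_manifest", "prevalence",
           "write_feature_table", "read_feature_table"]


@dataclass
class DatasetManifest:
    entries: pd.DataFrame  # path, label, slide_id, source_image_id
    class_counts: dict[str, int]
    total: int


def load_manifest(path: str | Path) -> DatasetManifest:
    """Load and validate a dataset manifest.

    Rejects missing files, labels outside the five-class set (naming the
    offending line) and duplicate crop paths."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest {path} does not exist")
    df = pd.read_csv(path, dtype=str)
    required = {"path", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    for col in ("slide_id", "source_image_id"):
        if col not in df.columns:
            df[col] = ""
    for i, lab in enumerate(df["label"]):
        if lab not in CLASS_LABELS:
            raise ValueError(
                f"unknown label {lab!r} at manifest line {i + 2}")
    dup = df["path"][df["path"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate crop path {dup.iloc[0]!r}")
    counts = {c: int((df["label"] == c).sum()) for c in CLASS_LABELS}
    return DatasetManifest(entries=df, class_counts=counts, total=len(df))


def prevalence(manifest: DatasetManifest, class_label: str) -> float:
    """Class count / total: the no-skill AUPRC baseline for that class."""
    if manifest.total == 0:
        raise ValueError("manifest is empty; prevalence undefined")
    if class_label not in CLASS_LABELS:
        raise ValueError(f"unknown class {class_label!r}")
    return manifest.class_counts[class_label] / manifest.total


_META_COLS = ("label", "slide_id")


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as CSV: canonical feature order then metadata
    columns, floats at full precision (lossless round-trip)."""
    feats = [c for c in (FEATURES_11 if set(FEATURES_11) <= set(df.columns)
                         else CORE9) if c in df.columns]
    missing = [c for c in df.columns if c not in feats and c not in _META_COLS]
    if missing:
        raise ValueError(f"unexpected column(s) {missing} in feature table")
    cols = feats + [c for c in _META_COLS if c in df.columns]
    df[cols].to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table, validating the header against the 11- or
    9-descriptor canonical sets and that all feature cells are numeric
    (NaN-flagged rows are preserved)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table {path} does not exist")
    df = pd.read_csv(path)
    feat_cols = [c for c in df.columns if c not in _META_COLS]
    if set(feat_cols) != set(FEATURES_11) and set(feat_cols) != set(CORE9):
        raise ValueError(
            "feature columns match neither the 11-descriptor nor the "
            f"core-9 set: {feat_cols}")
    for c in feat_cols:
        if not np.issubdtype(df[c].dtype, np.number):
            raise ValueError(f"non-numeric values in feature column {c!r}")
    return df
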