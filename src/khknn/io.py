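"""CSV readers and writers for feature tables, predictions, grids and scores.

Tables are plain header-bearing CSV (period decimal separator, fixed column
order). The label column (default ``"group"``) holds integer class ids with
1 = high-risk = positive. Column kind is inferred: a column whose value set
is contained in {0, 1} is binary, anything else continuous. Rows with any
missing value are dropped with a logged count; there is no imputation.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError
from .hyperplane import DistanceProfile, FeatureTable

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "write_predictions",
]

logger = logging.getLogger(__name__)

#: columns excluded by default when a table carries the clinical stroke-score
#: columns: both scores define or near-define the risk-group label, so keeping
#: them as predictors would leak the label. Overridable by the caller.
DEFAULT_EXCLUDED_COLUMNS: tuple[str, ...] = ("chads2", "cha2ds2_vasc")


def _infer_kind(col: pd.Series) -> str:
    vals = set(np.unique(col.to_numpy(dtype=float)))
    return "binary" if vals <= {0.0, 1.0} else "continuous"


def read_feature_table(
    path: str | Path,
    label_column: str = "group",
    excluded_columns: Iterable[str] = (),
) -> FeatureTable:
    """Load a labeled feature table from CSV.

    ``excluded_columns`` names predictors to drop (names absent from the
    file are ignored silently, so the default leak-guard list is safe on
    any table).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise InputError(f"label column {label_column!r} not found in {path.name}")
    drop = [c for c in excluded_columns if c in df.columns and c != label_column]
    if drop:
        df = df.drop(columns=drop)
    n_before = len(df)
    df = df.dropna()
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.warning("dropped %d row(s) with missing values from %s", n_dropped, path.name)
    feature_cols = [c for c in df.columns if c != label_column]
    if not feature_cols:
        raise InputError(f"no feature columns remain in {path.name}")
    for c in [label_column, *feature_cols]:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[c], errors="coerce").isna()].index
            row = int(bad[0]) if len(bad) else "?"
            raise InputError(
                f"unparseable numeric value in column {c!r}, row {row} of {path.name}"
            ) from exc
    values = df[feature_cols].to_numpy(dtype=float)
    labels = df[label_column].to_numpy()
    if not np.array_equal(labels, labels.astype(int)):
        raise InputError(f"label column {label_column!r} must hold integers")
    kinds = [_infer_kind(df[c]) for c in feature_cols]
    return FeatureTable(
        values=values,
        feature_names=list(feature_cols),
        feature_kinds=kinds,
        labels=labels.astype(int),
    )


def write_feature_table(table: FeatureTable, path: str | Path, label_column: str = "group") -> None:
    """Write a table to CSV with the label as the last column."""
    df = pd.DataFrame(table.values, columns=table.feature_names)
    df[label_column] = table.labels
    df.to_csv(path, index=False)


def write_predictions(
    profiles: Sequence[DistanceProfile], path: str | Path
) -> None:
    """Write per-query predictions with per-class squared distances."""
    if not profiles:
        pd.DataFrame(columns=["predicted_class"]).to_csv(path, index=False)
        return
    n_classes = len(profiles[0].per_class_distance_sq)
    rows = []
    for p in profiles:
        row = {"predicted_class": p.predicted_class}
        for c in range(n_classes):
            row[f"dist_sq_class{c}"] = p.per_class_distance_sq[c]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
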