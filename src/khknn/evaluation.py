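"""Jackknife (leave-one-out) evaluation and the (k, gamma) grid search.

The jackknife protocol rebuilds the model on the remaining n-1 rows for
every held-out sample — including refitting standardization statistics on
those n-1 rows, so no information from the held-out row leaks into the
scaling — and pools the n predictions into a single metric report. It is
fully deterministic: there is no randomness anywhere in the protocol.

The grid search sweeps k over a small integer range and the RBF bandwidth
gamma over powers of two (default k in 2..8, gamma in 2^-5..2^5, i.e.
7 x 11 = 77 configurations) with the ridge parameter lambda held at 1, and
selects the configuration with the best finite Matthews correlation
coefficient; NaN MCC never wins, and MCC ties are broken toward smaller k,
then smaller gamma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataError, ProtocolError
from .hyperplane import FeatureTable, classify
from .kernels import KernelSpec
from .metrics import MetricReport, compute_metrics, confusion_counts

__all__ = [
    "EvalConfig",
    "GridSearchResult",
    "standardize_fit",
    "standardize_apply",
    "jackknife_evaluate",
    "grid_search",
    "select_best",
    "grid_to_frame",
    "DEFAULT_K_VALUES",
    "DEFAULT_GAMMA_VALUES",
]

logger = logging.getLogger(__name__)

#: default sweep ranges: k from 2 to 8 step 1; gamma over 2^-5 .. 2^5 in
#: multiplicative steps of 2
DEFAULT_K_VALUES: tuple[int, ...] = tuple(range(2, 9))
DEFAULT_GAMMA_VALUES: tuple[float, ...] = tuple(2.0**e for e in range(-5, 6))


@dataclass(frozen=True)
class EvalConfig:
    """Configuration of one jackknife run.

    ``kernel=None`` selects the linear HKNN path. ``lambda_reg`` defaults
    to 1, the value the method is run with throughout; ``standardize``
    (default on) scales continuous columns to zero mean / unit variance
    using fold-local statistics.
    """

    k: int
    kernel: KernelSpec | None = None
    lambda_reg: float = 1.0
    standardize: bool = True
    positive_class: int = 1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError(f"k must be >= 1, got {self.k}")
        if self.kernel is not None and self.lambda_reg <= 0:
            raise ConfigError("kernel path requires lambda_reg > 0")
        if self.lambda_reg < 0:
            raise ConfigError("lambda_reg must be nonnegative")


@dataclass
class GridSearchResult:
    grid: list[tuple[int, float, MetricReport]]
    best_k: int
    best_gamma: float
    best_mcc: float
    criterion: str = field(default="mcc", init=False)


def standardize_fit(values: np.ndarray, feature_kinds: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-column (mean, sd) fitted on training rows only.

    Binary columns and zero-variance columns pass through untouched
    (mean 0, sd 1); a zero-variance continuous column logs a warning.
    """
    values = np.asarray(values, dtype=float)
    mean = np.zeros(values.shape[1])
    sd = np.ones(values.shape[1])
    for j, kind in enumerate(feature_kinds):
        if kind == "binary":
            continue
        m = values[:, j].mean()
        s = values[:, j].std()
        if s == 0.0:
            logger.warning("constant continuous column %d left unscaled", j)
            continue
        mean[j], sd[j] = m, s
    return mean, sd


def standardize_apply(rows: np.ndarray, params: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Apply fitted (mean, sd) to rows (which may be held-out data)."""
    mean, sd = params
    return (np.asarray(rows, dtype=float) - mean) / sd


def jackknife_evaluate(
    table: FeatureTable, config: EvalConfig
) -> tuple[MetricReport, np.ndarray]:
    """Leave-one-out evaluation; returns the pooled report and per-sample predictions."""
    n = table.n_samples
    if n < 3:
        raise DataError(f"jackknife requires n >= 3 samples, got {n}")
    table.require_all_classes()
    if table.n_classes < 2:
        raise DataError("jackknife requires at least 2 classes")
    class_ids = np.arange(table.n_classes)
    preds = np.empty(n, dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        train_vals = table.values[mask]
        train_labels = table.labels[mask]
        present = np.isin(class_ids, train_labels)
        if not present.all():
            missing = class_ids[~present].tolist()
            raise ProtocolError(
                f"fold {i}: training part lacks class(es) {missing}; "
                "hyperplane undefined"
            )
        query = table.values[i]
        if config.standardize:
            params = standardize_fit(train_vals, table.feature_kinds)
            train_vals = standardize_apply(train_vals, params)
            query = standardize_apply(query[None, :], params)[0]
        fold_table = FeatureTable(
            values=train_vals,
            feature_names=table.feature_names,
            feature_kinds=table.feature_kinds,
            labels=train_labels,
        )
        profile = classify(query, fold_table, config.k, config.kernel, config.lambda_reg)
        preds[i] = profile.predicted_class
    cc = confusion_counts(table.labels, preds, positive_class=config.positive_class)
    return compute_metrics(cc), preds


def select_best(
    grid: list[tuple[int, float, MetricReport]]
) -> tuple[int, float, float]:
    """Argmax of finite MCC over the grid; ties to smaller k, then smaller gamma."""
    best: tuple[int, float, float] | None = None
    for k, gamma, report in sorted(grid, key=lambda t: (t[0], t[1])):
        mcc = report.mcc
        if np.isnan(mcc):
            continue
        if best is None or mcc > best[2]:
            best = (k, gamma, mcc)
    if best is None:
        raise ProtocolError("degenerate grid: every configuration produced NaN MCC")
    return best


def grid_search(
    table: FeatureTable,
    k_values=DEFAULT_K_VALUES,
    gamma_values=DEFAULT_GAMMA_VALUES,
    lambda_reg: float = 1.0,
    standardize: bool = True,
    positive_class: int = 1,
) -> GridSearchResult:
    """Jackknife-evaluate every (k, gamma) pair with an RBF kernel at fixed lambda."""
    k_values = list(k_values)
    gamma_values = list(gamma_values)
    if not k_values or not gamma_values:
        raise ConfigError("grid search requires nonempty k and gamma ranges")
    if lambda_reg <= 0:
        raise ConfigError("grid search requires lambda_reg > 0")
    grid: list[tuple[int, float, MetricReport]] = []
    for k in k_values:
        for gamma in gamma_values:
            config = EvalConfig(
                k=k,
                kernel=KernelSpec("rbf", gamma),
                lambda_reg=lambda_reg,
                standardize=standardize,
                positive_class=positive_class,
            )
            report, _ = jackknife_evaluate(table, config)
            grid.append((k, gamma, report))
    best_k, best_gamma, best_mcc = select_best(grid)
    return GridSearchResult(grid=grid, best_k=best_k, best_gamma=best_gamma, best_mcc=best_mcc)


def grid_to_frame(result: GridSearchResult) -> pd.DataFrame:
    """Grid surface as a DataFrame (one row per configuration) for export/plotting."""
    rows = []
    for k, gamma, r in result.grid:
        rows.append({"k": k, "gamma": gamma, **r.as_dict()})
    return pd.DataFrame(rows, columns=["k", "gamma", "mcc", "acc", "sn", "spec", "pe", "npv", "fscore"])
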