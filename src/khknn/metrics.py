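"""Confusion counts and the seven binary-classification metrics.

ACC, SN (sensitivity/recall), Spec (specificity), PE (positive predictive
value/precision), NPV, F-score (harmonic mean of SN and PE) and the Matthews
correlation coefficient. Any metric whose defining denominator is zero is
NaN — never silently 0 and never an exception — so a degenerate classifier
(e.g. one that predicts every sample positive) reports SN=1, Spec=0,
NPV=NaN, MCC=NaN. Metrics are stored as fractions in [0, 1] (MCC in
[-1, 1]); percentage rendering happens only at the reporting boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import InputError

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "compute_metrics",
    "report_table",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise InputError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    """The seven metrics as fractions; NaN where undefined."""

    acc: float
    sn: float
    spec: float
    pe: float
    npv: float
    fscore: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mcc": self.mcc,
            "acc": self.acc,
            "sn": self.sn,
            "spec": self.spec,
            "pe": self.pe,
            "npv": self.npv,
            "fscore": self.fscore,
        }


def confusion_counts(y_true, y_pred, positive_class: int = 1) -> ConfusionCounts:
    """Count TP/TN/FP/FN with respect to the designated positive class."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape or t.ndim != 1 or t.size < 1:
        raise InputError(
            f"y_true and y_pred must be equal-length vectors, got {t.shape} and {p.shape}"
        )
    tpos = t == positive_class
    ppos = p == positive_class
    return ConfusionCounts(
        tp=int(np.sum(tpos & ppos)),
        tn=int(np.sum(~tpos & ~ppos)),
        fp=int(np.sum(~tpos & ppos)),
        fn=int(np.sum(tpos & ~ppos)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den != 0 else math.nan


def compute_metrics(cc: ConfusionCounts) -> MetricReport:
    """Evaluate all seven metrics from confusion counts.

    The MCC denominator is factored into two float square roots so large
    counts cannot overflow an intermediate integer product.
    """
    if cc.total == 0:
        raise InputError("cannot compute metrics on zero evaluated samples")
    tp, tn, fp, fn = float(cc.tp), float(cc.tn), float(cc.fp), float(cc.fn)
    acc = _ratio(tp + tn, tp + tn + fp + fn)
    sn = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    pe = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    if math.isnan(sn) or math.isnan(pe) or (sn + pe) == 0:
        fscore = math.nan
    else:
        fscore = 2.0 * sn * pe / (sn + pe)
    mcc_den = math.sqrt((tp + fn) * (tn + fp)) * math.sqrt((tp + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, mcc_den)
    return MetricReport(acc=acc, sn=sn, spec=spec, pe=pe, npv=npv, fscore=fscore, mcc=mcc)


def _fmt(x: float, decimals: int, percent: bool) -> str:
    if math.isnan(x):
        return "NaN"
    return f"{100.0 * x:.{decimals}f}" if percent else f"{x:.{decimals}f}"


def report_table(reports: dict[str, MetricReport], sep: str = ",") -> str:
    """Render reports as a delimited block: MCC, ACC(%), SN(%), Spec(%), PE(%), NPV(%), F_score.

    Percent columns carry two decimals; MCC and F_score four.
    """
    lines = [sep.join(["Method", "MCC", "ACC(%)", "SN(%)", "Spec(%)", "PE(%)", "NPV(%)", "F_score"])]
    for name, r in reports.items():
        lines.append(
            sep.join(
                [
                    name,
                    _fmt(r.mcc, 4, percent=False),
                    _fmt(r.acc, 2, percent=True),
                    _fmt(r.sn, 2, percent=True),
                    _fmt(r.spec, 2, percent=True),
                    _fmt(r.pe, 2, percent=True),
                    _fmt(r.npv, 2, percent=True),
                    _fmt(r.fscore, 4, percent=False),
                ]
            )
        )
    return "\n".join(lines) + "\n"
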