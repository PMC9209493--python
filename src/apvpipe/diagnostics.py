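"""Diagnostic test accuracy metrics and repeatability statistics.

The metric panel mirrors standard diagnostic-accuracy reporting: AUC,
operating threshold, sensitivity, specificity, accuracy, predictive values,
likelihood ratios, Youden index and diagnostic odds ratio.  Metrics whose
defining ratio divides by zero are reported as NA (a typed flag exported as
the literal string "NA"), never raised as an exception.

The positive-call convention is fixed: score >= threshold -> positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class LabelError(ValueError):
    pass


#: row order used when exporting report tables
REPORT_ROW_ORDER = (
    "AUC", "Threshold", "Specificity", "Sensitivity", "Accuracy",
    "NPV", "PPV", "LR+", "LR-", "Yi", "DOR",
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts must total > 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ROCCurve:
    """Threshold sweep (score >= threshold -> positive) plus trapezoid AUC."""

    thresholds: np.ndarray   # descending; first entry is +inf (no positives)
    sensitivity: np.ndarray
    fpr: np.ndarray          # 1 - specificity
    auc: float


def roc_curve(scores, labels) -> ROCCurve:
    """ROC over the unique observed scores.

    The trapezoid AUC of this sweep equals the Mann-Whitney U statistic
    divided by n1*n0, with ties contributing midranks (all scores identical
    gives AUC 0.5).
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise LabelError("both classes must be present to build a ROC curve")
    uniq = np.unique(s)[::-1]
    thresholds = np.concatenate([[np.inf], uniq])
    sens = np.empty(len(thresholds))
    fpr = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        pos = s >= t
        sens[i] = (pos & (y == 1)).sum() / n1
        fpr[i] = (pos & (y == 0)).sum() / n0
    auc = float(np.trapezoid(sens, fpr))
    return ROCCurve(thresholds=thresholds, sensitivity=sens, fpr=fpr, auc=auc)


def youden_threshold(curve: ROCCurve) -> float:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Ties are broken toward the smallest (finite) threshold.
    """
    j = curve.sensitivity - curve.fpr
    best = j.max()
    candidates = curve.thresholds[np.isclose(j, best)]
    finite = candidates[np.isfinite(candidates)]
    pool = finite if len(finite) else candidates
    return float(pool.min())


def confusion_at_threshold(scores, labels, threshold: float) -> ConfusionCounts:
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    pos = s >= threshold
    return ConfusionCounts(
        tp=int((pos & (y == 1)).sum()),
        fp=int((pos & (y == 0)).sum()),
        tn=int((~pos & (y == 0)).sum()),
        fn=int((~pos & (y == 1)).sum()),
    )


def balanced_auc(sensitivity: float, specificity: float) -> float:
    """(sensitivity + specificity) / 2: the hold-out AUC convention when only
    a single operating point is available.

    Equals the trapezoid AUC of the one-threshold ROC through
    (1 - specificity, sensitivity).
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    return (sensitivity + specificity) / 2.0


@dataclass
class DiagnosticReport:
    """Confusion-derived accuracy panel with NA conventions.

    Any metric whose denominator is zero carries ``nan`` and its name in
    ``na_flags``; exports print the literal "NA".
    """

    counts: ConfusionCounts
    auc: float = math.nan
    threshold: float = math.nan
    sensitivity: float = math.nan
    specificity: float = math.nan
    accuracy: float = math.nan
    ppv: float = math.nan
    npv: float = math.nan
    lr_pos: float = math.nan
    lr_neg: float = math.nan
    youden: float = math.nan
    dor: float = math.nan
    na_flags: set[str] = field(default_factory=set)

    _FIELD_BY_ROW = {
        "AUC": "auc", "Threshold": "threshold", "Specificity": "specificity",
        "Sensitivity": "sensitivity", "Accuracy": "accuracy", "NPV": "npv",
        "PPV": "ppv", "LR+": "lr_pos", "LR-": "lr_neg", "Yi": "youden",
        "DOR": "dor",
    }

    def to_series(self) -> pd.Series:
        vals = {}
        for row, attr in self._FIELD_BY_ROW.items():
            v = getattr(self, attr)
            vals[row] = "NA" if (attr in self.na_flags or (isinstance(v, float) and math.isnan(v))) else v
        return pd.Series(vals).reindex(list(REPORT_ROW_ORDER))

    def to_csv(self, path) -> None:
        self.to_series().rename("value").rename_axis("metric").to_csv(path)


def _safe_div(num: float, den: float, flag: str, flags: set[str]) -> float:
    if den == 0:
        flags.add(flag)
        return math.nan
    return num / den


def diagnostic_report(
    counts: ConfusionCounts,
    auc: float | None = None,
    threshold: float | None = None,
) -> DiagnosticReport:
    """Full metric panel from confusion counts.

    sens = TP/(TP+FN), spec = TN/(TN+FP), acc = (TP+TN)/total,
    PPV = TP/(TP+FP), NPV = TN/(TN+FN), LR+ = sens/(1-spec),
    LR- = (1-sens)/spec, Yi = sens+spec-1, DOR = TP*TN/(FP*FN).
    """
    flags: set[str] = set()
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    sens = _safe_div(tp, tp + fn, "sensitivity", flags)
    spec = _safe_div(tn, tn + fp, "specificity", flags)
    acc = (tp + tn) / counts.total
    ppv = _safe_div(tp, tp + fp, "ppv", flags)
    npv = _safe_div(tn, tn + fn, "npv", flags)
    if "sensitivity" in flags or "specificity" in flags:
        lr_pos = lr_neg = youden = math.nan
        flags.update({"lr_pos", "lr_neg", "youden"})
    else:
        lr_pos = _safe_div(sens, 1.0 - spec, "lr_pos", flags)
        lr_neg = _safe_div(1.0 - sens, spec, "lr_neg", flags)
        youden = sens + spec - 1.0
    dor = _safe_div(tp * tn, fp * fn, "dor", flags)
    return DiagnosticReport(
        counts=counts,
        auc=math.nan if auc is None else float(auc),
        threshold=math.nan if threshold is None else float(threshold),
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        ppv=ppv,
        npv=npv,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        youden=youden,
        dor=dor,
        na_flags=flags,
    )


def evaluate_scores(scores, labels, threshold: float, auc: float | None = None) -> DiagnosticReport:
    """Report at a fixed threshold; AUC defaults to the trapezoid ROC AUC."""
    if auc is None:
        auc = roc_curve(scores, labels).auc
    counts = confusion_at_threshold(scores, labels, threshold)
    return diagnostic_report(counts, auc=auc, threshold=threshold)


@dataclass
class ICCResult:
    """One-way random-effects, absolute-agreement, single-measurement ICC."""

    icc: float
    msb: float
    msw: float
    n_subjects: int
    k_measurements: int


def icc_oneway(x) -> ICCResult:
    """ICC(1,1) from the one-way ANOVA decomposition.

    ``x`` is an (n subjects) x (k repeated measurements) table with no
    missing cells.  ICC = (MSB - MSW) / (MSB + (k-1) MSW); duplicated
    measurement columns give exactly 1.
    """
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("expected a 2D subjects x measurements table")
    n, k = arr.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 measurements, got {arr.shape}")
    if np.isnan(arr).any():
        raise ValueError("missing cells are not allowed in the one-way ICC")
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    ssb = k * ((row_means - grand) ** 2).sum()
    ssw = ((arr - row_means[:, None]) ** 2).sum()
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    denom = msb + (k - 1) * msw
    icc = 1.0 if denom == 0 else float((msb - msw) / denom)
    return ICCResult(icc=icc, msb=float(msb), msw=float(msw), n_subjects=n, k_measurements=k)


@dataclass
class BlandAltmanResult:
    bias: float
    lower: float
    upper: float
    sd_diff: float


def bland_altman(a, b) -> BlandAltmanResult:
    """Mean difference and 95% limits of agreement (bias +/- 1.96 sd)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired measurements must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(bias=bias, lower=bias - 1.96 * sd, upper=bias + 1.96 * sd, sd_diff=sd)
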