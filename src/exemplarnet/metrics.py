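"""Evaluation statistics: confusion matrices, overall and per-class metrics,
Wilson confidence intervals, and McNemar paired tests.

Conventions: confusion-matrix rows are the true class, columns the predicted
class. All rates are reported as percentages; printed tables round half-up to
two decimals. UAR / UAP are the unweighted (macro) averages of per-class
recall / precision, and the overall F1 is the harmonic mean of UAR and UAP
(a ``macro_f1`` flag switches to the mean of per-class F1 scores instead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2
from sklearn.metrics import confusion_matrix as _sk_confusion
from statsmodels.stats.proportion import proportion_confint

from .errors import InputError
from .shallow import PredictionSet


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero at the given decimal, as printed tables do."""
    factor = 10.0 ** decimals
    return float(np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x))


@dataclass
class ConfusionMatrix:
    counts: np.ndarray                # K x K ints, rows = true, cols = predicted
    class_names: list[str]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    """Overall percentages; ``per_class`` is the Table-5-style frame."""

    accuracy: float
    uar: float
    uap: float
    f1: float
    n: int
    ci_low: float | None = None
    ci_high: float | None = None
    per_class: pd.DataFrame | None = None

    def to_text(self) -> str:
        lines = [
            f"n = {self.n}",
            f"Accuracy: {round_half_up(self.accuracy):.2f}%",
            f"UAR:      {round_half_up(self.uar):.2f}%",
            f"UAP:      {round_half_up(self.uap):.2f}%",
            f"F1:       {round_half_up(self.f1):.2f}%",
        ]
        if self.ci_low is not None:
            lines.append(f"95% CI (Wilson): [{self.ci_low:.2f}, {self.ci_high:.2f}]")
        if self.per_class is not None:
            lines.append("")
            lines.append(self.per_class.round(2).to_string())
        return "\n".join(lines)


@dataclass
class McNemarResult:
    b: int                            # A right, B wrong
    c: int                            # A wrong, B right
    chi2: float
    p: float
    corrected: bool
    degenerate: bool = False


def confusion_matrix(y_true, y_pred, class_names: list[str] | None = None,
                     ) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise InputError("y_true and y_pred must have equal length")
    if class_names is None:
        class_names = sorted(str(v) for v in np.unique(np.concatenate([y_true, y_pred])))
    known = set(class_names)
    seen = set(str(v) for v in np.unique(np.concatenate([y_true, y_pred])))
    if not seen <= known:
        raise InputError(f"labels {sorted(seen - known)} not in class_names")
    counts = _sk_confusion(y_true.astype(str), y_pred.astype(str), labels=class_names)
    return ConfusionMatrix(counts=counts.astype(np.int64), class_names=list(class_names))


def _per_class_arrays(cm: ConfusionMatrix):
    counts = cm.counts.astype(np.float64)
    tp = np.diag(counts)
    fn = counts.sum(axis=1) - tp
    fp = counts.sum(axis=0) - tp
    tn = counts.sum() - tp - fn - fp
    return tp, fn, fp, tn


def _safe_ratio(num: np.ndarray, den: np.ndarray, what: str,
                names: list[str]) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    for i in np.flatnonzero(~ok):
        warnings.warn(f"{what} undefined for class {names[i]} "
                      f"(zero denominator); excluded from macro average")
    return out


def overall_metrics(cm: ConfusionMatrix, macro_f1: bool = False) -> MetricsReport:
    """Accuracy, UAR, UAP, and overall F1 (%) from a confusion matrix.

    Classes absent from the truth (zero rows) are excluded from UAR with a
    warning; by default the overall F1 is the harmonic mean of UAR and UAP.
    """
    if cm.total == 0:
        raise InputError("empty confusion matrix")
    tp, fn, fp, tn = _per_class_arrays(cm)
    accuracy = 100.0 * tp.sum() / cm.total
    recall = _safe_ratio(tp, tp + fn, "recall", cm.class_names)
    precision = _safe_ratio(tp, tp + fp, "precision", cm.class_names)
    uar = 100.0 * np.nanmean(recall)
    uap = 100.0 * np.nanmean(precision)
    if macro_f1:
        with np.errstate(invalid="ignore"):
            per_f1 = 2 * precision * recall / (precision + recall)
        f1 = 100.0 * np.nanmean(per_f1)
    else:
        f1 = 2 * uar * uap / (uar + uap) if (uar + uap) > 0 else 0.0
    return MetricsReport(accuracy=accuracy, uar=uar, uap=uap, f1=f1, n=cm.total)


def per_class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """One-vs-rest sensitivity, specificity, precision, and F1 (%) per class,
    plus an unweighted macro-average row (NaN cells excluded with a warning)."""
    if cm.total == 0:
        raise InputError("empty confusion matrix")
    tp, fn, fp, tn = _per_class_arrays(cm)
    names = cm.class_names
    sens = _safe_ratio(tp, tp + fn, "sensitivity", names)
    spec = _safe_ratio(tn, tn + fp, "specificity", names)
    prec = _safe_ratio(tp, tp + fp, "precision", names)
    with np.errstate(invalid="ignore"):
        f1 = 2 * prec * sens / (prec + sens)
    df = pd.DataFrame({
        "sensitivity": 100 * sens,
        "specificity": 100 * spec,
        "precision": 100 * prec,
        "f1": 100 * f1,
    }, index=pd.Index(names, name="class"))
    df.loc["macro-average"] = df.mean(axis=0, skipna=True)
    return df


def wilson_interval(successes: int, n: int, confidence: float = 0.95,
                    ) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, in rounded percentages."""
    if n <= 0:
        raise InputError("n must be positive")
    if not 0 <= successes <= n:
        raise InputError(f"successes must lie in [0, {n}], got {successes}")
    low, high = proportion_confint(successes, n, alpha=1 - confidence,
                                   method="wilson")
    return round_half_up(100 * low), round_half_up(100 * high)


def mcnemar(preds_a: PredictionSet, preds_b: PredictionSet,
            corrected: bool = True) -> McNemarResult:
    """McNemar chi-square test on the discordant pairs of two classifiers
    evaluated on the same samples.

    ``b`` counts samples A classifies correctly and B incorrectly, ``c`` the
    reverse. With the default continuity correction the statistic is
    (|b - c| - 1)^2 / (b + c); the p-value is the chi-square(1 df) upper tail.
    ``b + c = 0`` yields a degenerate result with p = 1.
    """
    ya, yb = np.asarray(preds_a.y_true), np.asarray(preds_b.y_true)
    if ya.shape != yb.shape or not np.array_equal(ya, yb):
        raise InputError("prediction sets must share the same samples and truth")
    right_a = np.asarray(preds_a.y_pred) == ya
    right_b = np.asarray(preds_b.y_pred) == yb
    b = int(np.sum(right_a & ~right_b))
    c = int(np.sum(~right_a & right_b))
    if b + c == 0:
        return McNemarResult(b=b, c=c, chi2=0.0, p=1.0, corrected=corrected,
                             degenerate=True)
    num = (abs(b - c) - 1) ** 2 if corrected else (b - c) ** 2
    stat = num / (b + c)
    return McNemarResult(b=b, c=c, chi2=float(stat),
                         p=float(_chi2.sf(stat, df=1)), corrected=corrected)


def full_report(y_true, y_pred, class_names: list[str] | None = None,
                macro_f1: bool = False) -> MetricsReport:
    """Confusion matrix -> overall + per-class metrics + Wilson 95% CI in one go."""
    cm = confusion_matrix(y_true, y_pred, class_names)
    report = overall_metrics(cm, macro_f1=macro_f1)
    report.per_class = per_class_metrics(cm)
    correct = int(np.diag(cm.counts).sum())
    report.ci_low, report.ci_high = wilson_interval(correct, cm.total)
    return report
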