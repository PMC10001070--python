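"""Confusion matrices and one-vs-rest classification reports.

Conventions follow the reporting style common in the medical-imaging
classification literature: every class is scored one-vs-rest with

    recall      = TP / (TP + FN)
    precision   = TP / (TP + FP)
    specificity = TN / (TN + FP)
    F-score     = 2 P R / (P + R)
    MCC         = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

all expressed as percentages, and the per-class "accuracy" column reports
the per-class recall (the convention the benchmark tables' internal
arithmetic implies: a class's accuracy equals its recall, and the Average
accuracy equals the mean of recalls).  Macro averages are unweighted means
over classes.  Zero denominators yield 0 with a flag rather than an error.

Values are kept at full precision internally; rounding (half-up, 2 dp)
happens only when a report is rendered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "PerClassMetrics",
    "ClassReport",
    "confusion",
    "per_class_metrics",
    "macro_average",
    "class_report",
    "render_report",
    "round_half_up",
    "derive_binary_confusion",
]

METRIC_COLUMNS = ("Accuy", "Precn", "Recal", "Specy", "Fscore", "MCC")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), unlike banker's rounding."""
    factor = 10.0**ndigits
    return math.floor(x * factor + 0.5) / factor


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K count matrix; rows are true classes, columns predicted."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", c)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if c.shape[0] != len(self.class_names):
            raise ValueError("class_names must match matrix size")
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def ovr_counts(self, k: int) -> tuple[int, int, int, int]:
        """One-vs-rest (TP, FP, FN, TN) for class index k."""
        c = self.counts
        tp = int(c[k, k])
        fp = int(c[:, k].sum() - tp)
        fn = int(c[k, :].sum() - tp)
        tn = int(c.sum() - tp - fp - fn)
        return tp, fp, fn, tn


def confusion(true_labels, predicted_labels, K: int,
              class_names: tuple[str, ...] | None = None) -> ConfusionMatrix:
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError("label arrays must have equal length")
    if len(t) and (t.min() < 0 or t.max() >= K or p.min() < 0 or p.max() >= K):
        raise ValueError(f"labels must lie in [0, {K})")
    counts = np.zeros((K, K), dtype=int)
    np.add.at(counts, (t, p), 1)
    if class_names is None:
        class_names = tuple(f"class{i}" for i in range(K))
    return ConfusionMatrix(counts=counts, class_names=class_names)


@dataclass(frozen=True)
class PerClassMetrics:
    """One-vs-rest metrics for a single class, in percent."""

    accuracy: float  # == recall, by reporting convention
    precision: float
    recall: float
    specificity: float
    f_score: float
    mcc: float
    zero_denominator: bool = False

    def as_row(self) -> tuple[float, ...]:
        return (self.accuracy, self.precision, self.recall,
                self.specificity, self.f_score, self.mcc)


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def per_class_metrics(cm: ConfusionMatrix, k: int) -> PerClassMetrics:
    tp, fp, fn, tn = cm.ovr_counts(k)
    recall, z1 = _safe_div(tp, tp + fn)
    precision, z2 = _safe_div(tp, tp + fp)
    specificity, z3 = _safe_div(tn, tn + fp)
    f_score, z4 = _safe_div(2 * precision * recall, precision + recall)
    mcc_den = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc, z5 = _safe_div(tp * tn - fp * fn, mcc_den)
    return PerClassMetrics(
        accuracy=100.0 * recall,
        precision=100.0 * precision,
        recall=100.0 * recall,
        specificity=100.0 * specificity,
        f_score=100.0 * f_score,
        mcc=100.0 * mcc,
        zero_denominator=any((z1, z2, z3, z4, z5)),
    )


@dataclass
class ClassReport:
    """Per-class metric rows plus the unweighted macro average."""

    cm: ConfusionMatrix
    per_class: dict[str, PerClassMetrics] = field(init=False)
    average: PerClassMetrics = field(init=False)

    def __post_init__(self) -> None:
        self.per_class = {
            name: per_class_metrics(self.cm, k)
            for k, name in enumerate(self.cm.class_names)
        }
        self.average = macro_average(list(self.per_class.values()))

    def to_frame(self, ndigits: int = 2) -> pd.DataFrame:
        rows = {name: [round_half_up(v, ndigits) for v in m.as_row()]
                for name, m in self.per_class.items()}
        rows["Average"] = [round_half_up(v, ndigits)
                           for v in self.average.as_row()]
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=list(METRIC_COLUMNS))


def macro_average(metrics: list[PerClassMetrics]) -> PerClassMetrics:
    if not metrics:
        raise ValueError("no per-class metrics to average")
    arr = np.array([m.as_row() for m in metrics], dtype=float)
    mean = arr.mean(axis=0)
    return PerClassMetrics(*mean,
                           zero_denominator=any(m.zero_denominator
                                                for m in metrics))


def class_report(true_labels, predicted_labels,
                 class_names: tuple[str, ...]) -> ClassReport:
    cm = confusion(true_labels, predicted_labels, len(class_names), class_names)
    return ClassReport(cm)


def render_report(reports: dict[str, ClassReport], path=None) -> pd.DataFrame:
    """Stack phase-labelled reports into one table (CSV if path given).

    ``reports`` maps a phase label (e.g. "Training Phase (80%)") to its
    ClassReport; the output keeps the canonical column order Accuy, Precn,
    Recal, Specy, Fscore, MCC with class and Average rows per phase.
    """
    frames = []
    for phase, rep in reports.items():
        df = rep.to_frame()
        df.insert(0, "Phase", phase)
        df.insert(1, "Class", df.index)
        frames.append(df.reset_index(drop=True))
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["Phase", "Class", *METRIC_COLUMNS])
    if path is not None:
        out.to_csv(path, index=False)
    return out


def derive_binary_confusion(
    n: int,
    recall_pct: tuple[float, float],
    precision_pct: tuple[float, float],
    ndigits: int = 2,
) -> ConfusionMatrix:
    """Recover the unique binary confusion matrix behind printed metrics.

    Exhaustively enumerates all nonnegative integer matrices
    [[a, b], [c, d]] with a+b+c+d = n and returns the one whose per-class
    recalls and precisions, rounded half-up to ``ndigits``, reproduce the
    printed percentages.  Raises if no matrix or more than one matches —
    callers rely on uniqueness.
    """
    matches = []
    for a in range(n + 1):
        for b in range(n + 1 - a):
            for c in range(n + 1 - a - b):
                d = n - a - b - c
                vals = []
                ok = True
                for num, den in ((a, a + b), (d, c + d), (a, a + c), (d, b + d)):
                    if den == 0:
                        ok = False
                        break
                    vals.append(round_half_up(100.0 * num / den, ndigits))
                if not ok:
                    continue
                target = (recall_pct[0], recall_pct[1],
                          precision_pct[0], precision_pct[1])
                if all(abs(v - t) < 10.0**-ndigits / 2
                       for v, t in zip(vals, target)):
                    matches.append(np.array([[a, b], [c, d]]))
    if len(matches) != 1:
        raise ValueError(
            f"expected a unique matrix for n={n}, found {len(matches)}")
    return ConfusionMatrix(counts=matches[0], class_names=("class0", "class1"))
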