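"""Cross-validation schemes, confusion matrices, and metrics reporting.

Two CV schemes are provided: event-level stratified k-fold ("20% leave-out",
which knowingly lets events from one specimen span the model and test sets)
and leave-one-specimen-out ("full group leave-out", which does not).  Both
exclude outlier events from accuracy denominators; bad events must already
have been removed upstream.

Metrics follow the standard one-vs-rest definitions: sensitivity =
100*TP/(TP+FN) and specificity = 100*TN/(TN+FP), reported to 2 decimals.
Averaged metrics use the arithmetic mean and *population* SD, each rounded
half-away-from-zero to integer percent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .model import fit_pcalda, project
from .classify import call_event
from .spectra_io import IntensityMatrix

__all__ = [
    "ConfusionMatrix",
    "CVResult",
    "MetricsReport",
    "crossval_event",
    "crossval_fullgroup",
    "sensitivity_specificity",
    "average_metrics",
    "spatial_concordance",
    "build_report",
    "accounting",
]


@dataclass
class ConfusionMatrix:
    """C x C integer counts; rows = actual class, columns = predicted."""

    classes: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        C = len(self.classes)
        if self.counts.shape != (C, C):
            raise ValueError("counts must be C x C")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_pairs(
        cls, actual: Sequence[str], predicted: Sequence[str], classes: Sequence[str]
    ) -> "ConfusionMatrix":
        classes = list(classes)
        idx = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for a, p in zip(actual, predicted):
            counts[idx[str(a)], idx[str(p)]] += 1
        return cls(classes, counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        """Percent accuracy = 100 * trace / total."""
        return 100.0 * float(np.trace(self.counts)) / self.total if self.total else math.nan

    def ovr_counts(self, cls: str) -> tuple[int, int, int, int]:
        """One-vs-rest (TP, FN, FP, TN) for one class."""
        i = self.classes.index(cls)
        tp = int(self.counts[i, i])
        fn = int(self.counts[i].sum() - tp)
        fp = int(self.counts[:, i].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, fn, fp, tn

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


@dataclass
class CVResult:
    accuracy: float  # percent, over classifiable (non-outlier) test events
    confusion: ConfusionMatrix
    n_scored: int
    n_outliers: int
    n_iterations: int


def _run_splits(
    matrix: IntensityMatrix,
    y: np.ndarray,
    splits: Sequence[tuple[np.ndarray, np.ndarray]],
    classes: list[str],
    n_components: int | float,
) -> CVResult:
    actual: list[str] = []
    predicted: list[str] = []
    n_outliers = 0
    for train, test in splits:
        m = fit_pcalda(matrix.subset_rows(train), y[train], n_components=n_components)
        scores = project(m, matrix.subset_rows(test))
        for row, t in enumerate(test):
            pred = call_event(m, scores[row])
            if pred.status == "outlier":
                n_outliers += 1
                continue
            actual.append(str(y[t]))
            predicted.append(pred.called_class)
    cm = ConfusionMatrix.from_pairs(actual, predicted, classes)
    acc = 100.0 * sum(a == p for a, p in zip(actual, predicted)) / len(actual) \
        if actual else math.nan
    return CVResult(acc, cm, len(actual), n_outliers, len(splits))


def crossval_event(
    matrix: IntensityMatrix,
    labels: Sequence[str],
    folds: int = 5,
    seed: int = 0,
    n_components: int | float = 0.95,
    max_retries: int = 5,
) -> CVResult:
    """Event-level stratified k-fold CV (80% fit / 20% test per fold).

    Caveat by construction: events from one specimen may populate both the
    model and the test set, so accuracies are optimistically biased relative
    to :func:`crossval_fullgroup`.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    y = np.asarray(labels, dtype=object)
    classes = sorted(set(map(str, y)))
    last_err: Exception | None = None
    for attempt in range(max_retries):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        splits = list(skf.split(np.zeros(y.size), y.astype(str)))
        if any(len(set(map(str, y[tr]))) < len(classes) for tr, _ in splits):
            last_err = ValueError("a class was absent from a training split")
            continue
        try:
            return _run_splits(matrix, y, splits, classes, n_components)
        except ValueError as e:  # e.g. a train split left a class with 1 event
            last_err = e
    raise ValueError(f"cross-validation failed after {max_retries} redraws: {last_err}")


def crossval_fullgroup(
    matrix: IntensityMatrix,
    labels: Sequence[str],
    groups: Sequence[str],
    n_components: int | float = 0.95,
) -> CVResult:
    """Leave-one-specimen-out CV: one iteration per specimen, all of its
    events held out together (no specimen-level leakage)."""
    y = np.asarray(labels, dtype=object)
    g = np.asarray(groups, dtype=object)
    classes = sorted(set(map(str, y)))
    spec_class: dict[str, str] = {}
    for gi, yi in zip(g, y):
        spec_class.setdefault(str(gi), str(yi))
    per_class: dict[str, int] = {}
    for c in spec_class.values():
        per_class[c] = per_class.get(c, 0) + 1
    if min(per_class.values()) < 2:
        small = min(per_class, key=per_class.get)
        raise ValueError(f"class {small!r} has fewer than 2 specimens")
    specimens = sorted(set(map(str, g)))
    splits = []
    for s in specimens:
        test = np.flatnonzero(g.astype(str) == s)
        train = np.flatnonzero(g.astype(str) != s)
        splits.append((train, test))
    return _run_splits(matrix, y, splits, classes, n_components)


def sensitivity_specificity(tp: int, fn: int, fp: int, tn: int) -> tuple[float, float]:
    """One-vs-rest (sensitivity %, specificity %), each to 2 decimals.

    A zero denominator yields NaN (flagged by a warning), never a silent 0.
    """
    if min(tp, fn, fp, tn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fn > 0:
        sens = round(100.0 * tp / (tp + fn), 2)
    else:
        warnings.warn("sensitivity undefined: TP + FN == 0")
        sens = math.nan
    if tn + fp > 0:
        spec = round(100.0 * tn / (tn + fp), 2)
    else:
        warnings.warn("specificity undefined: TN + FP == 0")
        spec = math.nan
    return sens, spec


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def average_metrics(values: Sequence[float]) -> tuple[int, int]:
    """(mean, population SD) of percent values, rounded half-away-from-zero
    to integer percent."""
    vals = [v for v in values if not math.isnan(v)]
    if not vals:
        raise ValueError("no defined values to average")
    mean = float(np.mean(vals))
    sd = float(np.std(vals))  # population SD (divide by n)
    return _round_half_away(mean), _round_half_away(sd)


def spatial_concordance(frame: pd.DataFrame) -> tuple[float, float]:
    """(percent of classifiable events correct, percent of specimens whose
    classifiable events are all correct).

    ``frame`` needs columns specimen_id, expected_class, predicted_class,
    status.  Specimens with no classifiable event are excluded from the
    second rate.  Returns NaNs (with a warning) if nothing is classifiable.
    """
    cls = frame[frame["status"] == "classified"]
    if cls.empty:
        warnings.warn("no classifiable events; concordance undefined")
        return math.nan, math.nan
    correct = cls["expected_class"].astype(str) == cls["predicted_class"].astype(str)
    event_pct = 100.0 * float(correct.mean())
    unanimous = correct.groupby(cls["specimen_id"]).all()
    specimen_pct = 100.0 * float(unanimous.mean())
    return event_pct, specimen_pct


@dataclass
class MetricsReport:
    """Tables-style report: per-class one-vs-rest counts and rates, computed
    unthresholded (all classifiable events) and thresholded (only events
    whose posterior exceeds the probability threshold)."""

    classes: list[str]
    per_class: dict  # variant -> class -> {tp, fn, fp, tn, sensitivity, specificity}
    averages: dict  # variant -> metric -> (mean_int, sd_int)
    counts: dict[str, int]
    concordance: tuple[float, float]
    prob_threshold: float = 0.95
    confusion: dict = field(default_factory=dict)  # variant -> ConfusionMatrix

    def to_json(self) -> dict:
        doc = {
            "classes": self.classes,
            "per_class": self.per_class,
            "averages": {
                v: {m: list(ms) for m, ms in d.items()} for v, d in self.averages.items()
            },
            "counts": self.counts,
            "concordance": {
                "event_pct": self.concordance[0],
                "specimen_unanimous_pct": self.concordance[1],
            },
            "prob_threshold": self.prob_threshold,
            "confusion": {
                v: cm.counts.tolist() for v, cm in self.confusion.items()
            },
        }
        return doc


def build_report(frame: pd.DataFrame, prob_threshold: float = 0.95) -> MetricsReport:
    """Build the two-block metrics report from a per-event prediction frame.

    ``frame`` is the output of
    :func:`lipidlda.classify.predictions_to_frame`: one row per scored event
    with expected_class, predicted_class, status and passes_threshold.
    """
    classes = sorted(set(frame.loc[frame["status"] == "classified", "expected_class"]
                         .astype(str)))
    classifiable = frame[frame["status"] == "classified"]
    variants = {
        "unthresholded": classifiable,
        "thresholded": classifiable[classifiable["passes_threshold"].astype(bool)],
    }
    per_class: dict[str, dict] = {}
    averages: dict[str, dict] = {}
    confusion: dict[str, ConfusionMatrix] = {}
    for name, sub in variants.items():
        cm = ConfusionMatrix.from_pairs(
            sub["expected_class"].astype(str),
            sub["predicted_class"].astype(str),
            classes,
        )
        confusion[name] = cm
        block: dict[str, dict] = {}
        sens_vals, spec_vals = [], []
        for c in classes:
            tp, fn, fp, tn = cm.ovr_counts(c)
            sens, spec = sensitivity_specificity(tp, fn, fp, tn)
            block[c] = {"tp": tp, "fn": fn, "fp": fp, "tn": tn,
                        "sensitivity": sens, "specificity": spec}
            sens_vals.append(sens)
            spec_vals.append(spec)
        per_class[name] = block
        averages[name] = {
            "sensitivity": average_metrics(sens_vals),
            "specificity": average_metrics(spec_vals),
        }
    counts = accounting(
        total=len(frame),
        bad=int((frame["status"] == "bad").sum()),
        outlier=int((frame["status"] == "outlier").sum()),
        below_threshold=int(
            (classifiable["passes_threshold"].astype(bool) == False).sum()  # noqa: E712
        ),
    )
    return MetricsReport(
        classes=classes,
        per_class=per_class,
        averages=averages,
        counts=counts,
        concordance=spatial_concordance(frame),
        prob_threshold=prob_threshold,
        confusion=confusion,
    )


def accounting(
    total: int, bad: int, outlier: int, below_threshold: int = 0
) -> dict[str, int]:
    """Event accounting: classifiable = total - bad - outlier, and
    thresholded = classifiable - below_threshold."""
    if min(total, bad, outlier, below_threshold) < 0:
        raise ValueError("counts must be non-negative")
    classifiable = total - bad - outlier
    if classifiable < 0:
        raise ValueError("bad + outlier exceed the total event count")
    thresholded = classifiable - below_threshold
    if thresholded < 0:
        raise ValueError("below-threshold count exceeds the classifiable total")
    return {
        "total": total,
        "bad": bad,
        "outlier": outlier,
        "classifiable": classifiable,
        "below_threshold": below_threshold,
        "thresholded": thresholded,
    }
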