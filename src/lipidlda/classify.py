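"""Mahalanobis scoring of query events against a fitted PCA-LDA model.

An event is called by cluster overlap: it belongs to the nearest class (by
squared Mahalanobis distance) provided it falls inside that class's SD-gate
ellipsoid — a chi-square quantile gate on d2 with as many degrees of freedom
as the discriminant space has dimensions.  Events outside every gate are
outliers ("unclassifiable"); short-duration events are "bad" and carry no
scores at all.  The prediction probability is the equal-prior Gaussian
posterior of the called class, compared against a strict > threshold rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .model import PCALDAModel, project
from .spectra_io import EventMeta, IntensityMatrix, qc_flag_bad

__all__ = [
    "Prediction",
    "mahalanobis_d2",
    "class_posterior",
    "sd_gate_radius2",
    "call_event",
    "classify_cohort",
    "summarize_predictions",
    "predictions_to_frame",
]


@dataclass
class Prediction:
    """Per-event classification outcome."""

    event_id: str
    status: str  # classified | outlier | bad
    called_class: str | None
    posterior: float | None  # posterior of the called class
    d2: dict[str, float] | None  # per-class squared Mahalanobis distance
    posteriors: dict[str, float] | None  # full posterior vector
    passes_threshold: bool

    def __post_init__(self) -> None:
        if self.status not in ("classified", "outlier", "bad"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "bad" and (self.d2 is not None or self.called_class is not None):
            raise ValueError("bad events carry no scores")
        if self.status == "outlier" and self.called_class is not None:
            raise ValueError("outlier events carry no called class")


def mahalanobis_d2(model: PCALDAModel, score: np.ndarray) -> np.ndarray:
    """Per-class squared Mahalanobis distance of one discriminant-space point."""
    score = np.asarray(score, dtype=float).ravel()
    if not np.all(np.isfinite(score)):
        raise ValueError("non-finite discriminant score")
    if score.size != model.n_discriminants:
        raise ValueError("score dimensionality does not match the model")
    out = np.empty(len(model.classes_))
    for i in range(len(model.classes_)):
        delta = score - model.centroids_[i]
        out[i] = float(delta @ np.linalg.solve(model.covariances_[i], delta))
    return out


def class_posterior(model: PCALDAModel, d2: np.ndarray) -> np.ndarray:
    """Equal-prior Gaussian posterior over classes from squared distances.

    posterior_c is proportional to |Sigma_c|^(-1/2) * exp(-d2_c / 2),
    normalized over classes; stabilized by max-subtraction in the exponent.
    """
    d2 = np.asarray(d2, dtype=float)
    if not np.all(np.isfinite(d2)):
        raise ValueError("non-finite squared distances")
    _, logdets = np.linalg.slogdet(model.covariances_)
    logw = -0.5 * logdets - 0.5 * d2
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def sd_gate_radius2(model: PCALDAModel) -> float:
    """Squared-distance gate: chi-square quantile (df = dim) at the
    probability mass a 1-D Gaussian holds within ``sd_gate`` SDs."""
    level = float(chi2.cdf(model.sd_gate**2, df=1))
    return float(chi2.ppf(level, df=model.n_discriminants))


def call_event(model: PCALDAModel, score: np.ndarray, event_id: str = "") -> Prediction:
    """Gate + nearest-centroid class call for one QC-passed event."""
    d2 = mahalanobis_d2(model, score)
    post = class_posterior(model, d2)
    d2_map = {c: float(v) for c, v in zip(model.classes_, d2)}
    post_map = {c: float(v) for c, v in zip(model.classes_, post)}
    if float(d2.min()) > sd_gate_radius2(model):
        return Prediction(event_id, "outlier", None, None, d2_map, post_map, False)
    i = int(np.argmin(d2))  # ties resolve to the first class in model order
    p = float(post[i])
    return Prediction(
        event_id, "classified", model.classes_[i], p, d2_map, post_map,
        passes_threshold=p > model.prob_threshold,
    )


def classify_cohort(
    model: PCALDAModel,
    matrix: IntensityMatrix,
    meta: Sequence[EventMeta] | None = None,
    max_bad_duration_s: float = 3.0,
) -> list[Prediction]:
    """Score every event in the matrix; bad-QC events get status='bad'."""
    meta = list(meta) if meta is not None else list(matrix.meta)
    if len(meta) != matrix.n_events:
        raise ValueError("one EventMeta required per matrix row")
    flags = qc_flag_bad(meta, max_bad_duration_s=max_bad_duration_s)
    scores = project(model, matrix)
    preds: list[Prediction] = []
    for i, m in enumerate(meta):
        if flags[i] == "bad":
            preds.append(Prediction(m.event_id, "bad", None, None, None, None, False))
        else:
            preds.append(call_event(model, scores[i], event_id=m.event_id))
    return preds


def summarize_predictions(predictions: Sequence[Prediction]) -> dict[str, int]:
    """Event accounting: classifiable = total - bad - outlier."""
    total = len(predictions)
    bad = sum(p.status == "bad" for p in predictions)
    outlier = sum(p.status == "outlier" for p in predictions)
    below = sum(p.status == "classified" and not p.passes_threshold for p in predictions)
    classifiable = total - bad - outlier
    return {
        "total": total,
        "bad": bad,
        "outlier": outlier,
        "classifiable": classifiable,
        "below_threshold": below,
        "thresholded": classifiable - below,
    }


def predictions_to_frame(
    predictions: Sequence[Prediction],
    meta: Sequence[EventMeta],
) -> pd.DataFrame:
    """Per-event report: expected vs predicted class plus MS metrics."""
    by_id = {m.event_id: m for m in meta}
    rows = []
    for p in predictions:
        m = by_id[p.event_id]
        rows.append(
            {
                "event_id": p.event_id,
                "specimen_id": m.specimen_id,
                "expected_class": m.class_label,
                "predicted_class": p.called_class if p.called_class is not None else "",
                "status": p.status,
                "posterior": p.posterior if p.posterior is not None else np.nan,
                "passes_threshold": p.passes_threshold,
                "duration_s": m.duration_s,
                "tic": m.tic,
            }
        )
    return pd.DataFrame(rows)
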