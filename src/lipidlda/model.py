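"""PCA-LDA fitting, projection, loading ranking, permutation, learning curves.

The model mean-centres the binned intensity matrix, reduces it to ``k``
principal axes, then finds Fisher discriminant axes maximising the ratio of
between-class to within-class scatter with equal class priors.  Per-class
centroids and covariances are estimated in the (at most C-1 dimensional)
discriminant space; they drive the Mahalanobis class calls in
:mod:`lipidlda.classify`.

Discriminant axes are scaled so that the pooled within-class covariance in
discriminant space is the identity; their sign is fixed so the
largest-magnitude component is positive, making fits deterministic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .spectra_io import BinGrid, IntensityMatrix

__all__ = [
    "PCALDAModel",
    "LoadingRanking",
    "fit_pcalda",
    "project",
    "rank_loadings",
    "permute_labels",
    "learning_curve",
    "restrict_features",
]

#: Relative ridge added to near-singular covariances.
COV_RIDGE = 1e-8


@dataclass
class PCALDAModel:
    """Fitted PCA-LDA model with per-class Gaussian statistics.

    ``pc_loadings`` (bins x k) and ``lda_axes`` (k x d) compose to the linear
    map from centred bin space into discriminant space.
    """

    grid: BinGrid
    feature_bins: np.ndarray  # column labels the model was fitted on
    mean_: np.ndarray
    pc_loadings: np.ndarray
    lda_axes: np.ndarray
    classes_: list[str]
    centroids_: np.ndarray  # (C, d)
    covariances_: np.ndarray  # (C, d, d)
    sd_gate: float = 3.0
    prob_threshold: float = 0.95
    explained_variance_ratio_: np.ndarray = field(default_factory=lambda: np.zeros(0))
    pooled_cov_classes_: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.pc_loadings.shape[1]

    @property
    def n_discriminants(self) -> int:
        return self.lda_axes.shape[1]

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> dict:
        doc = {
            "grid": self.grid.to_dict(),
            "feature_bins": [float(x) for x in self.feature_bins],
            "mean": self.mean_.tolist(),
            "pc_loadings": self.pc_loadings.tolist(),
            "lda_axes": self.lda_axes.tolist(),
            "classes": list(self.classes_),
            "centroids": self.centroids_.tolist(),
            "covariances": self.covariances_.tolist(),
            "sd_gate": self.sd_gate,
            "prob_threshold": self.prob_threshold,
            "explained_variance_ratio": self.explained_variance_ratio_.tolist(),
            "pooled_cov_classes": list(self.pooled_cov_classes_),
        }
        if path is not None:
            Path(path).write_text(json.dumps(doc))
        return doc

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "PCALDAModel":
        doc = source if isinstance(source, dict) else json.loads(Path(source).read_text())
        return cls(
            grid=BinGrid.from_dict(doc["grid"]),
            feature_bins=np.asarray(doc["feature_bins"], dtype=float),
            mean_=np.asarray(doc["mean"], dtype=float),
            pc_loadings=np.asarray(doc["pc_loadings"], dtype=float),
            lda_axes=np.asarray(doc["lda_axes"], dtype=float),
            classes_=list(doc["classes"]),
            centroids_=np.asarray(doc["centroids"], dtype=float),
            covariances_=np.asarray(doc["covariances"], dtype=float),
            sd_gate=float(doc["sd_gate"]),
            prob_threshold=float(doc["prob_threshold"]),
            explained_variance_ratio_=np.asarray(doc["explained_variance_ratio"], dtype=float),
            pooled_cov_classes_=list(doc.get("pooled_cov_classes", [])),
        )


@dataclass
class LoadingRanking:
    """Bins ordered by their contribution to the discriminant axes."""

    bins: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("ranking scores must be non-increasing")

    def __len__(self) -> int:
        return self.bins.size

    def top(self, n: int) -> "LoadingRanking":
        return LoadingRanking(self.bins[:n].copy(), self.scores[:n].copy())


def _select_k(singular_values: np.ndarray, n_components: int | float,
              n_events: int, n_classes: int) -> int:
    rank = int(np.sum(singular_values > singular_values[0] * 1e-12)) if singular_values.size else 0
    rank = max(rank, 1)
    if isinstance(n_components, (int, np.integer)):
        k = int(n_components)
    else:
        if not 0.0 < n_components <= 1.0:
            raise ValueError("variance fraction must lie in (0, 1]")
        var = singular_values**2
        cum = np.cumsum(var) / var.sum()
        k = int(np.searchsorted(cum, n_components - 1e-12) + 1)
    cap = max(min(100, n_events - n_classes - 1), 1)
    k = min(k, cap, rank)
    # keep k >= C-1 where the data allow, so the LDA is not starved of axes
    k = max(k, min(n_classes - 1, rank, cap))
    return max(k, 1)


def fit_pcalda(
    matrix: IntensityMatrix,
    labels: Sequence[str] | None = None,
    n_components: int | float = 0.95,
    sd_gate: float = 3.0,
    prob_threshold: float = 0.95,
) -> PCALDAModel:
    """Fit the PCA-LDA model on good (QC-passed) events.

    ``n_components`` is either an explicit number of principal axes or a
    variance fraction in (0, 1]; the default keeps the smallest k explaining
    95% of variance, capped at min(100, n_events - C - 1).
    """
    X = matrix.values
    y = np.asarray(labels if labels is not None else matrix.labels, dtype=object)
    if y.size != X.shape[0]:
        raise ValueError("one label required per event row")
    classes = sorted(set(map(str, y)))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to fit a discriminant model")
    counts = {c: int(np.sum(y == c)) for c in classes}
    if min(counts.values()) < 2:
        small = min(counts, key=counts.get)
        raise ValueError(f"class {small!r} has fewer than 2 events")

    n, p = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean

    # SVD restricted to columns with signal: zero-variance columns get zero
    # loadings either way, and skipping them makes wide matrices cheap.
    active = np.flatnonzero(np.ptp(Xc, axis=0) > 0)
    if active.size == 0:
        raise ValueError("matrix has no varying columns")
    U, S, Vt = np.linalg.svd(Xc[:, active], full_matrices=False)
    k = _select_k(S, n_components, n, len(classes))
    T = U[:, :k] * S[:k]
    loadings = np.zeros((p, k))
    loadings[active] = Vt[:k].T
    evr = S**2 / np.sum(S**2)

    # Fisher LDA in PC space, equal class priors.
    mus = np.stack([T[y == c].mean(axis=0) for c in classes])
    mbar = mus.mean(axis=0)
    Sw = np.zeros((k, k))
    for c in classes:
        D = T[y == c] - mus[classes.index(c)]
        Sw += D.T @ D
    Sw /= max(n - len(classes), 1)
    tr = np.trace(Sw) / k if np.trace(Sw) > 0 else 1.0
    if np.linalg.cond(Sw) > 1e10:
        warnings.warn("within-class scatter near-singular; ridge-regularized")
        Sw = Sw + 1e-6 * tr * np.eye(k)
    else:
        Sw = Sw + 1e-12 * tr * np.eye(k)
    Sb = (mus - mbar).T @ (mus - mbar) / len(classes)
    evals, evecs = scipy.linalg.eigh(Sb, Sw)
    d = min(len(classes) - 1, k)
    W = evecs[:, ::-1][:, :d]  # descending eigenvalue order, WT Sw W = I
    # deterministic sign: largest-magnitude entry of each axis positive
    for j in range(d):
        i = np.argmax(np.abs(W[:, j]))
        if W[i, j] < 0:
            W[:, j] = -W[:, j]

    Z = T @ W
    centroids = np.stack([Z[y == c].mean(axis=0) for c in classes])
    pooled = np.zeros((d, d))
    for i, c in enumerate(classes):
        D = Z[y == c] - centroids[i]
        pooled += D.T @ D
    pooled /= max(n - len(classes), 1)
    pooled = _regularize(pooled)

    covariances = np.empty((len(classes), d, d))
    pooled_fallback: list[str] = []
    for i, c in enumerate(classes):
        nc = counts[c]
        if nc < d + 2:
            warnings.warn(f"class {c!r} too small for its own covariance; using pooled")
            covariances[i] = pooled
            pooled_fallback.append(c)
            continue
        D = Z[y == c] - centroids[i]
        cov = _regularize(D.T @ D / (nc - 1))
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            warnings.warn(f"class {c!r} covariance not positive definite; using pooled")
            cov = pooled
            pooled_fallback.append(c)
        covariances[i] = cov

    return PCALDAModel(
        grid=matrix.grid,
        feature_bins=np.asarray(matrix.column_labels, dtype=float),
        mean_=mean,
        pc_loadings=loadings,
        lda_axes=W,
        classes_=classes,
        centroids_=centroids,
        covariances_=covariances,
        sd_gate=sd_gate,
        prob_threshold=prob_threshold,
        explained_variance_ratio_=evr,
        pooled_cov_classes_=pooled_fallback,
    )


def _regularize(cov: np.ndarray) -> np.ndarray:
    """Symmetrize and ridge a covariance (relative ridge, absolute floor)."""
    cov = (cov + cov.T) / 2.0
    d = cov.shape[0]
    tr = np.trace(cov)
    ridge = COV_RIDGE * (tr / d) if tr > 0 else 0.0
    return cov + max(ridge, 1e-12) * np.eye(d)


def project(model: PCALDAModel, matrix: IntensityMatrix) -> np.ndarray:
    """Map events into discriminant space (rows x d); pure linear map."""
    cols = np.asarray(matrix.column_labels, dtype=float)
    if cols.size != model.feature_bins.size or not np.allclose(cols, model.feature_bins):
        raise ValueError("matrix columns do not match the model's feature bins")
    return (matrix.values - model.mean_) @ model.pc_loadings @ model.lda_axes


def project_points(model: PCALDAModel, values: np.ndarray) -> np.ndarray:
    """Project raw bin-space rows already aligned to the model's features."""
    return (np.atleast_2d(values) - model.mean_) @ model.pc_loadings @ model.lda_axes


def rank_loadings(model: PCALDAModel, top_n: int = 100) -> LoadingRanking:
    """Rank bins by the L2 norm of their composed discriminant loadings.

    The bins-to-discriminant map is ``pc_loadings @ lda_axes``; a bin's
    importance is the Euclidean norm of its row across all discriminant
    axes.  Ties are broken by ascending bin label.
    """
    B = model.pc_loadings @ model.lda_axes
    scores = np.linalg.norm(B, axis=1)
    bins = model.feature_bins
    order = np.lexsort((bins, -scores))
    ranking = LoadingRanking(bins[order].copy(), scores[order].copy())
    if top_n > len(ranking):
        warnings.warn(f"top_n={top_n} exceeds {len(ranking)} bins; returning all")
        return ranking
    return ranking.top(top_n)


def permute_labels(
    labels: Sequence[str],
    groups: Sequence[str],
    seed: int = 0,
) -> np.ndarray:
    """Specimen-level label permutation building balanced pseudo-classes.

    Specimens of each true class are shuffled and dealt round-robin across
    the class names (with rotating offsets), so every pseudo-class receives
    ~1/C of each true class's specimens — and hence ~equal numbers of events
    from every true class on balanced cohorts.  All events of one specimen
    share one pseudo-label.
    """
    labels = np.asarray(labels, dtype=object)
    groups = np.asarray(groups, dtype=object)
    classes = sorted(set(map(str, labels)))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to permute")
    spec_class: dict[str, str] = {}
    for g, c in zip(groups, labels):
        if spec_class.setdefault(str(g), str(c)) != str(c):
            raise ValueError(f"specimen {g!r} carries more than one class label")
    by_class: dict[str, list[str]] = {c: [] for c in classes}
    for g, c in spec_class.items():
        by_class[c].append(g)
    if min(len(v) for v in by_class.values()) < 2:
        raise ValueError("cannot permute: a class has a single specimen")
    rng = np.random.default_rng(seed)
    C = len(classes)
    pseudo: dict[str, str] = {}
    for j, c in enumerate(classes):
        specs = sorted(by_class[c])
        rng.shuffle(specs)
        for i, g in enumerate(specs):
            pseudo[g] = classes[(i + j) % C]
    return np.array([pseudo[str(g)] for g in groups], dtype=object)


def restrict_features(matrix: IntensityMatrix, bins: Sequence[float]) -> IntensityMatrix:
    """Column subset in the given bin-label order (sparse analysis input)."""
    idx = []
    cols = np.asarray(matrix.column_labels, dtype=float)
    for b in bins:
        hits = np.flatnonzero(np.abs(cols - float(b)) <= 1e-6)
        if hits.size == 0:
            raise KeyError(f"bin label {b!r} not present in the matrix columns")
        idx.append(int(hits[0]))
    return IntensityMatrix(
        grid=matrix.grid,
        values=matrix.values[:, idx].copy(),
        meta=list(matrix.meta),
        n_dropped_peaks=matrix.n_dropped_peaks,
        column_labels=cols[idx].copy(),
    )


def learning_curve(
    matrix: IntensityMatrix,
    labels: Sequence[str],
    groups: Sequence[str],
    fractions: Sequence[float],
    reps: int = 3,
    seed: int = 0,
    n_components: int | float = 0.95,
) -> pd.DataFrame:
    """Full-group CV accuracy versus fraction of specimens used.

    For each fraction < 1, specimens are subsampled per class (without
    replacement) ``reps`` times and leave-one-specimen-out CV is run on the
    subset; fraction 1.0 uses all data once.  Returns a frame with columns
    fraction, mean_accuracy, sd_accuracy, n_reps.
    """
    from .validate import crossval_fullgroup  # local import to avoid a cycle

    fractions = list(fractions)
    if sorted(fractions) != fractions:
        raise ValueError("fractions must be sorted ascending")
    if not np.isclose(fractions[-1], 1.0):
        raise ValueError("fractions must include 1.0")
    labels = np.asarray(labels, dtype=object)
    groups = np.asarray(groups, dtype=object)
    spec_class = {str(g): str(c) for g, c in zip(groups, labels)}
    by_class: dict[str, list[str]] = {}
    for g, c in spec_class.items():
        by_class.setdefault(c, []).append(g)
    rng = np.random.default_rng(seed)

    rows = []
    for frac in fractions:
        if np.isclose(frac, 1.0):
            res = crossval_fullgroup(matrix, labels, groups, n_components=n_components)
            rows.append((1.0, res.accuracy, 0.0, 1))
            continue
        keep_counts = {c: int(round(frac * len(v))) for c, v in by_class.items()}
        if min(keep_counts.values()) < 2:
            warnings.warn(f"fraction {frac} leaves <2 specimens in a class; skipped")
            continue
        accs = []
        for _ in range(reps):
            keep: set[str] = set()
            for c, specs in sorted(by_class.items()):
                chosen = rng.choice(sorted(specs), size=keep_counts[c], replace=False)
                keep.update(map(str, chosen))
            mask = np.array([str(g) in keep for g in groups])
            res = crossval_fullgroup(
                matrix.subset_rows(mask), labels[mask], groups[mask],
                n_components=n_components,
            )
            accs.append(res.accuracy)
        rows.append((frac, float(np.mean(accs)), float(np.std(accs)), reps))
    return pd.DataFrame(rows, columns=["fraction", "mean_accuracy", "sd_accuracy", "n_reps"])
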