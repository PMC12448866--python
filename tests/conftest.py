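"""Shared fixtures: synthetic cohorts and hand-built toy models."""

from __future__ import annotations

import numpy as np
import pytest

from lipidlda import (
    BinGrid,
    PCALDAModel,
    SimConfig,
    bin_events,
    fit_pcalda,
    simulate_cohort,
    tic_normalize,
)


@pytest.fixture(scope="session")
def grid() -> BinGrid:
    return BinGrid()


@pytest.fixture(scope="session")
def sep_cohort():
    """High-separation 3-class cohort: 6 specimens x 4 events per class."""
    cfg = SimConfig(
        classes={"mening": 6, "schwan": 6, "metast": 6},
        events_per_specimen=(4, 4),
        separation=1.5,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def sep_matrix(sep_cohort, grid):
    peaks, meta, _ = sep_cohort
    return tic_normalize(bin_events(peaks, grid, meta))


@pytest.fixture(scope="session")
def sep_model(sep_matrix):
    return fit_pcalda(sep_matrix)


def make_toy_model(
    centroids,
    covariances,
    classes=None,
    sd_gate: float = 3.0,
    prob_threshold: float = 0.95,
) -> PCALDAModel:
    """Model with given discriminant-space Gaussians and identity projection."""
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    C, d = centroids.shape
    covs = np.asarray(covariances, dtype=float).reshape(C, d, d)
    names = list(classes) if classes is not None else [f"c{i}" for i in range(C)]
    return PCALDAModel(
        grid=BinGrid(),
        feature_bins=np.array([100.05 + 0.1 * j for j in range(d)]),
        mean_=np.zeros(d),
        pc_loadings=np.eye(d),
        lda_axes=np.eye(d),
        classes_=names,
        centroids_=centroids,
        covariances_=covs,
        sd_gate=sd_gate,
        prob_threshold=prob_threshold,
    )
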