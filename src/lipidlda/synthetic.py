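"""Synthetic cohort generator with hierarchical specimen/event variance.

Generates peak lists + metadata that mimic the statistical structure the
analysis assumes: per-class lipid signatures anchored on the 41-bin marker
array, multiplicative log-normal specimen and event effects (inter- vs
intra-specimen heterogeneity), Gaussian m/z jitter around bin centres,
per-event TIC scaling, short-duration "bad" events, and class-unrelated
outlier events.  Everything is driven by one seed, so identical configs
reproduce byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .markers import MARKER_BINS
from .spectra_io import BinGrid, EventMeta, PeakList

__all__ = ["SimConfig", "CohortTruth", "default_signatures", "simulate_cohort"]


@dataclass
class SimConfig:
    """Cohort generator parameters.

    ``classes`` maps class name -> number of specimens.  ``signature_bins``
    maps class name -> sequence of (bin label, relative abundance); when
    omitted, :func:`default_signatures` builds signatures over the marker
    array at the given ``separation``.
    """

    classes: Mapping[str, int]
    events_per_specimen: tuple[int, int] = (8, 8)
    signature_bins: Mapping[str, Sequence[tuple[float, float]]] | None = None
    separation: float = 1.0
    sigma_specimen: float = 0.25
    sigma_event: float = 0.15
    mz_jitter_sd: float = 0.02
    n_baseline_peaks: int = 60
    baseline_scale: float = 0.5
    tic_mean: float = 3e6
    tic_sd: float = 2e6
    frac_bad: float = 0.0
    frac_outlier: float = 0.0
    duration_mean_s: float = 13.0
    duration_sd_s: float = 2.0
    seed: int = 0
    grid: BinGrid = field(default_factory=BinGrid)

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        if any(n <= 0 for n in self.classes.values()):
            raise ValueError("specimen counts must be positive")
        lo, hi = self.events_per_specimen
        if lo <= 0 or hi < lo:
            raise ValueError("events_per_specimen must be a positive (lo, hi) range")
        for name, val in (("frac_bad", self.frac_bad), ("frac_outlier", self.frac_outlier)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("sigma_specimen", "sigma_event", "mz_jitter_sd",
                     "tic_sd", "duration_sd_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total_specimens(self) -> int:
        """Total specimen count across all classes (cohort accounting)."""
        return int(sum(self.classes.values()))


@dataclass
class CohortTruth:
    """Ground truth for a generated cohort.

    ``events`` has one row per generated event with its true class and
    artifact status (clean / bad / outlier); ``planted_bins`` lists, per
    class, the signature bins carrying the class signal.
    """

    events: pd.DataFrame  # columns: event_id, true_class, artifact
    planted_bins: dict[str, list[float]]


def default_signatures(
    classes: Sequence[str],
    separation: float = 1.0,
    bins: Sequence[float] = MARKER_BINS,
    seed: int = 0,
) -> dict[str, list[tuple[float, float]]]:
    """Per-class relative-abundance signatures over the marker-array bins.

    A shared log-normal base abundance per bin is modulated per class by
    ``exp(separation * z)`` with fixed standard-normal draws, so classes
    share peak locations but differ in mean profile; ``separation = 0``
    yields identical signatures for every class.
    """
    rng = np.random.default_rng(seed)
    bins = [float(b) for b in bins]
    base = np.exp(rng.normal(0.0, 0.5, size=len(bins)))
    out: dict[str, list[tuple[float, float]]] = {}
    for name in classes:
        z = rng.standard_normal(len(bins))
        abund = base * np.exp(separation * z)
        out[name] = list(zip(bins, abund))
    return out


def simulate_cohort(
    config: SimConfig,
) -> tuple[list[PeakList], list[EventMeta], CohortTruth]:
    """Generate a cohort of peak lists + metadata under the hierarchical model.

    Per specimen a log-normal random effect (``sigma_specimen``, per bin) is
    drawn; per event a log-normal noise factor (``sigma_event``, per bin)
    multiplies it.  Peak m/z = bin centre + Gaussian jitter; intensities are
    scaled to a drawn TIC.  A ``frac_bad`` share of events gets duration
    <= 3 s; a ``frac_outlier`` share gets a class-unrelated uniform profile
    over the background bins.
    """
    rng = np.random.default_rng(config.seed)
    class_names = list(config.classes)
    signatures = config.signature_bins or default_signatures(
        class_names, separation=config.separation, seed=config.seed
    )
    sig_bins = {c: np.array([b for b, _ in signatures[c]]) for c in class_names}
    sig_abund = {c: np.array([a for _, a in signatures[c]]) for c in class_names}

    # Shared background bins drawn once per cohort from the grid, excluding
    # every signature bin so outliers carry no class signal.
    used = {float(b) for bins in sig_bins.values() for b in bins}
    candidates = np.array([b for b in config.grid.labels if float(b) not in used])
    n_bg = min(config.n_baseline_peaks, candidates.size)
    bg_bins = np.sort(rng.choice(candidates, size=n_bg, replace=False))
    bg_abund = config.baseline_scale * np.exp(rng.normal(0.0, 0.3, size=n_bg))

    peaklists: list[PeakList] = []
    meta: list[EventMeta] = []
    truth_rows: list[tuple[str, str, str]] = []

    for cls in class_names:
        bins_c = np.concatenate([sig_bins[cls], bg_bins])
        template = np.concatenate([sig_abund[cls], bg_abund])
        for s in range(config.classes[cls]):
            specimen_id = f"{cls}-s{s:03d}"
            spec_effect = np.exp(config.sigma_specimen * rng.standard_normal(bins_c.size))
            lo, hi = config.events_per_specimen
            n_events = int(rng.integers(lo, hi + 1))
            for k in range(n_events):
                event_id = f"{specimen_id}-e{k:02d}"
                is_bad = rng.random() < config.frac_bad
                is_outlier = (not is_bad) and rng.random() < config.frac_outlier
                if is_outlier:
                    ev_bins = bg_bins
                    abund = rng.uniform(0.05, 1.0, size=bg_bins.size)
                else:
                    ev_bins = bins_c
                    ev_effect = np.exp(config.sigma_event * rng.standard_normal(bins_c.size))
                    abund = template * spec_effect * ev_effect
                mz = ev_bins + rng.normal(0.0, config.mz_jitter_sd, size=ev_bins.size) \
                    if config.mz_jitter_sd > 0 else ev_bins.astype(float).copy()
                tic = max(rng.normal(config.tic_mean, config.tic_sd), 0.01 * config.tic_mean)
                intensity = abund * (tic / abund.sum())
                if is_bad:
                    duration = float(rng.uniform(0.2, 3.0))
                else:
                    duration = max(
                        float(rng.normal(config.duration_mean_s, config.duration_sd_s)), 3.1
                    )
                peaklists.append(PeakList(event_id=event_id, mz=mz, intensity=intensity))
                meta.append(EventMeta(event_id, specimen_id, cls, duration, float(tic)))
                status = "bad" if is_bad else ("outlier" if is_outlier else "clean")
                truth_rows.append((event_id, cls, status))

    truth = CohortTruth(
        events=pd.DataFrame(truth_rows, columns=["event_id", "true_class", "artifact"]),
        planted_bins={c: [float(b) for b in sig_bins[c]] for c in class_names},
    )
    return peaklists, meta, truth
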