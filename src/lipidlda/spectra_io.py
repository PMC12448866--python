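"""Peak-list and metadata I/O, fixed-grid spectral binning, normalization, QC.

A *sampling event* is one ~10-second acquisition yielding a centroided peak
list.  Events are binned onto a fixed 0.1-Da grid over [100, 1000) Da to form
the intensity matrix that every downstream stage consumes.  Bins are
half-open intervals ``[lo + i*w, lo + (i+1)*w)`` labelled by their midpoint,
so a peak at m/z 860.6646 lands in the bin labelled 860.65 and a peak at
exactly 860.7 lands in 860.75.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PeakList",
    "EventMeta",
    "BinGrid",
    "IntensityMatrix",
    "read_peak_lists",
    "write_peak_lists",
    "read_metadata",
    "write_metadata",
    "bin_events",
    "tic_normalize",
    "qc_flag_bad",
]

#: Metadata columns required by :func:`read_metadata`.
META_COLUMNS = ("event_id", "specimen_id", "class_label", "duration_s", "tic")

# Tolerance added (in bin-width units) before flooring, so that m/z values
# that are exact bin edges up to float representation bin deterministically.
_EDGE_EPS = 1e-7


@dataclass
class PeakList:
    """One sampling event's centroided peaks, sorted ascending by m/z."""

    event_id: str
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(self.mz <= 0):
            raise ValueError(f"event {self.event_id!r}: m/z values must be positive")
        if np.any(self.intensity < 0):
            raise ValueError(f"event {self.event_id!r}: intensities must be >= 0")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return self.mz.size


@dataclass(frozen=True)
class EventMeta:
    """Per-event metadata: provenance, label, and acquisition QC quantities."""

    event_id: str
    specimen_id: str
    class_label: str
    duration_s: float
    tic: float

    def __post_init__(self) -> None:
        if self.duration_s < 0:
            raise ValueError(f"event {self.event_id!r}: negative duration")
        if self.tic < 0:
            raise ValueError(f"event {self.event_id!r}: negative TIC")


@dataclass(frozen=True)
class BinGrid:
    """Half-open 0.1-Da binning grid ``[lo, hi)`` with midpoint labels."""

    lo: float = 100.0
    hi: float = 1000.0
    width: float = 0.1

    def __post_init__(self) -> None:
        if not (self.lo < self.hi and self.width > 0):
            raise ValueError("invalid grid: need lo < hi and width > 0")

    @property
    def n_bins(self) -> int:
        return int(round((self.hi - self.lo) / self.width))

    @property
    def labels(self) -> np.ndarray:
        """Midpoint label of every bin, rounded to cancel float accumulation."""
        i = np.arange(self.n_bins)
        return np.round(self.lo + (i + 0.5) * self.width, 6)

    def bin_index(self, mz: np.ndarray) -> np.ndarray:
        """Bin index per m/z; -1 for peaks outside ``[lo, hi)``."""
        mz = np.asarray(mz, dtype=float)
        idx = np.floor((mz - self.lo) / self.width + _EDGE_EPS).astype(int)
        idx[(idx < 0) | (idx >= self.n_bins)] = -1
        return idx

    def index_of_label(self, label: float) -> int:
        """Index of the bin with the given midpoint label (hard error if absent)."""
        idx = int(np.floor((label - self.lo) / self.width + _EDGE_EPS))
        if not (0 <= idx < self.n_bins) or abs(self.labels[idx] - label) > 1e-6:
            raise KeyError(f"no bin labelled {label!r} on grid {self}")
        return idx

    def to_dict(self) -> dict:
        return {"lo": self.lo, "hi": self.hi, "width": self.width}

    @classmethod
    def from_dict(cls, d: dict) -> "BinGrid":
        return cls(lo=d["lo"], hi=d["hi"], width=d["width"])


@dataclass
class IntensityMatrix:
    """Events x bins matrix with aligned per-event metadata.

    ``values[i, j]`` is the summed intensity of event ``i`` in bin ``j``.
    Before normalization each row sums to the event's total in-range
    intensity; after :func:`tic_normalize` each nonzero row sums to 1.
    """

    grid: BinGrid
    values: np.ndarray
    meta: list[EventMeta]
    n_dropped_peaks: int = 0
    zero_rows: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    column_labels: np.ndarray | None = None  # defaults to the full grid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.column_labels is None:
            self.column_labels = self.grid.labels
        else:
            self.column_labels = np.asarray(self.column_labels, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.column_labels.size:
            raise ValueError("values must be 2-D with one column per bin label")
        if len(self.meta) != self.values.shape[0]:
            raise ValueError("metadata/value row count mismatch")
        if self.zero_rows.size == 0:
            self.zero_rows = ~self.values.any(axis=1)

    @property
    def event_ids(self) -> list[str]:
        return [m.event_id for m in self.meta]

    @property
    def labels(self) -> np.ndarray:
        return np.array([m.class_label for m in self.meta], dtype=object)

    @property
    def specimens(self) -> np.ndarray:
        return np.array([m.specimen_id for m in self.meta], dtype=object)

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def subset_rows(self, mask: np.ndarray) -> "IntensityMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return IntensityMatrix(
            grid=self.grid,
            values=self.values[idx],
            meta=[self.meta[i] for i in idx],
            n_dropped_peaks=self.n_dropped_peaks,
            column_labels=self.column_labels,
        )

    # -- persistence -------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix as TSV plus a ``<path>.grid.json`` sidecar."""
        path = Path(path)
        df = pd.DataFrame(self.values, columns=[f"{x:g}" for x in self.column_labels])
        df.insert(0, "event_id", self.event_ids)
        df.to_csv(path, sep="\t", index=False)
        sidecar = {
            "grid": self.grid.to_dict(),
            "n_dropped_peaks": self.n_dropped_peaks,
            "columns": [float(x) for x in self.column_labels],
        }
        Path(str(path) + ".grid.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path, meta: Sequence[EventMeta]) -> "IntensityMatrix":
        path = Path(path)
        sidecar = json.loads(Path(str(path) + ".grid.json").read_text())
        grid = BinGrid.from_dict(sidecar["grid"])
        df = pd.read_csv(path, sep="\t")
        by_id = {m.event_id: m for m in meta}
        try:
            ordered = [by_id[e] for e in df["event_id"].astype(str)]
        except KeyError as e:
            raise ValueError(f"event {e.args[0]!r} missing from metadata") from None
        values = df.drop(columns=["event_id"]).to_numpy(dtype=float)
        columns = np.asarray(sidecar["columns"], dtype=float) if "columns" in sidecar else None
        return cls(grid=grid, values=values, meta=ordered,
                   n_dropped_peaks=sidecar.get("n_dropped_peaks", 0),
                   column_labels=columns)


# -- file readers/writers --------------------------------------------------


def _read_peaks_table(path: Path, fmt: str) -> pd.DataFrame:
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, dtype={"event_id": str})
        missing = {"event_id", "mz", "intensity"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing peak columns {sorted(missing)}")
        for col in ("mz", "intensity"):
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
                raise ValueError(f"{path}: unparseable {col} value at line {line}")
            df[col] = pd.to_numeric(df[col])
        if df[["mz", "intensity"]].isna().any().any():
            line = int(df[["mz", "intensity"]].isna().any(axis=1).idxmax()) + 2
            raise ValueError(f"{path}: missing value at line {line}")
        return df
    if fmt == "mzml":
        try:
            from pyteomics import mzml  # optional dependency
        except ImportError as e:  # pragma: no cover - environment dependent
            raise ImportError("mzML input requires the optional 'pyteomics' package") from e
        rows = []
        with mzml.MzML(str(path)) as reader:  # pragma: no cover
            for spec in reader:
                eid = spec.get("id", f"spectrum={len(rows)}")
                for m, i in zip(spec["m/z array"], spec["intensity array"]):
                    rows.append((str(eid), float(m), float(i)))
        return pd.DataFrame(rows, columns=["event_id", "mz", "intensity"])
    raise ValueError(f"unknown peak-list format {fmt!r}")


def read_metadata(path: str | Path) -> list[EventMeta]:
    """Read the event metadata TSV (event_id, specimen_id, class_label, duration_s, tic)."""
    df = pd.read_csv(path, sep="\t", dtype={"event_id": str, "specimen_id": str})
    missing = set(META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    if df["event_id"].duplicated().any():
        dup = df.loc[df["event_id"].duplicated(), "event_id"].iloc[0]
        raise ValueError(f"{path}: duplicate event_id {dup!r}")
    return [
        EventMeta(
            event_id=str(r.event_id),
            specimen_id=str(r.specimen_id),
            class_label=str(r.class_label),
            duration_s=float(r.duration_s),
            tic=float(r.tic),
        )
        for r in df.itertuples(index=False)
    ]


def write_metadata(meta: Iterable[EventMeta], path: str | Path) -> None:
    pd.DataFrame(
        [(m.event_id, m.specimen_id, m.class_label, m.duration_s, m.tic) for m in meta],
        columns=list(META_COLUMNS),
    ).to_csv(path, sep="\t", index=False)


def read_peak_lists(
    peaks_path: str | Path,
    meta_path: str | Path,
    format: str = "tsv",
) -> tuple[list[PeakList], list[EventMeta]]:
    """Read per-event peak lists joined with their metadata table.

    Returns one :class:`PeakList` per event in metadata order.  An event
    present in the peak file but absent from metadata is a hard error
    (referential integrity), as is the reverse.
    """
    df = _read_peaks_table(Path(peaks_path), format)
    meta = read_metadata(meta_path)
    known = {m.event_id for m in meta}
    seen = set(df["event_id"].astype(str))
    orphans = seen - known
    if orphans:
        raise ValueError(f"event {sorted(orphans)[0]!r} present in peaks but not in metadata")
    absent = known - seen
    if absent:
        raise ValueError(f"event {sorted(absent)[0]!r} present in metadata but has no peaks")
    grouped = {str(k): g for k, g in df.groupby("event_id", sort=False)}
    peaklists = [
        PeakList(
            event_id=m.event_id,
            mz=grouped[m.event_id]["mz"].to_numpy(),
            intensity=grouped[m.event_id]["intensity"].to_numpy(),
        )
        for m in meta
    ]
    return peaklists, meta


def write_peak_lists(peaklists: Iterable[PeakList], path: str | Path, format: str = "tsv") -> None:
    """Write peak lists to a long-format CSV/TSV (event_id, mz, intensity)."""
    if format not in ("csv", "tsv"):
        raise ValueError(f"unknown peak-list format {format!r}")
    sep = "," if format == "csv" else "\t"
    frames = [
        pd.DataFrame({"event_id": p.event_id, "mz": p.mz, "intensity": p.intensity})
        for p in peaklists
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


# -- binning / normalization / QC ------------------------------------------


def bin_events(
    peaklists: Sequence[PeakList],
    grid: BinGrid,
    meta: Sequence[EventMeta] | None = None,
) -> IntensityMatrix:
    """Sum each event's peak intensities into the grid's half-open bins.

    Peaks outside ``[grid.lo, grid.hi)`` are dropped and counted in the
    result's ``n_dropped_peaks``; total in-range intensity is conserved.
    Empty peak lists yield all-zero rows (flagged via ``zero_rows``).
    """
    if meta is None:
        meta = [
            EventMeta(p.event_id, specimen_id=p.event_id, class_label="unknown",
                      duration_s=0.0, tic=float(p.intensity.sum()))
            for p in peaklists
        ]
    if len(meta) != len(peaklists):
        raise ValueError("one EventMeta required per PeakList")
    values = np.zeros((len(peaklists), grid.n_bins))
    dropped = 0
    for row, p in enumerate(peaklists):
        if len(p) == 0:
            continue
        idx = grid.bin_index(p.mz)
        in_range = idx >= 0
        dropped += int((~in_range).sum())
        np.add.at(values[row], idx[in_range], p.intensity[in_range])
    if dropped:
        logger.info("bin_events: dropped %d peaks outside [%g, %g)", dropped, grid.lo, grid.hi)
    return IntensityMatrix(grid=grid, values=values, meta=list(meta), n_dropped_peaks=dropped)


def tic_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Divide each nonzero row by its own sum; zero rows are left as-is and flagged."""
    sums = matrix.values.sum(axis=1)
    zero = sums == 0
    if zero.any():
        logger.warning("tic_normalize: %d all-zero rows left unnormalized", int(zero.sum()))
    safe = np.where(zero, 1.0, sums)
    return IntensityMatrix(
        grid=matrix.grid,
        values=matrix.values / safe[:, None],
        meta=list(matrix.meta),
        n_dropped_peaks=matrix.n_dropped_peaks,
        zero_rows=zero,
    )


def qc_flag_bad(meta: Sequence[EventMeta], max_bad_duration_s: float = 3.0) -> np.ndarray:
    """Flag events 'bad' when signal duration <= threshold, else 'good'.

    Bad events carry no classifiable information and are excluded from model
    fitting and from every accuracy denominator downstream.
    """
    durations = np.array([m.duration_s for m in meta], dtype=float)
    if np.any(durations < 0):
        raise ValueError("negative signal duration in metadata")
    return np.where(durations <= max_bad_duration_s, "bad", "good")
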