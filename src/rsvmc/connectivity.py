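"""Functional-connectivity feature construction.

Turns per-subject ROI (region-of-interest) time series into subject x edge
matrices of Pearson correlations — one feature per unordered ROI pair.  With
the 90 cerebral parcels of the AAL atlas this yields 90*89/2 = 4,005 features
per subject.

Edge indexing convention (fixed, everything downstream depends on it):
flat edge ``e`` enumerates the strict upper triangle of the ROI x ROI matrix
row-major, 0-based, with pairs ``(i, j)``, ``i < j``.  So ``e = 0`` is
``(0, 1)`` and for 90 ROIs ``e = 4004`` is ``(88, 89)``.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TimeSeriesPanel",
    "EdgeIndex",
    "FCDataset",
    "load_aal_table",
    "normalize_and_slice",
    "compute_fc",
    "read_panel",
    "write_panel",
]

MIN_SERIES_LENGTH = 10


def load_aal_table(include_cerebellum: bool = False) -> pd.DataFrame:
    """Load the shipped AAL-116 parcel table.

    By default the 26 cerebellar parcels are filtered out, leaving the 90
    cerebral regions used for connectivity features.

    Returns a DataFrame with columns ``index`` (1-based atlas index), ``name``
    (short label, e.g. ``LING.R``), ``full_name``, ``lobe`` and ``cerebellum``
    (0/1 flag).
    """
    ref = importlib.resources.files("rsvmc.data") / "aal116.tsv"
    with importlib.resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t")
    if not include_cerebellum:
        table = table[table["cerebellum"] == 0].reset_index(drop=True)
    return table


@dataclass
class TimeSeriesPanel:
    """Labelled collection of per-subject ROI x time matrices.

    Parameters
    ----------
    subject_ids : list of str
    labels : array of 0/1 (1 = patient, 0 = control)
    series : list of (n_rois, n_timepoints) float arrays; lengths may differ
        across subjects until :func:`normalize_and_slice` is applied.
    sites : optional per-subject site identifiers.
    """

    subject_ids: list[str]
    labels: np.ndarray
    series: list[np.ndarray]
    sites: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.subject_ids) != len(self.series) or len(self.labels) != len(self.series):
            raise ValueError("subject_ids, labels and series must have equal length")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary (0 = control, 1 = patient)")
        rois = {m.shape[0] for m in self.series}
        if len(rois) > 1:
            raise ValueError(f"all subjects must share n_rois; found {sorted(rois)}")
        for sid, m in zip(self.subject_ids, self.series):
            if not np.isfinite(m).all():
                raise ValueError(f"subject {sid}: series contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return len(self.series)

    @property
    def n_rois(self) -> int:
        return self.series[0].shape[0]

    @property
    def min_length(self) -> int:
        return min(m.shape[1] for m in self.series)


class EdgeIndex:
    """Bijection between flat edge indices and ROI pairs (i < j), row-major."""

    def __init__(self, n_rois: int):
        if n_rois < 2:
            raise ValueError("need at least 2 ROIs")
        self.n_rois = int(n_rois)
        self._iu = np.triu_indices(self.n_rois, k=1)

    @property
    def n_edges(self) -> int:
        return self.n_rois * (self.n_rois - 1) // 2

    @property
    def pairs(self) -> np.ndarray:
        """All (E, 2) ROI pairs in flat-index order."""
        return np.column_stack(self._iu)

    def edge_to_rois(self, e: int) -> tuple[int, int]:
        if not 0 <= e < self.n_edges:
            raise IndexError(f"edge index {e} out of range [0, {self.n_edges})")
        return int(self._iu[0][e]), int(self._iu[1][e])

    def rois_to_edge(self, i: int, j: int) -> int:
        if i == j:
            raise ValueError("self-pairs (i == j) carry no edge")
        if i > j:
            i, j = j, i
        if i < 0 or j >= self.n_rois:
            raise IndexError(f"ROI pair ({i}, {j}) out of range for {self.n_rois} ROIs")
        # row-major upper triangle: rows 0..i-1 contribute (R-1-k) cells each
        return i * (2 * self.n_rois - i - 1) // 2 + (j - i - 1)

    def edge_names(self, roi_names: list[str] | pd.Series) -> list[str]:
        names = list(roi_names)
        return [f"{names[i]}_{names[j]}" for i, j in zip(*self._iu)]

    def to_dict(self) -> dict:
        return {
            "n_rois": self.n_rois,
            "n_edges": self.n_edges,
            "convention": "0-based, i<j, row-major strict upper triangle",
        }


@dataclass
class FCDataset:
    """Subjects x edges matrix of Pearson functional connectivity."""

    X: np.ndarray
    labels: np.ndarray
    edge_index: EdgeIndex
    subject_ids: list[str] = field(default_factory=list)
    degenerate_edges: np.ndarray | None = None  # flat indices where r was forced to 0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.X.shape[1] != self.edge_index.n_edges:
            raise ValueError(
                f"feature count {self.X.shape[1]} != R(R-1)/2 = {self.edge_index.n_edges}"
            )
        if self.X.shape[0] != len(self.labels):
            raise ValueError("labels length must match number of subjects")
        if np.abs(self.X).max(initial=0.0) > 1.0 + 1e-9:
            raise ValueError("Pearson coefficients must lie in [-1, 1]")
        if not self.subject_ids:
            self.subject_ids = [f"sub{i:04d}" for i in range(self.X.shape[0])]

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_edges(self) -> int:
        return self.X.shape[1]

    def to_frame(self, roi_names: list[str] | None = None) -> pd.DataFrame:
        cols = (
            self.edge_index.edge_names(roi_names)
            if roi_names is not None
            else [f"e{e}" for e in range(self.n_edges)]
        )
        frame = pd.DataFrame(self.X, columns=cols)
        frame.insert(0, "label", self.labels)
        frame.insert(0, "subject_id", self.subject_ids)
        return frame

    def write(self, path: str | Path, roi_names: list[str] | None = None) -> None:
        """Write the dataset as TSV plus a companion edge-convention JSON."""
        path = Path(path)
        self.to_frame(roi_names).to_csv(path, sep="\t", index=False)
        path.with_suffix(".json").write_text(json.dumps(self.edge_index.to_dict(), indent=1))

    @classmethod
    def read(cls, path: str | Path) -> "FCDataset":
        frame = pd.read_csv(path, sep="\t")
        X = frame.iloc[:, 2:].to_numpy(dtype=float)
        n_edges = X.shape[1]
        n_rois = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
        return cls(
            X=X,
            labels=frame["label"].to_numpy(),
            edge_index=EdgeIndex(n_rois),
            subject_ids=frame["subject_id"].astype(str).tolist(),
        )


def normalize_and_slice(
    panel: TimeSeriesPanel, target_length: int | str = "min"
) -> TimeSeriesPanel:
    """Z-score every ROI series and truncate all subjects to a uniform length.

    Each ROI series is standardised to mean 0, sd 1 (over its own time points)
    and then truncated to the first ``target_length`` samples; ``"min"`` uses
    the shortest series in the panel.  Standardisation makes the features
    invariant to per-site affine distortions of the signal.  A constant
    (zero-variance) series cannot be standardised and maps to all zeros with a
    logged warning; its edges get correlation 0 downstream.
    """
    if target_length == "min":
        length = panel.min_length
    else:
        length = int(target_length)
    if length < MIN_SERIES_LENGTH:
        raise ValueError(
            f"target_length {length} < {MIN_SERIES_LENGTH}: too short for stable correlations"
        )
    if length > panel.min_length:
        raise ValueError(
            f"target_length {length} exceeds shortest series ({panel.min_length})"
        )
    out = []
    for sid, mat in zip(panel.subject_ids, panel.series):
        sliced = np.asarray(mat, dtype=float)[:, :length]
        mean = sliced.mean(axis=1, keepdims=True)
        sd = sliced.std(axis=1, keepdims=True)
        # exact constancy, not sd == 0: a constant series has sd ~ 1e-16
        flat = (sliced.max(axis=1) - sliced.min(axis=1)) == 0
        if flat.any():
            logger.warning(
                "subject %s: %d constant ROI series mapped to zeros (ROIs %s)",
                sid, int(flat.sum()), np.flatnonzero(flat).tolist(),
            )
            warnings.warn(
                f"subject {sid}: constant ROI series mapped to zeros", stacklevel=2
            )
        sd[flat[:, None]] = 1.0
        z = (sliced - mean) / sd
        z[flat] = 0.0
        out.append(z)
    return TimeSeriesPanel(
        subject_ids=list(panel.subject_ids),
        labels=panel.labels.copy(),
        series=out,
        sites=None if panel.sites is None else np.asarray(panel.sites).copy(),
    )


def compute_fc(panel: TimeSeriesPanel) -> FCDataset:
    """Pearson-correlate every ROI pair of every subject.

    Requires a uniform-length panel (run :func:`normalize_and_slice` first).
    Entry ``(s, e)`` is the sample Pearson correlation of the two ROI series
    of subject ``s`` for edge ``e``; only the strict upper triangle is kept.
    Zero-variance series produce r = 0 (flagged), never NaN.
    """
    lengths = {m.shape[1] for m in panel.series}
    if len(lengths) > 1:
        raise ValueError("panel must be sliced to uniform length before compute_fc")
    index = EdgeIndex(panel.n_rois)
    iu = np.triu_indices(panel.n_rois, k=1)
    X = np.empty((panel.n_subjects, index.n_edges))
    degenerate: set[int] = set()
    for s, mat in enumerate(panel.series):
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(mat)
        bad = ~np.isfinite(corr)
        if bad.any():
            corr[bad] = 0.0
            flat_rois = np.flatnonzero(np.asarray(mat).std(axis=1) == 0)
            for i in flat_rois:
                for j in range(panel.n_rois):
                    if i != j:
                        degenerate.add(index.rois_to_edge(min(i, j), max(i, j)))
            logger.warning(
                "subject %s: zero-variance ROI(s) %s, affected correlations set to 0",
                panel.subject_ids[s], flat_rois.tolist(),
            )
        X[s] = np.clip(corr[iu], -1.0, 1.0)
    return FCDataset(
        X=X,
        labels=panel.labels.copy(),
        edge_index=index,
        subject_ids=list(panel.subject_ids),
        degenerate_edges=np.array(sorted(degenerate), dtype=int) if degenerate else None,
    )


def write_panel(panel: TimeSeriesPanel, outdir: str | Path) -> None:
    """Write one delimited matrix per subject plus a subjects TSV."""
    outdir = Path(outdir)
    ts_dir = outdir / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    for sid, mat in zip(panel.subject_ids, panel.series):
        np.savetxt(ts_dir / f"{sid}.tsv", mat, delimiter="\t", fmt="%.6g")
    meta = pd.DataFrame({
        "subject_id": panel.subject_ids,
        "group": panel.labels,
        "site": panel.sites if panel.sites is not None else 0,
    })
    meta.to_csv(outdir / "subjects.tsv", sep="\t", index=False)


def read_panel(indir: str | Path) -> TimeSeriesPanel:
    """Read a panel written by :func:`write_panel` (or hand-prepared likewise)."""
    indir = Path(indir)
    meta_path = indir / "subjects.tsv"
    if not meta_path.exists():
        raise FileNotFoundError(f"no subjects.tsv under {indir}")
    meta = pd.read_csv(meta_path, sep="\t")
    series, ids = [], []
    for sid in meta["subject_id"].astype(str):
        mat_path = indir / "timeseries" / f"{sid}.tsv"
        if not mat_path.exists():
            raise FileNotFoundError(f"missing time-series matrix for subject {sid}")
        series.append(np.atleast_2d(np.loadtxt(mat_path, delimiter="\t")))
        ids.append(sid)
    sites = meta["site"].to_numpy() if "site" in meta else None
    return TimeSeriesPanel(
        subject_ids=ids, labels=meta["group"].to_numpy(), series=series, sites=sites
    )
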