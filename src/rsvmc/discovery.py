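"""Discriminative-edge and pathogenic-region identification.

After screening, members whose validation accuracy exceeds a stricter
threshold (default 0.75) are the *superior* classifiers.  The appearance
frequency of each connectivity edge across superior members measures how
often the edge was available to a high-accuracy classifier; the k most
frequent edges are the *optimal features*, and each region's weight is the
number of optimal edges incident to it.  The highest-weight regions are
nominated as candidate pathogenic regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import EdgeIndex
from .ensemble import ClusterMember, RandomSVMClusterResults

__all__ = [
    "FeatureFrequencyTable",
    "ROIWeightTable",
    "superior_members",
    "feature_frequencies",
    "top_features",
    "roi_weights",
    "rank_regions",
    "export_connectome",
    "read_connectome",
]


@dataclass
class FeatureFrequencyTable:
    """Per-edge appearance counts across superior members."""

    counts: np.ndarray
    n_superior: int
    threshold: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts > self.n_superior).any():
            raise ValueError("edge count cannot exceed the number of superior members")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self, edge_index: EdgeIndex, roi_names: list[str] | None = None) -> pd.DataFrame:
        pairs = edge_index.pairs
        frame = pd.DataFrame({
            "edge": np.arange(len(self.counts)),
            "roi_a": pairs[:, 0],
            "roi_b": pairs[:, 1],
            "count": self.counts,
        })
        if roi_names is not None:
            names = list(roi_names)
            frame["roi_a_name"] = [names[i] for i in pairs[:, 0]]
            frame["roi_b_name"] = [names[j] for j in pairs[:, 1]]
        return frame


@dataclass
class ROIWeightTable:
    """Per-region weight = number of optimal edges touching the region."""

    weights: np.ndarray
    roi_names: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=int)
        if len(self.weights) != len(self.roi_names):
            raise ValueError("one weight per ROI name required")

    def to_frame(self) -> pd.DataFrame:
        order = np.lexsort((np.arange(len(self.weights)), -self.weights))
        return pd.DataFrame({
            "roi": order,
            "name": [self.roi_names[i] for i in order],
            "weight": self.weights[order],
            "rank": np.arange(1, len(order) + 1),
        })


def superior_members(
    results: RandomSVMClusterResults | list[ClusterMember], threshold: float = 0.75
) -> list[ClusterMember]:
    """Members with validation accuracy strictly greater than ``threshold``,
    sorted by accuracy descending (ties by member index for stability)."""
    members = results.members if isinstance(results, RandomSVMClusterResults) else results
    for m in members:
        if m.validation_accuracy is None:
            raise RuntimeError("cluster must be screened before selecting superior members")
    chosen = [m for m in members if m.validation_accuracy > threshold]
    if not chosen:
        raise RuntimeError(
            f"no member exceeds accuracy {threshold}; reduce the superior threshold"
        )
    return sorted(chosen, key=lambda m: (-m.validation_accuracy, m.index))


def feature_frequencies(
    members: list[ClusterMember], n_edges: int, threshold: float = 0.75
) -> FeatureFrequencyTable:
    """Count, for every edge, the superior members whose feature subset
    contains it.  Total count is exactly (#members) * d."""
    counts = np.zeros(n_edges, dtype=int)
    for m in members:
        counts[m.feature_indices] += 1
    return FeatureFrequencyTable(counts=counts, n_superior=len(members), threshold=threshold)


def top_features(table: FeatureFrequencyTable, k: int = 148) -> np.ndarray:
    """The k most frequent edges (flat indices).

    Boundary ties are broken by ascending edge index, so the output is
    bit-stable.  If fewer than k edges have nonzero counts, all nonzero-count
    edges are returned with a warning.
    """
    counts = table.counts
    if k > len(counts):
        raise ValueError(f"k={k} exceeds the number of edges ({len(counts)})")
    nonzero = int((counts > 0).sum())
    if nonzero < k:
        warnings.warn(
            f"only {nonzero} edges have nonzero frequency (< k={k}); returning those",
            stacklevel=2,
        )
        k = nonzero
    order = np.lexsort((np.arange(len(counts)), -counts))
    return np.sort(order[:k])


def roi_weights(
    optimal_edges: np.ndarray, edge_index: EdgeIndex, roi_names: list[str] | pd.Series
) -> ROIWeightTable:
    """Weight every region by its incidence in the optimal edge set.

    Each optimal edge increments both endpoint regions by 1, so weights sum
    to 2k exactly.
    """
    optimal_edges = np.asarray(optimal_edges, dtype=int)
    if len(optimal_edges) == 0:
        raise ValueError("optimal edge set is empty")
    weights = np.zeros(edge_index.n_rois, dtype=int)
    for e in optimal_edges:
        i, j = edge_index.edge_to_rois(int(e))
        weights[i] += 1
        weights[j] += 1
    return ROIWeightTable(weights=weights, roi_names=list(roi_names))


def rank_regions(table: ROIWeightTable, top_k: int | None = None) -> pd.DataFrame:
    """Regions ranked by weight descending (ties by ROI index)."""
    frame = table.to_frame()
    return frame.head(top_k) if top_k is not None else frame


def export_connectome(
    table: FeatureFrequencyTable,
    edge_index: EdgeIndex,
    roi_names: list[str] | pd.Series,
    path: str | Path,
    top_n: int = 20,
) -> pd.DataFrame:
    """Write the top-n most frequent edges as a viewer-friendly edge list.

    Output TSV has edge rows (roi_a, roi_b names plus frequency) followed by
    ``#node`` rows carrying per-region weights restricted to the exported
    edges (node sizes for connectome viewers).
    """
    if top_n > len(table.counts):
        raise ValueError(f"top_n={top_n} exceeds the number of edges")
    names = list(roi_names)
    order = np.lexsort((np.arange(len(table.counts)), -table.counts))
    chosen = np.sort(order[:top_n])
    node_w = roi_weights(chosen, edge_index, names)
    path = Path(path)
    with path.open("w") as fh:
        fh.write("roi_a\troi_b\tfrequency\n")
        for e in chosen:
            i, j = edge_index.edge_to_rois(int(e))
            fh.write(f"{names[i]}\t{names[j]}\t{table.counts[e]}\n")
        for r in np.flatnonzero(node_w.weights):
            fh.write(f"#node\t{names[r]}\t{node_w.weights[r]}\n")
    return read_connectome(path)


def read_connectome(path: str | Path) -> pd.DataFrame:
    """Read an edge list written by :func:`export_connectome` (edge rows
    only; node rows are exposed via the ``attrs['nodes']`` dict)."""
    edges, nodes = [], {}
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "#node":
                nodes[parts[1]] = int(parts[2])
            else:
                edges.append((parts[0], parts[1], int(parts[2])))
    frame = pd.DataFrame(edges, columns=header)
    frame.attrs["nodes"] = nodes
    return frame
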