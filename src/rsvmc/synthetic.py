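"""Synthetic two-group ROI time-series cohorts with planted connectivity effects.

The generator emulates the input of the analysis pipeline — a resting-state
cohort of patients and controls, each subject a matrix of per-region BOLD-like
time courses — with a known set of ROI pairs whose Pearson correlation differs
between the groups.  Ground truth (which edges and regions carry signal) is
returned alongside, so classification accuracy and region recovery can be
scored exactly.

Construction: for a planted edge (i, j) with target correlation r the two
series share a latent factor ``s``::

    x_i = sqrt(1 - a^2) * eps_i + a * s,     a = sqrt(|r|)
    x_j = sqrt(1 - a^2) * eps_j + sign(r) * a * s

with ``s``, ``eps`` independent unit-variance white noise, so the population
correlation of (x_i, x_j) is exactly ``a^2 = r`` (with the stated sign).
Planted edges must be vertex-disjoint, which keeps every non-planted pair at
population correlation 0 and keeps the construction exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import EdgeIndex, TimeSeriesPanel, write_panel

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_cohort",
    "generate_metadata",
    "write_cohort",
    "COHORT_REFERENCE_DISTRIBUTIONS",
]

# Group summary statistics (mean, sd) of the emulated ABIDE-I-like cohort:
# patients n=479, controls n=478.
COHORT_REFERENCE_DISTRIBUTIONS: dict[str, dict[int, tuple[float, float]]] = {
    "age": {1: (16.70, 8.23), 0: (17.20, 8.06)},
    "FIQ": {1: (105.21, 16.56), 0: (111.20, 12.80)},
    "PIQ": {1: (104.89, 17.06), 0: (108.61, 13.31)},
    "VIQ": {1: (103.25, 18.05), 0: (110.37, 13.50)},
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a planted-effect cohort.

    Parameters
    ----------
    n_per_group : subjects per label (group 1 = patient, group 0 = control).
    n_rois : regions per subject (default 90, the cerebral AAL count).
    n_timepoints : samples per ROI series (>= 10).
    planted_edges : ROI index pairs (i < j), vertex-disjoint, carrying the
        group-differential correlation.
    r_base, r_alt : target Pearson correlation on planted edges in group 0
        and group 1 respectively, each in (-1, 1).
    background_noise_sd : sd of the white-noise component (scales every
        series uniformly; correlations are unaffected).
    n_sites : number of acquisition sites; subjects are assigned round-robin.
    site_mean_shift, site_scale : site m transforms every series x to
        ``site_scale**m * x + site_mean_shift * m`` (site 0 is untouched).
        Affine, so population correlations are site-invariant by design.
    seed : master seed; fixes every generated byte.
    """

    n_per_group: int
    n_rois: int = 90
    n_timepoints: int = 150
    planted_edges: tuple[tuple[int, int], ...] = ()
    r_base: float = 0.1
    r_alt: float = 0.5
    background_noise_sd: float = 1.0
    n_sites: int = 1
    site_mean_shift: float = 0.0
    site_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted_edges",
                           tuple((int(i), int(j)) for i, j in self.planted_edges))
        if self.n_per_group <= 0:
            raise ValueError(f"n_per_group must be positive, got {self.n_per_group}")
        if self.n_rois < 2:
            raise ValueError(f"n_rois must be >= 2, got {self.n_rois}")
        if self.n_timepoints < 10:
            raise ValueError(f"n_timepoints must be >= 10, got {self.n_timepoints}")
        for name in ("r_base", "r_alt"):
            r = getattr(self, name)
            if not abs(r) < 1.0:
                raise ValueError(f"{name} must satisfy |r| < 1, got {r}")
        if self.background_noise_sd <= 0:
            raise ValueError(
                f"background_noise_sd must be positive, got {self.background_noise_sd}"
            )
        if self.n_sites < 1:
            raise ValueError(f"n_sites must be >= 1, got {self.n_sites}")
        seen: set[int] = set()
        for i, j in self.planted_edges:
            if not (0 <= i < j < self.n_rois):
                raise ValueError(f"planted_edges: invalid pair ({i}, {j}) for {self.n_rois} ROIs")
            if i in seen or j in seen:
                raise ValueError(
                    f"planted_edges must be vertex-disjoint; ROI reused in ({i}, {j})"
                )
            seen.update((i, j))

    @property
    def n_subjects(self) -> int:
        return 2 * self.n_per_group


@dataclass
class GroundTruth:
    """What was planted: edges (flat and pairwise), ROIs, per-group targets."""

    edge_pairs: tuple[tuple[int, int], ...]
    edge_flat: np.ndarray
    rois: np.ndarray
    r_by_group: dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "edge_pairs": [list(p) for p in self.edge_pairs],
            "edge_flat": self.edge_flat.tolist(),
            "rois": self.rois.tolist(),
            "r_by_group": {str(k): v for k, v in self.r_by_group.items()},
        }


def _planted_pair(rng: np.random.Generator, r: float, T: int) -> tuple[np.ndarray, np.ndarray]:
    a = np.sqrt(abs(r))
    b = np.sqrt(1.0 - a * a)
    s = rng.standard_normal(T)
    x = b * rng.standard_normal(T) + a * s
    y = b * rng.standard_normal(T) + np.sign(r) * a * s if r != 0 else rng.standard_normal(T)
    return x, y


def generate_cohort(spec: SyntheticSpec) -> tuple[TimeSeriesPanel, GroundTruth]:
    """Draw the cohort described by ``spec``.

    Subjects are ordered patients first (label 1), then controls (label 0);
    sites cycle round-robin within each group.  Reproducible: the output is a
    pure function of ``spec`` (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    R, T = spec.n_rois, spec.n_timepoints
    planted_rois = {roi for pair in spec.planted_edges for roi in pair}
    series: list[np.ndarray] = []
    labels: list[int] = []
    sites: list[int] = []
    ids: list[str] = []
    k = 0
    for group, r_target in ((1, spec.r_alt), (0, spec.r_base)):
        for _ in range(spec.n_per_group):
            mat = np.empty((R, T))
            free = [roi for roi in range(R) if roi not in planted_rois]
            if free:
                mat[free] = rng.standard_normal((len(free), T))
            for i, j in spec.planted_edges:
                mat[i], mat[j] = _planted_pair(rng, r_target, T)
            mat *= spec.background_noise_sd
            site = k % spec.n_sites
            if site > 0:
                mat = spec.site_scale**site * mat + spec.site_mean_shift * site
            series.append(mat)
            labels.append(group)
            sites.append(site)
            ids.append(f"sub{k:04d}")
            k += 1
    index = EdgeIndex(R)
    flat = np.array([index.rois_to_edge(i, j) for i, j in spec.planted_edges], dtype=int)
    truth = GroundTruth(
        edge_pairs=spec.planted_edges,
        edge_flat=flat,
        rois=np.array(sorted(planted_rois), dtype=int),
        r_by_group={0: spec.r_base, 1: spec.r_alt},
    )
    panel = TimeSeriesPanel(
        subject_ids=ids, labels=np.array(labels), series=series, sites=np.array(sites)
    )
    return panel, truth


def generate_metadata(
    spec: SyntheticSpec,
    seed: int | None = None,
    distributions: dict[str, dict[int, tuple[float, float]]] | None = None,
) -> pd.DataFrame:
    """Draw a demographics table (age, FIQ, PIQ, VIQ) for the cohort.

    Each variable is normal per group with configurable (mean, sd); defaults
    mimic the published ABIDE-I cohort summaries.  Independent of the time
    series — demographics are descriptive, never features.
    """
    dists = distributions if distributions is not None else COHORT_REFERENCE_DISTRIBUTIONS
    for var, per_group in dists.items():
        for g in (0, 1):
            if g not in per_group:
                raise ValueError(f"distributions[{var!r}] missing group {g}")
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    labels = np.concatenate(
        [np.ones(spec.n_per_group, dtype=int), np.zeros(spec.n_per_group, dtype=int)]
    )
    table = pd.DataFrame({
        "subject_id": [f"sub{k:04d}" for k in range(spec.n_subjects)],
        "group": labels,
        "site": np.arange(spec.n_subjects) % spec.n_sites,
    })
    for var, per_group in dists.items():
        vals = np.empty(spec.n_subjects)
        for g in (0, 1):
            mean, sd = per_group[g]
            mask = labels == g
            vals[mask] = rng.normal(mean, sd, mask.sum())
        table[var] = vals
    return table


def write_cohort(
    spec: SyntheticSpec, outdir: str | Path, metadata: bool = True
) -> tuple[TimeSeriesPanel, GroundTruth]:
    """Generate and write a cohort: per-subject matrices, subjects TSV with
    demographics, and a ground-truth JSON."""
    outdir = Path(outdir)
    panel, truth = generate_cohort(spec)
    write_panel(panel, outdir)
    if metadata:
        meta = generate_metadata(spec)
        meta.to_csv(outdir / "subjects.tsv", sep="\t", index=False)
    (outdir / "ground_truth.json").write_text(json.dumps(truth.to_dict(), indent=1))
    return panel, truth
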