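"""Parameter sweeps for the random SVM cluster.

Two hyperparameters dominate the ensemble's behaviour: the initial member
count n and the per-member sub-feature dimensionality d.  They are tuned
sequentially — n first (accuracy rises with n and then plateaus; the smallest
n at which the curve stabilises is chosen), then d with n fixed (d is chosen
by accuracy argmax).  Both selection rules are pure functions of the accuracy
curve, so they are unit-testable on hand-built curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import FCDataset
from .ensemble import DatasetSplit, RandomSVMCluster

__all__ = [
    "SweepResult",
    "select_stable",
    "select_argmax",
    "sweep_n",
    "sweep_d",
    "default_n_grid",
    "default_d_grid",
    "plot_sweep",
]


def default_n_grid() -> np.ndarray:
    """Member-count grid 5..600 in steps of 5."""
    return np.arange(5, 601, 5)


def default_d_grid(n_edges: int = 4005) -> np.ndarray:
    """Dimensionality grid 70..300 in steps of 2 (70 is the conventional
    ~sqrt(E) starting point for E = 4005); for smaller feature spaces the
    start falls back to round(sqrt(E)) and the end is clipped to E."""
    start = 70 if n_edges >= 4005 else max(2, int(round(np.sqrt(n_edges))))
    return np.arange(start, min(300, n_edges) + 1, 2)


@dataclass
class SweepResult:
    """Accuracy curve over a hyperparameter grid plus the selected value."""

    parameter: str
    grid: np.ndarray
    mean_accuracy: np.ndarray
    sd_accuracy: np.ndarray
    selected: int
    rule: str
    repeats: int = 1
    accuracies: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.selected not in self.grid:
            raise ValueError("selected value must be on the grid")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            self.parameter: self.grid,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "selected": (self.grid == self.selected).astype(int),
        })

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def select_stable(
    grid: np.ndarray, accuracy: np.ndarray, window: int = 5, tol: float = 0.02
) -> tuple[int, bool]:
    """Smallest grid value from which a trailing window of ``window``
    accuracies has range < ``tol``.

    Formalises "accuracy started to be stable": the curve is declared stable
    at the first grid point where the next ``window`` values (inclusive) vary
    by less than ``tol``.  Returns (selected value, found flag); when no
    window qualifies the grid maximum is returned with ``found=False`` and a
    warning.
    """
    grid = np.asarray(grid)
    accuracy = np.asarray(accuracy, dtype=float)
    if len(grid) != len(accuracy):
        raise ValueError("grid and accuracy must have equal length")
    if not (np.diff(grid) > 0).all():
        raise ValueError("grid must be strictly ascending")
    for start in range(len(grid) - window + 1):
        seg = accuracy[start : start + window]
        if seg.max() - seg.min() < tol:
            return int(grid[start]), True
    warnings.warn(
        f"no stable window (w={window}, tol={tol}) found; returning grid max",
        stacklevel=2,
    )
    return int(grid[-1]), False


def select_argmax(grid: np.ndarray, accuracy: np.ndarray) -> int:
    """Grid value with the highest accuracy; ties go to the smaller value
    (cheaper model, deterministic)."""
    grid = np.asarray(grid)
    accuracy = np.asarray(accuracy, dtype=float)
    if len(grid) != len(accuracy):
        raise ValueError("grid and accuracy must have equal length")
    return int(grid[np.argmax(accuracy)])


def _accuracy_at(
    fc: FCDataset,
    split: DatasetSplit,
    n: int,
    d: int,
    repeats: int,
    seed: int,
    **model_kwargs,
) -> np.ndarray:
    accs = np.empty(repeats)
    for r in range(repeats):
        # distinct deterministic stream per (grid point, repeat)
        member_seed = int(
            np.random.SeedSequence((seed, n, d, r)).generate_state(1)[0] % (2**31)
        )
        model = RandomSVMCluster(
            fc, split=split, n_members=n, n_features=d, seed=member_seed, **model_kwargs
        )
        accs[r] = model.fit().evaluate("test").accuracy
    return accs


def sweep_n(
    fc: FCDataset,
    split: DatasetSplit,
    d: int,
    grid: np.ndarray | None = None,
    repeats: int = 5,
    seed: int = 0,
    window: int = 5,
    tol: float = 0.02,
    **model_kwargs,
) -> SweepResult:
    """Sweep the member count n at fixed d and select by the stability rule.

    The split is shared across grid points so the curves are comparable;
    repeats re-randomise only member construction.
    """
    grid = default_n_grid() if grid is None else np.asarray(grid)
    all_accs = np.stack([_accuracy_at(fc, split, int(n), d, repeats, seed, **model_kwargs)
                         for n in grid])
    mean = all_accs.mean(axis=1)
    selected, _ = select_stable(grid, mean, window=window, tol=tol)
    return SweepResult(
        parameter="n", grid=grid, mean_accuracy=mean, sd_accuracy=all_accs.std(axis=1),
        selected=selected, rule=f"stability(w={window}, tol={tol})",
        repeats=repeats, accuracies=all_accs,
    )


def sweep_d(
    fc: FCDataset,
    split: DatasetSplit,
    n: int,
    grid: np.ndarray | None = None,
    repeats: int = 5,
    seed: int = 0,
    **model_kwargs,
) -> SweepResult:
    """Sweep the sub-feature dimensionality d at fixed n; select by argmax."""
    grid = default_d_grid(fc.n_edges) if grid is None else np.asarray(grid)
    if grid.min() < 1 or grid.max() > fc.n_edges:
        raise ValueError(f"d grid must lie within [1, {fc.n_edges}]")
    all_accs = np.stack([_accuracy_at(fc, split, n, int(d), repeats, seed, **model_kwargs)
                         for d in grid])
    mean = all_accs.mean(axis=1)
    return SweepResult(
        parameter="d", grid=grid, mean_accuracy=mean, sd_accuracy=all_accs.std(axis=1),
        selected=select_argmax(grid, mean), rule="argmax(ties->smaller)",
        repeats=repeats, accuracies=all_accs,
    )


def plot_sweep(result: SweepResult, path: str | Path) -> None:
    """Accuracy-vs-parameter curve with the selected point marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.errorbar(result.grid, result.mean_accuracy, yerr=result.sd_accuracy,
                fmt="-o", ms=3, lw=1, capsize=2)
    sel_idx = int(np.flatnonzero(result.grid == result.selected)[0])
    ax.axvline(result.selected, color="crimson", ls="--", lw=1,
               label=f"selected {result.parameter}={result.selected} "
                     f"(acc {result.mean_accuracy[sel_idx]:.3f})")
    ax.set_xlabel(result.parameter)
    ax.set_ylabel("test accuracy")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
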