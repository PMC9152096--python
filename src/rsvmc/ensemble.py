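"""Random SVM cluster: random-subspace / random-sample SVM ensemble.

The model: draw ``n`` members, each a binary SVM trained on ``M`` subjects
randomly drawn from the training set and ``d`` features randomly drawn
(without replacement) from the E = R(R-1)/2 connectivity edges.  Members are
screened on a held-out validation set — any member whose validation accuracy
falls strictly below 0.5 (worse than guessing) is deleted — and the surviving
k members classify test subjects by unweighted majority vote.

Organisation follows the model/results idiom: :class:`RandomSVMCluster` holds
data and configuration; :meth:`RandomSVMCluster.fit` trains and screens the
members and returns a :class:`RandomSVMClusterResults` carrying the members,
their diagnostics, prediction/evaluation methods and a ``summary()`` table.

Determinism: member m's randomness comes from a dedicated stream spawned from
``SeedSequence((seed, m))``, so results are reproducible and independent of
execution order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .connectivity import FCDataset

__all__ = [
    "DatasetSplit",
    "ClusterMember",
    "RandomSVMCluster",
    "RandomSVMClusterResults",
    "ClassificationReport",
    "split_dataset",
    "largest_remainder",
    "save_cluster",
    "load_cluster",
]


def largest_remainder(total: int, ratios: np.ndarray) -> np.ndarray:
    """Apportion ``total`` units over bins proportional to ``ratios``.

    Floor the ideal shares, then hand the leftover units to the bins with the
    largest fractional parts (ties broken toward earlier bins).
    """
    ratios = np.asarray(ratios, dtype=float)
    ideal = total * ratios / ratios.sum()
    alloc = np.floor(ideal).astype(int)
    frac = ideal - alloc
    order = np.lexsort((np.arange(len(ratios)), -frac))
    for b in order[: total - alloc.sum()]:
        alloc[b] += 1
    return alloc


@dataclass
class DatasetSplit:
    """Stratified train / validation / test partition of subject indices."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    ratios: tuple[float, float, float] = (4, 1, 5)
    seed: int = 0

    def __post_init__(self) -> None:
        sets = [np.asarray(s, dtype=int) for s in (self.train, self.validation, self.test)]
        self.train, self.validation, self.test = sets
        union = np.concatenate(sets)
        if len(np.unique(union)) != len(union):
            raise ValueError("split sets must be disjoint")

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.train), len(self.validation), len(self.test)

    def to_dict(self) -> dict:
        return {
            "train": self.train.tolist(),
            "validation": self.validation.tolist(),
            "test": self.test.tolist(),
            "ratios": list(self.ratios),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DatasetSplit":
        return cls(
            train=np.array(d["train"]), validation=np.array(d["validation"]),
            test=np.array(d["test"]), ratios=tuple(d["ratios"]), seed=d["seed"],
        )


def split_dataset(
    fc: FCDataset,
    ratios: tuple[float, float, float] = (4, 1, 5),
    seed: int = 0,
) -> DatasetSplit:
    """Split subjects into train/validation/test at the given ratios,
    stratified by class.

    Set totals come from largest-remainder apportionment of all subjects;
    per-class counts are then apportioned the same way, constrained to those
    totals, so each set preserves the patient/control proportion to within
    one subject per class.
    """
    ratios_arr = np.asarray(ratios, dtype=float)
    if len(ratios_arr) != 3 or (ratios_arr <= 0).any():
        raise ValueError(f"need three positive ratios, got {ratios}")
    labels = fc.labels
    classes = np.unique(labels)
    if len(classes) != 2 or min(np.bincount(labels)) < 2:
        raise ValueError("need at least 2 subjects in each of two classes")
    n = len(labels)
    totals = largest_remainder(n, ratios_arr)

    # per-class floors, then leftover units by largest fractional part subject
    # to per-class and per-set totals
    alloc: dict[int, np.ndarray] = {}
    frac_entries = []
    for c in classes:
        n_c = int((labels == c).sum())
        ideal = n_c * ratios_arr / ratios_arr.sum()
        alloc[c] = np.floor(ideal).astype(int)
        for s in range(3):
            frac_entries.append((ideal[s] - alloc[c][s], s, c))
    deficit = totals - sum(alloc[c] for c in classes)
    remaining = {c: int((labels == c).sum()) - int(alloc[c].sum()) for c in classes}
    frac_entries.sort(key=lambda t: (-t[0], t[1], t[2]))
    for _, s, c in frac_entries:
        if remaining[c] > 0 and deficit[s] > 0:
            alloc[c][s] += 1
            remaining[c] -= 1
            deficit[s] -= 1

    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    for c in classes:
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        start = 0
        for s in range(3):
            parts[s].extend(idx[start : start + alloc[c][s]])
            start += alloc[c][s]
    return DatasetSplit(
        train=np.sort(parts[0]), validation=np.sort(parts[1]), test=np.sort(parts[2]),
        ratios=tuple(ratios), seed=seed,
    )


@dataclass
class ClusterMember:
    """One randomized SVM: its subjects, its features, its fitted classifier."""

    index: int
    sample_indices: np.ndarray  # positions within the training set
    feature_indices: np.ndarray  # flat edge indices, sorted
    classifier: SVC | None = None
    validation_accuracy: float | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.classifier is None:
            raise RuntimeError(f"member {self.index} is not trained")
        return self.classifier.predict(X[:, self.feature_indices])


class RandomSVMCluster:
    """Random SVM cluster model over a connectivity dataset.

    Parameters
    ----------
    fc : FCDataset
        Subjects x edges Pearson-correlation features with binary labels.
    split : DatasetSplit, optional
        Train/validation/test partition; default is a fresh stratified 4:1:5
        split seeded from ``seed``.
    n_members : int
        Initial ensemble size n (default 360).
    n_features : int
        Sub-feature dimensionality d per member (default 148; clipped error
        if > E).
    n_samples : int, optional
        Subjects M drawn per member from the training set.  Default
        ``ceil(0.8 * |train|)`` without replacement.
    bootstrap : bool
        Draw the M subjects with replacement (bagging-style) instead.
    kernel, C : base-learner configuration (sklearn SVC); linear by default —
        correlation features are near-linear problems and a linear kernel
        keeps the feature-frequency interpretation clean.
    screen_threshold : float
        Validation accuracy strictly below this deletes a member (default 0.5).
    seed : int
        Master seed; member m uses ``SeedSequence((seed, m))``.
    """

    MAX_RESAMPLE = 100

    def __init__(
        self,
        fc: FCDataset,
        split: DatasetSplit | None = None,
        n_members: int = 360,
        n_features: int = 148,
        n_samples: int | None = None,
        bootstrap: bool = False,
        kernel: str = "linear",
        C: float = 1.0,
        screen_threshold: float = 0.5,
        seed: int = 0,
    ):
        self.fc = fc
        self.split = split if split is not None else split_dataset(fc, seed=seed)
        E = fc.n_edges
        if not 1 <= n_features <= E:
            raise ValueError(f"n_features must be in [1, {E}], got {n_features}")
        n_train = len(self.split.train)
        if n_samples is None:
            n_samples = int(np.ceil(0.8 * n_train))
        if not 2 <= n_samples <= n_train:
            raise ValueError(f"n_samples must be in [2, {n_train}], got {n_samples}")
        if n_members < 1:
            raise ValueError(f"n_members must be >= 1, got {n_members}")
        self.n_members = int(n_members)
        self.n_features = int(n_features)
        self.n_samples = int(n_samples)
        self.bootstrap = bool(bootstrap)
        self.kernel = kernel
        self.C = float(C)
        self.screen_threshold = float(screen_threshold)
        self.seed = int(seed)

    @classmethod
    def from_panel(cls, panel, target_length: int | str = "min", **kwargs) -> "RandomSVMCluster":
        """Build the model straight from a time-series panel (normalise,
        slice, correlate, then construct)."""
        from .connectivity import compute_fc, normalize_and_slice

        return cls(compute_fc(normalize_and_slice(panel, target_length)), **kwargs)

    def _make_member(self, m: int) -> ClusterMember:
        rng = np.random.default_rng(np.random.SeedSequence((self.seed, m)))
        y_train = self.fc.labels[self.split.train]
        n_train = len(self.split.train)
        for _ in range(self.MAX_RESAMPLE):
            samples = rng.choice(n_train, size=self.n_samples, replace=self.bootstrap)
            if len(np.unique(y_train[samples])) == 2:
                break
        else:
            raise RuntimeError(
                f"member {m}: could not draw a two-class subsample in "
                f"{self.MAX_RESAMPLE} tries (M={self.n_samples})"
            )
        features = np.sort(rng.choice(self.fc.n_edges, size=self.n_features, replace=False))
        return ClusterMember(index=m, sample_indices=np.sort(samples), feature_indices=features)

    def _train_member(self, member: ClusterMember) -> None:
        rows = self.split.train[member.sample_indices]
        X = self.fc.X[np.ix_(rows, member.feature_indices)]
        y = self.fc.labels[rows]
        member.classifier = SVC(kernel=self.kernel, C=self.C)
        member.classifier.fit(X, y)

    def fit(self, screen: bool = True) -> "RandomSVMClusterResults":
        """Train all n members and screen them on the validation set."""
        members = []
        for m in range(self.n_members):
            member = self._make_member(m)
            self._train_member(member)
            members.append(member)
        results = RandomSVMClusterResults(model=self, members=members)
        if screen:
            results.screen()
        return results


@dataclass
class ClassificationReport:
    """Accuracy / precision / recall with the patient class as positive."""

    accuracy: float
    precision: float
    recall: float
    n: int
    no_positive_predictions: bool = False

    def __str__(self) -> str:
        flag = "  [no positive predictions: precision reported as 0]" if self.no_positive_predictions else ""
        return (
            f"accuracy={self.accuracy:.4f} precision={self.precision:.4f} "
            f"recall={self.recall:.4f} (n={self.n}){flag}"
        )


class RandomSVMClusterResults:
    """Fitted random SVM cluster: members, screening diagnostics, voting."""

    def __init__(self, model: RandomSVMCluster, members: list[ClusterMember]):
        self.model = model
        self.members = members
        self.n_initial = len(members)
        self._screened = False

    # -- screening ---------------------------------------------------------

    def screen(self) -> "RandomSVMClusterResults":
        """Score every member on the validation set and delete those with
        accuracy strictly below the screening threshold."""
        if self._screened:
            raise RuntimeError("cluster already screened")
        fc, split = self.model.fc, self.model.split
        X_val = fc.X[split.validation]
        y_val = fc.labels[split.validation]
        for member in self.members:
            member.validation_accuracy = float(
                (member.predict(X_val) == y_val).mean()
            )
        kept = [
            m for m in self.members
            if m.validation_accuracy >= self.model.screen_threshold
        ]
        if not kept:
            raise RuntimeError(
                "screening removed every member; increase n_members or check "
                "that the data carry signal"
            )
        self.members = kept
        self._screened = True
        return self

    @property
    def k(self) -> int:
        """Post-screening member count."""
        return len(self.members)

    @property
    def validation_accuracies(self) -> np.ndarray:
        return np.array([m.validation_accuracy for m in self.members], dtype=float)

    # -- voting ------------------------------------------------------------

    def vote_fractions(self, X: np.ndarray) -> np.ndarray:
        """Fraction of members voting 'patient' for each sample — the
        ensemble's score in [0, 1], usable for P-R analysis."""
        if not self.members:
            raise RuntimeError("empty cluster")
        votes = np.zeros(X.shape[0])
        for member in self.members:
            votes += member.predict(X)
        return votes / len(self.members)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Majority-vote labels: patient iff vote fraction > 0.5; an exact
        tie (fraction = 0.5) is broken toward the patient label."""
        if not self.members:
            raise RuntimeError("empty cluster")
        votes = np.zeros(X.shape[0], dtype=int)
        for member in self.members:
            votes += member.predict(X)
        return (2 * votes >= len(self.members)).astype(int)

    def evaluate(self, subset: str = "test") -> ClassificationReport:
        """Accuracy, precision and recall on a split subset
        ('train' | 'validation' | 'test')."""
        split = self.model.split
        try:
            rows = getattr(split, subset)
        except AttributeError:
            raise ValueError(f"unknown subset {subset!r}") from None
        if len(rows) == 0:
            raise ValueError(f"subset {subset!r} is empty")
        y = self.model.fc.labels[rows]
        yhat = self.predict(self.model.fc.X[rows])
        return classification_report(y, yhat)

    # -- discovery hooks (thin delegates; see rsvmc.discovery) -------------

    def superior_members(self, threshold: float = 0.75) -> list[ClusterMember]:
        from .discovery import superior_members

        return superior_members(self, threshold=threshold)

    def feature_frequencies(self, threshold: float = 0.75):
        from .discovery import feature_frequencies, superior_members

        return feature_frequencies(
            superior_members(self, threshold=threshold),
            n_edges=self.model.fc.n_edges,
            threshold=threshold,
        )

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table of the fitted cluster."""
        model = self.model
        acc = self.validation_accuracies
        lines = [
            "Random SVM Cluster Results",
            "=" * 54,
            f"{'Members (initial n)':<32}{self.n_initial:>22}",
            f"{'Members kept (k)':<32}{self.k:>22}",
            f"{'Sub-feature dim (d)':<32}{model.n_features:>22}",
            f"{'Samples per member (M)':<32}{model.n_samples:>22}",
            f"{'Base learner':<32}{f'SVC({model.kernel}, C={model.C:g})':>22}",
            f"{'Screening threshold':<32}{model.screen_threshold:>22}",
            f"{'Split sizes (S1/S2/S3)':<32}{'/'.join(map(str, model.split.sizes)):>22}",
            f"{'Seed':<32}{model.seed:>22}",
        ]
        if self._screened and self.k:
            lines += [
                "-" * 54,
                f"{'Validation accuracy (mean)':<32}{acc.mean():>22.4f}",
                f"{'Validation accuracy (min/max)':<32}"
                f"{f'{acc.min():.3f} / {acc.max():.3f}':>22}",
            ]
            test = self.evaluate("test")
            lines += [
                f"{'Test accuracy':<32}{test.accuracy:>22.4f}",
                f"{'Test precision / recall':<32}"
                f"{f'{test.precision:.3f} / {test.recall:.3f}':>22}",
            ]
        lines.append("=" * 54)
        return "\n".join(lines)


def classification_report(y_true: np.ndarray, y_pred: np.ndarray) -> ClassificationReport:
    """Accuracy / precision / recall with patient (1) as the positive class.

    With no positive predictions precision is undefined; it is reported as 0
    with a flag rather than NaN.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(((y_pred == 1) & (y_true == 1)).sum())
    fp = int(((y_pred == 1) & (y_true == 0)).sum())
    fn = int(((y_pred == 0) & (y_true == 1)).sum())
    no_pos = (tp + fp) == 0
    if no_pos:
        warnings.warn("no positive predictions; precision reported as 0", stacklevel=2)
    return ClassificationReport(
        accuracy=float((y_pred == y_true).mean()),
        precision=0.0 if no_pos else tp / (tp + fp),
        recall=0.0 if (tp + fn) == 0 else tp / (tp + fn),
        n=len(y_true),
        no_positive_predictions=no_pos,
    )


def save_cluster(results: RandomSVMClusterResults, outdir: str | Path) -> None:
    """Serialize a fitted cluster as plain text: a manifest JSON plus
    per-member index arrays and validation accuracies.

    Members are retrainable from the recorded indices and configuration, so
    no binary model files are written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = results.model
    manifest = {
        "n_members": model.n_members,
        "k": results.k,
        "n_features": model.n_features,
        "n_samples": model.n_samples,
        "bootstrap": model.bootstrap,
        "kernel": model.kernel,
        "C": model.C,
        "screen_threshold": model.screen_threshold,
        "seed": model.seed,
        "split": model.split.to_dict(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    rows = [
        {
            "member": m.index,
            "validation_accuracy": m.validation_accuracy,
            "sample_indices": " ".join(map(str, m.sample_indices)),
            "feature_indices": " ".join(map(str, m.feature_indices)),
        }
        for m in results.members
    ]
    pd.DataFrame(rows).to_csv(outdir / "members.tsv", sep="\t", index=False)


def load_cluster(indir: str | Path, fc: FCDataset) -> RandomSVMClusterResults:
    """Rebuild a saved cluster against its dataset, retraining members from
    the recorded sample/feature indices."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    model = RandomSVMCluster(
        fc,
        split=DatasetSplit.from_dict(manifest["split"]),
        n_members=manifest["n_members"],
        n_features=manifest["n_features"],
        n_samples=manifest["n_samples"],
        bootstrap=manifest["bootstrap"],
        kernel=manifest["kernel"],
        C=manifest["C"],
        screen_threshold=manifest["screen_threshold"],
        seed=manifest["seed"],
    )
    table = pd.read_csv(indir / "members.tsv", sep="\t")
    members = []
    for _, row in table.iterrows():
        member = ClusterMember(
            index=int(row["member"]),
            sample_indices=np.fromstring(str(row["sample_indices"]), sep=" ", dtype=int),
            feature_indices=np.fromstring(str(row["feature_indices"]), sep=" ", dtype=int),
            validation_accuracy=float(row["validation_accuracy"]),
        )
        model._train_member(member)
        members.append(member)
    results = RandomSVMClusterResults(model=model, members=members)
    results._screened = True
    return results
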