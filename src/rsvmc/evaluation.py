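"""Benchmark harness, precision-recall curves and cohort statistics.

Compares the random SVM cluster against standard single learners (KNN, naive
Bayes, a feedforward neural network, a single SVM) and a random forest over
repeated random splits, with every method seeing identical splits within a
repeat so comparisons are paired.  Also provides the threshold-sweep P-R
curve used to compare scored classifiers, and the demographics summary tests
(Welch t from raw values or printed group summaries; chi-square on binned
age) used for cohort description tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .connectivity import FCDataset
from .ensemble import RandomSVMCluster, split_dataset

__all__ = [
    "BenchmarkResult",
    "REGISTERED_METHODS",
    "run_baselines",
    "pr_curve",
    "cohort_summary_tests",
]

# method name -> factory(seed) for the single-model baselines; the feedforward
# net ("mlp") stands in for product/backpropagation neural networks
REGISTERED_METHODS = ("knn", "bayes", "mlp", "svm", "rf", "rsvmc")


def _make_baseline(name: str, seed: int):
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "bayes":
        return GaussianNB()
    if name == "mlp":
        return MLPClassifier(hidden_layer_sizes=(32,), max_iter=300, random_state=seed)
    if name == "svm":
        return SVC(kernel="linear", C=1.0)
    if name == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise KeyError(name)


@dataclass
class BenchmarkResult:
    """Accuracy distribution (and pooled P-R scores) for one method."""

    method: str
    accuracies: np.ndarray
    scores: np.ndarray | None = None  # pooled test-set scores across repeats
    score_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if ((self.accuracies < 0) | (self.accuracies > 1)).any():
            raise ValueError("accuracies must lie in [0, 1]")

    def pr_curve(self) -> pd.DataFrame:
        if self.scores is None:
            raise ValueError(f"{self.method}: no scores recorded")
        return pr_curve(self.scores, self.score_labels)


def _scores(clf, X: np.ndarray) -> np.ndarray:
    if hasattr(clf, "decision_function"):
        return clf.decision_function(X)
    return clf.predict_proba(X)[:, 1]


def run_baselines(
    fc: FCDataset,
    methods: tuple[str, ...] = REGISTERED_METHODS,
    repeats: int = 50,
    ratios: tuple[float, float, float] = (4, 1, 5),
    seed: int = 0,
    cluster_kwargs: dict | None = None,
) -> list[BenchmarkResult]:
    """Repeatedly re-split the data and score every method on the test set.

    Each repeat draws a fresh stratified split shared by all methods (paired
    comparison).  Single-model baselines train on the training set; the
    random SVM cluster additionally uses the validation set for screening.
    Scores (decision function, positive-class probability, or vote fraction)
    are pooled across repeats for P-R curves.
    """
    unknown = [m for m in methods if m not in REGISTERED_METHODS]
    if unknown:
        raise ValueError(
            f"unknown method(s) {unknown}; registered: {list(REGISTERED_METHODS)}"
        )
    cluster_kwargs = dict(cluster_kwargs or {})
    acc: dict[str, list[float]] = {m: [] for m in methods}
    scores: dict[str, list[np.ndarray]] = {m: [] for m in methods}
    score_labels: list[np.ndarray] = []
    for rep in range(repeats):
        rep_seed = int(np.random.SeedSequence((seed, rep)).generate_state(1)[0] % (2**31))
        split = split_dataset(fc, ratios=ratios, seed=rep_seed)
        X_tr, y_tr = fc.X[split.train], fc.labels[split.train]
        X_te, y_te = fc.X[split.test], fc.labels[split.test]
        score_labels.append(y_te)
        for m in methods:
            if m == "rsvmc":
                results = RandomSVMCluster(
                    fc, split=split, seed=rep_seed, **cluster_kwargs
                ).fit()
                acc[m].append(float((results.predict(X_te) == y_te).mean()))
                scores[m].append(results.vote_fractions(X_te))
            else:
                clf = _make_baseline(m, rep_seed)
                clf.fit(X_tr, y_tr)
                acc[m].append(float((clf.predict(X_te) == y_te).mean()))
                scores[m].append(_scores(clf, X_te))
    pooled_labels = np.concatenate(score_labels)
    return [
        BenchmarkResult(
            method=m,
            accuracies=np.array(acc[m]),
            scores=np.concatenate(scores[m]),
            score_labels=pooled_labels,
        )
        for m in methods
    ]


def pr_curve(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Precision-recall curve by sweeping the decision threshold over every
    unique score value (predict positive at score >= threshold).

    Returns a DataFrame with columns threshold, precision, recall, sorted by
    recall ascending.  Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if len(np.unique(labels)) < 2:
        raise ValueError("P-R curve needs both classes in labels")
    n_pos = int((labels == 1).sum())
    # thresholds below the lowest positive score only add false positives at
    # recall already 1; the curve stops at the full-recall point
    thresholds = np.unique(scores)
    thresholds = thresholds[thresholds >= scores[labels == 1].min()]
    rows = []
    for thr in thresholds:
        pred = scores >= thr
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        precision = tp / (tp + fp) if tp + fp else 1.0
        rows.append((thr, precision, tp / n_pos))
    frame = pd.DataFrame(rows, columns=["threshold", "precision", "recall"])
    return frame.sort_values(["recall", "threshold"], ascending=[True, False]).reset_index(
        drop=True
    )


def _welch_from_stats(m1, s1, n1, m2, s2, n2) -> tuple[float, float]:
    t, p = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
    return float(t), float(p)


def cohort_summary_tests(
    data: pd.DataFrame | dict,
    group_col: str = "group",
    variables: list[str] | None = None,
    age_col: str = "age",
    age_bins: np.ndarray | None = None,
) -> pd.DataFrame:
    """Demographics comparison table: Welch t-tests per continuous variable
    plus a chi-square test on binned age.

    ``data`` is either a per-subject DataFrame with a binary ``group`` column,
    or a dict of printed group summaries
    ``{var: {group: (mean, sd, n)}}`` (age gets a t-test only in summary
    form, since binning needs raw values).  Output rows carry the
    "mean ± standard deviation" presentation per group, the statistic and the
    two-sided p-value.
    """
    rows = []
    if isinstance(data, dict):
        for var, per_group in data.items():
            try:
                m1, s1, n1 = per_group[1]
                m0, s0, n0 = per_group[0]
            except KeyError as err:
                raise ValueError(f"summaries for {var!r} must cover groups 0 and 1") from err
            if n1 < 2 or n0 < 2:
                raise ValueError(f"{var}: need n >= 2 per group")
            t, p = _welch_from_stats(m1, s1, n1, m0, s0, n0)
            rows.append({
                "variable": var,
                "patients": f"{m1:.2f} ± {s1:.2f}",
                "controls": f"{m0:.2f} ± {s0:.2f}",
                "test": "welch_t",
                "statistic": t,
                "p_value": p,
            })
        return pd.DataFrame(rows)

    if group_col not in data:
        raise ValueError(f"missing group column {group_col!r}")
    g1 = data[data[group_col] == 1]
    g0 = data[data[group_col] == 0]
    if len(g1) < 2 or len(g0) < 2:
        raise ValueError("need n >= 2 per group")
    if variables is None:
        variables = [
            c for c in data.columns
            if c not in (group_col, "subject_id", "site") and pd.api.types.is_numeric_dtype(data[c])
        ]
    for var in variables:
        x1, x0 = g1[var].to_numpy(float), g0[var].to_numpy(float)
        if var == age_col:
            bins = age_bins if age_bins is not None else np.arange(0, 91, 10)
            both = np.concatenate([x1, x0])
            edges = np.unique(np.clip(bins, both.min(), both.max() + 1e-9))
            c1, _ = np.histogram(x1, bins=edges)
            c0, _ = np.histogram(x0, bins=edges)
            contingency = np.vstack([c1, c0])
            keep = contingency.sum(axis=0) > 0
            chi2, p, _, _ = stats.chi2_contingency(contingency[:, keep])
            test, statistic = "chi_square", float(chi2)
        else:
            t, p = stats.ttest_ind(x1, x0, equal_var=False)
            test, statistic = "welch_t", float(t)
        rows.append({
            "variable": var,
            "patients": f"{x1.mean():.2f} ± {x1.std(ddof=1):.2f}",
            "controls": f"{x0.mean():.2f} ± {x0.std(ddof=1):.2f}",
            "test": test,
            "statistic": statistic,
            "p_value": float(p),
        })
    return pd.DataFrame(rows)
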