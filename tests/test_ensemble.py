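"""Splitting, cluster construction, screening, voting and evaluation."""

from types import SimpleNamespace

import numpy as np
import pytest
from sklearn.metrics import confusion_matrix
from sklearn.svm import SVC

from rsvmc import (
    ClusterMember,
    DatasetSplit,
    EdgeIndex,
    FCDataset,
    RandomSVMCluster,
    RandomSVMClusterResults,
    split_dataset,
)
from rsvmc.ensemble import classification_report, largest_remainder, load_cluster, save_cluster

from conftest import StubClassifier


def flat_fc(n_patients, n_controls, n_rois=3, rng=None):
    """Featureless dataset for split arithmetic tests."""
    rng = rng or np.random.default_rng(0)
    n = n_patients + n_controls
    E = n_rois * (n_rois - 1) // 2
    return FCDataset(
        X=rng.uniform(-1, 1, (n, E)),
        labels=np.array([1] * n_patients + [0] * n_controls),
        edge_index=EdgeIndex(n_rois),
    )


class TestSplit:
    def test_ten_subjects_split_4_1_5(self):
        split = split_dataset(flat_fc(5, 5), seed=0)
        assert split.sizes == (4, 1, 5)

    def test_cohort_scale_largest_remainder(self):
        """479/478 subjects at 4:1:5 allocate to 383/96/478 with per-class
        balance within one subject (verified by enumerating the allocation
        arithmetic)."""
        fc = flat_fc(479, 478)
        split = split_dataset(fc, seed=3)
        assert split.sizes == (383, 96, 478)
        for part, size in zip((split.train, split.validation, split.test), split.sizes):
            n_pat = int(fc.labels[part].sum())
            # class share within one subject of the overall 479/957 proportion
            assert abs(n_pat - size * 479 / 957) <= 1

    def test_partition_is_exhaustive_and_disjoint(self):
        fc = flat_fc(13, 17)
        split = split_dataset(fc, seed=1)
        union = np.concatenate([split.train, split.validation, split.test])
        assert sorted(union) == list(range(30))

    def test_seed_controls_the_permutation_not_the_sizes(self):
        fc = flat_fc(20, 20)
        a = split_dataset(fc, seed=5)
        b = split_dataset(fc, seed=5)
        c = split_dataset(fc, seed=6)
        np.testing.assert_array_equal(a.train, b.train)
        assert a.sizes == c.sizes
        assert not np.array_equal(a.train, c.train)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError, match="positive ratios"):
            split_dataset(flat_fc(5, 5), ratios=(4, -1, 5))
        with pytest.raises(ValueError, match="at least 2 subjects"):
            split_dataset(flat_fc(1, 9))

    def test_largest_remainder_apportionment(self):
        np.testing.assert_array_equal(largest_remainder(10, np.array([4, 1, 5])), [4, 1, 5])
        np.testing.assert_array_equal(largest_remainder(957, np.array([4, 1, 5])), [383, 96, 478])
        assert largest_remainder(7, np.array([1, 1, 1])).sum() == 7


class TestClusterConstruction:
    def test_members_have_distinct_sorted_features(self, fitted_cluster):
        for m in fitted_cluster.members:
            assert len(np.unique(m.feature_indices)) == len(m.feature_indices)
            assert (np.diff(m.feature_indices) > 0).all()

    def test_member_streams_differ(self, signal_fc):
        """Two members under one seed share a feature set only with
        vanishing probability for d << E."""
        fc, _ = signal_fc
        model = RandomSVMCluster(fc, n_members=100, n_features=10, seed=0)
        featsets = {tuple(model._make_member(m).feature_indices) for m in range(100)}
        assert len(featsets) == 100

    def test_refit_is_deterministic(self, signal_fc):
        fc, _ = signal_fc
        kwargs = dict(n_members=10, n_features=15, seed=3)
        split = split_dataset(fc, seed=1)
        r1 = RandomSVMCluster(fc, split=split, **kwargs).fit()
        r2 = RandomSVMCluster(fc, split=split, **kwargs).fit()
        X = fc.X[split.test]
        np.testing.assert_array_equal(r1.predict(X), r2.predict(X))
        np.testing.assert_array_equal(r1.validation_accuracies, r2.validation_accuracies)

    def test_degenerate_cluster_equals_single_svm(self, signal_fc):
        """n=1, d=E, M=|S1| collapses to one SVM on the whole training set."""
        fc, _ = signal_fc
        split = split_dataset(fc, seed=2)
        results = RandomSVMCluster(
            fc, split=split, n_members=1, n_features=fc.n_edges,
            n_samples=len(split.train), seed=0,
        ).fit()
        single = SVC(kernel="linear", C=1.0)
        single.fit(fc.X[split.train], fc.labels[split.train])
        X_test = fc.X[split.test]
        np.testing.assert_array_equal(results.predict(X_test), single.predict(X_test))

    def test_single_class_training_subset_rejected(self, signal_fc):
        fc, _ = signal_fc
        controls = np.flatnonzero(fc.labels == 0)
        split = DatasetSplit(train=controls[:10], validation=controls[10:14],
                             test=np.flatnonzero(fc.labels == 1))
        model = RandomSVMCluster(fc, split=split, n_members=2, n_features=5, seed=0)
        with pytest.raises(RuntimeError, match="member 0"):
            model.fit()

    @pytest.mark.parametrize(
        "kwargs", [{"n_features": 0}, {"n_features": 10**6}, {"n_samples": 1}, {"n_members": 0}]
    )
    def test_bad_hyperparameters_rejected(self, signal_fc, kwargs):
        fc, _ = signal_fc
        with pytest.raises(ValueError):
            RandomSVMCluster(fc, **kwargs)


def stub_results(member_outputs, val_accs=None):
    members = [
        ClusterMember(
            index=i,
            sample_indices=np.arange(2),
            feature_indices=np.arange(3),
            classifier=StubClassifier(out),
            validation_accuracy=None if val_accs is None else val_accs[i],
        )
        for i, out in enumerate(member_outputs)
    ]
    return RandomSVMClusterResults(model=SimpleNamespace(), members=members)


class TestVoting:
    def test_majority_of_three(self):
        res = stub_results([[1], [1], [0]])
        assert res.predict(np.zeros((1, 3))) == [1]

    def test_unanimous_members(self):
        for label in (0, 1):
            res = stub_results([[label]] * 5)
            assert res.predict(np.zeros((1, 3))) == [label]
            assert res.vote_fractions(np.zeros((1, 3)))[0] == float(label)

    def test_exact_tie_breaks_toward_patient(self):
        res = stub_results([[1], [0]])
        assert res.vote_fractions(np.zeros((1, 3)))[0] == 0.5
        assert res.predict(np.zeros((1, 3))) == [1]

    def test_matches_brute_force_tally(self):
        """predict == explicit per-sample vote count for k <= 5 members on
        20 samples, over many random member outputs."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            k = rng.integers(1, 6)
            outputs = rng.integers(0, 2, (k, 20))
            res = stub_results(list(outputs))
            X = np.zeros((20, 3))
            expected = np.array(
                [1 if 2 * outputs[:, s].sum() >= k else 0 for s in range(20)]
            )
            np.testing.assert_array_equal(res.predict(X), expected)
            np.testing.assert_allclose(
                res.vote_fractions(X), outputs.mean(axis=0), atol=1e-12
            )

    def test_empty_cluster_rejected(self):
        res = stub_results([[1]])
        res.members = []
        with pytest.raises(RuntimeError, match="empty"):
            res.predict(np.zeros((1, 3)))


class TestScreening:
    def test_screening_never_increases_and_survivors_pass(self, fitted_cluster):
        assert fitted_cluster.k <= fitted_cluster.n_initial
        assert (fitted_cluster.validation_accuracies >= 0.5).all()

    def test_boundary_member_at_exactly_half_is_kept(self, null_fc):
        """A member at exactly the threshold is not 'lower than' it."""
        split = split_dataset(null_fc, seed=0)
        results = RandomSVMCluster(
            null_fc, split=split, n_members=60, n_features=20, seed=1
        ).fit()
        accs = results.validation_accuracies
        assert (accs >= 0.5).all()
        # on no-signal data members at exactly 0.5 exist and survive
        assert (accs == 0.5).any()

    def test_null_data_removes_a_nontrivial_fraction(self):
        """Under the null a clear fraction of members scores strictly below
        chance and is deleted.  (The fraction sits well under 1/2 because
        near-constant predictors put point mass at exactly 0.5 on a balanced
        validation set, and the deletion rule is strict.)"""
        from rsvmc import SyntheticSpec

        from conftest import cohort_fc

        fc, _ = cohort_fc(SyntheticSpec(
            n_per_group=50, n_rois=20, n_timepoints=100,
            planted_edges=((0, 1),), r_base=0.3, r_alt=0.3, seed=11,
        ))
        removed = []
        for seed in range(5):
            split = split_dataset(fc, seed=seed)
            res = RandomSVMCluster(
                fc, split=split, n_members=60, n_features=20, seed=seed
            ).fit(screen=False)
            res.screen()
            removed.append(1 - res.k / res.n_initial)
        assert 0.05 < np.mean(removed) < 0.6

    def test_all_members_removed_raises(self):
        """Validation labels inverted relative to a separable training signal
        force every member below 0.5."""
        rng = np.random.default_rng(0)
        n = 30
        labels = np.array([1, 0] * (n // 2))
        X = rng.uniform(-0.1, 0.1, (n, 3))
        X[:20, 0] = labels[:20] * 2 - 1.0  # train rows: feature follows label
        X[20:, 0] = -(labels[20:] * 2 - 1.0)  # validation rows: inverted
        fc = FCDataset(X=X, labels=labels, edge_index=EdgeIndex(3))
        split = DatasetSplit(train=np.arange(20), validation=np.arange(20, 30),
                             test=np.arange(0))
        model = RandomSVMCluster(fc, split=split, n_members=5, n_features=3, seed=0)
        with pytest.raises(RuntimeError, match="screening removed every member"):
            model.fit()

    def test_double_screen_rejected(self, fitted_cluster):
        with pytest.raises(RuntimeError, match="already screened"):
            fitted_cluster.screen()


class TestEvaluation:
    def test_perfect_predictions(self):
        rep = classification_report([1, 0, 1, 0], [1, 0, 1, 0])
        assert (rep.accuracy, rep.precision, rep.recall) == (1.0, 1.0, 1.0)

    def test_all_control_predictions_flagged(self):
        with pytest.warns(UserWarning, match="no positive predictions"):
            rep = classification_report([1, 0, 1], [0, 0, 0])
        assert rep.recall == 0.0
        assert rep.precision == 0.0
        assert rep.no_positive_predictions

    def test_matches_confusion_matrix_recomputation(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            y = rng.integers(0, 2, 40)
            yhat = rng.integers(0, 2, 40)
            rep = classification_report(y, yhat)
            tn, fp, fn, tp = confusion_matrix(y, yhat, labels=[0, 1]).ravel()
            assert rep.accuracy == pytest.approx((tp + tn) / 40)
            if tp + fp:
                assert rep.precision == pytest.approx(tp / (tp + fp))
            if tp + fn:
                assert rep.recall == pytest.approx(tp / (tp + fn))

    def test_cluster_beats_average_member(self, signal_spec):
        """Majority voting outscores the mean individual member on planted
        signal — a statistical property over >= 10 seeds."""
        from dataclasses import replace

        from conftest import cohort_fc

        deltas = []
        for seed in range(10):
            fc, _ = cohort_fc(replace(signal_spec, seed=100 + seed))
            split = split_dataset(fc, seed=seed)
            res = RandomSVMCluster(
                fc, split=split, n_members=25, n_features=10, seed=seed
            ).fit()
            X, y = fc.X[split.test], fc.labels[split.test]
            member_acc = np.mean([(m.predict(X) == y).mean() for m in res.members])
            deltas.append(res.evaluate("test").accuracy - member_acc)
        assert np.mean(deltas) >= 0


def test_save_load_round_trip(tmp_path, signal_fc, fitted_cluster):
    fc, _ = signal_fc
    save_cluster(fitted_cluster, tmp_path / "cluster")
    loaded = load_cluster(tmp_path / "cluster", fc)
    assert loaded.k == fitted_cluster.k
    X = fc.X[fitted_cluster.model.split.test]
    np.testing.assert_array_equal(loaded.predict(X), fitted_cluster.predict(X))
    np.testing.assert_allclose(
        loaded.validation_accuracies, fitted_cluster.validation_accuracies
    )


def test_summary_mentions_key_quantities(fitted_cluster):
    text = fitted_cluster.summary()
    assert "Members kept (k)" in text
    assert str(fitted_cluster.k) in text
    assert "Test accuracy" in text
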