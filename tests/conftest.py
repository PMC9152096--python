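import numpy as np
import pytest

from rsvmc import (
    RandomSVMCluster,
    SyntheticSpec,
    compute_fc,
    generate_cohort,
    normalize_and_slice,
    split_dataset,
)


def cohort_fc(spec: SyntheticSpec):
    """Generate a cohort and return its connectivity dataset + ground truth."""
    panel, truth = generate_cohort(spec)
    return compute_fc(normalize_and_slice(panel)), truth


@pytest.fixture(scope="session")
def signal_spec():
    """Small strong-effect cohort: 3 planted edges, 20 subjects per group."""
    return SyntheticSpec(
        n_per_group=20,
        n_rois=20,
        n_timepoints=100,
        planted_edges=((0, 1), (2, 3), (4, 5)),
        r_base=0.0,
        r_alt=0.7,
        seed=7,
    )


@pytest.fixture(scope="session")
def signal_fc(signal_spec):
    return cohort_fc(signal_spec)


@pytest.fixture(scope="session")
def null_fc():
    """No-signal cohort of the same shape (r_base = r_alt)."""
    spec = SyntheticSpec(
        n_per_group=20,
        n_rois=20,
        n_timepoints=100,
        planted_edges=((0, 1), (2, 3), (4, 5)),
        r_base=0.3,
        r_alt=0.3,
        seed=7,
    )
    return cohort_fc(spec)[0]


@pytest.fixture(scope="session")
def fitted_cluster(signal_fc):
    """A screened cluster on the strong-effect cohort."""
    fc, _ = signal_fc
    split = split_dataset(fc, seed=0)
    return RandomSVMCluster(
        fc, split=split, n_members=40, n_features=30, seed=0
    ).fit()


class StubClassifier:
    """Fixed-output classifier for voting/counting oracle tests."""

    def __init__(self, outputs: np.ndarray):
        self.outputs = np.asarray(outputs, dtype=int)

    def predict(self, X):
        return self.outputs[: X.shape[0]]
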